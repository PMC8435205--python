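"""Unordered (Fitch) parsimony on rooted trees with polytomies.

Three views of the same optimization problem for a single alignment column:

* :func:`fitch_downpass` — Hartigan-style preliminary state sets and the
  parsimony length (number of state transformations).
* :func:`mpr_state_sets` — per-node sets of states appearing in at least one
  most parsimonious reconstruction (MPR), from a min-cost dynamic program
  over the observed alphabet (down costs + up costs).
* :func:`enumerate_mprs` — every MPR as a full node→state labeling
  (terminals with ambiguous state sets are resolved as part of the MPR),
  generated by cost-guided backtracking, so only optimal labelings are
  visited.

Terminal state sets may be ambiguous (IUPAC subsets, '?' as the full
alphabet); the cost of an edge into a terminal is 0 iff the parent's state
lies in the terminal's set, matching the usual treatment of uncertainty.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import dendropy

from moonjelly.trees import AnnotatedTree

Column = dict[str, frozenset[str]]
INF = 10 ** 9


def _check_column(tree: AnnotatedTree, column: Column) -> None:
    for label in tree.leaf_labels():
        if label not in column:
            raise ValueError(f"terminal {label!r} missing from column")
        if not column[label]:
            raise ValueError(f"terminal {label!r} has an empty state set")


def fitch_downpass(tree: AnnotatedTree, column: Column) -> tuple[dict[int, frozenset[str]], int]:
    """Hartigan down-pass: preliminary state sets and parsimony length.

    At each internal node the preliminary set is the set of states occurring
    in the maximum number of child preliminary sets; the length increases by
    ``(number of children) - (that maximum)``.  For bifurcations this is
    exactly Fitch's intersection/union rule.  Returns ``(sets, length)``
    where ``sets`` is keyed by ``id(node)``.
    """
    _check_column(tree, column)
    prelim: dict[int, frozenset[str]] = {}
    length = 0
    for node in tree.postorder():
        if node.is_leaf():
            prelim[id(node)] = column[node.taxon.label]
            continue
        counts: dict[str, int] = {}
        children = node.child_nodes()
        for child in children:
            for s in prelim[id(child)]:
                counts[s] = counts.get(s, 0) + 1
        k = max(counts.values())
        prelim[id(node)] = frozenset(s for s, c in counts.items() if c == k)
        length += len(children) - k
    return prelim, length


# ---------------------------------------------------------------------------
# min-cost DP (Sankoff with unit costs) over the observed alphabet


@dataclass
class _DP:
    alphabet: list[str]
    down: dict[int, np.ndarray]      # D[v][s]: min cost of v's subtree with v = s
    up: dict[int, np.ndarray]        # U[v][s]: min cost of the rest of the tree with v = s
    length: int
    nodes: list[dendropy.Node]

    def state_index(self, s: str) -> int:
        return self.alphabet.index(s)


def _dp_tables(tree: AnnotatedTree, column: Column) -> _DP:
    _check_column(tree, column)
    alphabet = sorted({s for label in tree.leaf_labels() for s in column[label]})
    k = len(alphabet)
    idx = {s: i for i, s in enumerate(alphabet)}
    down: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf():
            d = np.full(k, INF, dtype=np.int64)
            for s in column[node.taxon.label]:
                d[idx[s]] = 0
            down[id(node)] = d
        else:
            d = np.zeros(k, dtype=np.int64)
            for child in node.child_nodes():
                dc = down[id(child)]
                # min over child state t of D[c][t] + [t != s]
                best = dc.min()
                d += np.minimum(dc, best + 1)
            down[id(node)] = d
    up: dict[int, np.ndarray] = {id(tree.root): np.zeros(k, dtype=np.int64)}
    for node in tree.preorder():
        if node.is_leaf():
            continue
        uv = up[id(node)]
        children = node.child_nodes()
        contribs = []
        for child in children:
            dc = down[id(child)]
            contribs.append(np.minimum(dc, dc.min() + 1))
        total = uv + sum(contribs)
        for child, contrib in zip(children, contribs):
            rest = total - contrib  # cost of everything except child's subtree, parent = s
            # U[c][t] = min_s rest[s] + [t != s]
            best = rest.min()
            up[id(child)] = np.minimum(rest, best + 1)
    length = int(down[id(tree.root)].min())
    return _DP(alphabet, down, up, length, tree.postorder())


def mpr_state_sets(tree: AnnotatedTree, column: Column) -> tuple[dict[int, frozenset[str]], int]:
    """States appearing in at least one MPR, per node, plus the length.

    A state *s* belongs to node *v*'s MPR set iff forcing ``v = s`` still
    admits a reconstruction of minimal total cost.  Keyed by ``id(node)``.
    """
    dp = _dp_tables(tree, column)
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        total = dp.down[id(node)] + dp.up[id(node)]
        sets[id(node)] = frozenset(
            s for i, s in enumerate(dp.alphabet) if total[i] == dp.length
        )
    return sets, dp.length


def enumerate_mprs(
    tree: AnnotatedTree,
    column: Column,
    max_nodes: int = 20,
    max_mprs: int = 200_000,
) -> list[dict[int, str]]:
    """All most parsimonious reconstructions as full node→state labelings.

    Labelings are keyed by ``id(node)`` and cover terminals too: a terminal
    with an ambiguous state set takes every optimal resolution.  Exhaustive
    enumeration is guarded by ``max_nodes`` (internal nodes); use
    :func:`mpr_state_sets` for larger trees.
    """
    if tree.n_internal() > max_nodes:
        raise ValueError(
            f"tree has {tree.n_internal()} internal nodes > max_nodes={max_nodes}; "
            "use mpr_state_sets (up-pass mode) instead"
        )
    dp = _dp_tables(tree, column)
    idx = {s: i for i, s in enumerate(dp.alphabet)}

    root = tree.root
    droot = dp.down[id(root)]
    root_states = [s for s in dp.alphabet if droot[idx[s]] == dp.length]

    def expand(node: dendropy.Node, state: str) -> list[dict[int, str]]:
        """All optimal labelings of node's subtree given node = state."""
        if node.is_leaf():
            return [{id(node): state}]
        per_child: list[list[dict[int, str]]] = []
        for child in node.child_nodes():
            dc = dp.down[id(child)]
            cost = np.minimum(dc, dc.min() + 1)[idx[state]]
            # optimal child states given the parent's state
            opts = []
            for t in dp.alphabet:
                if dc[idx[t]] + (t != state) == cost:
                    opts.append(t)
            sub = []
            for t in opts:
                sub.extend(expand(child, t))
            per_child.append(sub)
        out: list[dict[int, str]] = []
        for combo in itertools.product(*per_child):
            lab = {id(node): state}
            for part in combo:
                lab.update(part)
            out.append(lab)
            if len(out) > max_mprs:
                raise ValueError(f"more than {max_mprs} MPRs; raise max_mprs or use mpr_state_sets")
        return out

    mprs: list[dict[int, str]] = []
    for s in root_states:
        mprs.extend(expand(root, s))
    if len(mprs) > max_mprs:
        raise ValueError(f"more than {max_mprs} MPRs; raise max_mprs or use mpr_state_sets")
    return mprs


def labeling_cost(tree: AnnotatedTree, column: Column, labeling: dict[int, str]) -> int:
    """Number of state transformations implied by a full labeling."""
    cost = 0
    for node in tree.preorder():
        for child in node.child_nodes():
            cost += labeling[id(node)] != labeling[id(child)]
    return cost
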