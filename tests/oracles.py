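"""Independent brute-force oracles used to validate the package.

Everything here deliberately avoids the code paths it checks: parsimony by
exhaustive labeling enumeration, Gower/Mantel/p-distance by naive loops,
Welch by the closed-form formula, monophyly by a full bipartition scan.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from moonjelly.trees import AnnotatedTree


# ---------------------------------------------------------------------------
# parsimony


def brute_force_parsimony(tree: AnnotatedTree, column):
    """Exhaustive minimum over all internal-node labelings.

    Returns ``(length, mpr_sets, optimal)`` where ``mpr_sets`` maps
    ``id(internal node)`` to the states it takes in >=1 optimal labeling.
    Edge cost into a terminal is 0 iff the parent's state is in the
    terminal's state set.
    """
    internal = tree.internal_nodes()
    alphabet = sorted({s for lab in tree.leaf_labels() for s in column[lab]})
    k = len(alphabet)
    idx = {s: i for i, s in enumerate(alphabet)}
    pos = {id(n): i for i, n in enumerate(internal)}
    m = len(internal)
    if k ** m > 2_000_000:
        raise ValueError(f"oracle instance too large: {k}^{m}")
    labelings = np.array(list(itertools.product(range(k), repeat=m)), dtype=np.int8)
    cost = np.zeros(len(labelings), dtype=np.int32)
    for node in internal:
        col_n = labelings[:, pos[id(node)]]
        for child in node.child_nodes():
            if child.is_leaf():
                allowed = np.array([s in column[child.taxon.label] for s in alphabet])
                cost += ~allowed[col_n]
            else:
                cost += col_n != labelings[:, pos[id(child)]]
    length = int(cost.min())
    opt = labelings[cost == length]
    mpr_sets = {
        id(n): frozenset(alphabet[i] for i in np.unique(opt[:, pos[id(n)]]))
        for n in internal
    }
    return length, mpr_sets, opt


def random_newick(labels, rng, polytomy_prob: float = 0.25) -> str:
    """Random rooted topology over ``labels``; occasional polytomies."""
    labels = list(labels)

    def build(group):
        if len(group) == 1:
            return group[0]
        n_parts = 3 if (len(group) >= 3 and rng.random() < polytomy_prob) else 2
        perm = list(group)
        rng.shuffle(perm)
        cuts = sorted(rng.choice(range(1, len(perm)), size=n_parts - 1, replace=False))
        parts, prev = [], 0
        for c in list(cuts) + [len(perm)]:
            parts.append(perm[prev:c])
            prev = c
        return "(" + ",".join(build(p) for p in parts) + ")"

    return build(labels) + ";"


def random_column(labels, rng, n_states: int = 3, ambiguity_prob: float = 0.0):
    states = ["A", "C", "G", "T", "-"][:n_states]
    col = {}
    for lab in labels:
        if ambiguity_prob and rng.random() < ambiguity_prob:
            size = int(rng.integers(2, n_states + 1))
            chosen = rng.choice(n_states, size=size, replace=False)
            col[lab] = frozenset(states[i] for i in chosen)
        else:
            col[lab] = frozenset({states[int(rng.integers(n_states))]})
    return col


# ---------------------------------------------------------------------------
# distances and correlations


def gower_loop(values: np.ndarray) -> np.ndarray:
    """Per-pair loop Gower with per-feature range normalization and NaN
    missing cells (ranges are 1 for a min-max scaled matrix)."""
    n, p = values.shape
    ranges = []
    for f in range(p):
        col = values[:, f][~np.isnan(values[:, f])]
        r = col.max() - col.min() if col.size else 0.0
        ranges.append(r if r > 0 else 1.0)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            total, count = 0.0, 0
            for f in range(p):
                a, b = values[i, f], values[j, f]
                if np.isnan(a) or np.isnan(b):
                    continue
                total += abs(a - b) / ranges[f]
                count += 1
            out[i, j] = total / count if count else np.nan
    np.fill_diagonal(out, 0.0)
    return out


def p_distance_loop(a: str, b: str, gap_as_difference: bool = False) -> float:
    skip = {"?", "N"} if gap_as_difference else {"?", "N", "-"}
    num = den = 0
    for x, y in zip(a, b):
        if x in skip or y in skip:
            continue
        den += 1
        if x != y:
            num += 1
    return num / den


def mantel_r_loop(dx: np.ndarray, dy: np.ndarray) -> float:
    xs, ys = [], []
    n = dx.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            xs.append(dx[i, j])
            ys.append(dy[i, j])
    return float(stats.pearsonr(xs, ys)[0])


def welch_formula(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def monophyly_scan(tree: AnnotatedTree, terminals) -> bool:
    """Bipartition scan: some node's descendant leaf set equals ``terminals``."""
    target = frozenset(terminals)
    sets: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf():
            sets[id(node)] = frozenset({node.taxon.label})
        else:
            acc = frozenset()
            for child in node.child_nodes():
                acc |= sets[id(child)]
            sets[id(node)] = acc
    return any(s == target for s in sets.values())
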