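"""Rooted trees with per-node support annotations.

Wraps a :class:`dendropy.Tree`.  Internal-node Newick labels of the form
``"GB/bootstrap"`` (e.g. ``"5/98"``) carry Goodman–Bremer support and
bootstrap resampling frequency; either half may be absent (``"5"``,
``"/98"``).  The parse pattern is configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import dendropy

DEFAULT_SUPPORT_PATTERN = (
    r"^\s*(?P<gb>-?\d+(?:\.\d+)?)?\s*(?:/\s*(?P<boot>\d+(?:\.\d+)?))?\s*$"
)


@dataclass(frozen=True)
class NodeSupport:
    """Support pair at one internal node; either value may be None."""

    goodman_bremer: float | None = None
    bootstrap: float | None = None

    def __post_init__(self) -> None:
        if self.bootstrap is not None and not (0 <= self.bootstrap <= 100):
            raise ValueError(f"bootstrap frequency {self.bootstrap} outside [0, 100]")


class AnnotatedTree:
    """Rooted tree (polytomies allowed) with terminal labels and supports."""

    def __init__(self, tree: dendropy.Tree, support_pattern: str = DEFAULT_SUPPORT_PATTERN):
        tree.is_rooted = True
        self.tree = tree
        self._pattern = re.compile(support_pattern)
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate terminal labels: {dup}")
        self._supports: dict[int, NodeSupport] = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            label = node.label
            if label:
                m = self._pattern.match(label)
                if m and (m.group("gb") or m.group("boot")):
                    self._supports[id(node)] = NodeSupport(
                        goodman_bremer=float(m.group("gb")) if m.group("gb") else None,
                        bootstrap=float(m.group("boot")) if m.group("boot") else None,
                    )

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path, support_pattern: str = DEFAULT_SUPPORT_PATTERN,
                    path: bool | None = None) -> "AnnotatedTree":
        """Read a Newick tree; ``source`` is a path if it exists on disk or
        ends with ``.nwk``/``.tre``, else a Newick string."""
        src = str(source)
        is_path = path if path is not None else (
            Path(src).exists() or src.endswith((".nwk", ".tre", ".newick"))
        )
        kwargs = dict(
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
        if is_path:
            tree = dendropy.Tree.get(path=src, **kwargs)
        else:
            tree = dendropy.Tree.get(data=src, **kwargs)
        return cls(tree, support_pattern)

    def to_newick(self, path: str | Path | None = None) -> str:
        s = self.tree.as_string(schema="newick", unquoted_underscores=True).strip()
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    # -- structure ----------------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def leaves(self) -> list[dendropy.Node]:
        return list(self.tree.leaf_node_iter())

    def postorder(self) -> list[dendropy.Node]:
        return list(self.tree.postorder_node_iter())

    def preorder(self) -> list[dendropy.Node]:
        return list(self.tree.preorder_node_iter())

    def internal_nodes(self) -> list[dendropy.Node]:
        return [n for n in self.tree.preorder_node_iter() if not n.is_leaf()]

    def n_internal(self) -> int:
        return len(self.internal_nodes())

    def mrca(self, labels) -> dendropy.Node:
        labels = list(labels)
        unknown = set(labels) - set(self.leaf_labels())
        if unknown:
            raise ValueError(f"terminals not in tree: {sorted(unknown)}")
        if len(labels) == 1:
            (leaf,) = [lf for lf in self.tree.leaf_node_iter() if lf.taxon.label == labels[0]]
            return leaf
        return self.tree.mrca(taxon_labels=labels)

    def leaf_set(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def support(self, node: dendropy.Node) -> NodeSupport:
        return self._supports.get(id(node), NodeSupport())

    def set_support(self, node: dendropy.Node, gb: float | None, boot: float | None) -> None:
        self._supports[id(node)] = NodeSupport(gb, boot)
        parts = ["" if gb is None else f"{gb:g}", "" if boot is None else f"{boot:g}"]
        node.label = "/".join(parts).rstrip("/") if any(parts) else None

    def stem_length(self, node: dendropy.Node) -> float | None:
        return node.edge.length

    def reroot_on_outgroup(self, outgroup_label: str) -> "AnnotatedTree":
        """Reroot so the named terminal is the sister of everything else."""
        tree = self.tree.clone(depth=1)
        og = tree.find_node_with_taxon_label(outgroup_label)
        if og is None:
            raise ValueError(f"outgroup terminal {outgroup_label!r} not in tree")
        tree.to_outgroup_position(og, update_bipartitions=False)
        return AnnotatedTree(tree)
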