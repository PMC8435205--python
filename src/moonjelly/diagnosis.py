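"""Diagnostic molecular synapomorphies for species clades.

For every alignment column, the classifier asks whether a state
transformation on the focal clade's *stem* branch is part of the
most-parsimonious optimization, and with which derived state the clade's
crown node ends up.  Quantifying over all MPRs gives the four categories
used throughout the species diagnoses:

* ``ambiguous`` — the stem transformation is present only in some MPRs, or
  different MPRs disagree on the derived state (white in figure/table
  color codes);
* ``unique_nonhomoplastic`` — derived state found in no terminal outside
  the clade, arising exactly once and never lost, in every MPR (black);
* ``unique_homoplastic`` — unique outside-absence, but the state is lost
  (reversal) or re-gained somewhere in at least one MPR (red);
* ``nonunique_homoplastic`` — the derived state also occurs outside the
  clade (blue).

Alignment positions are reported 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from moonjelly.alignments import AlignmentSet
from moonjelly.parsimony import enumerate_mprs
from moonjelly.trees import AnnotatedTree

CATEGORIES = (
    "ambiguous",
    "unique_nonhomoplastic",
    "unique_homoplastic",
    "nonunique_homoplastic",
)

#: Category → color code used in published synapomorphy tables.
CATEGORY_COLORS = {
    "ambiguous": "white",
    "unique_nonhomoplastic": "black",
    "unique_homoplastic": "red",
    "nonunique_homoplastic": "blue",
}


@dataclass(frozen=True)
class DiagnosticCharacter:
    """One diagnostic alignment column for a focal clade."""

    position: int          # 0-based alignment column
    derived_state: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _origins_and_losses(tree: AnnotatedTree, labeling: dict[int, str], s: str) -> tuple[int, int]:
    """Count gains and losses of state ``s`` in one full MPR labeling.

    The root carrying ``s`` counts as one origin; a gain is any branch whose
    parent lacks ``s`` and whose child has it, a loss the reverse.
    """
    origins = int(labeling[id(tree.root)] == s)
    losses = 0
    for node in tree.preorder():
        ls = labeling[id(node)]
        for child in node.child_nodes():
            lc = labeling[id(child)]
            if ls != s and lc == s:
                origins += 1
            elif ls == s and lc != s:
                losses += 1
    return origins, losses


def classify_synapomorphies(
    tree: AnnotatedTree,
    aln: AlignmentSet,
    focal_clade: set[str] | frozenset[str],
    positions=None,
    max_nodes: int = 64,
    max_mprs: int = 200_000,
) -> list[DiagnosticCharacter]:
    """Diagnostic characters of a monophyletic focal clade.

    ``focal_clade`` is the set of terminal labels; it must be exactly the
    leaf set of its MRCA (callers handle the non-monophyletic case by
    flagging, see :func:`diagnose_all`).  A single terminal is allowed: its
    stem is its terminal branch.  Positions with no stem transformation in
    any MPR are not reported.
    """
    focal = frozenset(focal_clade)
    if not focal:
        raise ValueError("focal clade is empty")
    missing = focal - set(tree.leaf_labels())
    if missing:
        raise ValueError(f"focal terminals not in tree: {sorted(missing)}")
    mrca = tree.mrca(focal)
    if tree.leaf_set(mrca) != focal:
        raise ValueError("focal clade is not monophyletic on this tree")
    if mrca is tree.root:
        return []  # no stem branch to optimize a transformation onto
    parent = mrca.parent_node

    outside = set(tree.leaf_labels()) - focal
    out: list[DiagnosticCharacter] = []
    positions = range(aln.length) if positions is None else positions
    for pos in positions:
        column = aln.column(pos)
        tree_column = {t: column[t] for t in tree.leaf_labels() if t in column}
        if len(tree_column) != len(tree.leaf_labels()):
            absent = set(tree.leaf_labels()) - set(tree_column)
            raise ValueError(f"alignment does not cover terminals: {sorted(absent)}")
        # invariant columns can never show a transformation
        union = frozenset().union(*tree_column.values())
        if len(union) == 1:
            continue
        mprs = enumerate_mprs(tree, tree_column, max_nodes=max_nodes, max_mprs=max_mprs)
        derived: set[str] = set()
        stem_in_all = True
        for lab in mprs:
            if lab[id(parent)] != lab[id(mrca)]:
                derived.add(lab[id(mrca)])
            else:
                stem_in_all = False
        if not derived:
            continue
        if not stem_in_all or len(derived) > 1:
            for s in sorted(derived):
                out.append(DiagnosticCharacter(pos, s, "ambiguous"))
            continue
        (s,) = derived
        unique = all(s not in tree_column[t] for t in outside)
        homoplastic = False
        for lab in mprs:
            origins, losses = _origins_and_losses(tree, lab, s)
            if origins > 1 or losses >= 1:
                homoplastic = True
                break
        if unique:
            category = "unique_homoplastic" if homoplastic else "unique_nonhomoplastic"
        else:
            category = "nonunique_homoplastic"
        out.append(DiagnosticCharacter(pos, s, category))
    return out


# ---------------------------------------------------------------------------
# per species × marker report


@dataclass
class DiagnosticEntry:
    """Diagnosis of one species on one marker."""

    species: str
    marker: str
    status: str                       # ok | non_monophyletic | marker_absent | single_terminal_disabled
    characters: list[DiagnosticCharacter] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        c = {cat: 0 for cat in CATEGORIES}
        for ch in self.characters:
            c[ch.category] += 1
        return c

    @property
    def total(self) -> int:
        return len(self.characters)


@dataclass
class DiagnosticReport:
    """All (species × marker) diagnoses plus tabular exports."""

    entries: dict[tuple[str, str], DiagnosticEntry] = field(default_factory=dict)

    def entry(self, species: str, marker: str) -> DiagnosticEntry:
        return self.entries[(species, marker)]

    def counts_table(self) -> pd.DataFrame:
        """Per-category counts in the per-species × marker count format."""
        rows = []
        for (species, marker), e in self.entries.items():
            row = {"species": species, "marker": marker, "status": e.status}
            row.update({f"n_{cat}": n for cat, n in e.counts.items()})
            row["N"] = e.total
            rows.append(row)
        return pd.DataFrame(rows)

    def character_table(self) -> pd.DataFrame:
        """Long-format listing: species, marker, position (0-based), state, category."""
        rows = [
            {
                "species": species,
                "marker": marker,
                "position": ch.position,
                "state": ch.derived_state,
                "category": ch.category,
                "color": CATEGORY_COLORS[ch.category],
            }
            for (species, marker), e in self.entries.items()
            for ch in e.characters
        ]
        return pd.DataFrame(rows, columns=["species", "marker", "position", "state", "category", "color"])


def diagnose_all(
    trees: dict[str, AnnotatedTree],
    alns: dict[str, AlignmentSet],
    allow_single_terminal: bool = True,
    max_nodes: int = 64,
    max_mprs: int = 200_000,
) -> DiagnosticReport:
    """Diagnose every species on every marker.

    For each (species, marker): if the marker has no sequence for the
    species the entry is flagged ``marker_absent``; if the species is not
    monophyletic on the marker tree it is flagged ``non_monophyletic`` with
    no characters; otherwise :func:`classify_synapomorphies` runs on the
    species clade.  Single-terminal species are diagnosed against their
    terminal branch when ``allow_single_terminal`` (default), else flagged.
    """
    if set(trees) != set(alns):
        raise ValueError(f"marker sets differ: trees={sorted(trees)} alignments={sorted(alns)}")
    species: dict[str, None] = {}
    for aln in alns.values():
        for sp in aln.species():
            species.setdefault(sp, None)
    if not species:
        raise ValueError("no species mapped in any alignment")

    report = DiagnosticReport()
    for marker in alns:
        aln, tree = alns[marker], trees[marker]
        present = set(tree.leaf_labels())
        for sp in species:
            terminals = [t for t in aln.species_terminals(sp) if t in present]
            if not terminals or aln.length == 0:
                report.entries[(sp, marker)] = DiagnosticEntry(sp, marker, "marker_absent")
                continue
            if len(terminals) == 1 and not allow_single_terminal:
                report.entries[(sp, marker)] = DiagnosticEntry(sp, marker, "single_terminal_disabled")
                continue
            focal = frozenset(terminals)
            mrca = tree.mrca(focal)
            if tree.leaf_set(mrca) != focal:
                report.entries[(sp, marker)] = DiagnosticEntry(sp, marker, "non_monophyletic")
                continue
            chars = classify_synapomorphies(
                tree, aln, focal, max_nodes=max_nodes, max_mprs=max_mprs
            )
            report.entries[(sp, marker)] = DiagnosticEntry(sp, marker, "ok", chars)
    return report
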