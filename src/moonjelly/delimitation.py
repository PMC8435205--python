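"""Species-hypothesis screening on annotated phylogenies.

A species hypothesis attains *primary* status when, on at least one
single-marker tree, its terminals form a monophyletic clade whose MRCA has
Goodman–Bremer support ≥ 2 and bootstrap resampling frequency ≥ 75
(thresholds configurable).  Primary hypotheses are then re-evaluated on the
concatenated tree (*corroborated* / *rejected*), recording the stem branch
length for the ad-hoc differentiation assessment — no branch-length cutoff
is imposed.  Sequence-set bookkeeping (completeness and chimerism of the
concatenated terminals) lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from moonjelly.trees import AnnotatedTree

DEFAULT_GB_MIN = 2.0
DEFAULT_BOOT_MIN = 75.0


def check_monophyly(tree: AnnotatedTree, terminals) -> tuple[bool, dendropy.Node]:
    """True iff the MRCA's descendants are exactly ``terminals``; returns the MRCA."""
    terminals = frozenset(terminals)
    if not terminals:
        raise ValueError("empty terminal set")
    mrca = tree.mrca(terminals)  # raises on unknown terminals
    return tree.leaf_set(mrca) == terminals, mrca


@dataclass
class MarkerEvidence:
    """Evaluation of one species on one tree."""

    marker: str
    present: bool
    monophyletic: bool = False
    goodman_bremer: float | None = None
    bootstrap: float | None = None
    passes: bool = False
    stem_length: float | None = None
    conflicting_terminals: list[str] = field(default_factory=list)


@dataclass
class SpeciesHypothesis:
    """A candidate species: terminal set plus per-tree evidence and status."""

    label: str
    terminals: frozenset[str]
    per_marker: dict[str, MarkerEvidence] = field(default_factory=dict)
    concatenated: MarkerEvidence | None = None
    status: str = "untestable"     # primary | corroborated | rejected | untestable
    localities: list[str] = field(default_factory=list)


def _evaluate(
    tree: AnnotatedTree,
    marker: str,
    terminals: frozenset[str],
    gb_min: float,
    boot_min: float,
) -> MarkerEvidence:
    present = terminals & set(tree.leaf_labels())
    if not present:
        return MarkerEvidence(marker, present=False)
    mono, mrca = check_monophyly(tree, present)
    ev = MarkerEvidence(marker, present=True, monophyletic=mono)
    if not mono:
        ev.conflicting_terminals = sorted(tree.leaf_set(mrca) - present)
        return ev
    sup = tree.support(mrca)
    ev.goodman_bremer = sup.goodman_bremer
    ev.bootstrap = sup.bootstrap
    ev.stem_length = tree.stem_length(mrca)
    # absent support at the MRCA counts as failing the threshold
    ev.passes = (
        sup.goodman_bremer is not None
        and sup.bootstrap is not None
        and sup.goodman_bremer >= gb_min
        and sup.bootstrap >= boot_min
    )
    if len(present) == 1:
        # a singleton is trivially monophyletic but its "clade" has no
        # internal support annotation; screening treats it as untestable
        ev.passes = False
    return ev


def screen_hypotheses(
    trees: dict[str, AnnotatedTree],
    species_map: dict[str, str],
    gb_min: float = DEFAULT_GB_MIN,
    boot_min: float = DEFAULT_BOOT_MIN,
) -> list[SpeciesHypothesis]:
    """Screen every species against every single-marker tree.

    Status after screening: ``primary`` when the monophyly + support + boot
    criterion holds on ≥1 marker; ``untestable`` when the species occurs on
    no tree; ``rejected`` otherwise.  Per-marker diagnostics are retained.
    """
    if not trees:
        raise ValueError("at least one marker tree is required")
    species: dict[str, list[str]] = {}
    for term, sp in species_map.items():
        species.setdefault(sp, []).append(term)
    out = []
    for sp, terms in species.items():
        hyp = SpeciesHypothesis(label=sp, terminals=frozenset(terms))
        any_present = False
        any_pass = False
        for marker, tree in trees.items():
            ev = _evaluate(tree, marker, hyp.terminals, gb_min, boot_min)
            hyp.per_marker[marker] = ev
            any_present |= ev.present
            any_pass |= ev.passes
        hyp.status = "primary" if any_pass else ("rejected" if any_present else "untestable")
        out.append(hyp)
    return out


def consolidate(
    concat_tree: AnnotatedTree,
    hypotheses: list[SpeciesHypothesis],
    gb_min: float = DEFAULT_GB_MIN,
    boot_min: float = DEFAULT_BOOT_MIN,
    localities: dict[str, str] | None = None,
) -> list[SpeciesHypothesis]:
    """Re-evaluate primary hypotheses on the concatenated tree.

    ``corroborated`` when the full criterion holds there; ``rejected`` when
    the species is non-monophyletic (conflicting terminals listed);
    otherwise the hypothesis stays ``primary`` (monophyletic but weakly
    supported — left to the ad-hoc branch-length/distribution judgment).
    The stem branch length is always recorded; ``localities`` (terminal →
    collection locality) is surfaced per hypothesis, never auto-decided.
    """
    for hyp in hypotheses:
        if localities:
            hyp.localities = sorted(
                {localities[t] for t in hyp.terminals if t in localities}
            )
        if hyp.status != "primary":
            continue
        ev = _evaluate(concat_tree, "concatenated", hyp.terminals, gb_min, boot_min)
        hyp.concatenated = ev
        if not ev.present:
            continue
        if not ev.monophyletic:
            hyp.status = "rejected"
        elif ev.passes:
            hyp.status = "corroborated"
    return hypotheses


def hypotheses_table(hypotheses: list[SpeciesHypothesis]) -> pd.DataFrame:
    """Flat per-species × tree evidence table."""
    rows = []
    for hyp in hypotheses:
        evs = dict(hyp.per_marker)
        if hyp.concatenated is not None:
            evs["concatenated"] = hyp.concatenated
        for marker, ev in evs.items():
            rows.append({
                "species": hyp.label,
                "tree": marker,
                "present": ev.present,
                "monophyletic": ev.monophyletic,
                "goodman_bremer": ev.goodman_bremer,
                "bootstrap": ev.bootstrap,
                "stem_length": ev.stem_length,
                "passes": ev.passes,
                "status": hyp.status,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence-set (concatenated terminal) bookkeeping


def sequence_set_stats(table: pd.DataFrame, markers: list[str]) -> dict[str, float]:
    """Completeness and chimerism percentages of concatenated terminals.

    ``table`` has one row per terminal taxon with, per marker ``m``, a
    column ``m`` holding the sequence id (empty/NaN = absent) and a boolean
    column ``m_chimeric`` (sequence taken from a different specimen).
    Returns percentages on the 0–100 scale:

    * ``pct_complete`` — terminals with sequences for all markers;
    * ``pct_nonchimeric`` — terminals whose present sequences all come from
      the same specimen;
    * ``mean_chimerism_pct`` — among chimeric terminals, the mean share of
      present sequences that are chimeric.
    """
    if table.empty:
        raise ValueError("empty sequence-set table")
    for m in markers:
        if m not in table.columns:
            raise ValueError(f"marker column {m!r} missing from table")
    present = table[markers].notna() & (table[markers].astype(str) != "")
    chim_cols = [f"{m}_chimeric" for m in markers]
    for c in chim_cols:
        if c not in table.columns:
            raise ValueError(f"chimeric flag column {c!r} missing from table")
    chimeric = table[chim_cols].fillna(False).astype(bool).to_numpy() & present.to_numpy()

    n = len(table)
    n_present = present.sum(axis=1).to_numpy()
    if (n_present == 0).any():
        raise ValueError("terminal with no sequences at all")
    n_chim = chimeric.sum(axis=1)
    complete = n_present == len(markers)
    nonchim = n_chim == 0
    chim_ratio = n_chim / n_present
    chimeric_sets = chim_ratio[~nonchim]
    return {
        "pct_complete": 100.0 * complete.sum() / n,
        "pct_nonchimeric": 100.0 * nonchim.sum() / n,
        "mean_chimerism_pct": (100.0 * float(chimeric_sets.mean())) if chimeric_sets.size else 0.0,
        "n_terminals": float(n),
    }
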