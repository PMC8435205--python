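"""Uncorrected p-distances and the intra/interspecific barcode-gap partition.

The uncorrected *p*-distance is the number of base mismatches divided by the
number of compared sites — no substitution-model correction, by design.
Two gap policies are available because reference implementations differ:

* ``pairwise_deletion`` (default): sites where either sequence has ``-``,
  ``?`` or ``N`` are excluded from numerator and denominator;
* ``gap_as_difference``: the gap is a fifth state (``-`` vs. a base is a
  mismatch, ``-`` vs. ``-`` a match); ``?``/``N`` sites are still excluded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from moonjelly.alignments import AlignmentSet

GAP_POLICIES = ("pairwise_deletion", "gap_as_difference")
_ALWAYS_EXCLUDED = {"?", "N"}


def p_distance(seq_a: str, seq_b: str, gap_policy: str = "pairwise_deletion") -> float:
    """Uncorrected p-distance between two aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    excluded = _ALWAYS_EXCLUDED | ({"-"} if gap_policy == "pairwise_deletion" else set())
    compared = 0
    mismatches = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in excluded or b in excluded:
            continue
        compared += 1
        mismatches += a != b
    if compared == 0:
        raise ValueError("no comparable sites between the two sequences")
    return mismatches / compared


def p_distance_matrix(aln: AlignmentSet, gap_policy: str = "pairwise_deletion") -> pd.DataFrame:
    """Square symmetric matrix of pairwise p-distances (fractions)."""
    terms = aln.terminals
    n = len(terms)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = p_distance(aln.sequences[terms[i]], aln.sequences[terms[j]], gap_policy)
        out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=terms, columns=terms)


@dataclass
class DistanceSummary:
    """Intra/interspecific partition of a pairwise p-distance matrix."""

    marker: str
    matrix: pd.DataFrame
    intra_ranges: dict[str, tuple[float, float] | None]            # per species (None: <2 seqs)
    inter_ranges: dict[tuple[str, str], tuple[float, float]]       # per species pair
    intra_values: np.ndarray
    inter_values: np.ndarray
    histogram: pd.DataFrame = field(repr=False)                    # bin_left(%), intra, inter
    bin_width: float = 0.5                                         # percentage points

    def range_table(self) -> pd.DataFrame:
        """Minimum – maximum summary rows, distances in percent."""
        rows = []
        for sp, rng in self.intra_ranges.items():
            rows.append({
                "marker": self.marker, "kind": "intra", "a": sp, "b": sp,
                "range": "" if rng is None else f"{100*rng[0]:.2f} - {100*rng[1]:.2f}",
            })
        for (a, b), rng in self.inter_ranges.items():
            rows.append({
                "marker": self.marker, "kind": "inter", "a": a, "b": b,
                "range": f"{100*rng[0]:.2f} - {100*rng[1]:.2f}",
            })
        return pd.DataFrame(rows)


def partition_distances(
    matrix: pd.DataFrame,
    species_map: dict[str, str],
    marker: str = "",
    bin_width: float = 0.5,
) -> DistanceSummary:
    """Split pairwise distances into intra- and interspecific partitions.

    Every unordered pair lands in exactly one partition; species with a
    single sequence contribute no intra entries (empty range, not an
    error).  Histograms are over distances in percent with ``bin_width``
    percentage-point bins.
    """
    terms = list(matrix.index)
    unmapped = [t for t in terms if t not in species_map]
    if unmapped:
        raise ValueError(f"terminals without species assignment: {unmapped}")
    intra: dict[str, list[float]] = {}
    inter: dict[tuple[str, str], list[float]] = {}
    for t in terms:
        intra.setdefault(species_map[t], [])
    for a, b in itertools.combinations(terms, 2):
        d = float(matrix.loc[a, b])
        sa, sb = species_map[a], species_map[b]
        if sa == sb:
            intra[sa].append(d)
        else:
            key = tuple(sorted((sa, sb)))
            inter.setdefault(key, []).append(d)
    intra_vals = np.array([d for v in intra.values() for d in v])
    inter_vals = np.array([d for v in inter.values() for d in v])
    top = float(max(intra_vals.max(initial=0.0), inter_vals.max(initial=0.0))) * 100
    edges = np.arange(0, top + 2 * bin_width, bin_width)
    hist = pd.DataFrame({
        "bin_left": edges[:-1],
        "intra": np.histogram(intra_vals * 100, bins=edges)[0],
        "inter": np.histogram(inter_vals * 100, bins=edges)[0],
    })
    return DistanceSummary(
        marker=marker,
        matrix=matrix,
        intra_ranges={
            sp: (min(v), max(v)) if v else None for sp, v in intra.items()
        },
        inter_ranges={k: (min(v), max(v)) for k, v in inter.items()},
        intra_values=intra_vals,
        inter_values=inter_vals,
        histogram=hist,
        bin_width=bin_width,
    )


@dataclass(frozen=True)
class GapReport:
    """Barcode-gap assessment for one marker."""

    marker: str
    max_intra: float
    min_inter: float
    strict_gap: bool                       # min inter > max intra
    margin: float | None                   # gap width when strict
    overlap: tuple[float, float] | None    # [min inter, max intra] when not


def gap_summary(ds: DistanceSummary) -> GapReport:
    """Strict-gap test between the intra- and interspecific partitions."""
    if ds.intra_values.size == 0 or ds.inter_values.size == 0:
        raise ValueError(
            f"marker {ds.marker or '?'}: a partition is empty; barcode gap undefined"
        )
    max_intra = float(ds.intra_values.max())
    min_inter = float(ds.inter_values.min())
    strict = min_inter > max_intra
    return GapReport(
        marker=ds.marker,
        max_intra=max_intra,
        min_inter=min_inter,
        strict_gap=strict,
        margin=(min_inter - max_intra) if strict else None,
        overlap=None if strict else (min_inter, max_intra),
    )
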