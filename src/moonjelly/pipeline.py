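"""End-to-end runs: configuration, fixed stage order, file I/O.

The morphospace run executes impute → size-correct → filter → scale →
Gower → NMDS (+ feature scores) → Mantel and writes every intermediate;
the diagnosis run executes monophyly screening → synapomorphy
classification → p-distance summaries → hypothesis report.  All
randomness flows through the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from moonjelly import delimitation, distances, morphometrics
from moonjelly.alignments import AlignmentSet, read_species_map
from moonjelly.diagnosis import diagnose_all
from moonjelly.traits import TraitMatrix
from moonjelly.trees import AnnotatedTree, DEFAULT_SUPPORT_PATTERN


@dataclass
class RunConfig:
    """Thresholds, seeds and paths shared by the pipelines."""

    # morphospace
    trait_csv: str | None = None
    feature_meta_csv: str | None = None
    alpha: float = 0.05
    variance_threshold: float = 1e-12
    excluded_features: tuple[str, ...] = morphometrics.DEFAULT_EXCLUDED
    mds_k: int = 2
    mds_restarts: int = 8
    mantel_permutations: int = 9999
    geo_method: str = "euclidean"
    # diagnosis / delimitation
    alignments: dict[str, str] = field(default_factory=dict)   # marker -> FASTA path
    trees: dict[str, str] = field(default_factory=dict)        # marker -> Newick path
    concat_tree: str | None = None
    species_map_csv: str | None = None
    support_pattern: str = DEFAULT_SUPPORT_PATTERN
    gb_min: float = 2.0
    boot_min: float = 75.0
    gap_policy: str = "pairwise_deletion"
    histogram_bin_width: float = 0.5
    allow_single_terminal: bool = True
    # shared
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.boot_min <= 100:
            raise ValueError("boot_min must be in [0, 100]")
        if self.gap_policy not in distances.GAP_POLICIES:
            raise ValueError(f"unknown gap policy {self.gap_policy!r}")

    # lossless round trip through JSON
    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["excluded_features"] = list(self.excluded_features)
        s = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        d["excluded_features"] = tuple(d.get("excluded_features", morphometrics.DEFAULT_EXCLUDED))
        return cls(**d)

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = json.loads(self.to_json())
        d.pop("out_dir", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_morphospace(config: RunConfig, tm: TraitMatrix | None = None) -> dict:
    """Morphometric pipeline; returns the JSON summary (also written to disk).

    ``tm`` may be passed directly (e.g. a simulated matrix); otherwise
    ``config.trait_csv`` is read.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if tm is None:
        if config.trait_csv is None:
            raise ValueError("no trait matrix: set trait_csv or pass tm")
        tm = TraitMatrix.from_csv(config.trait_csv, config.feature_meta_csv)

    model = morphometrics.fit_allometry(tm)
    model.to_frame().to_csv(out / "allometry.csv")

    # categorical and unfittable features cannot be imputed allometrically;
    # they are dropped up front (the later filter would remove them anyway)
    keep_cols = [
        c for c in tm.feature_codes
        if tm.features[c].kind != "categorical" and c in model and model.entries[c].fittable
    ]
    usable = tm.with_values(tm.values[keep_cols])

    n_missing = int(usable.mask.sum().sum())
    imputed = morphometrics.impute_missing(usable, model)
    imputed.to_csv(out / "imputed.csv")
    corrected = morphometrics.size_correct(imputed, model)
    corrected.to_csv(out / "size_corrected.csv")
    filtered, removal_log = morphometrics.filter_features(
        corrected, model, alpha=config.alpha,
        excluded=tuple(config.excluded_features),
        variance_threshold=config.variance_threshold,
    )
    removal_log.to_csv(out / "removal_log.csv", index=False)
    scaled = morphometrics.minmax_scale(filtered)
    scaled.to_csv(out / "scaled.csv")

    gower = morphometrics.gower_distance(scaled)
    gower.to_csv(out / "gower.csv")
    ordination = morphometrics.nmds(
        gower, k=config.mds_k, restarts=config.mds_restarts, seed=config.seed
    )
    ordination.scores.to_csv(out / "nmds_scores.csv")
    fscores = morphometrics.feature_scores(ordination, scaled)
    fscores.to_csv(out / "feature_scores.csv")

    # Mantel: field specimens with coordinates only
    keep = (~tm.aquarium) & tm.coords.notna().all(axis=1)
    keep = keep[keep].index
    geo = morphometrics.geographic_distances(tm.coords.loc[keep], method=config.geo_method)
    mantel = morphometrics.mantel_test(
        geo, gower.loc[keep, keep],
        permutations=config.mantel_permutations, seed=config.seed,
    )

    summary = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_specimens": len(tm.specimens),
        "n_features_in": len(tm.feature_codes),
        "n_features_retained": len(scaled.feature_codes),
        "n_cells_imputed": n_missing,
        "nmds_stress": ordination.stress,
        "nmds_converged": ordination.converged,
        "mantel": {
            "r": mantel.r, "r_squared": mantel.r_squared, "p": mantel.pvalue,
            "permutations": mantel.permutations, "n": mantel.n, "seed": mantel.seed,
        },
    }
    (out / "morphospace_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_diagnosis(
    config: RunConfig,
    alns: dict[str, AlignmentSet] | None = None,
    trees: dict[str, AnnotatedTree] | None = None,
    concat_tree: AnnotatedTree | None = None,
) -> dict:
    """Molecular pipeline; returns the JSON summary (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    species_map = None
    if config.species_map_csv:
        species_map = read_species_map(config.species_map_csv)
    if alns is None:
        alns = {
            marker: AlignmentSet.from_fasta(path, marker=marker, species_map=species_map)
            for marker, path in config.alignments.items()
        }
    if trees is None:
        trees = {
            marker: AnnotatedTree.from_newick(path, config.support_pattern)
            for marker, path in config.trees.items()
        }
    if concat_tree is None and config.concat_tree:
        concat_tree = AnnotatedTree.from_newick(config.concat_tree, config.support_pattern)

    for marker, aln in alns.items():
        if marker not in trees:
            raise ValueError(f"marker {marker} has an alignment but no tree")
        extra = set(trees[marker].leaf_labels()) - set(aln.terminals)
        if extra:
            raise ValueError(f"marker {marker}: tree terminals absent from alignment: {sorted(extra)}")
        if not aln.species_map:
            raise ValueError(f"marker {marker}: empty species map")

    report = diagnose_all(trees, alns, allow_single_terminal=config.allow_single_terminal)
    report.character_table().to_csv(out / "synapomorphies.tsv", sep="\t", index=False)
    counts = report.counts_table()
    counts.to_csv(out / "synapomorphy_counts.tsv", sep="\t", index=False)

    gap_reports = {}
    for marker, aln in alns.items():
        pmat = distances.p_distance_matrix(aln, gap_policy=config.gap_policy)
        pmat.to_csv(out / f"pdist_{marker}.csv")
        summary_d = distances.partition_distances(
            pmat, aln.species_map, marker=marker, bin_width=config.histogram_bin_width
        )
        summary_d.range_table().to_csv(out / f"pdist_ranges_{marker}.tsv", sep="\t", index=False)
        summary_d.histogram.to_csv(out / f"pdist_hist_{marker}.csv", index=False)
        try:
            gr = distances.gap_summary(summary_d)
            gap_reports[marker] = dataclasses.asdict(gr)
        except ValueError:
            gap_reports[marker] = None

    species_map_all: dict[str, str] = {}
    for aln in alns.values():
        species_map_all.update(aln.species_map)
    hypotheses = delimitation.screen_hypotheses(
        trees, species_map_all, gb_min=config.gb_min, boot_min=config.boot_min
    )
    if concat_tree is not None:
        hypotheses = delimitation.consolidate(
            concat_tree, hypotheses, gb_min=config.gb_min, boot_min=config.boot_min
        )
    delimitation.hypotheses_table(hypotheses).to_csv(
        out / "hypotheses.tsv", sep="\t", index=False
    )

    summary = {
        "config_digest": config.digest(),
        "markers": sorted(alns),
        "n_species": len(set(species_map_all.values())),
        "synapomorphy_counts": counts.to_dict(orient="records"),
        "barcode_gap": gap_reports,
        "hypothesis_status": {h.label: h.status for h in hypotheses},
    }
    (out / "diagnosis_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
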