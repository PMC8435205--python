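# Methods

This note documents the models, numerical choices and known limitations of
the package, and what the synthetic generators do and do not emulate.

## Allometric standardization and missing-data estimation

Features are assumed to follow a power law in bell diameter,
`Y = a · f1^b · exp(ε)` with log-normal noise. The slope *b* is fitted by
OLS of `ln Y` on `ln f1` over the **entire** dataset, never per locality:
locality samples are too small for stable per-group slopes, and a shared
slope is what makes the group-mean transformations below coherent. The
slope is base-invariant; the stored intercept is on the natural-log scale.
A feature with fewer than 3 usable (positive, observed) specimens is
flagged unfittable and must be dropped before imputation. A non-missing
value ≤ 0 is an input error (it would silently vanish in log space), and
is reported with specimen and feature names.

Size correction is Lleonart standardization `Y* = Y_i (f1_m / f1_i)^b`,
with `f1_m` the mean bell diameter of the specimen's locality group; f1
itself is never transformed. Missing cells are estimated *before*
correction by the inverse transformation
`Ŷ_i = mean_g(Y) · (f1_i / f1_m)^b`, where `mean_g` and `f1_m` are taken
over the specimens of the group with that feature observed. We use the
**raw** group mean (not the mean of size-corrected values): it is the
reading under which the estimate has the units and magnitude of the raw
trait, and the two coincide whenever group sizes are homogeneous or
`b = 1`. Consequence worth knowing: for `b ≠ 1` with within-group size
spread, the raw-mean estimator carries a small Jensen-gap bias of order
`b(b−1)·Var(f1)/f1_m²`; the noiseless-recovery tests therefore use `b = 1`
or homogeneous groups, and the noisy-recovery tests bound the error by the
generator's noise scale instead. Groups with no observation fall back to
the nearest locality group by great-circle distance between group
centroids; groups without coordinates (aquarium) require an explicit
fallback chain. The published workflow's "also accounting for
morphological similarity when possible" is inherently manual and is
exposed only as that explicit per-group override map.

Feature filtering drops, in order of precedence: categorical features;
a configurable exclusion list (default `f19`, `f20` — lobe and rhopalia
counts, which vary with asymmetric development); near-invariant features
(variance < 1e-12 after unit harmonization — no published cutoff exists,
so the threshold is configurable); and features whose allometric slope is
not significant at α = 0.05 (again configurable; no published α).

## Ordination and the Mantel test

Gower dissimilarity is the mean, over features observed in both
specimens, of the range-normalized absolute difference; after min–max
scaling every range is 1. A specimen pair sharing no observed feature is
an error rather than a guess.

"MDS" is implemented as non-metric MDS: disparities from
pool-adjacent-violators monotone regression (sklearn's isotonic
regression) of configuration distances on the input dissimilarities,
configuration updates by the Guttman majorization transform, objective
Kruskal stress-1 `√(Σ(d−d̂)²/Σd²)`. Eight restarts by default: one
classical-scaling (Torgerson PCoA) start plus seeded random starts; the
best-stress solution is returned together with its per-iteration stress
trajectory (monotone non-increasing up to 1e-9 slack) and the stress of
the PCoA start. Convergence tolerance 1e-9 on the stress decrease, cap
300 iterations. One- and two-point inputs embed exactly with stress 0.
Classical PCoA alone is available by taking the start configuration.
Feature scores are weighted averages of specimen coordinates with the
feature's scaled values as weights (the `wascores` convention), so they
lie in the convex hull of the specimen cloud; an all-zero-weight feature
is flagged undefined.

The Mantel statistic is the Pearson correlation of upper-triangle
vectors; we report r and r² (the squared Mantel r — the natural reading
when only an R² is printed). The p-value is one-tailed (greater), the
standard alternative for distance-matrix correlation, over simultaneous
row/column permutations with the +1 correction, so p ∈ [1/(B+1), 1] and
never 0. Default B = 9,999. Geographic distances are Euclidean on raw
decimal degrees by default — deliberately, for fidelity to the published
choice — with a great-circle (haversine, km) option off by default.
Aquarium specimens (no meaningful coordinates) are excluded from the
Mantel test but retained in the ordination.

## Parsimony machinery and synapomorphy categories

Alignment characters live on the five-state alphabet {A, C, G, T, –}:
the gap is an alignable indel state (informative in the ribosomal
markers), `?`/`N` are full uncertainty, IUPAC codes polymorphic subsets.
A gap-as-missing comparison can be had by recoding before input.

Three equivalent views of each column's optimization are implemented and
cross-checked: (i) a Hartigan-style down-pass (state sets occurring in the
maximum number of children; cost = children − max-count; exactly Fitch on
bifurcations, exact on polytomies); (ii) a Sankoff-style unit-cost DP over
the observed alphabet giving, via down- and up-costs, the per-node sets of
states realized in ≥ 1 MPR; (iii) cost-guided backtracking that
enumerates *all* MPRs as full node→state labelings (ambiguous terminals
are resolved as part of the MPR). Enumeration is guarded by `max_nodes`
(default 20 for the public API; the classifier raises it, relying on the
backtracking to visit only optimal labelings) and a `max_mprs` cap.

A column is a diagnostic candidate for a focal clade when, in at least
one MPR, the stem branch (parent → clade MRCA) carries a transformation
ending in derived state *s* at the crown. Category assignment quantifies
over all MPRs:

* **ambiguous** — the stem transformation is absent in some MPR, or MPRs
  disagree on *s* (one entry is reported per candidate state);
* otherwise unambiguous, and **unique** iff *s* occurs in no terminal
  state set outside the clade;
* **non-homoplastic** iff in every MPR *s* originates on exactly one
  branch (the root carrying *s* counts as an origin) *and* is never lost.
  A loss is a reversal and therefore homoplasy of the diagnostic state —
  this matters because a state gained on the stem and reverted inside the
  clade would otherwise count as "single-origin" despite being
  homoplastic.

Single-terminal species are diagnosable (their stem is the terminal
branch) and this is on by default, switchable off. A clade whose MRCA is
the root has no stem and yields no characters. Non-monophyletic species
are flagged with zero characters, never an exception, mirroring how
published synapomorphy tables mark them. Positions are reported 0-based.
Root placement is taken from the input Newick; an outgroup re-rooting
helper exists.

## Distances, barcode gap, screening

Uncorrected p = mismatches / compared sites. Default gap policy is
pairwise deletion (sites with `-`, `?`, `N` in either sequence excluded);
`gap_as_difference` treats the gap as a fifth state. Both are exposed
because the commercial package used for the published numbers does not
document its convention. Intra/interspecific partitions report min–max
ranges per species and species pair, pooled histograms (default bin 0.5
percentage points — the published figure's granularity is unstated), and
a strict-gap verdict (min inter > max intra) with the overlap interval
otherwise. Model-corrected distances and threshold clustering are
deliberately out of scope.

Hypothesis screening: a species is *primary* when on ≥ 1 single-marker
tree its terminals are monophyletic with Goodman–Bremer ≥ 2 and bootstrap
≥ 75 at the MRCA (thresholds configurable; missing support values fail
the threshold and are logged). Support is read at each tree's own MRCA of
the species' terminals present there. Consolidation on the concatenated
tree upgrades to *corroborated* or downgrades to *rejected*
(non-monophyly, with conflicting terminals listed); the branch-length
criterion is ad hoc in the source workflow, so stem lengths are reported,
never thresholded, and distribution is surfaced as locality lists for
human judgment. Screening is monotone in both thresholds. Singleton
species are trivially monophyletic but have no internal node support, so
they never pass screening.

## Synthetic generators: what they emulate, and what not

`simulate_traits` draws per-locality log-normal bell diameters, power-law
features with log-normal noise, an optional latitude-linear locality
effect (the planted geographic signal), and missingness that is
specimen-level first (a configurable fraction of "damaged" field
specimens, default 60%, matching the reality that missingness concentrates
in damaged/photograph-only individuals) and cell-level MCAR within those.
Aquarium specimens have no coordinates and no missing cells. Defaults: 10
localities × 16 + 8 aquarium ≈ 168 specimens, 24 allometric features
(b ∈ [0.6, 1.4], σ ∈ [0.05, 0.15]), 3 size-independent plants for the
significance filter, the excluded f19/f20 counts, one categorical
feature, and a weak latitudinal gradient (0.004 per degree on the log
scale). Not emulated: realistic trait covariance beyond the shared size
axis, measurement-unit heterogeneity, non-MCAR missingness.

`simulate_alignment` evolves background columns by an equal-rates
(Jukes–Cantor-style) process on the expanded species tree — each species
tip becomes a pectinate clade of n terminals (default 4) — and
**constructs** the planted diagnostic columns rather than evolving them,
so category ground truth is exact regardless of the stochastic
background: black = derived state on all clade terminals, invariant
elsewhere; red = derived state on all but the deepest nested terminal
(stem gain + forced internal reversal — this needs ≥ 2 derived grade
lineages above the loss, hence the pectinate expansion and the ≥ 4
terminal requirement, which the generator enforces); blue = clade plus
the topologically farthest other terminal (two forced origins; with few
species a nearby repeat would instead tie with a single deeper origin and
come out ambiguous — the planted test fixtures keep ≥ 3 non-sister
species); ambiguous = derived state on the two shallowest grade terminals
(stem gain ties with two independent gains). Support values are planted
per species crown. Background evolution can create *additional* genuine
synapomorphies; scoring against truth therefore checks recall of planted
sites and category exactness, not absence of extras. Not emulated: rate
heterogeneity, realistic base composition, indel processes (gaps appear
only if included in the state alphabet).

`simulate_sequence_sets` builds concatenated-terminal bookkeeping tables:
marker presence i.i.d. (≥ 1 forced), the first present sequence anchors
the set, later ones chimeric with a set probability. Passing tests on
these fixtures shows the statistics are computed correctly, not that the
published completeness/chimerism percentages are recovered — those
require the original supplementary table (see below).

## Problem sizes and runtime

The default test suite and the acceptance script are sized for a single
CPU: brute-force parsimony oracles run on trees of 5–9 leaves with 2–4
states (vectorized exhaustive enumeration), ≥ 100 instances per oracle;
the Mantel null calibration uses 200 replicate seeds at n = 30 with 499
permutations (the +1-corrected p at B = 499 gives an exact 5% null
rejection probability, so the 95% binomial band over 200 replicates is
4–16 rejections); the synthetic study uses 168 specimens and four
300–400-site markers with 24 terminals. The full suite runs in ~35 s, the
acceptance script in ~25 s.

## Limitations

* The reproduction of the published numbers (Mantel R² 0.067/0.083,
  sequence-set 30%/49%/60%, minimum interspecific COI distance 2%)
  requires the original supplementary tables and alignments, which are
  not redistributable here; the code paths consume exactly those CSV /
  FASTA shapes and the reproduction test runs whenever the files are
  placed under `data/real/`.
* Homoplasy evaluation follows the category semantics stated above; the
  original diagnostic software's internal reversal handling is not
  printed anywhere, so bit-compatibility with its output is not claimed.
* Tree search, Goodman–Bremer computation and bootstrap resampling are
  inputs, not functionality.
* The raw-group-mean imputation bias for `b ≠ 1` noted above is the one
  place where two defensible readings of the published formula diverge; a
  sensitivity comparison is a one-line change (impute with size-corrected
  group means) left to the analyst.
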