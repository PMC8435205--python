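# moonjelly

Analyses for integrative taxonomy of the moon-jellyfish genus *Aurelia*
(Scyphozoa: Ulmaridae), a textbook case of cryptic diversity: medusa
morphology is so plastic that specimens from opposite sides of the planet
can resemble each other more than lot-mates, while molecular markers
resolve dozens of species-level lineages. The package implements the two
analysis arms such a study needs, end to end, plus ground-truthed
synthetic-data generators so every stage is testable without any sequence
downloads or museum data.

## What it computes

**1. Allometry-corrected morphometric dissimilarity.**
Medusa features scale with bell diameter (f1), so shape must be compared
free of size. Each feature *Y* gets a log–log ordinary-least-squares fit
against f1 over the entire dataset, giving the allometric slope *b*;
specimens are then standardized to their locality group's mean bell
diameter f1<sub>m</sub> (Lleonart's method):

    Y* = Y_i · (f1_m / f1_i)^b

Missing measurements (damaged specimens) are estimated first by the
inverse transformation from the locality-group mean, falling back to the
nearest locality (great-circle distance between group centroids) when a
group has no observation. Features that are categorical, near-invariant,
or lack a significant allometric relationship are dropped; the rest are
scaled to [0, 1]. Specimen dissimilarity is the Gower coefficient (mean
range-normalized absolute difference over jointly observed features),
ordinated by non-metric multidimensional scaling (Kruskal stress-1,
monotone-regression disparities, Guttman majorization, random + classical
PCoA restarts) with features mapped in as weighted-average scores.
Geographic structure is tested with a Mantel permutation test (Pearson *r*
of distance-matrix upper triangles, one-tailed, 9,999 permutations,
+1-corrected p) between Euclidean coordinate distances and the Gower
matrix, excluding aquarium specimens. Welch's *t* compares specimen
groups on single features.

**2. Phylogeny-based species diagnosis.**
For each species clade on each single-marker tree (16S, COI, ITS1, 28S),
every alignment column is optimized by Fitch/Hartigan parsimony (gaps as a
fifth state, IUPAC codes as polymorphic subsets) and *all* most
parsimonious reconstructions (MPRs) are enumerated. A column is diagnostic
when a state transformation lands on the clade's stem branch; it is
classified **ambiguous** (white) when MPRs disagree about that
transformation, else **unique & non-homoplastic** (black: derived state
absent outside the clade, single origin, never reversed), **unique &
homoplastic** (red) or **non-unique & homoplastic** (blue). Species
hypotheses are screened by monophyly + Goodman–Bremer support ≥ 2 +
bootstrap ≥ 75 on at least one marker, re-evaluated on a concatenated
tree (recording stem branch lengths), and barcodes are assessed from
uncorrected p-distance partitions (intra- vs interspecific ranges,
histograms, strict-gap test). Sequence-set bookkeeping reports
completeness and chimerism of concatenated terminals.

## Worked example

```bash
python analysis/01_simulate_datasets.py   # writes results/data/
python analysis/02_morphospace.py
python analysis/03_diagnose_synapomorphies.py
python analysis/04_barcode_gap.py
python analysis/05_delimit_species.py
```

The first driver simulates 168 medusae (10 localities × 16 plus 8
aquarium specimens; 29 features with power-law allometry and missingness
concentrated in ~60% of field specimens) and four marker alignments on a
known 6-taxon species tree with 12 planted diagnostic sites each. The
second prints, for the arm with missing-data estimation:

```
[with estimation] 168 specimens, 24/29 features retained, 652 cells imputed
[with estimation] NMDS stress-1 = 0.0447
[with estimation] Mantel r^2 = 0.190, p = 0.0001 (9999 permutations, n = 160)
```

i.e. the ordination fits well (stress < 0.05), five features were dropped
by the filters (categorical, the lobe/rhopalia counts, and the
size-independent plants), and the planted latitudinal signal is detected
as a positive geography–morphology correlation. The diagnosis driver
recovers every planted synapomorphy with its exact category
(`planted sites recovered with exact category: 48/48`) and the barcode
driver reports, for the protein-coding marker,

```
[COI] max intra = 1.25%, min inter = 2.50% -> strict gap, margin 1.25 pp
[COI] sister species smithsoniana vs cebimarensis: 2.50 - 4.25%
```

— the closest species pair sits just above the intraspecific range, which
is why distance thresholds are reported but never used to delimit
species. A `moonjelly` console script exposes the same runs
(`moonjelly simulate|morphospace|diagnose`).

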