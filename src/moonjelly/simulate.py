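"""Ground-truthed synthetic data for every pipeline stage.

Two generators:

* :func:`simulate_traits` — power-law (allometric) trait matrices
  ``Y = a · f1^b · exp(ε)`` with locality structure, an optional
  latitude-linked locality effect (planted geographic signal for the
  Mantel test), and MCAR missingness applied *after* the true values are
  recorded.
* :func:`simulate_alignment` — alignments evolved on a known species tree
  (equal-rates substitution) with *constructed* diagnostic columns of each
  synapomorphy category, so classifier output can be scored against an
  exact plant.  Construction, not evolution, guarantees the category
  ground truth regardless of the stochastic background.

Every function is deterministic given its seed; fixtures regenerate
byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from moonjelly.alignments import AlignmentSet
from moonjelly.traits import FeatureMeta, TraitMatrix
from moonjelly.trees import AnnotatedTree

# ---------------------------------------------------------------------------
# traits


@dataclass(frozen=True)
class FeatureSim:
    """One simulated feature: ``Y = a · f1^b_true · exp(ε)``, ε ~ N(0, σ²).

    ``size_independent`` features ignore f1 entirely (b_true forced to 0);
    they are the plant for the significance filter.
    """

    code: str
    a: float = 1.0
    b_true: float = 1.0
    sigma: float = 0.05
    size_independent: bool = False
    kind: str = "continuous"

    @property
    def exponent(self) -> float:
        return 0.0 if self.size_independent else self.b_true


@dataclass(frozen=True)
class LocalitySim:
    """A locality group: centroid coordinates and log-normal f1 distribution."""

    name: str
    lat: float
    lon: float
    f1_log_mean: float = math.log(15.0)   # bell diameter ~15 cm
    f1_log_sigma: float = 0.25


@dataclass
class TraitSimSpec:
    """Study conditions for the trait generator."""

    localities: list[LocalitySim]
    features: list[FeatureSim]
    n_per_locality: int = 16
    missing_rate: float = 0.2
    missing_specimen_rate: float = 1.0   # fraction of specimens eligible for missingness
    geo_gradient: float = 0.0     # log-scale trait shift per degree latitude
    n_aquarium: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.missing_specimen_rate <= 1:
            raise ValueError("missing_specimen_rate must be in [0, 1]")
        if self.n_per_locality < 1 or not self.localities or not self.features:
            raise ValueError("degenerate simulation spec")


@dataclass
class TraitTruth:
    """Ground truth recorded before masking."""

    b_true: dict[str, float]
    true_values: pd.DataFrame
    missing_mask: pd.DataFrame
    spec: TraitSimSpec


def simulate_traits(spec: TraitSimSpec) -> tuple[TraitMatrix, TraitTruth]:
    """Generate a trait matrix with locality structure and MCAR missingness."""
    rng = np.random.default_rng(spec.seed)
    specimens, locs, lats, lons, aq = [], [], [], [], []
    f1 = []
    for loc in spec.localities:
        for i in range(spec.n_per_locality):
            specimens.append(f"{loc.name}_{i+1:02d}")
            locs.append(loc.name)
            lats.append(loc.lat)
            lons.append(loc.lon)
            aq.append(False)
            f1.append(math.exp(rng.normal(loc.f1_log_mean, loc.f1_log_sigma)))
    mean_lat = float(np.mean([loc.lat for loc in spec.localities]))
    for i in range(spec.n_aquarium):
        specimens.append(f"AQ_{i+1:02d}")
        locs.append("aquarium")
        lats.append(np.nan)
        lons.append(np.nan)
        aq.append(True)
        f1.append(math.exp(rng.normal(math.log(12.0), 0.2)))
    n = len(specimens)
    f1_arr = np.array(f1)
    lat_arr = np.array(lats)

    values = {}
    meta: dict[str, FeatureMeta] = {}
    for feat in spec.features:
        meta[feat.code] = FeatureMeta(feat.code, feat.kind)
        if feat.kind == "categorical":
            values[feat.code] = rng.integers(0, 3, size=n).astype(float)
            continue
        eps = rng.normal(0.0, feat.sigma, size=n)
        geo = np.where(np.isnan(lat_arr), 0.0, spec.geo_gradient * (lat_arr - mean_lat))
        values[feat.code] = feat.a * f1_arr ** feat.exponent * np.exp(geo + eps)
    true_df = pd.DataFrame(values, index=pd.Index(specimens, name="specimen_id"))

    mask = pd.DataFrame(False, index=true_df.index, columns=true_df.columns)
    if spec.missing_rate > 0:
        numeric = [f.code for f in spec.features if f.kind != "categorical"]
        aq_arr = np.array(aq)
        # damage is specimen-level first (photographed/damaged individuals),
        # then cell-level within the damaged specimens
        damaged = rng.random(n) < spec.missing_specimen_rate
        draw = rng.random((n, len(numeric))) < spec.missing_rate
        draw[~damaged, :] = False
        draw[aq_arr, :] = False  # aquarium medusae were measured complete
        for j, code in enumerate(numeric):
            col_mask = draw[:, j]
            if (~col_mask).sum() < 3:  # keep every feature fittable
                col_mask[:] = False
            mask[code] = col_mask
    masked = true_df.mask(mask)

    tm = TraitMatrix(
        values=masked,
        size=pd.Series(f1_arr, index=true_df.index, name="f1"),
        locality=pd.Series(locs, index=true_df.index, name="locality"),
        coords=pd.DataFrame({"lat": lats, "lon": lons}, index=true_df.index),
        aquarium=pd.Series(aq, index=true_df.index, name="aquarium"),
        features=meta,
    )
    truth = TraitTruth(
        b_true={f.code: f.exponent for f in spec.features if f.kind != "categorical"},
        true_values=true_df,
        missing_mask=mask,
        spec=spec,
    )
    return tm, truth


def default_trait_spec(seed: int = 0, **overrides) -> TraitSimSpec:
    """Default study conditions: 10 localities × 16 medusae plus 8 aquarium
    specimens (~168 total), ~30 features (24 allometric, 3 size-independent,
    the excluded lobe/rhopalia counts f19/f20, one categorical), 20% MCAR
    missingness, and a weak latitudinal locality effect."""
    rng = np.random.default_rng(seed + 104729)  # feature parameters, not data
    localities = [
        LocalitySim("BRA_SE", -23.8, -45.4, math.log(14.0), 0.22),
        LocalitySim("USA_NE", 41.5, -70.7, math.log(17.0), 0.25),
        LocalitySim("USA_SW", 33.8, -118.4, math.log(16.0), 0.25),
        LocalitySim("CAN_NE", 47.6, -52.7, math.log(18.0), 0.22),
        LocalitySim("ARG", -38.0, -57.5, math.log(15.0), 0.25),
        LocalitySim("JPN", 34.7, 135.2, math.log(13.0), 0.22),
        LocalitySim("PHL", 10.3, 123.9, math.log(12.0), 0.25),
        LocalitySim("MDV", 4.2, 73.5, math.log(11.0), 0.22),
        LocalitySim("DNK", 55.7, 12.6, math.log(16.0), 0.25),
        LocalitySim("ARC", 71.0, -156.0, math.log(19.0), 0.22),
    ]
    features: list[FeatureSim] = []
    allometric_codes = [f"f{i}" for i in list(range(2, 19)) + list(range(21, 28))]
    for code in allometric_codes:
        features.append(
            FeatureSim(
                code=code,
                a=float(rng.uniform(0.2, 2.0)),
                b_true=float(rng.uniform(0.6, 1.4)),
                sigma=float(rng.uniform(0.05, 0.15)),
            )
        )
    for i in range(3):
        features.append(
            FeatureSim(code=f"f4{i}", a=float(rng.uniform(1.0, 3.0)),
                       sigma=0.3, size_independent=True)
        )
    features.append(FeatureSim(code="f19", a=8.0, b_true=0.0, sigma=0.1,
                               size_independent=True, kind="meristic"))
    features.append(FeatureSim(code="f20", a=8.0, b_true=0.0, sigma=0.1,
                               size_independent=True, kind="meristic"))
    features.append(FeatureSim(code="f8", kind="categorical"))
    base = dict(
        localities=localities,
        features=features,
        n_per_locality=16,
        missing_rate=0.25,
        missing_specimen_rate=0.6,
        geo_gradient=0.004,
        n_aquarium=8,
        seed=seed,
    )
    base.update(overrides)
    return TraitSimSpec(**base)


# ---------------------------------------------------------------------------
# alignments on species trees


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one constructed diagnostic column."""

    position: int
    species: str
    category: str
    derived_state: str
    ancestral_state: str


@dataclass
class SeqSimSpec:
    """Study conditions for the sequence generator.

    ``planted`` lists (species, category, count) requests; categories are
    the four-way scheme.  ``rate`` is the expected number of substitutions
    per site per unit branch length for the background columns.
    """

    species_tree: str                       # Newick with branch lengths
    planted: list[tuple[str, str, int]] = field(default_factory=list)
    marker: str = "16S"
    length: int = 300
    rate: float = 0.3
    n_per_species: int = 4
    states: tuple[str, ...] = ("A", "C", "G", "T")
    within_species_edge: float = 0.02
    support_plan: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    default_support: tuple[float, float] = (10.0, 100.0)
    seed: int = 0


_CATEGORY_MIN_TERMINALS = {
    "unique_nonhomoplastic": 1,
    "unique_homoplastic": 4,
    "nonunique_homoplastic": 1,
    "ambiguous": 4,
}


def _expand_species_tree(spec: SeqSimSpec):
    """Expand each species tip into a pectinate clade of terminals.

    Returns (dendropy tree, terminal→species map, species→crown node).
    """
    tree = dendropy.Tree.get(
        data=spec.species_tree, schema="newick",
        preserve_underscores=True, rooting="force-rooted",
        suppress_internal_node_taxa=True,
    )
    ns = tree.taxon_namespace
    species_map: dict[str, str] = {}
    crowns: dict[str, dendropy.Node] = {}
    for leaf in list(tree.leaf_node_iter()):
        sp = leaf.taxon.label
        names = [f"{sp}_t{i+1}" for i in range(spec.n_per_species)]
        for name in names:
            species_map[name] = sp
        if spec.n_per_species == 1:
            leaf.taxon.label = names[0]
            crowns[sp] = leaf
            continue
        leaf.taxon = None  # becomes the crown (internal) node

        def make_leaf(name: str) -> dendropy.Node:
            nd = dendropy.Node()
            nd.taxon = ns.new_taxon(name)
            nd.edge.length = spec.within_species_edge
            return nd

        # pectinate: crown = (t1, (t2, (... (t_{n-1}, t_n))))
        current = make_leaf(names[-1])
        for name in reversed(names[1:-1]):
            parent = dendropy.Node()
            parent.edge.length = spec.within_species_edge
            parent.add_child(make_leaf(name))
            parent.add_child(current)
            current = parent
        leaf.add_child(make_leaf(names[0]))
        leaf.add_child(current)
        crowns[sp] = leaf
    return tree, species_map, crowns


def _evolve_column(tree: dendropy.Tree, states: tuple[str, ...], rate: float,
                   rng: np.random.Generator) -> dict[str, str]:
    k = len(states)
    assign: dict[int, str] = {id(tree.seed_node): states[rng.integers(k)]}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = assign[id(node.parent_node)]
        t = node.edge.length or 0.0
        # Jukes–Cantor style: substitution event may resample the same state
        if rng.random() < 1.0 - math.exp(-rate * t):
            assign[id(node)] = states[rng.integers(k)]
        else:
            assign[id(node)] = parent_state
    return {lf.taxon.label: assign[id(lf)] for lf in tree.leaf_node_iter()}


def _topo_distance(tree: dendropy.Tree, a: dendropy.Node, b: dendropy.Node) -> int:
    anc_a = {id(n): i for i, n in enumerate([a] + list(a.ancestor_iter()))}
    d = 0
    node = b
    while id(node) not in anc_a:
        node = node.parent_node
        d += 1
    return d + anc_a[id(node)]


def _plant_column(
    spec: SeqSimSpec,
    tree: dendropy.Tree,
    species_map: dict[str, str],
    crowns: dict[str, dendropy.Node],
    species: str,
    category: str,
    rng: np.random.Generator,
) -> tuple[dict[str, str], str, str]:
    """Construct one diagnostic column; returns (column, derived, ancestral)."""
    if species not in crowns:
        raise ValueError(f"species {species!r} not in the species tree")
    need = _CATEGORY_MIN_TERMINALS[category]
    if spec.n_per_species < need:
        raise ValueError(
            f"category {category} needs >= {need} terminals per species "
            f"(pectinate clade); spec has {spec.n_per_species}"
        )
    anc = spec.states[rng.integers(len(spec.states))]
    others = [s for s in spec.states if s != anc]
    der = others[rng.integers(len(others))]
    column = {t: anc for t in species_map}
    focal = [f"{species}_t{i+1}" for i in range(spec.n_per_species)]
    if category == "unique_nonhomoplastic":
        for t in focal:
            column[t] = der
    elif category == "unique_homoplastic":
        # gain on the stem, reversal on the deepest nested terminal
        for t in focal[:-1]:
            column[t] = der
    elif category == "ambiguous":
        # derived state on the two shallowest grade terminals only: the stem
        # gain then ties with two independent gains, so optimization varies
        for t in focal[:2]:
            column[t] = der
    elif category == "nonunique_homoplastic":
        for t in focal:
            column[t] = der
        other_species = [sp for sp in crowns if sp != species]
        if not other_species:
            raise ValueError("nonunique_homoplastic needs a second species")
        # farthest species by node-path distance, to force two origins
        far = max(other_species, key=lambda sp: _topo_distance(tree, crowns[species], crowns[sp]))
        column[f"{far}_t{spec.n_per_species}"] = der
    else:
        raise ValueError(f"unknown category {category!r}")
    return column, der, anc


def simulate_alignment(spec: SeqSimSpec) -> tuple[AlignmentSet, AnnotatedTree, list[PlantedSite]]:
    """Evolve a marker alignment with constructed diagnostic sites.

    Returns the alignment (with terminal→species map), the expanded,
    support-annotated tree, and the list of planted sites.
    """
    rng = np.random.default_rng(spec.seed)
    tree, species_map, crowns = _expand_species_tree(spec)

    n_planted = sum(c for _, _, c in spec.planted)
    if n_planted > spec.length:
        raise ValueError(f"{n_planted} planted sites exceed marker length {spec.length}")
    positions = rng.choice(spec.length, size=n_planted, replace=False) if n_planted else np.array([], int)

    columns: dict[int, dict[str, str]] = {}
    truth: list[PlantedSite] = []
    cursor = 0
    for sp, category, count in spec.planted:
        for _ in range(count):
            pos = int(positions[cursor])
            cursor += 1
            col, der, anc = _plant_column(spec, tree, species_map, crowns, sp, category, rng)
            columns[pos] = col
            truth.append(PlantedSite(pos, sp, category, der, anc))
    for pos in range(spec.length):
        if pos not in columns:
            columns[pos] = _evolve_column(tree, spec.states, spec.rate, rng)

    terminals = [lf.taxon.label for lf in tree.leaf_node_iter()]
    sequences = {t: "".join(columns[p][t] for p in range(spec.length)) for t in terminals}

    # support annotations: species crowns per plan, every other internal node default
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        node.label = None
    gb_d, boot_d = spec.default_support
    annotated = AnnotatedTree(tree)
    for node in annotated.internal_nodes():
        if node is annotated.root:
            continue
        annotated.set_support(node, gb_d, boot_d)
    for sp, crown in crowns.items():
        gb, boot = spec.support_plan.get(sp, spec.default_support)
        if not crown.is_leaf():
            annotated.set_support(crown, gb, boot)

    aln = AlignmentSet(marker=spec.marker, sequences=sequences, species_map=species_map)
    truth.sort(key=lambda s: s.position)
    return aln, annotated, truth


DEFAULT_SPECIES_TREE = (
    "((((smithsoniana:0.05,cebimarensis:0.05):0.10,mianzani:0.12):0.08,"
    "(coerulea:0.10,solida:0.10):0.10):0.15,outgroup:0.40);"
)


def default_seq_spec(seed: int = 0, marker: str = "16S", **overrides) -> SeqSimSpec:
    """Default sequence study conditions: six taxa (five ingroup species and
    an outgroup), four terminals per species, 300-site marker, and planted
    sites of every category for the two sister species plus one more."""
    base = dict(
        species_tree=DEFAULT_SPECIES_TREE,
        planted=[
            ("smithsoniana", "unique_nonhomoplastic", 3),
            ("smithsoniana", "unique_homoplastic", 2),
            ("smithsoniana", "nonunique_homoplastic", 1),
            ("cebimarensis", "unique_nonhomoplastic", 3),
            ("cebimarensis", "ambiguous", 1),
            ("coerulea", "unique_nonhomoplastic", 2),
        ],
        marker=marker,
        length=300,
        rate=0.3,
        n_per_species=4,
        seed=seed,
    )
    base.update(overrides)
    return SeqSimSpec(**base)


# ---------------------------------------------------------------------------
# sequence-set (concatenated terminal) tables


def simulate_sequence_sets(
    n_terminals: int = 100,
    markers: tuple[str, ...] = ("16S", "COI", "ITS1", "28S"),
    presence_prob: float = 0.7,
    chimeric_prob: float = 0.45,
    n_species: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic concatenated-terminal bookkeeping table.

    Each terminal has every marker with probability ``presence_prob``
    (at least one forced); the first present sequence anchors the set
    (non-chimeric) and every further present sequence is chimeric with
    probability ``chimeric_prob``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_terminals):
        present = rng.random(len(markers)) < presence_prob
        if not present.any():
            present[rng.integers(len(markers))] = True
        anchor = int(np.flatnonzero(present)[0])
        row: dict[str, object] = {
            "terminal": f"term_{i+1:03d}",
            "species": f"sp_{i % n_species + 1:02d}",
        }
        for j, m in enumerate(markers):
            if present[j]:
                row[m] = f"seq_{i+1:03d}_{m}"
                row[f"{m}_chimeric"] = bool(j != anchor and rng.random() < chimeric_prob)
            else:
                row[m] = ""
                row[f"{m}_chimeric"] = False
        rows.append(row)
    return pd.DataFrame(rows)
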