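"""Allometry-corrected morphometric dissimilarity analysis.

The pipeline, in its fixed order:

1. :func:`fit_allometry` — per-feature log–log OLS of trait against bell
   diameter f1 over the whole dataset, giving the allometric slope *b*.
2. :func:`impute_missing` — Lleonart-style estimation of missing cells from
   the locality-group mean rescaled by ``(f1_i / f1_m) ** b``.
3. :func:`size_correct` — Lleonart standardization
   ``Y* = Y_i * (f1_m / f1_i) ** b`` removing body-size effects.
4. :func:`filter_features` — drop categorical, configured, size-independent
   and near-invariant features.
5. :func:`minmax_scale` — per-feature scaling to [0, 1].
6. :func:`gower_distance` — mean range-normalized absolute difference.
7. :func:`nmds` — non-metric MDS (Kruskal stress-1) with weighted-average
   feature scores (:func:`feature_scores`).
8. :func:`mantel_test` — permutation correlation of geographic vs.
   morphological distance matrices.

All randomness is seeded; rerunning with the same seed is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from moonjelly.traits import TraitMatrix, SIZE_FEATURE

__all__ = [
    "AllometryEntry", "AllometryModel", "OrdinationResult", "MantelResult",
    "fit_allometry", "impute_missing", "size_correct", "filter_features",
    "minmax_scale", "gower_distance", "nmds", "feature_scores",
    "mantel_test", "welch_t", "geographic_distances", "great_circle_km",
]


# ---------------------------------------------------------------------------
# allometry


@dataclass(frozen=True)
class AllometryEntry:
    """Log–log regression of one feature on bell diameter f1.

    ``slope`` is base-invariant; the intercept is on the natural-log scale.
    ``fittable`` is False when fewer than 3 usable specimens exist.
    """

    feature: str
    slope: float
    intercept: float
    pvalue: float
    n: int
    fittable: bool = True


@dataclass
class AllometryModel:
    """Per-feature allometric fits, keyed by feature code."""

    entries: dict[str, AllometryEntry] = field(default_factory=dict)

    def __getitem__(self, feature: str) -> AllometryEntry:
        return self.entries[feature]

    def __contains__(self, feature: str) -> bool:
        return feature in self.entries

    def slope(self, feature: str) -> float:
        entry = self.entries[feature]
        if not entry.fittable:
            raise ValueError(f"feature {feature} has no allometric fit (n={entry.n} < 3)")
        return entry.slope

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slope": {f: e.slope for f, e in self.entries.items()},
                "intercept": {f: e.intercept for f, e in self.entries.items()},
                "pvalue": {f: e.pvalue for f, e in self.entries.items()},
                "n": {f: e.n for f, e in self.entries.items()},
                "fittable": {f: e.fittable for f, e in self.entries.items()},
            }
        )


def _fit_one(tm: TraitMatrix, feature: str) -> AllometryEntry:
    y = tm.values[feature]
    observed = y.notna()
    bad = y.index[observed & (y <= 0)]
    if len(bad):
        raise ValueError(
            f"nonpositive value for feature {feature} in specimen(s) {list(bad)}; "
            "log-log allometry requires strictly positive measurements"
        )
    x = tm.size[observed]
    yy = y[observed]
    n = int(observed.sum())
    if n < 3:
        return AllometryEntry(feature, math.nan, math.nan, math.nan, n, fittable=False)
    ly, lx = np.log(yy.to_numpy(float)), np.log(x.to_numpy(float))
    if np.ptp(ly) == 0.0:
        # invariant feature: zero slope by definition, certainly non-significant
        return AllometryEntry(feature, 0.0, float(ly[0]), 1.0, n)
    res = stats.linregress(lx, ly)
    return AllometryEntry(feature, float(res.slope), float(res.intercept), float(res.pvalue), n)


def fit_allometry(tm: TraitMatrix, feature: str | None = None):
    """OLS of log(Y) on log(f1) over the entire dataset (never per locality).

    With ``feature`` given, returns a single :class:`AllometryEntry`;
    otherwise fits every non-categorical feature and returns an
    :class:`AllometryModel`.  Features with fewer than 3 usable specimens
    come back flagged unfittable (they must be dropped before imputation).
    """
    if feature is not None:
        return _fit_one(tm, feature)
    model = AllometryModel()
    for code in tm.numeric_features():
        model.entries[code] = _fit_one(tm, code)
    return model


# ---------------------------------------------------------------------------
# geography helpers


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine distance in km (WGS84 mean radius)."""
    r = 6371.0088
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * r * math.asin(min(1.0, math.sqrt(a)))


def geographic_distances(coords: pd.DataFrame, method: str = "euclidean") -> pd.DataFrame:
    """Pairwise specimen distances from decimal-degree coordinates.

    ``euclidean`` (default) works on the raw decimal degrees; ``greatcircle``
    uses the haversine formula (km).  Rows with missing coordinates raise.
    """
    if coords[["lat", "lon"]].isna().any().any():
        bad = coords.index[coords[["lat", "lon"]].isna().any(axis=1)].tolist()
        raise ValueError(f"specimens without coordinates: {bad}")
    n = len(coords)
    out = np.zeros((n, n))
    lat = coords["lat"].to_numpy(float)
    lon = coords["lon"].to_numpy(float)
    if method == "euclidean":
        out = np.hypot(lat[:, None] - lat[None, :], lon[:, None] - lon[None, :])
    elif method == "greatcircle":
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = great_circle_km(lat[i], lon[i], lat[j], lon[j])
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(out, index=coords.index, columns=coords.index)


# ---------------------------------------------------------------------------
# imputation and size correction


def _nearest_groups(tm: TraitMatrix, group: str) -> list[str]:
    """Other locality groups ordered by great-circle centroid distance."""
    cent = tm.locality_centroids()
    if group not in cent.index or cent.loc[group].isna().any():
        raise ValueError(
            f"locality group {group!r} has no coordinates; nearest-locality "
            "fallback needs an explicit entry in the fallback map"
        )
    g = cent.loc[group]
    others = cent.drop(index=group).dropna()
    ranked = sorted(
        others.index,
        key=lambda o: great_circle_km(g["lat"], g["lon"], others.loc[o, "lat"], others.loc[o, "lon"]),
    )
    return ranked


def impute_missing(
    tm: TraitMatrix,
    am: AllometryModel,
    fallback: dict[str, list[str]] | None = None,
) -> TraitMatrix:
    """Estimate missing cells by inverse Lleonart scaling of group means.

    A missing value of feature ``Y`` for specimen *i* becomes
    ``mean_g(Y) * (f1_i / f1_m) ** b`` where ``mean_g`` and ``f1_m`` are the
    mean trait value and mean bell diameter over specimens of *i*'s locality
    group that have ``Y`` observed.  Groups without any observation fall back
    to the nearest locality group (great-circle distance between group
    centroids) that has one, or to an explicit ``fallback`` chain.  Observed
    cells are untouched; filled cells are flagged in ``imputed``.
    """
    fallback = fallback or {}
    out = tm.copy()
    values = out.values
    for feature in tm.numeric_features():
        col = values[feature]
        missing = col.isna()
        if not missing.any():
            continue
        if feature not in am or not am.entries[feature].fittable:
            raise ValueError(f"feature {feature} has missing cells but no allometric fit")
        b = am.slope(feature)
        observed_by_group: dict[str, tuple[float, float]] = {}
        for grp, members in tm.values.groupby(tm.locality).groups.items():
            obs = col.loc[members].dropna()
            if len(obs):
                f1m = float(tm.size.loc[obs.index].mean())
                observed_by_group[str(grp)] = (float(obs.mean()), f1m)
        if not observed_by_group:
            raise ValueError(
                f"feature {feature} observed in no locality group; drop it before imputation"
            )
        for spec in col.index[missing]:
            grp = str(tm.locality.loc[spec])
            if grp in observed_by_group:
                mean_y, f1m = observed_by_group[grp]
            else:
                chain = fallback.get(grp) or _nearest_groups(tm, grp)
                donor = next((g for g in chain if g in observed_by_group), None)
                if donor is None:
                    raise ValueError(
                        f"no locality in the fallback chain of {grp!r} has data for {feature}"
                    )
                mean_y, f1m = observed_by_group[donor]
            est = mean_y * (float(tm.size.loc[spec]) / f1m) ** b
            values.loc[spec, feature] = est
            out.imputed.loc[spec, feature] = True
    return out


def size_correct(tm: TraitMatrix, am: AllometryModel) -> TraitMatrix:
    """Lleonart size standardization ``Y* = Y_i * (f1_m / f1_i) ** b``.

    ``f1_m`` is the mean bell diameter of the specimen's locality group; the
    exponent *b* is the whole-dataset allometric slope.  Requires a complete
    matrix (impute first).  f1 itself is never transformed.
    """
    numeric = tm.numeric_features()
    if tm.values[numeric].isna().any().any():
        raise ValueError("matrix still has missing cells; run impute_missing first")
    out = tm.copy()
    f1m_by_group = tm.size.groupby(tm.locality).mean()
    f1m = tm.locality.map(f1m_by_group).to_numpy(float)
    f1i = tm.size.to_numpy(float)
    for feature in numeric:
        if feature not in am:
            raise ValueError(f"feature {feature} has no allometric fit; fit or drop it")
        b = am.slope(feature)
        out.values[feature] = tm.values[feature].to_numpy(float) * (f1m / f1i) ** b
    return out


# ---------------------------------------------------------------------------
# feature filtering and scaling

DEFAULT_EXCLUDED = ("f19", "f20")  # lobe / rhopalia counts: asymmetric development


def filter_features(
    tm: TraitMatrix,
    am: AllometryModel,
    alpha: float = 0.05,
    excluded: tuple[str, ...] = DEFAULT_EXCLUDED,
    variance_threshold: float = 1e-12,
) -> tuple[TraitMatrix, pd.DataFrame]:
    """Drop features unusable for the dissimilarity analysis.

    Rules, in order of precedence per feature:

    a. categorical kind (excluded from all numeric analyses);
    b. configured exclusion list (defaults to the lobe and rhopalia counts
       f19/f20, which vary with asymmetric development);
    c. near-zero variance (``mostly invariable``), below ``variance_threshold``;
    d. no significant allometric relationship with f1 (slope p ≥ ``alpha``),
       including features that could not be fitted at all.

    Returns the reduced matrix and a removal log (feature, rule, detail).
    """
    log_rows = []
    keep = []
    for feature in tm.feature_codes:
        meta = tm.features[feature]
        if meta.kind == "categorical":
            log_rows.append((feature, "categorical", meta.kind))
            continue
        if feature in excluded or meta.exclude:
            log_rows.append((feature, "configured_exclusion", ""))
            continue
        col = tm.values[feature].dropna()
        var = float(col.var(ddof=1)) if len(col) > 1 else 0.0
        if var < variance_threshold:
            log_rows.append((feature, "near_invariant", f"variance={var:.3g}"))
            continue
        entry = am.entries.get(feature)
        if entry is None or not entry.fittable:
            log_rows.append((feature, "unfittable", f"n={0 if entry is None else entry.n}"))
            continue
        if not (entry.pvalue < alpha):
            log_rows.append((feature, "nonsignificant_allometry", f"p={entry.pvalue:.3g}"))
            continue
        keep.append(feature)
    if not keep:
        raise ValueError("all features removed by filtering; relax alpha or inspect data")
    log = pd.DataFrame(log_rows, columns=["feature", "rule", "detail"])
    return tm.with_values(tm.values[keep]), log


def minmax_scale(tm: TraitMatrix) -> TraitMatrix:
    """Scale every feature to attain minimum 0 and maximum 1."""
    vals = tm.values
    if vals.isna().any().any():
        raise ValueError("matrix has missing cells; impute (or subset) before scaling")
    rng = vals.max() - vals.min()
    flat = rng.index[rng == 0].tolist()
    if flat:
        raise ValueError(f"constant feature(s) cannot be scaled: {flat}; filter first")
    return tm.with_values((vals - vals.min()) / rng)


# ---------------------------------------------------------------------------
# Gower dissimilarity


def gower_distance(tm: TraitMatrix | pd.DataFrame) -> pd.DataFrame:
    """Gower dissimilarity on a scaled matrix.

    ``d(i, j)`` is the mean over features observed in *both* specimens of
    ``|x_if - x_jf| / range_f``; after min–max scaling every range is 1.
    Symmetric, zero diagonal, values in [0, 1].
    """
    vals = tm.values if isinstance(tm, TraitMatrix) else tm
    X = vals.to_numpy(float)
    observed = ~np.isnan(X)
    rng = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
    rng = np.where(rng == 0, 1.0, rng)
    Xz = np.where(observed, X, 0.0)
    diff = np.abs(Xz[:, None, :] - Xz[None, :, :]) / rng
    both = observed[:, None, :] & observed[None, :, :]
    counts = both.sum(axis=2)
    if (counts == 0).any():
        ii, jj = np.nonzero(counts == 0)
        off = [(vals.index[i], vals.index[j]) for i, j in zip(ii, jj) if i < j]
        if off:
            raise ValueError(f"specimen pairs share no observed feature: {off[:5]}")
        counts = np.where(counts == 0, 1, counts)
    d = np.where(both, diff, 0.0).sum(axis=2) / counts
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=vals.index, columns=vals.index)


# ---------------------------------------------------------------------------
# non-metric MDS


@dataclass
class OrdinationResult:
    """NMDS configuration with Kruskal stress-1 diagnostics."""

    scores: pd.DataFrame          # specimens × k
    stress: float                 # Kruskal stress-1 of the best restart
    n_restarts: int
    seed: int
    converged: bool
    stress_history: list[float]   # per-iteration stress of the winning run
    pcoa_start_stress: float      # stress-1 evaluated at the classical-scaling start


def _validate_square(d: np.ndarray, name: str = "distance matrix") -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if (d < -1e-12).any():
        raise ValueError(f"{name} must be non-negative")


def _pcoa_config(d: np.ndarray, k: int) -> np.ndarray:
    """Classical scaling (Torgerson) start configuration."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    bmat = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(bmat)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def _config_distances(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def _stress1(dvec: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((dvec ** 2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((dvec - dhat) ** 2).sum()) / denom)


def _nmds_single(d: np.ndarray, x0: np.ndarray, max_iter: int, tol: float):
    """One majorization run: PAVA disparities + Guttman transform updates."""
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    diss = d[iu]
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    x = x0.copy()
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        dx = _config_distances(x)
        dvec = dx[iu]
        dhat = iso.fit(diss, dvec).predict(diss)
        s = _stress1(dvec, dhat)
        history.append(s)
        if len(history) > 1 and history[-2] - s < tol:
            converged = True
            break
        # Guttman transform with disparities as targets
        dhat_m = np.zeros_like(dx)
        dhat_m[iu] = dhat
        dhat_m += dhat_m.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dx > 0, dhat_m / np.where(dx == 0, 1.0, dx), 0.0)
        bmat = -ratio
        np.fill_diagonal(bmat, ratio.sum(axis=1))
        x = bmat @ x / n
        x -= x.mean(axis=0)
    return x, history, converged


def nmds(
    d: pd.DataFrame | np.ndarray,
    k: int = 2,
    restarts: int = 8,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Disparities come from pool-adjacent-violators monotone regression of the
    configuration distances on the input dissimilarities; configurations are
    updated by the Guttman majorization transform.  ``restarts`` runs are
    performed (one classical-scaling start plus random starts) and the
    best-stress solution is returned.  Deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(len(d))
    dm = np.asarray(d, dtype=float)
    _validate_square(dm)
    n = dm.shape[0]
    if n <= 2:
        x = np.zeros((n, k))
        if n == 2:
            x[1, 0] = dm[0, 1]
        scores = pd.DataFrame(x, index=index, columns=[f"nmds{i+1}" for i in range(k)])
        return OrdinationResult(scores, 0.0, 0, seed, True, [0.0], 0.0)

    rng = np.random.default_rng(seed)
    pcoa0 = _pcoa_config(dm, k)
    iu = np.triu_indices(n, 1)
    diss = dm[iu]
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    dvec0 = _config_distances(pcoa0)[iu]
    start_stress = _stress1(dvec0, iso.fit(diss, dvec0).predict(diss))

    inits = [pcoa0] + [rng.normal(size=(n, k)) for _ in range(max(0, restarts - 1))]
    best = None
    for x0 in inits:
        x, history, conv = _nmds_single(dm, x0, max_iter, tol)
        if best is None or history[-1] < best[1][-1]:
            best = (x, history, conv)
    x, history, conv = best
    scores = pd.DataFrame(x, index=index, columns=[f"nmds{i+1}" for i in range(k)])
    return OrdinationResult(scores, history[-1], len(inits), seed, conv, history, start_stress)


def feature_scores(ordination: OrdinationResult, tm: TraitMatrix | pd.DataFrame) -> pd.DataFrame:
    """Weighted-average feature scores in ordination space (vegan ``wascores``).

    Each feature is placed at the weighted average of specimen coordinates,
    the weights being the feature's scaled (non-negative) values.  Features
    with all-zero weight get NaN coordinates and ``defined = False``.
    """
    vals = tm.values if isinstance(tm, TraitMatrix) else tm
    if not vals.index.equals(ordination.scores.index):
        raise ValueError("trait matrix specimens do not match ordination specimens")
    W = vals.to_numpy(float)
    if np.isnan(W).any():
        raise ValueError("scaled matrix must be complete")
    if (W < 0).any():
        raise ValueError("weights must be non-negative (scale to [0, 1] first)")
    S = ordination.scores.to_numpy(float)
    totals = W.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (W.T @ S) / totals[:, None]
    out = pd.DataFrame(scores, index=vals.columns, columns=ordination.scores.columns)
    out["defined"] = totals > 0
    out.loc[~out["defined"], ordination.scores.columns] = np.nan
    return out


# ---------------------------------------------------------------------------
# Mantel test and Welch's t


@dataclass(frozen=True)
class MantelResult:
    r: float
    r_squared: float
    pvalue: float
    permutations: int
    n: int
    seed: int


def mantel_test(
    dx: pd.DataFrame | np.ndarray,
    dy: pd.DataFrame | np.ndarray,
    permutations: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    ``r`` is the Pearson correlation of the upper-triangle vectors; the
    p-value is one-tailed (greater) over ``permutations`` simultaneous
    row/column permutations of one matrix, with the +1 correction
    ``(1 + #[r_perm >= r_obs]) / (permutations + 1)``.
    """
    a = np.asarray(dx, float)
    b = np.asarray(dy, float)
    if a.shape != b.shape:
        raise ValueError("matrices must have identical shape")
    _validate_square(a, "dx")
    _validate_square(b, "dy")
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 specimens")
    if isinstance(dx, pd.DataFrame) and isinstance(dy, pd.DataFrame):
        if not dx.index.equals(dy.index):
            raise ValueError("specimen sets/order differ between matrices")
    iu = np.triu_indices(n, 1)
    xv = a[iu]
    xv = (xv - xv.mean()) / xv.std()
    yv = b[iu]
    if yv.std() == 0 or np.isnan(xv).any():
        raise ValueError("a distance matrix is constant; correlation undefined")
    yz = (yv - yv.mean()) / yv.std()
    m = len(xv)
    r_obs = float((xv * yz).sum() / m)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        p = rng.permutation(n)
        yp = b[np.ix_(p, p)][iu]
        yp = (yp - yp.mean()) / yp.std()
        if (xv * yp).sum() / m >= r_obs - 1e-15:
            count += 1
    pval = (1 + count) / (permutations + 1)
    return MantelResult(r_obs, r_obs ** 2, pval, permutations, n, seed)


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test (two-sided).

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("both samples have zero variance with different means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
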