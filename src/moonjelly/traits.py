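"""Specimen × feature trait matrices for medusa morphometrics.

A :class:`TraitMatrix` holds continuous/meristic/categorical features measured
on jellyfish medusae, the reference size variable (bell diameter, feature code
``f1``, in cm), a locality-group label per specimen, optional decimal-degree
coordinates (aquarium specimens have none), and an explicit missingness mask.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SIZE_FEATURE = "f1"
RESERVED_COLUMNS = ("specimen_id", "locality", "lat", "lon", "aquarium", SIZE_FEATURE)

VALID_KINDS = ("continuous", "meristic", "categorical")


@dataclass(frozen=True)
class FeatureMeta:
    """Metadata for one morphometric feature."""

    code: str
    kind: str = "continuous"
    exclude: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"feature {self.code}: unknown kind {self.kind!r}")


@dataclass
class TraitMatrix:
    """Specimens × features with size variable, locality grouping and mask.

    Parameters
    ----------
    values
        Real matrix indexed by specimen id, columns are feature codes.
        ``NaN`` marks a missing cell (mirrored in :attr:`mask`).
    size
        Bell diameter f1 per specimen (cm, strictly positive).
    locality
        Locality-group label per specimen.
    coords
        ``lat``/``lon`` decimal degrees per specimen; NaN where unknown.
    aquarium
        True for aquarium/lab specimens (no meaningful coordinates).
    features
        Per-feature metadata; defaults to continuous, not excluded.
    imputed
        Boolean frame marking cells filled by allometric estimation.
    """

    values: pd.DataFrame
    size: pd.Series
    locality: pd.Series
    coords: pd.DataFrame | None = None
    aquarium: pd.Series | None = None
    features: dict[str, FeatureMeta] = field(default_factory=dict)
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        if self.aquarium is None:
            self.aquarium = pd.Series(False, index=idx)
        if self.coords is None:
            self.coords = pd.DataFrame(np.nan, index=idx, columns=["lat", "lon"])
        if self.imputed is None:
            self.imputed = pd.DataFrame(False, index=idx, columns=self.values.columns)
        for obj, name in ((self.size, "size"), (self.locality, "locality"),
                          (self.aquarium, "aquarium")):
            if not obj.index.equals(idx):
                raise ValueError(f"{name} index does not match specimen index")
        if not (self.size > 0).all():
            bad = self.size.index[~(self.size > 0)].tolist()
            raise ValueError(f"bell diameter f1 must be strictly positive; offending specimens: {bad}")
        if self.locality.isna().any():
            bad = self.locality.index[self.locality.isna()].tolist()
            raise ValueError(f"specimens without locality label: {bad}")
        for code in self.values.columns:
            self.features.setdefault(code, FeatureMeta(code))

    # -- basic introspection ------------------------------------------------

    @property
    def specimens(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_codes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """True where the cell is missing."""
        return self.values.isna()

    def numeric_features(self) -> list[str]:
        """Feature codes with a numeric role (continuous or meristic)."""
        return [c for c in self.values.columns if self.features[c].kind != "categorical"]

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(
            values=self.values.copy(),
            size=self.size.copy(),
            locality=self.locality.copy(),
            coords=self.coords.copy(),
            aquarium=self.aquarium.copy(),
            features=dict(self.features),
            imputed=self.imputed.copy(),
        )

    def with_values(self, values: pd.DataFrame, imputed: pd.DataFrame | None = None) -> "TraitMatrix":
        """New matrix sharing specimen metadata, replacing the value block."""
        out = self.copy()
        out.values = values.copy()
        out.features = {c: self.features.get(c, FeatureMeta(c)) for c in values.columns}
        if imputed is not None:
            out.imputed = imputed.copy()
        else:
            out.imputed = out.imputed.reindex(columns=values.columns, fill_value=False)
        return out

    def locality_centroids(self) -> pd.DataFrame:
        """Mean (lat, lon) per locality group, NaN where no member has coordinates."""
        return self.coords.groupby(self.locality).mean()

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, feature_meta: str | Path | None = None) -> "TraitMatrix":
        """Read the trait-table dialect: one row per specimen.

        Reserved columns: ``specimen_id, locality, lat, lon, aquarium, f1``;
        every other column is a feature, empty cells are missing.  An optional
        feature-metadata CSV supplies columns ``feature, kind, exclude``.
        """
        df = pd.read_csv(path, dtype={"specimen_id": str, "locality": str})
        missing_cols = [c for c in ("specimen_id", "locality", SIZE_FEATURE) if c not in df.columns]
        if missing_cols:
            raise ValueError(f"trait CSV lacks required columns: {missing_cols}")
        df = df.set_index("specimen_id")
        feat_cols = [c for c in df.columns if c not in RESERVED_COLUMNS[1:]]
        meta: dict[str, FeatureMeta] = {}
        if feature_meta is not None:
            mdf = pd.read_csv(feature_meta)
            for _, row in mdf.iterrows():
                meta[str(row["feature"])] = FeatureMeta(
                    code=str(row["feature"]),
                    kind=str(row.get("kind", "continuous")),
                    exclude=bool(row.get("exclude", False)),
                )
        coords = pd.DataFrame(
            {
                "lat": pd.to_numeric(df["lat"], errors="coerce") if "lat" in df else np.nan,
                "lon": pd.to_numeric(df["lon"], errors="coerce") if "lon" in df else np.nan,
            },
            index=df.index,
        )
        aquarium = (
            df["aquarium"].fillna(False).astype(bool)
            if "aquarium" in df
            else pd.Series(False, index=df.index)
        )
        return cls(
            values=df[feat_cols].apply(pd.to_numeric, errors="coerce"),
            size=pd.to_numeric(df[SIZE_FEATURE]),
            locality=df["locality"],
            coords=coords,
            aquarium=aquarium,
            features=meta,
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, SIZE_FEATURE, self.size)
        out.insert(0, "aquarium", self.aquarium)
        out.insert(0, "lon", self.coords["lon"])
        out.insert(0, "lat", self.coords["lat"])
        out.insert(0, "locality", self.locality)
        out.index.name = "specimen_id"
        out.to_csv(path)
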