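"""Containers for aligned feature tables and cohort sample metadata.

A :class:`FeatureTable` mirrors the shape of an MS-DIAL alignment export:
one row per molecular feature (ionization mode, m/z, retention time,
optional structural annotation) and one peak-area column per sample.
Sample metadata is a plain DataFrame keyed by sample id carrying
participant, visit, sex, age band, BMI, batch, run order and analyzed
volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Leading per-feature columns in the delimited on-disk layout, in order.
FEATURE_COLUMNS = ["mode", "mz", "rt", "annotation"]
#: Optional annotation-metadata columns appended after the leading four.
EXTRA_FEATURE_COLUMNS = ["class", "subclass", "level"]

SAMPLE_COLUMNS = [
    "sample_id",
    "participant_id",
    "visit",
    "sex",
    "age_band",
    "bmi",
    "batch",
    "run_order",
    "volume",
]

MODES = ("ESI+", "ESI-")


@dataclass
class FeatureTable:
    """Features × samples peak-area matrix with per-feature metadata.

    Parameters
    ----------
    features
        One row per feature, indexed by unique ``feature_id``; must carry
        ``mode`` (``ESI+``/``ESI-``), ``mz`` (Da, > 0) and ``rt`` (min).
        ``annotation`` (name or empty), ``class``, ``subclass``, ``level``
        are optional.
    areas
        Nonnegative peak areas; same index as ``features``, one column
        per sample id.
    """

    features: pd.DataFrame
    areas: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.features.index.is_unique:
            raise ValueError("feature_id index must be unique")
        if not self.features.index.equals(self.areas.index):
            raise ValueError("features and areas must share the same index")
        missing = [c for c in ("mode", "mz", "rt") if c not in self.features.columns]
        if missing:
            raise ValueError(f"feature metadata missing columns: {missing}")
        bad_mode = set(self.features["mode"]) - set(MODES)
        if bad_mode:
            raise ValueError(f"unknown ionization modes: {sorted(bad_mode)}")
        if len(self.features) and not (self.features["mz"] > 0).all():
            raise ValueError("all m/z values must be positive")
        if len(self.areas.columns) and (self.areas.to_numpy() < 0).any():
            raise ValueError("peak areas must be nonnegative")

    # -- basic interface -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.areas.columns

    def __len__(self) -> int:
        return len(self.features)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.areas.copy())

    def subset(self, feature_ids) -> "FeatureTable":
        ids = pd.Index(feature_ids)
        return FeatureTable(self.features.loc[ids].copy(), self.areas.loc[ids].copy())

    def drop(self, feature_ids) -> "FeatureTable":
        ids = pd.Index(feature_ids)
        keep = self.features.index.difference(ids, sort=False)
        return self.subset(keep)

    def mean_areas(self) -> pd.Series:
        """Per-feature mean peak area across all samples."""
        return self.areas.mean(axis=1)

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the combined layout: feature_id + leading metadata columns
        followed by one column per sample."""
        cols = [c for c in FEATURE_COLUMNS + EXTRA_FEATURE_COLUMNS if c in self.features.columns]
        out = pd.concat([self.features[cols], self.areas], axis=1)
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        raw = pd.read_csv(path, sep="\t", index_col="feature_id")
        meta_cols = [c for c in FEATURE_COLUMNS + EXTRA_FEATURE_COLUMNS if c in raw.columns]
        sample_cols = [c for c in raw.columns if c not in meta_cols]
        return cls(raw[meta_cols].copy(), raw[sample_cols].astype(float))


def validate_sample_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata contract and return the frame indexed by
    sample_id.

    Requires unique (participant_id, visit) pairs and strictly positive
    analyzed volumes.
    """
    meta = metadata.copy()
    if meta.index.name != "sample_id":
        if "sample_id" not in meta.columns:
            raise ValueError("sample metadata needs a sample_id column or index")
        meta = meta.set_index("sample_id")
    missing = [c for c in SAMPLE_COLUMNS[1:] if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    if meta.duplicated(subset=["participant_id", "visit"]).any():
        raise ValueError("(participant_id, visit) pairs must be unique")
    if not (meta["volume"] > 0).all():
        raise ValueError("analyzed volumes must be positive")
    return meta


def align_samples(table: FeatureTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Return metadata rows for exactly the table's samples, in table order."""
    meta = validate_sample_metadata(metadata)
    missing = table.sample_ids.difference(meta.index)
    if len(missing):
        raise ValueError(f"samples missing from metadata: {list(missing)[:5]}")
    return meta.loc[table.sample_ids]


def series_to_matrix(series: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Pivot a tidy (substance, participant, visit, value) table to a
    substances × (participant, visit) matrix."""
    return series.pivot_table(
        index="substance", columns=["participant", "visit"], values=value_col, aggfunc="first"
    )


def rng_from_seed(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Normalize a seed or generator into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
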