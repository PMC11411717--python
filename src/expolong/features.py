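"""Reduction of an aligned two-mode feature table to the analysis matrix.

The documented pipeline order is blank filtering, cross-mode
deduplication, internal-standard PCA drift correction, then
volume normalization; :func:`process` runs the stages in that order and
logs feature counts after each one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .chem import neutral_from_mz
from .tables import FeatureTable

logger = logging.getLogger(__name__)

DEFAULT_MASS_TOL = 0.002  # Da, on (de)protonation-adjusted neutral masses
DEFAULT_RT_TOL = 0.2  # minutes


def neutral_mass(mz: float, mode: str) -> float:
    """Neutral mass from observed m/z after adjusting for (de)protonation.

    ESI+ features lose one proton mass, ESI- features gain one.
    """
    return neutral_from_mz(mz, mode)


def blank_filter(
    table: FeatureTable, blank_samples: list[str], min_ratio: float = 5.0
) -> FeatureTable:
    """Drop features whose mean sample area is below ``min_ratio`` times
    the mean blank area.

    Features with an all-zero blank mean are retained regardless, and a
    ratio exactly equal to ``min_ratio`` is retained (>= rule). Blank
    columns are removed from the output. Removed feature ids are logged.
    """
    blank_samples = list(blank_samples)
    missing = set(blank_samples) - set(table.sample_ids)
    if missing or not blank_samples:
        raise ValueError(f"blank samples absent from table: {sorted(missing)}")
    if min_ratio <= 1:
        warnings.warn(f"blank-filter min_ratio={min_ratio} <= 1 retains blank-level signal")

    sample_cols = [c for c in table.sample_ids if c not in blank_samples]
    blank_mean = table.areas[blank_samples].mean(axis=1)
    sample_mean = table.areas[sample_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sample_mean / blank_mean
    keep = (blank_mean == 0) | (ratio >= min_ratio)
    removed = list(table.feature_ids[~keep])
    logger.info("blank_filter: removed %d of %d features", len(removed), len(table))
    if removed:
        logger.debug("blank_filter removed ids: %s", removed)
    return FeatureTable(
        table.features.loc[keep].copy(), table.areas.loc[keep, sample_cols].copy()
    )


def _qualifying_pairs(
    features: pd.DataFrame, mass_tol: float, rt_tol: float
) -> list[tuple[str, str]]:
    """All cross-mode pairs within both tolerances, via a sorted-mass sweep."""
    adj = np.array([neutral_mass(m, md) for m, md in zip(features["mz"], features["mode"])])
    order = np.argsort(adj, kind="stable")
    ids = features.index.to_numpy()[order]
    modes = features["mode"].to_numpy()[order]
    rts = features["rt"].to_numpy(float)[order]
    masses = adj[order]
    pairs = []
    for i in range(len(masses)):
        j = i + 1
        while j < len(masses) and masses[j] - masses[i] <= mass_tol:
            if modes[i] != modes[j] and abs(rts[i] - rts[j]) <= rt_tol:
                pairs.append((ids[i], ids[j]))
            j += 1
    return pairs


def dedup_cross_mode(
    table: FeatureTable,
    mass_tol: float = DEFAULT_MASS_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> tuple[FeatureTable, list[str]]:
    """Remove redundant cross-mode detections of the same compound.

    Two features in opposite ionization modes are redundant when their
    (de)protonation-adjusted neutral masses differ by at most ``mass_tol``
    and their retention times by at most ``rt_tol``; the member with the
    lower mean peak area is discarded. Chains are resolved greedily from
    the highest mean area downward, re-checking pairs after each removal:
    a feature is dropped only when a *surviving* partner with higher mean
    area covers it, so the output contains no remaining qualifying pair
    and every removed feature keeps a surviving partner. Mean-area ties
    drop the ESI- member.
    """
    if len(table) == 0:
        return table.copy(), []
    pairs = _qualifying_pairs(table.features, mass_tol, rt_tol)
    if not pairs:
        return table.copy(), []

    mean_area = table.mean_areas()
    # keep priority: higher mean area wins; tie -> ESI+ wins, then id
    priority = {
        fid: (mean_area[fid], 1 if table.features.at[fid, "mode"] == "ESI+" else 0, fid)
        for fid in table.feature_ids
    }
    partners: dict[str, set[str]] = {}
    for a, b in pairs:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    removed: list[str] = []
    alive = set(table.feature_ids)
    for fid in sorted(partners, key=priority.__getitem__, reverse=True):
        if fid not in alive:
            continue
        for p in partners[fid]:
            if p in alive:  # processed later, so strictly lower priority
                alive.discard(p)
                removed.append(p)
    keep = [fid for fid in table.feature_ids if fid in alive]
    logger.info("dedup_cross_mode: removed %d of %d features", len(removed), len(table))
    return table.subset(keep), removed


def _log_with_zero_imputation(areas: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """log10 areas with per-feature zeros imputed at half the smallest
    nonzero area of that feature; returns (log matrix, zero mask)."""
    values = areas.to_numpy(float)
    zero_mask = values <= 0
    imputed = values.copy()
    for i in np.where(zero_mask.any(axis=1))[0]:
        nonzero = values[i][~zero_mask[i]]
        fill = nonzero.min() / 2 if len(nonzero) else 1.0
        imputed[i, zero_mask[i]] = fill
    return np.log10(imputed), zero_mask


def is_pca_correct(
    table: FeatureTable, is_matrix: pd.DataFrame, n_components: int = 2
) -> FeatureTable:
    """Correct instrumental/batch drift using PCA scores of the
    internal-standard intensities.

    The IS matrix (channels × samples) is log-transformed and
    unit-variance scaled per channel; per-sample scores on the first
    ``n_components`` principal components summarize the shared drift.
    Each feature's log area is regressed on those scores and replaced by
    residual + mean, then back-transformed, so corrected areas stay
    positive. Zeros are preserved as zeros. Constant IS channels are
    dropped with a warning; if none remain the table is returned
    unchanged.
    """
    missing = set(table.sample_ids) - set(is_matrix.columns)
    if missing:
        raise ValueError(f"IS matrix missing samples: {sorted(missing)[:5]}")
    n_samples = len(table.sample_ids)
    if n_components >= n_samples:
        raise ValueError("n_components must be smaller than the number of samples")

    is_values = is_matrix[table.sample_ids].to_numpy(float)
    if (is_values <= 0).any():
        raise ValueError("internal-standard intensities must be positive")
    log_is = np.log10(is_values)
    sd = log_is.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {constant.sum()} constant internal-standard channel(s)"
        )
        log_is, sd = log_is[~constant], sd[~constant]
    if log_is.shape[0] == 0:
        warnings.warn("no usable internal-standard channels; table returned unchanged")
        return table.copy()
    if log_is.shape[0] < n_components:
        n_components = log_is.shape[0]

    scaled = ((log_is.T - log_is.mean(axis=1)) / sd)  # samples x channels
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(scaled)
    scores -= scores.mean(axis=0)  # centered regressors

    log_areas, zero_mask = _log_with_zero_imputation(table.areas)
    centered = log_areas - log_areas.mean(axis=1, keepdims=True)
    beta, *_ = np.linalg.lstsq(scores, centered.T, rcond=None)  # k x features
    corrected_log = log_areas - (scores @ beta).T
    corrected = 10.0 ** corrected_log
    corrected[zero_mask] = 0.0
    out_areas = pd.DataFrame(corrected, index=table.feature_ids, columns=table.sample_ids)
    return FeatureTable(table.features.copy(), out_areas)


def volume_normalize(table: FeatureTable, metadata: pd.DataFrame) -> FeatureTable:
    """Divide each sample's areas by its analyzed volume.

    Samples with a missing or non-positive volume are dropped with a
    warning; samples absent from the metadata are an error.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    missing = set(table.sample_ids) - set(meta.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
    volumes = meta.loc[list(table.sample_ids), "volume"].astype(float)
    bad = volumes.isna() | (volumes <= 0)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} sample(s) without a valid volume")
    keep = list(volumes.index[~bad])
    areas = table.areas[keep].div(volumes[keep], axis=1)
    return FeatureTable(table.features.copy(), areas)


@dataclass
class ProcessLog:
    """Feature/sample counts recorded after each pipeline stage."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, stage: str, table: FeatureTable) -> None:
        self.stages.append((stage, len(table), len(table.sample_ids)))
        logger.info("%s: %d features x %d samples", stage, len(table), len(table.sample_ids))


def process(
    table: FeatureTable,
    metadata: pd.DataFrame,
    is_matrix: pd.DataFrame,
    blank_samples: list[str] | None = None,
    min_ratio: float = 5.0,
    mass_tol: float = DEFAULT_MASS_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
    n_components: int = 2,
) -> tuple[FeatureTable, ProcessLog]:
    """Run the full reduction in the documented order:
    blank_filter -> dedup_cross_mode -> is_pca_correct -> volume_normalize."""
    log = ProcessLog()
    log.record("input", table)
    if blank_samples:
        table = blank_filter(table, blank_samples, min_ratio)
        log.record("blank_filter", table)
    table, _ = dedup_cross_mode(table, mass_tol, rt_tol)
    log.record("dedup_cross_mode", table)
    table = is_pca_correct(table, is_matrix, n_components)
    log.record("is_pca_correct", table)
    table = volume_normalize(table, metadata)
    log.record("volume_normalize", table)
    return table, log
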