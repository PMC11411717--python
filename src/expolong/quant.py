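"""Targeted quantification, semiquantification and censoring substitution.

Targeted analytes are quantified by solvent calibration curves with
internal standards. Untargeted discoveries are semiquantified by
reference standardization: the ratio of a sample's peak area to the area
in a pooled reference plasma of externally determined concentration.
Left-censored values follow the biomonitoring substitution convention:
detected-below-MLOQ values are set to MLOQ/2 and nondetects to MLOQ/4.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

STATUS_QUANTIFIED = "quantified"
STATUS_BELOW_MLOQ = "below_mloq"
STATUS_NONDETECT = "nondetect"
STATUSES = (STATUS_QUANTIFIED, STATUS_BELOW_MLOQ, STATUS_NONDETECT)

#: statuses counted as "detected" for detection-frequency purposes:
#: a below-MLOQ signal is present, just not quantifiable.
DETECTED_STATUSES = (STATUS_QUANTIFIED, STATUS_BELOW_MLOQ)


@dataclass
class SubstanceSeries:
    """Longitudinal values for one substance, indexed by (participant, visit).

    ``data`` columns: participant, visit, value, status.
    """

    substance: str
    data: pd.DataFrame
    mloq: float | None = None

    def __post_init__(self) -> None:
        required = {"participant", "visit", "value", "status"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"series data missing columns: {sorted(missing)}")
        bad = set(self.data["status"]) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown statuses: {sorted(bad)}")

    def values_by_participant(self) -> pd.Series:
        return self.data.set_index(["participant", "visit"])["value"]


@dataclass
class CalibrationCurve:
    """Linear analyte/IS response-ratio calibration."""

    analyte: str
    levels: np.ndarray
    response_ratios: np.ndarray
    slope: float
    intercept: float
    mloq: float | None = None

    def predict(self, conc):
        return self.slope * np.asarray(conc, float) + self.intercept

    def invert(self, ratio):
        return (np.asarray(ratio, float) - self.intercept) / self.slope


def fit_calibration(
    levels,
    ratios,
    analyte: str = "",
    mloq: float | None = None,
    weighted: bool = False,
) -> CalibrationCurve:
    """Fit a least-squares calibration line of response ratio on
    concentration; optional 1/x weighting.

    Curves with non-positive slope are rejected.
    """
    levels = np.asarray(levels, float)
    ratios = np.asarray(ratios, float)
    if len(levels) < 3:
        raise ValueError("calibration needs at least 3 levels")
    if weighted:
        if (levels <= 0).any():
            raise ValueError("1/x weighting requires positive levels")
        w = 1.0 / levels
    else:
        w = np.ones_like(levels)
    X = np.column_stack([np.ones_like(levels), levels])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], ratios * sw, rcond=None)
    intercept, slope = coef
    if slope <= 0:
        raise ValueError(f"rejected calibration for {analyte!r}: slope {slope:.3g} <= 0")
    return CalibrationCurve(analyte, levels, ratios, float(slope), float(intercept), mloq)


def reference_standardize(
    feature_areas: pd.Series,
    ref_area: float | dict,
    ref_conc: float,
    batches: pd.Series | None = None,
) -> pd.Series:
    """Semiquantify a feature by ratio to the pooled reference plasma.

    ``concentration_s = area_s / ref_area * ref_conc`` per sample, where
    ``ref_conc`` is the externally determined (standard-addition)
    concentration in the pooled plasma. When ``ref_area`` is a mapping
    from batch label to the batch's pooled-plasma area and ``batches``
    gives each sample's batch, the standardization is applied per batch.
    """
    areas = feature_areas.astype(float)
    if isinstance(ref_area, dict):
        if batches is None:
            raise ValueError("per-batch ref_area requires a batches series")
        ref = batches.map(ref_area).astype(float).reindex(areas.index)
        if ref.isna().any():
            raise ValueError("missing pooled-plasma area for some batch")
    else:
        ref = pd.Series(float(ref_area), index=areas.index)
    if (ref <= 0).any():
        raise ValueError("substance not semiquantifiable: reference area is zero")
    return areas / ref * ref_conc


def censor_substitute(series: SubstanceSeries, mloq: float | None = None) -> SubstanceSeries:
    """Substitute censored values: below-MLOQ -> MLOQ/2, nondetect -> MLOQ/4.

    Quantified values and all statuses are preserved; the operation is
    idempotent.
    """
    mloq = mloq if mloq is not None else series.mloq
    data = series.data.copy()
    censored = data["status"].isin([STATUS_BELOW_MLOQ, STATUS_NONDETECT])
    if censored.any():
        if mloq is None or mloq <= 0:
            raise ValueError(f"{series.substance}: censored values need a positive MLOQ")
        data.loc[data["status"] == STATUS_BELOW_MLOQ, "value"] = mloq / 2
        data.loc[data["status"] == STATUS_NONDETECT, "value"] = mloq / 4
    return replace(series, data=data, mloq=mloq)


def detection_frequency(series: SubstanceSeries) -> float:
    """Fraction of samples in which the substance was detected
    (quantified or present below MLOQ)."""
    if len(series.data) == 0:
        raise ValueError("empty series")
    return float(series.data["status"].isin(DETECTED_STATUSES).mean())


def series_from_concentrations(
    substance: str,
    values: pd.Series,
    statuses: pd.Series,
    mloq: float | None = None,
) -> SubstanceSeries:
    """Assemble a SubstanceSeries from (participant, visit)-indexed
    concentration and status series."""
    idx = values.index
    data = pd.DataFrame(
        {
            "participant": idx.get_level_values(0),
            "visit": idx.get_level_values(1),
            "value": values.to_numpy(float),
            "status": statuses.reindex(idx).to_numpy(),
        }
    )
    return SubstanceSeries(substance, data, mloq)


def series_table(series_list: list[SubstanceSeries]) -> pd.DataFrame:
    """Tidy concentrations table (substance, participant, visit, value, status)."""
    frames = []
    for s in series_list:
        d = s.data.copy()
        d.insert(0, "substance", s.substance)
        frames.append(d)
    return pd.concat(frames, ignore_index=True)
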