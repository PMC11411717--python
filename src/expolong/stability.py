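"""Longitudinal stability: ICC estimation, reproducibility bins and the
four-quadrant exposure typology.

The intraclass correlation coefficient used here is the one-way
random-effects, single-measurement form ICC(1): the ratio of
between-individual variance to total (between + within) variance of
repeated measurements. A high ICC means individuals keep their rank
across visits; combined with detection frequency (DF) it places each
substance in one of four exposure types — rare-stable, common-stable,
common-unstable, rare-unstable — with a gap region left unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ICC_POOR_MAX = 0.40
ICC_EXCELLENT_MIN = 0.75

TYPE1 = "type1_rare_stable"
TYPE2 = "type2_common_stable"
TYPE3 = "type3_common_unstable"
TYPE4 = "type4_rare_unstable"
UNCLASSIFIED = "unclassified"


@dataclass
class StabilityRecord:
    substance: str
    substance_class: str
    df: float
    ms_between: float
    ms_within: float
    icc_raw: float
    icc: float
    icc_bin: str
    exposure_type: str


def _groups(values: np.ndarray, participants: np.ndarray) -> list[np.ndarray]:
    out = []
    for pid in pd.unique(participants):
        v = values[participants == pid]
        v = v[~np.isnan(v)]
        if len(v) >= 2:  # <2 visits carries no within-individual information
            out.append(v)
    return out


def icc_oneway(values, participants) -> tuple[float, float, float]:
    """One-way random-effects ICC from a vector of values grouped by
    participant.

    Returns ``(icc, ms_between, ms_within)`` with
    ``ICC = (MSB - MSW) / (MSB + (k - 1) MSW)`` where k is the harmonic
    mean of per-participant visit counts. Negative estimates are clamped
    to 0 (use :func:`icc_components` for the raw value). Zero total
    variance raises."""
    icc, msb, msw, _raw = icc_components(values, participants)
    return icc, msb, msw


def icc_components(values, participants) -> tuple[float, float, float, float]:
    """As :func:`icc_oneway` but also returning the unclamped estimate."""
    values = np.asarray(values, float)
    participants = np.asarray(participants)
    groups = _groups(values, participants)
    if len(groups) < 2:
        raise ValueError("ICC needs >=2 participants with >=2 visits each")
    counts = np.array([len(g) for g in groups], float)
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    n_total = counts.sum()
    n_groups = len(groups)
    msb = float((counts * (means - grand) ** 2).sum() / (n_groups - 1))
    msw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)) / (n_total - n_groups))
    if msb == 0 and msw == 0:
        raise ValueError("zero total variance: ICC undefined")
    k = stats.hmean(counts)
    raw = (msb - msw) / (msb + (k - 1) * msw)
    return float(np.clip(raw, 0.0, 1.0)), msb, msw, float(raw)


def icc_matrix(values: np.ndarray, participants: np.ndarray) -> np.ndarray:
    """Vectorized one-way ICC over many substances at once.

    ``values`` has shape (n_substances, n_observations) with complete
    (balanced) data; ``participants`` labels the observation axis.
    """
    values = np.asarray(values, float)
    participants = np.asarray(participants)
    pids, inverse = np.unique(participants, return_inverse=True)
    counts = np.bincount(inverse).astype(float)
    if (counts < 2).any() or len(pids) < 2:
        raise ValueError("balanced ICC needs >=2 participants with >=2 visits")
    sums = np.zeros((values.shape[0], len(pids)))
    np.add.at(sums.T, inverse, values.T)
    means = sums / counts
    grand = values.mean(axis=1, keepdims=True)
    n_total = values.shape[1]
    msb = ((means - grand) ** 2 * counts).sum(axis=1) / (len(pids) - 1)
    within = ((values - means[:, inverse]) ** 2).sum(axis=1)
    msw = within / (n_total - len(pids))
    k = stats.hmean(counts)
    raw = (msb - msw) / (msb + (k - 1) * msw)
    return np.clip(raw, 0.0, 1.0)


def icc_twoway(values, participants, visits) -> tuple[float, float, float]:
    """Two-way random-effects absolute-agreement ICC(2,1), for balanced
    data, as an alternative to the default one-way form."""
    frame = pd.DataFrame(
        {"value": np.asarray(values, float), "pid": participants, "visit": visits}
    ).dropna()
    wide = frame.pivot(index="pid", columns="visit", values="value")
    if wide.isna().any().any():
        raise ValueError("two-way ICC requires balanced complete data")
    data = wide.to_numpy()
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((data - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return float(np.clip(icc, 0.0, 1.0)), float(msr), float(mse)


def icc_bin(icc: float) -> str:
    """Reproducibility bin: <0.40 poor, 0.40-0.75 fair to good, >0.75
    excellent."""
    if not 0 <= icc <= 1:
        raise ValueError(f"ICC {icc} out of [0, 1]")
    if icc < ICC_POOR_MAX:
        return "poor"
    if icc <= ICC_EXCELLENT_MIN:
        return "fair_good"
    return "excellent"


def classify_exposure_type(
    icc: float,
    df: float,
    df_low: float = 0.20,
    df_high: float = 0.80,
    icc_stable: float = 0.6,
    icc_unstable: float = 0.4,
) -> str:
    """Place a substance in the DF x ICC exposure-type plane.

    Type 1 rare-stable (DF <= 20%, ICC >= 0.6), Type 2 common-stable
    (DF >= 80%, ICC >= 0.6), Type 3 common-unstable (DF >= 80%,
    ICC < 0.4), Type 4 rare-unstable (DF <= 20%, ICC < 0.4); mid-DF or
    intermediate-ICC substances are unclassified. DF thresholds are
    inclusive.
    """
    if not 0 <= icc <= 1 or not 0 <= df <= 1:
        raise ValueError(f"icc={icc}, df={df} out of [0, 1]")
    rare, common = df <= df_low, df >= df_high
    stable, unstable = icc >= icc_stable, icc < icc_unstable
    if rare and stable:
        return TYPE1
    if common and stable:
        return TYPE2
    if common and unstable:
        return TYPE3
    if rare and unstable:
        return TYPE4
    return UNCLASSIFIED


def stability_record(
    substance: str,
    substance_class: str,
    values,
    participants,
    df: float,
) -> StabilityRecord:
    """Full per-substance stability summary from longitudinal values on
    the analysis scale (default: log10 substituted concentrations)."""
    icc, msb, msw, raw = icc_components(values, participants)
    return StabilityRecord(
        substance=substance,
        substance_class=substance_class,
        df=df,
        ms_between=msb,
        ms_within=msw,
        icc_raw=raw,
        icc=icc,
        icc_bin=icc_bin(icc),
        exposure_type=classify_exposure_type(icc, df),
    )


def records_to_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in records])
    return frame.rename(columns={"substance_class": "class"})


def summarize_stability(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-class stability summary plus between-class ICC comparisons.

    ``records`` needs columns class, icc, exposure_type. Returns the
    per-class table (mean/median ICC, fraction <0.4 and >0.75, exposure
    type counts) and a dict of tests: pairwise two-tailed t-tests on
    class ICC means, one-way ANOVA, and Tukey HSD. With a single class
    the comparisons are omitted.
    """
    rows = []
    for cls, grp in records.groupby("class"):
        row = {
            "class": cls,
            "n": len(grp),
            "mean_icc": grp["icc"].mean(),
            "median_icc": grp["icc"].median(),
            "frac_poor": (grp["icc"] < ICC_POOR_MAX).mean(),
            "frac_excellent": (grp["icc"] > ICC_EXCELLENT_MIN).mean(),
        }
        for t in (TYPE1, TYPE2, TYPE3, TYPE4, UNCLASSIFIED):
            row[f"n_{t}"] = int((grp["exposure_type"] == t).sum())
        rows.append(row)
    summary = pd.DataFrame(rows)

    classes = list(summary["class"])
    tests: dict = {}
    if len(classes) >= 2:
        groups = [records.loc[records["class"] == c, "icc"].to_numpy() for c in classes]
        pairwise = {}
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    t, p = stats.ttest_ind(groups[i], groups[j])
                pairwise[(classes[i], classes[j])] = {"t": float(t), "p": float(p)}
        tests["t_tests"] = pairwise
        f, p = stats.f_oneway(*groups)
        tests["anova"] = {"F": float(f), "p": float(p)}
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tukey = pairwise_tukeyhsd(records["icc"].to_numpy(), records["class"].to_numpy())
        tests["tukey"] = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
    return summary, tests
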