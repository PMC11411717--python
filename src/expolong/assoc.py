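"""Group-difference testing and repeated-measures exposure-outcome models.

Sex differences are tested per substance with a rank-based two-group
comparison after a recorded Shapiro-Wilk normality check, Bonferroni
corrected over the tested panel. Exposure-outcome associations use a
linear mixed model on log10-log10 scale with participant-specific random
intercepts and slopes, optionally adjusted for baseline age and BMI,
falling back to a random-intercept-only fit when the random-slope
covariance is singular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .quant import SubstanceSeries, detection_frequency


def bonferroni(p, m: int):
    """Bonferroni-adjusted p-value: min(1, m·p)."""
    return np.minimum(1.0, np.asarray(p, float) * m)


@dataclass
class GroupTestResult:
    substance: str
    mean_male: float
    mean_female: float
    statistic: float
    p_raw: float
    p_bonferroni: float
    normality_p: float
    n_male: int
    n_female: int
    skipped: bool = False
    reason: str = ""


def _participant_sex(metadata: pd.DataFrame) -> pd.Series:
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    return meta.drop_duplicates("participant_id").set_index("participant_id")["sex"]


def sex_difference_tests(
    series_list: list[SubstanceSeries],
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    df_gate: float = 0.10,
    test: str = "ranksum",
) -> pd.DataFrame:
    """Per-substance male vs female comparison on the concentration scale.

    Substances at detection frequency <= ``df_gate`` are excluded before
    testing. ``test='ranksum'`` (default) uses the Mann-Whitney U test on
    all samples; ``test='signed_rank'`` applies the Wilcoxon signed-rank
    statistic to the sorted per-individual means of the two sexes
    truncated to equal length. Shapiro-Wilk normality p-values are
    recorded per substance. Bonferroni correction spans the substances
    actually tested.
    """
    sex_of = _participant_sex(metadata)
    if set(sex_of.unique()) < {"M", "F"}:
        raise ValueError("both sexes must be present")
    results: list[GroupTestResult] = []
    for s in series_list:
        if detection_frequency(s) <= df_gate:
            continue
        d = s.data.copy()
        d["sex"] = d["participant"].map(sex_of)
        male = d.loc[d["sex"] == "M", "value"].to_numpy(float)
        female = d.loc[d["sex"] == "F", "value"].to_numpy(float)
        base = GroupTestResult(
            substance=s.substance,
            mean_male=float(male.mean()) if len(male) else np.nan,
            mean_female=float(female.mean()) if len(female) else np.nan,
            statistic=np.nan, p_raw=np.nan, p_bonferroni=np.nan,
            normality_p=np.nan, n_male=len(male), n_female=len(female),
        )
        if len(male) == 0 or len(female) == 0:
            base.skipped, base.reason = True, "one sex only"
        elif np.std(np.concatenate([male, female])) == 0:
            base.skipped, base.reason = True, "constant values"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                base.normality_p = float(stats.shapiro(np.concatenate([male, female])).pvalue)
            if test == "ranksum":
                stat, p = stats.mannwhitneyu(male, female, alternative="two-sided")
            elif test == "signed_rank":
                mm = np.sort(d[d["sex"] == "M"].groupby("participant")["value"].mean().to_numpy())
                fm = np.sort(d[d["sex"] == "F"].groupby("participant")["value"].mean().to_numpy())
                n = min(len(mm), len(fm))
                stat, p = stats.wilcoxon(mm[:n], fm[:n])
            else:
                raise ValueError(f"unknown test {test!r}")
            base.statistic, base.p_raw = float(stat), float(p)
        results.append(base)
    tested = [r for r in results if not r.skipped]
    m = len(tested)
    for r in tested:
        r.p_bonferroni = float(bonferroni(r.p_raw, m))
    out = pd.DataFrame([vars(r) for r in results])
    out["significant"] = out["p_bonferroni"] < alpha
    return out


@dataclass
class LmmResult:
    outcome: str
    exposure: str
    slope: float
    slope_se: float
    p_raw: float
    p_bonferroni: float | None
    adjusted_for: str
    var_random_intercept: float
    var_random_slope: float | None
    n_obs: int
    n_participants: int
    converged: bool
    random_slope_dropped: bool


def _baseline_covariates(metadata: pd.DataFrame) -> pd.DataFrame:
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    base = meta.sort_values("visit").drop_duplicates("participant_id").set_index("participant_id")
    return base[[c for c in ("age", "bmi", "sex") if c in base.columns]]


def fit_exposure_outcome_lmm(
    outcome_series: SubstanceSeries,
    exposure_series: SubstanceSeries,
    metadata: pd.DataFrame,
    adjust: bool = False,
    stratify_sex: str | None = None,
) -> LmmResult:
    """Mixed model log10(outcome) ~ log10(exposure) [+ baseline age + BMI]
    with participant random intercepts and slopes.

    Values must be positive (run censoring substitution first). On a
    singular or non-converged random-slope fit the model is refit with
    random intercepts only and flagged via ``random_slope_dropped``.
    ``stratify_sex`` restricts to one sex (e.g. ``"F"``).
    """
    y = outcome_series.values_by_participant().rename("outcome")
    x = exposure_series.values_by_participant().rename("exposure")
    d = pd.concat([y, x], axis=1).dropna().reset_index()
    if (d[["outcome", "exposure"]] <= 0).any().any():
        raise ValueError(
            "non-positive values are not log-transformable; apply quant.censor_substitute first"
        )
    base = _baseline_covariates(metadata)
    d = d.join(base, on="participant")
    if stratify_sex is not None:
        d = d[d["sex"] == stratify_sex]
    counts = d.groupby("participant").size()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("each participant needs >=2 visits")
    d["log_outcome"] = np.log10(d["outcome"])
    d["log_exposure"] = np.log10(d["exposure"])

    fixed = "log_outcome ~ log_exposure" + (" + age + bmi" if adjust else "")

    def _fit(re_formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(fixed, d, groups=d["participant"], re_formula=re_formula)
            return model.fit(reml=True)

    dropped = False
    fit = _fit("~log_exposure")
    cov_re = fit.cov_re.to_numpy()
    singular = (
        not fit.converged
        or np.any(np.diag(cov_re) <= 1e-10)
        or np.linalg.matrix_rank(cov_re) < cov_re.shape[0]
        or not np.isfinite(fit.bse["log_exposure"])
    )
    if singular:
        dropped = True
        fit = _fit("1")
        # intercept variance itself at the zero boundary: the model is
        # effectively ordinary least squares; report the OLS fit
        if fit.cov_re.to_numpy()[0, 0] <= 1e-6 * fit.scale:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ols = smf.ols(fixed, d).fit()
            return LmmResult(
                outcome=outcome_series.substance,
                exposure=exposure_series.substance,
                slope=float(ols.params["log_exposure"]),
                slope_se=float(ols.bse["log_exposure"]),
                p_raw=float(ols.pvalues["log_exposure"]),
                p_bonferroni=None,
                adjusted_for="age+BMI" if adjust else "none",
                var_random_intercept=0.0,
                var_random_slope=None,
                n_obs=int(len(d)),
                n_participants=int(len(counts)),
                converged=True,
                random_slope_dropped=True,
            )
    cov_re = fit.cov_re.to_numpy()
    return LmmResult(
        outcome=outcome_series.substance,
        exposure=exposure_series.substance,
        slope=float(fit.params["log_exposure"]),
        slope_se=float(fit.bse["log_exposure"]),
        p_raw=float(fit.pvalues["log_exposure"]),
        p_bonferroni=None,
        adjusted_for="age+BMI" if adjust else "none",
        var_random_intercept=float(cov_re[0, 0]),
        var_random_slope=None if dropped else float(cov_re[1, 1]),
        n_obs=int(len(d)),
        n_participants=int(len(counts)),
        converged=bool(fit.converged),
        random_slope_dropped=dropped,
    )


def exposure_panel_lmm(
    outcome_series: SubstanceSeries,
    exposure_panel: list[SubstanceSeries],
    metadata: pd.DataFrame,
    adjust: bool = False,
    stratify_sex: str | None = None,
) -> pd.DataFrame:
    """Fit the outcome against each exposure in a panel and Bonferroni
    correct across the panel."""
    results = [
        fit_exposure_outcome_lmm(outcome_series, e, metadata, adjust, stratify_sex)
        for e in exposure_panel
    ]
    m = len(results)
    for r in results:
        r.p_bonferroni = float(bonferroni(r.p_raw, m))
    return pd.DataFrame([vars(r) for r in results])
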