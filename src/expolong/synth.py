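"""Synthetic longitudinal exposome cohorts with known ground truth.

The generator emulates the statistical structure of a repeated-measures
wellness cohort measured by two-mode LC-HRMS: 46 participants sampled at
6 visits (balanced sexes), hundreds of substances whose log10
concentrations decompose into an individual-level random effect and
visit-level noise (so the true ICC σb²/(σb²+σw²) is known per
substance), detection frequencies spread from rare to ubiquitous via
substance-specific MLOQs, multiplicative batch/run-order drift shared
between analytes and isotope-labeled internal standards of the same
ionization mode, redundant cross-mode feature pairs, correlated
parent-metabolite families, and a planted exposure-hormone association
with participant-specific random slopes.

Peak areas, not concentrations, are what the instrument reports: each
substance gets a fixed response factor, areas below a mode-specific
noise floor are censored to zero (nondetect), and concentrations below
the MLOQ are flagged detected-but-unquantifiable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .chem import mz_from_neutral, neutral_from_mz
from .suspects import DEFAULT_SHIFTS, theoretical_mz
from .tables import FeatureTable, rng_from_seed

LN10 = np.log(10.0)


@dataclass
class CohortDesign:
    """Study design and nuisance-structure parameters of a simulated cohort."""

    n_individuals: int = 46
    n_visits: int = 6
    sex_balance: float = 0.5  # fraction female
    age_bands: tuple[str, ...] = ("40-49", "50-59", "60-69")
    bmi_mean: float = 25.0
    bmi_sd: float = 4.0
    n_batches: int = 4
    seed: int = 0
    volume_range: tuple[float, float] = (50.0, 200.0)  # µL analyzed
    drift_batch_sd: float = 0.10  # sd of log10 per-batch factor
    drift_trend_amplitude: float = 0.30  # run-order trend, 1 -> 1+amplitude
    is_noise_cv: float = 0.05  # multiplicative noise on IS channels
    n_is_channels: int = 10  # split across the two modes
    noise_floor: float = 500.0  # area units; below -> nondetect
    n_blanks: int = 3
    blank_fraction: float = 0.01  # blank signal as fraction of mean area

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_visits < 2:
            raise ValueError("n_visits must be >= 2")
        if not 0 <= self.sex_balance <= 1:
            raise ValueError("sex_balance must be in [0, 1]")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


@dataclass
class SubstanceSpec:
    """True generative parameters of one substance.

    log10 concentration of individual i at visit j is
    ``log_mean + sex_effect·1[female] + b_i + e_ij`` with
    ``b_i ~ N(0, sigma_between²)`` and ``e_ij ~ N(0, sigma_within²)``,
    so the true ICC is ``σb²/(σb²+σw²)``.
    """

    name: str
    substance_class: str = "environmental"  # environmental | endogenous | ambiguous
    subclass: str = ""
    mode: str = "ESI+"
    neutral_mass: float = 300.0
    rt: float = 5.0
    log_mean: float = 0.0  # log10 concentration, e.g. log10 ng/mL
    sigma_between: float = 0.3
    sigma_within: float = 0.3
    mloq: float = 0.0  # concentration units; 0 -> never censored by MLOQ
    mdl: float | None = None  # detection limit; default MLOQ/2
    sex_effect: float = 0.0  # additive log10 shift for females
    annotation_level: int = 1

    def __post_init__(self) -> None:
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValueError(f"{self.name}: variance-component sds must be >= 0")
        if self.mode not in ("ESI+", "ESI-"):
            raise ValueError(f"{self.name}: unknown mode {self.mode!r}")

    @property
    def detection_limit(self) -> float:
        """Concentration below which no signal is seen at all: the stated
        MDL, or half the MLOQ when only an MLOQ is given."""
        if self.mdl is not None:
            return self.mdl
        return self.mloq / 2

    @property
    def true_icc(self) -> float:
        total = self.sigma_between**2 + self.sigma_within**2
        if total == 0:
            return float("nan")
        return self.sigma_between**2 / total


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    true_icc: dict[str, float] = field(default_factory=dict)
    substance_to_feature: dict[str, str] = field(default_factory=dict)
    concentrations: pd.DataFrame | None = None  # substances x samples
    statuses: pd.DataFrame | None = None  # substances x samples
    response_factors: dict[str, float] = field(default_factory=dict)
    batch_drift_factors: pd.DataFrame | None = None  # samples x modes
    is_matrix: pd.DataFrame | None = None  # IS channels x samples
    planted_duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_metabolite_families: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    planted_association: dict | None = None
    decoy_features: list[str] = field(default_factory=list)


def simulate_log_concentrations(
    n_individuals: int,
    n_visits: int,
    log_mean: float,
    sigma_between: float,
    sigma_within: float,
    rng,
    sex_effect: float = 0.0,
    female: np.ndarray | None = None,
) -> np.ndarray:
    """Draw an (n_individuals, n_visits) matrix of log10 concentrations
    from the additive variance-components model."""
    rng = rng_from_seed(rng)
    b = rng.normal(0.0, sigma_between, size=n_individuals)
    e = rng.normal(0.0, sigma_within, size=(n_individuals, n_visits))
    out = log_mean + b[:, None] + e
    if female is not None and sex_effect != 0.0:
        out = out + sex_effect * female.astype(float)[:, None]
    return out


def _sample_frame(design: CohortDesign, rng) -> pd.DataFrame:
    n = design.n_individuals
    pids = [f"P{i + 1:03d}" for i in range(n)]
    n_female = int(round(n * design.sex_balance))
    sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sexes)
    bands = rng.choice(design.age_bands, size=n)
    ages = np.array(
        [rng.uniform(float(b.split("-")[0]), float(b.split("-")[1])) for b in bands]
    ).round(1)
    bmi = np.clip(rng.normal(design.bmi_mean, design.bmi_sd, size=n), 16, None).round(1)

    rows = []
    for i, pid in enumerate(pids):
        for v in range(1, design.n_visits + 1):
            rows.append(
                {
                    "sample_id": f"{pid}_V{v}",
                    "participant_id": pid,
                    "visit": v,
                    "sex": sexes[i],
                    "age_band": bands[i],
                    "age": ages[i],
                    "bmi": bmi[i],
                }
            )
    meta = pd.DataFrame(rows)
    n_samples = len(meta)
    order = rng.permutation(n_samples) + 1
    meta["run_order"] = order
    meta["batch"] = pd.cut(meta["run_order"], design.n_batches, labels=False) + 1
    meta["volume"] = rng.uniform(*design.volume_range, size=n_samples).round(1)
    return meta


def _drift(design: CohortDesign, meta: pd.DataFrame, rng) -> pd.DataFrame:
    """Per-sample multiplicative drift per mode: batch factor x smooth
    monotone run-order trend."""
    n_samples = len(meta)
    out = {}
    for mode in ("ESI+", "ESI-"):
        batch_factors = 10.0 ** rng.normal(0.0, design.drift_batch_sd, size=design.n_batches)
        trend = 1.0 + design.drift_trend_amplitude * (meta["run_order"].to_numpy() - 1) / max(
            n_samples - 1, 1
        )
        out[mode] = batch_factors[meta["batch"].to_numpy() - 1] * trend
    return pd.DataFrame(out, index=meta["sample_id"])


def generate_cohort(
    design: CohortDesign,
    substances: list[SubstanceSpec],
    seed: int | None = None,
) -> tuple[FeatureTable, pd.DataFrame, CohortTruth]:
    """Generate the full cohort: feature table (with blanks appended as
    extra columns), sample metadata and ground truth.

    Same design seed, same inputs -> byte-identical output.
    """
    design.validate()
    if not substances:
        raise ValueError("substance list must be non-empty")
    rng = rng_from_seed(design.seed if seed is None else seed)
    meta = _sample_frame(design, rng)
    sample_ids = meta["sample_id"].to_list()
    drift = _drift(design, meta, rng)
    female = (meta.drop_duplicates("participant_id")["sex"] == "F").to_numpy()

    feature_rows = []
    area_rows = []
    conc_rows = []
    status_rows = []
    truth = CohortTruth(batch_drift_factors=drift)
    for k, spec in enumerate(substances):
        fid = f"F{k + 1:05d}"
        log_c = simulate_log_concentrations(
            design.n_individuals,
            design.n_visits,
            spec.log_mean,
            spec.sigma_between,
            spec.sigma_within,
            rng,
            spec.sex_effect,
            female,
        )
        conc = (10.0**log_c).reshape(-1)  # row-major: participant-major order
        rf = 10.0 ** rng.normal(5.0, 0.3)
        areas = rf * conc * drift[spec.mode].to_numpy()
        nondetect = (areas < design.noise_floor) | (conc < spec.detection_limit)
        below = (conc < spec.mloq) & ~nondetect
        status = np.where(nondetect, "nondetect", np.where(below, "below_mloq", "quantified"))
        areas = np.where(nondetect, 0.0, areas)

        feature_rows.append(
            {
                "feature_id": fid,
                "mode": spec.mode,
                "mz": mz_from_neutral(spec.neutral_mass, spec.mode),
                "rt": spec.rt,
                "annotation": spec.name,
                "class": spec.substance_class,
                "subclass": spec.subclass,
                "level": spec.annotation_level,
            }
        )
        area_rows.append(areas)
        conc_rows.append(conc)
        status_rows.append(status)
        truth.true_icc[spec.name] = spec.true_icc
        truth.substance_to_feature[spec.name] = fid
        truth.response_factors[spec.name] = rf

    features = pd.DataFrame(feature_rows).set_index("feature_id")
    areas = pd.DataFrame(np.array(area_rows), index=features.index, columns=sample_ids)
    truth.concentrations = pd.DataFrame(
        np.array(conc_rows), index=features.index, columns=sample_ids
    )
    truth.statuses = pd.DataFrame(np.array(status_rows), index=features.index, columns=sample_ids)

    # blanks: low-level noise at a configurable fraction of mean signal
    if design.n_blanks > 0:
        blank_cols = [f"BLANK_{b + 1}" for b in range(design.n_blanks)]
        mean_area = areas.mean(axis=1).to_numpy()
        blanks = (
            design.blank_fraction
            * mean_area[:, None]
            * rng.exponential(1.0, size=(len(features), design.n_blanks))
        )
        areas = pd.concat([areas, pd.DataFrame(blanks, index=features.index, columns=blank_cols)], axis=1)

    # internal standards carry the same per-mode drift
    n_pos = design.n_is_channels // 2
    is_rows = {}
    for c in range(design.n_is_channels):
        mode = "ESI+" if c < n_pos else "ESI-"
        base = 10.0 ** rng.uniform(5.0, 6.0)
        noise = (
            np.ones(len(sample_ids))
            if design.is_noise_cv == 0
            else np.exp(rng.normal(0.0, design.is_noise_cv, size=len(sample_ids)))
        )
        is_rows[f"IS_{mode}_{c + 1:02d}"] = base * drift[mode].to_numpy() * noise
    truth.is_matrix = pd.DataFrame(is_rows, index=sample_ids).T

    table = FeatureTable(features, areas)
    return table, meta, truth


def plant_cross_mode_duplicates(
    table: FeatureTable,
    n_pairs: int,
    seed,
    truth: CohortTruth | None = None,
) -> tuple[FeatureTable, CohortTruth]:
    """Append ESI- twins of randomly chosen ESI+ features.

    Each twin sits within 0.002 Da of its partner's
    (de)protonation-adjusted neutral mass and within 0.2 min in RT, with
    a strictly lower mean area, so every planted pair satisfies the
    cross-mode dedup predicate.
    """
    truth = truth if truth is not None else CohortTruth()
    if n_pairs == 0:
        return table.copy(), truth
    rng = rng_from_seed(seed)
    pos_ids = [f for f in table.feature_ids if table.features.at[f, "mode"] == "ESI+"]
    if n_pairs > len(pos_ids):
        raise ValueError(f"n_pairs={n_pairs} exceeds {len(pos_ids)} available ESI+ features")
    chosen = list(rng.choice(pos_ids, size=n_pairs, replace=False))

    new_features, new_areas = [], []
    for i, src in enumerate(chosen):
        neutral = neutral_from_mz(float(table.features.at[src, "mz"]), "ESI+")
        delta = rng.uniform(-0.0015, 0.0015)
        twin_mz = mz_from_neutral(neutral + delta, "ESI-")
        rt = float(table.features.at[src, "rt"]) + rng.uniform(-0.15, 0.15)
        src_areas = table.areas.loc[src].to_numpy(float)
        scale = rng.uniform(0.4, 0.8)
        twin_areas = src_areas * scale * np.exp(rng.normal(0, 0.05, size=len(src_areas)))
        if twin_areas.mean() >= src_areas.mean():  # enforce strictly lower mean
            twin_areas *= 0.9 * src_areas.mean() / twin_areas.mean()
        fid = f"D{i + 1:04d}"
        row = table.features.loc[src].copy()
        row["mode"], row["mz"], row["rt"] = "ESI-", twin_mz, max(rt, 0.1)
        new_features.append(row.rename(fid))
        new_areas.append(pd.Series(twin_areas, index=table.sample_ids, name=fid))
        truth.planted_duplicate_pairs.append((src, fid))

    features = pd.concat([table.features, pd.DataFrame(new_features)])
    areas = pd.concat([table.areas, pd.DataFrame(new_areas)])
    return FeatureTable(features, areas), truth


def _normalize_chains(transformations) -> list[tuple[str, ...]]:
    chains = []
    for t in transformations:
        chain = (t,) if isinstance(t, str) else tuple(t)
        for name in chain:
            if name not in DEFAULT_SHIFTS:
                raise ValueError(f"unknown transformation {name!r}")
        chains.append(chain)
    return chains


def plant_metabolite_family(
    table: FeatureTable,
    parent: SubstanceSpec,
    transformations,
    r_target: float = 0.97,
    seed=None,
    truth: CohortTruth | None = None,
    ppm_jitter: float = 1.0,
) -> tuple[FeatureTable, CohortTruth]:
    """Append nonannotated metabolite features of an annotated parent.

    ``transformations`` is a list of shift names or tuples of names; a
    tuple denotes a chain applied cumulatively (e.g.
    ``("hydroxylation", "sulfation_of_hydroxyl")`` is the sulfate of the
    hydroxy metabolite, correlated with — and mass-shifted from — that
    intermediate rather than the parent). Child m/z gets uniform jitter
    within ±``ppm_jitter`` ppm; child areas are an affine function of the
    anchor's areas with Gaussian noise sized so the expected Pearson
    correlation is ``r_target`` (exact when ``r_target`` is 1).
    """
    truth = truth if truth is not None else CohortTruth()
    rng = rng_from_seed(seed)
    chains = _normalize_chains(transformations)
    if not 0 < r_target <= 1:
        raise ValueError("r_target must be in (0, 1]")

    parent_fid = None
    for fid in table.feature_ids:
        if str(table.features.at[fid, "annotation"]) == parent.name:
            parent_fid = fid
            break
    if parent_fid is None:
        raise ValueError(f"parent {parent.name!r} not found among annotated features")

    # anchor registry: chain prefix -> (feature_id, neutral mass, areas)
    anchors: dict[tuple[str, ...], tuple[str, float, np.ndarray]] = {
        (): (parent_fid, parent.neutral_mass, table.areas.loc[parent_fid].to_numpy(float))
    }
    new_features, new_areas = [], []
    planted = truth.planted_metabolite_families.setdefault(parent_fid, [])
    for ci, chain in enumerate(sorted(chains, key=len)):
        prefix = chain[:-1]
        if prefix not in anchors:
            raise ValueError(f"chain {chain} lacks its intermediate {prefix}")
        anchor_fid, anchor_neutral, anchor_areas = anchors[prefix]
        shift = DEFAULT_SHIFTS[chain[-1]]
        theo = theoretical_mz(anchor_neutral, shift, parent.mode)
        mz = theo * (1 + rng.uniform(-ppm_jitter, ppm_jitter) * 1e-6)
        scale = rng.uniform(0.1, 0.5)
        signal = scale * anchor_areas
        if r_target < 1:
            sigma = scale * anchor_areas.std() * np.sqrt(1 / r_target**2 - 1)
            signal = np.clip(signal + rng.normal(0, sigma, size=len(signal)), 0, None)
        fid = f"M{len(truth.planted_metabolite_families)}_{ci + 1:02d}"
        new_features.append(
            pd.Series(
                {
                    "mode": parent.mode,
                    "mz": mz,
                    "rt": max(parent.rt - 0.5 * len(chain) + rng.uniform(-0.2, 0.2), 0.3),
                    "annotation": "",
                    "class": "",
                    "subclass": "",
                    "level": np.nan,
                },
                name=fid,
            )
        )
        new_areas.append(pd.Series(signal, index=table.sample_ids, name=fid))
        anchors[chain] = (fid, anchor_neutral + shift.delta_mass, signal)
        planted.append(("+".join(chain), fid))

    features = pd.concat([table.features, pd.DataFrame(new_features)])
    features["mz"] = features["mz"].astype(float)
    areas = pd.concat([table.areas, pd.DataFrame(new_areas)])
    return FeatureTable(features, areas), truth


def plant_decoys(
    table: FeatureTable,
    n_decoys: int,
    seed,
    mode: str = "ESI-",
    mz_range: tuple[float, float] = (100.0, 700.0),
    truth: CohortTruth | None = None,
    blank_fraction: float = 0.01,
) -> tuple[FeatureTable, CohortTruth]:
    """Append nonannotated decoy features at random m/z with lognormal
    areas uncorrelated with everything, for false-hit-rate testing.

    Columns named ``BLANK_*`` get only blank-level signal
    (``blank_fraction`` of the decoy's mean area) so decoys survive the
    blank filter like real features do.
    """
    truth = truth if truth is not None else CohortTruth()
    rng = rng_from_seed(seed)
    n_samples = len(table.sample_ids)
    is_blank = np.array([str(c).startswith("BLANK") for c in table.sample_ids])
    new_features, new_areas = [], []
    for i in range(n_decoys):
        fid = f"X{i + 1:04d}"
        new_features.append(
            pd.Series(
                {
                    "mode": mode,
                    "mz": rng.uniform(*mz_range),
                    "rt": rng.uniform(0.5, 16.0),
                    "annotation": "",
                    "class": "",
                    "subclass": "",
                    "level": np.nan,
                },
                name=fid,
            )
        )
        areas = 10.0 ** rng.normal(4.5, 0.5, size=n_samples)
        if is_blank.any():
            areas[is_blank] = (
                blank_fraction * areas[~is_blank].mean() * rng.exponential(1.0, size=is_blank.sum())
            )
        new_areas.append(pd.Series(areas, index=table.sample_ids, name=fid))
        truth.decoy_features.append(fid)
    features = pd.concat([table.features, pd.DataFrame(new_features)])
    features["mz"] = features["mz"].astype(float)
    areas = pd.concat([table.areas, pd.DataFrame(new_areas)])
    return FeatureTable(features, areas), truth


def plant_association(
    table: FeatureTable,
    meta: pd.DataFrame,
    truth: CohortTruth,
    exposure_name: str,
    outcome_spec: SubstanceSpec,
    slope: float = 0.5,
    random_slope_sd: float = 0.1,
    sigma_resid: float = 0.05,
    seed=None,
) -> tuple[FeatureTable, CohortTruth]:
    """Append an outcome substance whose log10 concentration responds to
    the named exposure with a fixed slope plus participant-specific
    random intercepts and slopes."""
    rng = rng_from_seed(seed)
    exp_fid = truth.substance_to_feature[exposure_name]
    log_x = np.log10(truth.concentrations.loc[exp_fid].to_numpy(float))
    log_x_c = log_x - log_x.mean()
    pids = meta["participant_id"].to_numpy()
    uniq = pd.unique(pids)
    u = dict(zip(uniq, rng.normal(0, outcome_spec.sigma_between, size=len(uniq))))
    s = dict(zip(uniq, rng.normal(0, random_slope_sd, size=len(uniq))))
    female = (meta["sex"] == "F").to_numpy().astype(float)
    log_y = (
        outcome_spec.log_mean
        + outcome_spec.sex_effect * female
        + np.array([u[p] for p in pids])
        + (slope + np.array([s[p] for p in pids])) * log_x_c
        + rng.normal(0, sigma_resid, size=len(pids))
    )
    conc = 10.0**log_y
    rf = 10.0 ** rng.normal(5.0, 0.3)
    drift = truth.batch_drift_factors[outcome_spec.mode].to_numpy()
    areas = rf * conc * drift
    fid = f"A{len(truth.substance_to_feature) + 1:05d}"
    row = pd.Series(
        {
            "mode": outcome_spec.mode,
            "mz": mz_from_neutral(outcome_spec.neutral_mass, outcome_spec.mode),
            "rt": outcome_spec.rt,
            "annotation": outcome_spec.name,
            "class": outcome_spec.substance_class,
            "subclass": outcome_spec.subclass,
            "level": outcome_spec.annotation_level,
        },
        name=fid,
    )
    features = pd.concat([table.features, pd.DataFrame([row])])
    sample_areas = pd.Series(areas, index=meta["sample_id"], name=fid)
    areas_frame = pd.concat([table.areas, pd.DataFrame([sample_areas]).reindex(columns=table.sample_ids).fillna(0.0)])
    truth.substance_to_feature[outcome_spec.name] = fid
    truth.concentrations.loc[fid] = pd.Series(conc, index=meta["sample_id"]).reindex(
        truth.concentrations.columns
    )
    truth.statuses.loc[fid] = "quantified"
    truth.planted_association = {
        "exposure": exposure_name,
        "outcome": outcome_spec.name,
        "slope": slope,
        "random_slope_sd": random_slope_sd,
    }
    return FeatureTable(features, areas_frame), truth


def cohort_series(
    truth: CohortTruth,
    meta: pd.DataFrame,
    substance: str,
    mloq: float | None = None,
):
    """True concentration series of a generated substance as a
    (participant, visit)-indexed SubstanceSeries with censoring statuses."""
    from .quant import series_from_concentrations

    fid = truth.substance_to_feature[substance]
    idx = pd.MultiIndex.from_arrays(
        [meta["participant_id"], meta["visit"]], names=["participant", "visit"]
    )
    values = pd.Series(
        truth.concentrations.loc[fid, meta["sample_id"]].to_numpy(float), index=idx
    )
    statuses = pd.Series(
        truth.statuses.loc[fid, meta["sample_id"]].to_numpy(), index=idx
    )
    return series_from_concentrations(substance, values, statuses, mloq)


def default_panel(
    n_environmental: int = 343,
    n_endogenous: int = 162,
    seed: int = 0,
) -> list[SubstanceSpec]:
    """A realistic mixed substance panel: detection frequencies spread
    over 2-100% and true ICC distributions centered near 0.30
    (environmental) and 0.40 (endogenous)."""
    rng = rng_from_seed(seed)
    subclasses = {
        "environmental": ["PFAS", "plasticizers", "pesticides", "PAHs", "parabens", "drugs"],
        "endogenous": ["steroids", "bile acids", "amino acids", "lipids"],
    }
    specs = []
    counter = 0
    for cls, n in (("environmental", n_environmental), ("endogenous", n_endogenous)):
        mean_icc = 0.30 if cls == "environmental" else 0.40
        a = 2.0
        b = a * (1 - mean_icc) / mean_icc
        for _ in range(n):
            counter += 1
            icc = float(np.clip(rng.beta(a, b), 0.005, 0.995))
            sigma_total = rng.uniform(0.25, 0.6)
            sb = np.sqrt(icc) * sigma_total
            sw = np.sqrt(1 - icc) * sigma_total
            log_mean = rng.uniform(-1.0, 1.5)
            target_df = rng.uniform(0.02, 1.0)
            mloq = 10.0 ** (log_mean + sigma_total * norm.ppf(1 - target_df)) if target_df < 1 else 0.0
            specs.append(
                SubstanceSpec(
                    name=f"{cls[:3]}_{counter:04d}",
                    substance_class=cls,
                    subclass=str(rng.choice(subclasses[cls])),
                    mode="ESI+" if rng.random() < 0.5 else "ESI-",
                    neutral_mass=float(rng.uniform(100, 800)),
                    rt=float(rng.uniform(0.5, 16.0)),
                    log_mean=log_mean,
                    sigma_between=float(sb),
                    sigma_within=float(sw),
                    mloq=float(mloq),
                    sex_effect=float(rng.choice([0.0, 0.0, 0.0, 0.2, -0.2])),
                    annotation_level=int(rng.choice([1, 2])),
                )
            )
    return specs


def write_cohort(
    outdir: str | Path,
    table: FeatureTable,
    meta: pd.DataFrame,
    truth: CohortTruth,
) -> dict[str, Path]:
    """Write the feature table, sample metadata, IS matrix and ground
    truth as delimited text / JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": outdir / "feature_table.tsv",
        "metadata": outdir / "sample_metadata.tsv",
        "is_matrix": outdir / "internal_standards.tsv",
        "truth": outdir / "truth.json",
    }
    table.to_tsv(paths["features"])
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    if truth.is_matrix is not None:
        truth.is_matrix.to_csv(paths["is_matrix"], sep="\t")
    if truth.concentrations is not None:
        paths["concentrations"] = outdir / "concentrations.tsv"
        truth.concentrations.to_csv(paths["concentrations"], sep="\t")
    if truth.statuses is not None:
        paths["statuses"] = outdir / "statuses.tsv"
        truth.statuses.to_csv(paths["statuses"], sep="\t")
    payload = {
        "true_icc": truth.true_icc,
        "substance_to_feature": truth.substance_to_feature,
        "planted_duplicate_pairs": truth.planted_duplicate_pairs,
        "planted_metabolite_families": truth.planted_metabolite_families,
        "planted_association": truth.planted_association,
        "decoy_features": truth.decoy_features,
        "response_factors": truth.response_factors,
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths
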