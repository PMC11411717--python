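"""Exposome-phenotype associations on the simulated cohort: per-substance
male vs female rank tests (Bonferroni corrected, DF > 10% gate) and the
planted PFAS-testosterone mixed model with random intercepts and slopes,
unadjusted and adjusted for baseline age and BMI.
"""

import json
from pathlib import Path

import pandas as pd

from expolong import assoc, quant

ROOT = Path(__file__).resolve().parents[1]


def load_series(cohort: Path, names=None):
    truth = json.loads((cohort / "truth.json").read_text())
    meta = pd.read_csv(cohort / "sample_metadata.tsv", sep="\t")
    conc = pd.read_csv(cohort / "concentrations.tsv", sep="\t", index_col=0)
    statuses = pd.read_csv(cohort / "statuses.tsv", sep="\t", index_col=0)
    specs = pd.read_csv(cohort / "substances.tsv", sep="\t").set_index("name")
    out = {}
    for name, fid in truth["substance_to_feature"].items():
        if names is not None and name not in names:
            continue
        mloq = float(specs.at[name, "mloq"]) if specs.at[name, "mloq"] > 0 else None
        data = pd.DataFrame(
            {
                "participant": meta["participant_id"],
                "visit": meta["visit"],
                "value": conc.loc[fid, meta["sample_id"]].to_numpy(float),
                "status": statuses.loc[fid, meta["sample_id"]].to_numpy(),
            }
        )
        series = quant.SubstanceSeries(name, data, mloq)
        out[name] = quant.censor_substitute(series) if mloq else series
    return out, meta, truth


def main() -> None:
    cohort = ROOT / "results" / "cohort"
    out = ROOT / "results" / "assoc"
    out.mkdir(parents=True, exist_ok=True)

    series, meta, truth = load_series(cohort)
    sex_results = assoc.sex_difference_tests(list(series.values()), meta)
    sex_results.to_csv(out / "sex_differences.tsv", sep="\t", index=False)
    sig = sex_results[sex_results["significant"] == True]  # noqa: E712
    print(f"sex differences: {len(sig)} of {len(sex_results)} tested substances "
          f"significant after Bonferroni")

    planted = truth["planted_association"]
    y = series[planted["outcome"]]
    x = series[planted["exposure"]]
    rows = []
    for adjust in (False, True):
        res = assoc.fit_exposure_outcome_lmm(y, x, meta, adjust=adjust, stratify_sex="F")
        rows.append(vars(res))
        print(f"{planted['exposure']} -> {planted['outcome']} "
              f"({res.adjusted_for}, females): slope {res.slope:.3f} "
              f"(SE {res.slope_se:.3f}, p={res.p_raw:.2e}); planted slope {planted['slope']}")
    pd.DataFrame(rows).to_csv(out / "lmm_results.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
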