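"""Simulate the study cohort: 46 participants x 6 visits, a mixed panel
of environmental and endogenous substances, planted cross-mode
duplicates, a diclofenac metabolite family, decoy features and a
PFAS-testosterone association.

Writes the feature table, sample metadata, internal-standard matrix,
substance specs and ground truth under results/cohort/.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from expolong import chem, synth

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    out = ROOT / "results" / "cohort"
    design = synth.CohortDesign(seed=seed)
    panel = synth.default_panel(343, 162, seed=seed)

    diclofenac = synth.SubstanceSpec(
        name="diclofenac", substance_class="environmental", subclass="drugs",
        mode="ESI-", neutral_mass=chem.formula_mass("C14H11Cl2NO2"), rt=11.0,
        log_mean=0.5, sigma_between=0.4, sigma_within=0.1,
    )
    pfos = synth.SubstanceSpec(
        name="pfos_like", substance_class="environmental", subclass="PFAS",
        mode="ESI-", neutral_mass=499.937, rt=12.5, log_mean=0.6,
        sigma_between=0.35, sigma_within=0.08,
    )
    panel += [diclofenac, pfos]

    table, meta, truth = synth.generate_cohort(design, panel)
    table, truth = synth.plant_cross_mode_duplicates(table, 25, seed=seed + 1, truth=truth)
    table, truth = synth.plant_metabolite_family(
        table, diclofenac,
        ["hydroxylation", ("hydroxylation", "sulfation_of_hydroxyl")],
        r_target=0.97, seed=seed + 2, truth=truth,
    )
    table, truth = synth.plant_decoys(table, 200, seed=seed + 3, truth=truth)
    testosterone = synth.SubstanceSpec(
        name="testosterone_like", substance_class="endogenous", subclass="steroids",
        mode="ESI+", neutral_mass=288.209, rt=9.8, log_mean=0.7,
        sigma_between=0.15, sigma_within=0.0, sex_effect=-0.8,
    )
    table, truth = synth.plant_association(
        table, meta, truth, "pfos_like", testosterone,
        slope=0.5, random_slope_sd=0.1, seed=seed + 4,
    )

    paths = synth.write_cohort(out, table, meta, truth)
    specs = pd.DataFrame([vars(s) for s in panel + [testosterone]])
    specs["true_icc"] = [s.true_icc for s in panel + [testosterone]]
    specs.to_csv(out / "substances.tsv", sep="\t", index=False)

    print(f"cohort: {len(meta)} samples, {len(table)} features "
          f"({len(truth.planted_duplicate_pairs)} planted duplicate pairs, "
          f"{sum(len(v) for v in truth.planted_metabolite_families.values())} planted metabolites, "
          f"{len(truth.decoy_features)} decoys)")
    for k, p in paths.items():
        print(f"  wrote {p.relative_to(ROOT)}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    main(**vars(parser.parse_args()))
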