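"""Coexposure structure: average-linkage clustering of log10 substance
profiles (1 - Pearson r distance, unit-variance scaled, per-individual
visit means) and the strongest Bonferroni-significant pairwise
correlations. Exports heatmap-ready matrices with metadata tracks.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from expolong import coexposure

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = ROOT / "results" / "cohort"
    out = ROOT / "results" / "coexposure"
    out.mkdir(parents=True, exist_ok=True)

    truth = json.loads((cohort / "truth.json").read_text())
    meta = pd.read_csv(cohort / "sample_metadata.tsv", sep="\t")
    conc = pd.read_csv(cohort / "concentrations.tsv", sep="\t", index_col=0)
    feats = pd.read_csv(cohort / "feature_table.tsv", sep="\t", index_col="feature_id")

    fid_to_name = {v: k for k, v in truth["substance_to_feature"].items()}
    matrix = np.log10(conc[meta["sample_id"]])
    matrix.index = [fid_to_name[f] for f in matrix.index]
    # drop substances with (near-)constant profiles before scaling
    keep = matrix.std(axis=1) > 1e-9
    matrix = matrix.loc[keep]

    row_meta = feats.loc[[truth["substance_to_feature"][n] for n in matrix.index],
                         ["class", "subclass", "level"]]
    row_meta.index = matrix.index
    layout = coexposure.hca_layout(
        matrix, sample_metadata=meta, average_over_visits=True, row_metadata=row_meta
    )
    paths = coexposure.export_heatmap(layout, out)
    print(f"clustered {matrix.shape[0]} substances x {layout.matrix.shape[1]} individuals")

    corr = coexposure.pairwise_correlations(matrix)
    corr = corr.sort_values("r", ascending=False)
    corr.to_csv(out / "pairwise_correlations.tsv", sep="\t", index=False)
    sig = corr[corr["significant"]]
    print(f"{len(sig)} of {len(corr)} pairs Bonferroni-significant; top coexposures:")
    print(sig.head(5)[["substance_a", "substance_b", "r", "p_adjusted", "n"]].to_string(index=False))
    for p in paths.values():
        print(f"  wrote {p.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
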