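"""Suspect screening of nonannotated features for diclofenac
metabolites: exact-mass transformation shifts plus correlation with the
parent (or an accepted metabolite), against the planted ground truth and
200 decoys.
"""

import json
from pathlib import Path

from expolong import suspects
from expolong.tables import FeatureTable

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = ROOT / "results" / "cohort"
    out = ROOT / "results" / "suspects"
    out.mkdir(parents=True, exist_ok=True)

    table = FeatureTable.from_tsv(cohort / "feature_table.tsv")
    truth = json.loads((cohort / "truth.json").read_text())
    parent_fid = truth["substance_to_feature"]["diclofenac"]

    hits = suspects.screen(parent_fid, table, ppm_tol=5.0, p_threshold=1e-3)
    frame = suspects.hits_to_frame(hits)
    frame.to_csv(out / "suspect_hits.tsv", sep="\t", index=False)

    planted = {fid for _, fid in truth["planted_metabolite_families"].get(parent_fid, [])}
    found = set(frame["candidate_feature"])
    decoys = set(truth["decoy_features"])
    sensitivity = len(planted & found) / len(planted) if planted else float("nan")
    false_rate = len(found & decoys) / len(decoys) if decoys else 0.0
    print(f"{len(hits)} hits; sensitivity {sensitivity:.2f} on {len(planted)} planted "
          f"metabolites; false-hit rate {false_rate:.4f} over {len(decoys)} decoys")
    for h in hits:
        print(f"  {h.candidate_feature}: {h.transformation} of {h.anchor_feature}, "
              f"m/z {h.observed_mz:.4f} ({h.ppm_error:+.2f} ppm), "
              f"r={h.r_with_anchor:.3f}, p={h.p:.2e}")


if __name__ == "__main__":
    main()
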