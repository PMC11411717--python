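"""Suspect screening of nonannotated features for phase I/II metabolites.

Given a parent compound detected in the cohort, candidate metabolite
features are screened by two criteria applied jointly:

1. exact mass: the candidate's m/z matches, within a ppm tolerance, the
   theoretical (de)protonated m/z of the parent (or an already accepted
   metabolite) shifted by a biotransformation mass difference
   (hydroxylation +O, sulfation +SO3, glucuronidation +C6H8O6, ...);
2. covariation: the candidate's per-sample peak areas correlate with the
   anchor compound's areas (Pearson, p below a threshold), since a true
   metabolite tracks its parent across repeated samples.

Anchoring is iterative so that metabolites of metabolites (for example a
hydroxylated drug and its downstream sulfate conjugate) are picked up in
a second pass, to a configurable depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chem import MONOISOTOPIC_MASS, mz_from_neutral, neutral_from_mz
from .tables import FeatureTable


@dataclass(frozen=True)
class TransformationShift:
    """A biotransformation expressed as an elemental composition delta.

    ``delta_mass`` must equal the monoisotopic mass of ``composition`` to
    1e-6 Da; the constructor enforces this.
    """

    name: str
    composition: dict[str, int]
    delta_mass: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in self.composition.items())
        if self.delta_mass is None:
            object.__setattr__(self, "delta_mass", mass)
        elif abs(self.delta_mass - mass) > 1e-6:
            raise ValueError(
                f"{self.name}: delta_mass {self.delta_mass} does not match "
                f"composition mass {mass:.7f}"
            )


#: Built-in shift table; editable copies can be round-tripped through
#: :func:`load_shift_table` / :func:`save_shift_table`.
DEFAULT_SHIFTS: dict[str, TransformationShift] = {
    s.name: s
    for s in [
        TransformationShift("hydroxylation", {"O": 1}),
        TransformationShift("sulfation_of_hydroxyl", {"S": 1, "O": 3}),
        TransformationShift("glucuronidation", {"C": 6, "H": 8, "O": 6}),
        TransformationShift("carbamoyl_glucuronidation", {"C": 7, "H": 8, "O": 8}),
        TransformationShift("demethylation", {"C": -1, "H": -2}),
    ]
}


def save_shift_table(path, shifts: dict[str, TransformationShift] | None = None) -> None:
    shifts = shifts or DEFAULT_SHIFTS
    rows = [
        {"name": s.name, "composition": _format_composition(s.composition), "delta_mass": s.delta_mass}
        for s in shifts.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_shift_table(path) -> dict[str, TransformationShift]:
    frame = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in frame.iterrows():
        comp = _parse_composition(row["composition"])
        out[row["name"]] = TransformationShift(row["name"], comp, float(row["delta_mass"]))
    return out


def _format_composition(comp: dict[str, int]) -> str:
    return ",".join(f"{el}:{n}" for el, n in sorted(comp.items()))


def _parse_composition(text: str) -> dict[str, int]:
    return {el: int(n) for el, n in (tok.split(":") for tok in text.split(","))}


def theoretical_mz(
    parent_neutral_mass: float, shift: TransformationShift | str, mode: str
) -> float:
    """Theoretical m/z of the (de)protonated transformation product."""
    if parent_neutral_mass <= 0:
        raise ValueError("parent mass must be positive")
    if isinstance(shift, str):
        shift = DEFAULT_SHIFTS[shift]
    return mz_from_neutral(parent_neutral_mass + shift.delta_mass, mode)


def ppm_error(theoretical: float, observed: float) -> float:
    """Signed mass error of an observation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass
class SuspectHit:
    """A candidate metabolite feature passing both screen criteria."""

    parent_feature: str
    candidate_feature: str
    anchor_feature: str
    transformation: str
    theoretical_mz: float
    observed_mz: float
    ppm_error: float
    rt: float
    r_with_anchor: float
    p: float
    mode: str
    depth: int


def screen(
    parent_feature: str,
    table: FeatureTable,
    shifts: dict[str, TransformationShift] | None = None,
    ppm_tol: float = 5.0,
    p_threshold: float = 1e-3,
    max_depth: int = 2,
) -> list[SuspectHit]:
    """Screen nonannotated features for metabolites of ``parent_feature``.

    A hit must match, within ``ppm_tol``, the theoretical shifted m/z of
    the parent or of an already accepted hit, and its areas must
    correlate with that anchor at Pearson p < ``p_threshold``. Accepted
    hits become anchors for the next round, to ``max_depth`` rounds.
    Output is independent of the candidate row order in the table.
    """
    shifts = shifts if shifts is not None else DEFAULT_SHIFTS
    feats = table.features
    if parent_feature not in feats.index:
        raise KeyError(f"parent feature {parent_feature!r} not in table")

    annotated = feats.get("annotation")
    if annotated is None:
        candidate_ids = list(feats.index)
    else:
        blank = annotated.isna() | (annotated.astype(str).str.strip() == "")
        candidate_ids = list(feats.index[blank])
    candidate_ids = sorted(set(candidate_ids) - {parent_feature})

    parent_neutral = neutral_from_mz(
        float(feats.at[parent_feature, "mz"]), feats.at[parent_feature, "mode"]
    )
    anchors: list[tuple[str, float]] = [(parent_feature, parent_neutral)]
    hits: list[SuspectHit] = []
    accepted: set[str] = set()

    for depth in range(1, max_depth + 1):
        next_anchors: list[tuple[str, float]] = []
        for anchor_id, anchor_neutral in anchors:
            anchor_areas = table.areas.loc[anchor_id].to_numpy(float)
            for shift in shifts.values():
                for cand_id in candidate_ids:
                    if cand_id in accepted:
                        continue
                    mode = feats.at[cand_id, "mode"]
                    theo = theoretical_mz(anchor_neutral, shift, mode)
                    obs = float(feats.at[cand_id, "mz"])
                    err = ppm_error(theo, obs)
                    if abs(err) > ppm_tol:
                        continue
                    cand_areas = table.areas.loc[cand_id].to_numpy(float)
                    if np.std(cand_areas) == 0 or np.std(anchor_areas) == 0:
                        continue  # correlation undefined for constant vectors
                    r, p = stats.pearsonr(anchor_areas, cand_areas)
                    if p >= p_threshold:
                        continue
                    accepted.add(cand_id)
                    hits.append(
                        SuspectHit(
                            parent_feature=parent_feature,
                            candidate_feature=cand_id,
                            anchor_feature=anchor_id,
                            transformation=shift.name,
                            theoretical_mz=theo,
                            observed_mz=obs,
                            ppm_error=err,
                            rt=float(feats.at[cand_id, "rt"]),
                            r_with_anchor=float(r),
                            p=float(p),
                            mode=mode,
                            depth=depth,
                        )
                    )
                    next_anchors.append((cand_id, neutral_from_mz(obs, mode)))
        if not next_anchors:
            break
        anchors = next_anchors
    return hits


def hits_to_frame(hits: list[SuspectHit]) -> pd.DataFrame:
    """Tabulate screen hits for export."""
    cols = [
        "parent_feature", "candidate_feature", "anchor_feature", "transformation",
        "theoretical_mz", "observed_mz", "ppm_error", "rt", "r_with_anchor",
        "p", "mode", "depth",
    ]
    return pd.DataFrame([vars(h) for h in hits], columns=cols)
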