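"""Coexposure discovery: pairwise correlation screens and hierarchical
clustering with heatmap-ready exports.

Clustering follows the convention of correlation-distance heatmaps:
substances are unit-variance scaled, dissimilarity is 1 - Pearson r, and
trees use average linkage. Column profiles can be per-sample or averaged
over each individual's visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def _pearson_p(r: np.ndarray, n) -> np.ndarray:
    """Two-sided p-value of a Pearson r at n paired observations (beta
    distribution of |r| under the null, as in scipy.stats.pearsonr)."""
    n = np.asarray(n, float)
    ab = n / 2 - 1
    with np.errstate(invalid="ignore"):
        p = 2 * stats.beta.sf(np.abs(r), ab, ab, loc=-1, scale=2)
    return np.clip(p, 0.0, 1.0)


def pairwise_correlations(
    matrix: pd.DataFrame, alpha: float = 0.05, correction: str = "bonferroni"
) -> pd.DataFrame:
    """All pairwise Pearson correlations between the rows of a
    substances × samples matrix.

    Missing values are handled by pairwise-complete deletion with the
    paired n reported. Pairs involving a constant vector get r = NaN and
    a flag. Bonferroni adjustment is min(1, p·m) over the m testable
    pairs.

    Returns a tidy frame: substance_a, substance_b, r, p, p_adjusted, n,
    significant, flag.
    """
    names = list(matrix.index)
    X = matrix.to_numpy(float)
    rows = []
    complete = not np.isnan(X).any()
    if complete:
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(X)
        n = X.shape[1]
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append((names[i], names[j], R[i, j], n))
    else:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                mask = ~np.isnan(X[i]) & ~np.isnan(X[j])
                n_ij = int(mask.sum())
                if n_ij < 3:
                    rows.append((names[i], names[j], np.nan, n_ij))
                    continue
                xi, xj = X[i, mask], X[j, mask]
                if xi.std() == 0 or xj.std() == 0:
                    rows.append((names[i], names[j], np.nan, n_ij))
                    continue
                rows.append((names[i], names[j], float(np.corrcoef(xi, xj)[0, 1]), n_ij))
    out = pd.DataFrame(rows, columns=["substance_a", "substance_b", "r", "n"])
    out["flag"] = out["r"].isna()
    out["p"] = _pearson_p(out["r"].to_numpy(), out["n"].to_numpy())
    out.loc[out["flag"], "p"] = np.nan
    m = int((~out["flag"]).sum())
    if correction == "bonferroni":
        out["p_adjusted"] = np.minimum(1.0, out["p"] * m)
    elif correction in (None, "none"):
        out["p_adjusted"] = out["p"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out["significant"] = out["p_adjusted"] < alpha
    return out[["substance_a", "substance_b", "r", "p", "p_adjusted", "n", "significant", "flag"]]


@dataclass
class ClusterLayout:
    """Ordered matrix plus trees and metadata tracks, ready for any
    heatmap renderer."""

    matrix: pd.DataFrame  # scaled, rows = substances, columns = profiles
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    col_metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def ordered_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]


def _correlation_linkage(X: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(X)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, None)  # symmetrize away float noise
    if np.isnan(D).any():
        raise ValueError("constant profile: correlation distance undefined")
    return hierarchy.average(squareform(D, checks=False))


def hca_layout(
    matrix: pd.DataFrame,
    sample_metadata: pd.DataFrame | None = None,
    average_over_visits: bool = False,
    scale: bool = True,
    row_metadata: pd.DataFrame | None = None,
) -> ClusterLayout:
    """Average-linkage clustering of substances and profiles with
    1 - Pearson r distance.

    With ``average_over_visits`` the columns are per-participant means
    of that individual's visits (requires sample metadata mapping sample
    id to participant); otherwise all samples are kept. Substances are
    unit-variance scaled (centered, sd 1) before distances unless
    ``scale`` is False. Leaf order is deterministic (scipy's tie-break
    by input index).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    data = matrix.astype(float)
    col_meta = pd.DataFrame(index=data.columns)
    if average_over_visits:
        if sample_metadata is None:
            raise ValueError("average_over_visits requires sample metadata")
        meta = (
            sample_metadata.set_index("sample_id")
            if "sample_id" in sample_metadata.columns
            else sample_metadata
        )
        participant = meta.loc[data.columns, "participant_id"]
        data = data.T.groupby(participant.to_numpy()).mean().T
        first = meta.drop_duplicates("participant_id").set_index("participant_id")
        keep = [c for c in ("sex", "age", "age_band", "bmi") if c in first.columns]
        col_meta = first.loc[data.columns, keep]
    elif sample_metadata is not None:
        meta = (
            sample_metadata.set_index("sample_id")
            if "sample_id" in sample_metadata.columns
            else sample_metadata
        )
        keep = [c for c in ("participant_id", "sex", "age", "age_band", "bmi") if c in meta.columns]
        col_meta = meta.loc[data.columns, keep]

    if scale:
        sd = data.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"constant substances cannot be scaled: {list(data.index[sd == 0])[:5]}")
        data = data.sub(data.mean(axis=1), axis=0).div(sd, axis=0)

    row_linkage = _correlation_linkage(data.to_numpy())
    col_linkage = _correlation_linkage(data.to_numpy().T)
    row_order = [data.index[i] for i in hierarchy.leaves_list(row_linkage)]
    col_order = [data.columns[i] for i in hierarchy.leaves_list(col_linkage)]
    rmeta = row_metadata.loc[data.index] if row_metadata is not None else pd.DataFrame(index=data.index)
    return ClusterLayout(data, row_order, col_order, row_linkage, col_linkage, rmeta, col_meta)


def cut_clusters(layout: ClusterLayout, height: float) -> pd.Series:
    """Flat cluster labels from cutting the substance tree at a height.

    Convenience only: published coexposure groups were highlighted
    manually, not extracted by a cut rule.
    """
    labels = hierarchy.fcluster(layout.row_linkage, t=height, criterion="distance")
    return pd.Series(labels, index=layout.matrix.index, name="cluster")


def export_heatmap(layout: ClusterLayout, outdir: str | Path) -> dict[str, Path]:
    """Write the ordered matrix, metadata tracks and linkage merge tables
    as delimited text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "heatmap_matrix.tsv",
        "row_metadata": outdir / "row_metadata.tsv",
        "col_metadata": outdir / "col_metadata.tsv",
        "row_linkage": outdir / "row_linkage.tsv",
        "col_linkage": outdir / "col_linkage.tsv",
    }
    ordered = layout.ordered_matrix()
    ordered.index.name = "substance"
    ordered.to_csv(paths["matrix"], sep="\t")
    rmeta = layout.row_metadata.loc[layout.row_order] if len(layout.row_metadata) else pd.DataFrame(index=pd.Index(layout.row_order))
    cmeta = layout.col_metadata.loc[layout.col_order] if len(layout.col_metadata) else pd.DataFrame(index=pd.Index(layout.col_order))
    rmeta.index.name = "substance"
    cmeta.index.name = "profile"
    rmeta.to_csv(paths["row_metadata"], sep="\t")
    cmeta.to_csv(paths["col_metadata"], sep="\t")
    cols = ["left", "right", "height", "count"]
    pd.DataFrame(layout.row_linkage, columns=cols).to_csv(paths["row_linkage"], sep="\t", index=False)
    pd.DataFrame(layout.col_linkage, columns=cols).to_csv(paths["col_linkage"], sep="\t", index=False)
    return paths


def read_heatmap(outdir: str | Path) -> ClusterLayout:
    """Re-import an exported heatmap; the ordered matrix defines the
    leaf orders."""
    outdir = Path(outdir)
    matrix = pd.read_csv(outdir / "heatmap_matrix.tsv", sep="\t", index_col="substance")
    rmeta = pd.read_csv(outdir / "row_metadata.tsv", sep="\t", index_col="substance")
    cmeta = pd.read_csv(outdir / "col_metadata.tsv", sep="\t", index_col="profile")
    row_linkage = pd.read_csv(outdir / "row_linkage.tsv", sep="\t").to_numpy(float)
    col_linkage = pd.read_csv(outdir / "col_linkage.tsv", sep="\t").to_numpy(float)
    return ClusterLayout(
        matrix, list(matrix.index), list(matrix.columns), row_linkage, col_linkage, rmeta, cmeta
    )
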