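"""Feature-table reduction: blank filter, cross-mode dedup (against a
brute-force oracle), IS-PCA drift correction and volume normalization."""

import numpy as np
import pandas as pd
import pytest

from expolong import features, synth
from expolong.chem import neutral_from_mz
from expolong.tables import FeatureTable

from conftest import random_two_mode_table


def dedup_oracle(table, mass_tol=0.002, rt_tol=0.2):
    """Independent brute-force dedup: each round, recompute the full
    all-pairs qualifying matrix among survivors, find the
    highest-keep-priority feature still in a qualifying pair, and discard
    its partners (the lower-area members), until no qualifying pair
    remains."""
    feats = table.features
    ids = list(table.feature_ids)
    adj = np.array([neutral_from_mz(m, md) for m, md in zip(feats["mz"], feats["mode"])])
    rt = feats["rt"].to_numpy(float)
    is_neg = (feats["mode"] == "ESI-").to_numpy()
    mean_area = table.mean_areas().to_numpy()
    keep_priority = [(mean_area[i], not is_neg[i], ids[i]) for i in range(len(ids))]
    alive = np.ones(len(ids), bool)
    removed = []
    while True:
        idx = np.where(alive)[0]
        a, r, neg = adj[idx], rt[idx], is_neg[idx]
        qual = (
            (np.abs(a[:, None] - a[None, :]) <= mass_tol)
            & (np.abs(r[:, None] - r[None, :]) <= rt_tol)
            & (neg[:, None] != neg[None, :])
        )
        np.fill_diagonal(qual, False)
        involved = idx[qual.any(axis=1)]
        if len(involved) == 0:
            break
        winner = max(involved, key=lambda i: keep_priority[i])
        losers = idx[qual[np.where(idx == winner)[0][0]]]
        for i in losers:
            alive[i] = False
            removed.append(ids[i])
    return [ids[i] for i in np.where(alive)[0]], removed


class TestBlankFilter:
    @pytest.fixture()
    def table_with_blanks(self):
        rng = np.random.default_rng(0)
        n = 10
        feats = pd.DataFrame(
            {"mode": ["ESI+"] * n, "mz": rng.uniform(100, 500, n), "rt": rng.uniform(1, 10, n)},
            index=[f"F{i}" for i in range(n)],
        )
        sample = np.full((n, 4), 1000.0)
        blank = np.zeros((n, 2))
        blank[0:3] = 500.0  # ratio 2 -> below min_ratio 5
        blank[3] = 200.0  # ratio 5 exactly -> boundary, retained
        areas = pd.DataFrame(
            np.hstack([sample, blank]),
            index=feats.index,
            columns=["S1", "S2", "S3", "S4", "BK1", "BK2"],
        )
        return FeatureTable(feats, areas)

    def test_planted_low_ratio_features_removed(self, table_with_blanks):
        out = features.blank_filter(table_with_blanks, ["BK1", "BK2"], min_ratio=5)
        assert len(out) == 7
        assert not any(f in out.feature_ids for f in ["F0", "F1", "F2"])

    def test_boundary_ratio_retained(self, table_with_blanks):
        out = features.blank_filter(table_with_blanks, ["BK1", "BK2"], min_ratio=5)
        assert "F3" in out.feature_ids  # ratio exactly 5 kept (>= rule)

    def test_zero_blank_mean_retained(self, table_with_blanks):
        out = features.blank_filter(table_with_blanks, ["BK1", "BK2"], min_ratio=5)
        assert all(f"F{i}" in out.feature_ids for i in range(4, 10))

    def test_blank_columns_dropped_from_output(self, table_with_blanks):
        out = features.blank_filter(table_with_blanks, ["BK1", "BK2"], min_ratio=5)
        assert not set(out.sample_ids) & {"BK1", "BK2"}

    def test_low_min_ratio_warns(self, table_with_blanks):
        with pytest.warns(UserWarning):
            features.blank_filter(table_with_blanks, ["BK1", "BK2"], min_ratio=0.5)

    def test_missing_blank_column_rejected(self, table_with_blanks):
        with pytest.raises(ValueError):
            features.blank_filter(table_with_blanks, ["NOPE"], min_ratio=5)


class TestDedup:
    def test_constructed_pair_drops_lower_area_member(self):
        feats = pd.DataFrame(
            {
                "mode": ["ESI+", "ESI-"],
                "mz": [301.1410, 299.1264],  # adjusted masses 0.000048 Da apart
                "rt": [5.0, 5.1],
            },
            index=["hi", "lo"],
        )
        areas = pd.DataFrame(
            [[100.0, 100.0], [40.0, 40.0]], index=feats.index, columns=["S1", "S2"]
        )
        out, removed = features.dedup_cross_mode(FeatureTable(feats, areas))
        assert removed == ["lo"] and list(out.feature_ids) == ["hi"]

    def test_rt_outside_tolerance_keeps_both(self):
        feats = pd.DataFrame(
            {"mode": ["ESI+", "ESI-"], "mz": [301.1410, 299.1264], "rt": [5.0, 5.25]},
            index=["a", "b"],
        )
        areas = pd.DataFrame([[100.0], [40.0]], index=feats.index, columns=["S1"])
        out, removed = features.dedup_cross_mode(FeatureTable(feats, areas))
        assert removed == [] and len(out) == 2

    def test_same_mode_never_deduped(self):
        feats = pd.DataFrame(
            {"mode": ["ESI+", "ESI+"], "mz": [301.1410, 301.1412], "rt": [5.0, 5.0]},
            index=["a", "b"],
        )
        areas = pd.DataFrame([[100.0], [40.0]], index=feats.index, columns=["S1"])
        _, removed = features.dedup_cross_mode(FeatureTable(feats, areas))
        assert removed == []

    def test_empty_table(self):
        feats = pd.DataFrame(columns=["mode", "mz", "rt"])
        out, removed = features.dedup_cross_mode(FeatureTable(feats, pd.DataFrame(index=feats.index)))
        assert len(out) == 0 and removed == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        table = random_two_mode_table(seed)
        out, removed = features.dedup_cross_mode(table)
        oracle_alive, oracle_removed = dedup_oracle(table)
        assert sorted(out.feature_ids) == sorted(oracle_alive)
        assert sorted(removed) == sorted(oracle_removed)

    def test_idempotent_and_partitioning(self):
        table = random_two_mode_table(123)
        out, removed = features.dedup_cross_mode(table)
        assert len(out) + len(removed) == len(table)
        again, removed2 = features.dedup_cross_mode(out)
        assert removed2 == [] and sorted(again.feature_ids) == sorted(out.feature_ids)

    def test_removed_features_have_surviving_partner(self):
        table = random_two_mode_table(7)
        out, removed = features.dedup_cross_mode(table)
        feats = table.features
        survivors = set(out.feature_ids)
        for fid in removed:
            adj = neutral_from_mz(feats.at[fid, "mz"], feats.at[fid, "mode"])
            partner = False
            for sid in survivors:
                if feats.at[sid, "mode"] == feats.at[fid, "mode"]:
                    continue
                adj2 = neutral_from_mz(feats.at[sid, "mz"], feats.at[sid, "mode"])
                if abs(adj - adj2) <= 0.002 and abs(feats.at[fid, "rt"] - feats.at[sid, "rt"]) <= 0.2:
                    partner = True
                    break
            assert partner, f"removed {fid} has no surviving partner"


def qc_style_cohort(seed=9, **overrides):
    """Zero-biology cohort: all variance in the areas is instrumental
    drift plus IS noise, like repeated injections of one pooled sample."""
    kwargs = dict(
        seed=seed, drift_batch_sd=0.15, drift_trend_amplitude=0.4,
        is_noise_cv=0.02, n_blanks=0, noise_floor=0.0,
    )
    kwargs.update(overrides)
    design = synth.CohortDesign(**kwargs)
    panel = [
        synth.SubstanceSpec(
            name=f"s{i}", sigma_between=0.0, sigma_within=0.0, log_mean=1.0,
            mode="ESI+" if i % 2 else "ESI-", neutral_mass=150.0 + 3 * i, rt=1 + 0.1 * i,
        )
        for i in range(60)
    ]
    return synth.generate_cohort(design, panel)


def median_cv(table):
    return float((table.areas.std(axis=1) / table.areas.mean(axis=1)).median())


class TestIsPcaCorrect:
    def test_reduces_drift_cv(self):
        table, meta, truth = qc_style_cohort()
        corrected = features.is_pca_correct(table, truth.is_matrix, 2)
        assert median_cv(corrected) < 0.5 * median_cv(table)

    def test_drift_free_table_unchanged(self):
        table, meta, truth = qc_style_cohort(
            drift_batch_sd=0.0, drift_trend_amplitude=0.0, is_noise_cv=0.0
        )
        with pytest.warns(UserWarning):
            corrected = features.is_pca_correct(table, truth.is_matrix, 2)
        rel = np.abs(corrected.areas.to_numpy() / table.areas.to_numpy() - 1)
        assert rel.max() < 1e-8

    def test_is_channels_batch_variance_removed(self):
        """Correcting the IS channels with their own PCA scores leaves
        almost no batch-explained variance."""
        table, meta, truth = qc_style_cohort()
        is_table = FeatureTable(
            pd.DataFrame(
                {
                    "mode": ["ESI+"] * len(truth.is_matrix),
                    "mz": np.linspace(200, 300, len(truth.is_matrix)),
                    "rt": np.linspace(1, 2, len(truth.is_matrix)),
                },
                index=truth.is_matrix.index,
            ),
            truth.is_matrix.copy(),
        )
        corrected = features.is_pca_correct(is_table, truth.is_matrix, 2)
        batches = meta.set_index("sample_id").loc[corrected.sample_ids, "batch"].to_numpy()
        for _, row in corrected.areas.iterrows():
            y = np.log10(row.to_numpy(float))
            grand = y.mean()
            ss_batch = sum(
                (y[batches == b].mean() - grand) ** 2 * (batches == b).sum()
                for b in np.unique(batches)
            )
            ss_tot = ((y - grand) ** 2).sum()
            assert ss_tot == 0 or ss_batch / ss_tot < 0.05

    def test_never_negative_and_zeros_preserved(self):
        table, meta, truth = qc_style_cohort(noise_floor=500.0)
        zero_mask = table.areas.to_numpy() == 0
        corrected = features.is_pca_correct(table, truth.is_matrix, 2)
        assert (corrected.areas.to_numpy() >= 0).all()
        assert (corrected.areas.to_numpy()[zero_mask] == 0).all()

    def test_too_many_components_rejected(self):
        table, meta, truth = qc_style_cohort(n_individuals=3, n_visits=2)
        with pytest.raises(ValueError):
            features.is_pca_correct(table, truth.is_matrix, n_components=6)


class TestVolumeNormalize:
    def test_divides_by_volume(self, small_cohort):
        table, meta, _ = small_cohort
        sub = table.subset(table.feature_ids[:5])
        sub = FeatureTable(sub.features, sub.areas[list(meta["sample_id"])])
        out = features.volume_normalize(sub, meta)
        vols = meta.set_index("sample_id")["volume"]
        expected = sub.areas.div(vols[sub.areas.columns], axis=1)
        pd.testing.assert_frame_equal(out.areas, expected)

    def test_unit_volumes_identity(self, small_cohort):
        table, meta, _ = small_cohort
        meta1 = meta.copy()
        meta1["volume"] = 1.0
        sub = table.subset(table.feature_ids[:5])
        sub = FeatureTable(sub.features, sub.areas[list(meta["sample_id"])])
        out = features.volume_normalize(sub, meta1)
        pd.testing.assert_frame_equal(out.areas, sub.areas)

    def test_fourfold_volume_scales_fourfold_down(self):
        feats = pd.DataFrame({"mode": ["ESI+"], "mz": [200.0], "rt": [1.0]}, index=["f"])
        areas = pd.DataFrame([[1000.0, 1000.0]], index=["f"], columns=["a", "b"])
        meta = pd.DataFrame({"sample_id": ["a", "b"], "volume": [50.0, 200.0]})
        out = features.volume_normalize(FeatureTable(feats, areas), meta)
        assert out.areas.at["f", "a"] == 4 * out.areas.at["f", "b"]

    def test_missing_volume_drops_sample(self):
        feats = pd.DataFrame({"mode": ["ESI+"], "mz": [200.0], "rt": [1.0]}, index=["f"])
        areas = pd.DataFrame([[10.0, 20.0]], index=["f"], columns=["a", "b"])
        meta = pd.DataFrame({"sample_id": ["a", "b"], "volume": [50.0, np.nan]})
        with pytest.warns(UserWarning):
            out = features.volume_normalize(FeatureTable(feats, areas), meta)
        assert list(out.sample_ids) == ["a"]


def test_process_runs_stages_in_order(small_cohort):
    table, meta, truth = small_cohort
    blanks = [c for c in table.sample_ids if c.startswith("BLANK")]
    out, log = features.process(table, meta, truth.is_matrix, blank_samples=blanks)
    stages = [s for s, _, _ in log.stages]
    assert stages == ["input", "blank_filter", "dedup_cross_mode", "is_pca_correct", "volume_normalize"]
    counts = [n for _, n, _ in log.stages]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
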