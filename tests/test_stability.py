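"""ICC estimation, reproducibility bins, exposure typing and class
summaries."""

import numpy as np
import pandas as pd
import pytest

from expolong import stability, synth


def balanced_data(seed=0, n_ind=20, n_vis=4, sb=0.5, sw=0.5):
    rng = np.random.default_rng(seed)
    vals = synth.simulate_log_concentrations(n_ind, n_vis, 0.0, sb, sw, rng).reshape(-1)
    parts = np.repeat([f"P{i}" for i in range(n_ind)], n_vis)
    return vals, parts


class TestIccOneway:
    def test_agrees_with_direct_variance_component_oracle(self):
        """On balanced data the estimator equals MSB/MSW computed
        directly from group means, to 1e-10."""
        vals, parts = balanced_data(seed=1)
        icc, msb, msw = stability.icc_oneway(vals, parts)
        mat = vals.reshape(20, 4)
        k = 4
        group_means = mat.mean(axis=1)
        grand = mat.mean()
        msb_direct = k * ((group_means - grand) ** 2).sum() / (len(group_means) - 1)
        msw_direct = ((mat - group_means[:, None]) ** 2).sum() / (mat.size - len(group_means))
        icc_direct = (msb_direct - msw_direct) / (msb_direct + (k - 1) * msw_direct)
        assert msb == pytest.approx(msb_direct, abs=1e-10)
        assert msw == pytest.approx(msw_direct, abs=1e-10)
        assert icc == pytest.approx(icc_direct, abs=1e-10)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        vals, parts = balanced_data(seed=2)
        icc, _, _ = stability.icc_oneway(vals, parts)
        frame = pd.DataFrame(
            {"targets": parts, "raters": np.tile(np.arange(4), 20), "ratings": vals}
        )
        table = pg.intraclass_corr(frame, targets="targets", raters="raters", ratings="ratings")
        icc1 = float(table.loc[table["Type"].str.startswith("ICC(1,1") | (table["Type"] == "ICC1"), "ICC"].iloc[0])
        assert icc == pytest.approx(icc1, abs=1e-8)

    def test_zero_within_variance_gives_one(self):
        vals, parts = balanced_data(seed=3, sw=0.0)
        icc, _, msw = stability.icc_oneway(vals, parts)
        assert icc == 1.0 and msw == 0.0

    def test_shared_mean_within_noise_only_clamped_to_zero(self):
        vals, parts = balanced_data(seed=4, n_ind=100, sb=0.0)
        icc, *_ , raw = stability.icc_components(vals, parts)
        assert icc < 0.05
        icc2, _, _ = stability.icc_oneway(np.tile([1.0, 2.0], 50), np.repeat(np.arange(50), 2))
        assert icc2 == 0.0  # negative raw estimate clamps to 0

    def test_affine_invariance(self):
        """ICC is unchanged by location/scale transforms of the values."""
        vals, parts = balanced_data(seed=5)
        icc, _, _ = stability.icc_oneway(vals, parts)
        icc_t, _, _ = stability.icc_oneway(3.7 * vals - 11.2, parts)
        assert icc == pytest.approx(icc_t, abs=1e-12)

    def test_unbalanced_uses_harmonic_mean_and_drops_singletons(self):
        vals, parts = balanced_data(seed=6)
        vals = np.append(vals, [0.3])
        parts = np.append(parts, ["LONER"])  # one visit: excluded
        icc, _, _ = stability.icc_oneway(vals, parts)
        icc_ref, _, _ = stability.icc_oneway(vals[:-1], parts[:-1])
        assert icc == pytest.approx(icc_ref)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            stability.icc_oneway([1.0, 1.0], ["a", "a"])
        with pytest.raises(ValueError):
            stability.icc_oneway([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(7)
        parts = np.repeat(np.arange(15), 4)
        vals = np.stack(
            [synth.simulate_log_concentrations(15, 4, 0.0, 0.4, 0.3, rng).reshape(-1) for _ in range(10)]
        )
        mat = stability.icc_matrix(vals, parts)
        for i in range(10):
            icc, _, _ = stability.icc_oneway(vals[i], parts)
            assert mat[i] == pytest.approx(icc, abs=1e-12)

    def test_twoway_close_to_oneway_without_visit_effects(self):
        vals, parts = balanced_data(seed=8, n_ind=40)
        visits = np.tile(np.arange(4), 40)
        icc1, _, _ = stability.icc_oneway(vals, parts)
        icc2, _, _ = stability.icc_twoway(vals, parts, visits)
        assert icc2 == pytest.approx(icc1, abs=0.05)


class TestIccBin:
    @pytest.mark.parametrize(
        "icc, expected",
        [
            (0.39, "poor"),
            (0.40, "fair_good"),
            (0.50, "fair_good"),
            (0.75, "fair_good"),
            (0.94, "excellent"),  # a highly persistent PFAS sits here
            (0.0, "poor"),
            (1.0, "excellent"),
        ],
    )
    def test_bins(self, icc, expected):
        assert stability.icc_bin(icc) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stability.icc_bin(1.2)


class TestClassifyExposureType:
    @pytest.mark.parametrize(
        "icc, df, expected",
        [
            (0.64, 0.032, stability.TYPE1),  # triphenylphosphine oxide
            (0.94, 1.00, stability.TYPE2),  # PFHxS
            (0.005, 0.83, stability.TYPE3),  # 1,3-diphenyl guanidine
            (0.33, 0.20, stability.TYPE4),  # 2,6-ditert-butyl-4-nitrophenol
            (0.5, 0.5, stability.UNCLASSIFIED),
            (0.45, 0.9, stability.UNCLASSIFIED),  # mid-ICC gap
            (0.9, 0.5, stability.UNCLASSIFIED),  # mid-DF gap
        ],
    )
    def test_worked_examples_and_gaps(self, icc, df, expected):
        assert stability.classify_exposure_type(icc, df) == expected

    def test_partition_is_disjoint_and_total(self):
        """Every (icc, df) grid point maps to exactly one label."""
        for icc in np.linspace(0, 1, 41):
            for df in np.linspace(0, 1, 41):
                label = stability.classify_exposure_type(icc, df)
                regions = [
                    df <= 0.20 and icc >= 0.6,
                    df >= 0.80 and icc >= 0.6,
                    df >= 0.80 and icc < 0.4,
                    df <= 0.20 and icc < 0.4,
                ]
                assert sum(regions) <= 1
                if not any(regions):
                    assert label == stability.UNCLASSIFIED

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stability.classify_exposure_type(1.1, 0.5)
        with pytest.raises(ValueError):
            stability.classify_exposure_type(0.5, -0.1)


class TestSummaries:
    def make_records(self, iccs_by_class):
        rows = []
        for cls, iccs in iccs_by_class.items():
            for i, icc in enumerate(iccs):
                rows.append(
                    {
                        "substance": f"{cls}{i}",
                        "class": cls,
                        "df": 0.9,
                        "icc": icc,
                        "exposure_type": stability.classify_exposure_type(icc, 0.9),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_distributions_give_null_comparison(self):
        iccs = list(np.linspace(0.1, 0.9, 9))
        records = self.make_records({"environmental": iccs, "endogenous": iccs})
        summary, tests = stability.summarize_stability(records)
        means = summary.set_index("class")["mean_icc"]
        assert means["environmental"] == pytest.approx(means["endogenous"])
        assert tests["t_tests"][("endogenous", "environmental")]["p"] == pytest.approx(1.0)

    def test_fraction_below_04(self):
        records = self.make_records({"only": [0.1, 0.5, 0.9]})
        summary, tests = stability.summarize_stability(records)
        assert summary["frac_poor"].iloc[0] == pytest.approx(1 / 3)
        assert summary["frac_excellent"].iloc[0] == pytest.approx(1 / 3)
        assert tests == {}  # single class: comparisons omitted

    def test_power_at_study_group_sizes(self):
        """True mean ICCs 0.30 vs 0.40 at n = 343/162 separate in most
        replicates."""
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 25
        for _ in range(n_rep):
            env = np.clip(rng.beta(2.0, 2.0 * 0.7 / 0.3, size=343), 0, 1)
            endo = np.clip(rng.beta(2.0, 2.0 * 0.6 / 0.4, size=162), 0, 1)
            records = self.make_records({"environmental": list(env), "endogenous": list(endo)})
            _, tests = stability.summarize_stability(records)
            if tests["t_tests"][("endogenous", "environmental")]["p"] < 0.05:
                hits += 1
        assert hits / n_rep > 0.8


def test_stability_record_assembly():
    vals, parts = balanced_data(seed=10, sb=0.6, sw=0.2)
    rec = stability.stability_record("pfhxs_like", "environmental", vals, parts, df=1.0)
    assert rec.exposure_type == stability.TYPE2
    assert rec.icc_bin in {"fair_good", "excellent"}
    frame = stability.records_to_frame([rec])
    assert list(frame["class"]) == ["environmental"]
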