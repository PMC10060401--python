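"""Statistics layer: summary t, Bonferroni, factorial engines."""

import numpy as np
import pandas as pd
import pytest

from swrlab import group_stats as gs


class TestTFromSummaries:
    def test_immobility_summary_reproduces_published_t(self):
        """Published immobility means/SEMs reproduce t(17) = 5.785."""
        wt = gs.GroupSummary(mean=100.8, sem=10.18, n=10)
        ko = gs.GroupSummary(mean=184.8, sem=10.29, n=9)
        res = gs.t_from_summaries(wt, ko, variant="pooled")
        assert res.df == 17
        assert abs(res.statistic) == pytest.approx(5.785, abs=0.02)
        assert res.p < 0.001

    def test_swapped_n_split_also_matches(self):
        res = gs.t_from_summaries(
            gs.GroupSummary(100.8, 10.18, 9), gs.GroupSummary(184.8, 10.29, 10)
        )
        assert abs(res.statistic) == pytest.approx(5.785, abs=0.02)

    def test_identical_groups(self):
        a = gs.GroupSummary(50.0, 2.0, 10)
        res = gs.t_from_summaries(a, a)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_matches_raw_sample_t(self, variant):
        """Summary-statistic t equals scipy's t on the raw samples."""
        from scipy import stats as sstats

        rng = np.random.default_rng(21)
        x = rng.normal(10.0, 3.0, size=12)
        y = rng.normal(12.0, 4.0, size=15)
        res = gs.t_from_summaries(
            gs.GroupSummary.from_samples(x),
            gs.GroupSummary.from_samples(y),
            variant=variant,
        )
        ref = sstats.ttest_ind(x, y, equal_var=(variant == "pooled"))
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_scale_invariance(self):
        a = gs.GroupSummary(10.0, 1.0, 8)
        b = gs.GroupSummary(12.0, 1.5, 9)
        c = 42.0
        r1 = gs.t_from_summaries(a, b)
        r2 = gs.t_from_summaries(
            gs.GroupSummary(a.mean * c, a.sem * c, a.n),
            gs.GroupSummary(b.mean * c, b.sem * c, b.n),
        )
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            gs.GroupSummary(10.0, 1.0, 1)


class TestBonferroni:
    def test_basic_adjustment(self):
        np.testing.assert_allclose(gs.bonferroni([0.01, 0.04]), [0.02, 0.08])

    def test_capped_at_one(self):
        assert gs.bonferroni([0.9], m=5)[0] == 1.0

    def test_single_comparison_identity(self):
        assert gs.bonferroni([0.3], m=1)[0] == pytest.approx(0.3)

    def test_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.random(20))
        adj = gs.bonferroni(p)
        assert np.all(adj >= p)
        assert np.all(np.diff(adj) >= 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gs.bonferroni([1.5])


class TestFitFactorial:
    def test_one_factor_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "group": ["a"] * 10 + ["b"] * 10,
                "y": np.r_[rng.normal(0, 1, 10), rng.normal(1, 1, 10)],
            }
        )
        res = gs.fit_factorial(df, "y", between=["group"])
        a = gs.GroupSummary.from_samples(df[df.group == "a"].y.to_numpy())
        b = gs.GroupSummary.from_samples(df[df.group == "b"].y.to_numpy())
        t = gs.t_from_summaries(a, b).statistic
        assert res.statistic.iloc[0] == pytest.approx(t**2, abs=1e-8)

    def test_mixed_design_detects_planted_interaction(self):
        from swrlab.synthetic import BehaviorSimConfig, simulate_behavior

        profile = {}
        for v in ("control", "DREADD"):
            for d in ("VEH", "CNO"):
                profile[("WT", v, d, "N1")], profile[("WT", v, d, "F")] = 60.0, 20.0
                profile[("KO", v, d, "N1")], profile[("KO", v, d, "F")] = 40.0, 40.0
        cfg = BehaviorSimConfig(
            n_per_group=13, effect_profile=profile, noise_sd=20.0,
            trials=("N1", "F"), drugs=("VEH",), seed=3,
        )
        table = simulate_behavior(cfg)
        sub = table[table.virus == "control"]
        res = gs.fit_factorial(
            sub, "interaction_time", between=["genotype"], within=["trial"],
            subject="mouse_id",
        )
        inter = res[res.term == "genotype:trial"].iloc[0]
        assert inter.p < 0.05

    def test_lmm_route_runs_full_design(self, behavior_table):
        nf = behavior_table[behavior_table.trial.isin(["N1", "F"])]
        res = gs.fit_factorial(
            nf, "interaction_time",
            between=["genotype", "virus", "drug"], within=["trial"],
            subject="mouse_id",
        )
        assert "genotype:virus:drug:trial" in set(res.term)
        assert ((res.p >= 0.0) & (res.p <= 1.0)).all()

    def test_electrode_shuffle_invariance(self):
        """Relabeling electrodes within a mouse leaves the fit unchanged."""
        rng = np.random.default_rng(8)
        rows = []
        for g in ("WT", "KO"):
            for m in range(6):
                mouse = f"{g}{m}"
                u = rng.normal(0, 1)
                for e in range(3):
                    rows.append(
                        {"mouse_id": mouse, "genotype": g, "electrode": e,
                         "power": u + rng.normal(0, 0.5) + (0.8 if g == "KO" else 0.0)}
                    )
        df = pd.DataFrame(rows)
        res1 = gs.fit_factorial(df, "power", between=["genotype"], within=[],
                                subject="mouse_id")
        shuffled = df.copy()
        shuffled["electrode"] = rng.permutation(shuffled["electrode"].to_numpy())
        res2 = gs.fit_factorial(shuffled, "power", between=["genotype"], within=[],
                                subject="mouse_id")
        assert res1.statistic.iloc[0] == pytest.approx(res2.statistic.iloc[0], rel=1e-8)

    def test_all_missing_rejected(self):
        df = pd.DataFrame({"g": ["a", "b"], "y": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            gs.fit_factorial(df, "y", between=["g"])

    def test_no_factors_rejected(self):
        with pytest.raises(ValueError):
            gs.fit_factorial(pd.DataFrame({"y": [1.0, 2.0]}), "y")


class TestPearsonCorr:
    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        y = x * 0.5 + rng.normal(size=10)
        res = gs.pearson_corr(x, y)
        from scipy import stats as sstats

        ref = sstats.pearsonr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestTukey:
    def test_pairwise_table_shape(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b", "c"], 8),
                "y": rng.normal(size=24) + np.repeat([0.0, 1.0, 2.0], 8),
            }
        )
        res = gs.tukey_pairwise(df, "y", "group")
        assert len(res) == 3  # three pairwise comparisons
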