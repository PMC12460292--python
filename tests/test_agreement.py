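import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from disctls.agreement import (Conventions, DegenerateDataError, VolumeAgreement,
                               bland_altman, build_report, ccc, grr, holm_adjust,
                               kruskal_wallis, mann_whitney_u, regression_metrics)
from disctls.synthetic import generate_paired_dataset


class TestRegressionMetrics:
    def test_hand_worked_pair(self):
        m = regression_metrics([100, 200], [110, 190])
        assert m["rmse"] == pytest.approx(10.0)
        assert m["bias"] == pytest.approx(0.0)
        assert m["rrmse"] == pytest.approx(100 * 10 / 150)

    def test_identity_is_perfect(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["rmse"] == 0 and m["bias"] == 0 and m["re"] == 0
        assert m["r_squared"] == 1.0 and m["rrmse"] == 0

    def test_rrmse_normalises_by_observed_mean(self):
        # an RMSE of 6.49 cm³ against observations averaging 148.62 cm³
        # corresponds to a relative RMSE of 4.37 %
        obs = np.array([148.62, 148.62])
        est = obs + np.array([6.49, -6.49])
        m = regression_metrics(obs, est)
        assert m["rmse"] == pytest.approx(6.49)
        assert round(m["rrmse"], 2) == 4.37

    def test_rrmse_scale_invariant(self, rng):
        x = rng.uniform(50, 300, 40)
        y = x + rng.normal(0, 10, 40)
        a = regression_metrics(x, y)["rrmse"]
        b = regression_metrics(x * 7.3, y * 7.3)["rrmse"]
        assert a == pytest.approx(b, rel=1e-12)


class TestBlandAltman:
    def test_reported_limits_reproduce(self):
        # pairs whose differences have mean −5.31 and sample SD 25.70 — the
        # agreement summary of the 123-disc validation — must yield limits
        # −55.68 and 45.06 (to 2 decimals)
        d_target, s_target = -5.31, 25.70
        diffs = d_target + s_target * np.array([-1.0, 0.0, 1.0])  # sample SD 1 basis
        obs = np.array([100.0, 200.0, 300.0])
        ba = bland_altman(obs, obs + diffs)
        assert ba["mean_diff"] == pytest.approx(d_target)
        assert ba["sd_diff"] == pytest.approx(s_target)
        assert round(ba["uloa"], 2) == 45.06
        assert round(ba["lloa"], 2) == -55.68

    def test_identity(self):
        ba = bland_altman([1, 2, 3], [1, 2, 3])
        assert ba["mean_diff"] == 0 and ba["sd_diff"] == 0
        assert ba["uloa"] == 0 and ba["lloa"] == 0

    def test_sample_sd_and_196(self):
        obs = np.array([10.0, 10.0, 10.0])
        est = obs + np.array([-1.0, 0.0, 1.0])
        ba = bland_altman(obs, est)
        assert ba["sd_diff"] == pytest.approx(1.0)  # (n-1) denominator
        assert ba["uloa"] == pytest.approx(1.96)
        assert ba["lloa"] == pytest.approx(-1.96)

    def test_limits_width_is_392_s(self, rng):
        obs = rng.uniform(50, 200, 30)
        est = obs + rng.normal(0, 20, 30)
        ba = bland_altman(obs, est)
        assert ba["uloa"] - ba["lloa"] == pytest.approx(2 * 1.96 * ba["sd_diff"])

    def test_direction_convention(self):
        obs, est = [100.0, 200.0], [90.0, 190.0]
        a = bland_altman(obs, est, Conventions(diff_direction="est_minus_obs"))
        b = bland_altman(obs, est, Conventions(diff_direction="obs_minus_est"))
        assert a["mean_diff"] == pytest.approx(-10.0)
        assert b["mean_diff"] == pytest.approx(10.0)


class TestCCC:
    def test_perfect_agreement(self):
        assert ccc([1, 2, 3], [1, 2, 3]) == 1.0

    def test_shifted_series_hand_value(self):
        # ρ=1, population σ² = 2/3 each, mean gap 1 → 2·(2/3)/(4/3 + 1) = 4/7
        assert ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7)

    def test_scaled_series_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = 2 * x
        rho = np.corrcoef(x, y)[0, 1]
        sx, sy = x.std(), y.std()
        expected = 2 * rho * sx * sy / (sx**2 + sy**2 + (x.mean() - y.mean())**2)
        got = ccc(x, y)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got < 1.0

    def test_ccc_bounded_by_pearson(self, rng):
        x = rng.uniform(0, 10, 50)
        y = 0.8 * x + rng.normal(0, 1, 50) + 2.0
        rho = abs(np.corrcoef(x, y)[0, 1])
        assert abs(ccc(x, y)) <= rho + 1e-12

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            ccc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGRR:
    def test_no_measurement_variance(self):
        res = grr([[10, 10, 10], [20, 20, 20], [30, 30, 30]])
        assert res["grr_percent"] == 0.0

    def test_all_variance_is_measurement(self):
        res = grr([[9, 10, 11], [10, 11, 9], [11, 9, 10]])
        assert res["grr_percent"] == 100.0  # part variance truncated at 0

    def test_simulation_recovery(self):
        # 10 parts × 3 repeats, σ²_parts = 9, σ²_repeat = 1 → expected GRR 10 %
        g = np.random.default_rng(11)
        vals = []
        for _ in range(500):
            parts = g.normal(0, 3.0, 10)
            data = parts[:, None] + g.normal(0, 1.0, (10, 3))
            vals.append(grr(list(data))["grr_percent"])
        assert np.mean(vals) == pytest.approx(10.0, abs=2.0)


class TestKruskalWallis:
    def test_single_group_collapses_to_zero(self):
        assert kruskal_wallis([[1, 2, 3]])["H"] == 0.0

    def test_matches_reference_implementation(self):
        groups = [[1, 2, 3], [4, 5, 6]]
        ours = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert ours["H"] == pytest.approx(ref.statistic, abs=1e-10)
        assert ours["p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_matches_reference_with_ties(self, rng):
        groups = [rng.integers(0, 6, 12).astype(float) for _ in range(3)]
        ours = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert ours["H"] == pytest.approx(ref.statistic, abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=10), rng.normal(size=8), rng.normal(size=12)]
        h1 = kruskal_wallis(groups)["H"]
        h2 = kruskal_wallis([np.exp(g) for g in groups])["H"]
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_all_identical_raises(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[5.0, 5.0], [5.0, 5.0]])


class TestMannWhitney:
    def test_hand_worked_statistic(self):
        # group1 (1,2): R₁ = 3, U = 2·2 + 2·3/2 − 3 = 4
        res = mann_whitney_u([1, 2], [3, 4])
        assert res["U1"] == 4.0

    def test_identical_groups_null_center(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res["p"] >= 0.99

    def test_exact_p_matches_enumeration(self):
        # n1 = n2 = 4, no ties: exact p must equal full 70-arrangement
        # enumeration (independent itertools oracle) and the reference
        # implementation's exact method
        from itertools import combinations
        g1, g2 = [1.2, 3.4, 5.6, 9.9], [2.1, 4.3, 6.5, 7.7]
        res = mann_whitney_u(g1, g2)
        pooled = np.array(g1 + g2)
        ranks = sps.rankdata(pooled)
        n1 = n2 = 4
        mid = n1 * n2 / 2

        def u_of(subset):
            r1 = ranks[list(subset)].sum()
            return n1 * n2 + n1 * (n1 + 1) / 2 - r1

        u_obs = u_of(range(4))
        dev = abs(u_obs - mid)
        hits = sum(abs(u_of(s) - mid) >= dev - 1e-12
                   for s in combinations(range(8), 4))
        assert res["p"] == pytest.approx(hits / 70)
        ref = sps.mannwhitneyu(g1, g2, alternative="two-sided", method="exact")
        assert res["p"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_one_sided_statistics_sum(self, rng):
        g1, g2 = rng.normal(size=9), rng.normal(size=14)
        res = mann_whitney_u(g1, g2)
        assert res["U1"] + res["U2"] == pytest.approx(9 * 14)

    def test_normal_approx_close_to_reference(self, rng):
        g1 = rng.integers(0, 10, 20).astype(float)
        g2 = rng.integers(0, 10, 25).astype(float) + 1.0
        ours = mann_whitney_u(g1, g2)
        ref = sps.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
        assert ours["p"] == pytest.approx(ref.pvalue, rel=1e-6)


class TestHolm:
    def test_step_down_values_and_cap(self):
        adj = holm_adjust([0.01, 0.04, 0.03, 0.9])
        assert adj[0] == pytest.approx(0.04)   # 4 × 0.01
        assert adj[2] == pytest.approx(0.09)   # max so far vs 3 × 0.03
        assert adj[3] == pytest.approx(0.9)
        assert all(a <= 1 for a in adj)
        # adjusted order follows raw order monotonically
        raw = [0.01, 0.04, 0.03, 0.9]
        pairs = sorted(zip(raw, adj))
        assert all(b2 >= b1 for (_, b1), (_, b2) in zip(pairs, pairs[1:]))


class TestVolumeAgreementModel:
    def _df(self, rng, n=40, bias=-5.0, sd=10.0):
        ref = rng.uniform(80, 300, n)
        return pd.DataFrame({
            "id": [f"s{i}" for i in range(n)],
            "species": ["A"] * (n // 2) + ["B"] * (n - n // 2),
            "estimated_volume": ref + bias + rng.normal(0, sd, n),
            "reference_volume": ref,
        })

    def test_singleton_species_skipped_with_note(self, rng):
        df = self._df(rng)
        df.loc[len(df)] = ["solo", "C", 100.0, 101.0]
        res = VolumeAgreement(df).fit()
        assert "C" not in res.per_species
        assert any("single sample" in n for n in res.notes)
        assert res.n == len(df)

    def test_identity_data(self):
        df = pd.DataFrame({"id": list("abcd"), "species": ["X", "X", "Y", "Y"],
                           "estimated_volume": [1.0, 2.0, 3.0, 4.0],
                           "reference_volume": [1.0, 2.0, 3.0, 4.0]})
        res = VolumeAgreement(df).fit()
        assert res.overall["rmse"] == 0
        assert res.ccc == 1.0
        assert res.kruskal_wallis is None  # degenerate: surfaced as not applicable
        assert any("not applicable" in n for n in res.notes)

    def test_injected_species_bias_detected(self):
        rejections = 0
        for seed in range(30):
            g = np.random.default_rng(seed)
            df = self._df(g, n=60, bias=0.0, sd=10.0)
            shift = df["species"] == "B"
            df.loc[shift, "estimated_volume"] += 30.0  # +3σ shift for one species
            res = VolumeAgreement(df).fit()
            rejections += res.kruskal_wallis["p"] < 0.05
        assert rejections >= 29

    def test_report_serializes_and_summarizes(self, rng):
        samples = generate_paired_dataset(seed=5)
        res = build_report(samples)
        blob = res.to_dict()
        import json
        json.dumps(blob)  # must be JSON-serializable
        assert blob["n"] == 123
        assert set(blob["per_species"]) == {
            "Altingia excelsa", "Robinia pseudoacacia",
            "Platycladus orientalis", "Quercus suber"}
        text = res.summary()
        assert "Bland–Altman" in text and "rRMSE" in text
        assert res.grr is not None  # replicate triplets present

    def test_bias_recovery_within_sampling_bound(self):
        # injected −5 cm³ bias, σ = 25 cm³, n = 123 → d̄ within 3σ/√n of −5
        bound = 3 * 25.0 / np.sqrt(123)
        for seed in (0, 1, 2):
            res = build_report(generate_paired_dataset(seed=seed))
            assert abs(res.bland_altman["mean_diff"] - (-5.0)) <= bound
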