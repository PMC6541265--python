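"""Small-study-bias methods: oracles, frozen reference values, invariants."""
import math

import numpy as np
import pytest

from smallmeta.bias import (cumulative_meta, egger_test, limit_meta,
                            top_precision, trim_and_fill)
from smallmeta.pooling import MetaAnalysis


class TestEgger:
    def test_symmetric_funnel_has_null_intercept(self, mirrored_set):
        z, v = mirrored_set
        res = egger_test(z, v)
        assert abs(res.t_stat) < 1.5
        assert res.df == len(z) - 2

    def test_normal_equations_oracle_four_studies(self):
        # closed-form OLS of z/se on 1/se, written out independently
        z = np.array([0.5, 0.3, 0.2, 0.1])
        v = np.array([0.05, 0.02, 0.01, 0.005])
        y, x = z / np.sqrt(v), 1 / np.sqrt(v)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        s2 = ((y - intercept - slope * x) ** 2).sum() / 2
        se_int = math.sqrt(s2 * (1 / 4 + x.mean() ** 2 / sxx))
        res = egger_test(z, v)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.t_stat == pytest.approx(intercept / se_int, abs=1e-10)

    def test_frozen_metafor_reference(self):
        # regtest(..., model="lm", predictor="sei") on the same four studies
        res = egger_test([0.5, 0.3, 0.2, 0.1], [0.05, 0.02, 0.01, 0.005])
        assert res.intercept == pytest.approx(2.691493586346, abs=1e-9)
        assert res.t_stat == pytest.approx(14.792790764879, abs=1e-8)
        assert res.p == pytest.approx(0.004538738835, abs=1e-9)
        assert res.slope == pytest.approx(-0.083910438098, abs=1e-9)

    def test_weighted_variant_runs_and_flags_same_direction(self, toy_asym):
        z, v = toy_asym
        classical = egger_test(z, v)
        weighted = egger_test(z, v, weighted=True)
        assert np.sign(classical.intercept) == np.sign(weighted.intercept)

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError):
            egger_test([0.1, 0.2], [0.01, 0.01])


class TestTrimAndFill:
    def test_symmetric_set_imputes_nothing(self, mirrored_set):
        z, v = mirrored_set
        res = trim_and_fill(z, v)
        assert res.k0 == 0
        unadjusted = MetaAnalysis(z, v).fit("DL")
        assert res.r_adjusted == pytest.approx(unadjusted.r_pooled, abs=1e-12)

    def test_frozen_metafor_reference_on_asymmetric_set(self, toy_asym):
        z, v = toy_asym
        res = trim_and_fill(z, v, method="DL")
        assert res.k0 == 5
        assert res.side == "right"
        assert res.results.mu_z == pytest.approx(0.065911636717, abs=1e-9)
        fe = trim_and_fill(z, v, method="FE")
        assert fe.results.mu_z == pytest.approx(0.059770114943, abs=1e-9)

    def test_rank_oracle_first_iteration(self, toy_asym):
        # brute-force L0 = (4*T - n(n+1))/(2n-1) at the full-set FE center
        z, v = toy_asym
        w = 1 / v
        center = (w * z).sum() / w.sum()
        dev = z - center
        ranks = np.argsort(np.argsort(np.abs(dev))) + 1
        t_sum = ranks[dev > 0].sum()
        l0 = max(0, round((4 * t_sum - 10 * 11) / 19))
        res = trim_and_fill(z, v)
        assert res.k0 >= l0  # iteration can only move k0 upward here

    def test_observed_studies_never_removed(self, toy_asym):
        z, v = toy_asym
        res = trim_and_fill(z, v)
        observed = res.filled[~res.filled["filled"]]
        assert len(observed) == len(z)
        np.testing.assert_allclose(np.sort(observed["z"]), np.sort(z))

    def test_idempotent_on_its_own_filled_set(self, toy_asym):
        z, v = toy_asym
        first = trim_and_fill(z, v)
        filled = first.filled
        second = trim_and_fill(filled["z"].to_numpy(), filled["se"].to_numpy() ** 2)
        assert second.k0 == 0

    def test_left_side_mirror_symmetry(self, toy_asym):
        z, v = toy_asym
        right = trim_and_fill(z, v)
        left = trim_and_fill(-z, v)
        assert left.side == "left"
        assert left.k0 == right.k0
        assert left.results.mu_z == pytest.approx(-right.results.mu_z, abs=1e-12)


class TestCumulative:
    def test_starts_at_most_precise_and_ends_at_full_pool(self, toy_het):
        z, v = toy_het
        cum = cumulative_meta(z, v)
        assert cum["k"].tolist() == [1, 2, 3, 4, 5]
        i_best = int(np.argmin(v))
        assert cum.iloc[0]["r_pooled"] == pytest.approx(np.tanh(z[i_best]))
        full = MetaAnalysis(z, v).fit("DL")
        assert cum.iloc[-1]["r_pooled"] == pytest.approx(full.r_pooled, abs=1e-12)

    def test_drifts_upward_on_selection_biased_data(self):
        from smallmeta.aggregate import aggregate_dataset
        from smallmeta.simulate import SyntheticConfig, generate

        drifts = []
        for seed in range(30):
            cfg = SyntheticConfig(k=40, mu_z=0.0, tau=0.0, m_outcomes=1,
                                  selection=0.9, seed=300 + seed)
            studies = aggregate_dataset(generate(cfg))
            cum = cumulative_meta(studies["z"].to_numpy(),
                                  studies["var_z"].to_numpy())
            half = len(cum) // 2
            drifts.append(cum.iloc[-1]["r_pooled"] - cum.iloc[half]["r_pooled"])
        assert np.mean(drifts) > 0


class TestTopPrecision:
    def test_k10_uses_single_most_precise(self):
        z = np.linspace(0.1, 1.0, 10)
        v = np.linspace(0.005, 0.05, 10)
        res = top_precision(z, v)
        assert res.k == 1
        assert res.r_pooled == pytest.approx(np.tanh(0.1))

    def test_ties_broken_by_study_id(self):
        z = np.array([0.4, 0.1, 0.2] + [0.3] * 9)
        v = np.array([0.01, 0.01, 0.01] + [0.05] * 9)
        ids = ["b", "a", "c"] + [f"x{i}" for i in range(9)]
        res = top_precision(z, v, study_ids=ids, frac=0.10)
        assert res.k == 2
        assert res.model.study_ids == ["a", "b"]

    def test_closer_to_truth_than_re_under_selection(self):
        from smallmeta.aggregate import aggregate_dataset
        from smallmeta.simulate import SyntheticConfig, generate

        wins = 0
        n_trials = 60
        for seed in range(n_trials):
            cfg = SyntheticConfig(k=40, mu_z=0.0, tau=0.0, m_outcomes=1,
                                  n_sigma=1.0, selection=0.9, seed=400 + seed)
            studies = aggregate_dataset(generate(cfg))
            model = MetaAnalysis.from_dataframe(studies)
            re = model.fit("DL")
            top = top_precision(studies["z"].to_numpy(),
                                studies["var_z"].to_numpy(),
                                study_ids=studies["study_id"].tolist())
            wins += abs(top.r_pooled) < abs(re.r_pooled)
        assert wins / n_trials >= 0.8


def limit_meta_oracle(z, v):
    """Second, independent evaluation of the extended-model equations via
    explicit weighted normal equations on the untransformed scale."""
    z, v = np.asarray(z, float), np.asarray(v, float)
    k = len(z)
    w = 1 / v
    mu_f = (w * z).sum() / w.sum()
    Q = (w * (z - mu_f) ** 2).sum()
    C = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - (k - 1)) / C)
    # WLS of z on x = sqrt(v + tau2) with weights 1/(v + tau2)
    x = np.sqrt(v + tau2)
    wr = 1 / (v + tau2)
    swx, sw = (wr * x).sum(), wr.sum()
    sxx, swz, sxz = (wr * x * x).sum(), (wr * z).sum(), (wr * x * z).sum()
    det = sw * sxx - swx**2
    beta = (sxx * swz - swx * sxz) / det   # intercept in z = beta + alpha*x
    alpha = (sw * sxz - swx * swz) / det
    return beta + alpha * math.sqrt(tau2), alpha, beta, tau2


class TestLimitMeta:
    def test_no_slope_by_construction_matches_pooled(self, mirrored_set):
        z, v = mirrored_set
        res = limit_meta(z, v)
        pooled = MetaAnalysis(z, v).fit("DL")
        assert res.r_limit == pytest.approx(pooled.r_pooled, abs=0.02)

    def test_matches_independent_normal_equations_oracle(self, toy_het):
        z, v = toy_het
        res = limit_meta(z, v)
        z_adj, alpha, beta, tau2 = limit_meta_oracle(z, v)
        assert res.z_limit == pytest.approx(z_adj, abs=1e-10)
        assert res.alpha == pytest.approx(alpha, abs=1e-10)
        assert res.beta == pytest.approx(beta, abs=1e-10)
        assert res.tau2 == pytest.approx(tau2, abs=1e-12)

    def test_q_decomposition_and_shrinkage_bounds(self, toy_het, toy_asym):
        for z, v in (toy_het, toy_asym):
            res = limit_meta(z, v)
            assert res.Q_small >= 0 and res.Q_resid >= 0
            assert res.Q_small + res.Q_resid <= res.Q + 1e-9
            assert np.all((res.G >= 0) & (res.G <= 1))

    def test_tau_zero_note_and_regression_limit(self):
        z, v = [0.2, 0.3, 0.4, 0.25], [1 / 50, 1 / 100, 1 / 150, 1 / 80]
        res = limit_meta(z, v)
        assert res.tau2 == 0.0
        assert "tau^2 = 0" in res.note
        assert res.z_limit == pytest.approx(res.beta, abs=1e-12)

    def test_adjustment_variants_agree_in_sign(self, toy_asym):
        z, v = toy_asym
        beta0 = limit_meta(z, v, adjust="beta0")
        betalim = limit_meta(z, v, adjust="betalim")
        mulim = limit_meta(z, v, adjust="mulim")
        unadjusted = MetaAnalysis(z, v).fit("DL").r_pooled
        for res in (beta0, betalim, mulim):
            assert res.r_limit < unadjusted  # all shrink the inflated estimate

    def test_d_conversion_of_limit_estimate(self, toy_het):
        res = limit_meta(*toy_het)
        assert res.d_limit == pytest.approx(
            2 * res.r_limit / math.sqrt(1 - res.r_limit**2), rel=1e-12)
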