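"""Random-effects pooling: frozen external reference values, hand oracle,
cross-checks against an independent library implementation, and invariants."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smallmeta.data import StudyEffect
from smallmeta.pooling import (MetaAnalysis, pool_fixed_effects,
                               pool_random_effects)


def dl_oracle(z, v):
    """Spreadsheet-style DerSimonian-Laird, written independently of the model."""
    z, v = np.asarray(z, float), np.asarray(v, float)
    w = 1 / v
    mu_f = (w * z).sum() / w.sum()
    Q = (w * (z - mu_f) ** 2).sum()
    tau2 = max(0.0, (Q - (len(z) - 1)) / (w.sum() - (w**2).sum() / w.sum()))
    wr = 1 / (v + tau2)
    return (wr * z).sum() / wr.sum(), tau2, Q


class TestAgainstFrozenMetaforValues:
    """Reference values computed once with the R package metafor (rma/regtest)."""

    def test_heterogeneous_five_study_set(self, toy_het):
        z, v = toy_het
        res = MetaAnalysis(z, v).fit("DL")
        assert res.mu_z == pytest.approx(0.252943234933, abs=1e-9)
        assert res.se_z == pytest.approx(0.090651987370, abs=1e-9)
        assert res.tau2 == pytest.approx(0.029283707865, abs=1e-9)
        assert res.Q == pytest.approx(19.795454545455, abs=1e-9)
        assert res.I2 == pytest.approx(79.79334099, abs=1e-6)
        lo, hi = res.conf_int_z()
        assert lo == pytest.approx(0.075268604560, abs=1e-9)
        assert hi == pytest.approx(0.430617865305, abs=1e-9)

    def test_reml_and_pm_estimators(self, toy_het):
        z, v = toy_het
        assert MetaAnalysis(z, v).fit("REML").tau2 == pytest.approx(
            0.036724984896, abs=1e-6)
        assert MetaAnalysis(z, v).fit("PM").tau2 == pytest.approx(
            0.037513584311, abs=1e-3)

    def test_homogeneous_three_study_set(self):
        z, v = [0.2, 0.3, 0.4], [1 / 50, 1 / 100, 1 / 150]
        res = MetaAnalysis(z, v).fit("DL")
        assert res.mu_z == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert res.tau2 == 0.0
        assert res.Q == pytest.approx(5.0 / 3.0, abs=1e-12)


class TestAgainstIndependentImplementations:
    def test_dl_matches_hand_oracle_to_1e10(self, toy_het):
        z, v = toy_het
        res = MetaAnalysis(z, v).fit("DL")
        mu_o, tau2_o, q_o = dl_oracle(z, v)
        assert res.mu_z == pytest.approx(mu_o, abs=1e-10)
        assert res.tau2 == pytest.approx(tau2_o, abs=1e-10)
        assert res.Q == pytest.approx(q_o, abs=1e-10)

    def test_dl_matches_statsmodels(self, toy_het):
        from statsmodels.stats.meta_analysis import combine_effects

        z, v = toy_het
        ours = MetaAnalysis(z, v).fit("DL")
        sm_res = combine_effects(z, v, method_re="dl")
        assert ours.tau2 == pytest.approx(sm_res.tau2, abs=1e-10)
        frame = sm_res.summary_frame()
        assert ours.mu_z == pytest.approx(
            frame.loc["random effect", "eff"], abs=1e-10)


class TestTrivialAndDegenerate:
    def test_identical_studies_pool_to_themselves(self):
        studies = [StudyEffect(f"S{i}", 0.2, np.arctanh(0.2), 1 / 47, 50, 1)
                   for i in range(6)]
        res = pool_random_effects(studies)
        assert res.r_pooled == pytest.approx(0.2, abs=1e-12)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.tau2 == 0.0
        assert res.I2 == 0.0

    def test_fixed_equals_random_when_tau_zero(self):
        z, v = [0.2, 0.3, 0.4], [1 / 50, 1 / 100, 1 / 150]
        re = pool_random_effects(MetaAnalysis(z, v))
        fe = pool_fixed_effects(MetaAnalysis(z, v))
        assert re.r_pooled == pytest.approx(fe.r_pooled, abs=1e-12)

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            MetaAnalysis([0.2], [0.01]).fit()

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            MetaAnalysis([0.2, 0.3], [0.01, 0.0])


class TestInvariants:
    def test_reordering_does_not_move_estimate(self, toy_het):
        z, v = toy_het
        perm = np.array([3, 1, 4, 0, 2])
        a = MetaAnalysis(z, v).fit("DL")
        b = MetaAnalysis(z[perm], v[perm]).fit("DL")
        assert a.r_pooled == pytest.approx(b.r_pooled, abs=1e-14)
        assert a.tau2 == pytest.approx(b.tau2, abs=1e-14)

    def test_re_interval_at_least_as_wide_as_fe(self, toy_het):
        z, v = toy_het
        re = MetaAnalysis(z, v).fit("DL")
        fe = MetaAnalysis(z, v).fit_fixed()
        assert (re.ci_high - re.ci_low) >= (fe.ci_high - fe.ci_low) - 1e-12

    def test_adding_study_at_pooled_value_is_neutral(self, toy_het):
        z, v = toy_het
        base = MetaAnalysis(z, v).fit("DL")
        z2 = np.append(z, base.mu_z)
        v2 = np.append(v, 0.02)
        grown = MetaAnalysis(z2, v2).fit("DL")
        assert grown.mu_z == pytest.approx(base.mu_z, abs=5e-3)

    def test_ci_brackets_estimate_and_i2_definition(self, toy_het):
        z, v = toy_het
        res = MetaAnalysis(z, v).fit("DL")
        assert res.ci_low <= res.r_pooled <= res.ci_high
        assert res.I2 == pytest.approx(max(0, (res.Q - res.df) / res.Q) * 100)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_pm_solves_its_estimating_equation(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(4, 12)
        v = rng.uniform(0.002, 0.05, k)
        z = rng.normal(0.2, 0.15, k) + rng.normal(0, np.sqrt(v))
        model = MetaAnalysis(z, v)
        res = model.fit("PM")
        if res.tau2 > 0:
            w = 1 / (v + res.tau2)
            mu = (w * z).sum() / w.sum()
            assert (w * (z - mu) ** 2).sum() == pytest.approx(k - 1, abs=1e-5)


class TestParameterRecovery:
    def test_recovery_without_selection(self):
        """k=200 studies, mu_z=.15, tau=.10: pooled r and tau2 recover truth."""
        from smallmeta.aggregate import aggregate_dataset
        from smallmeta.simulate import SyntheticConfig, generate

        rhats, tau2s = [], []
        for seed in range(100):
            cfg = SyntheticConfig(k=200, mu_z=0.15, tau=0.10, m_outcomes=1,
                                  seed=seed)
            studies = aggregate_dataset(generate(cfg))
            res = MetaAnalysis.from_dataframe(studies).fit("DL")
            rhats.append(res.r_pooled)
            tau2s.append(res.tau2)
        assert abs(np.mean(rhats) - np.tanh(0.15)) < 0.02
        assert abs(np.mean(tau2s) - 0.01) < 0.25 * 0.01


class TestReporting:
    def test_summary_contains_key_numbers(self, toy_het):
        res = MetaAnalysis(*toy_het).fit("DL")
        text = res.summary()
        assert "0.2475" in text or f"{res.r_pooled:.4f}" in text
        assert "I^2" in text and "tau^2" in text

    def test_to_dict_roundtrips_core_fields(self, toy_het):
        res = MetaAnalysis(*toy_het).fit("DL")
        d = res.to_dict()
        assert d["k"] == 5 and d["estimator"] == "DL"
        assert d["ci_low"] < d["r_pooled"] < d["ci_high"]
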