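"""Poisson tail bounds, compound Poisson-normal rates, heterologous bounds, AUROC."""

import math

import numpy as np
import pytest
from scipy.stats import poisson

from immfp import (
    ScoreDistributionModel,
    ToyRecombinationModel,
    det_and_auroc,
    downsample,
    equal_error_rule,
    fit_model_from_data,
    heterologous_bound_I,
    heterologous_bound_S,
    i_error_rates,
    s_error_bounds,
)
from immfp.error_model import shared_surprise_moments, surprise_moments
from immfp.pgen import default_toy_model
from immfp.synthetic import SyntheticConfig, generate_repertoire


def model(m_a=40.0, m_h=3.0, mu=5.0, var=9.0, mu_sh=1.5, var_sh=2.0):
    return ScoreDistributionModel(
        m_a=m_a, m_h=m_h, surprise_mean=mu, surprise_var=var,
        surprise_mean_shared=mu_sh, surprise_var_shared=var_sh,
    )


def equiprobable_model(K: int) -> ToyRecombinationModel:
    """K equiprobable sequences: K V tails, one J head, no insertions."""
    bases = "ACGT"
    tails = tuple(bases[i % 4] * 3 + bases[i // 4] * 3 for i in range(K))
    return ToyRecombinationModel(
        v_tails=tails, v_probs=(1.0 / K,) * K, j_heads=("GGATTC",), j_probs=(1.0,), p_ins=1.0
    )


class TestSBounds:
    def test_zero_threshold_is_void_probability(self):
        fnr, _ = s_error_bounds(0.0, model(m_a=10.0))
        assert fnr == pytest.approx(math.exp(-10.0), rel=1e-9)

    def test_no_heterologous_sharing_means_no_false_positives(self):
        for r in (0.0, 1.0, 7.5):
            assert s_error_bounds(r, model(m_h=0.0))[1] == 0.0

    @pytest.mark.parametrize("r", [0, 3, 12, 40])
    @pytest.mark.parametrize("m", [0.5, 8.0, 60.0])
    def test_integer_threshold_reproduces_poisson_partial_sum(self, r, m):
        fnr, fpr = s_error_bounds(r, model(m_a=m, m_h=m))
        partial = sum(math.exp(-m) * m**k / math.factorial(k) for k in range(r + 1))
        assert fnr == pytest.approx(partial, abs=1e-12)
        assert fpr == pytest.approx(1.0 - partial, abs=1e-12)

    def test_monotone_in_threshold(self):
        m = model()
        rs = np.linspace(0, 80, 40)
        fnr = [s_error_bounds(r, m)[0] for r in rs]
        fpr = [s_error_bounds(r, m)[1] for r in rs]
        assert all(a <= b + 1e-12 for a, b in zip(fnr, fnr[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(fpr, fpr[1:]))


class TestIRates:
    def test_cdf_limits(self):
        m = model()
        assert i_error_rates(-1e9, m)[0] == pytest.approx(0.0, abs=1e-12)
        assert i_error_rates(1e9, m)[0] == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_no_sharing_puts_all_mass_at_zero(self):
        m = model(m_a=0.0)
        assert i_error_rates(5.0, m)[0] == 1.0
        assert i_error_rates(-5.0, m)[0] == 0.0

    def test_matches_monte_carlo_oracle(self):
        """Compound Poisson-normal rates agree with direct simulation (3 SE)."""
        m = model()
        rng = np.random.default_rng(17)
        n = 10**6
        S = rng.poisson(m.m_a, n)
        I = np.where(S > 0, S * m.surprise_mean + np.sqrt(S * m.surprise_var) * rng.standard_normal(n), 0.0)
        Sh = rng.poisson(m.m_h, n)
        Ih = np.where(Sh > 0, Sh * m.surprise_mean_shared + np.sqrt(Sh * m.surprise_var_shared) * rng.standard_normal(n), 0.0)
        for r in (-5.0, 10.0, 120.0, 200.0):
            fnr, fpr = i_error_rates(r, m)
            e_fnr, e_fpr = (I < r).mean(), (Ih > r).mean()
            se1 = np.sqrt(max(e_fnr * (1 - e_fnr), 1e-12) / n)
            se2 = np.sqrt(max(e_fpr * (1 - e_fpr), 1e-12) / n)
            assert abs(fnr - e_fnr) < 3 * se1 + 1e-6
            assert abs(fpr - e_fpr) < 3 * se2 + 1e-6

    @pytest.mark.parametrize("r", [0.5, 5.5, 10.5])
    def test_reduces_to_s_statistic_when_surprise_degenerate(self, r):
        """With unit mean and zero variance, I is S; rates match the Poisson form."""
        m = model(m_a=10.0, m_h=2.0, mu=1.0, var=0.0, mu_sh=1.0, var_sh=0.0)
        fnr, fpr = i_error_rates(r, m)
        assert fnr == pytest.approx(float(poisson.cdf(math.floor(r), 10.0)), abs=1e-10)
        assert fpr == pytest.approx(float(poisson.sf(math.floor(r), 2.0)), abs=1e-10)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            model(var=-1.0)


class TestHeterologousBounds:
    def test_equiprobable_sequences_collision_rate(self):
        """K equiprobable sequences, q = 1: bound = M1*M2/K exactly in expectation."""
        K = 8
        bound = heterologous_bound_S(100, 200, equiprobable_model(K), q=1.0, n_draws=5000, seed=0)
        assert bound == pytest.approx(100 * 200 / K, rel=1e-9)  # all draws have p = 1/K

    def test_empty_sample_bound_is_zero(self):
        m = default_toy_model()
        assert heterologous_bound_S(0, 1000, m) == 0.0
        assert heterologous_bound_I(0, 1000, m) == 0.0

    def test_linear_in_sample_sizes(self):
        m = default_toy_model()
        b1 = heterologous_bound_S(1000, 1000, m, n_draws=2000, seed=5)
        b2 = heterologous_bound_S(2000, 1000, m, n_draws=2000, seed=5)
        assert b2 == pytest.approx(2 * b1, rel=1e-9)

    def test_single_public_sequence_closed_form(self):
        """P_gen = 1 for the only sequence: bound_I = -γ·M1·M2."""
        m = ToyRecombinationModel(("ACACAC",), (1.0,), ("GTGTGT",), (1.0,), p_ins=1.0)
        assert heterologous_bound_I(10, 20, m, q=1.0, gamma=12.0) == pytest.approx(-12.0 * 200)

    def test_invalid_selection_factor(self):
        with pytest.raises(ValueError):
            heterologous_bound_S(10, 10, default_toy_model(), q=0.0)


class TestDetAuroc:
    def test_indistinguishable_classes_give_chance(self):
        m = model(m_a=5.0, m_h=5.0, mu=2.0, var=4.0, mu_sh=2.0, var_sh=4.0)
        _, auroc = det_and_auroc(m, "I")
        assert auroc == pytest.approx(0.5, abs=0.01)

    def test_perfect_separation(self):
        m = model(m_a=50.0, m_h=0.0)
        for stat in ("S", "I"):
            _, auroc = det_and_auroc(m, stat)
            assert auroc > 0.999

    def test_monotone_in_autologous_rate(self):
        aurocs = [
            det_and_auroc(model(m_a=ma, m_h=2.0), "I")[1] for ma in (3.0, 6.0, 12.0, 24.0)
        ]
        assert all(a <= b + 1e-6 for a, b in zip(aurocs, aurocs[1:]))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            det_and_auroc(model(), "I", r_grid=[])

    def test_equal_error_rule_balances_bounds(self):
        rule = equal_error_rule(model(), "I")
        assert rule.fnr_bound < 0.05 and rule.fpr_bound < 0.05
        assert abs(rule.fnr_bound - rule.fpr_bound) < 0.05


@pytest.fixture(scope="module")
def two_deep_reps():
    rng = np.random.default_rng(40)
    reps = []
    for seed in (41, 42):
        truth = generate_repertoire(SyntheticConfig(n_clones=2000, seed=seed), rng)
        reps.append(downsample(truth, 50_000, rng))
    return reps


class TestModelFitting:
    def test_worst_case_individual_sets_autologous_rate(self, two_deep_reps):
        from immfp import expected_autologous_S

        fitted = fit_model_from_data(two_deep_reps, 1000, 1000, default_toy_model(), seed=1)
        expect = min(expected_autologous_S(r, 1000, 1000) for r in two_deep_reps)
        assert fitted.m_a == pytest.approx(expect)
        assert fitted.m_a > fitted.m_h * 0  # m_h finite; dominance checked below

    def test_convergently_shared_sequences_are_more_public(self):
        """Sequences generated in two independent cohorts have lower surprise
        (higher P_gen) than generic draws."""
        m = default_toy_model()
        mu, var = surprise_moments(m, gamma=12.0, n_draws=20000, seed=2)
        mu_sh, var_sh = shared_surprise_moments(m, gamma=12.0, n_draws=20000, seed=2)
        assert mu_sh < mu
        assert var_sh < var

    def test_requires_at_least_one_repertoire(self):
        with pytest.raises(ValueError):
            fit_model_from_data([], 100, 100, default_toy_model())
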