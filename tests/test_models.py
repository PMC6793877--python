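"""Outcome encodings, the value function, choice rule and likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import effortchoice as ec
from effortchoice.models import P_EPS


class TestEncoding:
    def test_reference_maps_to_zero_for_delta_kinds(self):
        for kind in ("delta_linear", "delta_quadratic", "delta_power"):
            assert ec.encode_outcome(35.0, kind, gamma=1.61) == pytest.approx(0.0)

    def test_linear_extremes(self):
        assert ec.encode_outcome(0.0, "delta_linear") == pytest.approx(35.0)
        assert ec.encode_outcome(70.0, "delta_linear") == pytest.approx(-35.0)

    def test_quadratic_loss_extreme(self):
        assert ec.encode_outcome(70.0, "delta_quadratic") == pytest.approx(-3675.0)

    def test_power_kind_requires_gamma(self):
        with pytest.raises(ValueError, match="gamma"):
            ec.encode_outcome(35.0, "delta_power")

    def test_sign_convention(self):
        # effort reductions and money gains positive; increases/losses negative
        assert ec.encode_outcome(14.0, "delta_power", gamma=2.0) > 0
        assert ec.encode_outcome(56.0, "delta_power", gamma=2.0) < 0
        assert ec.encode_outcome(-50.0, "money_power_signed", gamma=0.7) < 0
        assert ec.encode_outcome(50.0, "money_linear") == 50.0

    def test_absolute_power_always_nonnegative(self):
        b = np.arange(0, 71, 3.5)
        assert (ec.encode_outcome(b, "absolute_power", gamma=1.24) >= 0).all()

    def test_zero_to_the_gamma_is_zero(self):
        # continuous extension 0**g := 0 keeps the b=0 / $0 arms defined
        assert ec.encode_outcome(0.0, "absolute_power", gamma=0.0) == 0.0
        assert ec.encode_outcome(0.0, "money_power_signed", gamma=0.5) == 0.0


class TestSubjectiveValue:
    def test_identity_for_gains_at_alpha_one(self):
        assert ec.subjective_value(10.0, alpha=1.0, lam=3.0) == pytest.approx(10.0)

    def test_loss_scaling(self):
        assert ec.subjective_value(-10.0, alpha=1.0, lam=1.52) == pytest.approx(-15.2)
        assert ec.subjective_value(-10.0, alpha=1.0, lam=1.0) == pytest.approx(-10.0)

    def test_zero_maps_to_zero(self):
        assert ec.subjective_value(0.0, alpha=0.0, lam=2.0) == 0.0

    @given(x=st.floats(0.1, 100), lam=st.floats(0.1, 5), alpha=st.floats(0.1, 3))
    @settings(max_examples=50, deadline=None)
    def test_odd_symmetry_scaled_by_lam(self, x, lam, alpha):
        sv_gain = ec.subjective_value(x, alpha, lam)
        sv_loss = ec.subjective_value(-x, alpha, lam)
        assert sv_loss == pytest.approx(-lam * sv_gain, rel=1e-9)


class TestLotteryUtility:
    def test_symmetric_gamble_symmetric_valuation(self, hybrid):
        params = {"lam": 1.0, "gamma": 1.0, "mu": 1.0}
        # b=0 gain arm vs b=70 loss arm: X = +35 / −35
        assert hybrid.lottery_utility(0.0, 70.0, params) == pytest.approx(0.0)

    def test_loss_aversion_shifts_utility(self):
        m = ec.get_model("no_sensitivity_linear")
        # X+ = 10 (b=25), X− = −10 (b=45), lam=2 → 0.5·10 − 0.5·2·10 = −5
        assert m.lottery_utility(25.0, 45.0, {"lam": 2.0, "mu": 1.0}) == pytest.approx(-5.0)

    def test_degenerate_reference_lottery_is_zero(self, hybrid):
        params = {"lam": 0.71, "gamma": 1.61, "mu": 0.064}
        assert hybrid.lottery_utility(35.0, 35.0, params) == pytest.approx(0.0)

    def test_linear_symmetric_equals_expected_value(self):
        m = ec.get_model("no_loss_aversion_linear")
        b_gain, b_loss = 14.0, 63.0
        ev = 0.5 * (35 - b_gain) + 0.5 * (35 - b_loss)
        assert m.lottery_utility(b_gain, b_loss, {"mu": 1.0}) == pytest.approx(ev)


class TestSureBet:
    def test_reference_framed_models_have_zero_sure_bet(self):
        for name in ("symmetric_linear", "no_sensitivity_quadratic",
                     "loss_aversion_encoding", "symmetric_money"):
            m = ec.get_model(name)
            params = {p: 1.0 for p in m.free_params}
            assert ec.sure_bet_utility(m, params) == 0.0

    def test_zero_effort_reference_sure_bet(self):
        m = ec.get_model("zero_effort_reference")
        assert ec.sure_bet_utility(m, {"gamma": 1.0, "mu": 1.0}) == pytest.approx(-35.0)

    def test_large_money_reference_sure_bet(self):
        m = ec.get_model("large_money_reference")
        assert ec.sure_bet_utility(m, {"gamma": 1.0, "mu": 1.0}) == pytest.approx(100.0)


class TestAcceptProbability:
    def test_mu_zero_is_random_choice(self):
        assert ec.accept_probability(123.4, 0.0, 0.0) == pytest.approx(0.5)

    def test_indifference_is_half(self):
        assert ec.accept_probability(3.0, 3.0, 7.0) == pytest.approx(0.5)

    def test_deterministic_limit(self):
        assert ec.accept_probability(1.0, 0.0, 1e6) == pytest.approx(1.0)
        assert ec.accept_probability(-1.0, 0.0, 1e6) == pytest.approx(0.0)

    def test_stable_at_extreme_arguments(self):
        p = ec.accept_probability(-1e6, 0.0, 10.0)
        assert 0.0 <= p <= 1.0 and np.isfinite(p)

    @given(du=st.floats(-3, 3), mu=st.floats(0.001, 8))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_utility_difference(self, du, mu):
        # arguments kept below logistic float saturation
        p1 = ec.accept_probability(du, 0.0, mu)
        p2 = ec.accept_probability(du + 1.0, 0.0, mu)
        assert p2 > p1


class TestNegativeLogLikelihood:
    def test_random_choice_gives_n_log_two(self):
        n = 20
        nll = ec.negative_log_likelihood(np.ones(n), np.full(n, 0.5))
        assert nll == pytest.approx(n * np.log(2))

    def test_single_trial(self):
        assert ec.negative_log_likelihood([1], [0.9]) == pytest.approx(-np.log(0.9))

    def test_additivity_under_duplication(self):
        r = [1, 0, 1]
        p = [0.7, 0.2, 0.9]
        assert ec.negative_log_likelihood(r + r, p + p) == pytest.approx(
            2 * ec.negative_log_likelihood(r, p))

    def test_matches_explicit_bernoulli_product(self):
        # brute-force oracle on a small instance
        rng = np.random.default_rng(0)
        r = rng.integers(0, 2, size=8)
        p = rng.uniform(0.05, 0.95, size=8)
        product = np.prod([pi if ri else 1 - pi for ri, pi in zip(r, p)])
        assert ec.negative_log_likelihood(r, p) == pytest.approx(-np.log(product))

    def test_finite_under_deterministic_probabilities(self):
        nll = ec.negative_log_likelihood([1, 0], [0.0, 1.0])
        assert np.isfinite(nll)
        assert nll == pytest.approx(-2 * np.log(P_EPS))

    def test_rejects_empty_and_nonbinary(self):
        with pytest.raises(ValueError):
            ec.negative_log_likelihood([], [])
        with pytest.raises(ValueError):
            ec.negative_log_likelihood([2], [0.5])


class TestModelSpaceStructure:
    def test_effort_space_has_eight_models_with_expected_arity(self):
        space = ec.effort_model_space()
        assert len(space) == 8
        arity = {m.name: m.n_params for m in space}
        assert arity["symmetric_linear"] == 3
        assert arity["no_sensitivity_quadratic"] == 2
        assert arity["no_loss_aversion_linear"] == 1
        assert arity["zero_effort_reference"] == 2
        assert arity["loss_aversion_encoding"] == 3

    def test_financial_space_has_five_models(self):
        assert len(ec.financial_model_space()) == 5

    def test_hybrid_with_gamma_one_nests_linear_no_sensitivity(self, eff_grid):
        hybrid = ec.get_model("loss_aversion_encoding")
        linear = ec.get_model("no_sensitivity_linear")
        b_gain = eff_grid["b_gain"].to_numpy()
        b_loss = eff_grid["b_loss"].to_numpy()
        for lam, mu in [(0.5, 0.3), (1.7, 2.0)]:
            p_h = hybrid.accept_probability(b_gain, b_loss, {"lam": lam, "gamma": 1.0, "mu": mu})
            p_l = linear.accept_probability(b_gain, b_loss, {"lam": lam, "mu": mu})
            assert np.allclose(p_h, p_l)

    def test_get_model_unknown_name(self):
        with pytest.raises(KeyError):
            ec.get_model("nonexistent")


def test_delta_models_monotone_in_arm_severity(hybrid):
    """P(accept) falls as the loss arm worsens and rises as the gain arm improves."""
    params = {"lam": 0.71, "gamma": 1.61, "mu": 0.1}
    losses = np.arange(35.0, 70.1, 3.5)
    p_vs_loss = hybrid.accept_probability(np.full_like(losses, 17.5), losses, params)
    assert (np.diff(p_vs_loss) < 0).all()
    gains = np.arange(0.0, 35.1, 3.5)
    p_vs_gain = hybrid.accept_probability(gains, np.full_like(gains, 52.5), params)
    assert (np.diff(p_vs_gain) < 0).all()  # larger b_gain = smaller gain
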