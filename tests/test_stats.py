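"""Rejection matrices, Mann-Kendall, SV tables, parameter comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import effortchoice as ec


class TestRejectionMatrix:
    def test_all_accept_gives_zero_matrix(self, eff_grid):
        ch = eff_grid.copy()
        ch["subject_id"] = "s1"
        ch["response"] = 1
        rej = ec.rejection_matrix(ch)
        assert (rej.matrix.to_numpy() == 0).all()
        assert rej.matrix.shape == (11, 11)

    def test_single_subject_cells_are_thirds(self, eff_grid, hybrid):
        rng = np.random.default_rng(0)
        ch = ec.simulate_choices({"lam": 1.0, "gamma": 1.0, "mu": 0.05},
                                 hybrid, eff_grid, rng)
        rej = ec.rejection_matrix(ch)
        vals = rej.matrix.to_numpy().ravel()
        assert np.isin(np.round(vals * 3), [0, 1, 2, 3]).all()

    def test_deterministic_ev_rule_splits_along_diagonal(self, eff_grid):
        """mu→∞ symmetric linear chooser: reject iff |loss| > |gain|."""
        model = ec.get_model("no_loss_aversion_linear")
        rng = np.random.default_rng(1)
        ch = ec.simulate_choices({"mu": 1e6}, model, eff_grid, rng)
        rej = ec.rejection_matrix(ch)
        for gain_pct, loss_pct in itertools.product(range(-100, 1, 10), range(0, 101, 10)):
            v = rej.matrix.loc[gain_pct, loss_pct]
            if loss_pct > -gain_pct:
                assert v == 1.0
            elif loss_pct < -gain_pct:
                assert v == 0.0

    def test_marginals_are_matrix_means(self, eff_grid, hybrid):
        rng = np.random.default_rng(2)
        ch = ec.simulate_choices({"lam": 0.71, "gamma": 1.61, "mu": 0.064},
                                 hybrid, eff_grid, rng)
        rej = ec.rejection_matrix(ch)
        assert np.allclose(rej.gain_marginal, rej.matrix.mean(axis=1))
        assert np.allclose(rej.loss_marginal, rej.matrix.mean(axis=0))

    def test_missing_cells_are_nan(self):
        ch = pd.DataFrame({
            "subject_id": ["s1"] * 2, "task": ["EFF"] * 2,
            "gain_pct": [-10, -20], "loss_pct": [10, 20], "response": [1, 0]})
        rej = ec.rejection_matrix(ch)
        assert np.isnan(rej.matrix.loc[-10, 20])
        assert rej.matrix.loc[-20, 20] == 1.0


class TestMannKendall:
    def test_strictly_increasing_length_11(self):
        t = ec.mann_kendall_trend(np.arange(11))
        assert t.s == 55 and t.p_value < 0.001

    def test_strictly_decreasing_antisymmetry(self):
        t = ec.mann_kendall_trend(np.arange(11)[::-1])
        assert t.s == -55

    def test_constant_sequence(self):
        t = ec.mann_kendall_trend(np.ones(8))
        assert t.s == 0 and t.p_value == 1.0

    def test_requires_four_points(self):
        with pytest.raises(ValueError):
            ec.mann_kendall_trend([1, 2, 3])

    @given(st.lists(st.integers(0, 5), min_size=4, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_s_matches_exhaustive_pair_oracle(self, xs):
        t = ec.mann_kendall_trend(xs)
        s_oracle = sum(np.sign(xs[j] - xs[i])
                       for i in range(len(xs)) for j in range(i + 1, len(xs)))
        assert t.s == s_oracle
        assert 0.0 <= t.p_value <= 1.0


class TestSvByCondition:
    def test_symmetric_parameters_mirror(self, hybrid):
        tab = ec.sv_by_condition({"lam": 1.0, "gamma": 1.0, "mu": 1.0}, hybrid)
        assert np.allclose(tab["sv_gain"], -tab["sv_loss"])
        assert len(tab) == 10

    def test_convex_encoding_steepens_losses(self, hybrid):
        tab = ec.sv_by_condition({"lam": 1.0, "gamma": 2.0, "mu": 1.0}, hybrid)
        assert (tab["sv_loss"].abs() > tab["sv_gain"].abs()).all()

    def test_money_conditions_are_dollars(self):
        m = ec.get_model("symmetric_money")
        tab = ec.sv_by_condition({"lam": 1.52, "alpha": 0.74, "mu": 1.24}, m)
        assert np.allclose(tab["condition"], np.arange(10, 101, 10))
        assert (tab["sv_loss"] < 0).all() and (tab["sv_gain"] > 0).all()


class TestLossGainRatio:
    def test_symmetric_case_is_one(self, hybrid):
        assert ec.loss_gain_ratio({"lam": 1.0, "gamma": 1.0, "mu": 1.0}, hybrid) == \
            pytest.approx(1.0)

    def test_quadratic_closed_form(self, hybrid):
        """gamma=2, lam=1: per-condition ratio ((35+d)²−35²)/(35²−(35−d)²)."""
        d = np.arange(3.5, 35.01, 3.5)
        expected = np.mean(((35 + d) ** 2 - 35**2) / (35**2 - (35 - d) ** 2))
        got = ec.loss_gain_ratio({"lam": 1.0, "gamma": 2.0, "mu": 1.0}, hybrid)
        assert got == pytest.approx(expected)
        assert got > 1.0

    def test_relief_seeking_lowers_ratio(self, hybrid):
        assert ec.loss_gain_ratio({"lam": 0.5, "gamma": 1.0, "mu": 1.0}, hybrid) == \
            pytest.approx(0.5)


class TestCompareParameters:
    def test_no_difference_when_all_at_null(self):
        rep = ec.compare_parameters(np.ones(10), null_value=1.0)
        assert rep["wilcoxon_p"] == 1.0

    def test_identical_vectors_correlate_perfectly(self):
        a = np.array([0.4, 0.7, 1.1, 1.6, 0.9])
        rep = ec.compare_parameters(a, a.copy())
        assert rep["pearson_r"] == pytest.approx(1.0)
        assert rep["wilcoxon_p"] == 1.0

    def test_shifted_parameters_detected(self):
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(np.log(1.5), 0.1, size=18))
        rep = ec.compare_parameters(vals, null_value=1.0)
        assert rep["wilcoxon_p"] < 0.001
        assert rep["median"] > 1.3

    def test_directionality_consistency_count(self):
        a = np.array([1.2, 1.3, 0.7, 0.8, 1.5])
        b = np.array([1.1, 0.9, 0.6, 0.9, 1.4])
        rep = ec.compare_parameters(a, b, null_value=1.0)
        # pairs 0, 2, 3, 4 agree in direction; pair 1 straddles unity
        assert rep["consistent_directionality"] == 4

    def test_shared_latents_correlate_between_sessions(self, eff_grid, hybrid):
        """Test-retest: per-subject lam latents recovered from two sessions correlate."""
        from effortchoice.cohort import ParamDist
        dist = {"lam": ParamDist("lognormal", 0.71, (0.14, 0.99)),
                "gamma": 1.61, "mu": 0.2}
        spec = ec.CohortSpec(12, "EFF", hybrid, dist, eff_grid, seed=31)
        lams, fit_a, fit_b = [], [], []
        for i in range(12):
            params = ec.draw_subject_params(spec, i)
            lams.append(params["lam"])
            for session_seed, store in ((1, fit_a), (2, fit_b)):
                rng = np.random.default_rng(1000 * session_seed + i)
                ch = ec.simulate_choices(params, hybrid, eff_grid, rng)
                fit = ec.fit_subject(ch, hybrid, n_restarts=10, seed=i)
                store.append(fit.params["lam"])
        rep = ec.compare_parameters(np.array(fit_a), np.array(fit_b))
        assert rep["pearson_r"] > 0.8
        assert rep["wilcoxon_p"] > 0.05  # same latents: no systematic shift

    def test_requires_three_observations(self):
        with pytest.raises(ValueError):
            ec.compare_parameters([1.0, 2.0])


def test_sv_condition_anova_runs(eff_grid, hybrid):
    """Delegated RM-ANOVA returns the domain × condition effect table."""
    rng = np.random.default_rng(3)
    rows = []
    for i in range(6):
        lam = float(np.exp(rng.normal(np.log(0.71), 0.3)))
        rows.append({"subject_id": f"s{i}", "lam": lam,
                     "gamma": float(np.exp(rng.normal(np.log(1.61), 0.2))), "mu": 0.1})
    fits = pd.DataFrame(rows)
    table = ec.sv_condition_anova(fits, hybrid)
    sources = set(table["Source"])
    assert "domain" in sources and "condition" in sources
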