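"""Unit and property tests for the elementary model mechanisms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from lookdyn import (
    ActivationState,
    InvalidParameterError,
    InvalidStateError,
    ModelParams,
    boost,
    decay,
    duration_distribution,
    sample_duration,
    selection_probabilities,
)

BASELINES = np.array([1.1, 1.0, 0.37])


class TestSelectionProbabilities:
    @pytest.mark.parametrize(
        "a, nu, rho, current, expected",
        [
            (BASELINES, 1.0, 0.0, None, np.array([0.44534, 0.40486, 0.14980])),
            (np.ones(3), 1.0, 0.0, None, np.full(3, 1 / 3)),
            (np.ones(3), 1.0, 1.0, 0, np.array([0.5, 0.25, 0.25])),
        ],
    )
    def test_examples(self, a, nu, rho, current, expected):
        p = ModelParams(nu=nu, rho=rho)
        pi = selection_probabilities(a, p, current=current)
        np.testing.assert_allclose(pi, expected, atol=5e-6)

    def test_winner_takes_all_limit(self):
        """Very large nu selects the highest-activation AOI almost surely."""
        p = ModelParams(nu=200.0, rho=0.0)
        pi = selection_probabilities(np.array([1.54, 1.0, 0.37]), p)
        assert pi[0] > 1 - 1e-10

    def test_rejects_bad_state(self):
        p = ModelParams()
        with pytest.raises(InvalidStateError):
            selection_probabilities(np.array([1.0, -1.0, 0.4]), p)
        with pytest.raises(InvalidStateError):
            selection_probabilities(np.array([1.0, np.nan, 0.4]), p)
        with pytest.raises(InvalidStateError):
            selection_probabilities(np.ones(3), p, current=5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.floats(0.05, 20.0), min_size=3, max_size=3),
        nu=st.floats(0.1, 50.0),
        rho=st.floats(0.0, 5.0),
        current=st.sampled_from([None, 0, 1, 2]),
    )
    def test_is_a_distribution(self, a, nu, rho, current):
        pi = selection_probabilities(
            np.array(a), ModelParams(nu=nu, rho=rho), current=current
        )
        assert np.all(pi >= 0) and np.all(pi <= 1)
        assert abs(pi.sum() - 1.0) < 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.floats(0.1, 5.0), min_size=3, max_size=3),
        bump=st.floats(0.01, 5.0),
        rho=st.floats(0.0, 3.0),
    )
    def test_monotone_in_activation_and_bias(self, a, bump, rho):
        p = ModelParams(nu=1.3, rho=rho)
        a = np.array(a)
        pi = selection_probabilities(a, p, current=1)
        a2 = a.copy()
        a2[0] += bump
        pi2 = selection_probabilities(a2, p, current=1)
        assert pi2[0] >= pi[0]
        p_hi = ModelParams(nu=1.3, rho=rho + 1.0)
        pi3 = selection_probabilities(a, p_hi, current=1)
        assert pi3[1] >= pi[1]  # larger refixation bias favours current AOI

    def test_nu_growth_converges_to_argmax(self):
        a = np.array([1.3, 1.0, 0.9])
        last = 0.0
        for nu in (1, 5, 25, 125, 625):
            pi = selection_probabilities(a, ModelParams(nu=float(nu), rho=0.0))
            assert pi[0] >= last
            last = pi[0]
        assert last > 1 - 1e-8


class TestDecay:
    def test_identity_at_zero_dt(self):
        p = ModelParams()
        s = ActivationState(np.array([2.0, 1.5, 0.5]))
        out = decay(s, 0.0, p)
        np.testing.assert_array_equal(out.a, s.a)

    def test_halving_time(self):
        """omega = ln2/100 halves the excess above baseline every 100 ms."""
        p = ModelParams(omega=np.log(2) / 100, a0=(1.0, 1.0, 0.37))
        s = ActivationState(np.array([2.0, 1.0, 0.37]))
        out = decay(s, 100.0, p)
        assert out.a[0] == pytest.approx(1.5, abs=1e-12)
        assert out.t == pytest.approx(100.0)

    def test_asymptotic_baseline(self):
        p = ModelParams()
        s = ActivationState(np.array([5.0, 3.0, 2.0]))
        out = decay(s, 1e9, p)
        np.testing.assert_allclose(out.a, p.a0, atol=1e-12)

    def test_negative_dt_rejected(self):
        with pytest.raises(InvalidStateError):
            decay(ActivationState(np.ones(3)), -1.0, ModelParams())

    def test_closed_form_matches_numerical_integration(self, rng):
        """The exponential closed form solves da/dt = omega(a0 - a) exactly.

        Checked against high-order numerical integration over a full
        5-second trial for randomized initial values, baselines and rates.
        """
        worst = 0.0
        for _ in range(20):
            A = rng.uniform(0.4, 5.0, size=3)
            a0 = rng.uniform(0.2, 1.5, size=3)
            omega = rng.uniform(1e-4, 5e-3)
            p = ModelParams(omega=omega, a0=tuple(a0))
            ts = np.linspace(0.0, 5000.0, 41)
            sol = solve_ivp(
                lambda t, a: omega * (a0 - a), (0.0, 5000.0), A,
                t_eval=ts, rtol=1e-10, atol=1e-12,
            )
            for k, t in enumerate(ts):
                closed = decay(ActivationState(A), t, p).a
                worst = max(worst, np.max(np.abs(closed - sol.y[:, k])))
        assert worst < 1e-6


class TestBoost:
    def test_target_boost(self):
        p = ModelParams(lam=(1.4, 1.1, 1.1))
        s = ActivationState(np.array(p.a0))
        out = boost(s, 0, p)
        assert out.a[0] == pytest.approx(1.54)
        np.testing.assert_array_equal(out.a[1:], s.a[1:])

    def test_unit_lambda_is_identity(self):
        p = ModelParams(lam=(1.0, 1.0, 1.0))
        s = ActivationState(np.array([1.2, 0.8, 0.5]))
        np.testing.assert_array_equal(boost(s, 1, p).a, s.a)

    def test_outside_boost(self):
        p = ModelParams(lam=(1.4, 1.1, 1.1))
        out = boost(ActivationState(np.array(p.a0)), 2, p)
        np.testing.assert_allclose(out.a, [1.1, 1.0, 0.407])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        ops=st.lists(
            st.tuples(st.sampled_from([0, 1, 2]), st.floats(0.0, 2000.0)),
            min_size=1, max_size=30,
        )
    )
    def test_dynamics_never_drop_below_baseline(self, ops):
        """Boosts raise, decay stops at baseline: a_i >= a0_i always."""
        p = ModelParams()
        s = ActivationState.at_baseline(p)
        for aoi, dt in ops:
            s = decay(boost(s, aoi, p), dt, p)
            assert np.all(s.a >= np.array(p.a0) - 1e-12)


class TestDurations:
    def test_unmodulated_distribution(self):
        p = ModelParams(gamma=0.0, sigma=8.0, mu_t=200.0)
        shape, rate = duration_distribution(1.54, p)
        assert shape == pytest.approx(8.0)
        assert rate == pytest.approx(0.04)
        # gamma=0: identical law for any activation
        assert duration_distribution(0.37, p) == (shape, rate)

    def test_modulated_mean(self):
        p = ModelParams(gamma=0.5, sigma=8.0, mu_t=200.0)
        shape, rate = duration_distribution(1.0, p)
        assert shape / rate == pytest.approx(300.0)

    def test_rejects_nonpositive_activation(self):
        with pytest.raises(InvalidStateError):
            duration_distribution(0.0, ModelParams())

    def test_sample_moments(self, rng):
        p = ModelParams(gamma=0.0, sigma=8.0, mu_t=200.0)
        draws = np.array([sample_duration(1.0, p, rng) for _ in range(100_000)])
        se = 200.0 / np.sqrt(8.0) / np.sqrt(draws.size)
        assert abs(draws.mean() - 200.0) < 3 * se
        cv2 = draws.var() / draws.mean() ** 2
        assert cv2 == pytest.approx(1 / 8.0, rel=0.05)

    def test_sampling_is_deterministic_given_seed(self):
        p = ModelParams()
        a = [sample_duration(1.0, p, np.random.default_rng(7)) for _ in range(3)]
        b = [sample_duration(1.0, p, np.random.default_rng(7)) for _ in range(3)]
        assert a == b


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"nu": 0.0}, {"nu": -1.0}, {"rho": -0.1}, {"omega": 0.0},
            {"lam": (0.9, 1.1, 1.1)}, {"gamma": -0.5}, {"mu_t": 0.0},
            {"sigma": -2.0}, {"a0": (0.0, 1.0, 0.37)}, {"mu_t": np.inf},
        ],
    )
    def test_bounds_enforced(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ModelParams(**kwargs)

    def test_vector_round_trip(self):
        p = ModelParams(nu=2.0, rho=0.7, lam=(1.5, 1.2, 1.05))
        q = ModelParams.from_vector(p.to_vector(), a0=p.a0)
        assert p == q

    def test_named_access(self):
        p = ModelParams()
        assert p.value_of("lam2") == p.lam[1]
        assert p.with_value("mu_t", 250.0).mu_t == 250.0
        with pytest.raises(InvalidParameterError):
            p.value_of("delta")
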