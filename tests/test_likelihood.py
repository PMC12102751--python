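"""Likelihood tests, including an independent arithmetic oracle.

The oracle replays the deterministic activation dynamics with explicit
step-by-step arithmetic and scipy's gamma density/survival functions —
separate from the implementation under test, which uses its own packed
replay and stable log-forms.
"""

import numpy as np
import pytest
from scipy import stats as sps

from lookdyn import (
    DataError,
    InvalidParameterError,
    ModelParams,
    ScanPath,
    dataset_loglik,
    default_profile_grid,
    profile_loglik,
    scanpath_loglik,
    simulate_individual,
)
from lookdyn._fastlik import fast_total_loglik
from lookdyn.likelihood import loglik_terms, pack_paths

ORACLE_PARAMS = ModelParams(
    nu=1.3, rho=0.4, omega=2e-3, lam=(1.4, 1.1, 1.1), gamma=0.5, mu_t=220.0, sigma=7.0
)


def oracle_loglik(aois, durations, truncated_last, p: ModelParams) -> float:
    """Step-by-step arithmetic replay of the sequential likelihood."""
    a = np.array(p.a0, dtype=float)
    total = 0.0
    n = len(aois)
    for j, (i, T) in enumerate(zip(aois, durations)):
        a[i] = a[i] * p.lam[i]                      # boost at onset
        mu_eff = p.mu_t * (1.0 + p.gamma * a[i])
        scale = mu_eff / p.sigma
        if truncated_last and j == n - 1:
            total += sps.gamma.logsf(T, p.sigma, scale=scale)
        else:
            total += sps.gamma.logpdf(T, p.sigma, scale=scale)
        a = np.array(p.a0) + (a - np.array(p.a0)) * np.exp(-p.omega * T)
        if j < n - 1:
            k = aois[j + 1]
            w = a ** p.nu
            w[i] += p.rho
            total += np.log(w[k] / w.sum())
    return total


class TestScanpathLoglik:
    @pytest.mark.parametrize(
        "aois, durs, trunc",
        [
            ([0, 0], [200.0, 300.0], True),
            ([0, 1, 0], [200.0, 300.0, 150.0], True),
            ([2, 1, 1, 0], [120.0, 340.0, 260.0, 90.0], False),
        ],
    )
    def test_matches_arithmetic_oracle(self, aois, durs, trunc):
        path = ScanPath.from_arrays(
            aois, durs, trial_duration_ms=sum(durs), last_truncated=trunc
        )
        bd = scanpath_loglik(path, ORACLE_PARAMS)
        expected = oracle_loglik(aois, durs, trunc, ORACLE_PARAMS)
        assert bd.total == pytest.approx(expected, abs=1e-9)
        assert bd.total == pytest.approx(
            bd.selection_term + bd.duration_term, abs=1e-10
        )
        assert bd.n_fixations == len(aois)

    def test_first_fixation_aoi_is_conditioned_on(self):
        """Single-fixation paths carry only a duration term."""
        path = ScanPath.from_arrays([1], [250.0], trial_duration_ms=250.0)
        bd = scanpath_loglik(path, ORACLE_PARAMS)
        assert bd.selection_term == 0.0
        assert bd.total == bd.duration_term

    def test_higher_at_generating_parameters(self, params):
        """Averaged over trials, the generating parameters beat a strong
        perturbation of the target boost."""
        sess = simulate_individual(params, 100, seed=17)
        wrong = params.replace(lam=(3 * 1.4, 1.1, 1.1))
        ll_true = dataset_loglik(sess.scan_paths, params).total
        ll_wrong = dataset_loglik(sess.scan_paths, wrong).total
        assert ll_true > ll_wrong

    def test_collapsed_model_gives_iid_gamma_durations(self, neutral_params):
        """gamma=0, lam=1, rho=0: duration term is an iid gamma likelihood."""
        rng = np.random.default_rng(3)
        durs = rng.gamma(8.0, 200.0 / 8.0, size=40)
        path = ScanPath.from_arrays([int(x) for x in rng.integers(0, 3, 40)],
                                    durs, trial_duration_ms=durs.sum())
        bd = scanpath_loglik(path, neutral_params)
        p = neutral_params
        expected = sps.gamma.logpdf(durs, p.sigma, scale=p.mu_t / p.sigma).sum()
        assert bd.duration_term == pytest.approx(expected, abs=1e-8)

    def test_invalid_inputs(self, params):
        with pytest.raises(DataError):
            dataset_loglik([], params)
        with pytest.raises(DataError):
            ScanPath.from_arrays([0, 1], [200.0, -5.0], trial_duration_ms=195.0)
        # a gap between fixations violates contiguity
        with pytest.raises(DataError):
            ScanPath(
                fixations=(
                    (0, 0.0, 200.0, False),
                    (1, 300.0, 100.0, False),
                ),
                trial_duration_ms=400.0,
            )


class TestDatasetLoglik:
    def test_additive_over_trials(self, params):
        sess = simulate_individual(params, 6, seed=21)
        paths = sess.scan_paths
        total = dataset_loglik(paths, params).total
        parts = sum(scanpath_loglik(p, params).total for p in paths)
        assert total == pytest.approx(parts, abs=1e-8)
        # singleton reduces to scanpath_loglik
        assert dataset_loglik(paths[:1], params).total == pytest.approx(
            scanpath_loglik(paths[0], params).total, abs=1e-10
        )
        # order invariance
        perm = [paths[i] for i in np.random.default_rng(0).permutation(len(paths))]
        assert dataset_loglik(perm, params).total == pytest.approx(total, abs=1e-8)

    def test_fast_path_agrees_with_reference(self, session_32, rng):
        """The compiled MCMC path reproduces the reference replay."""
        packed = pack_paths(session_32.scan_paths)
        a0 = np.array(session_32.params.a0)
        for _ in range(25):
            theta = np.array([
                rng.uniform(0.5, 3.0), rng.uniform(0.0, 1.5), rng.uniform(2e-4, 5e-3),
                rng.uniform(1.0, 2.0), rng.uniform(1.0, 2.0), rng.uniform(1.0, 2.0),
                rng.uniform(0.0, 1.0), rng.uniform(120.0, 400.0), rng.uniform(2.0, 15.0),
            ])
            sel, dur = loglik_terms(packed, theta[None, :], a0)
            ref = float(sel[0] + dur[0])
            fast = fast_total_loglik(packed, theta, a0)
            assert fast == pytest.approx(ref, abs=1e-9 * max(1.0, abs(ref)))

    def test_parameter_bounds_raise_not_minus_inf(self, session_32):
        packed = pack_paths(session_32.scan_paths)
        bad = ModelParams().to_vector()
        bad[0] = -1.0
        with pytest.raises(InvalidParameterError):
            loglik_terms(packed, bad[None, :], np.array([1.1, 1.0, 0.37]))


class TestProfileLoglik:
    def test_single_point_grid_equals_dataset_loglik(self, params, session_32):
        prof = profile_loglik(
            session_32.scan_paths, params, "mu_t", np.array([params.mu_t])
        )
        assert prof.loglik_values[0] == pytest.approx(
            dataset_loglik(session_32.scan_paths, params).total, abs=1e-8
        )

    def test_omega_profile_peaks_near_truth(self, params):
        sess = simulate_individual(params, 150, seed=31)
        grid = default_profile_grid(params, "omega", n_points=21)
        prof = profile_loglik(sess.scan_paths, params, "omega", grid)
        k = int(np.argmax(prof.loglik_values))
        k_true = int(np.argmin(np.abs(np.log(grid) - np.log(params.omega))))
        assert abs(k - k_true) <= 1

    def test_lam1_profile_separates_regimes(self):
        """Data generated with a strong target boost prefer lam1=1.4 to 1.1."""
        strong = ModelParams(lam=(1.4, 1.1, 1.1))
        sess = simulate_individual(strong, 150, seed=32)
        grid = np.array([1.1, 1.4])
        prof = profile_loglik(sess.scan_paths, strong, "lam1", grid)
        assert prof.loglik_values[1] > prof.loglik_values[0]

    def test_grid_validation(self, params, session_32):
        with pytest.raises(InvalidParameterError):
            profile_loglik(session_32.scan_paths, params, "omega",
                           np.array([2e-3, 1e-3]))
        with pytest.raises(InvalidParameterError):
            profile_loglik(session_32.scan_paths, params, "lam1",
                           np.array([0.5, 1.5]))
        with pytest.raises(InvalidParameterError):
            profile_loglik(session_32.scan_paths, params, "zeta", np.array([1.0]))

    def test_profile_is_smooth_on_fine_grids(self, params):
        """No spurious jumps: second differences stay bounded relative to
        the profile's overall curvature scale."""
        sess = simulate_individual(params, 40, seed=33)
        grid = np.geomspace(params.mu_t / 1.5, params.mu_t * 1.5, 41)
        prof = profile_loglik(sess.scan_paths, params, "mu_t", grid)
        d2 = np.diff(prof.loglik_values, 2)
        assert np.max(np.abs(d2)) < 0.1 * (
            prof.loglik_values.max() - prof.loglik_values.min() + 1.0
        )
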