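"""Bayesian estimation of the nine free gaze-model parameters.

The posterior is sampled per individual with the affine-invariant
ensemble sampler (emcee) on a transformed scale: logs of the strictly
positive parameters, ``log(rho + eps)`` / ``log(gamma + eps)`` for the
two nonnegative ones and ``log(lambda - 1 + eps)`` for the boost
factors, so every point of the sampling space maps to a legal parameter
vector. Priors are independent normals on the transformed scale
(log-normal on the natural scale), weakly informative around plausible
infant gaze dynamics. Walkers start in a small ball around a
Nelder-Mead MAP estimate found from the prior mean, which makes short
chains usable; convergence diagnostics (rank-normalised R-hat and
effective sample size, walkers treated as chains) are attached to every
fit. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import emcee
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._fastlik import fast_total_loglik
from .likelihood import PackedPaths, pack_paths
from .params import DEFAULT_BASELINES, PARAM_NAMES, InvalidParameterError, ModelParams
from .scanpath import ScanPath
from .simulate import SimulatedSession, TrialConfig, simulate_individual

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorChain",
    "RecoveryReport",
    "default_priors",
    "transform_to_unconstrained",
    "transform_to_natural",
    "fit_individual",
    "posterior_predict",
    "recovery_experiment",
    "coverage_table",
]

#: Offsets keeping the log transforms finite at the closed lower bounds
#: rho = 0, gamma = 0 and lambda = 1.
EPS_NONNEG = 1e-2
EPS_LAM = 1e-2

_LOG_COLS = (0, 2, 7, 8)        # nu, omega, mu_t, sigma: plain log
_SHIFT_COLS = (1, 6)            # rho, gamma: log(x + eps)
_LAM_COLS = (3, 4, 5)           # lambdas: log(x - 1 + eps)


def transform_to_unconstrained(theta: np.ndarray) -> np.ndarray:
    """Map natural-scale parameter rows to the unconstrained MCMC scale."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    z = np.empty_like(theta)
    z[:, list(_LOG_COLS)] = np.log(theta[:, list(_LOG_COLS)])
    z[:, list(_SHIFT_COLS)] = np.log(theta[:, list(_SHIFT_COLS)] + EPS_NONNEG)
    z[:, list(_LAM_COLS)] = np.log(theta[:, list(_LAM_COLS)] - 1.0 + EPS_LAM)
    return z


def transform_to_natural(z: np.ndarray) -> np.ndarray:
    """Inverse of :func:`transform_to_unconstrained`; always in-bounds."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    theta = np.empty_like(z)
    theta[:, list(_LOG_COLS)] = np.exp(z[:, list(_LOG_COLS)])
    theta[:, list(_SHIFT_COLS)] = np.maximum(
        np.exp(z[:, list(_SHIFT_COLS)]) - EPS_NONNEG, 0.0
    )
    theta[:, list(_LAM_COLS)] = 1.0 + np.maximum(
        np.exp(z[:, list(_LAM_COLS)]) - EPS_LAM, 0.0
    )
    return theta


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors on the transformed parameter scale."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float)
        s = np.asarray(self.sd, dtype=float)
        if m.shape != (9,) or s.shape != (9,):
            raise InvalidParameterError("prior mean/sd must have length 9")
        if np.any(s <= 0):
            raise InvalidParameterError("prior sds must be > 0")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "sd", s)

    def logpdf(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(z)
        r = (z - self.mean) / self.sd
        return -0.5 * np.sum(r * r, axis=1) - np.sum(np.log(self.sd)) \
            - 4.5 * np.log(2.0 * np.pi)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.mean + self.sd * rng.standard_normal((n, 9))


def default_priors() -> PriorSpec:
    """Weakly informative defaults.

    Centres (natural scale): nu ~ 1.5, rho ~ 0.5, omega ~ 1.5e-3 /ms
    (decay half-life ~0.5 s), lambda - 1 ~ 0.2, gamma ~ 0.3, mu_t ~ 250
    ms, sigma ~ 6; log-scale sds of 0.4-1.0 span roughly an order of
    magnitude around each centre.
    """
    centre = np.array([1.5, 0.5, 1.5e-3, 1.2, 1.2, 1.2, 0.3, 250.0, 6.0])
    mean = transform_to_unconstrained(centre)[0]
    sd = np.array([0.6, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.4, 0.5])
    return PriorSpec(mean=mean, sd=sd)


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-sampler settings; defaults suit a 32-trial individual."""

    n_walkers: int = 32
    n_steps: int = 2500
    burn_frac: float = 0.5
    init_scale: float = 0.02
    map_maxfev: int = 4000

    def __post_init__(self) -> None:
        if self.n_walkers < 18:
            raise InvalidParameterError("need at least 2x9 walkers")
        if self.n_steps < 2:
            raise InvalidParameterError("n_steps must be >= 2")
        if not 0.0 <= self.burn_frac < 1.0:
            raise InvalidParameterError("burn_frac must be in [0, 1)")

    @property
    def n_burn(self) -> int:
        return int(self.burn_frac * self.n_steps)


#: Chains whose rank-normalised R-hat exceeds this are flagged, not hidden.
RHAT_THRESHOLD = 1.05


@dataclass
class PosteriorChain:
    """Post-burn-in posterior draws for one individual.

    ``draws`` is (n_draws, 9) on the natural parameter scale in
    :data:`~lookdyn.params.PARAM_NAMES` order.
    """

    draws: np.ndarray
    log_prob: np.ndarray
    param_names: tuple[str, ...]
    a0: tuple[float, float, float]
    rhat: np.ndarray
    ess: np.ndarray
    acceptance_fraction: float
    map_params: ModelParams
    seed: int
    n_walkers: int
    converged: bool = True

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def median_params(self) -> ModelParams:
        return ModelParams.from_vector(np.median(self.draws, axis=0), a0=self.a0)

    def credible_interval(self, level: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
        alpha = 0.5 * (1.0 - level)
        lo = np.quantile(self.draws, alpha, axis=0)
        hi = np.quantile(self.draws, 1.0 - alpha, axis=0)
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(self.param_names))
        df["log_prob"] = self.log_prob
        return df

    def export_csv(self, path) -> None:
        """One row per draw, header = parameter names (generic MCMC tools)."""
        self.to_frame().to_csv(path, index=False)


def _diagnostics(chain_zw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """R-hat and ESS per parameter; chain_zw is (steps, walkers, 9)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        ds = az.convert_to_dataset(np.swapaxes(chain_zw, 0, 1))
        rhat = np.asarray(az.rhat(ds)["x"].values, dtype=float)
        ess = np.asarray(az.ess(ds)["x"].values, dtype=float)
    return rhat, ess


def fit_individual(
    paths: Optional[list[ScanPath]],
    priors: Optional[PriorSpec] = None,
    mcmc_config: Optional[MCMCConfig] = None,
    seed: int = 0,
    a0: tuple[float, float, float] = DEFAULT_BASELINES,
    prior_only: bool = False,
) -> PosteriorChain:
    """Sample the posterior over the nine free parameters for one individual.

    ``prior_only=True`` drops the likelihood (for validating the sampler:
    posterior quantiles must then reproduce the prior).
    """
    priors = priors or default_priors()
    cfg = mcmc_config or MCMCConfig()
    if prior_only:
        packed = None
    else:
        if not paths:
            raise InvalidParameterError("need at least one trial (or prior_only=True)")
        packed = pack_paths(paths)
    a0_arr = np.asarray(a0, dtype=float)

    def log_post_one(z: np.ndarray) -> float:
        lp = float(priors.logpdf(z[None, :])[0])
        if packed is None:
            return lp
        theta = transform_to_natural(z[None, :])[0]
        ll = fast_total_loglik(packed, theta, a0_arr)
        if not np.isfinite(ll):
            return -np.inf
        return lp + ll

    def log_post_vec(zs: np.ndarray) -> np.ndarray:
        return np.array([log_post_one(z) for z in np.atleast_2d(zs)])

    # deterministic MAP from the prior mean; short chains then only need
    # to explore the mode, not find it
    res = minimize(
        lambda z: -log_post_one(z),
        priors.mean,
        method="Nelder-Mead",
        options={"maxfev": cfg.map_maxfev, "xatol": 1e-4, "fatol": 1e-4},
    )
    z_map = res.x
    if not np.isfinite(log_post_one(z_map)):
        raise RuntimeError("non-finite posterior at the MAP initialisation point")

    rng = np.random.default_rng(seed)
    p0 = z_map + cfg.init_scale * rng.standard_normal((cfg.n_walkers, 9))
    # differential-evolution moves mix much faster than the default
    # stretch move on this correlated 9-d posterior
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        cfg.n_walkers, 9, log_post_vec, vectorize=True, moves=moves
    )
    sampler.random_state = np.random.RandomState(seed % (2**31)).get_state()
    sampler.run_mcmc(p0, cfg.n_steps, progress=False)

    chain_z = sampler.get_chain(discard=cfg.n_burn)       # (steps, walkers, 9)
    logp = sampler.get_log_prob(discard=cfg.n_burn)
    rhat, ess = _diagnostics(chain_z)
    flat_z = chain_z.reshape(-1, 9)
    draws = transform_to_natural(flat_z)
    chain = PosteriorChain(
        draws=draws,
        log_prob=logp.reshape(-1),
        param_names=PARAM_NAMES,
        a0=tuple(a0_arr),
        rhat=rhat,
        ess=ess,
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
        map_params=ModelParams.from_vector(transform_to_natural(z_map[None, :])[0], a0=tuple(a0_arr)),
        seed=int(seed),
        n_walkers=cfg.n_walkers,
        converged=bool(np.all(rhat < RHAT_THRESHOLD)),
    )
    return chain


def posterior_predict(
    chain: PosteriorChain,
    n_draws: int,
    trial_template: TrialConfig = TrialConfig(),
    n_trials: int = 32,
    seed: int = 0,
) -> list[SimulatedSession]:
    """Simulate sessions from parameter vectors drawn from the posterior.

    Draws are taken without replacement; each returned session carries
    the index of its generating draw.
    """
    if n_draws < 0:
        raise InvalidParameterError("n_draws must be >= 0")
    if n_draws > chain.n_draws:
        raise InvalidParameterError(
            f"requested {n_draws} draws but chain holds {chain.n_draws}"
        )
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    idx = rng.choice(chain.n_draws, size=n_draws, replace=False)
    sessions = []
    for child, i in zip(ss.spawn(n_draws + 1)[1:], idx):
        params = ModelParams.from_vector(chain.draws[i], a0=chain.a0)
        sess = simulate_individual(params, n_trials, trial_template, seed=child)
        sess.draw_index = int(i)
        sessions.append(sess)
    return sessions


@dataclass
class RecoveryReport:
    """Truth vs. posterior summary for one simulate-and-refit replicate."""

    true_params: ModelParams
    medians: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    covered: np.ndarray
    rhat: np.ndarray
    ess: np.ndarray
    seed: int

    @property
    def n_covered(self) -> int:
        return int(np.sum(self.covered))


def recovery_experiment(
    true_params: ModelParams,
    n_trials: int = 32,
    priors: Optional[PriorSpec] = None,
    mcmc_config: Optional[MCMCConfig] = None,
    n_replicates: int = 1,
    master_seed: int = 0,
    trial_config: TrialConfig = TrialConfig(),
    ci_level: float = 0.9,
) -> list[RecoveryReport]:
    """Simulate one-individual datasets at known parameters and refit.

    The central test of the inference machinery: with the same amount of
    data as a single experimental session, credible intervals should
    cover the generating values for most parameters.
    """
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    reports = []
    truth = true_params.to_vector()
    for r in range(n_replicates):
        sim_seed = (master_seed * 1000003 + 2 * r) % (2**31)
        fit_seed = (master_seed * 1000003 + 2 * r + 1) % (2**31)
        session = simulate_individual(true_params, n_trials, trial_config, seed=sim_seed)
        chain = fit_individual(
            session.scan_paths, priors, mcmc_config, seed=fit_seed, a0=true_params.a0
        )
        lo, hi = chain.credible_interval(ci_level)
        med = np.median(chain.draws, axis=0)
        reports.append(
            RecoveryReport(
                true_params=true_params,
                medians=med,
                ci_low=lo,
                ci_high=hi,
                covered=(lo <= truth) & (truth <= hi),
                rhat=chain.rhat,
                ess=chain.ess,
                seed=fit_seed,
            )
        )
    return reports


def coverage_table(reports: list[RecoveryReport]) -> pd.DataFrame:
    """Per-parameter coverage rate and median interval width."""
    cov = np.mean([r.covered for r in reports], axis=0)
    width = np.median([r.ci_high - r.ci_low for r in reports], axis=0)
    med = np.median([r.medians for r in reports], axis=0)
    truth = reports[0].true_params.to_vector()
    return pd.DataFrame(
        {
            "parameter": PARAM_NAMES,
            "truth": truth,
            "median_estimate": med,
            "coverage": cov,
            "median_ci_width": width,
        }
    )
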