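"""Sequential likelihood of observed scan paths.

Given a parameter vector, the activation dynamics along an *observed*
path are deterministic: the likelihood replays boost and decay along the
data and accumulates, per fixation, the log gamma density of the observed
duration (log survival function for the truncated final fixation) and the
log selection probability of the observed next AOI. The first fixation's
AOI is conditioned on — the model does not specify the initial selection
— but its duration is scored.

All accumulation happens in log space with stable log-gamma forms. The
module evaluates many parameter vectors at once (used by profile scans
and by the ensemble sampler); :mod:`lookdyn._fastlik` holds a numba
fast path for MCMC that is tested against this implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaincc, gammaln

from .params import N_AOI, PARAM_NAMES, DataError, InvalidParameterError, ModelParams
from .scanpath import ScanPath

__all__ = [
    "LogLikBreakdown",
    "PackedPaths",
    "pack_paths",
    "scanpath_loglik",
    "dataset_loglik",
    "dataset_loglik_many",
    "ProfileGrid",
    "profile_loglik",
    "default_profile_grid",
]


@dataclass(frozen=True)
class LogLikBreakdown:
    """Total log-likelihood split into selection and duration terms."""

    total: float
    selection_term: float
    duration_term: float
    n_fixations: int


@dataclass(frozen=True)
class PackedPaths:
    """Flat array view of a list of scan paths for fast replay.

    ``next_aoi[j] == -1`` marks fixations with no scored transition (the
    last fixation of each trial); ``is_first[j]`` marks trial starts where
    activations reset to baseline and no selection term is accrued for
    the fixation's own AOI.
    """

    aoi: np.ndarray
    duration: np.ndarray
    truncated: np.ndarray
    is_first: np.ndarray
    next_aoi: np.ndarray
    n_trials: int


def pack_paths(paths: list[ScanPath] | ScanPath) -> PackedPaths:
    if isinstance(paths, ScanPath):
        paths = [paths]
    if not paths:
        raise DataError("need at least one scan path")
    aoi, dur, trunc, first, nxt = [], [], [], [], []
    for p in paths:
        if not isinstance(p, ScanPath):
            raise DataError("inputs must be ScanPath objects")
        a = p.aois
        aoi.append(a)
        dur.append(p.durations)
        trunc.append(p.truncated_flags)
        f = np.zeros(len(p), dtype=bool)
        f[0] = True
        first.append(f)
        nx = np.concatenate([a[1:], [-1]])
        nxt.append(nx)
    return PackedPaths(
        aoi=np.concatenate(aoi).astype(np.int64),
        duration=np.concatenate(dur).astype(float),
        truncated=np.concatenate(trunc).astype(bool),
        is_first=np.concatenate(first).astype(bool),
        next_aoi=np.concatenate(nxt).astype(np.int64),
        n_trials=len(paths),
    )


def _theta_matrix(params) -> tuple[np.ndarray, np.ndarray]:
    """Normalise input to a (K, 9) matrix + (3,) baselines."""
    if isinstance(params, ModelParams):
        return params.to_vector()[None, :], np.array(params.a0)
    raise InvalidParameterError("params must be a ModelParams instance")


def loglik_terms(
    packed: PackedPaths, theta: np.ndarray, a0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(selection, duration) log-likelihood terms for each row of ``theta``.

    ``theta`` is a (K, 9) matrix in :data:`~lookdyn.params.PARAM_NAMES`
    order; every row must satisfy the parameter bounds (checked).
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[1] != 9:
        raise InvalidParameterError("theta must have 9 columns")
    nu, rho, omega = theta[:, 0], theta[:, 1], theta[:, 2]
    lam = theta[:, 3:6].T.copy()          # (3, K)
    g, mu, s = theta[:, 6], theta[:, 7], theta[:, 8]
    if not np.all(np.isfinite(theta)):
        raise InvalidParameterError("non-finite parameter value")
    if (np.any(nu <= 0) or np.any(rho < 0) or np.any(omega <= 0)
            or np.any(lam < 1) or np.any(g < 0) or np.any(mu <= 0) or np.any(s <= 0)):
        raise InvalidParameterError("parameter bound violated")

    K = theta.shape[0]
    a0col = np.asarray(a0, dtype=float)[:, None]          # (3, 1)
    a = np.broadcast_to(a0col, (N_AOI, K)).copy()          # (3, K)
    log_s = np.log(s)
    gln_s = gammaln(s)
    sel = np.zeros(K)
    dur_ll = np.zeros(K)

    aois = packed.aoi
    durs = packed.duration
    truncs = packed.truncated
    firsts = packed.is_first
    nxts = packed.next_aoi
    for j in range(len(aois)):
        if firsts[j]:
            a = np.broadcast_to(a0col, (N_AOI, K)).copy()
        i = aois[j]
        T = durs[j]
        a[i] *= lam[i]                                    # boost at onset
        mu_eff = mu * (1.0 + g * a[i])
        rate = s / mu_eff
        if truncs[j]:
            # right-censored: log survival of the gamma law
            dur_ll += np.log(gammaincc(s, rate * T))
        else:
            dur_ll += s * np.log(rate) - gln_s + (s - 1.0) * np.log(T) - rate * T
        a = a0col + (a - a0col) * np.exp(-omega * T)[None, :]
        k = nxts[j]
        if k >= 0:
            log_w = nu[None, :] * np.log(a)               # (3, K)
            m = log_w.max(axis=0)
            w = np.exp(log_w - m[None, :])
            w[i] += rho * np.exp(-m)
            sel += np.log(w[k]) - np.log(w.sum(axis=0))
    return sel, dur_ll


def scanpath_loglik(path: ScanPath, params: ModelParams) -> LogLikBreakdown:
    """Log-likelihood of one observed trial under ``params``."""
    packed = pack_paths(path)
    theta, a0 = _theta_matrix(params)
    sel, dur = loglik_terms(packed, theta, a0)
    return LogLikBreakdown(
        total=float(sel[0] + dur[0]),
        selection_term=float(sel[0]),
        duration_term=float(dur[0]),
        n_fixations=len(path),
    )


def dataset_loglik(paths: list[ScanPath], params: ModelParams) -> LogLikBreakdown:
    """Summed log-likelihood over independent trials."""
    if not paths:
        raise DataError("need at least one scan path")
    packed = pack_paths(paths)
    theta, a0 = _theta_matrix(params)
    sel, dur = loglik_terms(packed, theta, a0)
    return LogLikBreakdown(
        total=float(sel[0] + dur[0]),
        selection_term=float(sel[0]),
        duration_term=float(dur[0]),
        n_fixations=int(len(packed.aoi)),
    )


def dataset_loglik_many(
    paths: list[ScanPath] | PackedPaths, theta: np.ndarray, a0
) -> np.ndarray:
    """Total log-likelihood for each row of a (K, 9) parameter matrix."""
    packed = paths if isinstance(paths, PackedPaths) else pack_paths(paths)
    sel, dur = loglik_terms(packed, theta, np.asarray(a0, dtype=float))
    return sel + dur


@dataclass(frozen=True)
class ProfileGrid:
    """Log-likelihood along a one-parameter grid, others held fixed."""

    parameter_name: str
    grid_values: np.ndarray
    loglik_values: np.ndarray

    @property
    def argmax_value(self) -> float:
        return float(self.grid_values[int(np.argmax(self.loglik_values))])


def default_profile_grid(
    params: ModelParams, name: str, n_points: int = 21, span: float = 4.0
) -> np.ndarray:
    """Log-spaced grid around the current value of one parameter.

    For boost factors the grid is log-spaced in ``lambda - 1`` so it
    stays on the legal side of the lower bound ``lambda >= 1``.
    """
    x = params.value_of(name)
    if name.startswith("lam"):
        base = x - 1.0
        if base <= 0:
            raise InvalidParameterError("profile grid needs lambda > 1")
        return 1.0 + np.geomspace(base / span, base * span, n_points)
    if x <= 0:
        raise InvalidParameterError(f"profile grid needs {name} > 0")
    return np.geomspace(x / span, x * span, n_points)


def profile_loglik(
    paths: list[ScanPath],
    params: ModelParams,
    parameter_name: str,
    grid: np.ndarray,
) -> ProfileGrid:
    """Likelihood profile: scan one parameter, all others fixed."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 1:
        raise InvalidParameterError("grid must be a 1-D array")
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise InvalidParameterError("grid must be strictly increasing")
    if parameter_name not in PARAM_NAMES:
        raise InvalidParameterError(f"unknown parameter {parameter_name!r}")
    theta = np.tile(params.to_vector(), (len(grid), 1))
    col = PARAM_NAMES.index(parameter_name)
    theta[:, col] = grid
    for row in theta:
        ModelParams.from_vector(row, a0=params.a0)  # bound check per grid point
    packed = pack_paths(paths)
    ll = dataset_loglik_many(packed, theta, params.a0)
    return ProfileGrid(parameter_name=parameter_name, grid_values=grid, loglik_values=ll)
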