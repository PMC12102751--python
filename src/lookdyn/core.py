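"""Elementary mechanisms of the activation-based gaze model.

Four operations compose the whole dynamics:

* :func:`selection_probabilities` — a power-weighted Luce choice rule with
  an additive refixation bias gives the probability of each AOI being the
  next saccade target,
* :func:`decay` — exponential relaxation of activations to their fixed
  baselines (closed-form solution of ``da/dt = omega * (a0 - a)``),
* :func:`boost` — multiplicative increase of the fixated AOI's activation
  at fixation onset,
* :func:`duration_distribution` / :func:`sample_duration` — gamma-law
  fixation timing with activation-modulated mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    N_AOI,
    InvalidParameterError,
    InvalidStateError,
    ModelParams,
)

__all__ = [
    "ActivationState",
    "selection_probabilities",
    "sample_next_aoi",
    "decay",
    "boost",
    "duration_distribution",
    "sample_duration",
]


@dataclass(frozen=True)
class ActivationState:
    """Activations of the three AOIs at clock time ``t`` (ms)."""

    a: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.shape != (N_AOI,):
            raise InvalidStateError("activation vector must have three entries")
        if not np.all(np.isfinite(a)) or np.any(a <= 0):
            raise InvalidStateError("activations must be finite and > 0")
        if self.t < 0:
            raise InvalidStateError("clock time must be >= 0")
        object.__setattr__(self, "a", a)

    @classmethod
    def at_baseline(cls, params: ModelParams) -> "ActivationState":
        return cls(a=np.array(params.a0, dtype=float), t=0.0)


def _check_activations(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)) or np.any(a <= 0):
        raise InvalidStateError("activations must be finite and > 0")
    return a


def selection_weights(a: np.ndarray, params: ModelParams, current: int | None) -> np.ndarray:
    """Unnormalised selection weights ``a_i^nu + rho * delta(i, current)``.

    Computed on a max-rescaled scale so that very large ``nu``
    (winner-takes-all regime) does not overflow; the scaling cancels in
    the normalisation of :func:`selection_probabilities`.
    """
    a = _check_activations(a)
    log_w = params.nu * np.log(a)
    m = log_w.max()
    w = np.exp(log_w - m)
    if current is not None and params.rho > 0:
        if not 0 <= current < N_AOI:
            raise InvalidStateError(f"current AOI must be in 0..{N_AOI - 1}")
        w[current] += params.rho * np.exp(-m)
    return w


def selection_probabilities(
    state: ActivationState | np.ndarray,
    params: ModelParams,
    current: int | None = None,
) -> np.ndarray:
    """Probability of each AOI being selected as the next saccade target.

    ``pi_i = (a_i^nu + rho * delta_{i,current}) / sum_k (a_k^nu + rho *
    delta_{k,current})``.  ``current=None`` disables the refixation bias
    (used for the first fixation of a trial, where there is no currently
    fixated AOI).
    """
    a = state.a if isinstance(state, ActivationState) else state
    if current is not None and not 0 <= int(current) < N_AOI:
        raise InvalidStateError(f"current AOI must be in 0..{N_AOI - 1}")
    w = selection_weights(a, params, None if current is None else int(current))
    return w / w.sum()


def sample_next_aoi(
    a: np.ndarray,
    params: ModelParams,
    current: int | None,
    rng: np.random.Generator,
) -> int:
    """Draw the next saccade target from the selection probabilities."""
    pi = selection_probabilities(a, params, current=current)
    return int(rng.choice(N_AOI, p=pi))


def decay(state: ActivationState, dt: float, params: ModelParams) -> ActivationState:
    """Relax activations toward baseline over ``dt`` ms (closed form).

    ``a_i(t+dt) = a_i(t) exp(-omega dt) + a0_i (1 - exp(-omega dt))`` — the
    exact solution of the decay ODE, so no numerical integration error.
    """
    if dt < 0:
        raise InvalidStateError("dt must be >= 0")
    a0 = np.asarray(params.a0)
    f = np.exp(-params.omega * dt)
    return ActivationState(a=a0 + (state.a - a0) * f, t=state.t + dt)


def boost(state: ActivationState, target: int, params: ModelParams) -> ActivationState:
    """Multiply the fixated AOI's activation by its boost factor lambda."""
    if not 0 <= int(target) < N_AOI:
        raise InvalidStateError(f"target AOI must be in 0..{N_AOI - 1}")
    a = state.a.copy()
    a[target] *= params.lam[target]
    return ActivationState(a=a, t=state.t)


def duration_distribution(
    activation_at_onset: float, params: ModelParams
) -> tuple[float, float]:
    """Gamma (shape, rate) of the fixation duration for a given activation.

    The effective mean is ``mu' = mu_t * (1 + gamma * a)`` with ``a`` the
    activation of the fixated AOI immediately after the onset boost; the
    gamma law has shape ``sigma`` and rate ``sigma / mu'`` so its mean is
    ``mu'`` and its CV is ``1/sqrt(sigma)`` independent of activation.
    """
    a = float(activation_at_onset)
    if not np.isfinite(a) or a <= 0:
        raise InvalidStateError("activation must be finite and > 0")
    mu_eff = params.mu_t * (1.0 + params.gamma * a)
    return params.sigma, params.sigma / mu_eff


def sample_duration(
    activation_at_onset: float, params: ModelParams, rng: np.random.Generator
) -> float:
    """Draw one fixation duration (ms) from the activation-modulated gamma law."""
    shape, rate = duration_distribution(activation_at_onset, params)
    d = rng.gamma(shape, 1.0 / rate)
    # a numerically-zero draw would break duration logs downstream
    return float(max(d, np.finfo(float).tiny))
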