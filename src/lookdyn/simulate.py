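"""Event-driven generative simulation of scan paths.

A trial is simulated as an alternating sequence of discrete events:
fixation onset (boost the fixated AOI), gamma-distributed fixation
duration (mean modulated by the post-boost activation), continuous decay
of all activations during the fixation, and saccadic selection of the
next AOI from the relative activations with refixation bias. Saccade
durations are neglected, so fixations tile the trial without gaps; the
final fixation is truncated at the trial boundary and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import sample_duration, sample_next_aoi
from .params import N_AOI, ModelParams
from .scanpath import Fixation, ScanPath

__all__ = [
    "TrialConfig",
    "SimulatedSession",
    "simulate_trial",
    "simulate_individual",
    "trace_activations",
]


@dataclass(frozen=True)
class TrialConfig:
    """Trial-level settings.

    ``initial_aoi=None`` samples the first fixated AOI from the baseline
    selection probabilities (with the refixation bias inactive, since no
    AOI is fixated yet); an integer pins the first AOI for tests.
    """

    trial_duration_ms: float = 5000.0
    initial_aoi: Optional[int] = None

    def __post_init__(self) -> None:
        if self.trial_duration_ms <= 0:
            raise ValueError("trial duration must be > 0")
        if self.initial_aoi is not None and not 0 <= self.initial_aoi < N_AOI:
            raise ValueError("initial_aoi must be in 0..2 or None")


@dataclass
class SimulatedSession:
    """A set of simulated trials sharing one parameter vector.

    ``activation_trace`` (when recorded) is an array with columns
    ``t, a_target, a_distractor, a_outside`` sampled on a regular grid.
    """

    scan_paths: list[ScanPath]
    params: ModelParams
    activation_trace: Optional[np.ndarray] = None
    draw_index: Optional[int] = None


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trial(
    params: ModelParams, config: TrialConfig = TrialConfig(), rng=None
) -> ScanPath:
    """Simulate one trial; returns a contiguous :class:`ScanPath`."""
    rng = _resolve_rng(rng)
    T = config.trial_duration_ms
    a0 = np.array(params.a0, dtype=float)
    lam = np.array(params.lam, dtype=float)
    a = a0.copy()

    if config.initial_aoi is None:
        aoi = sample_next_aoi(a, params, current=None, rng=rng)
    else:
        aoi = int(config.initial_aoi)

    fixations: list[Fixation] = []
    t = 0.0
    while True:
        a[aoi] *= lam[aoi]                       # boost at fixation onset
        dur = sample_duration(a[aoi], params, rng)
        truncated = t + dur > T
        if truncated:
            dur = T - t                          # discard the full sampled value
        fixations.append(Fixation(aoi, t, dur, truncated))
        a = a0 + (a - a0) * np.exp(-params.omega * dur)
        t += dur
        if truncated or t >= T:
            break
        aoi = sample_next_aoi(a, params, current=aoi, rng=rng)
    return ScanPath(fixations=tuple(fixations), trial_duration_ms=T)


def simulate_individual(
    params: ModelParams,
    n_trials: int,
    config: TrialConfig = TrialConfig(),
    seed: int | np.random.SeedSequence = 0,
) -> SimulatedSession:
    """Simulate ``n_trials`` independent trials for one individual.

    Per-trial random streams are spawned from the master seed with
    :class:`numpy.random.SeedSequence`, so trial ``k`` is reproducible
    independently of how many other trials are simulated.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_trials)
    paths = [
        simulate_trial(params, config, rng=np.random.default_rng(child))
        for child in children
    ]
    return SimulatedSession(scan_paths=paths, params=params)


def trace_activations(
    params: ModelParams,
    config: TrialConfig = TrialConfig(),
    sample_every: float = 1.0,
    rng=None,
) -> SimulatedSession:
    """Simulate one trial and record the activation time series.

    The trace is evaluated from the closed-form decay between fixation
    onsets, so it is exact up to grid resolution: piecewise exponential
    with a multiplicative jump of the fixated AOI at each onset.
    """
    if sample_every <= 0:
        raise ValueError("sample_every must be > 0")
    rng = _resolve_rng(rng)
    path = simulate_trial(params, config, rng)
    a0 = np.array(params.a0, dtype=float)
    lam = np.array(params.lam, dtype=float)

    # replay: post-boost activation at each fixation onset
    post_boost = np.empty((len(path), N_AOI))
    a = a0.copy()
    for j, f in enumerate(path):
        a[f.aoi] *= lam[f.aoi]
        post_boost[j] = a
        a = a0 + (a - a0) * np.exp(-params.omega * f.duration_ms)

    times = np.arange(0.0, config.trial_duration_ms + 0.5 * sample_every, sample_every)
    times = times[times <= config.trial_duration_ms]
    onsets = path.onsets
    # at exactly a fixation onset the trace takes the pre-boost (left-limit)
    # value, so the t=0 sample equals the baseline activations
    idx = np.searchsorted(onsets, times, side="left") - 1
    grid = np.empty((len(times), 1 + N_AOI))
    grid[:, 0] = times
    for k, (t, j) in enumerate(zip(times, idx)):
        if j < 0:
            grid[k, 1:] = a0
        else:
            dt = t - onsets[j]
            grid[k, 1:] = a0 + (post_boost[j] - a0) * np.exp(-params.omega * dt)
    return SimulatedSession(scan_paths=[path], params=params, activation_trace=grid)
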