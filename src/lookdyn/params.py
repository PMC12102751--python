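"""Model parameters for the activation-based gaze model.

The model describes gaze allocation over three areas of interest (AOIs):
the target picture, the distractor picture, and everything else on or off
the screen ("outside"). Each AOI carries a latent activation; relative
activations set the probabilities of saccadic selection, a fixation boosts
the fixated AOI's activation multiplicatively, and activations relax
exponentially back to fixed baselines. Fixation durations are gamma
distributed with a mean modulated by the activation of the fixated AOI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "TARGET",
    "DISTRACTOR",
    "OUTSIDE",
    "AOI_LABELS",
    "PARAM_NAMES",
    "ModelParams",
    "InvalidParameterError",
    "InvalidStateError",
    "DataError",
]

# AOI indices used throughout the package (0-based; serialized as T/D/M).
TARGET, DISTRACTOR, OUTSIDE = 0, 1, 2
AOI_LABELS = ("T", "D", "M")
N_AOI = 3

#: Canonical order of the nine free parameters used for inference vectors.
PARAM_NAMES = ("nu", "rho", "omega", "lam1", "lam2", "lam3", "gamma", "mu_t", "sigma")

#: Fixed baseline activations (target, distractor, outside). Held constant
#: during inference; only the dynamical parameters are estimated.
DEFAULT_BASELINES = (1.1, 1.0, 0.37)


class InvalidParameterError(ValueError):
    """A model parameter violates its bound (e.g. lambda < 1)."""


class InvalidStateError(ValueError):
    """An activation state is non-finite or non-positive."""


class DataError(ValueError):
    """Observed scan-path data violate the format invariants."""


@dataclass(frozen=True)
class ModelParams:
    """The nine free parameters plus fixed baselines of one individual.

    Parameters
    ----------
    nu
        Selection exponent weighting relative activations; ``nu=1`` is
        Luce's choice rule, ``nu -> inf`` gives winner-takes-all selection.
    rho
        Additive refixation bias (activation units) favouring the
        currently fixated AOI in the selection rule.
    omega
        Activation decay rate in 1/ms; activations above baseline relax
        to baseline as ``exp(-omega * t)``.
    lam
        Boost factors ``(lam1, lam2, lam3) >= 1`` applied multiplicatively
        to the fixated AOI's activation at fixation onset.
    gamma
        Gain of the activation modulation of mean fixation duration
        (``mu_t * (1 + gamma * a)``); ``gamma=0`` removes any AOI
        dependence of timing.
    mu_t
        Nominal mean fixation duration in ms.
    sigma
        Gamma shape parameter of the fixation-duration distribution
        (CV^2 = 1/sigma).
    a0
        Fixed baseline activations (target, distractor, outside);
        constants, not inferred.
    """

    nu: float = 1.0
    rho: float = 0.3
    omega: float = 1.5e-3
    lam: tuple[float, float, float] = (1.4, 1.1, 1.1)
    gamma: float = 0.5
    mu_t: float = 200.0
    sigma: float = 8.0
    a0: tuple[float, float, float] = DEFAULT_BASELINES

    def __post_init__(self) -> None:
        lam = tuple(float(x) for x in self.lam)
        a0 = tuple(float(x) for x in self.a0)
        if len(lam) != N_AOI or len(a0) != N_AOI:
            raise InvalidParameterError("lam and a0 must have three entries")
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "a0", a0)
        checks = [
            (self.nu > 0, "nu must be > 0"),
            (self.rho >= 0, "rho must be >= 0"),
            (self.omega > 0, "omega must be > 0"),
            (all(x >= 1 for x in lam), "boost factors lam must be >= 1"),
            (self.gamma >= 0, "gamma must be >= 0"),
            (self.mu_t > 0, "mu_t must be > 0"),
            (self.sigma > 0, "sigma must be > 0"),
            (all(x > 0 for x in a0), "baselines a0 must be > 0"),
        ]
        vals = [self.nu, self.rho, self.omega, *lam, self.gamma, self.mu_t, self.sigma, *a0]
        if not np.all(np.isfinite(vals)):
            raise InvalidParameterError("parameters must be finite")
        for ok, msg in checks:
            if not ok:
                raise InvalidParameterError(msg)

    def to_vector(self) -> np.ndarray:
        """Free parameters as a length-9 array in :data:`PARAM_NAMES` order."""
        return np.array(
            [self.nu, self.rho, self.omega, *self.lam, self.gamma, self.mu_t, self.sigma],
            dtype=float,
        )

    @classmethod
    def from_vector(
        cls, vec: Iterable[float], a0: tuple[float, float, float] = DEFAULT_BASELINES
    ) -> "ModelParams":
        v = np.asarray(list(vec), dtype=float)
        if v.shape != (9,):
            raise InvalidParameterError("parameter vector must have length 9")
        return cls(
            nu=v[0], rho=v[1], omega=v[2], lam=(v[3], v[4], v[5]),
            gamma=v[6], mu_t=v[7], sigma=v[8], a0=a0,
        )

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with some fields replaced (validated)."""
        return replace(self, **kwargs)

    def with_value(self, name: str, value: float) -> "ModelParams":
        """Return a copy with one named free parameter set to ``value``."""
        if name not in PARAM_NAMES:
            raise InvalidParameterError(f"unknown parameter {name!r}")
        if name.startswith("lam"):
            i = int(name[3]) - 1
            lam = list(self.lam)
            lam[i] = value
            return self.replace(lam=tuple(lam))
        return self.replace(**{name: value})

    def value_of(self, name: str) -> float:
        if name not in PARAM_NAMES:
            raise InvalidParameterError(f"unknown parameter {name!r}")
        if name.startswith("lam"):
            return self.lam[int(name[3]) - 1]
        return getattr(self, name)
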