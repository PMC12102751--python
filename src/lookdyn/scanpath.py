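"""Scan-path containers: ordered fixation sequences for single trials."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .params import N_AOI, DataError

__all__ = ["Fixation", "ScanPath"]

#: Absolute tolerance (ms) for the contiguity check between fixations.
CONTIGUITY_TOL = 1e-6


class Fixation(NamedTuple):
    """One fixation: AOI index (0=target, 1=distractor, 2=outside),
    onset and duration in ms, and whether it was cut off by trial end."""

    aoi: int
    onset_ms: float
    duration_ms: float
    truncated: bool = False


@dataclass(frozen=True)
class ScanPath:
    """An ordered, contiguous fixation sequence for one trial.

    Saccade durations are neglected, so each fixation starts exactly when
    the previous one ends; only the last fixation may be truncated by the
    trial boundary.
    """

    fixations: tuple[Fixation, ...]
    trial_duration_ms: float = 5000.0

    def __post_init__(self) -> None:
        fx = tuple(Fixation(int(f[0]), float(f[1]), float(f[2]), bool(f[3])) for f in self.fixations)
        object.__setattr__(self, "fixations", fx)
        if self.trial_duration_ms <= 0:
            raise DataError("trial duration must be > 0")
        if not fx:
            raise DataError("a scan path must contain at least one fixation")
        t = 0.0
        for j, f in enumerate(fx):
            if not 0 <= f.aoi < N_AOI:
                raise DataError(f"fixation {j}: AOI index {f.aoi} out of range")
            if f.duration_ms <= 0:
                raise DataError(f"fixation {j}: non-positive duration")
            if abs(f.onset_ms - t) > CONTIGUITY_TOL:
                raise DataError(
                    f"fixation {j}: onset {f.onset_ms} ms leaves a gap "
                    f"(expected {t} ms); scan paths must be contiguous"
                )
            if f.truncated and j != len(fx) - 1:
                raise DataError(f"fixation {j}: only the last fixation may be truncated")
            t = f.onset_ms + f.duration_ms
        if t > self.trial_duration_ms + CONTIGUITY_TOL:
            raise DataError("fixations extend past the trial duration")

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self):
        return iter(self.fixations)

    @property
    def aois(self) -> np.ndarray:
        return np.array([f.aoi for f in self.fixations], dtype=np.int64)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([f.onset_ms for f in self.fixations], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return np.array([f.duration_ms for f in self.fixations], dtype=float)

    @property
    def truncated_flags(self) -> np.ndarray:
        return np.array([f.truncated for f in self.fixations], dtype=bool)

    @property
    def total_looking_ms(self) -> float:
        return float(self.durations.sum())

    @classmethod
    def from_arrays(
        cls,
        aois: Sequence[int],
        durations: Sequence[float],
        trial_duration_ms: float = 5000.0,
        last_truncated: bool = False,
    ) -> "ScanPath":
        """Build a contiguous path from AOI and duration sequences."""
        onsets = np.concatenate([[0.0], np.cumsum(np.asarray(durations, dtype=float))[:-1]])
        n = len(aois)
        fx = [
            Fixation(int(a), float(o), float(d), last_truncated and j == n - 1)
            for j, (a, o, d) in enumerate(zip(aois, onsets, durations, strict=True))
        ]
        return cls(fixations=tuple(fx), trial_duration_ms=trial_duration_ms)
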