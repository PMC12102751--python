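"""Descriptive microstructure measures of scan paths.

The same summaries are computed for experimental and simulated data:
mean fixation durations (overall, per AOI, first fixations), gaze
durations (first fixation plus direct refixations on the same AOI), the
3x3 matrix of AOI transition probabilities, the proportion of target
looking, and the refixation rate. Truncated final fixations are by
default excluded from duration statistics but counted as looking time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .params import DISTRACTOR, N_AOI, TARGET, AOI_LABELS, DataError
from .scanpath import ScanPath

__all__ = [
    "TruncationPolicy",
    "MicrostructureSummary",
    "summarize",
    "prop_target_looking",
    "compare_summaries",
    "summaries_to_frame",
]

MEASURES = (
    "mean_fixdur_all",
    "mean_fixdur_T",
    "mean_fixdur_D",
    "mean_fixdur_M",
    "first_fixdur_mean",
    "gaze_duration_T",
    "gaze_duration_D",
    "gaze_duration_M",
    "prop_target_looking",
    "refixation_rate",
    *(f"trans_{a}{b}" for a in AOI_LABELS for b in AOI_LABELS),
)


@dataclass(frozen=True)
class TruncationPolicy:
    """How truncated (trial-boundary) fixations enter the summaries."""

    exclude_from_durations: bool = True
    include_in_looking_time: bool = True


@dataclass(frozen=True)
class MicrostructureSummary:
    """Per-individual descriptive statistics of gaze microstructure.

    Transition-matrix rows with no outgoing saccade are NaN (flagged
    missing, never zero-filled). Durations are in ms.
    """

    mean_fixdur_all: float
    mean_fixdur_by_aoi: np.ndarray
    first_fixdur_mean: float
    gaze_duration_by_aoi: np.ndarray
    transition_matrix: np.ndarray
    prop_target_looking: float
    refixation_rate: float
    n_fixations: int

    def as_dict(self) -> dict[str, float]:
        d = {
            "mean_fixdur_all": self.mean_fixdur_all,
            "first_fixdur_mean": self.first_fixdur_mean,
            "prop_target_looking": self.prop_target_looking,
            "refixation_rate": self.refixation_rate,
        }
        for i, lab in enumerate(AOI_LABELS):
            d[f"mean_fixdur_{lab}"] = float(self.mean_fixdur_by_aoi[i])
            d[f"gaze_duration_{lab}"] = float(self.gaze_duration_by_aoi[i])
        for i, a in enumerate(AOI_LABELS):
            for j, b in enumerate(AOI_LABELS):
                d[f"trans_{a}{b}"] = float(self.transition_matrix[i, j])
        return d


def _duration_mask(path: ScanPath, policy: TruncationPolicy) -> np.ndarray:
    keep = np.ones(len(path), dtype=bool)
    if policy.exclude_from_durations:
        keep &= ~path.truncated_flags
    return keep


def summarize(
    paths: list[ScanPath],
    truncation_policy: TruncationPolicy = TruncationPolicy(),
) -> MicrostructureSummary:
    """Compute all microstructure measures over a set of trials."""
    if not paths:
        raise DataError("need at least one scan path")
    pol = truncation_policy

    durs_all: list[float] = []
    durs_by_aoi: list[list[float]] = [[], [], []]
    first_fix: list[float] = []
    gaze: list[list[float]] = [[], [], []]
    counts = np.zeros((N_AOI, N_AOI), dtype=float)
    n_fix = 0

    for p in paths:
        aois = p.aois
        durations = p.durations
        keep = _duration_mask(p, pol)
        n_fix += len(p)
        durs_all.extend(durations[keep])
        for i in range(N_AOI):
            durs_by_aoi[i].extend(durations[keep & (aois == i)])
        for a, b in zip(aois[:-1], aois[1:]):
            counts[a, b] += 1
        # runs of consecutive fixations on the same AOI; the first run on
        # each AOI yields its first-fixation and gaze duration for this trial
        seen: set[int] = set()
        j = 0
        while j < len(aois):
            k = j
            while k + 1 < len(aois) and aois[k + 1] == aois[j]:
                k += 1
            i = int(aois[j])
            if i not in seen:
                seen.add(i)
                run_keep = keep[j : k + 1]
                run_durs = durations[j : k + 1][run_keep]
                if keep[j]:
                    first_fix.append(float(durations[j]))
                if run_durs.size:
                    gaze[i].append(float(run_durs.sum()))
            j = k + 1

    row_sums = counts.sum(axis=1)
    trans = np.full((N_AOI, N_AOI), np.nan)
    nonzero = row_sums > 0
    trans[nonzero] = counts[nonzero] / row_sums[nonzero, None]
    n_trans = counts.sum()
    refix = float(np.trace(counts) / n_trans) if n_trans > 0 else np.nan

    def _mean(xs) -> float:
        return float(np.mean(xs)) if len(xs) else np.nan

    return MicrostructureSummary(
        mean_fixdur_all=_mean(durs_all),
        mean_fixdur_by_aoi=np.array([_mean(d) for d in durs_by_aoi]),
        first_fixdur_mean=_mean(first_fix),
        gaze_duration_by_aoi=np.array([_mean(g) for g in gaze]),
        transition_matrix=trans,
        prop_target_looking=prop_target_looking(paths),
        refixation_rate=refix,
        n_fixations=n_fix,
    )


def prop_target_looking(
    paths: list[ScanPath],
    denominator_mode: Literal["target_plus_distractor", "total_trial"] = "target_plus_distractor",
) -> float:
    """Proportion of looking time on the target.

    Default denominator is target + distractor looking time (the field's
    convention for two-picture preferential-looking trials); the
    ``total_trial`` mode divides by summed trial durations instead.
    Truncated fixations count as observed looking time.
    """
    if not paths:
        raise DataError("need at least one scan path")
    t_time = d_time = 0.0
    total_trial = 0.0
    for p in paths:
        aois = p.aois
        durations = p.durations
        t_time += durations[aois == TARGET].sum()
        d_time += durations[aois == DISTRACTOR].sum()
        total_trial += p.trial_duration_ms
    if denominator_mode == "target_plus_distractor":
        denom = t_time + d_time
    elif denominator_mode == "total_trial":
        denom = total_trial
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if denom <= 0:
        raise DataError("zero looking-time denominator; proportion undefined")
    return float(t_time / denom)


def summaries_to_frame(
    summaries: list[MicrostructureSummary], ids: Optional[list] = None
) -> pd.DataFrame:
    """Tidy table: one row per individual x measure."""
    if ids is None:
        ids = list(range(len(summaries)))
    rows = []
    for i, s in zip(ids, summaries):
        for m, v in s.as_dict().items():
            rows.append({"individual": i, "measure": m, "value": v})
    return pd.DataFrame(rows)


def compare_summaries(
    per_individual_a: list[MicrostructureSummary],
    per_individual_b: list[MicrostructureSummary],
) -> pd.DataFrame:
    """Pearson correlation across individuals, per measure.

    Individuals must be matched by position. Measures with zero variance
    (or too many missing values) are flagged with NaN correlation.
    """
    if len(per_individual_a) != len(per_individual_b):
        raise DataError("summary lists must be matched and equal length")
    if len(per_individual_a) < 3:
        raise DataError("need at least 3 matched individuals")
    da = pd.DataFrame([s.as_dict() for s in per_individual_a])
    db = pd.DataFrame([s.as_dict() for s in per_individual_b])
    rows = []
    for m in MEASURES:
        x, y = da[m].to_numpy(), db[m].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            rows.append({"measure": m, "r": np.nan, "p_value": np.nan, "n": int(ok.sum())})
            continue
        r, p = sps.pearsonr(x[ok], y[ok])
        rows.append({"measure": m, "r": float(r), "p_value": float(p), "n": int(ok.sum())})
    return pd.DataFrame(rows)
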