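"""Fixation-report files, configuration, and run manifests.

The interchange format is a tidy CSV of fixation records::

    subject_id,age_months,trial_id,fix_index,aoi,onset_ms,duration_ms,truncated

with AOI labels T (target), D (distractor), M (missing/outside); numeric
labels 1/2/3 are also accepted on read. Within a trial, fixations are
1-indexed and contiguous (onset of record k+1 equals onset+duration of
record k; the first onset is 0) and only the last record may be
truncated. Strict reading aborts on any violation naming the offending
line; lenient reading drops the offending trial and logs a warning.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import AOI_LABELS, DataError
from .scanpath import CONTIGUITY_TOL, Fixation, ScanPath
from .simulate import SimulatedSession

logger = logging.getLogger("lookdyn")

__all__ = [
    "FIXREPORT_COLUMNS",
    "SubjectData",
    "write_fixation_report",
    "read_fixation_report",
    "sessions_to_report",
    "load_config",
    "write_manifest",
]

FIXREPORT_COLUMNS = [
    "subject_id",
    "age_months",
    "trial_id",
    "fix_index",
    "aoi",
    "onset_ms",
    "duration_ms",
    "truncated",
]

_AOI_FROM_LABEL = {lab: i for i, lab in enumerate(AOI_LABELS)}
_AOI_FROM_LABEL.update({"1": 0, "2": 1, "3": 2})
_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


@dataclass
class SubjectData:
    """All trials of one subject as in-memory scan paths."""

    subject_id: str
    age_months: float
    paths: list[ScanPath]
    trial_ids: list[str] = field(default_factory=list)


def sessions_to_report(
    sessions: dict[str, SimulatedSession],
    ages: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Flatten simulated sessions into the fixation-report table."""
    rows = []
    for sid, sess in sessions.items():
        age = float(ages[sid]) if ages else float("nan")
        for t, path in enumerate(sess.scan_paths):
            for j, f in enumerate(path):
                rows.append(
                    {
                        "subject_id": sid,
                        "age_months": age,
                        "trial_id": f"t{t:03d}",
                        "fix_index": j + 1,
                        "aoi": AOI_LABELS[f.aoi],
                        "onset_ms": round(f.onset_ms, 3),
                        "duration_ms": round(f.duration_ms, 3),
                        "truncated": bool(f.truncated),
                    }
                )
    return pd.DataFrame(rows, columns=FIXREPORT_COLUMNS)


def write_fixation_report(
    sessions: dict[str, SimulatedSession],
    path,
    ages: dict[str, float] | None = None,
) -> None:
    sessions_to_report(sessions, ages).to_csv(path, index=False, lineterminator="\n")


def _parse_trial(
    sub: str, trial: str, grp: pd.DataFrame, trial_duration_ms: float
) -> ScanPath:
    grp = grp.sort_values("fix_index")
    idx = grp["fix_index"].to_numpy()
    lines = grp["_line"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(grp) + 1)):
        raise DataError(
            f"trial {trial!r} of subject {sub!r}: fix_index not consecutive "
            f"from 1 (lines {lines.min()}-{lines.max()})"
        )
    fixations = []
    expected_onset = 0.0
    for _, rec in grp.iterrows():
        label = str(rec["aoi"]).strip()
        if label not in _AOI_FROM_LABEL:
            raise DataError(
                f"line {rec['_line']}: unknown AOI label {label!r} "
                f"(allowed: {', '.join(AOI_LABELS)} or 1/2/3)"
            )
        onset = float(rec["onset_ms"])
        dur = float(rec["duration_ms"])
        if abs(onset - expected_onset) > max(CONTIGUITY_TOL, 2e-3):
            raise DataError(
                f"line {rec['_line']}: trial {trial!r} of subject {sub!r} has a "
                f"gap (onset {onset} ms, expected {expected_onset:.3f} ms)"
            )
        tr = rec["truncated"]
        if isinstance(tr, str):
            low = tr.strip().lower()
            if low in _TRUE:
                tr = True
            elif low in _FALSE:
                tr = False
            else:
                raise DataError(f"line {rec['_line']}: bad truncated flag {tr!r}")
        fixations.append(Fixation(_AOI_FROM_LABEL[label], onset, dur, bool(tr)))
        expected_onset = onset + dur
    snapped = _recontiguize(fixations)
    total = sum(f.duration_ms for f in snapped)
    try:
        return ScanPath(
            fixations=tuple(snapped),
            # ms values are written with <=3 decimals, so the rounded sum can
            # exceed the nominal trial length by a hair
            trial_duration_ms=max(trial_duration_ms, total),
        )
    except DataError as e:
        raise DataError(f"trial {trial!r} of subject {sub!r}: {e}") from e


def _recontiguize(fixations: list[Fixation]) -> list[Fixation]:
    """Snap onsets to exact contiguity (rounding in files is ~1e-3 ms)."""
    out = []
    t = 0.0
    for f in fixations:
        out.append(Fixation(f.aoi, t, f.duration_ms, f.truncated))
        t += f.duration_ms
    return out


def read_fixation_report(
    path, strict: bool = True, trial_duration_ms: float = 5000.0
) -> dict[str, SubjectData]:
    """Read and validate a fixation-report CSV into per-subject scan paths.

    In strict mode any invariant violation raises :class:`DataError`
    naming the line; in lenient mode the offending trial is dropped with
    a logged warning and parsing continues.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str, "aoi": str})
    missing = [c for c in FIXREPORT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"malformed header: missing columns {missing}")
    for col in ("onset_ms", "duration_ms", "fix_index", "age_months"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise DataError(f"column {col!r} must be numeric")
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1

    subjects: dict[str, SubjectData] = {}
    for sub, sgrp in df.groupby("subject_id", sort=True):
        ages = sgrp["age_months"].dropna().unique()
        age = float(ages[0]) if len(ages) else float("nan")
        paths, trial_ids = [], []
        for trial, tgrp in sgrp.groupby("trial_id", sort=True):
            try:
                paths.append(_parse_trial(str(sub), str(trial), tgrp, trial_duration_ms))
                trial_ids.append(str(trial))
            except DataError as e:
                if strict:
                    raise
                logger.warning("dropping trial %r of subject %r: %s", trial, sub, e)
        if paths:
            subjects[str(sub)] = SubjectData(
                subject_id=str(sub), age_months=age, paths=paths, trial_ids=trial_ids
            )
        elif strict:
            raise DataError(f"subject {sub!r} has no valid trials")
    return subjects


def load_config(path) -> dict:
    """Load a YAML (or JSON) run-configuration file into a dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise DataError(f"config file {path} must contain a mapping")
    return cfg


def write_manifest(out_dir, command: str, resolved_config: dict, seed: int) -> Path:
    """Write the run manifest every command emits for reproducibility."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": resolved_config,
        "seed": int(seed),
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return p
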