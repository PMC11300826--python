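"""Trajectory-log IO, snippet extraction, factor standardization and the
trial table shared by every downstream stage."""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LOG_COLUMNS",
    "DEFAULT_CHANNELS",
    "TrajectorySnippet",
    "CognitiveProfile",
    "FactorTransform",
    "TrialRecord",
    "read_trajectory_log",
    "write_trajectory_log",
    "extract_snippets",
    "standardize_factors",
    "build_trial_table",
    "save_snippets",
    "load_snippets",
]

LOG_COLUMNS = [
    "time_s", "speed_mps", "accel_mps2", "dist_to_light_m", "light_phase",
    "hmi_active", "approach_idx", "lap_id", "condition", "subject_id",
]

#: channel order fed to the encoder: continuous signals, phase one-hot, hmi flag
DEFAULT_CHANNELS = ("speed_mps", "accel_mps2", "dist_to_light_m",
                    "phase_G", "phase_Y", "phase_R", "hmi_active")

_PHASES = ("G", "Y", "R")


class LogFormatError(ValueError):
    """Trajectory-log file violates the schema."""


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySnippet:
    """Fixed-length driving window ending right before a green-to-yellow
    transition, plus the driver's action at the transition step."""

    subject_id: str
    channels: np.ndarray          # (T, C)
    channel_names: tuple[str, ...]
    dt: float
    anchor_time: float            # time of the transition step (first step after window)
    action: np.ndarray            # (speed, accel) at the transition step
    lap_id: int = 0
    approach_idx: int = 0
    condition: str = "none"

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.action = np.asarray(self.action, dtype=float)
        if self.channels.ndim != 2:
            raise ValueError("channels must be a (T, C) matrix")
        if self.channels.shape[1] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")

    @property
    def window(self) -> int:
        return self.channels.shape[0]


@dataclass
class CognitiveProfile:
    """Named cognitive measures for one subject, raw and standardized."""

    subject_id: str
    measures: dict[str, float]
    standardized: dict[str, float] = field(default_factory=dict)

    def raw_vector(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.measures[n] for n in names], dtype=float)

    def z_vector(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.standardized[n] for n in names], dtype=float)


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    lap_id: int
    approach_idx: int
    condition: str
    had_yellow: bool
    mean_yellow_speed: float | None = None
    max_yellow_speed: float | None = None


# ---------------------------------------------------------------------------
# log IO
# ---------------------------------------------------------------------------

def write_trajectory_log(log: pd.DataFrame, path) -> None:
    missing = [c for c in LOG_COLUMNS if c not in log.columns]
    if missing:
        raise LogFormatError(f"log is missing columns: {missing}")
    log.to_csv(path, index=False, columns=[c for c in log.columns])


def read_trajectory_log(path) -> pd.DataFrame:
    """Read and validate a trajectory-log CSV.

    Raises :class:`LogFormatError` naming the offending column or the
    1-based line numbers of malformed rows.
    """
    path = pathlib.Path(path)
    try:
        log = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise LogFormatError(f"{path}: empty trajectory log") from None
    if log.empty:
        raise LogFormatError(f"{path}: empty trajectory log")
    missing = [c for c in LOG_COLUMNS if c not in log.columns]
    if missing:
        raise LogFormatError(f"{path}: missing required column(s) {missing}")

    bad_lines: list[int] = []
    for col in ("time_s", "speed_mps", "accel_mps2", "dist_to_light_m"):
        vals = pd.to_numeric(log[col], errors="coerce")
        bad = vals.isna() & log[col].notna() | log[col].isna()
        bad_lines.extend((log.index[bad] + 2).tolist())  # +2: header and 0-base
        log[col] = vals
    bad_phase = ~log["light_phase"].isin(_PHASES)
    bad_lines.extend((log.index[bad_phase] + 2).tolist())
    if bad_lines:
        shown = sorted(set(bad_lines))[:10]
        raise LogFormatError(f"{path}: malformed rows at lines {shown}")

    for (sid, lap), grp in log.groupby(["subject_id", "lap_id"], sort=False):
        t = grp["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            k = int(np.flatnonzero(np.diff(t) <= 0)[0])
            line = int(grp.index[k + 1]) + 2
            raise LogFormatError(
                f"{path}: non-monotone time for subject {sid} lap {lap} at line {line}")
    return log


# ---------------------------------------------------------------------------
# snippet extraction
# ---------------------------------------------------------------------------

def _channel_matrix(grp: pd.DataFrame, channels: Sequence[str]) -> np.ndarray:
    cols = []
    for name in channels:
        if name.startswith("phase_"):
            cols.append((grp["light_phase"] == name[-1]).to_numpy(float))
        else:
            cols.append(grp[name].to_numpy(float))
    return np.column_stack(cols)


def extract_snippets(
    log: pd.DataFrame,
    window: int = 100,
    channels: Sequence[str] = DEFAULT_CHANNELS,
) -> tuple[list[TrajectorySnippet], int]:
    """Cut one strictly-causal window per green-to-yellow transition.

    The window covers the ``window`` steps *before* the transition instant;
    the transition step itself supplies the action target (next-step speed
    and acceleration).  Transitions with fewer than ``window`` steps of
    history in their lap are skipped; the skip count is returned.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    snippets: list[TrajectorySnippet] = []
    skipped = 0
    for (sid, lap), grp in log.groupby(["subject_id", "lap_id"], sort=False):
        grp = grp.reset_index(drop=True)
        phase = grp["light_phase"].to_numpy()
        trans = np.flatnonzero((phase[1:] == "Y") & (phase[:-1] == "G")) + 1
        t = grp["time_s"].to_numpy()
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.1
        mat = _channel_matrix(grp, channels)
        for k in trans:
            if k < window:
                skipped += 1
                continue
            snippets.append(TrajectorySnippet(
                subject_id=str(sid),
                channels=mat[k - window: k],
                channel_names=tuple(channels),
                dt=dt,
                anchor_time=float(t[k]),
                action=np.array([grp["speed_mps"].iat[k], grp["accel_mps2"].iat[k]]),
                lap_id=int(lap),
                approach_idx=int(grp["approach_idx"].iat[k]),
                condition=str(grp["condition"].iat[k]),
            ))
    return snippets, skipped


# ---------------------------------------------------------------------------
# factor standardization
# ---------------------------------------------------------------------------

class FactorTransform:
    """Per-measure affine standardization (population-sd convention).

    Fitted on a training subject table; persistable and invertible so the
    exact training statistics can be reused at test time.
    """

    def __init__(self, means: dict[str, float], sds: dict[str, float]):
        self.means = dict(means)
        self.sds = dict(sds)

    @classmethod
    def fit(cls, table: pd.DataFrame, names: Sequence[str]) -> "FactorTransform":
        means, sds = {}, {}
        for n in names:
            col = table[n].to_numpy(float)
            if len(np.unique(col)) < 2:
                raise ValueError(f"measure {n!r} is constant; cannot standardize")
            means[n] = float(col.mean())
            sds[n] = float(col.std(ddof=0))
        return cls(means, sds)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for n in self.means:
            out[n] = (table[n] - self.means[n]) / self.sds[n]
        return out

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for n in self.means:
            out[n] = table[n] * self.sds[n] + self.means[n]
        return out

    def to_json(self) -> str:
        return json.dumps({"means": self.means, "sds": self.sds})

    @classmethod
    def from_json(cls, s: str) -> "FactorTransform":
        d = json.loads(s)
        return cls(d["means"], d["sds"])


def standardize_factors(
    table: pd.DataFrame, names: Sequence[str]
) -> tuple[list[CognitiveProfile], FactorTransform]:
    """Fit a standardization on the subject table and return per-subject
    profiles carrying both raw and standardized measures."""
    tf = FactorTransform.fit(table, names)
    ztab = tf.transform(table)
    profiles = []
    for i in range(len(table)):
        sid = str(table["subject_id"].iloc[i])
        profiles.append(CognitiveProfile(
            subject_id=sid,
            measures={n: float(table[n].iloc[i]) for n in names},
            standardized={n: float(ztab[n].iloc[i]) for n in names},
        ))
    return profiles, tf


# ---------------------------------------------------------------------------
# trial table
# ---------------------------------------------------------------------------

def build_trial_table(log: pd.DataFrame) -> pd.DataFrame:
    """One row per subject x lap x light approach with yellow-phase speed
    statistics (over phase == Y steps only)."""
    rows = []
    for (sid, lap, a), grp in log.groupby(
            ["subject_id", "lap_id", "approach_idx"], sort=True):
        ymask = grp["light_phase"] == "Y"
        cond = str(grp["condition"].iloc[0])
        if ymask.any():
            ys = grp.loc[ymask, "speed_mps"]
            rows.append((sid, lap, a, cond, True, float(ys.mean()), float(ys.max())))
        else:
            rows.append((sid, lap, a, cond, False, np.nan, np.nan))
    return pd.DataFrame(rows, columns=[
        "subject_id", "lap_id", "approach_idx", "condition", "had_yellow",
        "mean_yellow_speed", "max_yellow_speed"])


# ---------------------------------------------------------------------------
# snippet archives
# ---------------------------------------------------------------------------

def save_snippets(snippets: list[TrajectorySnippet], path) -> None:
    """Dump snippets as an NPZ tensor archive plus a JSON sidecar."""
    path = pathlib.Path(path)
    arr = np.stack([s.channels for s in snippets])
    actions = np.stack([s.action for s in snippets])
    np.savez_compressed(path.with_suffix(".npz"), channels=arr, actions=actions)
    meta = {
        "subject_ids": [s.subject_id for s in snippets],
        "anchor_times": [s.anchor_time for s in snippets],
        "lap_ids": [s.lap_id for s in snippets],
        "approach_idx": [s.approach_idx for s in snippets],
        "conditions": [s.condition for s in snippets],
        "dt": snippets[0].dt,
        "channel_names": list(snippets[0].channel_names),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_snippets(path) -> list[TrajectorySnippet]:
    path = pathlib.Path(path)
    with np.load(path.with_suffix(".npz")) as z:
        arr, actions = z["channels"], z["actions"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return [
        TrajectorySnippet(
            subject_id=meta["subject_ids"][i],
            channels=arr[i],
            channel_names=tuple(meta["channel_names"]),
            dt=meta["dt"],
            anchor_time=meta["anchor_times"][i],
            action=actions[i],
            lap_id=meta["lap_ids"][i],
            approach_idx=meta["approach_idx"][i],
            condition=meta["conditions"][i],
        )
        for i in range(len(arr))
    ]
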