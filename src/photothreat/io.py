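"""On-disk representations and run configuration.

Everything the pipeline reads or writes lives in plain-text formats: the
dual-channel recording, the event log and the behavior track are CSV files
with fixed column names; the run configuration is YAML (or JSON).  Times are
seconds as float64, referenced to recording start.  Event intervals are
half-open ``[onset, offset)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RawRecording",
    "EventLog",
    "BehaviorTrack",
    "RunConfig",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_behavior",
    "write_behavior",
    "load_config",
]


class FormatError(ValueError):
    """An on-disk file violates the documented dialect."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class RawRecording:
    """Dual-channel photometry signal on a shared sample clock.

    ``gcamp`` is the calcium-dependent channel (460-490 nm excitation);
    ``isosbestic`` is the calcium-independent 415 nm control channel, used
    only for artifact screening.
    """

    time_s: np.ndarray
    gcamp: np.ndarray
    isosbestic: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.gcamp = np.asarray(self.gcamp, dtype=float)
        self.isosbestic = np.asarray(self.isosbestic, dtype=float)
        n = len(self.time_s)
        if len(self.gcamp) != n or len(self.isosbestic) != n:
            raise FormatError(
                f"channel lengths differ: time={n}, gcamp={len(self.gcamp)}, "
                f"isosbestic={len(self.isosbestic)}"
            )
        dt = np.diff(self.time_s)
        if n > 1:
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                raise FormatError(
                    f"time not strictly increasing at row {bad[0] + 1}"
                )
            med_dt = float(np.median(dt))
            if abs(1.0 / med_dt - self.fs_hz) > 0.01 * self.fs_hz:
                raise FormatError(
                    f"fs_hz={self.fs_hz} inconsistent with median time step "
                    f"{med_dt:.6g} s"
                )

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) + 1.0 / self.fs_hz


@dataclass
class EventLog:
    """Labeled events on the recording clock.

    Stored as a DataFrame with columns ``label, onset_s, offset_s,
    trial_index``; ``offset_s`` is NaN for instantaneous events (loom
    expansion onsets are time stamps, not intervals).
    """

    events: pd.DataFrame

    COLUMNS = ("label", "onset_s", "offset_s", "trial_index")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.events)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"event log missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["label"] = df["label"].astype(str)
        df["onset_s"] = df["onset_s"].astype(float)
        df["offset_s"] = df["offset_s"].astype(float)
        df["trial_index"] = df["trial_index"].astype(int)
        if (df["label"].str.len() == 0).any():
            raise FormatError("empty event label")
        has_off = df["offset_s"].notna()
        bad = df.index[has_off & (df["offset_s"] <= df["onset_s"])]
        if len(bad):
            raise FormatError(
                f"event at row {bad[0]}: offset_s <= onset_s"
            )
        df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
        # overlapping intervals of one label are a logging error upstream
        for label, grp in df[has_off].groupby("label"):
            on = grp["onset_s"].to_numpy()
            off = grp["offset_s"].to_numpy()
            if np.any(on[1:] < off[:-1]):
                raise FormatError(f"overlapping '{label}' intervals")
        self.events = df

    def __len__(self) -> int:
        return len(self.events)

    def select(self, label: str) -> pd.DataFrame:
        return self.events[self.events["label"] == label].reset_index(drop=True)

    def onsets(self, label: str) -> np.ndarray:
        return self.select(label)["onset_s"].to_numpy()

    def trial_onsets(self, label: str) -> np.ndarray:
        """First onset of each trial_index for `label` (loom trials hold
        several expansion time stamps; alignment uses the first)."""
        sel = self.select(label)
        return (
            sel.groupby("trial_index")["onset_s"].min().sort_index().to_numpy()
        )


@dataclass
class BehaviorTrack:
    """Timestamped trajectory and/or motion index with rearing annotations.

    At least one of position (``x_cm``/``y_cm``) or ``motion_index`` must be
    present.  Rearing events are manual annotations carried through the
    pipeline, never computed.
    """

    frame_time_s: np.ndarray
    frame_rate_hz: float
    x_cm: Optional[np.ndarray] = None
    y_cm: Optional[np.ndarray] = None
    motion_index: Optional[np.ndarray] = None
    rearing_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.frame_time_s = np.asarray(self.frame_time_s, dtype=float)
        if len(self.frame_time_s) == 0:
            raise FormatError("behavior track is empty")
        if np.any(np.diff(self.frame_time_s) <= 0):
            raise FormatError("frame times not strictly increasing")
        for name in ("x_cm", "y_cm", "motion_index"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != len(self.frame_time_s):
                    raise FormatError(f"{name} length mismatch")
                setattr(self, name, v)
        if self.x_cm is None and self.motion_index is None:
            raise FormatError("need positions or a motion index")
        if (self.x_cm is None) != (self.y_cm is None):
            raise FormatError("x_cm and y_cm must come together")
        self.rearing_times_s = np.sort(
            np.asarray(self.rearing_times_s, dtype=float)
        )

    @property
    def has_position(self) -> bool:
        return self.x_cm is not None

    @property
    def n_frames(self) -> int:
        return len(self.frame_time_s)

    def speed_cm_s(self) -> np.ndarray:
        """Per-frame centroid speed; first frame copies the second.

        Falls back to the motion index when no positions are stored, in
        which case the units are whatever the index was recorded in.
        """
        if self.has_position:
            dx = np.diff(self.x_cm)
            dy = np.diff(self.y_cm)
            dt = np.diff(self.frame_time_s)
            sp = np.hypot(dx, dy) / dt
            return np.concatenate([sp[:1], sp])
        return self.motion_index.copy()


# ---------------------------------------------------------------------------
# run configuration

_WINDOW_DEFAULTS = {
    "loom": {"baseline_s": 2.0, "response_s": 2.0},
    "cs": {"baseline_s": 1.5, "response_s": 2.0},
    "us": {"baseline_s": 0.5, "response_s": 0.5},
}


@dataclass
class RunConfig:
    """Every tunable of the analysis, preloaded with the published protocol.

    Defaults: analysis at 120 Hz, first-order detrend, robust-z artifact
    threshold 5, 10% peak-height discard, event windows of 2/2 s (loom),
    1.5/2 s (CS) and 0.5/0.5 s (US), freezing bouts >= 1 s, escape threshold
    3x the pre-loom mean speed, 30 s loom scoring window, 25 s pre-CS window.
    """

    analysis_fs_hz: float = 120.0
    detrend_order: int = 1
    qc_z_threshold: float = 5.0
    peak_discard_fraction: float = 0.10
    windows: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _WINDOW_DEFAULTS.items()}
    )
    freezing_min_bout_s: float = 1.0
    freezing_motion_threshold: float = 1.0
    escape_multiplier: float = 3.0
    escape_smooth_s: float = 0.25
    scoring_window_s: float = 30.0
    precs_window_s: float = 25.0

    def __post_init__(self) -> None:
        for name in (
            "analysis_fs_hz",
            "qc_z_threshold",
            "freezing_min_bout_s",
            "freezing_motion_threshold",
            "escape_multiplier",
            "escape_smooth_s",
            "scoring_window_s",
            "precs_window_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.detrend_order < 0:
            raise ValueError("detrend_order must be >= 0")
        if not (0.0 <= self.peak_discard_fraction < 1.0):
            raise ValueError("peak_discard_fraction must be in [0, 1)")
        for label, w in self.windows.items():
            if set(w) != {"baseline_s", "response_s"}:
                raise ValueError(f"window '{label}' needs baseline_s/response_s")
            if w["baseline_s"] <= 0 or w["response_s"] <= 0:
                raise ValueError(f"window '{label}' durations must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON configuration; absent keys fall back to the
    documented defaults, unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    if "windows" in data:
        merged = {k: dict(v) for k, v in _WINDOW_DEFAULTS.items()}
        for label, w in data["windows"].items():
            merged.setdefault(label, {}).update(w)
        data = {**data, "windows": merged}
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# CSV readers / writers


def read_recording(path: str | Path) -> RawRecording:
    """Read ``recording.csv`` (columns ``time_s,gcamp,isosbestic``)."""
    df = pd.read_csv(path)
    for col in ("time_s", "gcamp", "isosbestic"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            # file line number: header is line 1, offending sample bad[0]+1
            raise FormatError(
                f"{path}: time not strictly increasing at row {bad[0] + 3}"
            )
        fs = 1.0 / float(np.median(dt))
    else:
        fs = 1.0
    return RawRecording(
        time_s=t,
        gcamp=df["gcamp"].to_numpy(dtype=float),
        isosbestic=df["isosbestic"].to_numpy(dtype=float),
        fs_hz=fs,
    )


def write_recording(rec: RawRecording, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": rec.time_s, "gcamp": rec.gcamp, "isosbestic": rec.isosbestic}
    ).to_csv(path, index=False, float_format="%.12g")


def read_events(path: str | Path) -> EventLog:
    """Read ``events.csv`` (``label,onset_s,offset_s,trial_index``; an empty
    offset marks an instantaneous event)."""
    df = pd.read_csv(path)
    missing = set(EventLog.COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return EventLog(df)


def write_events(log: EventLog, path: str | Path) -> None:
    log.events.to_csv(path, index=False, float_format="%.12g")


def read_behavior(path: str | Path, frame_rate_hz: float | None = None) -> BehaviorTrack:
    """Read ``behavior.csv`` (``frame_time_s[,x_cm,y_cm][,motion_index]
    [,rearing]``); the optional 0/1 ``rearing`` column marks annotated
    rearing frames."""
    df = pd.read_csv(path)
    if "frame_time_s" not in df.columns:
        raise FormatError(f"{path}: missing column 'frame_time_s'")
    t = df["frame_time_s"].to_numpy(dtype=float)
    if frame_rate_hz is None:
        frame_rate_hz = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    kw = {}
    if "x_cm" in df.columns and "y_cm" in df.columns:
        kw["x_cm"] = df["x_cm"].to_numpy(dtype=float)
        kw["y_cm"] = df["y_cm"].to_numpy(dtype=float)
    if "motion_index" in df.columns:
        kw["motion_index"] = df["motion_index"].to_numpy(dtype=float)
    if "rearing" in df.columns:
        kw["rearing_times_s"] = t[df["rearing"].to_numpy(dtype=float) > 0]
    return BehaviorTrack(frame_time_s=t, frame_rate_hz=frame_rate_hz, **kw)


def write_behavior(track: BehaviorTrack, path: str | Path) -> None:
    cols = {"frame_time_s": track.frame_time_s}
    if track.has_position:
        cols["x_cm"] = track.x_cm
        cols["y_cm"] = track.y_cm
    if track.motion_index is not None:
        cols["motion_index"] = track.motion_index
    rearing = np.zeros(track.n_frames)
    if len(track.rearing_times_s):
        idx = np.searchsorted(track.frame_time_s, track.rearing_times_s)
        idx = np.clip(idx, 0, track.n_frames - 1)
        rearing[idx] = 1.0
    cols["rearing"] = rearing
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
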