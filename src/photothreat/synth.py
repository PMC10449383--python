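"""Seedable synthetic photometry sessions and behavior tracks.

The generator emulates the structure of a looming / threat-conditioning
recording session so every downstream stage can be verified against known
ground truth: an exponentially photobleaching fluorescence baseline,
event-locked calcium transients with GCaMP-like difference-of-exponential
kinetics, Gaussian sensor noise, optional step artifacts on the isosbestic
control channel, and open-field locomotion traces with freezing bouts,
rearing annotations and escape sprints.

It does not model habituation, learning, or any video/pixel-level process;
transient amplitudes and kinetics are plausible placeholders, since real
sessions do not constrain them numerically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import BehaviorTrack, EventLog, RawRecording

__all__ = [
    "SessionSpec",
    "TransientSpec",
    "ProtocolSpec",
    "BehaviorSpec",
    "GroundTruth",
    "transient_kernel",
    "transient_peak_time_s",
    "generate_event_schedule",
    "generate_photometry_session",
    "generate_behavior_track",
]


@dataclass(frozen=True)
class SessionSpec:
    """Recording-level parameters of a synthetic photometry session.

    ``fs_hz`` defaults to 1 kHz, a desk-scale stand-in for the 11 kHz
    acquisition rate of the real system (both are far above the 120 Hz
    analysis rate, so the choice only affects runtime).  ``bleach_tau_s``
    defaults to 10x a typical session so that the exponential bleaching
    trend is locally near-linear, matching the first-order detrend the
    analysis applies; shorter taus act as a stress-test knob.
    """

    duration_s: float
    fs_hz: float = 1000.0
    bleach_amplitude: float = 0.05
    bleach_tau_s: float = 3000.0
    noise_sd: float = 0.005
    baseline_f0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.baseline_f0 <= 0:
            raise ValueError("baseline_f0 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bleach_tau_s <= 0:
            raise ValueError("bleach_tau_s must be positive")


@dataclass(frozen=True)
class TransientSpec:
    """One event-locked calcium transient.

    The kernel is a peak-normalized difference of exponentials,
    ``(1 - exp(-t/rise)) * exp(-t/decay)``, scaled so its maximum equals
    ``amplitude`` in dF/F units.  Defaults approximate GCaMP7s/8m bulk
    kinetics (fast rise, ~1 s decay).
    """

    onset_s: float
    amplitude: float = 0.05
    rise_tau_s: float = 0.1
    decay_tau_s: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (0 < self.rise_tau_s < self.decay_tau_s):
            raise ValueError("need 0 < rise_tau_s < decay_tau_s")


@dataclass(frozen=True)
class ProtocolSpec:
    """Trial structure of a looming or conditioning session.

    Looming: each trial is ``loom_reps_per_trial`` expansions, each
    250 ms expand + 250 ms hold + 2 s pause (consecutive onsets 2.5 s
    apart).  Conditioning: each trial is a 20 s tone (CS) co-terminating
    with a 2 s footshock (US); inter-trial intervals are drawn uniformly
    from 35-120 s.
    """

    kind: str
    n_trials: int
    loom_expand_s: float = 0.25
    loom_hold_s: float = 0.25
    loom_pause_s: float = 2.0
    loom_reps_per_trial: int = 5
    cs_duration_s: float = 20.0
    us_duration_s: float = 2.0
    iti_range_s: tuple[float, float] = (35.0, 120.0)
    lead_in_s: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in {"loom", "conditioning"}:
            raise ValueError("kind must be 'loom' or 'conditioning'")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in (
            "loom_expand_s",
            "loom_hold_s",
            "loom_pause_s",
            "cs_duration_s",
            "us_duration_s",
            "lead_in_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.loom_reps_per_trial < 1:
            raise ValueError("loom_reps_per_trial must be >= 1")
        lo, hi = self.iti_range_s
        if not (0 < lo <= hi):
            raise ValueError("iti_range_s must satisfy 0 < min <= max")

    @property
    def loom_period_s(self) -> float:
        return self.loom_expand_s + self.loom_hold_s + self.loom_pause_s


@dataclass(frozen=True)
class BehaviorSpec:
    """Script of a synthetic open-field session.

    The arena defaults to the 37 x 40 cm looming box.  Freezing bouts,
    rearing instants and escape windows are placed by the caller (usually
    from a generated event schedule) and become the ground truth the
    scoring stage is checked against.
    """

    duration_s: float
    arena_w_cm: float = 37.0
    arena_h_cm: float = 40.0
    frame_rate_hz: float = 30.0
    freeze_bouts: tuple[tuple[float, float], ...] = ()
    rearing_times_s: tuple[float, ...] = ()
    escape_windows: tuple[tuple[float, float, float], ...] = ()
    baseline_speed_cm_s: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.baseline_speed_cm_s <= 0:
            raise ValueError("baseline_speed_cm_s must be positive")
        object.__setattr__(
            self, "freeze_bouts", tuple(tuple(b) for b in self.freeze_bouts)
        )
        object.__setattr__(
            self, "escape_windows", tuple(tuple(w) for w in self.escape_windows)
        )
        object.__setattr__(
            self, "rearing_times_s", tuple(self.rearing_times_s)
        )
        for a, b in self.freeze_bouts:
            if not (0 <= a < b <= self.duration_s):
                raise ValueError(f"freeze bout ({a}, {b}) outside session")
        for a, b, m in self.escape_windows:
            if not (0 <= a < b <= self.duration_s):
                raise ValueError(f"escape window ({a}, {b}) outside session")
            if m <= 1:
                raise ValueError("escape speed_multiplier must be > 1")
        for t in self.rearing_times_s:
            if not (0 <= t <= self.duration_s):
                raise ValueError(f"rearing time {t} outside session")
        # a frame cannot freeze and sprint at once
        for a, b in self.freeze_bouts:
            for c, d, _ in self.escape_windows:
                if a < d and c < b:
                    raise ValueError(
                        f"freeze bout ({a}, {b}) overlaps escape window ({c}, {d})"
                    )


@dataclass
class GroundTruth:
    """What the generator actually put into a session (JSON-serializable)."""

    transients: list[TransientSpec] = field(default_factory=list)
    event_schedule: Optional[EventLog] = None
    freeze_bouts: list[tuple[float, float]] = field(default_factory=list)
    rearing_times_s: list[float] = field(default_factory=list)
    escape_windows: list[tuple[float, float, float]] = field(default_factory=list)
    artifact_times_s: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "transients": [dataclasses.asdict(t) for t in self.transients],
            "event_schedule": (
                self.event_schedule.events.to_dict(orient="records")
                if self.event_schedule is not None
                else None
            ),
            "freeze_bouts": [list(b) for b in self.freeze_bouts],
            "rearing_times_s": list(self.rearing_times_s),
            "escape_windows": [list(w) for w in self.escape_windows],
            "artifact_times_s": list(self.artifact_times_s),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        sched = None
        if d.get("event_schedule") is not None:
            sched = EventLog(pd.DataFrame(d["event_schedule"]))
        return cls(
            transients=[TransientSpec(**t) for t in d["transients"]],
            event_schedule=sched,
            freeze_bouts=[tuple(b) for b in d["freeze_bouts"]],
            rearing_times_s=list(d["rearing_times_s"]),
            escape_windows=[tuple(w) for w in d["escape_windows"]],
            artifact_times_s=list(d["artifact_times_s"]),
        )


# ---------------------------------------------------------------------------
# transient kernel


def transient_peak_time_s(rise_tau_s: float, decay_tau_s: float) -> float:
    """Onset-to-peak latency of the difference-of-exponentials kernel.

    Setting the derivative of (1 - e^{-t/r}) e^{-t/d} to zero gives
    t* = r * ln(1 + d/r).
    """
    return rise_tau_s * np.log(1.0 + decay_tau_s / rise_tau_s)


def transient_kernel(t_s: np.ndarray, spec: TransientSpec) -> np.ndarray:
    """Evaluate one transient's dF/F contribution on absolute times ``t_s``."""
    dt = np.asarray(t_s, dtype=float) - spec.onset_s
    out = np.zeros_like(dt)
    pos = dt > 0
    raw = (1.0 - np.exp(-dt[pos] / spec.rise_tau_s)) * np.exp(
        -dt[pos] / spec.decay_tau_s
    )
    tp = transient_peak_time_s(spec.rise_tau_s, spec.decay_tau_s)
    peak = (1.0 - np.exp(-tp / spec.rise_tau_s)) * np.exp(-tp / spec.decay_tau_s)
    out[pos] = spec.amplitude * raw / peak
    return out


# ---------------------------------------------------------------------------
# generators


def generate_event_schedule(protocol: ProtocolSpec, seed: int) -> EventLog:
    """Lay out trial events on the session clock.

    Conditioning trials emit a ``cs`` interval and a ``us`` interval whose
    offset coincides with the CS offset; loom trials emit one instantaneous
    ``loom`` onset per expansion, consecutive onsets one expand+hold+pause
    period apart.  Inter-trial intervals (offset of one trial to onset of
    the next) are drawn uniformly from ``iti_range_s`` and quantized to a
    1/1024 s grid — sub-ms resolution, exact in binary floating point, so
    within-trial spacings stay exact after accumulating trial starts.
    """
    rng = np.random.default_rng(seed)
    lo, hi = protocol.iti_range_s
    itis = rng.uniform(lo, hi, size=protocol.n_trials - 1)
    itis = np.clip(np.round(itis * 1024.0) / 1024.0, lo, hi)
    rows = []
    t = protocol.lead_in_s
    for k in range(protocol.n_trials):
        if protocol.kind == "conditioning":
            cs_on = t
            cs_off = cs_on + protocol.cs_duration_s
            us_off = cs_off
            us_on = us_off - protocol.us_duration_s
            rows.append(("cs", cs_on, cs_off, k))
            rows.append(("us", us_on, us_off, k))
            trial_end = cs_off
        else:
            for r in range(protocol.loom_reps_per_trial):
                rows.append(("loom", t + r * protocol.loom_period_s, np.nan, k))
            trial_end = t + protocol.loom_reps_per_trial * protocol.loom_period_s
        if k < protocol.n_trials - 1:
            t = trial_end + itis[k]
    df = pd.DataFrame(rows, columns=list(EventLog.COLUMNS))
    return EventLog(df)


def generate_photometry_session(
    spec: SessionSpec,
    transients: Sequence[TransientSpec] = (),
    artifacts: Sequence[float] = (),
    artifact_step: float | None = None,
) -> tuple[RawRecording, GroundTruth]:
    """Render a dual-channel recording from a session script.

    GCaMP channel: ``F0 * (1 + bleach * exp(-t/tau)) * (1 + sum of transient
    kernels) + noise``.  Isosbestic channel: an independent bleaching trend
    (same tau, half the amplitude, 60% of F0) plus its own noise, with an
    additive step of ``artifact_step`` (default ``0.05 * baseline_f0``) at
    each artifact time — the "sudden change" the QC stage must catch.
    """
    for tr in transients:
        if not (0 <= tr.onset_s < spec.duration_s):
            raise ValueError(f"transient onset {tr.onset_s} outside session")
    for a in artifacts:
        if not (0 <= a < spec.duration_s):
            raise ValueError(f"artifact time {a} outside session")
    if artifact_step is None:
        artifact_step = 0.05 * spec.baseline_f0

    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs_hz))
    t = np.arange(n) / spec.fs_hz

    bleach = spec.bleach_amplitude * np.exp(-t / spec.bleach_tau_s)
    dff = np.zeros(n)
    for tr in transients:
        dff += transient_kernel(t, tr)
    gcamp = spec.baseline_f0 * (1.0 + bleach) * (1.0 + dff)
    if spec.noise_sd > 0:
        gcamp = gcamp + rng.normal(0.0, spec.noise_sd, size=n)

    iso0 = 0.6 * spec.baseline_f0
    iso = iso0 * (1.0 + 0.5 * spec.bleach_amplitude * np.exp(-t / spec.bleach_tau_s))
    if spec.noise_sd > 0:
        iso = iso + rng.normal(0.0, spec.noise_sd, size=n)
    for a in artifacts:
        iso = iso + artifact_step * (t >= a)

    rec = RawRecording(time_s=t, gcamp=gcamp, isosbestic=iso, fs_hz=spec.fs_hz)
    truth = GroundTruth(
        transients=list(transients), artifact_times_s=list(artifacts)
    )
    return rec, truth


def generate_behavior_track(spec: BehaviorSpec) -> tuple[BehaviorTrack, GroundTruth]:
    """Emit a scripted open-field trajectory.

    The animal random-walks at ``baseline_speed_cm_s`` (direction is a
    slowly wandering heading), stops dead inside freeze bouts, and moves at
    ``multiplier x baseline`` inside escape windows.  Positions reflect off
    the arena walls; steps are small relative to the arena, so reflection
    barely perturbs per-frame speed.  A per-frame motion index (centroid
    displacement in cm) is emitted alongside positions.
    """
    rng = np.random.default_rng(spec.seed)
    fps = spec.frame_rate_hz
    n = int(round(spec.duration_s * fps))
    t = np.arange(n) / fps

    speed = np.full(n, spec.baseline_speed_cm_s)
    for a, b in spec.freeze_bouts:
        speed[(t >= a) & (t < b)] = 0.0
    for a, b, m in spec.escape_windows:
        speed[(t >= a) & (t < b)] = m * spec.baseline_speed_cm_s

    heading = np.cumsum(rng.normal(0.0, 0.4, size=n))
    step = speed / fps
    dx = step * np.cos(heading)
    dy = step * np.sin(heading)

    x = np.empty(n)
    y = np.empty(n)
    x[0] = spec.arena_w_cm / 2.0
    y[0] = spec.arena_h_cm / 2.0
    # bounce by flipping the heading BEFORE the step is taken, so every
    # emitted displacement has exactly the scripted length and the observed
    # per-frame speed equals the script (freezing/escape ground truth is
    # then recoverable exactly)
    sx, sy = 1.0, 1.0
    for i in range(1, n):
        if not (0.0 <= x[i - 1] + sx * dx[i] <= spec.arena_w_cm):
            sx = -sx
        if not (0.0 <= y[i - 1] + sy * dy[i] <= spec.arena_h_cm):
            sy = -sy
        x[i] = x[i - 1] + sx * dx[i]
        y[i] = y[i - 1] + sy * dy[i]

    motion = np.concatenate([[0.0], np.hypot(np.diff(x), np.diff(y))])
    # snap annotations to the frame grid so round-trips are exact
    rearing = np.array(
        [t[min(int(round(r * fps)), n - 1)] for r in spec.rearing_times_s]
    )
    track = BehaviorTrack(
        frame_time_s=t,
        frame_rate_hz=fps,
        x_cm=x,
        y_cm=y,
        motion_index=motion,
        rearing_times_s=rearing,
    )
    truth = GroundTruth(
        freeze_bouts=list(spec.freeze_bouts),
        rearing_times_s=list(rearing),
        escape_windows=list(spec.escape_windows),
    )
    return track, truth
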