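"""Defensive-behavior scoring from trajectories or motion indices.

Implements the published scoring rules: freezing is complete immobility
(motion below threshold) lasting at least 1 s; freezing percentage is
time-frozen over window length x 100; pre-CS freezing averages the 25 s
before each tone; the differential rearing score is the rearing count in
the 30 s after loom onset minus the count in the 30 s before (negative =
exploratory suppression); an escape is a run of smoothed speed exceeding
three times the pre-loom average.  Rearing and tail rattling were scored
manually at the source, so both are annotation pass-throughs here, never
detected from the track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import BehaviorTrack, EventLog, RunConfig

__all__ = [
    "FreezeBout",
    "detect_freezing",
    "freezing_percentage",
    "pre_cs_freezing",
    "rearing_differential",
    "detect_escapes",
    "locomotion_metrics",
    "score_loom_trials",
    "score_conditioning_trials",
]


@dataclass(frozen=True)
class FreezeBout:
    """One immobility bout, ``[start_s, stop_s)``, at least ``min_bout_s``
    long by construction."""

    start_s: float
    stop_s: float

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


def detect_freezing(
    track: BehaviorTrack,
    motion_threshold: float = 1.0,
    min_bout_s: float = 1.0,
) -> list[FreezeBout]:
    """Maximal sub-threshold runs of at least ``min_bout_s``.

    Motion is the per-frame speed (cm/s from positions, or the recorded
    motion index).  A run of k consecutive sub-threshold frames spans
    k / frame_rate seconds; runs shorter than the minimum are discarded —
    a 0.5 s pause is not freezing.
    """
    motion = track.speed_cm_s()
    frozen = motion < motion_threshold
    bouts: list[FreezeBout] = []
    i = 0
    n = len(frozen)
    while i < n:
        if not frozen[i]:
            i += 1
            continue
        j = i
        while j < n and frozen[j]:
            j += 1
        duration = (j - i) / track.frame_rate_hz
        if duration >= min_bout_s:
            start = track.frame_time_s[i]
            bouts.append(FreezeBout(start_s=start, stop_s=start + duration))
        i = j
    return bouts


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def freezing_percentage(
    bouts: Sequence[FreezeBout], window: tuple[float, float]
) -> float:
    """100 x (bout time inside the window) / (window length); bouts are
    clipped to the window."""
    start, stop = window
    if stop <= start:
        raise ValueError("window must have positive length")
    total = sum(_overlap(b.start_s, b.stop_s, start, stop) for b in bouts)
    return 100.0 * total / (stop - start)


def pre_cs_freezing(
    bouts: Sequence[FreezeBout],
    cs_events: EventLog,
    precs_window_s: float = 25.0,
) -> tuple[float, list[int]]:
    """Mean freezing % over the ``precs_window_s`` before each CS onset.

    A CS whose pre-window underflows the session start is skipped; the
    returned list holds the skipped trial indices.
    """
    sel = cs_events.select("cs")
    if sel.empty:
        raise ValueError("no 'cs' events in the log")
    values = []
    skipped = []
    for _, row in sel.iterrows():
        lo = row["onset_s"] - precs_window_s
        if lo < 0:
            skipped.append(int(row["trial_index"]))
            continue
        values.append(freezing_percentage(bouts, (lo, row["onset_s"])))
    if not values:
        raise ValueError("every pre-CS window underflows the session")
    return float(np.mean(values)), skipped


def rearing_differential(
    rearing_times_s: np.ndarray | Sequence[float],
    loom_onset_s: float,
    window_s: float = 30.0,
) -> tuple[int, int, int]:
    """Rearing counts in ``[onset - w, onset)`` and ``[onset, onset + w)``
    and their difference (post minus pre).  An event exactly at onset falls
    in the post window (half-open convention)."""
    r = np.asarray(rearing_times_s, dtype=float)
    pre = int(np.sum((r >= loom_onset_s - window_s) & (r < loom_onset_s)))
    post = int(np.sum((r >= loom_onset_s) & (r < loom_onset_s + window_s)))
    return pre, post, post - pre


def detect_escapes(
    track: BehaviorTrack,
    loom_onset_s: float,
    multiplier: float = 3.0,
    window_s: float = 30.0,
    smooth_s: float = 0.25,
) -> Optional[int]:
    """Count escape sprints in the 30 s after loom onset.

    The reference speed is the mean over the 30 s pre-onset window; speed is
    smoothed with a ``smooth_s`` moving average to suppress frame jitter; an
    escape is a maximal run of smoothed speed strictly above ``multiplier x
    reference``.  Returns ``None`` (not evaluable) when the reference speed
    is zero — a mouse that never moved before the loom has no baseline to
    triple.
    """
    t = track.frame_time_s
    speed = track.speed_cm_s()
    k = max(1, int(round(smooth_s * track.frame_rate_hz)))
    if k > 1:
        kernel = np.ones(k) / k
        speed = np.convolve(speed, kernel, mode="same")
    pre = (t >= loom_onset_s - window_s) & (t < loom_onset_s)
    if not pre.any():
        raise ValueError("pre-loom segment is empty")
    ref = float(speed[pre].mean())
    if ref == 0:
        return None
    post = (t >= loom_onset_s) & (t < loom_onset_s + window_s)
    above = speed[post] > multiplier * ref
    # count rising edges = maximal supra-threshold runs
    return int(np.sum(np.diff(np.concatenate([[0], above.astype(int)])) == 1))


def locomotion_metrics(
    track: BehaviorTrack,
    grid_lines_x: Sequence[float],
    center_rect: tuple[float, float, float, float],
    window: tuple[float, float] | None = None,
) -> Optional[tuple[int, float]]:
    """Line crosses and center-time percentage over ``window``.

    ``grid_lines_x`` are vertical line positions (cm); a cross is a sign
    change of ``x - line`` between consecutive frames.  ``center_rect`` is
    ``(x0, y0, x1, y1)``.  Returns ``None`` for motion-index-only tracks,
    which carry no position to score.
    """
    if not track.has_position:
        return None
    t = track.frame_time_s
    if window is None:
        sel = np.ones(len(t), dtype=bool)
    else:
        sel = (t >= window[0]) & (t < window[1])
    x = track.x_cm[sel]
    y = track.y_cm[sel]
    if x.size == 0:
        raise ValueError("no frames inside the scoring window")
    crosses = 0
    for line in grid_lines_x:
        s = np.sign(x - line)
        # frames exactly on the line adopt the previous side
        for i in range(1, len(s)):
            if s[i] == 0:
                s[i] = s[i - 1]
        crosses += int(np.sum(s[1:] * s[:-1] < 0))
    x0, y0, x1, y1 = center_rect
    in_center = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
    center_pct = 100.0 * float(in_center.sum()) / len(x)
    return crosses, center_pct


# ---------------------------------------------------------------------------
# per-trial score tables


def score_loom_trials(
    track: BehaviorTrack,
    events: EventLog,
    cfg: RunConfig | None = None,
    tail_rattling_counts: Sequence[int] | None = None,
) -> pd.DataFrame:
    """One row per loom trial: freezing % in the 30 s scoring window,
    rearing pre/post/differential, escape count, tail-rattling passthrough."""
    if cfg is None:
        cfg = RunConfig()
    onsets = events.trial_onsets("loom")
    if onsets.size == 0:
        raise ValueError("no 'loom' events in the log")
    bouts = detect_freezing(
        track, cfg.freezing_motion_threshold, cfg.freezing_min_bout_s
    )
    w = cfg.scoring_window_s
    rows = []
    for i, onset in enumerate(onsets):
        pre, post, diff = rearing_differential(track.rearing_times_s, onset, w)
        escapes = detect_escapes(
            track, onset, cfg.escape_multiplier, w, cfg.escape_smooth_s
        )
        rows.append(
            {
                "trial": i,
                "freezing_pct": freezing_percentage(bouts, (onset, onset + w)),
                "rearing_pre": pre,
                "rearing_post": post,
                "rearing_differential": diff,
                "escape_events": escapes if escapes is not None else np.nan,
                "escape_evaluable": escapes is not None,
                "tail_rattling": (
                    tail_rattling_counts[i]
                    if tail_rattling_counts is not None
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def score_conditioning_trials(
    track: BehaviorTrack,
    events: EventLog,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """One row per CS: freezing % during the tone and in the 25 s before."""
    if cfg is None:
        cfg = RunConfig()
    sel = events.select("cs")
    if sel.empty:
        raise ValueError("no 'cs' events in the log")
    bouts = detect_freezing(
        track, cfg.freezing_motion_threshold, cfg.freezing_min_bout_s
    )
    rows = []
    for _, row in sel.iterrows():
        on, off = row["onset_s"], row["offset_s"]
        lo = on - cfg.precs_window_s
        rows.append(
            {
                "trial": int(row["trial_index"]),
                "freezing_pct": freezing_percentage(bouts, (on, off)),
                "pre_cs_freezing_pct": (
                    freezing_percentage(bouts, (lo, on)) if lo >= 0 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
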