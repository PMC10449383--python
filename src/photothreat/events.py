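"""Event-aligned analysis: peri-event z-scoring, peak-filtered AUC,
time-to-peak.

Trials are aligned to event onsets (for looming trials, to the first
expansion of each five-expansion trial), standardized against the mean and
population SD of their own pre-event baseline, and quantified by (a) the
area under retained above-baseline regions — a region is kept only if its
peak height reaches 10% of the window's min-to-max range, mirroring the
Prism-style peak filter — and (b) the latency from onset to the maximal
z-scored sample.  Trials, not sessions, are the unit of exclusion: a trial
is dropped if an isosbestic artifact falls inside its window or its
baseline is degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EventLog, RunConfig
from .signal import ProcessedTrace

__all__ = [
    "WindowSpec",
    "AlignedTrialSet",
    "TrialMetrics",
    "align_trials",
    "zscore_baseline",
    "compute_auc",
    "time_to_peak",
    "trial_metrics",
    "summarize_trials",
]


@dataclass(frozen=True)
class WindowSpec:
    """Peri-event window: ``baseline_s`` before onset, ``response_s`` after.

    Published defaults: loom 2 s / 2 s, CS 1.5 s / 2 s, US 0.5 s / 0.5 s.
    """

    label: str
    baseline_s: float
    response_s: float

    def __post_init__(self) -> None:
        if self.baseline_s <= 0 or self.response_s <= 0:
            raise ValueError("window durations must be positive")

    @classmethod
    def from_config(cls, label: str, cfg: RunConfig) -> "WindowSpec":
        if label not in cfg.windows:
            raise KeyError(f"no window definition for label '{label}'")
        w = cfg.windows[label]
        return cls(label=label, baseline_s=w["baseline_s"], response_s=w["response_s"])


@dataclass
class AlignedTrialSet:
    """Trial x time matrix on a common onset-relative clock.

    ``z`` holds raw dF/F straight after alignment and baseline-standardized
    values after :func:`zscore_baseline` (``standardized`` says which).
    Rows of invalid trials are kept, NaN-filled, and excluded from every
    group summary.
    """

    z: np.ndarray
    rel_time_s: np.ndarray
    window: WindowSpec
    fs_hz: float
    trial_qc: np.ndarray
    qc_reasons: list[str]
    standardized: bool = False

    @property
    def n_trials(self) -> int:
        return self.z.shape[0]

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.rel_time_s < 0

    @property
    def response_mask(self) -> np.ndarray:
        return self.rel_time_s >= 0

    @property
    def n_retained(self) -> int:
        return int(self.trial_qc.sum())

    def to_long_frame(self) -> pd.DataFrame:
        trials = np.repeat(np.arange(self.n_trials), len(self.rel_time_s))
        return pd.DataFrame(
            {
                "trial": trials,
                "rel_time_s": np.tile(self.rel_time_s, self.n_trials),
                "z": self.z.ravel(),
            }
        )


@dataclass
class TrialMetrics:
    """Per-trial quantification of one aligned response."""

    auc: float
    time_to_peak_s: float
    peak_z: float
    retained_peak_count: int


# ---------------------------------------------------------------------------
# alignment and standardization


def align_trials(
    trace: ProcessedTrace, events: EventLog, window: WindowSpec
) -> AlignedTrialSet:
    """Cut one onset-aligned row per trial out of the processed trace.

    Samples are selected by the half-open window ``[-baseline_s,
    response_s)`` on onset-relative time; all rows share the sample grid of
    the analysis rate.  A trial is invalid when its window runs off the
    recording or contains an isosbestic QC flag.
    """
    onsets = events.trial_onsets(window.label)
    if onsets.size == 0:
        raise ValueError(f"no '{window.label}' events in the log")
    fs = trace.fs_hz
    n_pre = int(round(window.baseline_s * fs))
    n_post = int(round(window.response_s * fs))
    rel = np.arange(-n_pre, n_post) / fs
    n_cols = n_pre + n_post

    z = np.full((onsets.size, n_cols), np.nan)
    qc = np.ones(onsets.size, dtype=bool)
    reasons = [""] * onsets.size
    t0 = trace.time_s[0]
    flagged = np.asarray(trace.qc.flagged_times_s, dtype=float)
    for i, onset in enumerate(onsets):
        i0 = int(round((onset - t0) * fs)) - n_pre
        i1 = i0 + n_cols
        if i0 < 0 or i1 > len(trace.dff):
            qc[i] = False
            reasons[i] = "window extends past recording"
            continue
        lo = onset - window.baseline_s
        hi = onset + window.response_s
        if flagged.size and np.any((flagged >= lo) & (flagged < hi)):
            qc[i] = False
            reasons[i] = "isosbestic artifact inside window"
            continue
        z[i] = trace.dff[i0:i1]
    return AlignedTrialSet(
        z=z,
        rel_time_s=rel,
        window=window,
        fs_hz=fs,
        trial_qc=qc,
        qc_reasons=reasons,
        standardized=False,
    )


def zscore_baseline(aligned: AlignedTrialSet) -> AlignedTrialSet:
    """Standardize each trial against its own pre-event baseline.

    z = (x - mean of baseline) / SD of baseline, with the population SD
    (divisor n).  A zero-SD baseline marks the trial invalid rather than
    letting NaN/inf propagate.
    """
    bl = aligned.baseline_mask
    if not bl.any():
        raise ValueError("empty baseline segment")
    z = aligned.z.copy()
    qc = aligned.trial_qc.copy()
    reasons = list(aligned.qc_reasons)
    for i in range(aligned.n_trials):
        if not qc[i]:
            continue
        mu = z[i, bl].mean()
        sd = z[i, bl].std()  # ddof=0: population SD
        if sd == 0 or not np.isfinite(sd):
            qc[i] = False
            reasons[i] = "degenerate baseline (zero SD)"
            z[i] = np.nan
            continue
        z[i] = (z[i] - mu) / sd
    return AlignedTrialSet(
        z=z,
        rel_time_s=aligned.rel_time_s,
        window=aligned.window,
        fs_hz=aligned.fs_hz,
        trial_qc=qc,
        qc_reasons=reasons,
        standardized=True,
    )


# ---------------------------------------------------------------------------
# per-trial metrics


def _positive_regions(z: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive samples with z > 0, as [start, stop)."""
    pos = z > 0
    if not pos.any():
        return []
    edges = np.diff(pos.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if pos[0]:
        starts.insert(0, 0)
    if pos[-1]:
        stops.append(len(z))
    return list(zip(starts, stops))


def compute_auc(
    z: np.ndarray,
    rel_time_s: np.ndarray,
    discard_fraction: float = 0.10,
) -> tuple[float, int]:
    """Peak-filtered area under the curve over the response window.

    Above-baseline regions (baseline = 0 in z units, since the trace is
    baseline-standardized) are enumerated; a region whose peak height is
    strictly below ``discard_fraction`` of the window's max-minus-min range
    is discarded; the rest contribute their trapezoidal area.  Negative
    deflections never contribute.  Returns ``(auc, retained_peak_count)``.
    """
    z = np.asarray(z, dtype=float)
    rel = np.asarray(rel_time_s, dtype=float)
    resp = rel >= 0
    zr = z[resp]
    tr = rel[resp]
    if zr.size == 0:
        raise ValueError("response window is empty")
    span = float(zr.max() - zr.min())
    cutoff = discard_fraction * span
    terms: list[float] = []
    kept = 0
    for a, b in _positive_regions(zr):
        height = float(zr[a:b].max())
        if height < cutoff:
            continue
        kept += 1
        # trapezoid terms, summed with fsum so the total is correctly
        # rounded and independent of accumulation order
        terms.extend(
            (tr[i + 1] - tr[i]) * (zr[i] + zr[i + 1]) / 2.0
            for i in range(a, b - 1)
        )
    return math.fsum(terms), kept


def time_to_peak(z: np.ndarray, rel_time_s: np.ndarray) -> float:
    """Latency from onset to the maximal sample in the response window;
    ties go to the earliest sample."""
    rel = np.asarray(rel_time_s, dtype=float)
    resp = rel >= 0
    zr = np.asarray(z, dtype=float)[resp]
    if zr.size == 0:
        raise ValueError("response window is empty")
    return float(rel[resp][int(np.argmax(zr))])


def trial_metrics(
    aligned: AlignedTrialSet, discard_fraction: float = 0.10
) -> pd.DataFrame:
    """Per-trial AUC (z·s), time-to-peak (s), peak z, and QC flag."""
    if not aligned.standardized:
        raise ValueError("standardize trials before computing metrics")
    rows = []
    resp = aligned.response_mask
    for i in range(aligned.n_trials):
        if not aligned.trial_qc[i]:
            rows.append(
                {
                    "trial": i,
                    "label": aligned.window.label,
                    "auc": np.nan,
                    "time_to_peak_s": np.nan,
                    "peak_z": np.nan,
                    "retained_peak_count": 0,
                    "qc": False,
                    "qc_reason": aligned.qc_reasons[i],
                }
            )
            continue
        auc, kept = compute_auc(
            aligned.z[i], aligned.rel_time_s, discard_fraction
        )
        rows.append(
            {
                "trial": i,
                "label": aligned.window.label,
                "auc": auc,
                "time_to_peak_s": time_to_peak(aligned.z[i], aligned.rel_time_s),
                "peak_z": float(aligned.z[i, resp].max()),
                "retained_peak_count": kept,
                "qc": True,
                "qc_reason": "",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TrialSummary:
    """Group summary over retained trials: mean trace, SEM band, heatmap."""

    rel_time_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    heatmap: np.ndarray
    metrics: pd.DataFrame
    n_retained: int
    empty: bool = False


def summarize_trials(
    aligned: AlignedTrialSet, discard_fraction: float = 0.10
) -> TrialSummary:
    """Mean +/- SEM across retained trials per time point, the trial-ordered
    heatmap matrix, and the per-trial metric table.  With zero retained
    trials an explicit empty summary is returned (``empty=True``)."""
    metrics = trial_metrics(aligned, discard_fraction)
    keep = aligned.trial_qc
    n = int(keep.sum())
    if n == 0:
        nan = np.full_like(aligned.rel_time_s, np.nan)
        return TrialSummary(
            rel_time_s=aligned.rel_time_s,
            mean=nan,
            sem=nan.copy(),
            heatmap=np.empty((0, len(aligned.rel_time_s))),
            metrics=metrics,
            n_retained=0,
            empty=True,
        )
    zk = aligned.z[keep]
    mean = zk.mean(axis=0)
    sem = zk.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return TrialSummary(
        rel_time_s=aligned.rel_time_s,
        mean=mean,
        sem=sem,
        heatmap=zk,
        metrics=metrics,
        n_retained=n,
    )
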