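"""Raw recording -> quality-controlled dF/F at the analysis rate.

The chain is fixed: local-average downsampling of both channels to the
analysis rate (120 Hz by default), a least-squares polynomial baseline fit
(first order by default) to the downsampled calcium channel over the whole
recording, dF/F = (signal - fit) / fit, and an artifact screen on the
downsampled isosbestic channel.  The isosbestic channel never enters the
normalization itself; it is purely a discard criterion, so any sudden
step on it flags the session (and, downstream, the trials it touches).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import RawRecording, RunConfig

__all__ = [
    "QCReport",
    "ProcessedTrace",
    "downsample_local_average",
    "fit_baseline_polynomial",
    "compute_dff",
    "qc_isosbestic",
    "process_recording",
]


@dataclass
class QCReport:
    """Outcome of the isosbestic sudden-change screen."""

    passed: bool
    max_isosbestic_jump_z: float
    flagged_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "passed": bool(self.passed),
            "max_isosbestic_jump_z": float(self.max_isosbestic_jump_z),
            "flagged_times_s": [float(t) for t in self.flagged_times_s],
        }


@dataclass
class ProcessedTrace:
    """dF/F at the analysis rate, with the baseline fit and QC attached."""

    time_s: np.ndarray
    dff: np.ndarray
    fs_hz: float
    fit_coeffs: np.ndarray
    qc: QCReport

    def __post_init__(self) -> None:
        if len(self.time_s) != len(self.dff):
            raise ValueError("time_s and dff length mismatch")


def downsample_local_average(
    x: np.ndarray, fs_in: float, fs_out: float
) -> np.ndarray:
    """Bin-average ``x`` from ``fs_in`` down to roughly ``fs_out``.

    The bin width is ``round(fs_in / fs_out)`` samples (11 kHz -> 120 Hz is
    a non-integer ratio, 91.67; the nearest integer bin is used and the
    effective output rate is ``fs_in / width``).  A trailing partial bin is
    dropped.  Constant signals are preserved exactly.
    """
    if fs_out > fs_in:
        raise ValueError(f"fs_out={fs_out} exceeds fs_in={fs_in}")
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    x = np.asarray(x, dtype=float)
    width = int(round(fs_in / fs_out))
    if width <= 1:
        return x.copy()
    n_bins = len(x) // width
    return x[: n_bins * width].reshape(n_bins, width).mean(axis=1)


def effective_fs(fs_in: float, fs_out: float) -> float:
    """Output rate actually realized by the integer bin width."""
    width = int(round(fs_in / fs_out))
    return fs_in if width <= 1 else fs_in / width


def fit_baseline_polynomial(
    trace: np.ndarray, order: int = 1, t: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares polynomial baseline.

    Returns ``(coeffs, fitted)`` with coefficients in ascending order
    (intercept first), evaluated at the sample times (sample index when
    ``t`` is omitted).
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) <= order + 1:
        raise ValueError(f"need more than {order + 1} samples for order {order}")
    if t is None:
        t = np.arange(len(trace), dtype=float)
    else:
        t = np.asarray(t, dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis (all sample times equal)")
    coeffs = np.polynomial.polynomial.polyfit(t, trace, order)
    fitted = np.polynomial.polynomial.polyval(t, coeffs)
    return coeffs, fitted


def compute_dff(gcamp: np.ndarray, fitted: np.ndarray) -> np.ndarray:
    """dF/F = (signal - fitted baseline) / fitted baseline, elementwise."""
    gcamp = np.asarray(gcamp, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if np.any(fitted <= 0):
        raise ValueError(
            "fitted baseline is non-positive; trace unusable for ratio "
            "normalization"
        )
    return (gcamp - fitted) / fitted


def qc_isosbestic(
    isosbestic: np.ndarray,
    threshold_z: float = 5.0,
    time_s: np.ndarray | None = None,
) -> QCReport:
    """Flag sudden changes in the isosbestic control channel.

    First differences are standardized against their own median and
    MAD-derived scale (robust, so a single large step cannot mask itself);
    samples whose |z| exceeds ``threshold_z`` are flagged.  A slow drift has
    near-constant differences and passes; a constant channel passes with a
    jump z of 0.
    """
    iso = np.asarray(isosbestic, dtype=float)
    if len(iso) < 3:
        raise ValueError("need at least 3 samples for the isosbestic screen")
    d = np.diff(iso)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = d.std()
    if scale == 0:
        return QCReport(passed=True, max_isosbestic_jump_z=0.0)
    z = (d - med) / scale
    flagged = np.nonzero(np.abs(z) > threshold_z)[0]
    if time_s is None:
        # report the later sample of each offending difference, as an index
        times = (flagged + 1).astype(float)
    else:
        times = np.asarray(time_s, dtype=float)[flagged + 1]
    return QCReport(
        passed=flagged.size == 0,
        max_isosbestic_jump_z=float(np.max(np.abs(z))),
        flagged_times_s=times,
    )


def process_recording(rec: RawRecording, cfg: RunConfig | None = None) -> ProcessedTrace:
    """Full signal chain: downsample -> polynomial detrend -> dF/F -> QC."""
    if cfg is None:
        cfg = RunConfig()
    g = downsample_local_average(rec.gcamp, rec.fs_hz, cfg.analysis_fs_hz)
    iso = downsample_local_average(rec.isosbestic, rec.fs_hz, cfg.analysis_fs_hz)
    t = downsample_local_average(rec.time_s, rec.fs_hz, cfg.analysis_fs_hz)
    fs = effective_fs(rec.fs_hz, cfg.analysis_fs_hz)
    coeffs, fitted = fit_baseline_polynomial(g, cfg.detrend_order, t=t)
    dff = compute_dff(g, fitted)
    qc = qc_isosbestic(iso, cfg.qc_z_threshold, time_s=t)
    return ProcessedTrace(time_s=t, dff=dff, fs_hz=fs, fit_coeffs=coeffs, qc=qc)
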