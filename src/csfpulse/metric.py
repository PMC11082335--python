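"""The dynamic CSF pulsation metric from paired-slice ROI signals.

For every retained measurement ``n`` the pulsed CSF volume is estimated
from the upper/lower target-slice signal ratio:

    CSFpulse(n) = (1/alpha - 1) * (S_i(n) / S_{i-1}(n) - 1) * ROIvolume

where ``alpha`` is the interslice saturation ratio and ``ROIvolume`` the
CSF ROI volume of the upper target slice.  Negative values (flow outside
the capture range or descending at that measurement) are clamped to zero.
Per-subject summaries are the mean of the clamped series (pulsation
strength), the mean absolute within-subject z-score (variability), and the
fraction of measurements with a positive raw value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bloch import AlphaCalibration, CalibrationError

__all__ = [
    "SliceSignals",
    "PulseSeries",
    "SignalDataError",
    "compute_csfpulse_series",
    "summarize_series",
    "temporal_highpass",
]

#: Initial dummy-equilibration measurements excluded from every computation.
DEFAULT_N_DISCARD = 5


class SignalDataError(ValueError):
    """Raised for unusable ROI signal values (non-positive denominator)."""


@dataclass(frozen=True)
class SliceSignals:
    """Per-measurement ROI signals of the target slice pair.

    ``s_lower``/``s_upper`` cover all acquired measurements; the first
    ``n_discard`` are dropped before any computation.
    """

    s_lower: np.ndarray
    s_upper: np.ndarray
    n_discard: int = DEFAULT_N_DISCARD

    def __post_init__(self) -> None:
        lower = np.asarray(self.s_lower, dtype=float)
        upper = np.asarray(self.s_upper, dtype=float)
        if lower.ndim != 1 or upper.ndim != 1 or lower.size != upper.size:
            raise ValueError("s_lower and s_upper must be equal-length 1-D")
        if self.n_discard < 0 or self.n_discard >= lower.size:
            raise ValueError(
                f"n_discard {self.n_discard} leaves no retained measurements "
                f"out of {lower.size}"
            )
        object.__setattr__(self, "s_lower", lower)
        object.__setattr__(self, "s_upper", upper)

    @property
    def n_total(self) -> int:
        return int(self.s_lower.size)

    @property
    def retained_lower(self) -> np.ndarray:
        return self.s_lower[self.n_discard :]

    @property
    def retained_upper(self) -> np.ndarray:
        return self.s_upper[self.n_discard :]


@dataclass(frozen=True)
class PulseSeries:
    """Dynamic CSFpulse values for one subject with summary statistics."""

    raw: np.ndarray
    clamped: np.ndarray
    mean_pulse: float
    abs_z_mean: float | None
    positive_ratio: float
    roi_volume_mm3: float = field(default=float("nan"))

    def __len__(self) -> int:
        return int(self.raw.size)


def compute_csfpulse_series(
    signals: SliceSignals,
    alpha: AlphaCalibration | float,
    roi_volume_mm3: float,
) -> PulseSeries:
    """Apply the pulsation estimator to a subject's paired-slice signals.

    The raw series is ``(1/alpha - 1)(S_i/S_{i-1} - 1) * ROIvolume`` over
    the retained measurements; the clamped series sets negatives to zero.
    The estimator is invariant to joint rescaling of both signals.
    """
    a = alpha.alpha if isinstance(alpha, AlphaCalibration) else float(alpha)
    if a <= 0 or abs(a - 1.0) < 1e-9:
        raise CalibrationError(f"alpha must be in (0, 1) or (1, inf), got {a}")
    if roi_volume_mm3 <= 0:
        raise ValueError("roi_volume_mm3 must be positive")
    lower = signals.retained_lower
    upper = signals.retained_upper
    bad = np.flatnonzero(lower <= 0)
    if bad.size:
        # 1-based measurement numbers in acquisition counting
        nums = (bad + signals.n_discard + 1).tolist()
        raise SignalDataError(
            f"non-positive lower-slice signal at measurement(s) {nums[:10]}"
        )
    raw = (1.0 / a - 1.0) * (upper / lower - 1.0) * roi_volume_mm3
    clamped = np.maximum(raw, 0.0)
    series = PulseSeries(
        raw=raw,
        clamped=clamped,
        mean_pulse=float(np.mean(clamped)),
        abs_z_mean=None,
        positive_ratio=float(np.mean(raw > 0)),
        roi_volume_mm3=roi_volume_mm3,
    )
    mean_pulse, abs_z_mean, positive_ratio = summarize_series(series)
    return PulseSeries(
        raw=raw,
        clamped=clamped,
        mean_pulse=mean_pulse,
        abs_z_mean=abs_z_mean,
        positive_ratio=positive_ratio,
        roi_volume_mm3=roi_volume_mm3,
    )


def summarize_series(series: PulseSeries) -> tuple[float, float | None, float]:
    """(mean_pulse, abs_z_mean, positive_ratio) of a dynamic series.

    The mean and the z-scores are computed on the clamped series (the
    analysed quantity), with the sample (n-1) SD; the positive ratio on the
    raw series, ties at exactly zero counting as non-positive.  A constant
    series has no defined z-score: ``abs_z_mean`` is None with a warning.
    """
    if series.raw.size < 2:
        raise ValueError("series must contain at least 2 measurements")
    clamped = series.clamped
    mean_pulse = float(np.mean(clamped))
    sd = float(np.std(clamped, ddof=1))
    if sd == 0.0:
        warnings.warn(
            "constant CSFpulse series: absolute z-score undefined",
            stacklevel=2,
        )
        abs_z_mean: float | None = None
    else:
        abs_z_mean = float(np.mean(np.abs((clamped - mean_pulse) / sd)))
    positive_ratio = float(np.mean(series.raw > 0))
    return mean_pulse, abs_z_mean, positive_ratio


def temporal_highpass(
    signal: np.ndarray, cutoff_hz: float, tr_ms: float
) -> np.ndarray:
    """Remove slow drift below ``cutoff_hz`` while preserving the mean level.

    Gaussian-weighted running-line detrending (local linear fit with
    ``sigma = 0.5 / cutoff`` seconds, the FSL high-pass convention): the
    smooth local trend is subtracted and the original mean re-added, so the
    absolute signal scale the ratio metric depends on is preserved.  A pure
    linear drift is removed entirely; broadband content is nearly
    untouched.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("signal must be 1-D with at least 3 samples")
    tr_s = tr_ms / 1000.0
    nyquist = 1.0 / (2.0 * tr_s)
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be in (0, Nyquist={nyquist:.4g} Hz)"
        )
    n = x.size
    t = np.arange(n) * tr_s
    sigma_s = 0.5 / cutoff_hz
    # weighted local linear fit at every time point (N^2 but N ~ 155)
    dt = t[None, :] - t[:, None]
    w = np.exp(-0.5 * (dt / sigma_s) ** 2)
    s0 = w.sum(axis=1)
    s1 = (w * dt).sum(axis=1)
    s2 = (w * dt**2).sum(axis=1)
    b0 = (w * x[None, :]).sum(axis=1)
    b1 = (w * dt * x[None, :]).sum(axis=1)
    det = s0 * s2 - s1**2
    trend = (s2 * b0 - s1 * b1) / det
    # re-add the removed trend's mean so the overall signal level (which
    # the ratio metric depends on) is preserved exactly
    return x - trend + float(np.mean(trend))
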