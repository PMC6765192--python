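"""ΔF/F₀ conversion and spontaneous calcium-transient detection.

The baseline F₀ is a low percentile of the raw fluorescence (global, or
rolling for drifting baselines).  Transients are found by correlating the
detrended ΔF/F₀ with a causal exponential template matched to the indicator's
decay, thresholded at a noise-scaled amplitude (robust MAD estimate), with
detected templates peeled off and the baseline re-estimated so clustered
events do not bias each other's baselines.  Peaks closer than
``min_separation_s`` are merged, keeping the larger one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "CalciumTrace",
    "TransientSet",
    "delta_f_over_f",
    "estimate_noise_sd",
    "detect_transients",
    "transient_frequency",
]


@dataclass
class CalciumTrace:
    """Uniformly sampled fluorescence trace (arbitrary units, F >= 0)."""

    t: np.ndarray
    F: np.ndarray
    roi_id: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if len(self.t) != len(self.F):
            raise ValueError("t and F must have equal length")
        if len(self.t) < 10:
            raise ValueError("trace too short (need >= 10 samples)")
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            raise ValueError("time must be strictly increasing")
        if np.ptp(dts) > 1e-6 * dts.mean():
            raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0] + self.dt)


@dataclass
class TransientSet:
    """Detected transients of one trace."""

    peak_times: np.ndarray
    peak_amplitudes: np.ndarray  # ΔF/F₀ units
    frequency: float  # events/min

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")


def delta_f_over_f(
    trace: CalciumTrace,
    baseline_method: str = "global_percentile",
    p: float = 20.0,
    window_s: float = 30.0,
) -> np.ndarray:
    """(F - F₀)/F₀ with F₀ the ``p``-th percentile of F.

    ``global_percentile`` uses one scalar F₀; ``percentile_rolling`` a running
    percentile over ``window_s`` (robust to slow drift).
    """
    F = trace.F
    if np.any(F < 0):
        raise ValueError("fluorescence must be non-negative")
    if baseline_method == "global_percentile":
        f0 = np.percentile(F, p)
        f0 = np.full_like(F, f0)
    elif baseline_method == "percentile_rolling":
        w = max(3, int(round(window_s / trace.dt)) | 1)
        f0 = ndimage.percentile_filter(F, p, size=w, mode="nearest")
    else:
        raise ValueError(f"unknown baseline_method {baseline_method!r}")
    if np.any(f0 <= 0):
        raise ValueError("baseline estimate is non-positive")
    return (F - f0) / f0


def estimate_noise_sd(dff: np.ndarray, detrend_window_s: float = 10.0, dt: float = 1.0) -> float:
    """Robust noise sd: 1.4826 · MAD of the median-detrended series."""
    dff = np.asarray(dff, dtype=float)
    w = max(3, int(round(detrend_window_s / dt)) | 1)
    resid = dff - ndimage.median_filter(dff, size=w, mode="nearest")
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))))


def _matched_score(resid: np.ndarray, dt: float, tau_s: float) -> np.ndarray:
    """Correlate with a causal exponential template, normalised so a clean
    transient of amplitude A scores A at its onset sample."""
    L = max(2, int(round(5.0 * tau_s / dt)))
    kernel = np.exp(-np.arange(L) * dt / tau_s)
    score = np.convolve(resid, kernel[::-1], mode="full")[L - 1 : L - 1 + len(resid)]
    return score / (kernel**2).sum()


def detect_transients(
    dff: np.ndarray,
    dt: float,
    min_amp: float | None = None,
    min_amp_sd: float = 3.0,
    min_amp_floor: float = 0.01,
    min_separation_s: float = 2.0,
    tau_s: float = 2.0,
    detrend_window_s: float = 20.0,
    prominence_frac: float = 0.4,
    n_refine: int = 2,
) -> TransientSet:
    """Detect transients in a ΔF/F₀ series by matched-template filtering.

    The residual after a running-percentile detrend is correlated with a
    causal exponential-decay template of time constant ``tau_s`` (the
    indicator's decay time); pooling the whole decay instead of the single
    peak sample gives the ~2x SNR gain that makes near-threshold events
    detectable.  Local maxima of the score above ``min_amp`` (with prominence
    at least ``prominence_frac`` of it, suppressing shoulder echoes on decay
    tails) are events.  Detected templates are then peeled off and the
    baseline re-estimated from the cleaned trace (``n_refine`` rounds), which
    undoes the downward bias that neighbouring transients exert on a purely
    rolling baseline.

    ``min_amp`` defaults to ``min_amp_sd`` (3) times the robust noise sd
    (1.4826 x MAD of the first-differenced series / sqrt(2) — the difference
    trace is insensitive to slowly decaying transients), floored at
    ``min_amp_floor`` ΔF/F₀.  Events within ``min_separation_s`` collapse to
    the larger one.  Reported times point at transient onsets; amplitudes are
    matched-filter estimates in ΔF/F₀ units.
    """
    dff = np.asarray(dff, dtype=float)
    n = len(dff)
    tgrid = np.arange(n) * dt
    w = max(3, int(round(detrend_window_s / dt)) | 1)
    d1 = np.diff(dff)
    noise_sd = float(1.4826 * np.median(np.abs(d1 - np.median(d1))) / math.sqrt(2.0))
    if min_amp is None:
        min_amp = max(min_amp_sd * noise_sd, min_amp_floor)
    distance = max(1, int(round(min_separation_s / dt)))
    peak_kwargs = dict(height=min_amp, distance=distance, prominence=prominence_frac * min_amp)

    base = ndimage.percentile_filter(dff, 20, size=w, mode="nearest")
    resid = dff - base
    resid -= np.median(resid)
    peaks = np.empty(0, dtype=int)
    for _ in range(max(1, n_refine)):
        score = _matched_score(resid, dt, tau_s)
        peaks, _ = signal.find_peaks(score, **peak_kwargs)
        model = np.zeros(n)
        for pk in peaks:
            model[pk:] += max(score[pk], 0.0) * np.exp(-(tgrid[pk:] - tgrid[pk]) / tau_s)
        cleaned = dff - model
        base = ndimage.median_filter(cleaned, size=w, mode="nearest")
        resid = dff - base
        resid -= np.median(cleaned - base)
    score = _matched_score(resid, dt, tau_s)
    peaks, _ = signal.find_peaks(score, **peak_kwargs)
    duration = n * dt
    return TransientSet(
        peak_times=peaks * dt,
        peak_amplitudes=score[peaks],
        frequency=60.0 * len(peaks) / duration,
    )


def transient_frequency(ts: TransientSet, duration_s: float) -> float:
    """Transient rate in events/min: 60 · count / duration."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return 60.0 * len(ts.peak_times) / duration_s
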