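"""Automated sigma-band spindle detectors, run with their published defaults.

Five classic single-channel detectors, each a fixed-parameter transform from
a 100 Hz broad-band EEG trace to an event list:

- ``envelope_threshold`` — Hilbert envelope of the 11-15 Hz signal, seeds at
  8x the record-mean envelope extended down to 2x the mean.
- ``rms_std`` — RMS of the 11.3-15.7 Hz signal in 100 ms windows (50 ms
  step), thresholded at 1.5x the standard deviation of the RMS series.
- ``rms_percentile`` — RMS of the 11-15 Hz signal in contiguous 25 ms
  windows, thresholded at the record's 95th percentile.
- ``wavelet`` — squared magnitude of a 13 Hz complex Morlet transform,
  0.1 s moving average, thresholded at 4.5x its record mean.
- ``a7`` — four features per 0.3 s window (0.1 s step): absolute sigma
  power, relative sigma power, sigma/broad-band covariance and correlation;
  a window is spindle-positive when all four exceed their thresholds
  (1.25 uV^2 on the log10 scale, 1.6 x STD, 1.3 x STD, 0.69).

Sigma-band filtering inside the detectors uses a gentler 4th-order
zero-phase Butterworth (configurable): the steep 10th-order conditioning
filter rings far beyond short bursts and would smear strong spindles into
over-long events. Baseline statistics (means, STDs, percentiles) are taken
over the full artifact-free record; a7 additionally z-scores two features against a 30 s
centred rolling baseline. Emitted events are clipped to a configurable
duration range (default 0.3-3.0 s) and never overlap.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .preprocess import Signal, bandpass_filter

__all__ = [
    "DetectorParams", "detect_envelope_threshold", "detect_rms_std",
    "detect_rms_percentile", "detect_wavelet", "detect_a7", "DETECTORS",
]

Interval = tuple[float, float]


@dataclass(frozen=True)
class DetectorParams:
    """Duration bounds shared by all detectors (their papers state none;
    a bound is needed to suppress degenerate events)."""

    min_duration_s: float = 0.3
    max_duration_s: float = 3.0

    def __post_init__(self):
        if not (0 < self.min_duration_s < self.max_duration_s):
            raise ValueError("need 0 < min_duration_s < max_duration_s")


def _duration_filter(intervals: list[Interval], params: DetectorParams) -> list[Interval]:
    return [(on, du) for on, du in intervals
            if params.min_duration_s - 1e-9 <= du <= params.max_duration_s + 1e-9]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as half-open index pairs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_overlaps(intervals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for on, du in sorted(intervals):
        if out and on <= out[-1][0] + out[-1][1]:
            p_on, p_du = out[-1]
            out[-1] = (p_on, max(p_on + p_du, on + du) - p_on)
        else:
            out.append((on, du))
    return out


def _warn_short(sig: Signal, minimum_s: float = 30.0) -> None:
    if sig.duration < minimum_s:
        warnings.warn(f"record of {sig.duration:.1f} s is shorter than "
                      f"{minimum_s:g} s; record-level baseline statistics "
                      f"may be unstable")


def detect_envelope_threshold(sig: Signal, band: tuple[float, float] = (11.0, 15.0),
                              upper_factor: float = 8.0, lower_factor: float = 2.0,
                              envelope: str = "analytic", filter_order: int = 4,
                              params: DetectorParams = DetectorParams()
                              ) -> list[Interval]:
    """Dual-threshold envelope detector.

    Seeds are samples where the sigma envelope exceeds ``upper_factor`` times
    its record mean; each seed is extended bidirectionally while the envelope
    stays at or above ``lower_factor`` times the mean. ``envelope`` is the
    magnitude of the analytic signal by default, or ``"rectified"`` for a
    rectified-and-smoothed (0.1 s moving average) variant.
    """
    _warn_short(sig)
    x = bandpass_filter(sig, *band, order=filter_order).samples
    if envelope == "analytic":
        env = np.abs(sps.hilbert(x))
    elif envelope == "rectified":
        env = uniform_filter1d(np.abs(x), size=max(int(round(0.1 * sig.fs)), 1))
    else:
        raise ValueError(f"unknown envelope mode {envelope!r}")
    mean = float(env.mean())
    if mean == 0.0:
        return []
    seeds = env > upper_factor * mean
    if not seeds.any():
        return []
    above_lower = env >= lower_factor * mean
    intervals = []
    for i0, i1 in _runs(above_lower):
        if seeds[i0:i1].any():
            intervals.append((sig.start_time + i0 / sig.fs, (i1 - i0) / sig.fs))
    return _duration_filter(_merge_overlaps(intervals), params)


def _sliding_rms(x: np.ndarray, fs: float, win_s: float, step_s: float
                 ) -> tuple[np.ndarray, np.ndarray, float]:
    """RMS per window; returns (rms values, window start times, window length s)."""
    win = max(int(round(win_s * fs)), 1)
    step = max(int(round(step_s * fs)), 1)
    starts = np.arange(0, x.size - win + 1, step)
    sq = np.cumsum(np.concatenate([[0.0], x ** 2]))
    rms = np.sqrt((sq[starts + win] - sq[starts]) / win)
    return rms, starts / fs, win / fs


def detect_rms_std(sig: Signal, band: tuple[float, float] = (11.3, 15.7),
                   window_s: float = 0.1, step_s: float = 0.05,
                   std_factor: float = 1.5, threshold_mode: str = "std",
                   filter_order: int = 4,
                   params: DetectorParams = DetectorParams()) -> list[Interval]:
    """Sliding-RMS detector thresholded on the spread of the RMS series.

    ``threshold_mode="std"`` applies the literal threshold 1.5 x STD of the
    record's RMS series; ``"mean_plus_std"`` uses mean + 1.5 x STD instead.
    Events span from the start of the first window in a supra-threshold run
    to the end of the last.
    """
    _warn_short(sig)
    x = bandpass_filter(sig, *band, order=filter_order).samples
    rms, t0, win_len = _sliding_rms(x, sig.fs, window_s, step_s)
    std = float(rms.std())
    if threshold_mode == "std":
        thr = std_factor * std
    elif threshold_mode == "mean_plus_std":
        thr = float(rms.mean()) + std_factor * std
    else:
        raise ValueError(f"unknown threshold mode {threshold_mode!r}")
    if std == 0.0:
        return []
    intervals = [(sig.start_time + t0[i0], t0[i1 - 1] + win_len - t0[i0])
                 for i0, i1 in _runs(rms > thr)]
    return _duration_filter(_merge_overlaps(intervals), params)


def detect_rms_percentile(sig: Signal, band: tuple[float, float] = (11.0, 15.0),
                          window_s: float = 0.025, step_s: float = 0.025,
                          percentile: float = 95.0, filter_order: int = 4,
                          params: DetectorParams = DetectorParams()) -> list[Interval]:
    """Contiguous-window RMS detector thresholded at a record percentile."""
    _warn_short(sig)
    x = bandpass_filter(sig, *band, order=filter_order).samples
    rms, t0, win_len = _sliding_rms(x, sig.fs, window_s, step_s)
    thr = float(np.percentile(rms, percentile))
    intervals = [(sig.start_time + t0[i0], t0[i1 - 1] + win_len - t0[i0])
                 for i0, i1 in _runs(rms > thr)]
    return _duration_filter(_merge_overlaps(intervals), params)


def morlet_power(sig: Signal, center_hz: float = 13.0,
                 half_power_halfwidth_hz: float = 3.0) -> np.ndarray:
    """Squared magnitude of a single-scale complex Morlet transform.

    The Gaussian time width is chosen so the power response falls to half its
    maximum ``half_power_halfwidth_hz`` away from the centre (3 Hz by
    default, i.e. half-power points near 10 and 16 Hz for a 13 Hz centre).
    """
    sigma_t = np.sqrt(np.log(2.0) / (half_power_halfwidth_hz ** 2 * 4 * np.pi ** 2))
    half = int(np.ceil(5 * sigma_t * sig.fs))
    t = np.arange(-half, half + 1) / sig.fs
    kernel = np.exp(2j * np.pi * center_hz * t) * np.exp(-t ** 2 / (2 * sigma_t ** 2))
    kernel /= np.sum(np.abs(kernel))
    w = sps.fftconvolve(sig.samples.astype(complex), kernel, mode="same")
    return np.abs(w) ** 2


def detect_wavelet(sig: Signal, center_hz: float = 13.0,
                   moving_average_s: float = 0.1, mean_factor: float = 4.5,
                   params: DetectorParams = DetectorParams()) -> list[Interval]:
    """Morlet-wavelet power detector: 0.1 s moving average of the squared
    13 Hz Morlet magnitude, thresholded at 4.5x its record mean."""
    _warn_short(sig)
    power = morlet_power(sig, center_hz=center_hz)
    ma = uniform_filter1d(power, size=max(int(round(moving_average_s * sig.fs)), 1))
    mean = float(ma.mean())
    if mean == 0.0:
        return []
    intervals = [(sig.start_time + i0 / sig.fs, (i1 - i0) / sig.fs)
                 for i0, i1 in _runs(ma > mean_factor * mean)]
    return _duration_filter(_merge_overlaps(intervals), params)


def _rolling_zscore(x: np.ndarray, n: int) -> np.ndarray:
    """z-score against a centred rolling baseline of ``n`` points."""
    mean = uniform_filter1d(x, size=n, mode="nearest")
    sq = uniform_filter1d(x ** 2, size=n, mode="nearest")
    var = np.maximum(sq - mean ** 2, 0.0)
    std = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(std > 0, (x - mean) / std, 0.0)
    return z


def detect_a7(sig: Signal, band: tuple[float, float] = (11.0, 16.0),
              window_s: float = 0.3, step_s: float = 0.1,
              abs_power_thresh_uv2: float = 1.25, rel_power_z: float = 1.6,
              covariance_z: float = 1.3, correlation_thresh: float = 0.69,
              baseline_s: float = 30.0, filter_order: int = 4,
              params: DetectorParams = DetectorParams()) -> list[Interval]:
    """The A7 four-feature sigma detector.

    Per 0.3 s window (0.1 s step) over the sigma-filtered (11-16 Hz) and
    broad-band signals:

    1. absolute sigma power, log10 of the window mean square, must exceed
       log10(1.25 uV^2);
    2. relative sigma power (sigma fraction of the window's power),
       log10-transformed and z-scored against a 30 s centred rolling
       baseline, must exceed 1.6;
    3. sigma/broad-band covariance, log10-transformed and z-scored against
       the same baseline, must exceed 1.3;
    4. sigma/broad-band Pearson correlation must exceed 0.69.

    Contiguous spindle-positive windows merge into events.
    """
    if sig.duration < baseline_s:
        raise ValueError(f"record of {sig.duration:.1f} s shorter than the "
                         f"{baseline_s:g} s rolling baseline")
    fs = sig.fs
    broad = sig.samples
    sigma = bandpass_filter(sig, *band, order=filter_order).samples
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    starts = np.arange(0, broad.size - win + 1, step)
    tiny = 1e-12

    def win_view(x):
        return np.lib.stride_tricks.sliding_window_view(x, win)[::step][:starts.size]

    sw, bw = win_view(sigma), win_view(broad)
    ms_sigma = np.mean(sw ** 2, axis=1)
    ms_broad = np.mean(bw ** 2, axis=1)
    abs_feat = np.log10(np.maximum(ms_sigma, tiny))

    rel = ms_sigma / np.maximum(ms_broad, tiny)
    rel_feat = np.log10(np.maximum(rel, tiny))

    s_c = sw - sw.mean(axis=1, keepdims=True)
    b_c = bw - bw.mean(axis=1, keepdims=True)
    cov = np.mean(s_c * b_c, axis=1)
    # signed log10(1+|cov|): monotone, defined for any sign, no outliers from
    # near-zero covariances that would inflate the rolling baseline's spread
    cov_feat = np.sign(cov) * np.log10(1.0 + np.abs(cov))

    denom = np.sqrt(np.mean(s_c ** 2, axis=1) * np.mean(b_c ** 2, axis=1))
    corr = np.divide(cov, denom, out=np.zeros_like(cov), where=denom > tiny)

    n_baseline = max(int(round(baseline_s / step_s)), 1)
    positive = (
        (abs_feat > np.log10(abs_power_thresh_uv2))
        & (_rolling_zscore(rel_feat, n_baseline) > rel_power_z)
        & (_rolling_zscore(cov_feat, n_baseline) > covariance_z)
        & (corr > correlation_thresh)
    )
    intervals = [(sig.start_time + starts[i0] / fs,
                  (starts[i1 - 1] + win - starts[i0]) / fs)
                 for i0, i1 in _runs(positive)]
    return _duration_filter(_merge_overlaps(intervals), params)


#: registry used by the CLI and the evaluation scripts
DETECTORS = {
    "envelope": detect_envelope_threshold,
    "rms_std": detect_rms_std,
    "rms_percentile": detect_rms_percentile,
    "wavelet": detect_wavelet,
    "a7": detect_a7,
}
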