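"""By-subject spindle characterization and group statistics.

Per event: duration, maximum peak-to-peak amplitude of the 11-16 Hz filtered
signal (largest swing between consecutive local extrema), and dominant
oscillation frequency — the arg-max of the FFT magnitude of the 10-16 Hz
filtered event segment with 5 s of zero-padding (frequency resolution
1/(duration + 5) Hz). Per subject: spindle density in spindles per minute
(spm) over the scored block time, and means of the per-event quantities.

Group contrasts (younger vs older, female vs male) use the two-sided
Mann-Whitney test; cross-method agreement uses squared Pearson correlation
of the per-subject vectors.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotations import EpochGrid
from .preprocess import Signal, bandpass_filter

__all__ = [
    "SubjectMetrics", "GroupComparison", "spindle_density", "event_amplitude",
    "event_frequency", "subject_metrics", "characteristic_correlation",
    "compare_groups", "frequency_histogram",
]

AMPLITUDE_BAND = (11.0, 16.0)
FREQUENCY_BAND = (10.0, 16.0)
ZERO_PAD_S = 5.0
FREQ_SEARCH_RANGE = (9.0, 17.0)  # guards the arg-max against filter-skirt leakage
FEATURES = ("density", "duration", "amplitude", "frequency")


@dataclass(frozen=True)
class SubjectMetrics:
    """Per-subject spindle summary. Means are NaN when the subject has no events."""

    subject_id: str
    n_events: int
    scored_minutes: float
    density_spm: float
    mean_duration_s: float
    mean_amplitude_uv: float
    mean_frequency_hz: float

    def feature(self, name: str) -> float:
        return {"density": self.density_spm, "duration": self.mean_duration_s,
                "amplitude": self.mean_amplitude_uv,
                "frequency": self.mean_frequency_hz}[name]


@dataclass(frozen=True)
class GroupComparison:
    """Per-feature medians and two-sided Mann-Whitney p for two groups."""

    group_names: tuple[str, str]
    medians: dict
    p_values: dict

    def stars(self, feature: str) -> str:
        p = self.p_values[feature]
        for thr, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if p <= thr:
                return s
        return ""


def spindle_density(n_events: int, scored_seconds: float) -> float:
    """Spindles per minute over the scored time (115 s per block)."""
    if not scored_seconds > 0:
        raise ValueError("scored time must be positive")
    return n_events / (scored_seconds / 60.0)


def _local_extrema(x: np.ndarray) -> np.ndarray:
    """Values of strict/plateau local extrema, endpoints included."""
    if x.size < 3:
        return x
    d = np.diff(x)
    sign = np.sign(d)
    # carry sign through flats so plateaus count once
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turning = np.flatnonzero(sign[1:] * sign[:-1] < 0) + 1
    idx = np.concatenate([[0], turning, [x.size - 1]])
    return x[idx]


def event_amplitude(signal: Signal, onset_s: float, duration_s: float,
                    band: tuple[float, float] = AMPLITUDE_BAND) -> float:
    """Maximum peak-to-peak amplitude (µV) of the sigma-filtered event.

    Peak-to-peak means the largest absolute difference between consecutive
    local extrema (trough-to-peak or peak-to-trough) inside the event span,
    after 11-16 Hz band-pass of the whole record (filtering the full signal
    avoids edge transients inside short events).
    """
    n_ev = int(round(duration_s * signal.fs))
    if n_ev < 2:
        raise ValueError(f"event of {duration_s} s too short at {signal.fs} Hz")
    filtered = bandpass_filter(signal, *band)
    seg = filtered.segment(onset_s, duration_s).samples
    extrema = _local_extrema(seg)
    if extrema.size < 2:
        return 0.0
    return float(np.max(np.abs(np.diff(extrema))))


def event_frequency(signal: Signal, onset_s: float, duration_s: float,
                    band: tuple[float, float] = FREQUENCY_BAND,
                    zero_pad_s: float = ZERO_PAD_S,
                    energy_floor: float = 1e-12) -> float:
    """Dominant oscillation frequency (Hz) of a spindle event.

    The record is band-passed 10-16 Hz, the event segment is zero-padded by
    5 s, and the frequency of maximum FFT energy within 9-17 Hz is returned.
    NaN if the band-passed segment carries essentially no energy.
    """
    n_ev = int(round(duration_s * signal.fs))
    if n_ev < 2:
        raise ValueError(f"event of {duration_s} s too short at {signal.fs} Hz")
    filtered = bandpass_filter(signal, *band)
    seg = filtered.segment(onset_s, duration_s).samples
    if float(np.mean(seg ** 2)) < energy_floor:
        return math.nan
    padded = np.concatenate([seg, np.zeros(int(round(zero_pad_s * signal.fs)))])
    spectrum = np.abs(np.fft.rfft(padded))
    freqs = np.fft.rfftfreq(padded.size, d=1.0 / signal.fs)
    lo, hi = FREQ_SEARCH_RANGE
    window = (freqs >= lo) & (freqs <= hi)
    k = int(np.argmax(spectrum[window]))
    return float(freqs[window][k])


def subject_metrics(events, signal: Signal, grid: EpochGrid,
                    subject_id: str = "s1") -> SubjectMetrics:
    """Aggregate per-event measures into one per-subject summary."""
    intervals = [(float(e[0]), float(e[1])) if not hasattr(e, "onset_s")
                 else (float(e.onset_s), float(e.duration_s)) for e in events]
    scored_s = grid.total_scored_seconds
    density = spindle_density(len(intervals), scored_s)
    if not intervals:
        return SubjectMetrics(subject_id, 0, scored_s / 60.0, density,
                              math.nan, math.nan, math.nan)
    durations = [d for _, d in intervals]
    amps = [event_amplitude(signal, o, d) for o, d in intervals]
    freqs = [event_frequency(signal, o, d) for o, d in intervals]
    return SubjectMetrics(
        subject_id=subject_id, n_events=len(intervals),
        scored_minutes=scored_s / 60.0, density_spm=density,
        mean_duration_s=float(np.mean(durations)),
        mean_amplitude_uv=float(np.mean(amps)),
        mean_frequency_hz=float(np.nanmean(freqs)),
    )


def characteristic_correlation(metrics_a, metrics_b,
                               features=FEATURES) -> dict:
    """Squared Pearson correlation (r²) per feature between two methods'
    per-subject vectors, with the standard two-sided p-value.

    Subjects are paired by position. Features with zero variance on either
    side are reported as (nan, nan).
    """
    if len(metrics_a) != len(metrics_b):
        raise ValueError("paired per-subject lists must have equal length")
    if len(metrics_a) < 3:
        raise ValueError("need at least 3 paired subjects")
    out = {}
    for feat in features:
        a = np.array([m.feature(feat) for m in metrics_a])
        b = np.array([m.feature(feat) for m in metrics_b])
        if np.std(a) == 0 or np.std(b) == 0:
            out[feat] = (math.nan, math.nan)
            continue
        r, p = stats.pearsonr(a, b)
        out[feat] = (float(r * r), float(p))
    return out


def compare_groups(metrics, labels, group_names=None,
                   features=FEATURES) -> GroupComparison:
    """Two-sided Mann-Whitney comparison of per-subject features between two
    groups (e.g. younger vs older, female vs male)."""
    labels = list(labels)
    if len(labels) != len(metrics):
        raise ValueError("labels must align with metrics")
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    g0 = [m for m, l in zip(metrics, labels) if l == uniq[0]]
    g1 = [m for m, l in zip(metrics, labels) if l == uniq[1]]
    if not g0 or not g1:
        raise ValueError("both groups must be non-empty")
    medians, pvals = {}, {}
    for feat in features:
        a = np.array([m.feature(feat) for m in g0])
        b = np.array([m.feature(feat) for m in g1])
        medians[feat] = (float(np.median(a)), float(np.median(b)))
        pvals[feat] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    names = tuple(group_names) if group_names else (str(uniq[0]), str(uniq[1]))
    return GroupComparison(group_names=names, medians=medians, p_values=pvals)


def frequency_histogram(frequencies, bin_width_hz: float = 0.25,
                        freq_range: tuple[float, float] = (9.0, 17.0)
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Cohort-level histogram of dominant frequencies (default 0.25 Hz bins
    over 9-17 Hz). Returns (counts, bin edges)."""
    lo, hi = freq_range
    edges = np.arange(lo, hi + bin_width_hz / 2, bin_width_hz)
    values = np.asarray([f for f in frequencies if not math.isnan(f)], dtype=float)
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges
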