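"""EEG conditioning: zero-phase band-pass filtering and polyphase resampling.

The study pipeline conditions every recording the same way: a 10th-order
Butterworth band-pass (0.3-30 Hz) applied forward-backward so the phase
response is zero, followed by polyphase resampling to a common 100 Hz rate.
All downstream stages (consensus building, characterization, detection)
assume a 100 Hz broad-band signal.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = ["Signal", "bandpass_filter", "resample_to", "read_signal_csv", "write_signal_csv", "read_signal_edf"]

#: broad-band conditioning band (Hz)
BROADBAND = (0.3, 30.0)
#: common analysis rate (Hz)
ANALYSIS_FS = 100.0
#: total Butterworth order of the band-pass (scipy's N is half of this for a band filter)
FILTER_ORDER = 10


@dataclass(frozen=True)
class Signal:
    """A single-channel EEG trace in microvolts.

    Sample ``i`` covers the half-open time interval
    ``[start_time + i/fs, start_time + (i+1)/fs)``.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1:
            raise ValueError("Signal samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs

    def segment(self, onset_s: float, duration_s: float) -> "Signal":
        """Extract ``[onset_s, onset_s + duration_s)`` (recording coordinates)."""
        i0 = int(round((onset_s - self.start_time) * self.fs))
        i1 = int(round((onset_s + duration_s - self.start_time) * self.fs))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        if i1 <= i0:
            raise ValueError(f"empty segment [{onset_s}, {onset_s + duration_s})")
        return Signal(self.samples[i0:i1], self.fs, self.start_time + i0 / self.fs)


def _design_bandpass(low: float, high: float, fs: float, order: int = FILTER_ORDER) -> np.ndarray:
    if not (0 < low < high):
        raise ValueError(f"band edges must satisfy 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise ValueError(f"high edge {high} Hz at/above Nyquist ({fs / 2} Hz)")
    # zero-pole-gain design converted to second-order sections; N doubles for
    # a band-pass so N = order // 2 yields the stated total order
    return sps.butter(order // 2, [low, high], btype="bandpass", output="sos", fs=fs)


def bandpass_filter(sig: Signal, low: float, high: float, order: int = FILTER_ORDER,
                    padtype: str = "odd", padlen: int | None = None) -> Signal:
    """Zero-phase Butterworth band-pass.

    The filter is designed in zero-pole-gain form, converted to second-order
    sections, and applied forward-backward (``sosfiltfilt``), which squares the
    magnitude response and cancels the phase. Edge effects are controlled by
    odd-reflection padding; the default pad length covers six cycles of the
    low band edge (the slowest transient), capped at the signal length.

    Raises
    ------
    ValueError
        If a band edge is at/above Nyquist or the signal is too short for
        stable forward-backward filtering.
    """
    sos = _design_bandpass(low, high, sig.fs, order=order)
    min_len = 3 * (2 * sos.shape[0] + 1)
    if sig.n_samples <= min_len:
        raise ValueError(
            f"signal of {sig.n_samples} samples too short for forward-backward "
            f"filtering (needs > {min_len})"
        )
    if padlen is None:
        padlen = max(min_len, int(np.ceil(6 * sig.fs / low)))
    padlen = min(padlen, sig.n_samples - 1)
    out = sps.sosfiltfilt(sos, sig.samples, padtype=padtype, padlen=padlen)
    return replace(sig, samples=np.ascontiguousarray(out))


def bandpass_frequency_response(low: float, high: float, fs: float,
                                freqs: np.ndarray, order: int = FILTER_ORDER) -> np.ndarray:
    """Magnitude response of the zero-phase filter at ``freqs`` (Hz).

    Forward-backward application squares the single-pass magnitude.
    """
    sos = _design_bandpass(low, high, fs, order=order)
    _, h = sps.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    return np.abs(h) ** 2


def resample_to(sig: Signal, target_fs: float, max_denominator: int = 1000) -> Signal:
    """Polyphase resampling to ``target_fs``.

    The rational conversion factor is the exact rate ratio reduced to lowest
    terms; the polyphase anti-alias filter cuts off at the lower of the two
    Nyquist frequencies (scipy's ``resample_poly`` default).
    """
    if not target_fs > 0:
        raise ValueError(f"target rate must be positive, got {target_fs}")
    if target_fs == sig.fs:
        return sig
    ratio = Fraction(target_fs / sig.fs).limit_denominator(max_denominator)
    out = sps.resample_poly(sig.samples, ratio.numerator, ratio.denominator)
    return Signal(out, fs=sig.fs * ratio.numerator / ratio.denominator,
                  start_time=sig.start_time)


def condition(sig: Signal, band: tuple[float, float] = BROADBAND,
              target_fs: float = ANALYSIS_FS) -> Signal:
    """Standard conditioning: broad-band filter then resample to 100 Hz."""
    out = bandpass_filter(sig, *band)
    return resample_to(out, target_fs)


def read_signal_csv(path) -> Signal:
    """Read a plain sampled-signal file: header line ``fs=<Hz>``, one value per line."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("fs="):
            raise ValueError(f"{path}: first line must be 'fs=<Hz>', got {header!r}")
        fs = float(header[3:])
        samples = np.loadtxt(fh, dtype=float, ndmin=1)
    return Signal(samples, fs=fs)


def write_signal_csv(path, sig: Signal) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"fs={sig.fs:g}\n")
        np.savetxt(fh, sig.samples, fmt="%.6f")


def read_signal_edf(path, channel: str = "C3") -> Signal:
    """Read one channel from an EDF recording (requires ``mne``)."""
    import mne  # deferred: EDF support is optional

    raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
    data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> microvolts
    return Signal(data, fs=float(raw.info["sfreq"]))
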