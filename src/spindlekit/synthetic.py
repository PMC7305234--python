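"""Synthetic EEG with ground-truth spindles, and simulated scorer panels.

The EEG generator emulates the statistical shape the pipeline assumes:
115 s blocks of artifact-free N2-like background (1/f^alpha noise) with
Hann-enveloped constant-frequency sigma bursts injected at a controlled
density. The ground-truth event list is returned alongside the trace, so
consensus building, evaluation, characterization and the detectors can all
be checked against known parameters.

The scorer simulator emulates imperfect human markings: each scorer detects
each true event with an amplitude-dependent probability, jitters the
boundaries, rates confidence by the event's amplitude tertile, and adds
Poisson false positives. All randomness flows from a single seed through
independent sub-streams.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .annotations import (AnnotationSet, ConfidenceLevel, EpochGrid, ScoredEvent,
                          ScorerRecord, build_epoch_grid, BLOCK_LENGTH_S)
from .preprocess import Signal

__all__ = ["EEGSimConfig", "ScorerSimConfig", "TruthEvent", "simulate_eeg",
           "simulate_panel", "HIGH_SNR_EEG"]


@dataclass(frozen=True)
class TruthEvent:
    """An injected spindle: where it is and what was injected."""

    onset_s: float
    duration_s: float
    frequency_hz: float
    amplitude_uv: float  # peak-to-peak at the envelope maximum

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class EEGSimConfig:
    """Study-shaped synthetic EEG: N2-like background plus sigma bursts.

    Defaults mirror the sampling design and the cohort's spindle statistics:
    115 s blocks at 100 Hz, ~3 spindles per minute of 0.5-1.5 s at 11-16 Hz
    with 20-50 uV peak-to-peak on a 15 uV-rms 1/f background.
    """

    n_blocks: int = 3
    block_length_s: float = BLOCK_LENGTH_S
    fs: float = 100.0
    background_alpha: float = 1.0
    background_rms_uv: float = 15.0
    density_spm: float = 3.0
    duration_range_s: tuple[float, float] = (0.5, 1.5)
    frequency_range_hz: tuple[float, float] = (11.0, 16.0)
    amplitude_range_uv: tuple[float, float] = (20.0, 50.0)
    min_gap_s: float = 0.5       # dead time between consecutive events
    edge_margin_s: float = 1.0   # keep events clear of block edges
    chirp_hz_per_s: float = 0.0  # optional linear frequency drift within a burst

    def __post_init__(self):
        if self.n_blocks < 0 or self.density_spm < 0:
            raise ValueError("n_blocks and density must be non-negative")
        lo, hi = self.duration_range_s
        if not (0 < lo <= hi):
            raise ValueError("invalid duration range")
        # mean inter-event spacing must accommodate the dead time
        if self.density_spm * (hi + self.min_gap_s) > 60.0:
            raise ValueError(
                f"density {self.density_spm} spm incompatible with "
                f"{self.min_gap_s} s dead time at durations up to {hi} s")


#: a deliberately easy regime for detector sanity checks: strong bursts in
#: the middle of the sigma band, quiet background (not a claim about real N2
#: sleep; mid-band frequencies keep the bursts inside every detector's
#: published pass-band)
HIGH_SNR_EEG = EEGSimConfig(background_rms_uv=8.0, amplitude_range_uv=(60.0, 90.0),
                            density_spm=2.0, frequency_range_hz=(11.5, 14.5))


def _pink_noise(n: int, fs: float, alpha: float, rms: float,
                rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha Gaussian noise, band-limited to 0.3 Hz - Nyquist, unit-free rms."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    nz = freqs >= 0.3
    gain[nz] = freqs[nz] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * gain, n=n)
    return x * (rms / np.sqrt(np.mean(x ** 2)))


def _place_events(config: EEGSimConfig, rng: np.random.Generator) -> list[TruthEvent]:
    events: list[TruthEvent] = []
    lo_d, hi_d = config.duration_range_s
    for b in range(config.n_blocks):
        b0 = b * config.block_length_s
        n = rng.poisson(config.density_spm * config.block_length_s / 60.0)
        onsets = np.sort(rng.uniform(config.edge_margin_s,
                                     config.block_length_s - hi_d - config.edge_margin_s,
                                     size=n))
        last_end = -np.inf
        for on in onsets:
            dur = rng.uniform(lo_d, hi_d)
            if on < last_end + config.min_gap_s:  # thinning keeps the dead time
                continue
            freq = rng.uniform(*config.frequency_range_hz)
            amp = rng.uniform(*config.amplitude_range_uv)
            events.append(TruthEvent(b0 + on, dur, freq, amp))
            last_end = on + dur
    return events


def simulate_eeg(config: EEGSimConfig = EEGSimConfig(), seed: int | None = None
                 ) -> tuple[Signal, list[TruthEvent], EpochGrid]:
    """Generate (signal, ground-truth events, epoch grid) from a single seed.

    Bursts are Hann-enveloped sinusoids: the recorded amplitude is the
    peak-to-peak value at the envelope maximum, the recorded frequency the
    (constant, unless ``chirp_hz_per_s`` is set) oscillation frequency.
    """
    ss = np.random.SeedSequence(seed)
    bg_rng, ev_rng, ph_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
    n = int(round(config.n_blocks * config.block_length_s * config.fs))
    samples = _pink_noise(n, config.fs, config.background_alpha,
                          config.background_rms_uv, bg_rng) if n else np.zeros(0)
    events = _place_events(config, ev_rng)
    for ev in events:
        i0 = int(round(ev.onset_s * config.fs))
        i1 = int(round(ev.end_s * config.fs))
        t = np.arange(i1 - i0) / config.fs
        phase = ph_rng.uniform(0, 2 * np.pi)
        inst_freq = ev.frequency_hz + config.chirp_hz_per_s * (t - t[-1] / 2)
        carrier = np.sin(2 * np.pi * np.cumsum(inst_freq) / config.fs + phase)
        samples[i0:i1] += (ev.amplitude_uv / 2.0) * np.hanning(i1 - i0) * carrier
    grid = build_epoch_grid([b * config.block_length_s
                             for b in range(config.n_blocks)], fs=config.fs)
    return Signal(samples, fs=config.fs), events, grid


@dataclass(frozen=True)
class ScorerSimConfig:
    """One simulated scorer's behaviour.

    Detection probability is ``sensitivity x logistic((amp - midpoint)/scale)``;
    with the default midpoint/scale the logistic saturates and the probability
    is effectively ``sensitivity`` for any realistic amplitude. Confidence is
    the event's amplitude tertile within the recording (top third = high),
    optionally perturbed one level with probability ``confidence_noise``.
    """

    subtype: str = "expert"
    sensitivity: float = 0.95
    amp_midpoint_uv: float = 0.0
    amp_scale_uv: float = 2.0
    jitter_sd_s: float = 0.05
    fp_rate_per_min: float = 0.5
    fp_duration_range_s: tuple[float, float] = (0.3, 1.0)
    confidence_noise: float = 0.0
    view_fraction: float = 1.0
    min_marked_duration_s: float = 0.3

    def __post_init__(self):
        if not (0 <= self.sensitivity <= 1):
            raise ValueError("sensitivity must be in [0, 1]")
        if self.jitter_sd_s < 0 or self.fp_rate_per_min < 0:
            raise ValueError("jitter sd and fp rate must be non-negative")
        if not (0 < self.view_fraction <= 1):
            raise ValueError("view fraction must be in (0, 1]")


_CONF_ORDER = (ConfidenceLevel.LOW, ConfidenceLevel.MEDIUM, ConfidenceLevel.HIGH)


def _amplitude_tertiles(truth: list[TruthEvent]) -> np.ndarray:
    amps = np.array([e.amplitude_uv for e in truth])
    if amps.size == 0:
        return np.zeros(0, dtype=int)
    t1, t2 = np.quantile(amps, [1 / 3, 2 / 3])
    return np.digitize(amps, [t1, t2])  # 0 = low tertile, 2 = top


def _containing_epoch(grid: EpochGrid, onset: float, duration: float,
                      viewed: frozenset[str]) -> str | None:
    for ep in grid.epochs:
        if ep.epoch_id in viewed and ep.contains(onset, duration):
            return ep.epoch_id
    return None


def simulate_panel(truth: list[TruthEvent], grid: EpochGrid, n_scorers: int = 10,
                   config: ScorerSimConfig = ScorerSimConfig(),
                   configs: list[ScorerSimConfig] | None = None,
                   seed: int | None = None, subject_id: str = "sim01"
                   ) -> AnnotationSet:
    """Simulate a panel of imperfect scorers marking the ground truth.

    ``configs`` gives one config per scorer; otherwise ``config`` is shared.
    """
    if configs is None:
        configs = [config] * n_scorers
    if len(configs) < 1:
        raise ValueError("need at least one scorer")
    tertile = _amplitude_tertiles(truth)
    ss = np.random.SeedSequence(seed)
    records = []
    for k, (cfg, sub_ss) in enumerate(zip(configs, ss.spawn(len(configs)))):
        rng = np.random.default_rng(sub_ss)
        prefix = {"expert": "exp", "researcher": "res", "nonexpert": "ne"}[cfg.subtype]
        scorer_id = f"{prefix}{k:02d}"

        if cfg.view_fraction >= 1.0:
            viewed = frozenset(grid.epoch_ids)
        else:
            mask = rng.uniform(size=len(grid.epoch_ids)) < cfg.view_fraction
            viewed = frozenset(ep for ep, m in zip(grid.epoch_ids, mask) if m)

        marks: list[tuple[float, float, ConfidenceLevel]] = []
        for ev, tert in zip(truth, tertile):
            p = cfg.sensitivity * expit((ev.amplitude_uv - cfg.amp_midpoint_uv)
                                        / cfg.amp_scale_uv)
            if rng.uniform() >= p:
                continue
            on = ev.onset_s + rng.normal(0, cfg.jitter_sd_s)
            end = ev.end_s + rng.normal(0, cfg.jitter_sd_s)
            dur = max(end - on, cfg.min_marked_duration_s)
            level = int(tert)
            if cfg.confidence_noise > 0 and rng.uniform() < cfg.confidence_noise:
                level = int(np.clip(level + rng.choice([-1, 1]), 0, 2))
            marks.append((on, dur, _CONF_ORDER[level]))

        # Poisson false positives over the viewed block time
        minutes = grid.total_scored_seconds / 60.0 * (len(viewed) / max(len(grid.epoch_ids), 1))
        for _ in range(rng.poisson(cfg.fp_rate_per_min * minutes)):
            dur = rng.uniform(*cfg.fp_duration_range_s)
            block = int(rng.integers(grid.n_blocks))
            b0 = grid.block_starts[block]
            on = b0 + rng.uniform(0, BLOCK_LENGTH_S - dur)
            marks.append((on, dur, ConfidenceLevel.LOW))

        # keep each scorer's marks disjoint (matcher invariant): first wins
        marks.sort(key=lambda m: m[0])
        events: list[ScoredEvent] = []
        last_end = -np.inf
        for on, dur, conf in marks:
            if on < last_end:
                continue
            ep_id = _containing_epoch(grid, on, dur, viewed)
            if ep_id is None:
                continue
            events.append(ScoredEvent(on, dur, conf, ep_id))
            last_end = on + dur
        records.append(ScorerRecord(scorer_id=scorer_id, subtype=cfg.subtype,
                                    viewed_epochs=viewed, events=events))
    return AnnotationSet(subject_id=subject_id, grid=grid, records=records)
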