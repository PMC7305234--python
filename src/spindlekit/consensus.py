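"""Confidence-weighted group-consensus spindle events from scorer panels.

Each scorer's markings are rasterized to a per-sample weight track at 100 Hz
(high = 1, medium = 0.75, low = 0.5, unmarked = 0; where two overlapping
epochs cover the same instant, the scorer's highest score wins). Tracks are
averaged sample-by-sample over the scorers who actually viewed each sample,
and maximal runs of mean score strictly above the group-consensus threshold
(GCt) become candidate spindles. Candidates are then cleaned: short adjacent
candidates (< 0.1 s apart, at least one member < 0.3 s) are merged, and
events shorter than 0.3 s or longer than 2.5 s are dropped.

The consensus of the expert panel is the gold standard (GS).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationSet, EpochGrid, ScorerRecord

__all__ = [
    "ConsensusConfig", "ScoreTrack", "ConsensusEvent", "ConsensusEvents",
    "rasterize_scorer", "average_scores", "threshold_and_clean",
    "build_group_consensus", "leave_one_out_consensus",
]


@dataclass(frozen=True)
class ConsensusConfig:
    """Thresholding and cleanup parameters of the consensus pipeline."""

    gct: float = 0.2            # group-consensus threshold, strict >
    merge_gap_s: float = 0.1    # adjacent candidates closer than this may merge
    min_duration_s: float = 0.3
    max_duration_s: float = 2.5

    def __post_init__(self):
        if not (0.0 <= self.gct < 1.0):
            raise ValueError(f"gct must be in [0, 1), got {self.gct}")
        if not (0 < self.min_duration_s < self.max_duration_s):
            raise ValueError("need 0 < min_duration_s < max_duration_s")


@dataclass(frozen=True)
class ScoreTrack:
    """Per-sample mean weighted score with per-sample viewer counts."""

    scores: np.ndarray        # mean weighted score in [0, 1]; 0 where unviewed
    viewer_counts: np.ndarray
    fs: float

    def __post_init__(self):
        s, c = np.asarray(self.scores), np.asarray(self.viewer_counts)
        if s.shape != c.shape:
            raise ValueError("scores and viewer_counts must align")
        if s.size and (s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValueError("scores must lie in [0, 1]")
        if np.any(s[c == 0] != 0):
            raise ValueError("score must be 0 wherever viewer count is 0")


@dataclass(frozen=True)
class ConsensusEvent:
    onset_s: float
    duration_s: float
    peak_score: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class ConsensusEvents:
    """Cleaned consensus event list with provenance (panel subtype + GCt)."""

    events: tuple[ConsensusEvent, ...]
    subtype: str | None = None
    gct: float | None = None
    n_scorers: int | None = None

    @property
    def is_gold_standard(self) -> bool:
        return self.subtype == "expert"

    def intervals(self) -> list[tuple[float, float]]:
        return [(e.onset_s, e.duration_s) for e in self.events]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def _sample_range(onset_s: float, duration_s: float, fs: float) -> tuple[int, int]:
    # round-half-even on both edges: [round(onset*fs), round(end*fs))
    return int(round(onset_s * fs)), int(round((onset_s + duration_s) * fs))


def rasterize_scorer(record: ScorerRecord, grid: EpochGrid,
                     epoch_subset: frozenset[str] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one scorer to (weight track, viewed mask) at the grid rate.

    Sample weight is the maximum confidence weight over the scorer's markings
    covering that sample — the epoch-overlap rule: an instant shown on two
    consecutive epochs keeps the scorer's highest score. ``epoch_subset``
    optionally restricts which of the scorer's viewed epochs count (used by
    the partial-consensus experiment).
    """
    n = grid.n_samples
    weights = np.zeros(n)
    viewed = np.zeros(n, dtype=bool)
    epochs = record.viewed_epochs if epoch_subset is None \
        else record.viewed_epochs & epoch_subset
    for ep_id in epochs:
        ep = grid.epoch(ep_id)
        i0, i1 = _sample_range(ep.start_s, ep.length_s, grid.fs)
        viewed[i0:i1] = True
    for ev in record.events:
        if ev.epoch_id is not None and ev.epoch_id not in epochs:
            continue
        i0, i1 = _sample_range(ev.onset_s, ev.duration_s, grid.fs)
        i0, i1 = max(i0, 0), min(i1, n)
        w = ev.confidence.weight
        np.maximum(weights[i0:i1], w, out=weights[i0:i1])
    weights[~viewed] = 0.0
    return weights, viewed


def average_scores(tracks: list[tuple[np.ndarray, np.ndarray]],
                   fs: float) -> ScoreTrack:
    """Average per-scorer weight tracks over the scorers viewing each sample.

    The denominator at a sample is the number of viewers of that sample, not
    the panel size: a scorer who never saw an epoch neither adds weight nor
    dilutes the average there. Samples nobody viewed get score 0, count 0.
    """
    if not tracks:
        raise ValueError("need at least one scorer track")
    weight_sum = np.sum([w for w, _ in tracks], axis=0)
    counts = np.sum([v for _, v in tracks], axis=0).astype(int)
    scores = np.divide(weight_sum, counts, out=np.zeros_like(weight_sum),
                       where=counts > 0)
    return ScoreTrack(scores=scores, viewer_counts=counts, fs=fs)


def _runs_above(scores: np.ndarray, gct: float) -> list[tuple[int, int]]:
    """Maximal runs of samples with score strictly greater than gct."""
    above = scores > gct
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(run_starts.tolist(), run_ends.tolist()))


def threshold_and_clean(track: ScoreTrack, config: ConsensusConfig) -> ConsensusEvents:
    """Threshold a score track at the GCt, then merge and duration-filter.

    Cleanup order follows the pipeline definition: first merge adjacent
    candidates closer than ``merge_gap_s`` where at least one member is
    shorter than ``min_duration_s`` (repeated to fixpoint), then drop events
    outside [min_duration_s, max_duration_s].
    """
    fs = track.fs
    cand = [(i0 / fs, i1 / fs, float(track.scores[i0:i1].max()))
            for i0, i1 in _runs_above(track.scores, config.gct)]

    # merge pass to fixpoint
    changed = True
    while changed:
        changed = False
        out = []
        for c in cand:
            if out:
                a, b = out[-1], c
                gap = b[0] - a[1]
                short = (a[1] - a[0] < config.min_duration_s
                         or b[1] - b[0] < config.min_duration_s)
                if gap < config.merge_gap_s and short:
                    out[-1] = (a[0], b[1], max(a[2], b[2]))
                    changed = True
                    continue
            out.append(c)
        cand = out

    events = tuple(
        ConsensusEvent(onset_s=a, duration_s=b - a, peak_score=p)
        for a, b, p in cand
        if config.min_duration_s - 1e-9 <= b - a <= config.max_duration_s + 1e-9
    )
    return ConsensusEvents(events=events)


def build_group_consensus(annotations: AnnotationSet,
                          subtype: str | None = "expert",
                          config: ConsensusConfig = ConsensusConfig(),
                          epoch_scorers: dict[str, set[str]] | None = None
                          ) -> ConsensusEvents:
    """Full consensus pipeline: rasterize -> average -> threshold & clean.

    ``subtype`` selects the panel ("expert" yields the gold standard); None
    uses every scorer. ``epoch_scorers`` optionally maps epoch id -> the
    scorer ids whose view of that epoch counts (partial consensus).
    """
    panel = annotations.scorers(subtype)
    if not panel:
        raise ValueError(f"no scorers of subtype {subtype!r} in annotation set")
    grid = annotations.grid
    tracks = []
    for rec in panel:
        subset = None
        if epoch_scorers is not None:
            subset = frozenset(ep for ep, ids in epoch_scorers.items()
                               if rec.scorer_id in ids)
        tracks.append(rasterize_scorer(rec, grid, epoch_subset=subset))
    track = average_scores(tracks, fs=grid.fs)
    events = threshold_and_clean(track, config)
    return ConsensusEvents(events=events.events, subtype=subtype,
                           gct=config.gct, n_scorers=len(panel))


def leave_one_out_consensus(annotations: AnnotationSet, excluded_scorer: str,
                            subtype: str | None = "expert",
                            config: ConsensusConfig = ConsensusConfig()
                            ) -> ConsensusEvents:
    """Consensus with one scorer removed from numerator and denominator.

    Used when scoring an individual against the panel, so their own markings
    cannot inflate their apparent agreement.
    """
    panel = annotations.scorers(subtype)
    ids = [r.scorer_id for r in panel]
    if excluded_scorer not in ids:
        raise KeyError(f"scorer {excluded_scorer!r} not in "
                       f"{subtype or 'full'} panel {ids}")
    if len(panel) < 2:
        raise ValueError("leave-one-out undefined for a single-scorer panel")
    rest = [r for r in panel if r.scorer_id != excluded_scorer]
    grid = annotations.grid
    tracks = [rasterize_scorer(r, grid) for r in rest]
    events = threshold_and_clean(average_scores(tracks, fs=grid.fs), config)
    return ConsensusEvents(events=events.events, subtype=subtype,
                           gct=config.gct, n_scorers=len(rest))
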