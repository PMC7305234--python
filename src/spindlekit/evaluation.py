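"""Event-level scoring: IoU matching, precision/recall/f1, threshold sweeps,
GCt optimization and the scorers-needed experiment.

Spindles are variable-length events, so detections are matched to reference
events by interval intersection-over-union (IoU). Matching is one-to-one and
greedy on the globally greatest IoU: an event can be claimed by at most one
detection; other detections overlapping the same event count as false
positives. The study's default overlap threshold is 0.2.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationSet
from .consensus import (ConsensusConfig, ConsensusEvents, build_group_consensus,
                        leave_one_out_consensus)

__all__ = [
    "EvalConfig", "MatchResult", "iou_overlap", "match_events",
    "precision_recall_f1", "sweep_overlap_threshold", "evaluate_individual",
    "optimize_gct", "scorers_needed_experiment", "default_gct_schedule",
]

Interval = tuple[float, float]  # (onset_s, duration_s)


@dataclass(frozen=True)
class EvalConfig:
    """Matching parameters. Ties in IoU go to the earlier event, then the
    earlier detection."""

    overlap_threshold: float = 0.2

    def __post_init__(self):
        if not (0.0 <= self.overlap_threshold <= 1.0):
            raise ValueError(f"overlap threshold must be in [0, 1], "
                             f"got {self.overlap_threshold}")


@dataclass(frozen=True)
class MatchResult:
    """TP/FP/FN bookkeeping from one matching run."""

    matches: tuple[tuple[int, int, float], ...]  # (event idx, detection idx, IoU)
    fp_detections: tuple[int, ...]
    fn_events: tuple[int, ...]

    @property
    def tp(self) -> int:
        return len(self.matches)

    @property
    def fp(self) -> int:
        return len(self.fp_detections)

    @property
    def fn(self) -> int:
        return len(self.fn_events)

    @property
    def precision(self) -> float:
        return precision_recall_f1(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self) -> float:
        return precision_recall_f1(self.tp, self.fp, self.fn)[1]

    @property
    def f1(self) -> float:
        return precision_recall_f1(self.tp, self.fp, self.fn)[2]


def iou_overlap(event: Interval, detection: Interval) -> float:
    """Intersection over union of two [onset, onset+duration) intervals."""
    (a0, ad), (b0, bd) = event, detection
    if ad <= 0 or bd <= 0:
        raise ValueError("intervals must have positive duration")
    a1, b1 = a0 + ad, b0 + bd
    inter = max(0.0, min(a1, b1) - max(a0, b0))
    if inter == 0.0:
        return 0.0
    union = (a1 - a0) + (b1 - b0) - inter
    return inter / union


def _check_sorted_disjoint(intervals: list[Interval], name: str) -> None:
    for (a0, ad), (b0, bd) in zip(intervals, intervals[1:]):
        if b0 < a0:
            raise ValueError(f"{name} list not sorted by onset")
        if b0 < a0 + ad - 1e-9:
            raise ValueError(f"{name} events [{a0},{a0 + ad}) and [{b0},{b0 + bd}) overlap")


def match_events(events: list[Interval], detections: list[Interval],
                 config: EvalConfig = EvalConfig()) -> MatchResult:
    """Greedy one-to-one matching on globally greatest IoU.

    Repeatedly pick the unmatched (event, detection) pair with the highest
    IoU at or above the overlap threshold (zero-overlap pairs never match),
    record it, and remove both; ties break to the earlier event onset, then
    the earlier detection onset. Leftover detections are FP, leftover events
    FN. Both input lists must be sorted and internally non-overlapping.
    """
    events = [(float(o), float(d)) for o, d in events]
    detections = [(float(o), float(d)) for o, d in detections]
    _check_sorted_disjoint(events, "event")
    _check_sorted_disjoint(detections, "detection")
    thr = config.overlap_threshold

    # candidate pairs with IoU >= threshold (and > 0)
    pairs = []
    for i, ev in enumerate(events):
        for j, det in enumerate(detections):
            if det[0] >= ev[0] + ev[1]:
                break
            if det[0] + det[1] <= ev[0]:
                continue
            iou = iou_overlap(ev, det)
            if iou > 0.0 and iou >= thr:
                pairs.append((i, j, iou))
    # sort by (-iou, event onset, detection onset): greedy pop order
    pairs.sort(key=lambda p: (-p[2], events[p[0]][0], detections[p[1]][0]))

    used_ev: set[int] = set()
    used_det: set[int] = set()
    matches = []
    for i, j, iou in pairs:
        if i in used_ev or j in used_det:
            continue
        matches.append((i, j, iou))
        used_ev.add(i)
        used_det.add(j)
    matches.sort()
    return MatchResult(
        matches=tuple(matches),
        fp_detections=tuple(j for j in range(len(detections)) if j not in used_det),
        fn_events=tuple(i for i in range(len(events)) if i not in used_ev),
    )


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), f1 = harmonic mean.

    Degenerate conventions (so sweep curves stay plottable): precision is 0
    when no detections exist, recall is NaN when there are no reference
    events, and f1 is 0 whenever precision + recall is 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    r = 0.0 if math.isnan(recall) else recall
    f1 = 2 * precision * r / (precision + r) if precision + r > 0 else 0.0
    return precision, recall, f1


def _as_intervals(events) -> list[Interval]:
    if isinstance(events, ConsensusEvents):
        return events.intervals()
    out = []
    for ev in events:
        if hasattr(ev, "onset_s"):
            out.append((float(ev.onset_s), float(ev.duration_s)))
        else:
            out.append((float(ev[0]), float(ev[1])))
    return out


def sweep_overlap_threshold(events, detections, thresholds) -> np.ndarray:
    """f1 at each overlap threshold (ascending); non-increasing by construction."""
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    ev, det = _as_intervals(events), _as_intervals(detections)
    return np.array([match_events(ev, det, EvalConfig(t)).f1 for t in thresholds])


def evaluate_individual(annotations: AnnotationSet, scorer_id: str,
                        subtype: str | None = "expert",
                        consensus_config: ConsensusConfig = ConsensusConfig(),
                        eval_config: EvalConfig = EvalConfig()) -> MatchResult:
    """Score one scorer's markings against the leave-one-out consensus.

    The scorer's events are taken as detections regardless of their
    confidence labels (confidence shapes the consensus, not eventhood).
    """
    reference = leave_one_out_consensus(annotations, scorer_id, subtype,
                                        consensus_config)
    rec = annotations.record(scorer_id)
    detections = sorted(((ev.onset_s, ev.duration_s) for ev in rec.events))
    return match_events(reference.intervals(), _merge_duplicate_marks(detections),
                        eval_config)


def _merge_duplicate_marks(detections: list[Interval]) -> list[Interval]:
    """Union overlapping marks from one scorer (the same spindle marked in two
    overlapping epochs) so the detection list satisfies the matcher invariant."""
    out: list[Interval] = []
    for on, du in detections:
        if out and on < out[-1][0] + out[-1][1]:
            p_on, p_du = out[-1]
            out[-1] = (p_on, max(p_on + p_du, on + du) - p_on)
        else:
            out.append((on, du))
    return out


def optimize_gct(annotations: AnnotationSet, gct_grid,
                 subtype: str | None = "expert",
                 eval_config: EvalConfig = EvalConfig(),
                 consensus_config: ConsensusConfig = ConsensusConfig()
                 ) -> tuple[float, np.ndarray]:
    """Choose the GCt maximizing mean individual f1 against leave-one-out GS.

    Returns (best gct, objective curve over the grid); ties go to the
    smallest grid value. The grid defaults elsewhere to 0.05..0.95 step 0.05.
    """
    gct_grid = [float(g) for g in gct_grid]
    if not gct_grid:
        raise ValueError("empty GCt grid")
    panel = annotations.scorers(subtype)
    if len(panel) < 2:
        raise ValueError("GCt optimization needs at least two scorers")
    curve = []
    for gct in gct_grid:
        cfg = ConsensusConfig(gct=gct, merge_gap_s=consensus_config.merge_gap_s,
                              min_duration_s=consensus_config.min_duration_s,
                              max_duration_s=consensus_config.max_duration_s)
        f1s = [evaluate_individual(annotations, r.scorer_id, subtype, cfg,
                                   eval_config).f1 for r in panel]
        curve.append(float(np.mean(f1s)))
    curve = np.asarray(curve)
    best = gct_grid[int(np.argmax(curve))]  # argmax returns first max: smallest gct
    return best, curve


def default_gct_schedule(n: int, optimum: float = 0.2, n_at_optimum: int = 5) -> float:
    """GCt as a function of panel size: 0.4 for one scorer per epoch, linear
    down (or up) to the subtype optimum at ``n_at_optimum`` scorers, constant
    beyond."""
    if n < 1:
        raise ValueError("panel size must be >= 1")
    if n >= n_at_optimum:
        return optimum
    frac = (n - 1) / (n_at_optimum - 1)
    return 0.4 + frac * (optimum - 0.4)


def scorers_needed_experiment(annotations: AnnotationSet, reference_events,
                              n_list, n_repeats: int = 3,
                              gct_schedule=default_gct_schedule,
                              seed: int | None = None,
                              subtype: str | None = None,
                              eval_config: EvalConfig = EvalConfig(),
                              consensus_config: ConsensusConfig = ConsensusConfig()
                              ) -> dict[int, tuple[float, float]]:
    """Partial-consensus f1 as a function of scorers per epoch.

    For each panel size n: draw (``n_repeats`` times) n scorers per epoch
    uniformly without replacement among that epoch's viewers, build the
    partial group consensus with ``gct_schedule(n)``, and score it against
    ``reference_events``. Returns {n: (mean f1, sd f1)} across draws. Epochs
    with fewer than n viewers fall back to all their viewers; if more than 5%
    of epochs need the fallback a warning is issued.
    """
    rng = np.random.default_rng(seed)
    panel = annotations.scorers(subtype)
    grid = annotations.grid
    viewers_by_epoch = {
        ep: [r.scorer_id for r in panel if ep in r.viewed_epochs]
        for ep in grid.epoch_ids
    }
    reference = _as_intervals(reference_events)
    results: dict[int, tuple[float, float]] = {}
    for n in n_list:
        short_epochs = sum(1 for v in viewers_by_epoch.values() if len(v) < n)
        if short_epochs > 0.05 * len(viewers_by_epoch):
            warnings.warn(
                f"panel size {n}: {short_epochs}/{len(viewers_by_epoch)} epochs "
                f"have fewer viewers; falling back to all viewers there")
        cfg = ConsensusConfig(gct=gct_schedule(n),
                              merge_gap_s=consensus_config.merge_gap_s,
                              min_duration_s=consensus_config.min_duration_s,
                              max_duration_s=consensus_config.max_duration_s)
        f1s = []
        for _ in range(n_repeats):
            selection = {}
            for ep, viewers in viewers_by_epoch.items():
                if len(viewers) <= n:
                    selection[ep] = set(viewers)
                else:
                    chosen = rng.choice(len(viewers), size=n, replace=False)
                    selection[ep] = {viewers[k] for k in chosen}
            partial = build_group_consensus(annotations, subtype, cfg,
                                            epoch_scorers=selection)
            f1s.append(match_events(reference, partial.intervals(),
                                    eval_config).f1)
        results[n] = (float(np.mean(f1s)), float(np.std(f1s)))
    return results
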