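"""Data model and I/O for scorer annotations and the block/epoch sampling grid.

Recordings are sampled as non-overlapping 115 s blocks of artifact-free N2
sleep. Each block is scored in 5 epochs of 25 s that overlap by 2.5 s
(offsets 0, 22.5, 45, 67.5, 90 s within the block), so an instant inside an
overlap zone is seen twice by the same scorer.

All coordinates are seconds from recording start, 0-based, half-open
intervals [onset, onset + duration). Events serialize at millisecond
precision with round-half-even.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfidenceLevel", "ScoredEvent", "Epoch", "EpochGrid", "ScorerRecord",
    "AnnotationSet", "build_epoch_grid", "read_annotations", "write_annotations",
    "read_events", "write_events",
]

BLOCK_LENGTH_S = 115.0
EPOCH_LENGTH_S = 25.0
EPOCH_STRIDE_S = 22.5  # 2.5 s overlap between consecutive epochs
EPOCHS_PER_BLOCK = 5
GRID_FS = 100.0


class ConfidenceLevel(enum.Enum):
    """Scorer confidence that a marked box contains a spindle.

    The numeric weight is the per-sample score contribution: 1 for high,
    0.75 for medium, 0.5 for low; an unmarked sample contributes 0.
    """

    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"

    @property
    def weight(self) -> float:
        return {"high": 1.0, "medium": 0.75, "low": 0.5}[self.value]

    @classmethod
    def parse(cls, label: str) -> "ConfidenceLevel":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise ValueError(f"unknown confidence label {label!r} "
                             f"(expected one of high/medium/low)") from None


@dataclass(frozen=True)
class ScoredEvent:
    """One spindle marking: [onset_s, onset_s + duration_s) with a confidence."""

    onset_s: float
    duration_s: float
    confidence: ConfidenceLevel = ConfidenceLevel.HIGH
    epoch_id: str | None = None

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ValueError(f"event duration must be positive, got {self.duration_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class Epoch:
    epoch_id: str
    start_s: float
    length_s: float = EPOCH_LENGTH_S

    @property
    def end_s(self) -> float:
        return self.start_s + self.length_s

    def contains(self, onset_s: float, duration_s: float) -> bool:
        return self.start_s <= onset_s and onset_s + duration_s <= self.end_s + 1e-9


@dataclass(frozen=True)
class EpochGrid:
    """The 115 s block / 25 s epoch sampling design of a recording."""

    block_starts: tuple[float, ...]
    fs: float = GRID_FS

    @property
    def n_blocks(self) -> int:
        return len(self.block_starts)

    @property
    def epochs(self) -> tuple[Epoch, ...]:
        out = []
        for b, start in enumerate(self.block_starts):
            for e in range(EPOCHS_PER_BLOCK):
                out.append(Epoch(f"b{b}e{e}", start + e * EPOCH_STRIDE_S))
        return tuple(out)

    @property
    def epoch_ids(self) -> tuple[str, ...]:
        return tuple(ep.epoch_id for ep in self.epochs)

    def epoch(self, epoch_id: str) -> Epoch:
        for ep in self.epochs:
            if ep.epoch_id == epoch_id:
                return ep
        raise KeyError(f"epoch {epoch_id!r} not in grid")

    @property
    def total_scored_seconds(self) -> float:
        """Unique signal time covered: 115 s per block."""
        return BLOCK_LENGTH_S * self.n_blocks

    @property
    def end_s(self) -> float:
        return max((s + BLOCK_LENGTH_S for s in self.block_starts), default=0.0)

    @property
    def n_samples(self) -> int:
        return int(round(self.end_s * self.fs))

    def sample_slice(self, start_s: float, end_s: float) -> slice:
        # round-half-even on sample boundaries, matching rasterization
        return slice(int(round(start_s * self.fs)), int(round(end_s * self.fs)))


def build_epoch_grid(block_starts, fs: float = GRID_FS) -> EpochGrid:
    """Build the epoch grid for 115 s blocks starting at ``block_starts`` (s).

    Raises
    ------
    ValueError
        If two blocks overlap (names the colliding pair).
    """
    starts = tuple(sorted(float(s) for s in block_starts))
    for a, b in zip(starts, starts[1:]):
        if b < a + BLOCK_LENGTH_S:
            raise ValueError(f"blocks starting at {a} s and {b} s overlap "
                             f"(blocks are {BLOCK_LENGTH_S:g} s long)")
    return EpochGrid(starts, fs=fs)


@dataclass
class ScorerRecord:
    """One scorer: which epochs they viewed and what they marked there."""

    scorer_id: str
    subtype: str  # expert | researcher | nonexpert
    viewed_epochs: frozenset[str]
    events: list[ScoredEvent] = field(default_factory=list)

    SUBTYPES = ("expert", "researcher", "nonexpert")

    def __post_init__(self):
        if self.subtype not in self.SUBTYPES:
            raise ValueError(f"unknown scorer subtype {self.subtype!r}")
        self.viewed_epochs = frozenset(self.viewed_epochs)


@dataclass
class AnnotationSet:
    """All scorer records for one subject, tied to its epoch grid."""

    subject_id: str
    grid: EpochGrid
    records: list[ScorerRecord]

    def __post_init__(self):
        known = set(self.grid.epoch_ids)
        for rec in self.records:
            bad = rec.viewed_epochs - known
            if bad:
                raise ValueError(f"scorer {rec.scorer_id}: unknown epoch ids {sorted(bad)}")
            for ev in rec.events:
                if ev.epoch_id is not None and ev.epoch_id not in rec.viewed_epochs:
                    raise ValueError(
                        f"scorer {rec.scorer_id}: event at {ev.onset_s} s assigned to "
                        f"unviewed epoch {ev.epoch_id}")

    def scorers(self, subtype: str | None = None) -> list[ScorerRecord]:
        if subtype is None:
            return list(self.records)
        return [r for r in self.records if r.subtype == subtype]

    def record(self, scorer_id: str) -> ScorerRecord:
        for r in self.records:
            if r.scorer_id == scorer_id:
                return r
        raise KeyError(f"no scorer {scorer_id!r} in annotation set")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["subject_id", "scorer_id", "subtype", "epoch_id",
                      "onset_s", "duration_s", "confidence"]
VIEW_COLUMNS = ["scorer_id", "epoch_id"]
EVENT_COLUMNS = ["subject_id", "onset_s", "duration_s", "score"]


def read_annotations(path, views_path, grid: EpochGrid) -> AnnotationSet:
    """Read an annotation TSV plus its companion views TSV.

    The views file is mandatory: a scorer who viewed an epoch and marked
    nothing still contributes weight 0 there, which the event rows alone
    cannot express.
    """
    path, views_path = Path(path), Path(views_path)
    if not views_path.exists():
        raise FileNotFoundError(f"missing views file {views_path} "
                                f"(required companion of {path})")
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    views = pd.read_csv(views_path, sep="\t", dtype=str)
    missing = set(VIEW_COLUMNS) - set(views.columns)
    if missing:
        raise ValueError(f"{views_path}: missing columns {sorted(missing)}")

    viewed: dict[str, set[str]] = {}
    for _, row in views.iterrows():
        viewed.setdefault(str(row.scorer_id), set()).add(str(row.epoch_id))

    subject_ids = set(ann.subject_id.astype(str)) if len(ann) else set()
    if len(subject_ids) > 1:
        raise ValueError(f"{path}: multiple subject ids {sorted(subject_ids)}")
    subject_id = subject_ids.pop() if subject_ids else "unknown"

    events_by_scorer: dict[str, list[ScoredEvent]] = {s: [] for s in viewed}
    subtype_by_scorer: dict[str, str] = {}
    for i, row in ann.iterrows():
        line = i + 2  # 1-based, after header
        scorer = str(row.scorer_id)
        try:
            conf = ConfidenceLevel.parse(row.confidence)
            onset, dur = float(row.onset_s), float(row.duration_s)
        except ValueError as exc:
            raise ValueError(f"{path} line {line}: {exc}") from None
        if scorer not in viewed:
            raise ValueError(f"{path} line {line}: scorer {scorer!r} has no rows "
                             f"in views file {views_path}")
        epoch_id = str(row.epoch_id)
        if epoch_id not in viewed[scorer]:
            raise ValueError(f"{path} line {line}: event epoch {epoch_id!r} "
                             f"not viewed by scorer {scorer!r}")
        try:
            ep = grid.epoch(epoch_id)
        except KeyError as exc:
            raise ValueError(f"{path} line {line}: {exc.args[0]}") from None
        if not ep.contains(onset, dur):
            raise ValueError(
                f"{path} line {line}: event [{onset}, {onset + dur}) s outside its "
                f"epoch {epoch_id} [{ep.start_s}, {ep.end_s}) s")
        prev = subtype_by_scorer.setdefault(scorer, str(row.subtype))
        if prev != str(row.subtype):
            raise ValueError(f"{path} line {line}: scorer {scorer!r} subtype changed "
                             f"from {prev!r} to {row.subtype!r}")
        events_by_scorer[scorer].append(ScoredEvent(onset, dur, conf, epoch_id))

    records = [
        ScorerRecord(scorer_id=s, subtype=subtype_by_scorer.get(s, "expert"),
                     viewed_epochs=frozenset(eps),
                     events=sorted(events_by_scorer.get(s, []), key=lambda e: e.onset_s))
        for s, eps in sorted(viewed.items())
    ]
    return AnnotationSet(subject_id=subject_id, grid=grid, records=records)


def write_annotations(path, views_path, annotations: AnnotationSet) -> None:
    rows = []
    for rec in annotations.records:
        for ev in rec.events:
            rows.append({
                "subject_id": annotations.subject_id, "scorer_id": rec.scorer_id,
                "subtype": rec.subtype, "epoch_id": ev.epoch_id,
                "onset_s": _fmt_s(ev.onset_s), "duration_s": _fmt_s(ev.duration_s),
                "confidence": ev.confidence.value,
            })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)
    vrows = [{"scorer_id": rec.scorer_id, "epoch_id": ep}
             for rec in annotations.records for ep in sorted(rec.viewed_epochs)]
    pd.DataFrame(vrows, columns=VIEW_COLUMNS).to_csv(views_path, sep="\t", index=False)


def _fmt_s(x: float) -> str:
    """Seconds at millisecond precision, round-half-even."""
    return format(np.round(float(x), 3), ".3f")


def write_events(path, events, scores=None, subject_id: str = "s1",
                 bed_path=None, fs: float = GRID_FS) -> None:
    """Write an event list TSV (onset/duration in seconds, 3 decimals).

    ``events`` is a sequence of (onset_s, duration_s) pairs or objects with
    those attributes; ``scores`` an optional parallel sequence. Optionally
    also emits a BED-style export with 0-based half-open sample coordinates.
    """
    pairs = [_as_interval(ev) for ev in events]
    if scores is None:
        scores = [1.0] * len(pairs)
    rows = [{"subject_id": subject_id, "onset_s": _fmt_s(on), "duration_s": _fmt_s(du),
             "score": format(float(sc), ".4f")}
            for (on, du), sc in zip(pairs, scores, strict=True)]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        with Path(bed_path).open("w") as fh:
            for k, ((on, du), sc) in enumerate(zip(pairs, scores)):
                i0 = int(round(on * fs))
                i1 = int(round((on + du) * fs))
                fh.write(f"{subject_id}\t{i0}\t{i1}\tspindle_{k}\t{float(sc):.4f}\n")


def read_events(path) -> tuple[list[tuple[float, float]], list[float]]:
    """Read an event list TSV back: ([(onset_s, duration_s), ...], [score, ...])."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    events = [(float(o), float(d)) for o, d in zip(df.onset_s, df.duration_s)]
    return events, [float(s) for s in df.score]


def _as_interval(ev) -> tuple[float, float]:
    if hasattr(ev, "onset_s"):
        return float(ev.onset_s), float(ev.duration_s)
    on, du = ev[0], ev[1]
    return float(on), float(du)
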