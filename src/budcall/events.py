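"""Post-processing of frame-wise division probabilities into discrete events.

Frame probabilities are thresholded into binary calls, maximal runs of
positive calls are collapsed into single division events (consecutive
positives come from the same bud emergence seen across overlapping
windows), and the number of events over the movie is the cell's predicted
replicative lifespan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "EventTimeline",
    "PostprocessConfig",
    "threshold_probabilities",
    "collapse_runs",
    "replicative_lifespan",
    "timeline_from_probabilities",
    "write_timeline_csv",
    "read_timeline_csv",
]


@dataclass
class EventTimeline:
    """Strictly increasing division frames for one cell; ``rls`` is the count."""

    cell_id: str
    division_frames: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.division_frames = [int(f) for f in self.division_frames]
        if any(f < 0 for f in self.division_frames):
            raise ValidationError("division_frames must be >= 0")
        if any(
            b <= a for a, b in zip(self.division_frames, self.division_frames[1:])
        ):
            raise ValidationError("division_frames must be strictly increasing")

    @property
    def rls(self) -> int:
        return len(self.division_frames)


@dataclass(frozen=True)
class PostprocessConfig:
    probability_threshold: float = 0.5
    merge_gap_frames: int = 0
    event_time_rule: str = "run_start"

    def __post_init__(self):
        if not 0.0 < self.probability_threshold < 1.0:
            raise ValidationError("probability_threshold must be in (0, 1)")
        if self.merge_gap_frames < 0:
            raise ValidationError("merge_gap_frames must be >= 0")
        if self.event_time_rule not in ("run_start", "run_midpoint"):
            raise ValidationError(
                f"event_time_rule must be 'run_start' or 'run_midpoint', "
                f"got {self.event_time_rule!r}"
            )


def threshold_probabilities(probs, threshold: float) -> np.ndarray:
    """Binary calls: 1 where p >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must be in (0, 1)")
    p = np.asarray(probs, dtype=float)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValidationError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(np.int8)


def _runs(calls: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of 1s as (start, end) inclusive."""
    padded = np.concatenate([[0], calls, [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def collapse_runs(calls, config: PostprocessConfig | None = None,
                  cell_id: str = "cell") -> EventTimeline:
    """Collapse runs of positive calls into one event each.

    Runs separated by at most ``merge_gap_frames`` zeros are merged; each
    merged run yields a single event at its start frame (default) or
    midpoint.
    """
    if config is None:
        config = PostprocessConfig()
    calls = np.asarray(calls)
    if calls.size and not np.isin(calls, (0, 1)).all():
        raise ValidationError("calls must be binary (0/1)")
    runs = _runs(calls.astype(np.int8))
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] - 1 <= config.merge_gap_frames:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    if config.event_time_rule == "run_start":
        frames = [start for start, _ in merged]
    else:
        frames = [(start + end) // 2 for start, end in merged]
    return EventTimeline(cell_id, frames)


def replicative_lifespan(timeline: EventTimeline) -> int:
    """Number of division events = predicted replicative lifespan."""
    return timeline.rls


def timeline_from_probabilities(probs, config: PostprocessConfig | None = None,
                                cell_id: str = "cell") -> EventTimeline:
    """Threshold then collapse: the full probability-to-events chain."""
    if config is None:
        config = PostprocessConfig()
    calls = threshold_probabilities(probs, config.probability_threshold)
    return collapse_runs(calls, config, cell_id=cell_id)


def write_timeline_csv(timelines, path) -> None:
    """Same schema as the annotations CSV (cell_id, division_frame) so
    predictions and ground truth are directly comparable."""
    if isinstance(timelines, EventTimeline):
        timelines = [timelines]
    rows = [
        {"cell_id": t.cell_id, "division_frame": f}
        for t in timelines
        for f in t.division_frames
    ]
    pd.DataFrame(rows, columns=["cell_id", "division_frame"]).to_csv(
        path, index=False
    )


def read_timeline_csv(path) -> list[EventTimeline]:
    df = pd.read_csv(path)
    for col in ("cell_id", "division_frame"):
        if col not in df.columns:
            raise SchemaError(f"timeline CSV missing column {col!r}")
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        frames = sorted(int(f) for f in grp["division_frame"])
        out.append(EventTimeline(str(cell_id), frames))
    return out
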