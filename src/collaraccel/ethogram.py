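"""Behaviour vocabulary, label-track operations, and hierarchy collapsing.

The ethogram has 17 fine-scale classes (16 named behaviours plus the
rag-bag "other"). Two coarser vocabularies are derived by fixed collapsing
maps:

* medium — the four sedentary postures (crouch, lie, sit, stand) merge into
  "sedentary"; walking and trotting stalks merge into "moving stalk";
  pounce, too instantaneous to categorise reliably, is folded into "other";
* coarse — locomotory behaviours (the four gaits, moving stalks, pounce)
  become "active", non-locomotory ones except head movement become
  "inactive"; "head movement" and "other" survive as their own classes.

The hierarchy ships as a plain CSV (``fine,medium,coarse``) so other
ethograms can be supplied.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .devicesim import UNASSIGNABLE, AccelTrace, LabelTrack

LEVELS = ("fine", "medium", "coarse")


@dataclass(frozen=True)
class BehaviourHierarchy:
    """Total fine→medium and fine→coarse label maps."""

    medium_map: dict[str, str]
    coarse_map: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.medium_map) != set(self.coarse_map):
            raise ValueError("medium and coarse maps cover different labels")

    @property
    def fine_labels(self) -> tuple[str, ...]:
        return tuple(self.medium_map)

    def vocabulary(self, level: str) -> tuple[str, ...]:
        if level == "fine":
            return self.fine_labels
        m = self.medium_map if level == "medium" else self.coarse_map
        seen: dict[str, None] = {}
        for v in m.values():
            seen.setdefault(v)
        return tuple(seen)

    def map_for(self, level: str) -> dict[str, str]:
        if level == "medium":
            return self.medium_map
        if level == "coarse":
            return self.coarse_map
        raise ValueError(f"no collapsing map for level {level!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BehaviourHierarchy":
        for col in ("fine", "medium", "coarse"):
            if col not in df.columns:
                raise ValueError(f"hierarchy table missing column {col!r}")
        return cls(medium_map=dict(zip(df["fine"], df["medium"])),
                   coarse_map=dict(zip(df["fine"], df["coarse"])))

    @classmethod
    def from_csv(cls, path) -> "BehaviourHierarchy":
        return cls.from_frame(pd.read_csv(path))


def default_hierarchy() -> BehaviourHierarchy:
    """The packaged 17-class ethogram hierarchy."""
    ref = importlib.resources.files("collaraccel.data").joinpath(
        "ethogram_hierarchy.csv")
    with importlib.resources.as_file(ref) as path:
        return BehaviourHierarchy.from_csv(path)


def align_labels(intervals: pd.DataFrame, trace: AccelTrace) -> LabelTrack:
    """Assign each sample the behaviour of its covering interval.

    ``intervals`` has columns start_s, end_s, behaviour with half-open
    coverage [start, end): a sample exactly on a boundary belongs to the
    later interval. Samples covered by no interval become unassignable.
    Overlapping intervals are rejected.
    """
    iv = intervals.sort_values("start_s").reset_index(drop=True)
    starts = iv["start_s"].to_numpy(float)
    ends = iv["end_s"].to_numpy(float)
    if np.any(ends <= starts):
        raise ValueError("intervals must satisfy start < end")
    overlap = np.nonzero(starts[1:] < ends[:-1])[0]
    if overlap.size:
        i = int(overlap[0])
        raise ValueError(
            f"overlapping label intervals: [{starts[i]}, {ends[i]}) and "
            f"[{starts[i + 1]}, {ends[i + 1]})")
    labels = np.full(len(trace), UNASSIGNABLE, dtype=object)
    idx = np.searchsorted(starts, trace.time, side="right") - 1
    valid = idx >= 0
    covered = valid & (trace.time < ends[np.clip(idx, 0, None)])
    labels[covered] = iv["behaviour"].to_numpy(object)[idx[covered]]
    return LabelTrack(labels, level="fine")


def drop_unassignable(dataset: pd.DataFrame,
                      label_col: str = "behaviour"
                      ) -> tuple[pd.DataFrame, int]:
    """Remove rows whose label is the unassignable sentinel.

    Returns the filtered dataset and the number of rows removed (the
    analogue of discarding footage where the animal was obscured).
    """
    mask = dataset[label_col] == UNASSIGNABLE
    removed = int(mask.sum())
    out = dataset.loc[~mask].reset_index(drop=True)
    if out.empty and removed:
        warnings.warn("all rows were unassignable; dataset is empty",
                      stacklevel=2)
    return out, removed


def collapse(labels: LabelTrack, level: str,
             hierarchy: BehaviourHierarchy) -> LabelTrack:
    """Collapse a fine-resolution label track to medium or coarse.

    Collapsing a track already at the requested level is the identity.
    """
    if labels.level == level:
        return LabelTrack(labels.labels.copy(), level=level)
    if labels.level != "fine":
        raise ValueError("collapse expects a fine-resolution track")
    mapping = hierarchy.map_for(level)
    out = np.empty(len(labels), dtype=object)
    for i, lab in enumerate(labels.labels):
        if lab == UNASSIGNABLE:
            out[i] = UNASSIGNABLE
            continue
        try:
            out[i] = mapping[lab]
        except KeyError:
            raise KeyError(f"label {lab!r} absent from {level} map") from None
    return LabelTrack(out, level=level)


def collapse_counts(fine_counts: dict[str, int], level: str,
                    hierarchy: BehaviourHierarchy) -> dict[str, int]:
    """Collapse a fine-label multiset (as counts) to a coarser level."""
    mapping = hierarchy.map_for(level)
    out: dict[str, int] = {}
    for lab, n in fine_counts.items():
        try:
            tgt = mapping[lab]
        except KeyError:
            raise KeyError(f"label {lab!r} absent from {level} map") from None
        out[tgt] = out.get(tgt, 0) + n
    return out


def count_by_label(labels: LabelTrack) -> dict[str, int]:
    """Exact multiset counts of a label track; counts sum to its length."""
    vals, counts = np.unique(np.asarray(labels.labels, dtype=str),
                             return_counts=True)
    return {str(v): int(c) for v, c in zip(vals, counts)}
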