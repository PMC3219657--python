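"""Sliding-window genomic properties and cumulative skew analysis.

Nucleotide skews flip sign where the replication leading strand changes,
so the running sum of windowed GC skew along a chromosome traces a
Lambda- or V-shaped curve whose extrema are candidate replication
origin/terminus positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .genome_io import SequenceRecord

logger = logging.getLogger(__name__)

_UNAMBIGUOUS = "ACGT"


@dataclass
class PropertyTrack:
    """A windowed numeric genomic property.

    ``starts`` are 1-based window start positions; window ``i`` covers
    ``starts[i] .. starts[i] + window_size - 1`` (truncated at the
    sequence end on linear sequences, wrapped on circular ones).
    """

    name: str
    seq_id: str
    window_size: int
    step: int
    starts: list[int]
    values: list[float]
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.values):
            raise ValueError("starts and values must have equal length")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if any(b <= a for a, b in zip(self.starts, self.starts[1:])):
            raise ValueError("window starts must be strictly increasing")
        if not self.stats:
            self.stats = track_stats(self.values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def coverage_length(self) -> int:
        """Total bp spanned from position 1 to the end of the last window."""
        return self.starts[-1] + self.window_size - 1 if self.starts else 0

    @classmethod
    def from_values(cls, name, seq_id, window_size, step, starts, values) -> "PropertyTrack":
        return cls(
            name=name, seq_id=seq_id, window_size=window_size, step=step,
            starts=list(starts), values=[float(v) for v in values],
        )


@dataclass
class ExtremaReport:
    """Positions and values of the global minimum and maximum of a track."""

    min_pos: int
    min_value: float
    max_pos: int
    max_value: float

    def __post_init__(self) -> None:
        if self.min_value > self.max_value:
            raise ValueError("min_value must be <= max_value")


def track_stats(values: Sequence[float]) -> dict:
    """min/max/mean/sd summary as shown in atlas legends (population sd)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return {"min": math.nan, "max": math.nan, "mean": math.nan, "sd": math.nan}
    return {
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "sd": float(arr.std()),
    }


def window_size_for(length: int, resolution: int) -> int:
    """Window size (bp) that condenses ``length`` bp into <= ``resolution`` units.

    E.g. a 4,639,000 bp chromosome at a 4,000-unit track resolution
    gives ceil(4639000/4000) = 1160 bp windows.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    if resolution > length:
        raise ValueError(
            f"resolution {resolution} exceeds sequence length {length}: window would be sub-bp"
        )
    return -(-length // resolution)


def _counts(window: str) -> dict[str, int]:
    w = window.upper()
    return {b: w.count(b) for b in _UNAMBIGUOUS}


def gc_skew(window: str) -> float:
    """(G - C) / (G + C); 0.0 when the window has no G or C."""
    c = _counts(window)
    denom = c["G"] + c["C"]
    return (c["G"] - c["C"]) / denom if denom else 0.0


def at_skew(window: str) -> float:
    """(A - T) / (A + T); 0.0 when the window has no A or T."""
    c = _counts(window)
    denom = c["A"] + c["T"]
    return (c["A"] - c["T"]) / denom if denom else 0.0


def keto_skew(window: str) -> float:
    """Keto (G+T) minus amino (A+C) excess over all unambiguous bases."""
    c = _counts(window)
    denom = sum(c.values())
    return (c["G"] + c["T"] - c["A"] - c["C"]) / denom if denom else 0.0


def gc_content(window: str) -> float:
    """(G + C) fraction of unambiguous bases in the window."""
    c = _counts(window)
    denom = sum(c.values())
    return (c["G"] + c["C"]) / denom if denom else 0.0


PROPERTY_FUNCTIONS: dict[str, Callable[[str], float]] = {
    "gc_skew": gc_skew,
    "at_skew": at_skew,
    "keto_skew": keto_skew,
    "gc_content": gc_content,
}


def sliding_property(
    record: "SequenceRecord",
    window: int,
    step: int | None = None,
    fn: Callable[[str], float] = gc_skew,
    name: str | None = None,
) -> PropertyTrack:
    """Apply a per-window function along the sequence.

    Windows tile from position 1 with the given step (default: adjacent
    non-overlapping tiles).  On a linear sequence the final partial
    window is computed over the remaining bases; on a circular sequence
    it wraps through position 1.  Ambiguous bases never enter any count.
    """
    if step is None:
        step = window
    length = record.length
    if not 1 <= window <= length:
        raise ValueError(f"window {window} outside 1..{length}")
    if step < 1:
        raise ValueError("step must be >= 1")
    residues = record.residues
    starts, values = [], []
    zero_denominator = 0
    for start in range(1, length + 1, step):
        end = start + window - 1
        if end <= length:
            chunk = residues[start - 1 : end]
        elif record.topology == "circular":
            chunk = residues[start - 1 :] + residues[: end - length]
        else:
            chunk = residues[start - 1 :]
        if not any(b in chunk for b in _UNAMBIGUOUS):
            zero_denominator += 1
        starts.append(start)
        values.append(fn(chunk))
    if zero_denominator:
        logger.info(
            "%d window(s) contained no unambiguous base; skew/content values default to 0",
            zero_denominator,
        )
    return PropertyTrack.from_values(
        name=name or getattr(fn, "__name__", "property"),
        seq_id=record.id, window_size=window, step=step, starts=starts, values=values,
    )


def cumulate(track: PropertyTrack) -> PropertyTrack:
    """Running sum of a windowed property (e.g. cumulative GC skew)."""
    csum = np.cumsum(np.asarray(track.values, dtype=float))
    return PropertyTrack.from_values(
        name=f"{track.name} cumulative", seq_id=track.seq_id,
        window_size=track.window_size, step=track.step,
        starts=track.starts, values=csum.tolist(),
    )


def locate_extrema(track: PropertyTrack) -> ExtremaReport:
    """Global minimum and maximum of a track; ties broken by smallest position."""
    if len(track) == 0:
        raise ValueError("cannot locate extrema of an empty track")
    arr = np.asarray(track.values, dtype=float)
    imin = int(arr.argmin())
    imax = int(arr.argmax())
    return ExtremaReport(
        min_pos=track.starts[imin], min_value=float(arr[imin]),
        max_pos=track.starts[imax], max_value=float(arr[imax]),
    )
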