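"""Genomic interval primitives and the interval algebra used by peak annotation.

Coordinates are 0-based half-open throughout (BED convention). All public
functions accept and return :class:`GenomicInterval` objects; readers are
responsible for converting 1-based inputs at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "validate_intervals",
    "merge_intervals",
    "intervals_overlap",
    "total_length",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome name must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(start must be < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def validate_intervals(intervals: Iterable[GenomicInterval], label: str = "input") -> list[GenomicInterval]:
    """Return intervals as a list, raising a descriptive error on bad records.

    Tuples ``(chrom, start, end)`` are promoted to :class:`GenomicInterval`.
    """
    out: list[GenomicInterval] = []
    for i, iv in enumerate(intervals):
        if not isinstance(iv, GenomicInterval):
            try:
                iv = GenomicInterval(*iv)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{label} record {i}: {exc}") from exc
        out.append(iv)
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended intervals; result sorted by (chrom, start)."""
    ivs = sorted(validate_intervals(intervals))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def intervals_overlap(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> bool:
    """True if any interval in ``a`` overlaps any interval in ``b`` by >= 1 bp."""
    for x in a:
        for y in b:
            if x.overlaps(y):
                return True
    return False


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total number of bases covered, counting shared bases once."""
    return sum(len(iv) for iv in merge_intervals(intervals))
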