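"""Per-chromosome interval indexes for overlap queries.

Thin wrapper around :mod:`intervaltree` keyed by chromosome. Half-open
coordinates; a query returns payloads of every stored interval sharing
at least 1 bp with the query range.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Any, Iterable, Tuple

from intervaltree import IntervalTree


class GenomeIndex:
    """Maps (chrom, start, stop) ranges to payload objects."""

    def __init__(self, items: Iterable[Tuple[str, int, int, Any]] = ()):
        self._trees: dict = defaultdict(IntervalTree)
        for chrom, start, stop, payload in items:
            self.add(chrom, start, stop, payload)

    def add(self, chrom: str, start: int, stop: int, payload: Any) -> None:
        if stop <= start:  # intervaltree rejects empty intervals
            return
        self._trees[chrom].addi(start, stop, payload)

    def overlapping(self, chrom: str, start: int, stop: int) -> list:
        if chrom not in self._trees:
            return []
        return [iv.data for iv in self._trees[chrom].overlap(start, stop)]

    def any_overlap(self, chrom: str, start: int, stop: int) -> bool:
        return chrom in self._trees and bool(self._trees[chrom].overlap(start, stop))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def edge_distance(start_a: int, stop_a: int, start_b: int, stop_b: int) -> int:
    """Nearest-edge distance between two half-open intervals on one
    chromosome; 0 iff they share at least 1 bp."""
    return max(start_a - stop_b, start_b - stop_a, 0)
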