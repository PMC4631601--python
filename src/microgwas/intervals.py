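"""Genomic intervals and BED3 input/output.

All coordinates are 0-based, half-open ``[start, end)`` — the native BED
convention. A SNP at position ``p`` overlaps an interval iff
``start <= p < end``. Strand is ignored throughout: open-chromatin peaks
and SNP overlap are strandless.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Interval",
    "PeakSet",
    "read_bed",
    "write_bed",
    "intersect_peaks",
    "union_peaks",
]


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class PeakSet:
    """A labelled, sorted, merged set of intervals (e.g. one cell line's DHS peaks).

    The constructor sorts by (chrom, start) and merges overlapping or
    book-ended intervals, so any two stored intervals on the same
    chromosome are separated by at least one base.
    """

    label: str = ""
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = _sort_merge(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.intervals == other.intervals and self.label == other.label

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome (m, 2) arrays of [start, end) pairs, sorted."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def contains_positions(self, chroms: Iterable[str], positions: Iterable[int]) -> np.ndarray:
        """Boolean membership of 0-based positions (s <= p < e)."""
        chroms = list(chroms)
        pos = np.asarray(list(positions), dtype=np.int64)
        mask = np.zeros(len(pos), dtype=bool)
        table = self.by_chrom()
        for c in set(chroms):
            rows = table.get(c)
            idx = np.array([i for i, cc in enumerate(chroms) if cc == c], dtype=np.int64)
            if rows is None or len(idx) == 0:
                continue
            starts, ends = rows[:, 0], rows[:, 1]
            # rightmost interval with start <= p; half-open, so p < end means inside
            j = np.searchsorted(starts, pos[idx], side="right") - 1
            ok = j >= 0
            ok[ok] = pos[idx][ok] < ends[j[ok]]
            mask[idx] = ok
        return mask


def _sort_merge(intervals: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[Interval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path: str | Path, label: str | None = None) -> PeakSet:
    """Read a BED3+ file into a sorted, merged :class:`PeakSet`.

    Only the first three columns (chrom, start, end) are interpreted.
    Malformed records are rejected with the offending line number, never
    coerced. Transparent gzip support by ``.gz`` suffix.
    """
    path = Path(path)
    intervals: list[Interval] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates {s!r}, {e!r}") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start {start}")
            intervals.append(Interval(chrom, start, end))
    return PeakSet(label=label if label is not None else path.stem, intervals=intervals)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED3. read(write(S)) is the identity for merged S."""
    with _open_text(path, "wt") as fh:
        for iv in peaks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def intersect_peaks(a: PeakSet, b: PeakSet, label: str | None = None) -> PeakSet:
    """Base-pair intersection of two peak sets.

    Returns exactly the bases present in both inputs. Associative and
    commutative, which is what makes the iterated per-tissue intersection
    well defined regardless of cell-line order.
    """
    out: list[Interval] = []
    bb = b.by_chrom()
    for chrom, arows in a.by_chrom().items():
        brows = bb.get(chrom)
        if brows is None:
            continue
        i = j = 0
        while i < len(arows) and j < len(brows):
            s = max(arows[i, 0], brows[j, 0])
            e = min(arows[i, 1], brows[j, 1])
            if s < e:
                out.append(Interval(chrom, int(s), int(e)))
            if arows[i, 1] < brows[j, 1]:
                i += 1
            else:
                j += 1
    if label is None:
        label = f"{a.label}&{b.label}" if a.label or b.label else ""
    return PeakSet(label=label, intervals=out)


def union_peaks(peaksets: Iterable[PeakSet], label: str = "") -> PeakSet:
    """Merged union of several peak sets."""
    ivs: list[Interval] = []
    for ps in peaksets:
        ivs.extend(ps.intervals)
    return PeakSet(label=label, intervals=ivs)
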