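"""Half-open genomic-interval arithmetic.

All coordinates in this package are 0-based, half-open ``[start, end)``
(BED convention).  The three operations implemented here — pairwise
``overlap``, gap-tolerant ``merge`` and capped ``nearest`` — are the
functional core behind peak classification, gene annotation and
enhancer-to-gene linkage.  Chromosome names are matched literally; there
is no "chr" aliasing.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "overlap",
    "merge",
    "nearest",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on a named chromosome.

    ``strand`` is one of ``+``, ``-`` or ``.`` and is carried but ignored
    by overlap/merge/nearest; only the gene-annotation layer is
    strand-aware.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> Optional[int]:
        """Edge distance: 0 when overlapping or abutting, else the gap.

        Returns ``None`` for intervals on different chromosomes, where a
        distance is undefined.
        """
        if self.chrom != other.chrom:
            return None
        if self.start < other.end and other.start < self.end:
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


class IntervalSet:
    """Intervals grouped by chromosome, kept sorted by (start, end).

    Duplicates are permitted; construction sorts, it never deduplicates.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom in by_chrom:
            by_chrom[chrom].sort(key=lambda iv: (iv.start, iv.end))
        # chromosomes iterate in name order for deterministic output
        self._by_chrom = {c: by_chrom[c] for c in sorted(by_chrom)}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def on(self, chrom: str) -> list[GenomicInterval]:
        return self._by_chrom.get(chrom, [])

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {len(self._by_chrom)} chromosomes)"


@dataclass(frozen=True)
class OverlapPair:
    """One reported overlap: the two source intervals and their intersection."""

    a: GenomicInterval
    b: GenomicInterval
    intersection: GenomicInterval


def overlap(
    a: IntervalSet, b: IntervalSet, min_overlap: int = 1
) -> list[OverlapPair]:
    """All (a, b) pairs whose intersection spans >= ``min_overlap`` bp.

    Output is ordered by (chrom, a.start, b.start).  Half-open abutment
    ([0,100) vs [100,200)) is not an overlap.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    pairs: list[OverlapPair] = []
    for chrom in a.chromosomes:
        ivs_b = b.on(chrom)
        if not ivs_b:
            continue
        b_starts = [iv.start for iv in ivs_b]
        for iv_a in a.on(chrom):
            # b intervals are start-sorted; any b with start >= a.end
            # cannot overlap, but earlier-starting long b intervals can.
            hi = bisect.bisect_left(b_starts, iv_a.end)
            for iv_b in ivs_b[:hi]:
                inter = iv_a.intersection_length(iv_b)
                if inter >= min_overlap:
                    pairs.append(
                        OverlapPair(
                            iv_a,
                            iv_b,
                            GenomicInterval(
                                chrom,
                                max(iv_a.start, iv_b.start),
                                min(iv_a.end, iv_b.end),
                            ),
                        )
                    )
    pairs.sort(key=lambda p: (p.a.chrom, p.a.start, p.a.end, p.b.start, p.b.end))
    return pairs


def merge(s: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Coalesce intervals transitively whenever the gap between them is
    <= ``max_gap`` bp (gap = next.start - prev.end; overlap counts as
    gap 0).  A gap of exactly ``max_gap`` merges.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[GenomicInterval] = []
    for chrom in s.chromosomes:
        cur_start = cur_end = None
        for iv in s.on(chrom):
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(merged)


@dataclass(frozen=True)
class NearestHit:
    query: GenomicInterval
    subject: Optional[GenomicInterval]
    distance: Optional[int]
    # all equally-near subjects, for callers that want to see ties
    ties: tuple[GenomicInterval, ...] = field(default=())


def nearest(
    query: IntervalSet, subjects: IntervalSet, max_distance: int
) -> list[NearestHit]:
    """For each query, the closest subject within ``max_distance`` bp.

    Distance is 0 for any overlap, otherwise the gap between the closest
    edges.  Ties on distance resolve to the subject with the smaller
    start (then smaller end); all tied subjects are reported in
    ``ties``.  Queries with nothing in range get subject ``None``.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    hits: list[NearestHit] = []
    for chrom in query.chromosomes:
        subs = subjects.on(chrom)
        for q in query.on(chrom):
            best: list[GenomicInterval] = []
            best_d: Optional[int] = None
            for s_iv in subs:
                d = q.distance_to(s_iv)
                if d is None or d > max_distance:
                    continue
                if best_d is None or d < best_d:
                    best_d, best = d, [s_iv]
                elif d == best_d:
                    best.append(s_iv)
            if best_d is None:
                hits.append(NearestHit(q, None, None))
            else:
                best.sort(key=lambda iv: (iv.start, iv.end))
                hits.append(NearestHit(q, best[0], best_d, tuple(best)))
    return hits


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED6 into an IntervalSet.

    Columns beyond the sixth are ignored; a ``.`` score reads as None.
    """
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(
                GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
            )
    return IntervalSet(intervals)


def _format_score(score: Optional[float]) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(s: IntervalSet, path: str | Path, bed6: bool | None = None) -> None:
    """Write BED3 or BED6.  With ``bed6=None`` the width is BED6 iff any
    interval carries a name, score or explicit strand, so a BED3
    round-trips byte-identically.
    """
    ivs = list(s)
    if bed6 is None:
        bed6 = any(
            iv.name is not None or iv.score is not None or iv.strand != "."
            for iv in ivs
        )
    with open(path, "w") as fh:
        for iv in ivs:
            if bed6:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{_format_score(iv.score)}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def clip(iv: GenomicInterval, chrom_length: Optional[int] = None) -> GenomicInterval:
    """Clip an interval at 0 and (optionally) the chromosome end."""
    start = max(0, iv.start)
    end = iv.end if chrom_length is None else min(iv.end, chrom_length)
    if start == iv.start and end == iv.end:
        return iv
    return replace(iv, start=start, end=end)
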