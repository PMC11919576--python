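"""Coordinate-safe genomic interval algebra.

All modules in this package use a single coordinate convention: 0-based,
half-open ``[start, end)``.  Formats that are 1-based on disk (VCF positions,
Bismark coverage) are converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

FEATURE_CLASSES = frozenset(
    {
        "coding_gene",
        "promoter",
        "enhancer",
        "five_prime_utr",
        "three_prime_utr",
        "lncRNA",
        "lncRNA_promoter",
        "miRNA",
        "smallRNA",
        "dyadic",
        "cgi_island",
        "cgi_shore",
        "cgi_shelf",
        "exon",
        "intron",
    }
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``.

    ``start`` is 0-based inclusive, ``end`` is 0-based exclusive.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end} (end must exceed start)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        """True when the 0-based position ``pos`` lies inside the interval."""
        return chrom == self.chrom and self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class FeatureSet:
    """A named genomic feature (gene, regulatory segment, annotation track element)."""

    id: str
    name: str
    feature_class: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature_class {self.feature_class!r}")
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start))
        if self.total_length() <= 0:
            raise ValueError(f"feature {self.id} has zero total length")

    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)


def reciprocal_overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when on different chromosomes.

    Symmetric in its arguments.  Both intervals must be non-empty (guaranteed
    by the :class:`GenomicInterval` invariant).
    """
    ov = a.overlap_length(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint intervals.

    Adjacent (book-ended) intervals are merged.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of two interval sets (each first merged to disjoint form)."""
    am, bm = merge_intervals(a), merge_intervals(b)
    out = []
    for iva in am:
        for ivb in bm:
            if iva.overlaps(ivb):
                out.append(
                    GenomicInterval(
                        iva.chrom, max(iva.start, ivb.start), min(iva.end, ivb.end)
                    )
                )
    return merge_intervals(out)


class IntervalIndex:
    """Per-chromosome interval tree over (interval, payload) pairs.

    Thin wrapper around :mod:`intervaltree` that keeps the package's half-open
    convention and offers point and interval queries.
    """

    def __init__(
        self, items: Iterable[tuple[GenomicInterval, object]] | None = None
    ) -> None:
        self._trees: dict[str, IntervalTree] = {}
        if items:
            for iv, payload in items:
                self.add(iv, payload)

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalIndex":
        return cls((iv, iv) for iv in intervals)

    def add(self, iv: GenomicInterval, payload: object) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)

    def query_point(self, chrom: str, pos: int) -> list[object]:
        """Payloads of intervals containing the 0-based position ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.at(pos)]

    def query(self, iv: GenomicInterval) -> list[object]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end)]

    def overlaps_point(self, chrom: str, pos: int) -> bool:
        return bool(self.query_point(chrom, pos))

    def overlaps(self, iv: GenomicInterval) -> bool:
        return bool(self.query(iv))

    def __iter__(self) -> Iterator[object]:
        for tree in self._trees.values():
            for hit in tree:
                yield hit.data


def vcf_pos_to_interval(chrom: str, pos: int, ref: str) -> GenomicInterval:
    """Map a 1-based VCF position to the half-open interval spanned by REF."""
    return GenomicInterval(chrom, pos - 1, pos - 1 + max(1, len(ref)))


def interval_to_vcf_pos(iv: GenomicInterval) -> int:
    """Inverse of :func:`vcf_pos_to_interval` for the position component."""
    return iv.start + 1


def sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)
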