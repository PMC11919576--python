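"""Two-caller CNV consensus and cross-sample recurrent region construction.

Per sample, calls reported by both callers with >= 50% reciprocal overlap
and matching type are merged by coordinate averaging; consensus calls are
then clustered across samples with the same reciprocal-overlap rule
(connected components), annotated with overlapping genes, and compared
between cohorts with a per-region one-sided Fisher test.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .intervals import GenomicInterval, reciprocal_overlap_fraction

CNV_TYPES = ("DEL", "DUP")


@dataclass(frozen=True)
class CnvCall:
    """One caller's CNV call in one sample."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    caller: str

    def __post_init__(self) -> None:
        if self.cnv_type not in CNV_TYPES:
            raise ValidationError(f"cnv_type must be DEL or DUP, got {self.cnv_type!r}")


@dataclass
class ConsensusRegion:
    """Cross-sample recurrent CNV region."""

    interval: GenomicInterval
    cnv_type: str
    supporting_samples: frozenset[str]
    overlapped_genes: list[str] = field(default_factory=list)
    case_control_p: float | None = None
    case_control_q: float | None = None

    @property
    def patient_frequency(self) -> int:
        return len(self.supporting_samples)

    @property
    def length(self) -> int:
        return self.interval.length


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def _average_interval(intervals: list[GenomicInterval]) -> GenomicInterval:
    start = _round_half_up(sum(iv.start for iv in intervals) / len(intervals))
    end = _round_half_up(sum(iv.end for iv in intervals) / len(intervals))
    assert end > start, "coordinate averaging produced an empty interval"
    return GenomicInterval(intervals[0].chrom, start, end)


def consensus_intersect(
    calls_a: list[CnvCall], calls_b: list[CnvCall], min_reciprocal: float = 0.5
) -> list[CnvCall]:
    """Per-sample consensus: same-type caller pairs at >= min_reciprocal overlap.

    Pairing is greedy on the best reciprocal overlap; each call is used at
    most once.  The merged call averages the two start and the two end
    coordinates (rounding half up).  Unmatched calls are dropped.
    """
    by_key_a: dict[tuple[str, str, str], list[CnvCall]] = defaultdict(list)
    by_key_b: dict[tuple[str, str, str], list[CnvCall]] = defaultdict(list)
    for c in calls_a:
        by_key_a[(c.sample_id, c.cnv_type, c.interval.chrom)].append(c)
    for c in calls_b:
        by_key_b[(c.sample_id, c.cnv_type, c.interval.chrom)].append(c)
    out: list[CnvCall] = []
    for key in sorted(set(by_key_a) & set(by_key_b)):
        group_a = sorted(by_key_a[key], key=lambda c: (c.interval.start, c.interval.end))
        group_b = sorted(by_key_b[key], key=lambda c: (c.interval.start, c.interval.end))
        pairs = []
        for i, ca in enumerate(group_a):
            for j, cb in enumerate(group_b):
                ro = reciprocal_overlap_fraction(ca.interval, cb.interval)
                if ro >= min_reciprocal:
                    pairs.append((ro, i, j))
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for ro, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            merged = _average_interval([group_a[i].interval, group_b[j].interval])
            out.append(
                CnvCall(
                    sample_id=key[0], interval=merged, cnv_type=key[1], caller="AB"
                )
            )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.sample_id))
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_across_samples(
    calls: list[CnvCall], min_reciprocal: float = 0.5
) -> list[ConsensusRegion]:
    """Connected-component clustering of same-type calls across samples.

    Calls are linked when their reciprocal overlap is >= min_reciprocal;
    each component becomes one region whose interval is the coordinate-wise
    mean (rounded half up) of its member calls.  Output is sorted by
    descending patient frequency then coordinates and is independent of the
    input order.
    """
    regions: list[ConsensusRegion] = []
    by_key: dict[tuple[str, str], list[CnvCall]] = defaultdict(list)
    for c in calls:
        by_key[(c.cnv_type, c.interval.chrom)].append(c)
    for (cnv_type, _chrom), group in sorted(by_key.items()):
        group = sorted(group, key=lambda c: (c.interval.start, c.interval.end, c.sample_id))
        uf = _UnionFind(len(group))
        # sweep: only overlapping pairs can satisfy the reciprocal rule
        for i, ci in enumerate(group):
            for j in range(i + 1, len(group)):
                cj = group[j]
                if cj.interval.start >= ci.interval.end:
                    break
                if (
                    reciprocal_overlap_fraction(ci.interval, cj.interval)
                    >= min_reciprocal
                ):
                    uf.union(i, j)
        members: dict[int, list[CnvCall]] = defaultdict(list)
        for i, c in enumerate(group):
            members[uf.find(i)].append(c)
        for root in sorted(members):
            comp = members[root]
            regions.append(
                ConsensusRegion(
                    interval=_average_interval([c.interval for c in comp]),
                    cnv_type=cnv_type,
                    supporting_samples=frozenset(c.sample_id for c in comp),
                )
            )
    regions.sort(
        key=lambda r: (
            -r.patient_frequency,
            r.interval.chrom,
            r.interval.start,
            r.interval.end,
            r.cnv_type,
        )
    )
    return regions


def annotate_regions(
    regions: list[ConsensusRegion],
    genes: list[tuple[GenomicInterval, str]],
) -> list[ConsensusRegion]:
    """Attach gene names overlapping each region by >= 1 bp, in genomic order."""
    genes_sorted = sorted(genes, key=lambda g: (g[0].chrom, g[0].start, g[1]))
    out = []
    for r in regions:
        names = []
        for iv, name in genes_sorted:
            if r.interval.overlaps(iv) and name not in names:
                names.append(name)
        out.append(replace(r, overlapped_genes=names))
    return out


def compare_region_frequencies(
    regions: list[ConsensusRegion],
    case_n: int,
    control_counts: list[int],
    control_n: int,
    alpha_q: float = 0.05,
) -> pd.DataFrame:
    """Per-region one-sided Fisher test of case vs control carrier frequency.

    ``control_counts`` aligns with ``regions``.  BH adjustment across
    regions; returns a table mirroring the recurrent-region report
    (coordinates, type, patient frequency, length, genes, p, q).
    """
    from .burden import fisher_one_sided  # local import avoids a cycle

    if control_n <= 0:
        raise ValidationError("control_n must be positive")
    if len(control_counts) != len(regions):
        raise ValidationError("control_counts must align with regions")
    rows = []
    pvals = []
    for r, c in zip(regions, control_counts):
        a = min(r.patient_frequency, case_n)
        p = fisher_one_sided(a, case_n - a, c, control_n - c)
        pvals.append(p)
        rows.append(
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "cnv_type": r.cnv_type,
                "patient_frequency": r.patient_frequency,
                "cnv_length": r.length,
                "overlapped_genes": ";".join(r.overlapped_genes),
                "control_carriers": c,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(pvals, method="fdr_bh")[1]
        df["significant"] = df["q"] <= alpha_q
    return df
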