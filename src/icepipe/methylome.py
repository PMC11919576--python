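"""Differential-methylome pipeline.

Coverage filtering, per-sample hypomethylated-region (HMR) calling (a
transparent threshold segmenter; externally called HMR BEDs are accepted
directly), cross-sample recurrent-HMR scanning over 100-bp windows,
annotation-context classification, region-level differential testing with
BH adjustment, gene mapping, and hypergeometric gene-set enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .intervals import GenomicInterval, IntervalIndex
from .io import MethylomeSample

ANNOTATION_GROUPS = ("promoter", "enhancer", "dyadic", "none")
CGI_CONTEXTS = ("island", "shore", "shelf", "open_sea")


@dataclass(frozen=True)
class Hmr:
    """One sample's hypomethylated region."""

    sample_id: str
    interval: GenomicInterval
    n_cpg: int
    mean_beta: float

    def __post_init__(self) -> None:
        if self.n_cpg < 1:
            raise ValidationError("HMR must contain at least one CpG")
        if not (0.0 <= self.mean_beta <= 1.0):
            raise ValidationError(f"mean_beta {self.mean_beta} outside [0,1]")


@dataclass(frozen=True)
class RecurrentHmr:
    """Region where at least the threshold fraction of samples has an HMR."""

    interval: GenomicInterval
    sample_fraction: float
    annotation_group: str = "none"
    cgi_context: str = "open_sea"


# ---------------------------------------------------------------------------
# Per-sample processing
# ---------------------------------------------------------------------------


def filter_coverage(sample: MethylomeSample, min_reads: int = 5) -> MethylomeSample:
    """Keep CpGs with coverage >= min_reads (the segmentation default)."""
    rec = sample.records
    keep = (rec["meth"] + rec["unmeth"]) >= min_reads
    return MethylomeSample(sample.sample_id, rec.loc[keep].reset_index(drop=True))


def call_hmrs_simple(
    sample: MethylomeSample,
    beta_max: float = 0.5,
    min_cpg: int = 4,
    max_gap: int = 500,
) -> list[Hmr]:
    """Threshold HMR segmenter.

    Maximal runs of >= min_cpg consecutive covered CpGs with beta <= beta_max
    and inter-CpG gap <= max_gap become HMRs spanning the first to last CpG
    (half-open).  A deliberately simple, fully specified stand-in for an
    HMM-based segmenter; upstream HMR BEDs can be supplied instead via
    :func:`hmrs_from_bed`.
    """
    out: list[Hmr] = []
    rec = sample.records
    beta = sample.beta
    cov = sample.coverage
    for chrom, idx in rec.groupby("chrom", sort=True).groups.items():
        pos = rec.loc[idx, "pos"].to_numpy()
        b = beta[idx]
        low = (cov[idx] > 0) & (b <= beta_max)
        run: list[int] = []
        def flush(run_idx: list[int]) -> None:
            if len(run_idx) >= min_cpg:
                first, last = pos[run_idx[0]], pos[run_idx[-1]]
                out.append(
                    Hmr(
                        sample.sample_id,
                        GenomicInterval(str(chrom), int(first) - 1, int(last)),
                        len(run_idx),
                        float(np.mean(b[run_idx])),
                    )
                )
        for i in range(len(pos)):
            if not low[i]:
                flush(run)
                run = []
                continue
            if run and pos[i] - pos[run[-1]] > max_gap:
                flush(run)
                run = []
            run.append(i)
        flush(run)
    return out


def hmrs_from_bed(
    rows: list[tuple[GenomicInterval, str]] | list[GenomicInterval],
    sample_id: str,
) -> list[Hmr]:
    """Wrap externally called HMR intervals (e.g. an upstream segmenter's BED)."""
    out = []
    for row in rows:
        iv = row[0] if isinstance(row, tuple) else row
        out.append(Hmr(sample_id, iv, n_cpg=1, mean_beta=0.0))
    return out


# ---------------------------------------------------------------------------
# Recurrent-HMR scan
# ---------------------------------------------------------------------------


def recurrence_scan(
    hmrs_by_sample: dict[str, list[Hmr]],
    n_samples: int | None = None,
    window: int = 100,
    min_fraction: float = 0.05,
    focal_max: int = 10_000,
) -> list[RecurrentHmr]:
    """Merge 100-bp windows where >= min_fraction of samples have an HMR.

    HMRs longer than ``focal_max`` are discarded first.  The genome is tiled
    in non-overlapping windows anchored at coordinate 0; maximal runs of
    adjacent qualifying windows merge into one region whose
    ``sample_fraction`` is the fraction of samples with an HMR overlapping
    the merged region.
    """
    if n_samples is None:
        n_samples = len(hmrs_by_sample)
    if n_samples == 0:
        raise ValidationError("recurrence_scan requires at least one sample")
    # per (chrom, sample): covered window index ranges
    focal: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for sample, hmrs in hmrs_by_sample.items():
        for h in hmrs:
            if h.interval.length > focal_max:
                continue
            w0 = h.interval.start // window
            w1 = (h.interval.end - 1) // window  # last window touched
            focal.setdefault(h.interval.chrom, {}).setdefault(sample, []).append((w0, w1))
    out: list[RecurrentHmr] = []
    threshold = min_fraction * n_samples - 1e-9
    for chrom in sorted(focal):
        per_sample = focal[chrom]
        n_win = max(w1 for ranges in per_sample.values() for _, w1 in ranges) + 1
        counts = np.zeros(n_win, dtype=np.int32)
        for sample, ranges in per_sample.items():
            # count each sample at most once per window via a coverage diff array
            diff = np.zeros(n_win + 1, dtype=np.int32)
            for w0, w1 in ranges:
                diff[w0] += 1
                diff[w1 + 1] -= 1
            counts += (np.cumsum(diff[:-1]) > 0).astype(np.int32)
        qualifying = counts >= threshold
        # maximal runs of consecutive qualifying windows
        idx = np.flatnonzero(qualifying)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for s_i, e_i in zip(starts, ends):
            region = GenomicInterval(chrom, int(idx[s_i]) * window, (int(idx[e_i]) + 1) * window)
            # fraction based on actual HMR overlap with the merged region
            overlap_samples = 0
            for sample, hmrs in hmrs_by_sample.items():
                if any(
                    h.interval.length <= focal_max and h.interval.overlaps(region)
                    for h in hmrs
                ):
                    overlap_samples += 1
            out.append(RecurrentHmr(region, overlap_samples / n_samples))
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out


def classify_hmr_context(
    region: GenomicInterval | RecurrentHmr,
    promoters: list[GenomicInterval],
    enhancers: list[GenomicInterval],
    dyadic: list[GenomicInterval],
    islands: list[GenomicInterval],
    shores: list[GenomicInterval],
    shelves: list[GenomicInterval],
) -> tuple[str, str]:
    """First-overlap classification with precedence promoter > enhancer > dyadic
    and island > shore > shelf; (none, open_sea) when nothing overlaps."""
    iv = region.interval if isinstance(region, RecurrentHmr) else region
    group = "none"
    for name, track in (("promoter", promoters), ("enhancer", enhancers), ("dyadic", dyadic)):
        if any(iv.overlaps(t) for t in track):
            group = name
            break
    context = "open_sea"
    for name, track in (("island", islands), ("shore", shores), ("shelf", shelves)):
        if any(iv.overlaps(t) for t in track):
            context = name
            break
    return group, context


def annotate_recurrent_hmrs(
    regions: list[RecurrentHmr],
    promoters: list[GenomicInterval],
    enhancers: list[GenomicInterval],
    dyadic: list[GenomicInterval],
    islands: list[GenomicInterval],
    shores: list[GenomicInterval],
    shelves: list[GenomicInterval],
) -> list[RecurrentHmr]:
    out = []
    for r in regions:
        group, context = classify_hmr_context(
            r, promoters, enhancers, dyadic, islands, shores, shelves
        )
        out.append(replace(r, annotation_group=group, cgi_context=context))
    return out


# ---------------------------------------------------------------------------
# Region methylation matrix and DMR testing
# ---------------------------------------------------------------------------


def region_id(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def region_methylation_matrix(
    regions: list[GenomicInterval | RecurrentHmr],
    samples: list[MethylomeSample],
) -> tuple[pd.DataFrame, list[GenomicInterval]]:
    """Coverage-weighted mean beta per region x sample.

    Entry = sum(meth) / sum(meth + unmeth) over covered CpGs inside the
    region; NaN when the sample has no covered CpG there.  Regions with no
    CpG in any sample are dropped with a warning.
    """
    ivs = [r.interval if isinstance(r, RecurrentHmr) else r for r in regions]
    cols = {}
    for s in samples:
        rec = s.records
        meth_sum = np.zeros(len(ivs))
        cov_sum = np.zeros(len(ivs))
        for chrom, idx in rec.groupby("chrom", sort=False).groups.items():
            pos0 = rec.loc[idx, "pos"].to_numpy() - 1  # 0-based
            meth = rec.loc[idx, "meth"].to_numpy().astype(float)
            cov = meth + rec.loc[idx, "unmeth"].to_numpy()
            cm = np.concatenate([[0.0], np.cumsum(meth)])
            cc = np.concatenate([[0.0], np.cumsum(cov)])
            for k, iv in enumerate(ivs):
                if iv.chrom != chrom:
                    continue
                lo = np.searchsorted(pos0, iv.start, side="left")
                hi = np.searchsorted(pos0, iv.end, side="left")
                meth_sum[k] += cm[hi] - cm[lo]
                cov_sum[k] += cc[hi] - cc[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            cols[s.sample_id] = np.where(cov_sum > 0, meth_sum / cov_sum, np.nan)
    mat = pd.DataFrame(cols, index=[region_id(iv) for iv in ivs])
    empty = mat.isna().all(axis=1)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} regions with no covered CpG in any sample dropped",
            stacklevel=2,
        )
    kept = [iv for iv, e in zip(ivs, empty) if not e]
    return mat.loc[~empty.to_numpy()], kept


def dmr_test(
    matrix: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
    alpha_q: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Row-wise two-sample t-test of region mean methylation, BH-adjusted.

    The default is the pooled-variance (Student) test; ``equal_var=False``
    switches to Welch.  Rows with fewer than two non-missing values in
    either group, or zero variance in both groups with equal means, are
    excluded and flagged.  ``delta`` is case mean minus control mean on the
    beta scale; ``direction`` is hypo when delta < 0.  The DMR set is
    q <= alpha_q.
    """
    X = matrix[case_ids].to_numpy(dtype=float)
    Y = matrix[control_ids].to_numpy(dtype=float)
    nx = np.sum(~np.isnan(X), axis=1)
    ny = np.sum(~np.isnan(Y), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mx, my = np.nanmean(X, axis=1), np.nanmean(Y, axis=1)
        vx, vy = np.nanvar(X, axis=1, ddof=1), np.nanvar(Y, axis=1, ddof=1)
    delta = mx - my
    degenerate = (vx == 0) & (vy == 0) & (delta == 0)
    testable = (nx >= 2) & (ny >= 2) & ~degenerate
    t = np.full(len(matrix), np.nan)
    p = np.full(len(matrix), np.nan)
    if equal_var:
        df_ = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / np.where(df_ > 0, df_, 1)
        se = np.sqrt(sp2 * (1 / np.maximum(nx, 1) + 1 / np.maximum(ny, 1)))
    else:
        se = np.sqrt(vx / np.maximum(nx, 1) + vy / np.maximum(ny, 1))
        num = (vx / nx + vy / ny) ** 2
        den = (vx / nx) ** 2 / np.maximum(nx - 1, 1) + (vy / ny) ** 2 / np.maximum(ny - 1, 1)
        df_ = np.where(den > 0, num / np.where(den > 0, den, 1), 1)
    ok = testable & (se > 0)
    t[ok] = delta[ok] / se[ok]
    p[ok] = 2.0 * t_dist.sf(np.abs(t[ok]), df_[ok])
    # zero pooled variance with unequal means: infinitely strong separation
    zero_se = testable & (se == 0) & (delta != 0)
    t[zero_se] = np.sign(delta[zero_se]) * np.inf
    p[zero_se] = 0.0
    out = pd.DataFrame(
        {
            "region": matrix.index,
            "n_case": nx,
            "n_control": ny,
            "mean_beta_case": mx,
            "mean_beta_control": my,
            "delta": delta,
            "t_statistic": t,
            "p": p,
            "excluded": ~(testable & ((se > 0) | zero_se)),
        }
    )
    q = np.full(len(out), np.nan)
    inc = ~out["excluded"].to_numpy()
    if inc.any():
        q[inc] = multipletests(out.loc[inc, "p"], method="fdr_bh")[1]
    out["q"] = q
    out["direction"] = np.where(out["delta"] < 0, "hypo", "hyper")
    out["is_dmr"] = inc & (out["q"] <= alpha_q)
    return out


def hypo_fraction(dmrs: pd.DataFrame) -> float:
    """Fraction of DMRs with direction hypo (case less methylated)."""
    sub = dmrs.loc[dmrs["is_dmr"]] if "is_dmr" in dmrs.columns else dmrs
    if len(sub) == 0:
        raise ValidationError("hypo_fraction of an empty DMR set is undefined")
    return float((sub["direction"] == "hypo").mean())


def select_recurrent_differential(
    recurrent: list[RecurrentHmr],
    deltas: dict[str, float],
    min_recurrence: float = 0.10,
    max_delta: float = -0.1,
) -> list[RecurrentHmr]:
    """Recurrent regions (> min_recurrence of samples) that are hypomethylated
    in cases beyond max_delta; sorted by descending recurrence.

    ``deltas`` maps region id (chrom:start-end) to the differential
    methylation of that region; regions without a delta are skipped.
    """
    picked = [
        r
        for r in recurrent
        if r.sample_fraction > min_recurrence
        and region_id(r.interval) in deltas
        and deltas[region_id(r.interval)] < max_delta
    ]
    picked.sort(key=lambda r: (-r.sample_fraction, r.interval.chrom, r.interval.start))
    return picked


def map_dmrs_to_genes(
    dmr_intervals: list[GenomicInterval],
    gene_parts: list[tuple[GenomicInterval, str, str]],
    parts: tuple[str, ...] = ("promoter", "exon", "intron"),
) -> list[str]:
    """Genes whose promoter, exon, or intron overlaps any DMR (unique, sorted)."""
    index = IntervalIndex()
    for iv, gene, part in gene_parts:
        if part in parts:
            index.add(iv, gene)
    genes: set[str] = set()
    for iv in dmr_intervals:
        genes.update(index.query(iv))
    return sorted(genes)


def geneset_enrichment(
    query_genes: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    alpha_q: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of query genes in each set.

    p = P(X >= overlap) drawing |query| genes from the universe with the
    set's members as successes; BH adjustment across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty gene universe")
    query = set(query_genes) & uni
    rows = []
    pvals = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & uni
        overlap = len(query & members)
        p = float(hypergeom.sf(overlap - 1, len(uni), len(members), len(query)))
        pvals.append(p)
        rows.append(
            {
                "set_id": set_id,
                "overlap": overlap,
                "set_size": len(members),
                "universe_size": len(uni),
                "n_query": len(query),
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(pvals, method="fdr_bh")[1]
        df["significant"] = df["q"] <= alpha_q
        df = df.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    return df
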