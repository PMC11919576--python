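"""Gene- and regulatory-segment rare-variant burden testing.

Dominant-model carrier counting, one-sided Fisher's exact test on the 2x2
carrier table, genomic-inflation calibration over site-quality tranches
(lambda95), mutation-rate tables, and variant-sharing summaries.

Table orientation is [[case carriers, case non-carriers],
[control carriers, control non-carriers]].  For summary-only controls
(AC/AN cohorts) the carrier count is the capped sum of alternate allele
counts over qualifying variants, treating each counted allele as a distinct
carrier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2, hypergeom, ttest_ind
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .intervals import FeatureSet, GenomicInterval, IntervalIndex, merge_intervals
from .io import VariantRecord

CHI2_1DF_95 = 3.841459  # 95th percentile of chi-square with 1 df

# ---------------------------------------------------------------------------
# Qualifying-variant selection
# ---------------------------------------------------------------------------


def select_qualifying_coding(
    variants: list[VariantRecord], af_max: float = 0.01
) -> list[VariantRecord]:
    """Rare coding-altering variants: AF <= af_max and missense/lof."""
    return [
        v for v in variants if v.pop_af <= af_max and v.consequence in ("missense", "lof")
    ]


def select_qualifying_noncoding(
    variants: list[VariantRecord], af_max: float = 0.001
) -> list[VariantRecord]:
    """Rare noncoding variants called deleterious by all three predictors."""
    return [
        v for v in variants if v.pop_af <= af_max and all(v.deleterious_flags)
    ]


def select_benign(
    variants: list[VariantRecord], mode: str = "coding", af_max: float | None = None
) -> list[VariantRecord]:
    """Rare benign variants used for inflation calibration.

    Coding mode: rare synonymous (AF <= 0.01 by default).  Noncoding mode:
    rare (AF <= 0.001 by default) with no deleterious call from any of the
    three predictors.
    """
    if mode == "coding":
        af = 0.01 if af_max is None else af_max
        return [v for v in variants if v.pop_af <= af and v.consequence == "synonymous"]
    if mode == "noncoding":
        af = 0.001 if af_max is None else af_max
        return [
            v
            for v in variants
            if v.pop_af <= af
            and v.consequence == "noncoding"
            and not any(v.deleterious_flags)
        ]
    raise ValidationError(f"unknown benign mode {mode!r}")


# ---------------------------------------------------------------------------
# Depth matching and region filters
# ---------------------------------------------------------------------------


@dataclass
class CallableMask:
    """Bases where at least ``required_fraction`` of samples are covered in both cohorts."""

    intervals: list[GenomicInterval]
    required_fraction: float = 0.9

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)
        self._index = IntervalIndex.from_intervals(self.intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        return self._index.overlaps_point(chrom, pos0)


def _coverage_rows(track) -> list[tuple[str, int, int, float]]:
    if isinstance(track, pd.DataFrame):
        return [
            (str(r.chrom), int(r.start), int(r.end), float(r.fraction))
            for r in track.itertuples()
        ]
    return [(iv.chrom, iv.start, iv.end, float(f)) for iv, f in track]


def build_callable_mask(
    case_coverage, control_coverage, required_fraction: float = 0.9
) -> CallableMask:
    """Intersect the two fraction-covered tracks at the required threshold.

    Tracks are (interval, fraction) pairs or DataFrames with columns
    chrom/start/end/fraction.  Chromosome sets must agree.
    """
    case_rows = _coverage_rows(case_coverage)
    ctrl_rows = _coverage_rows(control_coverage)
    case_chroms = {r[0] for r in case_rows}
    ctrl_chroms = {r[0] for r in ctrl_rows}
    if case_chroms != ctrl_chroms:
        only_case = sorted(case_chroms - ctrl_chroms)
        only_ctrl = sorted(ctrl_chroms - case_chroms)
        raise ValidationError(
            f"coverage tracks disagree on chromosomes: case-only {only_case}, control-only {only_ctrl}"
        )
    ok_case = [GenomicInterval(c, s, e) for c, s, e, f in case_rows if f >= required_fraction]
    ok_ctrl = [GenomicInterval(c, s, e) for c, s, e, f in ctrl_rows if f >= required_fraction]
    from .intervals import intersect_intervals

    return CallableMask(intersect_intervals(ok_case, ok_ctrl), required_fraction)


def apply_region_filters(
    variants: list[VariantRecord],
    mask: CallableMask | None,
    lcr: list[GenomicInterval] | None,
) -> list[VariantRecord]:
    """Keep variants inside the callable mask and outside low-complexity regions."""
    lcr_index = IntervalIndex.from_intervals(lcr) if lcr else None
    out = []
    for v in variants:
        pos0 = v.pos - 1
        if mask is not None and not mask.contains(v.chrom, pos0):
            continue
        if lcr_index is not None and lcr_index.overlaps_point(v.chrom, pos0):
            continue
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# Carrier counting
# ---------------------------------------------------------------------------


def count_case_carriers(variants: list[VariantRecord]) -> int:
    """Distinct case samples with at least one qualifying alternate allele.

    Missing genotypes count as non-carriers.
    """
    if not variants:
        return 0
    carrier = None
    for v in variants:
        mask = v.carriers()
        carrier = mask if carrier is None else (carrier | mask)
    return int(carrier.sum())


def carrier_missing_rate(variants: list[VariantRecord]) -> float:
    """Fraction of genotype calls that are missing across the feature's variants."""
    total = sum(len(v.case_doses) for v in variants)
    if total == 0:
        return 0.0
    return sum(v.n_missing() for v in variants) / total


def estimate_control_carriers(variants: list[VariantRecord], control_n: int) -> int:
    """Summed control allele counts over qualifying variants, capped at control_n."""
    return min(sum(v.control_ac for v in variants), control_n)


def group_by_feature(
    variants: list[VariantRecord], features: list[FeatureSet]
) -> dict[str, list[VariantRecord]]:
    """Assign variants to every feature whose footprint contains their position."""
    index = IntervalIndex()
    for f in features:
        for iv in f.intervals:
            index.add(iv, f.id)
    grouped: dict[str, list[VariantRecord]] = {f.id: [] for f in features}
    for v in variants:
        for fid in index.query_point(v.chrom, v.pos - 1):
            grouped[fid].append(v)
    return grouped


# ---------------------------------------------------------------------------
# One-sided Fisher's exact test
# ---------------------------------------------------------------------------


def fisher_one_sided(a: int, b: int, c: int, d: int, midp: bool = False) -> float:
    """P(X >= a) for the 2x2 table [[a, b], [c, d]] with all margins fixed.

    Exact hypergeometric upper tail (enrichment of carriers in the case
    row), accumulated in log space.  With ``midp=True`` half the probability
    of the observed table is subtracted — the standard correction when the
    p-values feed a genomic-inflation diagnostic, where the discreteness of
    the exact test would otherwise read as deflation.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or v != int(v):
            raise ValidationError(f"count {name}={v} must be a non-negative integer")
    if a + b == 0 or c + d == 0:
        raise ValidationError("both rows of the 2x2 table must have positive totals")
    N, K, n = a + b + c + d, a + c, a + b
    kmax = min(n, K)
    if a > kmax:
        raise ValidationError("case carriers exceed the table margins")
    ks = np.arange(a, kmax + 1)
    logp = hypergeom.logpmf(ks, N, K, n)
    p = float(np.exp(logsumexp(logp)))
    if midp:
        p -= 0.5 * float(np.exp(logp[0]))
    return min(max(p, 0.0), 1.0)


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio of the carrier table; infinity when b*c == 0 with a*d > 0."""
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# Burden scan
# ---------------------------------------------------------------------------

BURDEN_COLUMNS = [
    "feature_id",
    "case_carriers",
    "case_n",
    "control_carriers",
    "control_n",
    "n_variants",
    "missing_rate",
    "p_one_sided",
    "odds_ratio",
    "bonferroni_alpha",
    "significant",
    "untested",
]


def burden_scan(
    features: list[FeatureSet],
    case_variants: list[VariantRecord],
    control_variants: list[VariantRecord],
    case_n: int,
    control_n: int,
    alpha: float = 0.05,
    control_mode: str = "summary",
    midp: bool = False,
) -> pd.DataFrame:
    """One burden test per feature under the dominant model.

    ``control_mode='summary'`` sums control AC over qualifying variants
    (capped at control_n); ``'genotyped'`` counts carrier samples from the
    control records' genotype doses.  Features with no tested variant are
    reported with p = 1 and flagged ``untested``.  The Bonferroni threshold
    is alpha divided by the number of features tested in this run.
    """
    if control_mode not in ("summary", "genotyped"):
        raise ValidationError(f"unknown control_mode {control_mode!r}")
    case_groups = group_by_feature(case_variants, features)
    control_groups = group_by_feature(control_variants, features)
    n_features = len(features)
    if n_features == 0:
        raise ValidationError("no features to test")
    bonferroni_alpha = alpha / n_features
    rows = []
    for f in sorted(features, key=lambda f: f.id):
        cvs = case_groups[f.id]
        tvs = control_groups[f.id]
        a = min(count_case_carriers(cvs), case_n)
        if control_mode == "summary":
            c = estimate_control_carriers(tvs, control_n)
        else:
            c = min(count_case_carriers(tvs), control_n)
        untested = len(cvs) + len(tvs) == 0
        if untested:
            p = 1.0
        else:
            p = fisher_one_sided(a, case_n - a, c, control_n - c, midp=midp)
        rows.append(
            {
                "feature_id": f.id,
                "case_carriers": a,
                "case_n": case_n,
                "control_carriers": c,
                "control_n": control_n,
                "n_variants": len(cvs),
                "missing_rate": carrier_missing_rate(cvs),
                "p_one_sided": p,
                "odds_ratio": odds_ratio(a, case_n - a, c, control_n - c),
                "bonferroni_alpha": bonferroni_alpha,
                "significant": (not untested) and p < bonferroni_alpha,
                "untested": untested,
            }
        )
    df = pd.DataFrame(rows, columns=BURDEN_COLUMNS)
    return df.sort_values(
        ["p_one_sided", "feature_id"], kind="mergesort"
    ).reset_index(drop=True)


def qq_table(p_values) -> pd.DataFrame:
    """Observed vs expected -log10 p for a QQ plot, sorted most significant first."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = len(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {
            "observed_neglog10p": -np.log10(np.clip(p, 1e-300, 1.0)),
            "expected_neglog10p": -np.log10(expected),
        }
    )


# ---------------------------------------------------------------------------
# Genomic inflation at the 95th percentile
# ---------------------------------------------------------------------------


def lambda95(p_values) -> float:
    """Inflation factor at the 95th percentile of chi-square-transformed p-values.

    Each p is mapped to the 1-df chi-square quantile Q(1 - p); lambda95 is
    the empirical 95th percentile (linear interpolation) divided by the
    chi-square 95th percentile 3.841459.  Requires at least 20 p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 20:
        raise ValidationError(f"lambda95 needs >= 20 p-values, got {p.size}")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values outside [0, 1]")
    if np.any(p == 0):
        warnings.warn("p = 0 clipped to the smallest positive float", stacklevel=2)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    x = chi2.isf(p, df=1)
    return float(np.percentile(x, 95.0) / CHI2_1DF_95)


@dataclass
class CalibrationResult:
    """Outcome of the quality-tranche inflation sweep."""

    tranche_grid: list[float]
    lambda95_by_tranche: dict[float, float]
    chosen_tranche: float | None
    tolerance_band: tuple[float, float]
    diagnostic: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tranche": list(self.lambda95_by_tranche),
                "lambda95": list(self.lambda95_by_tranche.values()),
                "chosen": [t == self.chosen_tranche for t in self.lambda95_by_tranche],
            }
        )


def calibration_sweep(
    case_variants: list[VariantRecord],
    control_variants: list[VariantRecord],
    features: list[FeatureSet],
    case_n: int,
    control_n: int,
    tranche_grid=(0.90, 0.95, 1.0),
    mode: str = "coding",
    tolerance: tuple[float, float] = (0.95, 1.05),
    control_mode: str = "summary",
) -> CalibrationResult:
    """Pick the largest quality tranche whose benign-burden lambda95 is in tolerance.

    For each grid value q the case variants are thresholded at the (1 - q)
    quantile of their site-quality metric, a benign burden scan is run
    against the (untranched) control cohort, and lambda95 is computed from
    the mid-p values of tested features.  Ties break toward more data
    (largest q).
    """
    quals = np.array([v.qual_metric for v in case_variants], dtype=float)
    if quals.size == 0:
        raise ValidationError("no case variants to calibrate on")
    control_benign = select_benign(control_variants, mode=mode)
    lambdas: dict[float, float] = {}
    for q in sorted(tranche_grid):
        cut = np.quantile(quals, 1.0 - q)
        kept = [v for v in case_variants if v.qual_metric >= cut]
        case_benign = select_benign(kept, mode=mode)
        scan = burden_scan(
            features,
            case_benign,
            control_benign,
            case_n,
            control_n,
            control_mode=control_mode,
            midp=True,
        )
        tested = scan.loc[~scan["untested"], "p_one_sided"]
        lambdas[q] = lambda95(tested.to_numpy())
    in_tol = [q for q, lam in lambdas.items() if tolerance[0] <= lam <= tolerance[1]]
    chosen = max(in_tol) if in_tol else None
    diagnostic = (
        ""
        if chosen is not None
        else f"no tranche in tolerance {tolerance}; lambda95 by tranche: {lambdas}"
    )
    return CalibrationResult(sorted(tranche_grid), lambdas, chosen, tolerance, diagnostic)


def apply_tranche(
    variants: list[VariantRecord], tranche: float
) -> list[VariantRecord]:
    """Keep the top ``tranche`` fraction of variants by site quality."""
    quals = np.array([v.qual_metric for v in variants], dtype=float)
    cut = np.quantile(quals, 1.0 - tranche)
    return [v for v in variants if v.qual_metric >= cut]


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------


def mutations_per_mb(
    samples: list[str],
    variants: list[VariantRecord],
    class_intervals: dict[str, list[GenomicInterval]],
    coding_class: str = "coding_gene",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample, per-class mutation rates and t-tests against the coding class.

    Returns (summary, per_sample) where summary has mean/sd rate per class
    and the BH-adjusted p of a two-sample t-test of that class's per-sample
    rates against the coding class.
    """
    lengths = {
        cls: sum(iv.length for iv in ivs) for cls, ivs in class_intervals.items()
    }
    for cls, L in lengths.items():
        if L <= 0:
            raise ValidationError(f"segment class {cls} has zero total length")
    index = IntervalIndex()
    for cls, ivs in class_intervals.items():
        for iv in ivs:
            index.add(iv, cls)
    counts = {cls: np.zeros(len(samples)) for cls in class_intervals}
    for v in variants:
        hit_classes = set(index.query_point(v.chrom, v.pos - 1))
        if not hit_classes:
            continue
        mask = v.carriers()
        for cls in hit_classes:
            counts[cls][: len(mask)] += mask
    per_sample = pd.DataFrame(
        {cls: counts[cls] / (lengths[cls] / 1e6) for cls in class_intervals},
        index=samples,
    )
    rows = []
    other = [c for c in class_intervals if c != coding_class]
    pvals = []
    for cls in other:
        x, y = per_sample[cls].to_numpy(), per_sample[coding_class].to_numpy()
        if np.allclose(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = ttest_ind(x, y, equal_var=True)
        pvals.append(p)
        rows.append({"segment_class": cls, "t_vs_coding": t, "p_vs_coding": p})
    tests = pd.DataFrame(rows, columns=["segment_class", "t_vs_coding", "p_vs_coding"])
    tests["q_vs_coding"] = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    summary = pd.DataFrame(
        {
            "segment_class": list(class_intervals),
            "length_mb": [lengths[c] / 1e6 for c in class_intervals],
            "rate_mean": [per_sample[c].mean() for c in class_intervals],
            "rate_sd": [per_sample[c].std(ddof=1) for c in class_intervals],
        }
    ).merge(tests, on="segment_class", how="left")
    return summary, per_sample


def variant_sharing_summary(
    variants: list[VariantRecord],
) -> tuple[float, dict[int, int]]:
    """Fraction of observed variants carried by at most one case, plus histogram.

    Only variants carried by at least one case enter the denominator (a
    variant nobody carries is unobserved).
    """
    hist: dict[int, int] = {}
    for v in variants:
        k = int(v.carriers().sum())
        hist[k] = hist.get(k, 0) + 1
    observed = {k: n for k, n in hist.items() if k >= 1}
    total = sum(observed.values())
    if total == 0:
        return 0.0, hist
    singletons = observed.get(1, 0)
    return singletons / total, dict(sorted(hist.items()))
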