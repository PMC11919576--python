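"""Synthetic case/control cohort generator.

Emulates the statistical structure the downstream analyses assume — per-gene
rare-variant carrier rates with designated risk genes, gnomAD-style summary
allele counts, low-quality genotyping artifacts confined to a quality
tranche, dual-caller CNV calls with boundary jitter and FP/FN noise, and
beta-binomial methylomes with planted hypomethylated blocks and
case-hypomethylated regions — on a small two-chromosome toy genome so the
full pipeline runs at desk scale.

All randomness flows from one root seed through named substreams (one per
logical output), so regenerating a single component is stable against
changes elsewhere.  Identical config + seed reproduces every output
bit-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cnv import CnvCall
from .errors import ValidationError
from .intervals import FeatureSet, GenomicInterval
from .io import (
    MISSING_DOSE,
    MethylomeSample,
    VariantRecord,
    write_bed,
    write_bismark_cov,
    write_case_vcf,
    write_control_vcf,
    write_gmt,
)

SEGMENT_CLASSES = (
    "promoter",
    "enhancer",
    "five_prime_utr",
    "three_prime_utr",
    "lncRNA",
    "lncRNA_promoter",
    "miRNA",
    "smallRNA",
)

# Per-class mutation densities (mutations per Mb per sample) used for the
# common-variant background; coding slightly below the regulatory classes,
# small-RNA classes highest, as seen in whole-genome cohorts.
DEFAULT_CLASS_MUT_RATES = {
    "coding_gene": 14.70,
    "promoter": 15.15,
    "enhancer": 16.00,
    "five_prime_utr": 15.50,
    "three_prime_utr": 15.80,
    "lncRNA": 16.47,
    "lncRNA_promoter": 15.90,
    "miRNA": 19.83,
    "smallRNA": 20.46,
}


@dataclass(frozen=True)
class RiskGene:
    gene_id: str
    case_rate: float
    control_rate: float


@dataclass(frozen=True)
class CnvTruthRegion:
    region_id: str
    interval: GenomicInterval
    cnv_type: str  # DEL or DUP
    case_frequency: int
    control_frequency: int


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    Cohort sizes default to 51 cases with genotypes, 350 in-house genotyped
    controls, 9197 summary-only controls, and 48/45 case/control methylomes.
    """

    seed: int = 0
    # cohort sizes
    n_case: int = 51
    n_control_inhouse: int = 350
    n_control_summary: int = 9197
    n_case_meth: int = 48
    n_control_meth: int = 45
    # toy genome
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    tile_size: int = 10_000
    n_genes: int = 1000
    n_segments: int = 1000
    # rare-variant burden structure (per-feature per-sample carrier rates)
    background_carrier_rate: float = 0.01
    benign_carrier_rate: float = 0.10
    noncoding_carrier_rate: float = 0.01
    noncoding_benign_rate: float = 0.10
    sites_per_gene: int = 3
    benign_sites_per_gene: int = 2
    risk_genes: list[RiskGene] = field(
        default_factory=lambda: [
            RiskGene("g0010", 0.30, 0.01),
            RiskGene("g0310", 0.30, 0.01),
            RiskGene("g0610", 0.30, 0.01),
        ]
    )
    # genotyping artifacts (case-only synonymous sites at low site quality)
    # The artifact stratum is sized to the tranche being calibrated: with one
    # artifact site in ~a third of genes, artifact sites make up ~4-5% of case
    # sites, so the 95% quality tranche separates them almost exactly — the
    # scenario in which tranche calibration is the right remedy.
    inject_artifacts: bool = False
    artifact_quality_quantile: float = 0.05
    artifact_gene_fraction: float = 0.33
    artifact_carrier_rate: float = 0.25
    qual_mean: float = 25.0
    qual_sd: float = 5.0
    # common-variant background for mutation-rate tables
    class_mut_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MUT_RATES)
    )
    common_site_carrier_freq: float = 0.3
    # coverage masks
    mask_dropout_rate: float = 0.0
    # CNV caller noise
    cnv_truth: list[CnvTruthRegion] | None = None
    cnv_jitter_sd: float = 50.0
    cnv_fp_rate: float = 1.0
    cnv_fn_rate: float = 0.1
    # methylome
    meth_background_beta: float = 0.85
    meth_hmr_beta: float = 0.10
    meth_diff_base_beta: float = 0.25
    meth_effect: float = -0.20
    meth_hypo_fraction: float = 0.90
    meth_overdispersion: float = 0.02
    meth_region_sd: float = 0.05
    meth_depth_mean: float = 30.0
    n_diff_regions: int = 100
    n_recurrent_hmr: int = 60
    n_private_hmr: int = 200
    n_background_regions: int = 500
    cpgs_per_region: int = 20
    cpg_spacing: int = 40

    def __post_init__(self) -> None:
        for name in (
            "background_carrier_rate",
            "benign_carrier_rate",
            "noncoding_carrier_rate",
            "noncoding_benign_rate",
            "artifact_gene_fraction",
            "artifact_carrier_rate",
            "mask_dropout_rate",
            "cnv_fn_rate",
            "meth_hypo_fraction",
            "meth_overdispersion",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0,1]")
        for name in ("n_case", "n_control_inhouse", "n_control_summary", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_tiles < max(self.n_genes, self.n_segments):
            raise ValidationError("toy genome too small for the requested feature counts")

    @property
    def n_tiles(self) -> int:
        return sum(L // self.tile_size for L in self.chrom_lengths.values())


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: one generator per logical output, derived from the root seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode()) & 0x7FFFFFFF])


# ---------------------------------------------------------------------------
# Toy genome layout
# ---------------------------------------------------------------------------


@dataclass
class ToyGenome:
    """Deterministic feature layout: one gene per 10 kb tile.

    Tile anatomy (offsets within the tile): promoter [200,1000), gene body
    [1000,3000) with exons [1000,1500) and [2500,3000) flanking an intron,
    one regulatory segment [4000,5000) (class round-robin), and a
    low-complexity stretch [8000,8200) on every fifth tile.
    """

    config: SimulationConfig
    tiles: list[tuple[str, int]] = field(init=False)  # (chrom, tile start)
    genes: list[FeatureSet] = field(init=False)
    gene_parts: list[tuple[GenomicInterval, str, str]] = field(init=False)
    segments: list[FeatureSet] = field(init=False)
    lcr: list[GenomicInterval] = field(init=False)

    def __post_init__(self) -> None:
        cfg = self.config
        self.tiles = []
        for chrom, L in cfg.chrom_lengths.items():
            for k in range(L // cfg.tile_size):
                self.tiles.append((chrom, k * cfg.tile_size))
        self.genes = []
        self.gene_parts = []
        for g in range(cfg.n_genes):
            chrom, t0 = self.tiles[g]
            name = f"g{g:04d}"
            body = GenomicInterval(chrom, t0 + 1000, t0 + 3000)
            self.genes.append(FeatureSet(name, name, "coding_gene", [body]))
            self.gene_parts.extend(
                [
                    (GenomicInterval(chrom, t0 + 200, t0 + 1000), name, "promoter"),
                    (GenomicInterval(chrom, t0 + 1000, t0 + 1500), name, "exon"),
                    (GenomicInterval(chrom, t0 + 1500, t0 + 2500), name, "intron"),
                    (GenomicInterval(chrom, t0 + 2500, t0 + 3000), name, "exon"),
                ]
            )
        self.segments = []
        for s in range(cfg.n_segments):
            chrom, t0 = self.tiles[s]
            cls = SEGMENT_CLASSES[s % len(SEGMENT_CLASSES)]
            name = f"seg{s:04d}"
            self.segments.append(
                FeatureSet(name, name, cls, [GenomicInterval(chrom, t0 + 4000, t0 + 5000)])
            )
        self.lcr = [
            GenomicInterval(chrom, t0 + 8000, t0 + 8200)
            for i, (chrom, t0) in enumerate(self.tiles)
            if i % 5 == 0
        ]

    def exon_positions(self, gene_index: int) -> tuple[str, int, int]:
        chrom, t0 = self.tiles[gene_index]
        return chrom, t0 + 1000, t0 + 3000

    def class_intervals(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {"coding_gene": []}
        for g in self.genes:
            out["coding_gene"].extend(g.intervals)
        for seg in self.segments:
            out.setdefault(seg.feature_class, []).extend(seg.intervals)
        return out


# ---------------------------------------------------------------------------
# Burden cohort
# ---------------------------------------------------------------------------


@dataclass
class BurdenCohort:
    config: SimulationConfig
    genome: ToyGenome
    case_samples: list[str]
    case_records: list[VariantRecord]
    inhouse_samples: list[str]
    inhouse_records: list[VariantRecord]
    summary_records: list[VariantRecord]
    case_mask: pd.DataFrame  # chrom, start, end, fraction
    control_mask: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_segments: pd.DataFrame


_BASES = np.array(list("ACGT"))


def _draw_doses(rng: np.random.Generator, n: int, rate: float, hom_fraction: float) -> np.ndarray:
    """Per-sample doses for one site: carrier w.p. rate, hom w.p. hom_fraction|carrier."""
    carrier = rng.random(n) < rate
    hom = rng.random(n) < hom_fraction
    return np.where(carrier, np.where(hom, 2, 1), 0).astype(np.int8)


def _site_positions(rng: np.random.Generator, lo: int, hi: int, n: int) -> np.ndarray:
    pos = rng.choice(np.arange(lo, hi), size=n, replace=False)
    return np.sort(pos)


def _feature_sites(
    rng: np.random.Generator,
    cohort_rngs: dict[str, np.random.Generator],
    chrom: str,
    lo: int,
    hi: int,
    n_sites: int,
    consequence_pool: Sequence[str],
    af_lo: float,
    af_hi: float,
    flags: tuple[bool, bool, bool],
    gene_rate_case: float,
    gene_rate_inhouse: float,
    gene_rate_summary: float,
    n_case: int,
    n_inhouse: int,
    n_summary: int,
    qual: np.ndarray,
    case_only: bool = False,
) -> tuple[list[VariantRecord], list[VariantRecord], list[VariantRecord], np.ndarray]:
    """Simulate one feature's sites for all three cohorts.

    The per-feature carrier rate is split evenly over its sites.  Returns the
    case-genotyped, in-house-genotyped and summary records plus the case
    carrier mask (any site)."""
    positions = _site_positions(rng, lo, hi, n_sites)
    # carriers are drawn per feature per sample at the configured rate, then
    # each carrier is assigned to one of the feature's sites; this keeps the
    # per-feature carrier probability exactly at the configured value
    def genotype_matrix(rng_c, n: int, rate: float) -> np.ndarray:
        doses = np.zeros((n_sites, n), dtype=np.int8)
        carrier = rng_c.random(n) < rate
        site_of = rng_c.integers(0, n_sites, size=n)
        hom = rng_c.random(n) < 0.05
        idx = np.flatnonzero(carrier)
        doses[site_of[idx], idx] = np.where(hom[idx], 2, 1)
        return doses

    doses_case = genotype_matrix(cohort_rngs["case"], n_case, gene_rate_case)
    if not case_only:
        doses_inh = genotype_matrix(cohort_rngs["inhouse"], n_inhouse, gene_rate_inhouse)
        site_rate_sum = gene_rate_summary / n_sites
        acs = cohort_rngs["summary"].binomial(n_summary, site_rate_sum, size=n_sites)
    else:
        doses_inh = np.zeros((n_sites, n_inhouse), dtype=np.int8)
        acs = np.zeros(n_sites, dtype=int)
    case_rec, inh_rec, sum_rec = [], [], []
    for i, pos0 in enumerate(positions):
        ref, alt_off = _BASES[rng.integers(4)], rng.integers(1, 4)
        alt = _BASES[(np.where(_BASES == ref)[0][0] + alt_off) % 4]
        csq = consequence_pool[rng.integers(len(consequence_pool))]
        af = float(rng.uniform(af_lo, af_hi))
        common = dict(
            chrom=chrom,
            pos=int(pos0) + 1,  # VCF 1-based
            ref=str(ref),
            alt=str(alt),
            pop_af=af,
            consequence=csq,
            deleterious_flags=flags,
            qual_metric=float(qual[i]),
        )
        case_rec.append(
            VariantRecord(case_doses=tuple(int(d) for d in doses_case[i]), **common)
        )
        inh_rec.append(
            VariantRecord(case_doses=tuple(int(d) for d in doses_inh[i]), **common)
        )
        sum_rec.append(
            VariantRecord(control_ac=int(acs[i]), control_an=2 * n_summary, **common)
        )
    case_carrier = (doses_case >= 1).any(axis=0)
    return case_rec, inh_rec, sum_rec, case_carrier


def simulate_burden_cohort(config: SimulationConfig) -> BurdenCohort:
    """Generate the full genotype layer of the synthetic cohort.

    Per gene: qualifying coding sites (missense/lof, AF <= 0.01) at the
    background carrier rate (risk genes elevated in cases only), plus rare
    synonymous sites for inflation calibration.  Per regulatory segment:
    rare deleterious and rare benign noncoding sites.  Optionally, case-only
    synonymous artifact sites whose quality metric lies below the configured
    quality quantile.  Common variants at per-class densities supply the
    mutation-rate background.  Summary controls are never materialised as
    genotypes; only AC/AN are drawn.
    """
    cfg = config
    genome = ToyGenome(cfg)
    case_samples = [f"case{j:03d}" for j in range(cfg.n_case)]
    inhouse_samples = [f"ctrl{j:03d}" for j in range(cfg.n_control_inhouse)]
    risk = {r.gene_id: r for r in cfg.risk_genes}
    layout_rng = _rng(cfg.seed, "burden-layout")
    cohort_rngs = {
        "case": _rng(cfg.seed, "burden-case"),
        "inhouse": _rng(cfg.seed, "burden-inhouse"),
        "summary": _rng(cfg.seed, "burden-summary"),
    }
    qual_rng = _rng(cfg.seed, "burden-qual")

    case_records: list[VariantRecord] = []
    inhouse_records: list[VariantRecord] = []
    summary_records: list[VariantRecord] = []
    truth_gene_rows = []

    def genuine_qual(n: int) -> np.ndarray:
        return np.maximum(qual_rng.normal(cfg.qual_mean, cfg.qual_sd, n), 1.0)

    # --- genes: qualifying coding + benign synonymous sites
    for g, gene in enumerate(genome.genes):
        chrom, lo, hi = genome.exon_positions(g)
        r = risk.get(gene.id)
        case_rate = r.case_rate if r else cfg.background_carrier_rate
        ctrl_rate = r.control_rate if r else cfg.background_carrier_rate
        c_rec, i_rec, s_rec, carriers = _feature_sites(
            layout_rng, cohort_rngs, chrom, lo, lo + 500, cfg.sites_per_gene,
            ("missense", "missense", "lof"), 5e-5, 0.01, (True, True, True),
            case_rate, ctrl_rate, ctrl_rate,
            cfg.n_case, cfg.n_control_inhouse, cfg.n_control_summary,
            genuine_qual(cfg.sites_per_gene),
        )
        case_records += c_rec
        inhouse_records += i_rec
        summary_records += s_rec
        c_rec, i_rec, s_rec, _ = _feature_sites(
            layout_rng, cohort_rngs, chrom, hi - 500, hi, cfg.benign_sites_per_gene,
            ("synonymous",), 1e-4, 0.01, (False, False, False),
            cfg.benign_carrier_rate, cfg.benign_carrier_rate, cfg.benign_carrier_rate,
            cfg.n_case, cfg.n_control_inhouse, cfg.n_control_summary,
            genuine_qual(cfg.benign_sites_per_gene),
        )
        case_records += c_rec
        inhouse_records += i_rec
        summary_records += s_rec
        truth_gene_rows.append(
            {
                "feature_id": gene.id,
                "kind": "risk" if r else "background",
                "case_rate": case_rate,
                "control_rate": ctrl_rate,
                "case_carriers_true": int(carriers.sum()),
            }
        )

    # --- regulatory segments: rare deleterious + rare benign noncoding sites
    truth_seg_rows = []
    for s, seg in enumerate(genome.segments):
        iv = seg.intervals[0]
        c_rec, i_rec, s_rec, carriers = _feature_sites(
            layout_rng, cohort_rngs, iv.chrom, iv.start, iv.start + iv.length // 2, 1,
            ("noncoding",), 1e-5, 0.001, (True, True, True),
            cfg.noncoding_carrier_rate, cfg.noncoding_carrier_rate, cfg.noncoding_carrier_rate,
            cfg.n_case, cfg.n_control_inhouse, cfg.n_control_summary,
            genuine_qual(1),
        )
        case_records += c_rec
        inhouse_records += i_rec
        summary_records += s_rec
        c_rec, i_rec, s_rec, _ = _feature_sites(
            layout_rng, cohort_rngs, iv.chrom, iv.start + iv.length // 2, iv.end, 1,
            ("noncoding",), 1e-5, 0.001, (False, False, False),
            cfg.noncoding_benign_rate, cfg.noncoding_benign_rate, cfg.noncoding_benign_rate,
            cfg.n_case, cfg.n_control_inhouse, cfg.n_control_summary,
            genuine_qual(1),
        )
        case_records += c_rec
        inhouse_records += i_rec
        summary_records += s_rec
        truth_seg_rows.append(
            {
                "feature_id": seg.id,
                "kind": "background",
                "case_rate": cfg.noncoding_carrier_rate,
                "control_rate": cfg.noncoding_carrier_rate,
                "case_carriers_true": int(carriers.sum()),
            }
        )

    # --- artifact sites: case-only, synonymous, low quality
    if cfg.inject_artifacts:
        art_rng = _rng(cfg.seed, "burden-artifact")
        n_art = int(round(cfg.artifact_gene_fraction * cfg.n_genes))
        art_genes = sorted(art_rng.choice(cfg.n_genes, size=n_art, replace=False))
        for g in art_genes:
            chrom, lo, hi = genome.exon_positions(g)
            # quality placed well below the genuine lower tail so the
            # configured tranche cleanly separates artifact from genuine calls
            qual = art_rng.uniform(3.0, 12.0, 1)
            c_rec, i_rec, s_rec, _ = _feature_sites(
                layout_rng, cohort_rngs, chrom, hi - 1000, hi - 500, 1,
                ("synonymous",), 1e-4, 0.01, (False, False, False),
                cfg.artifact_carrier_rate, 0.0, 0.0,
                cfg.n_case, cfg.n_control_inhouse, cfg.n_control_summary,
                qual, case_only=True,
            )
            case_records += c_rec
            inhouse_records += i_rec
            summary_records += s_rec
            truth_gene_rows.append(
                {
                    "feature_id": f"g{g:04d}:artifact",
                    "kind": "artifact",
                    "case_rate": cfg.artifact_carrier_rate,
                    "control_rate": 0.0,
                    "case_carriers_true": -1,
                }
            )

    # --- common variants at per-class densities (mutation-rate background)
    common_rng = _rng(cfg.seed, "burden-common")
    f = cfg.common_site_carrier_freq
    class_ivs = genome.class_intervals()
    for cls in sorted(class_ivs):
        rate = cfg.class_mut_rates.get(cls, 0.0)
        if rate <= 0:
            continue
        ivs = class_ivs[cls]
        total_len = sum(iv.length for iv in ivs)
        n_sites = int(round(rate * total_len / 1e6 / f))
        if n_sites == 0:
            continue
        # sample positions uniformly over the class footprint
        offs = np.sort(common_rng.choice(total_len, size=min(n_sites, total_len), replace=False))
        bounds = np.cumsum([iv.length for iv in ivs])
        idx = np.searchsorted(bounds, offs, side="right")
        for off, i in zip(offs, idx):
            iv = ivs[i]
            pos0 = iv.start + int(off - (bounds[i - 1] if i else 0))
            ref = _BASES[common_rng.integers(4)]
            alt = _BASES[(np.where(_BASES == ref)[0][0] + common_rng.integers(1, 4)) % 4]
            csq = "synonymous" if cls == "coding_gene" else "noncoding"
            doses = _draw_doses(cohort_rngs["case"], cfg.n_case, f, 0.25)
            case_records.append(
                VariantRecord(
                    chrom=iv.chrom, pos=pos0 + 1, ref=str(ref), alt=str(alt),
                    pop_af=f, consequence=csq, deleterious_flags=(False, False, False),
                    qual_metric=float(genuine_qual(1)[0]),
                    case_doses=tuple(int(d) for d in doses),
                )
            )

    # --- coverage masks (fraction of samples covered per tile, both cohorts)
    mask_rng = _rng(cfg.seed, "burden-mask")
    rows_case, rows_ctrl = [], []
    for chrom, t0 in genome.tiles:
        fc = 0.90 + 0.099 * mask_rng.beta(5, 2)
        ft = 0.90 + 0.099 * mask_rng.beta(5, 2)
        if cfg.mask_dropout_rate > 0 and mask_rng.random() < cfg.mask_dropout_rate:
            if mask_rng.random() < 0.5:
                fc = mask_rng.uniform(0.3, 0.89)
            else:
                ft = mask_rng.uniform(0.3, 0.89)
        rows_case.append((chrom, t0, t0 + cfg.tile_size, round(fc, 4)))
        rows_ctrl.append((chrom, t0, t0 + cfg.tile_size, round(ft, 4)))
    cols = ["chrom", "start", "end", "fraction"]
    return BurdenCohort(
        config=cfg,
        genome=genome,
        case_samples=case_samples,
        case_records=case_records,
        inhouse_samples=inhouse_samples,
        inhouse_records=inhouse_records,
        summary_records=summary_records,
        case_mask=pd.DataFrame(rows_case, columns=cols),
        control_mask=pd.DataFrame(rows_ctrl, columns=cols),
        truth_genes=pd.DataFrame(truth_gene_rows),
        truth_segments=pd.DataFrame(truth_seg_rows),
    )


# ---------------------------------------------------------------------------
# CNV call sets
# ---------------------------------------------------------------------------


def default_cnv_truth(config: SimulationConfig) -> list[CnvTruthRegion]:
    """Twenty 5-kb truth regions spread across the toy genome.

    Patient frequencies span the range seen in recurrent-CNV tables (a few
    highly recurrent regions down to a frequency of 3); roughly three
    quarters are deletions.
    """
    freqs = [39, 19, 12, 10, 8, 8, 6, 6, 5, 5, 4, 4, 4, 4, 3, 3, 3, 3, 3, 3]
    genome = ToyGenome(config)
    regions = []
    step = max(1, config.n_tiles // (len(freqs) + 1))
    for i, fq in enumerate(freqs):
        chrom, t0 = genome.tiles[(i + 1) * step - 1]
        cnv_type = "DEL" if i % 4 != 3 else "DUP"
        regions.append(
            CnvTruthRegion(
                region_id=f"cnv{i:02d}",
                interval=GenomicInterval(chrom, t0 + 2000, t0 + 7000),
                cnv_type=cnv_type,
                case_frequency=min(fq, config.n_case),
                control_frequency=[0, 1, 0, 2, 0, 3, 0, 0, 1, 0][i % 10],
            )
        )
    return regions


@dataclass
class CnvSim:
    config: SimulationConfig
    truth: list[CnvTruthRegion]
    truth_samples: dict[str, list[str]]  # region_id -> supporting case samples
    calls_a: list[CnvCall]
    calls_b: list[CnvCall]


def _jitter_interval(
    rng: np.random.Generator, iv: GenomicInterval, sd: float
) -> GenomicInterval:
    """Add independent Gaussian jitter to both boundaries; resample degenerate draws."""
    for _ in range(100):
        s = int(round(iv.start + rng.normal(0.0, sd))) if sd > 0 else iv.start
        e = int(round(iv.end + rng.normal(0.0, sd))) if sd > 0 else iv.end
        if e > s and s >= 0:
            return GenomicInterval(iv.chrom, s, e)
    raise ValidationError(f"jitter sd {sd} repeatedly produced empty intervals for {iv}")


def simulate_cnv_callsets(config: SimulationConfig) -> CnvSim:
    """Emit two noisy caller views of a shared per-sample CNV truth.

    Each carrier sample's true region appears in each caller independently
    with probability 1 - FN, boundaries jittered with the configured sd;
    each caller additionally emits Poisson false-positive calls per sample.
    """
    cfg = config
    truth = cfg.cnv_truth if cfg.cnv_truth is not None else default_cnv_truth(cfg)
    rng = _rng(cfg.seed, "cnv")
    samples = [f"case{j:03d}" for j in range(cfg.n_case)]
    truth_samples: dict[str, list[str]] = {}
    calls_a: list[CnvCall] = []
    calls_b: list[CnvCall] = []
    chroms = list(cfg.chrom_lengths)
    for region in truth:
        carriers = sorted(rng.choice(cfg.n_case, size=region.case_frequency, replace=False))
        truth_samples[region.region_id] = [samples[j] for j in carriers]
        for j in carriers:
            for caller, sink in (("A", calls_a), ("B", calls_b)):
                if rng.random() < cfg.cnv_fn_rate:
                    continue
                sink.append(
                    CnvCall(
                        sample_id=samples[j],
                        interval=_jitter_interval(rng, region.interval, cfg.cnv_jitter_sd),
                        cnv_type=region.cnv_type,
                        caller=caller,
                    )
                )
    # false positives, independent between callers
    for j, sample in enumerate(samples):
        for caller, sink in (("A", calls_a), ("B", calls_b)):
            for _ in range(rng.poisson(cfg.cnv_fp_rate)):
                chrom = chroms[rng.integers(len(chroms))]
                L = cfg.chrom_lengths[chrom]
                length = int(rng.integers(1000, 10000))
                start = int(rng.integers(0, L - length))
                sink.append(
                    CnvCall(
                        sample_id=sample,
                        interval=GenomicInterval(chrom, start, start + length),
                        cnv_type="DEL" if rng.random() < 0.75 else "DUP",
                        caller=caller,
                    )
                )
    key = lambda c: (c.sample_id, c.interval.chrom, c.interval.start, c.interval.end)
    calls_a.sort(key=key)
    calls_b.sort(key=key)
    return CnvSim(cfg, truth, truth_samples, calls_a, calls_b)


# ---------------------------------------------------------------------------
# Methylomes
# ---------------------------------------------------------------------------


@dataclass
class MethylomeSim:
    config: SimulationConfig
    genome: ToyGenome
    case_samples: list[MethylomeSample]
    control_samples: list[MethylomeSample]
    truth_hmrs: pd.DataFrame  # planted recurrent HMR blocks
    truth_diff: pd.DataFrame  # planted differential regions


def _beta_binomial(
    rng: np.random.Generator, depth: np.ndarray, mean: np.ndarray, rho: float
) -> np.ndarray:
    """Methylated counts with mean ``mean`` and intra-CpG overdispersion rho.

    rho = 0 degenerates to the plain binomial."""
    if rho <= 0:
        return rng.binomial(depth, mean)
    conc = 1.0 / rho - 1.0
    p = rng.beta(np.maximum(mean * conc, 1e-6), np.maximum((1.0 - mean) * conc, 1e-6))
    return rng.binomial(depth, p)


def simulate_methylomes(config: SimulationConfig) -> MethylomeSim:
    """Generate per-CpG count methylomes for cases and controls.

    Regions of ``cpgs_per_region`` CpGs sit on successive gene promoters of
    the toy genome.  Background regions are highly methylated; planted
    recurrent-HMR blocks drop to the HMR mean in a per-region fraction of
    samples; planted differential regions sit at an intermediate mean in
    controls with the case mean shifted by the configured effect (hypo in
    the configured fraction of regions).  Per-CpG counts are beta-binomial
    around a per-sample-region mean with a Gaussian region-level random
    effect.
    """
    cfg = config
    genome = ToyGenome(cfg)
    rng = _rng(cfg.seed, "methylome")
    n_reg = (
        cfg.n_background_regions + cfg.n_recurrent_hmr + cfg.n_diff_regions + cfg.n_private_hmr
    )
    if n_reg > len(genome.tiles):
        raise ValidationError("toy genome too small for the requested methylome regions")
    kinds = (
        ["background"] * cfg.n_background_regions
        + ["recurrent_hmr"] * cfg.n_recurrent_hmr
        + ["differential"] * cfg.n_diff_regions
        + ["private_hmr"] * cfg.n_private_hmr
    )
    order = rng.permutation(n_reg)  # interleave kinds across the genome
    kinds = [kinds[i] for i in order]

    n_case, n_ctrl = cfg.n_case_meth, cfg.n_control_meth
    n_samp = n_case + n_ctrl
    is_case = np.arange(n_samp) < n_case

    # per-region structural draws
    rec_presence = rng.uniform(0.05, 0.60, n_reg)  # used for recurrent blocks
    diff_sign = np.where(rng.random(n_reg) < cfg.meth_hypo_fraction, -1.0, 1.0)
    # per (sample, region) mean methylation
    means = np.full((n_samp, n_reg), cfg.meth_background_beta)
    hmr_rows, diff_rows = [], []
    for r, kind in enumerate(kinds):
        chrom, t0 = genome.tiles[r]
        start = t0 + 200
        end = start + (cfg.cpgs_per_region - 1) * cfg.cpg_spacing + 1
        gene = f"g{r:04d}" if r < cfg.n_genes else ""
        if kind == "recurrent_hmr":
            present = rng.random(n_samp) < rec_presence[r]
            means[present, r] = cfg.meth_hmr_beta
            hmr_rows.append(
                {
                    "region_id": f"hmr{r:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "presence": rec_presence[r],
                    "n_present": int(present.sum()),
                    "gene": gene,
                }
            )
        elif kind == "private_hmr":
            present = rng.random(n_samp) < 0.02
            means[present, r] = cfg.meth_hmr_beta
        elif kind == "differential":
            effect = diff_sign[r] * abs(cfg.meth_effect)
            means[~is_case, r] = cfg.meth_diff_base_beta
            means[is_case, r] = np.clip(cfg.meth_diff_base_beta + effect, 0.01, 0.99)
            diff_rows.append(
                {
                    "region_id": f"dmr{r:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "effect": effect,
                    "direction": "hypo" if effect < 0 else "hyper",
                    "gene": gene,
                }
            )
    # sample-region random effect, then expand to CpGs
    means = np.clip(means + rng.normal(0.0, cfg.meth_region_sd, means.shape), 0.01, 0.99)
    n_cpg = n_reg * cfg.cpgs_per_region
    cpg_means = np.repeat(means, cfg.cpgs_per_region, axis=1)
    depth = rng.poisson(cfg.meth_depth_mean, (n_samp, n_cpg))
    meth = _beta_binomial(rng, depth, cpg_means, cfg.meth_overdispersion)

    chrom_arr, pos_arr = [], []
    for r in range(n_reg):
        chrom, t0 = genome.tiles[r]
        base = t0 + 200
        for j in range(cfg.cpgs_per_region):
            chrom_arr.append(chrom)
            pos_arr.append(base + j * cfg.cpg_spacing + 1)  # 1-based on disk
    chrom_arr = np.array(chrom_arr)
    pos_arr = np.array(pos_arr)
    order_idx = np.lexsort((pos_arr, chrom_arr))

    def make_sample(i: int, name: str) -> MethylomeSample:
        df = pd.DataFrame(
            {
                "chrom": chrom_arr[order_idx],
                "pos": pos_arr[order_idx],
                "meth": meth[i, order_idx],
                "unmeth": depth[i, order_idx] - meth[i, order_idx],
            }
        )
        return MethylomeSample(name, df)

    cases = [make_sample(i, f"mcase{i:03d}") for i in range(n_case)]
    controls = [make_sample(n_case + i, f"mctrl{i:03d}") for i in range(n_ctrl)]
    return MethylomeSim(
        cfg,
        genome,
        cases,
        controls,
        truth_hmrs=pd.DataFrame(hmr_rows),
        truth_diff=pd.DataFrame(diff_rows),
    )


# ---------------------------------------------------------------------------
# Writers and toy gene sets
# ---------------------------------------------------------------------------


def simulate_genesets(
    config: SimulationConfig, n_sets: int = 30, set_size: int = 40
) -> dict[str, list[str]]:
    """Toy GMT: random gene sets plus one set enriched for planted DMR genes."""
    rng = _rng(config.seed, "genesets")
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    sets = {
        f"set{k:02d}": sorted(rng.choice(genes, size=set_size, replace=False).tolist())
        for k in range(n_sets)
    }
    sim = simulate_methylomes(config)
    planted = [g for g in sim.truth_diff["gene"].tolist() if g][: set_size // 2]
    filler = sorted(rng.choice(genes, size=set_size - len(planted), replace=False).tolist())
    sets["set_planted"] = sorted(set(planted + filler))
    return sets


def write_burden_cohort(cohort: BurdenCohort, outdir: str | Path) -> dict[str, Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "case_vcf": out / "case.vcf",
        "inhouse_vcf": out / "control_inhouse.vcf",
        "summary_vcf": out / "control_summary.vcf",
        "genes_bed": out / "genes.bed",
        "segments_bed": out / "segments.bed",
        "gene_parts_bed": out / "gene_parts.bed",
        "lcr_bed": out / "lcr.bed",
        "case_mask_bed": out / "mask_case.bed",
        "control_mask_bed": out / "mask_control.bed",
        "truth_genes": out / "truth_genes.tsv",
        "truth_segments": out / "truth_segments.tsv",
    }
    write_case_vcf(paths["case_vcf"], cohort.case_samples, cohort.case_records)
    write_case_vcf(paths["inhouse_vcf"], cohort.inhouse_samples, cohort.inhouse_records)
    write_control_vcf(paths["summary_vcf"], cohort.summary_records)
    write_bed(paths["genes_bed"], [(g.intervals[0], g.id) for g in cohort.genome.genes])
    write_bed(
        paths["segments_bed"],
        [(s.intervals[0], s.id, s.feature_class) for s in cohort.genome.segments],
    )
    write_bed(
        paths["gene_parts_bed"],
        [(iv, gene, part) for iv, gene, part in cohort.genome.gene_parts],
    )
    write_bed(paths["lcr_bed"], cohort.genome.lcr)
    cohort.case_mask.to_csv(paths["case_mask_bed"], sep="\t", header=False, index=False)
    cohort.control_mask.to_csv(paths["control_mask_bed"], sep="\t", header=False, index=False)
    cohort.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    cohort.truth_segments.to_csv(paths["truth_segments"], sep="\t", index=False)
    return paths


def write_cnv_callsets(sim: CnvSim, outdir: str | Path) -> dict[str, Path]:
    out = Path(outdir)
    for sub in ("caller_a", "caller_b"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    samples = sorted({c.sample_id for c in sim.calls_a + sim.calls_b} | set(sim.truth_samples and sum(sim.truth_samples.values(), [])))
    for sample in samples:
        for sub, calls in (("caller_a", sim.calls_a), ("caller_b", sim.calls_b)):
            rows = [
                (c.interval, c.cnv_type)
                for c in calls
                if c.sample_id == sample
            ]
            write_bed(out / sub / f"{sample}.bed", rows)
    truth = pd.DataFrame(
        [
            {
                "region_id": t.region_id,
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "cnv_type": t.cnv_type,
                "case_frequency": t.case_frequency,
                "control_frequency": t.control_frequency,
            }
            for t in sim.truth
        ]
    )
    truth_path = out / "truth_cnv.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"dir": out, "truth": truth_path}


def write_methylomes(sim: MethylomeSim, outdir: str | Path) -> dict[str, Path]:
    out = Path(outdir)
    (out / "case").mkdir(parents=True, exist_ok=True)
    (out / "control").mkdir(parents=True, exist_ok=True)
    for s in sim.case_samples:
        write_bismark_cov(out / "case" / f"{s.sample_id}.cov", s)
    for s in sim.control_samples:
        write_bismark_cov(out / "control" / f"{s.sample_id}.cov", s)
    sim.truth_hmrs.to_csv(out / "truth_hmrs.tsv", sep="\t", index=False)
    sim.truth_diff.to_csv(out / "truth_diff.tsv", sep="\t", index=False)
    return {"dir": out}
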