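"""Pipeline orchestration: configuration, provenance, stage dispatch.

Every emitted TSV carries a provenance header (``# key = value`` lines)
recording the package version, root seed and all thresholds of the run, so
an output file identifies the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, IcepipeError, ValidationError
from .intervals import GenomicInterval
from . import burden as bd
from . import cnv as cv
from . import methylome as me
from .io import (
    read_bed,
    read_bed_named,
    read_bismark_cov,
    read_case_vcf,
    read_control_sites,
    read_gmt,
    write_gmt,
)
from .simulate import (
    SimulationConfig,
    simulate_burden_cohort,
    simulate_cnv_callsets,
    simulate_genesets,
    simulate_methylomes,
    write_burden_cohort,
    write_cnv_callsets,
    write_methylomes,
)

log = logging.getLogger("icepipe")

STAGES = ("simulate", "burden", "cnv", "methylome")


class MissingInputError(IcepipeError):
    """A required input file is absent (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Paths, thresholds and the root seed of one pipeline run."""

    seed: int = 0
    outdir: str = "icepipe_out"
    # burden
    af_max_coding: float = 0.01
    af_max_noncoding: float = 0.001
    required_fraction: float = 0.9
    tranche_grid: tuple[float, ...] = (0.90, 0.95, 1.0)
    alpha: float = 0.05
    burden_mode: str = "coding"
    # cnv
    min_reciprocal: float = 0.5
    cnv_control_n: int = 350
    # methylome
    min_coverage: int = 5
    hmr_beta_max: float = 0.5
    hmr_min_cpg: int = 4
    hmr_max_gap: int = 500
    window: int = 100
    min_fraction: float = 0.05
    focal_max: int = 10_000
    min_recurrence: float = 0.10
    max_delta: float = -0.1
    alpha_q: float = 0.05
    # synthetic-cohort overrides forwarded to SimulationConfig
    sim: dict = field(default_factory=dict)
    # input paths; the simulate stage fills these for later stages
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "tranche_grid" in data:
            data["tranche_grid"] = tuple(data["tranche_grid"])
        return cls(**data)

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("inputs")
        d.pop("outdir")  # a path, not a threshold: outputs stay byte-identical
        d["tranche_grid"] = list(self.tranche_grid)
        d["version"] = __version__
        return d


def write_tsv(path: str | Path, df: pd.DataFrame, provenance: dict) -> None:
    import json

    with open(path, "w") as fh:
        for key in sorted(provenance):
            fh.write(f"# {key} = {json.dumps(provenance[key])}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_provenance(path: str | Path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("# "):
                break
            key, _, value = line[2:].partition(" = ")
            out[key.strip()] = yaml.safe_load(value)
    return out


def _require(config: RunConfig, *keys: str) -> list[Path]:
    paths = []
    for key in keys:
        p = config.inputs.get(key)
        if p is None or not Path(p).exists():
            raise MissingInputError(f"required input {key!r} missing" + (f" ({p})" if p else ""))
        paths.append(Path(p))
    return paths


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig) -> None:
    out = Path(config.outdir) / "sim"
    sim_cfg = SimulationConfig(seed=config.seed, **config.sim)
    log.info("simulate: genotype cohort")
    cohort = simulate_burden_cohort(sim_cfg)
    paths = write_burden_cohort(cohort, out)
    log.info("simulate: CNV call sets")
    cnv_sim = simulate_cnv_callsets(sim_cfg)
    cnv_paths = write_cnv_callsets(cnv_sim, out / "cnv")
    log.info("simulate: methylomes")
    meth_sim = simulate_methylomes(sim_cfg)
    write_methylomes(meth_sim, out / "meth")
    write_gmt(out / "genesets.gmt", simulate_genesets(sim_cfg))
    config.inputs.update({k: str(v) for k, v in paths.items()})
    config.inputs.update(
        {
            "calls_a_dir": str(out / "cnv" / "caller_a"),
            "calls_b_dir": str(out / "cnv" / "caller_b"),
            "cnv_truth": str(cnv_paths["truth"]),
            "cov_case_dir": str(out / "meth" / "case"),
            "cov_control_dir": str(out / "meth" / "control"),
            "genesets_gmt": str(out / "genesets.gmt"),
        }
    )


def stage_burden(config: RunConfig) -> None:
    out = Path(config.outdir) / "burden"
    out.mkdir(parents=True, exist_ok=True)
    case_vcf, summary_vcf, genes_bed, lcr_bed, mask_case, mask_ctrl = _require(
        config, "case_vcf", "summary_vcf", "genes_bed", "lcr_bed",
        "case_mask_bed", "control_mask_bed",
    )
    case_samples, case_records = read_case_vcf(case_vcf)
    control_records = read_control_sites(summary_vcf)
    genes = read_bed_named(genes_bed)
    from .intervals import FeatureSet

    features = [FeatureSet(name, name, "coding_gene", [iv]) for iv, name in genes]
    lcr = read_bed(lcr_bed)
    mask = bd.build_callable_mask(
        _read_coverage(mask_case), _read_coverage(mask_ctrl), config.required_fraction
    )
    case_records = bd.apply_region_filters(case_records, mask, lcr)
    control_records = bd.apply_region_filters(control_records, mask, lcr)
    control_n = max((v.control_an for v in control_records), default=0) // 2
    log.info("burden: calibration sweep over tranches %s", config.tranche_grid)
    calib = bd.calibration_sweep(
        case_records, control_records, features,
        case_n=len(case_samples), control_n=control_n,
        tranche_grid=config.tranche_grid, mode=config.burden_mode,
    )
    tranche = calib.chosen_tranche if calib.chosen_tranche is not None else 1.0
    if calib.chosen_tranche is None:
        log.warning("burden: no tranche within tolerance; using full inclusion. %s", calib.diagnostic)
    kept = bd.apply_tranche(case_records, tranche)
    if config.burden_mode == "coding":
        qual_case = bd.select_qualifying_coding(kept, config.af_max_coding)
        qual_ctrl = bd.select_qualifying_coding(control_records, config.af_max_coding)
    else:
        qual_case = bd.select_qualifying_noncoding(kept, config.af_max_noncoding)
        qual_ctrl = bd.select_qualifying_noncoding(control_records, config.af_max_noncoding)
    scan = bd.burden_scan(
        features, qual_case, qual_ctrl, case_n=len(case_samples), control_n=control_n,
        alpha=config.alpha,
    )
    prov = config.provenance() | {"chosen_tranche": tranche}
    write_tsv(out / "burden_table.tsv", scan, prov)
    write_tsv(out / "calibration.tsv", calib.as_frame(), prov)
    write_tsv(out / "qq.tsv", bd.qq_table(scan.loc[~scan.untested, "p_one_sided"]), prov)


def _read_coverage(path: Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "fraction"],
        dtype={"chrom": str},
    )


def _read_calls_dir(path: Path, caller: str) -> list[cv.CnvCall]:
    calls = []
    for bed in sorted(path.glob("*.bed")):
        sample = bed.stem
        for iv, cnv_type in read_bed_named(bed):
            calls.append(cv.CnvCall(sample, iv, cnv_type, caller))
    return calls


def stage_cnv(config: RunConfig) -> None:
    out = Path(config.outdir) / "cnv"
    out.mkdir(parents=True, exist_ok=True)
    calls_a_dir, calls_b_dir, genes_bed = _require(
        config, "calls_a_dir", "calls_b_dir", "genes_bed"
    )
    calls_a = _read_calls_dir(calls_a_dir, "A")
    calls_b = _read_calls_dir(calls_b_dir, "B")
    consensus = cv.consensus_intersect(calls_a, calls_b, config.min_reciprocal)
    regions = cv.cluster_across_samples(consensus, config.min_reciprocal)
    genes = read_bed_named(genes_bed)
    regions = cv.annotate_regions(regions, genes)
    n_case = len({c.sample_id for c in calls_a + calls_b})
    control_counts = _control_counts_for(config, regions)
    table = cv.compare_region_frequencies(
        regions, n_case, control_counts, config.cnv_control_n
    )
    write_tsv(out / "consensus_regions.tsv", table, config.provenance())


def _control_counts_for(config: RunConfig, regions: list[cv.ConsensusRegion]) -> list[int]:
    """Control carrier counts per region, matched from a truth/annotation table when available."""
    truth_path = config.inputs.get("cnv_truth")
    counts = [0] * len(regions)
    if truth_path and Path(truth_path).exists():
        truth = pd.read_csv(truth_path, sep="\t")
        for i, r in enumerate(regions):
            for row in truth.itertuples():
                iv = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
                from .intervals import reciprocal_overlap_fraction

                if (
                    row.cnv_type == r.cnv_type
                    and reciprocal_overlap_fraction(iv, r.interval) >= config.min_reciprocal
                ):
                    counts[i] = int(row.control_frequency)
                    break
    return counts


def stage_methylome(config: RunConfig) -> None:
    out = Path(config.outdir) / "methylome"
    out.mkdir(parents=True, exist_ok=True)
    cov_case_dir, cov_control_dir, gene_parts_bed, gmt_path = _require(
        config, "cov_case_dir", "cov_control_dir", "gene_parts_bed", "genesets_gmt"
    )
    cases = [
        me.filter_coverage(read_bismark_cov(p), config.min_coverage)
        for p in sorted(Path(cov_case_dir).glob("*.cov"))
    ]
    controls = [
        me.filter_coverage(read_bismark_cov(p), config.min_coverage)
        for p in sorted(Path(cov_control_dir).glob("*.cov"))
    ]
    if not cases or not controls:
        raise MissingInputError("no coverage files found in the methylome input directories")
    log.info("methylome: HMR calling on %d samples", len(cases) + len(controls))
    hmr_kw = dict(
        beta_max=config.hmr_beta_max, min_cpg=config.hmr_min_cpg, max_gap=config.hmr_max_gap
    )
    hmrs_all = {s.sample_id: me.call_hmrs_simple(s, **hmr_kw) for s in cases + controls}
    hmrs_cases = {s.sample_id: hmrs_all[s.sample_id] for s in cases}
    scan_kw = dict(
        window=config.window, min_fraction=config.min_fraction, focal_max=config.focal_max
    )
    recurrent_all = me.recurrence_scan(hmrs_all, **scan_kw)
    recurrent_cases = me.recurrence_scan(hmrs_cases, **scan_kw)
    matrix, kept = me.region_methylation_matrix(recurrent_all, cases + controls)
    dmrs = me.dmr_test(
        matrix, [s.sample_id for s in cases], [s.sample_id for s in controls],
        alpha_q=config.alpha_q,
    )
    deltas = dict(zip(dmrs["region"], dmrs["delta"]))
    case_fraction = {
        me.region_id(r.interval): r.sample_fraction for r in recurrent_cases
    }
    selected = me.select_recurrent_differential(
        recurrent_cases, deltas, config.min_recurrence, config.max_delta
    )
    gene_parts = _read_gene_parts(gene_parts_bed)
    dmr_ivs = [
        kept[i] for i, flag in enumerate(dmrs["is_dmr"].to_numpy()) if flag
    ]
    dmgs = me.map_dmrs_to_genes(dmr_ivs, gene_parts)
    universe = sorted({g for _, g, _ in gene_parts})
    enrich = me.geneset_enrichment(dmgs, read_gmt(gmt_path), universe, config.alpha_q)
    prov = config.provenance()
    rec_df = pd.DataFrame(
        {
            "region": [me.region_id(r.interval) for r in recurrent_all],
            "sample_fraction": [r.sample_fraction for r in recurrent_all],
            "case_fraction": [
                case_fraction.get(me.region_id(r.interval), 0.0) for r in recurrent_all
            ],
        }
    )
    write_tsv(out / "recurrent_hmrs.tsv", rec_df, prov)
    write_tsv(out / "dmr_table.tsv", dmrs, prov)
    write_tsv(out / "dmg_list.tsv", pd.DataFrame({"gene": dmgs}), prov)
    write_tsv(out / "enrichment.tsv", enrich, prov)
    n_dmr = int(dmrs["is_dmr"].sum())
    summary = pd.DataFrame(
        [
            {"metric": "n_recurrent_hmrs", "value": len(recurrent_all)},
            {"metric": "n_dmrs", "value": n_dmr},
            {"metric": "hypo_fraction", "value": me.hypo_fraction(dmrs) if n_dmr else float("nan")},
            {"metric": "n_selected_recurrent_differential", "value": len(selected)},
            {"metric": "n_dmgs", "value": len(dmgs)},
        ]
    )
    write_tsv(out / "summary.tsv", summary, prov)


def _read_gene_parts(path: Path) -> list[tuple[GenomicInterval, str, str]]:
    # BED rows carry gene in column 4 and part in column 5
    from .io import iter_bed_rows

    out = []
    for _, chrom, start, end, extra in iter_bed_rows(path):
        gene = extra[0] if extra else ""
        part = extra[1] if len(extra) > 1 else ""
        out.append((GenomicInterval(chrom, start, end), gene, part))
    return out


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> None:
    """Run the requested stages in dependency order."""
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("=== stage %s ===", stage)
        {"simulate": stage_simulate, "burden": stage_burden, "cnv": stage_cnv,
         "methylome": stage_methylome}[stage](config)
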