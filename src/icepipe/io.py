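"""Readers and writers for the standard formats the pipeline touches.

VCF is read through :mod:`cyvcf2`; BED, Bismark coverage and GMT are plain
column formats handled with pandas/stdlib.  Every reader converts external
coordinates (1-based VCF and Bismark positions) into the package's canonical
0-based half-open convention only where interval arithmetic is needed; the
record types below preserve the on-disk 1-based position so round trips are
lossless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import ConfigurationError, ParseError, ValidationError
from .intervals import GenomicInterval

MISSING_DOSE = -1  # sentinel for an uncalled genotype

CONSEQUENCES = ("synonymous", "missense", "lof", "noncoding")


@dataclass(frozen=True)
class VcfInfoKeys:
    """INFO keys under which annotations are expected.

    The annotation stack that produced them (VEP/dbNSFP-style) is upstream of
    this package, so the key names are configurable; these are the defaults
    the simulator also writes.
    """

    pop_af: str = "MAX_AF"
    consequence: str = "CSQ"
    deleterious: tuple[str, str, str] = ("GERP_DEL", "GWAVA_DEL", "CADD_DEL")
    qual_metric: str = "QD"


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site after multi-allelic splitting.

    ``pos`` is the 1-based position exactly as read from the VCF.
    ``case_doses`` holds per-case-sample alternate-allele doses in
    {0, 1, 2, MISSING_DOSE}; it is empty for control-summary records.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual_metric: float = 0.0
    pass_flag: bool = True
    case_doses: tuple[int, ...] = ()
    control_ac: int = 0
    control_an: int = 0
    pop_af: float = 0.0
    consequence: str = "noncoding"
    deleterious_flags: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self) -> None:
        if not (0 <= self.control_ac <= max(self.control_an, 0)) and self.control_an:
            raise ValidationError(
                f"AC {self.control_ac} exceeds AN {self.control_an} at {self.chrom}:{self.pos}"
            )
        if not (0.0 <= self.pop_af <= 1.0):
            raise ValidationError(f"pop_af {self.pop_af} outside [0,1] at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence {self.consequence!r}")
        bad = set(self.case_doses) - {0, 1, 2, MISSING_DOSE}
        if bad:
            raise ValidationError(f"invalid doses {bad} at {self.chrom}:{self.pos}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos - 1, self.pos - 1 + max(1, len(self.ref)))

    def carriers(self) -> np.ndarray:
        """Boolean mask of case samples carrying at least one alternate allele.

        Missing genotypes count as non-carriers (reported separately as
        missingness by the burden module).
        """
        doses = np.asarray(self.case_doses)
        return doses >= 1

    def n_missing(self) -> int:
        return int(np.sum(np.asarray(self.case_doses) == MISSING_DOSE)) if self.case_doses else 0


@dataclass
class MethylomeSample:
    """Per-CpG methylation counts for one sample.

    ``records`` has columns chrom, pos (1-based), meth, unmeth and is sorted
    by (chrom, pos).  ``beta`` is meth/(meth+unmeth), NaN at zero coverage.
    """

    sample_id: str
    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "pos", "meth", "unmeth"])
    )

    def __post_init__(self) -> None:
        req = ["chrom", "pos", "meth", "unmeth"]
        if list(self.records.columns[:4]) != req:
            self.records = self.records[req]
        if (self.records[["meth", "unmeth"]].to_numpy() < 0).any():
            raise ValidationError(f"negative methylation counts in sample {self.sample_id}")
        self.records = self.records.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )

    @property
    def coverage(self) -> np.ndarray:
        return (self.records["meth"] + self.records["unmeth"]).to_numpy()

    @property
    def beta(self) -> np.ndarray:
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.records["meth"].to_numpy() / cov, np.nan)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _info_per_alt(value, n_alt: int, i: int):
    """Pick the per-alternate component of an INFO value (Number=A or scalar).

    cyvcf2 hands back tuples for numeric Number=A fields but a single
    comma-joined string for string-typed ones."""
    if isinstance(value, str) and n_alt > 1 and value.count(",") == n_alt - 1:
        return value.split(",")[i]
    if isinstance(value, (tuple, list, np.ndarray)):
        return value[i] if len(value) == n_alt else value[0]
    return value


def read_case_vcf(
    path: str | Path,
    info_keys: VcfInfoKeys = VcfInfoKeys(),
    pass_only: bool = False,
) -> tuple[list[str], list[VariantRecord]]:
    """Read a genotyped cohort VCF into biallelic :class:`VariantRecord` s.

    Multi-allelic sites are split into one record per alternate allele, with
    per-alternate INFO components (Number=A) taken for that allele.  Raises
    :class:`ConfigurationError` when a required INFO key is absent from the
    header and :class:`ParseError` (naming the record index) on malformed
    content.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    header_ids = {h["ID"] for h in vcf.header_iter() if h.type == "INFO"}
    required = [info_keys.pop_af, info_keys.consequence, info_keys.qual_metric,
                *info_keys.deleterious]
    missing = [k for k in required if k not in header_ids]
    if missing:
        raise ConfigurationError(
            f"{path}: required INFO keys missing from header: {', '.join(missing)}"
        )
    records: list[VariantRecord] = []
    n_rec = 0
    try:
        for v in vcf:
            n_rec += 1
            alts = v.ALT
            gts = v.genotypes  # [a0, a1, phased] per sample
            for i, alt in enumerate(alts):
                doses = []
                for gt in gts:
                    alleles = gt[:-1]
                    if any(a < 0 for a in alleles):
                        doses.append(MISSING_DOSE)
                    else:
                        doses.append(sum(1 for a in alleles if a == i + 1))
                pass_flag = v.FILTER is None  # cyvcf2: None means PASS/'.'
                if pass_only and not pass_flag:
                    continue
                flags = tuple(
                    bool(int(_info_per_alt(v.INFO.get(k, 0), len(alts), i) or 0))
                    for k in info_keys.deleterious
                )
                records.append(
                    VariantRecord(
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        qual_metric=float(v.INFO.get(info_keys.qual_metric, 0.0) or 0.0),
                        pass_flag=pass_flag,
                        case_doses=tuple(doses),
                        pop_af=float(_info_per_alt(v.INFO.get(info_keys.pop_af, 0.0), len(alts), i) or 0.0),
                        consequence=str(_info_per_alt(v.INFO.get(info_keys.consequence, "noncoding"), len(alts), i)),
                        deleterious_flags=flags,  # type: ignore[arg-type]
                    )
                )
    except ValidationError:
        raise
    except Exception as exc:  # cyvcf2/htslib parse failures
        raise ParseError(f"{path}: malformed VCF near record {n_rec + 1}: {exc}") from exc
    return samples, records


def read_control_sites(path: str | Path) -> list[VariantRecord]:
    """Read a summary-only (AC/AN) control VCF; genotypes are not expected."""
    path = str(path)
    vcf = VCF(path)
    records: list[VariantRecord] = []
    n_rec = 0
    try:
        for v in vcf:
            n_rec += 1
            alts = v.ALT
            an = v.INFO.get("AN")
            if an is None:
                raise ValidationError(f"{path}: record {v.CHROM}:{v.POS} lacks AN")
            ac_val = v.INFO.get("AC")
            if ac_val is None:
                raise ValidationError(f"{path}: record {v.CHROM}:{v.POS} lacks AC")
            for i, alt in enumerate(alts):
                ac = int(_info_per_alt(ac_val, len(alts), i))
                if ac > int(an):
                    raise ValidationError(
                        f"{path}: AC {ac} > AN {an} at {v.CHROM}:{v.POS}"
                    )
                records.append(
                    VariantRecord(
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        control_ac=ac,
                        control_an=int(an),
                        pop_af=float(_info_per_alt(v.INFO.get("MAX_AF", 0.0), len(alts), i) or 0.0),
                        consequence=str(_info_per_alt(v.INFO.get("CSQ", "noncoding"), len(alts), i)),
                    )
                )
    except ValidationError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: malformed VCF near record {n_rec + 1}: {exc}") from exc
    return records


_VCF_INFO_HEADER = """\
##INFO=<ID=MAX_AF,Number=A,Type=Float,Description="Maximum population allele frequency">
##INFO=<ID=CSQ,Number=A,Type=String,Description="Consequence class">
##INFO=<ID=GERP_DEL,Number=A,Type=Integer,Description="GERP++ deleterious call (0/1)">
##INFO=<ID=GWAVA_DEL,Number=A,Type=Integer,Description="GWAVA deleterious call (0/1)">
##INFO=<ID=CADD_DEL,Number=A,Type=Integer,Description="CADD deleterious call (0/1)">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Total allele number">
"""


def _dose_to_gt(d: int) -> str:
    return {0: "0/0", 1: "0/1", 2: "1/1", MISSING_DOSE: "./."}[d]


def write_case_vcf(path: str | Path, samples: Sequence[str], records: Sequence[VariantRecord]) -> None:
    """Write genotyped records as VCF 4.2 with this package's INFO keys."""
    contigs = sorted({r.chrom for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(_VCF_INFO_HEADER)
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
            info = (
                f"MAX_AF={r.pop_af:.6g};CSQ={r.consequence};"
                f"GERP_DEL={int(r.deleterious_flags[0])};GWAVA_DEL={int(r.deleterious_flags[1])};"
                f"CADD_DEL={int(r.deleterious_flags[2])};QD={r.qual_metric:.4f}"
            )
            filt = "PASS" if r.pass_flag else "LowQual"
            gts = "\t".join(_dose_to_gt(d) for d in r.case_doses)
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t{filt}\t{info}\tGT\t{gts}\n"
            )


def write_control_vcf(path: str | Path, records: Sequence[VariantRecord]) -> None:
    """Write summary-only (AC/AN) control records as sites-only VCF."""
    contigs = sorted({r.chrom for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(_VCF_INFO_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
            info = (
                f"AC={r.control_ac};AN={r.control_an};MAX_AF={r.pop_af:.6g};CSQ={r.consequence}"
            )
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def iter_bed_rows(path: str | Path) -> Iterator[tuple[int, str, int, int, list[str]]]:
    """Yield (lineno, chrom, start, end, extra_columns) from a BED file.

    BED is 0-based half-open on disk, which matches the internal convention,
    so coordinates pass through unchanged.  Raises :class:`ValidationError`
    naming the line on empty or inverted intervals.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start or start < 0:
                raise ValidationError(f"{path}:{lineno}: invalid interval [{start},{end})")
            yield lineno, cols[0], start, end, cols[3:]


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ as sorted intervals (extra columns ignored)."""
    ivs = [GenomicInterval(c, s, e) for _, c, s, e, _ in iter_bed_rows(path)]
    return sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))


def read_bed_named(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read BED4+ as sorted (interval, name) pairs; name defaults to ''."""
    rows = [
        (GenomicInterval(c, s, e), extra[0] if extra else "")
        for _, c, s, e, extra in iter_bed_rows(path)
    ]
    return sorted(rows, key=lambda r: (r[0].chrom, r[0].start, r[0].end, r[1]))


def write_bed(path: str | Path, rows: Iterable[GenomicInterval | tuple]) -> None:
    """Write intervals (or (interval, *extra) tuples) as BED."""
    with open(path, "w") as fh:
        for row in rows:
            if isinstance(row, GenomicInterval):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")
            else:
                iv, *extra = row
                fh.write("\t".join([iv.chrom, str(iv.start), str(iv.end), *map(str, extra)]) + "\n")


# ---------------------------------------------------------------------------
# Bismark coverage
# ---------------------------------------------------------------------------


def read_bismark_cov(path: str | Path, sample_id: str | None = None) -> MethylomeSample:
    """Read a 6-column Bismark coverage file (1-based positions).

    The %-methylation column is ignored in favour of the raw counts; if it
    disagrees with the counts beyond rounding a warning is issued and the
    counts win.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "end", "pct", "meth", "unmeth"],
        dtype={"chrom": str},
    )
    cov = df["meth"] + df["unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        implied = np.where(cov > 0, 100.0 * df["meth"] / cov, 0.0)
    off = (cov > 0) & (np.abs(implied - df["pct"]) > 0.5)
    if off.any():
        warnings.warn(
            f"{path}: {int(off.sum())} rows where %methylation disagrees with counts; counts used",
            stacklevel=2,
        )
    rec = df[["chrom", "pos", "meth", "unmeth"]].copy()
    return MethylomeSample(sample_id or path.stem.replace(".cov", ""), rec)


def write_bismark_cov(path: str | Path, sample: MethylomeSample) -> None:
    df = sample.records
    cov = (df["meth"] + df["unmeth"]).to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * df["meth"].to_numpy() / cov, 0.0)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "end": df["pos"],
            "pct": np.round(pct, 6),
            "meth": df["meth"],
            "unmeth": df["unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT (set id, description, genes...) into an ordered mapping."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: GMT rows need id, description, >=1 gene")
            sets[cols[0]] = cols[2:]
    return sets


def write_gmt(path: str | Path, sets: dict[str, Sequence[str]]) -> None:
    with open(path, "w") as fh:
        for set_id, genes in sets.items():
            fh.write("\t".join([set_id, "na", *genes]) + "\n")
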