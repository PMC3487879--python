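"""Readers and writers for the pipeline's tabular formats.

Native dialect is TSV, UTF-8, ``.`` as the missing token. Formats:

* expression / detection TSV — probe x sample, first column ``probe_id``,
  header row of sample IDs; the two files must be shape-identical;
* genotypes — long TSV (``sample_id  snp_id  code``) or a VCF whose GT
  fields are translated to minor-allele dosages (0/0 -> 0, 0/1 -> 1,
  1/1 -> 2, ./. -> missing; phased separators accepted);
* covariates TSV — ``sample_id  age  status`` (case/control,
  case-insensitive);
* SNP loci TSV — ``chrom  pos  snp_id`` with 1-based positions;
* gene intervals — BED (0-based half-open), name column = probe/gene ID;
* gene sets — GMT (see :mod:`candeqtl.enrich`);
* results TSV — fixed AssociationRecord column order, with perm_p also
  rendered at 1/B resolution in scientific notation (``1.00E-04``).

Every reader raises a located :class:`~candeqtl.qcnorm.ValidationError` on
malformed input rather than silently coercing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assocscan import AssociationRecord, GenotypeTable, records_to_frame
from .covadjust import CovariateTable
from .genomics import GenomicLocus
from .qcnorm import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

MISSING_TOKEN = "."

RESULT_COLUMNS = [
    "snp_id", "probe_id", "n_used", "coding", "beta", "t_stat",
    "nominal_p", "r2", "adj_r2", "perm_p", "perm_p_display", "cis_trans",
]


@dataclass
class PipelineConfig:
    """File paths and stage parameters for a full run, loadable from YAML."""

    expression: str = ""
    detection: str = ""
    genotypes: str = ""
    covariates: str = ""
    snp_loci: str = ""
    gene_bed: str = ""
    gmt: str = ""
    input_scale: str = "raw"
    alpha: float = 0.05
    fail_fraction: float = 0.25
    log_offset: float = 1.0
    coding: str = "additive"
    permutations: int = 10_000
    seed: int = 0
    scheme: str = "joint"
    pseudocount: str = "none"
    window_bp: int = 1_000_000
    distance_anchor: str = "interval-edge"
    thresholds: tuple[float, ...] = (0.05, 0.01, 0.001)

    def __post_init__(self) -> None:
        self.thresholds = tuple(sorted(self.thresholds, reverse=True))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _read_tsv_matrix(path: str, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN])
    df.index.name = index_name
    non_numeric = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index[0]
        raise ValidationError(
            f"{path}: non-numeric cell at row {bad!r}, column {col!r}"
        )
    return df


def read_expression_matrix(
    path: str, detection_path: str | None = None, scale_flag: str = "raw"
) -> ExpressionMatrix:
    """Probe x sample intensity TSV, optionally with a detection-P TSV."""
    intensities = _read_tsv_matrix(path, "probe_id")
    detection = None
    if detection_path is not None:
        detection = _read_tsv_matrix(detection_path, "probe_id")
        if detection.shape != intensities.shape:
            raise ValidationError(
                f"detection matrix {detection_path} shape {detection.shape} "
                f"!= intensity matrix {path} shape {intensities.shape}"
            )
        if list(detection.index) != list(intensities.index) or list(
            detection.columns
        ) != list(intensities.columns):
            raise ValidationError(
                f"{detection_path}: probe/sample labels differ from {path}"
            )
    logger.info("read expression: %d probes x %d samples from %s",
                *intensities.shape, path)
    return ExpressionMatrix(
        intensities=intensities, detection_p=detection, scale_flag=scale_flag
    )


def write_expression_matrix(expr: ExpressionMatrix, path: str,
                            detection_path: str | None = None) -> None:
    expr.intensities.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)
    if detection_path is not None:
        if expr.detection_p is None:
            raise ValidationError("matrix has no detection P-values to write")
        expr.detection_p.to_csv(detection_path, sep="\t", na_rep=MISSING_TOKEN)


def _read_genotypes_vcf(path: str) -> GenotypeTable:
    import pysam

    rows: dict[str, dict[str, float]] = {}
    alleles: dict[str, tuple[str, str]] = {}
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            if snp_id in rows:
                raise ValidationError(f"{path}: duplicate SNP ID {snp_id!r}")
            if rec.alts and len(rec.alts) == 1:
                alleles[snp_id] = (rec.ref, rec.alts[0])
            col: dict[str, float] = {}
            for sample in samples:
                gt = rec.samples[sample]["GT"]
                if gt is None or any(a is None for a in gt):
                    col[sample] = np.nan
                else:
                    col[sample] = float(sum(gt))
            rows[snp_id] = col
    codes = pd.DataFrame(rows).loc[samples]
    codes.index.name = "sample_id"
    return GenotypeTable(codes=codes, alleles=alleles)


def _read_genotypes_tsv(path: str) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["sample_id", "snp_id", "code"]
    if list(df.columns)[:3] != expected:
        raise ValidationError(
            f"{path}: genotype TSV must have columns {expected}, got {list(df.columns)}"
        )
    dup = df.duplicated(subset=["sample_id", "snp_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate (sample, SNP) pair ({row.sample_id}, {row.snp_id})"
        )
    codes = df["code"].where(df["code"] != MISSING_TOKEN)
    numeric = pd.to_numeric(codes, errors="coerce")
    bad = codes.notna() & numeric.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
        raise ValidationError(f"{path}:{line}: genotype code {codes[bad.idxmax()]!r} not numeric")
    out_of_range = numeric.notna() & ~numeric.isin([0, 1, 2])
    if out_of_range.any():
        line = int(out_of_range.idxmax()) + 2
        raise ValidationError(
            f"{path}:{line}: genotype code {numeric[out_of_range.idxmax()]} not in {{0,1,2}}"
        )
    wide = (
        df.assign(code=numeric)
        .pivot(index="sample_id", columns="snp_id", values="code")
        .rename_axis(index="sample_id", columns=None)
    )
    table = GenotypeTable(codes=wide)
    for snp, maf in table.maf.items():
        logger.info("observed MAF for %s: %.4f", snp, maf)
    return table


def read_genotypes(path: str, format: str = "tsv") -> GenotypeTable:
    """Load a genotype table from long TSV or VCF."""
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValidationError(f"genotype format must be tsv or vcf, got {format!r}")


def write_genotypes(table: GenotypeTable, path: str) -> None:
    long = (
        table.codes.rename_axis(index="sample_id")
        .reset_index()
        .melt(id_vars="sample_id", var_name="snp_id", value_name="code")
    )
    long["code"] = long["code"].map(
        lambda v: MISSING_TOKEN if pd.isna(v) else str(int(v))
    )
    long.to_csv(path, sep="\t", index=False)


def read_covariates(path: str) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN])
    expected = {"sample_id", "age", "status"}
    if not expected.issubset(df.columns):
        raise ValidationError(
            f"{path}: covariate TSV needs columns {sorted(expected)}, got {list(df.columns)}"
        )
    return CovariateTable(table=df.set_index("sample_id")[["age", "status"]])


def write_covariates(cov: CovariateTable, path: str) -> None:
    cov.table.rename_axis(index="sample_id").to_csv(path, sep="\t")


def read_snp_loci(path: str) -> dict[str, GenomicLocus]:
    """SNP locus TSV: chrom, pos (1-based), snp_id."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    expected = ["chrom", "pos", "snp_id"]
    if list(df.columns)[:3] != expected:
        raise ValidationError(
            f"{path}: SNP locus TSV must have columns {expected}, got {list(df.columns)}"
        )
    loci = {}
    for _, row in df.iterrows():
        if row.snp_id in loci:
            raise ValidationError(f"{path}: duplicate SNP ID {row.snp_id!r}")
        loci[row.snp_id] = GenomicLocus.from_snp_1based(row.chrom, int(row.pos))
    logger.info("read %d SNP loci from %s (1-based -> 0-based)", len(loci), path)
    return loci


def read_gene_bed(path: str) -> dict[str, GenomicLocus]:
    """BED intervals (0-based half-open); column 4 is the probe/gene ID."""
    loci: dict[str, GenomicLocus] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(
                    f"{path}:{lineno}: BED line needs chrom, start, end, name"
                )
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if name in loci:
                raise ValidationError(f"{path}:{lineno}: duplicate gene ID {name!r}")
            loci[name] = GenomicLocus.gene_interval(chrom, start, end)
    logger.info("read %d gene intervals from %s", len(loci), path)
    return loci


def _format_perm_p(p: float | None, B: int) -> str:
    if p is None:
        return MISSING_TOKEN
    return f"{round(p * B) / B:.2E}"


def write_association_table(
    records: list[AssociationRecord], path: str, permutations: int = 10_000
) -> None:
    """Write scan results as TSV in fixed column order, SNP-major.

    ``perm_p`` is written at full precision plus a display column rounded
    to the 1/B grid in scientific notation.
    """
    if not records:
        raise ValidationError("no association records to write")
    frame = records_to_frame(records)
    # SNP-major; stable sort keeps the scan's probe order within each SNP.
    frame = frame.sort_values("snp_id", kind="mergesort").reset_index(drop=True)
    frame["perm_p_display"] = [
        _format_perm_p(p, permutations) for p in frame["perm_p"]
    ]
    frame = frame[RESULT_COLUMNS]
    frame.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)
    logger.info("wrote %d association records to %s", len(frame), path)


def read_association_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN])
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: result table missing columns {sorted(missing)}")
    return df


def ensure_dir(path: str | Path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
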