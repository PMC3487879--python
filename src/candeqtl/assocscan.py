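"""Per SNP-probe association scan by simple linear regression.

Each candidate SNP is tested against each transcript's covariate-adjusted
residual by ordinary least squares of residual on genotype dosage (0/1/2
copies of the minor allele, or a 0/1 carrier indicator under dominant
coding). The statistics reported per pair are the slope, the two-sided
t-test P-value, r-squared, and the small-sample adjusted r-squared

    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - 2)

for the one-predictor model. Samples with missing genotype are dropped
pairwise. The closed-form simple-regression algebra used here is the same
algebra the permutation engine vectorizes, so the permuted and observed
statistics are exactly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .covadjust import ResidualMatrix
from .qcnorm import ValidationError

logger = logging.getLogger(__name__)

CODING_ADDITIVE = "additive"
CODING_DOMINANT = "dominant"
_CODINGS = (CODING_ADDITIVE, CODING_DOMINANT)


@dataclass
class GenotypeTable:
    """Sample x SNP additive genotype codes.

    ``codes`` is indexed by sample ID with SNP-ID columns; entries are
    0/1/2 (copies of the minor allele) or NaN for missing. ``alleles``
    optionally maps SNP ID to (major, minor) allele labels.
    """

    codes: pd.DataFrame
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.codes.index.has_duplicates:
            dups = self.codes.index[self.codes.index.duplicated()].unique()
            raise ValidationError(f"duplicate sample IDs in genotypes: {list(dups)[:5]}")
        if self.codes.columns.has_duplicates:
            dups = self.codes.columns[self.codes.columns.duplicated()].unique()
            raise ValidationError(f"duplicate SNP IDs in genotypes: {list(dups)[:5]}")
        vals = self.codes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValidationError(
                f"genotype code {vals[tuple(bad)]!r} at sample "
                f"{self.codes.index[bad[0]]!r}, SNP {self.codes.columns[bad[1]]!r} "
                "not in {0, 1, 2, missing}"
            )
        self.codes = self.codes.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def maf(self) -> pd.Series:
        """Observed minor-allele frequency per SNP (missing codes excluded)."""
        return self.codes.mean(axis=0, skipna=True) / 2.0


@dataclass
class AssociationRecord:
    """One SNP-probe pair's regression summary."""

    snp_id: str
    probe_id: str
    n_used: int
    coding: str
    beta: float
    t_stat: float
    nominal_p: float
    r2: float
    adj_r2: float
    perm_p: float | None = None
    cis_trans: str | None = None
    degenerate: bool = False


def _adjusted_r2(r2: float, n: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def _code_genotype(codes: np.ndarray, coding: str) -> np.ndarray:
    if coding == CODING_ADDITIVE:
        return codes
    return (codes > 0).astype(float)


def regress_pair(
    residuals_for_probe: np.ndarray,
    codes_for_snp: np.ndarray,
    coding: str = CODING_ADDITIVE,
    snp_id: str = "",
    probe_id: str = "",
) -> AssociationRecord:
    """Simple OLS of one probe's residuals on one SNP's coded genotype.

    Missing genotypes are dropped pairwise; ``n_used`` records the
    remainder. A genotype that is constant after missing-data removal
    yields a degenerate record (beta 0, P 1) rather than an error, so a
    full scan never aborts on a monomorphic SNP.
    """
    if coding not in _CODINGS:
        raise ValidationError(f"coding must be one of {_CODINGS}, got {coding!r}")
    y = np.asarray(residuals_for_probe, dtype=float)
    g = np.asarray(codes_for_snp, dtype=float)
    if y.shape != g.shape or y.ndim != 1:
        raise ValidationError(
            f"residual and genotype vectors must be 1-D and equal length "
            f"(got {y.shape} vs {g.shape})"
        )
    keep = ~np.isnan(g) & ~np.isnan(y)
    y, g = y[keep], _code_genotype(g[keep], coding)
    n = y.size
    if n < 3:
        raise ValidationError(f"need >=3 non-missing pairs, got {n}")

    def _degenerate() -> AssociationRecord:
        return AssociationRecord(
            snp_id=snp_id, probe_id=probe_id, n_used=n, coding=coding,
            beta=0.0, t_stat=0.0, nominal_p=1.0, r2=0.0,
            adj_r2=_adjusted_r2(0.0, n), degenerate=True,
        )

    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        return _degenerate()

    sxy = float(gc @ yc)
    beta = sxy / sxx
    r2 = min(sxy * sxy / (sxx * syy), 1.0)
    df = n - 2
    if r2 >= 1.0:
        t = np.inf if beta > 0 else -np.inf
        p = 0.0
    else:
        t = np.sign(sxy) * np.sqrt(df * r2 / (1.0 - r2))
        p = 2.0 * stats.t.sf(abs(t), df)
    return AssociationRecord(
        snp_id=snp_id, probe_id=probe_id, n_used=n, coding=coding,
        beta=beta, t_stat=float(t), nominal_p=float(p), r2=r2,
        adj_r2=_adjusted_r2(r2, n),
    )


def scan_all(
    residuals: ResidualMatrix,
    genotypes: GenotypeTable,
    coding: str = CODING_ADDITIVE,
) -> list[AssociationRecord]:
    """Regress every probe on every SNP; SNP-major, probe order preserved.

    Returns exactly n_probes x n_snps records, degenerate pairs included
    and flagged.
    """
    if set(residuals.sample_ids) != set(genotypes.sample_ids):
        only_r = sorted(set(residuals.sample_ids) - set(genotypes.sample_ids))
        only_g = sorted(set(genotypes.sample_ids) - set(residuals.sample_ids))
        raise ValidationError(
            f"sample mismatch: residual-only={only_r[:5]}, genotype-only={only_g[:5]}"
        )
    codes = genotypes.codes.loc[residuals.sample_ids]
    records: list[AssociationRecord] = []
    for snp_id in genotypes.snp_ids:
        g = codes[snp_id].to_numpy(dtype=float)
        for probe_id, y in zip(residuals.probe_ids, residuals.values):
            records.append(regress_pair(y, g, coding, snp_id=snp_id, probe_id=probe_id))
    logger.info(
        "association scan: %d probes x %d SNPs = %d records (%s coding)",
        len(residuals.probe_ids), len(genotypes.snp_ids), len(records), coding,
    )
    return records


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Tabulate records in the fixed output column order."""
    return pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "probe_id": r.probe_id,
                "n_used": r.n_used,
                "coding": r.coding,
                "beta": r.beta,
                "t_stat": r.t_stat,
                "nominal_p": r.nominal_p,
                "r2": r.r2,
                "adj_r2": r.adj_r2,
                "perm_p": r.perm_p,
                "cis_trans": r.cis_trans,
            }
            for r in records
        ]
    )
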