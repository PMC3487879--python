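"""Covariate residualization of expression phenotypes.

Association testing in this pipeline is two-stage: each transcript is first
regressed (ordinary least squares) on an intercept, age in years, and a 0/1
case indicator; the residuals become the phenotype that every SNP is tested
against. Residualizing once, up front, keeps the permutation engine cheap
— the covariate fit never has to be repeated inside the permutation loop —
and matches the common practice of testing genotype against
covariate-adjusted residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qcnorm import SCALE_NORMALIZED, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

STATUS_CASE = "case"
STATUS_CONTROL = "control"


@dataclass
class CovariateTable:
    """Per-sample age (years) and case/control status.

    ``table`` is indexed by sample ID with columns ``age`` (positive float)
    and ``status`` (``case`` or ``control``). Missing values are rejected at
    construction — the pipeline refuses to impute covariates silently.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique()
            raise ValidationError(f"duplicate sample IDs in covariates: {list(dups)[:5]}")
        missing_cols = {"age", "status"} - set(self.table.columns)
        if missing_cols:
            raise ValidationError(f"covariate table missing columns: {sorted(missing_cols)}")
        if self.table["age"].isna().any() or self.table["status"].isna().any():
            bad = self.table.index[
                self.table["age"].isna() | self.table["status"].isna()
            ]
            raise ValidationError(f"missing covariate values for samples: {list(bad)[:5]}")
        status = self.table["status"].astype(str).str.lower()
        bad = sorted(set(status) - {STATUS_CASE, STATUS_CONTROL})
        if bad:
            raise ValidationError(f"status values must be case/control, got: {bad}")
        self.table = self.table.assign(status=status)
        if (self.table["age"] <= 0).any():
            bad = self.table.index[self.table["age"] <= 0]
            raise ValidationError(f"non-positive ages for samples: {list(bad)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def age(self) -> np.ndarray:
        return self.table["age"].to_numpy(dtype=float)

    @property
    def status_indicator(self) -> np.ndarray:
        """0/1 indicator, 1 = case."""
        return (self.table["status"] == STATUS_CASE).to_numpy(dtype=float)

    @property
    def n_cases(self) -> int:
        return int(self.status_indicator.sum())

    @property
    def n_controls(self) -> int:
        return len(self.table) - self.n_cases


@dataclass
class ResidualMatrix:
    """Probe x sample covariate-adjusted residuals (mean zero per probe)."""

    residuals: pd.DataFrame

    @property
    def probe_ids(self) -> list[str]:
        return list(self.residuals.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.residuals.columns)

    @property
    def values(self) -> np.ndarray:
        return self.residuals.to_numpy(dtype=float)


def residualize(expr: ExpressionMatrix, cov: CovariateTable) -> ResidualMatrix:
    """Regress every probe on {intercept, age, case indicator}; keep residuals.

    The design matrix is shared across probes, so the hat projection is
    computed once and applied to the whole matrix. A covariate that is
    constant across samples (e.g. a cases-only cohort) is dropped with a
    warning rather than producing a singular fit.

    Raises
    ------
    ValidationError
        If the expression matrix is not quantile-normalized or the sample
        sets differ.
    """
    if expr.scale_flag != SCALE_NORMALIZED:
        raise ValidationError(
            f"expression must be {SCALE_NORMALIZED} before residualization "
            f"(got scale_flag={expr.scale_flag!r})"
        )
    expr_samples = set(expr.sample_ids)
    cov_samples = set(cov.sample_ids)
    if expr_samples != cov_samples:
        only_expr = sorted(expr_samples - cov_samples)
        only_cov = sorted(cov_samples - expr_samples)
        raise ValidationError(
            f"sample mismatch: expression-only={only_expr[:5]}, covariate-only={only_cov[:5]}"
        )

    # Align covariate rows to the expression column order.
    aligned = cov.table.loc[expr.sample_ids]
    age = aligned["age"].to_numpy(dtype=float)
    status = (aligned["status"] == STATUS_CASE).to_numpy(dtype=float)

    columns = [np.ones_like(age)]
    for name, col in (("age", age), ("status", status)):
        if np.ptp(col) == 0:
            logger.warning("covariate %r is constant across samples; dropped", name)
        else:
            columns.append(col)
    design = np.column_stack(columns)

    y = expr.intensities.to_numpy(dtype=float).T  # samples x probes
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = (y - design @ coef).T

    logger.info(
        "residualized %d probes on %d covariate columns (n=%d samples)",
        expr.n_probes, design.shape[1] - 1, expr.n_samples,
    )
    return ResidualMatrix(
        residuals=pd.DataFrame(
            resid, index=expr.intensities.index, columns=expr.intensities.columns
        )
    )
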