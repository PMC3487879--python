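"""Probe-level quality control and quantile normalization.

Illumina BeadChip summarised data come as a probe x sample intensity matrix
with a companion matrix of detection P-values (one per probe per sample,
testing signal against background beads). The standard preprocessing for
expression-QTL work on such arrays is

1. drop probes that are not reliably detected: a probe is excluded when its
   detection P exceeds ``alpha`` (0.05) in at least a ``fail_fraction``
   (25%) of samples;
2. log2-transform the intensities and quantile-normalize across samples so
   every array shares the same value distribution (the rank-wise means).

Both steps are deterministic and the matrix records which scale it is on so
downstream stages can refuse un-normalized input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed scale states, in the only order transitions may occur.
SCALE_RAW = "raw"
SCALE_LOG2 = "log2"
SCALE_NORMALIZED = "log2-quantile-normalized"
_SCALES = (SCALE_RAW, SCALE_LOG2, SCALE_NORMALIZED)


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class ExpressionMatrix:
    """Probe x sample expression values with optional detection P-values.

    Parameters
    ----------
    intensities
        DataFrame indexed by probe ID with sample-ID columns. Non-negative
        on the raw scale; any real value once log-transformed.
    detection_p
        Same-shape DataFrame of per-measurement detection P-values in
        [0, 1], or None when the upstream platform provides none.
    scale_flag
        One of ``raw``, ``log2``, ``log2-quantile-normalized``.
    """

    intensities: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    scale_flag: str = SCALE_RAW

    def __post_init__(self) -> None:
        if self.scale_flag not in _SCALES:
            raise ValidationError(
                f"unknown scale_flag {self.scale_flag!r}; expected one of {_SCALES}"
            )
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()].unique()
            raise ValidationError(f"duplicate probe IDs: {list(dups)[:5]}")
        if self.intensities.columns.has_duplicates:
            dups = self.intensities.columns[self.intensities.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample IDs: {list(dups)[:5]}")
        if self.detection_p is not None:
            if self.detection_p.shape != self.intensities.shape:
                raise ValidationError(
                    "detection_p shape "
                    f"{self.detection_p.shape} != intensities shape {self.intensities.shape}"
                )
            vals = self.detection_p.to_numpy()
            if np.any((vals < 0) | (vals > 1)):
                raise ValidationError("detection_p values must lie in [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]


def detection_filter(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    fail_fraction: float = 0.25,
) -> ExpressionMatrix:
    """Drop probes not detected above background in enough samples.

    A probe is *retained* iff the number of samples with detection
    P > ``alpha`` is strictly below ``fail_fraction`` x n_samples, i.e. it
    is excluded when it fails in at least that fraction of samples.

    Raises
    ------
    ValidationError
        If the matrix carries no detection P-values (use --no-qc to skip
        filtering in that case) or the thresholds are out of range.
    """
    if expr.detection_p is None:
        raise ValidationError(
            "expression matrix has no detection P-values; "
            "skip QC explicitly (--no-qc) if your platform provides none"
        )
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if not 0 < fail_fraction <= 1:
        raise ValidationError(f"fail_fraction must be in (0, 1], got {fail_fraction}")

    n = expr.n_samples
    fails = (expr.detection_p.to_numpy() > alpha).sum(axis=1)
    keep = fails < fail_fraction * n
    out = ExpressionMatrix(
        intensities=expr.intensities.loc[keep],
        detection_p=expr.detection_p.loc[keep],
        scale_flag=expr.scale_flag,
    )
    logger.info(
        "detection filter (P>%g in >=%g%% of %d samples): %d of %d probes retained",
        alpha, 100 * fail_fraction, n, out.n_probes, expr.n_probes,
    )
    return out


def _log2_with_offset(values: np.ndarray, offset: float) -> np.ndarray:
    # Background-subtracted intensities can be <= 0; shift before log.
    shifted = values + offset
    if np.any(shifted <= 0):
        raise ValidationError(
            f"non-positive intensities remain after adding log offset {offset}; "
            "increase --log-offset"
        )
    return np.log2(shifted)


def quantile_normalize(expr: ExpressionMatrix, log_offset: float = 1.0) -> ExpressionMatrix:
    """Quantile-normalize log2 intensities across samples.

    Raw matrices are log2-transformed first (after adding ``log_offset`` to
    guard against non-positive background-subtracted values). Each sample's
    values are then replaced by the across-sample means of the order
    statistics, assigned by within-sample rank; tied ranks receive the mean
    of the corresponding rank-wise means, so the map is deterministic and
    preserves within-sample rank order.
    """
    if expr.scale_flag == SCALE_NORMALIZED:
        return expr
    if expr.n_probes < 2:
        raise ValidationError("quantile normalization needs at least 2 probes")

    values = expr.intensities.to_numpy(dtype=float)
    if expr.scale_flag == SCALE_RAW:
        values = _log2_with_offset(values, log_offset)
        logger.info("log2-transformed raw intensities (offset %g)", log_offset)

    if expr.n_samples == 1:
        normalized = values
    else:
        # Rank-wise means of the column-sorted matrix are the common target
        # distribution; a run of tied values gets the mean of the target
        # entries spanning its ranks.
        sorted_cols = np.sort(values, axis=0)
        target = sorted_cols.mean(axis=1)
        normalized = np.empty_like(values)
        for j in range(values.shape[1]):
            col = values[:, j]
            order = np.argsort(col, kind="mergesort")
            xs = col[order]
            run_starts = np.flatnonzero(np.r_[True, xs[1:] != xs[:-1]])
            run_sums = np.add.reduceat(target, run_starts)
            run_lens = np.diff(np.r_[run_starts, xs.size])
            out_sorted = np.repeat(run_sums / run_lens, run_lens)
            normalized[order, j] = out_sorted

    out = ExpressionMatrix(
        intensities=pd.DataFrame(
            normalized, index=expr.intensities.index, columns=expr.intensities.columns
        ),
        detection_p=expr.detection_p,
        scale_flag=SCALE_NORMALIZED,
    )
    logger.info(
        "quantile-normalized %d probes x %d samples", out.n_probes, out.n_samples
    )
    return out
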