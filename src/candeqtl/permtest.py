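"""Permutation-adjusted P-values for the association scan.

The adjusted ("permuted") P-value of a SNP-probe pair is the fraction of
B phenotype relabelings whose nominal P-value ties or beats the observed
one. Because the nominal P of a simple regression is a monotone function
of r-squared at fixed degrees of freedom, the engine compares r-squared
directly and never evaluates the t distribution inside the loop.

Two relabeling schemes are provided:

``joint`` (default)
    One permutation of the sample labels per iteration, shared by every
    pair. This matches permuting the expression phenotypes relative to the
    genotypes, costs O(B) relabelings regardless of the number of pairs,
    and preserves transcript-transcript correlation in the null.
``per_pair``
    Independent relabelings per pair; useful for comparing schemes on
    small problems.

With ``pseudocount="none"`` the estimator is count/B, so a pair never
beaten in B permutations reports exactly 0 and the smallest nonzero value
is 1/B; ``add_one`` gives the strictly positive (count+1)/(B+1) variant.

``exact_permutation_oracle`` enumerates all n! relabelings (n <= 8) and is
the ground truth the Monte-Carlo engine is validated against.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .assocscan import AssociationRecord, GenotypeTable
from .covadjust import ResidualMatrix
from .qcnorm import ValidationError

logger = logging.getLogger(__name__)

#: Absolute tolerance on r-squared when counting permuted >= observed.
#: Relabelings that tie the observed statistic must count against the pair;
#: without slack, float summation order breaks exact ties arbitrarily.
R2_TIE_TOL = 1e-9

SCHEME_JOINT = "joint"
SCHEME_PER_PAIR = "per_pair"
PSEUDOCOUNT_NONE = "none"
PSEUDOCOUNT_ADD_ONE = "add_one"


@dataclass
class PermutationConfig:
    """Settings for the permutation scan."""

    B: int = 10_000
    seed: int = 0
    scheme: str = SCHEME_JOINT
    pseudocount: str = PSEUDOCOUNT_NONE

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValidationError(f"permutation count B must be >= 1, got {self.B}")
        if self.scheme not in (SCHEME_JOINT, SCHEME_PER_PAIR):
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        if self.pseudocount not in (PSEUDOCOUNT_NONE, PSEUDOCOUNT_ADD_ONE):
            raise ValidationError(f"unknown pseudocount {self.pseudocount!r}")


def _r2_matrix(resid: np.ndarray, g: np.ndarray) -> np.ndarray:
    """r-squared of each residual row against one centered genotype vector.

    ``resid`` is probes x samples (already restricted to the SNP's
    non-missing samples); ``g`` must have nonzero variance.
    """
    gc = g - g.mean()
    sxx = gc @ gc
    rc = resid - resid.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", rc, rc)
    sxy = rc @ gc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, sxy * sxy / (sxx * syy), 0.0)
    return r2


def permutation_scan(
    residuals: ResidualMatrix,
    genotypes: GenotypeTable,
    records: list[AssociationRecord],
    config: PermutationConfig,
) -> list[AssociationRecord]:
    """Attach permutation-adjusted P-values to scan records, in place.

    ``records`` must come from ``scan_all`` on the same residuals and
    genotypes (SNP-major order). Degenerate pairs get perm_p = 1. The
    observed r-squared is recomputed with the same vectorized algebra used
    for the permuted statistics, so the tie comparison (permuted >=
    observed counts against the pair) is exact.
    """
    snp_ids = genotypes.snp_ids
    probe_ids = residuals.probe_ids
    n_probes, n_snps = len(probe_ids), len(snp_ids)
    if len(records) != n_probes * n_snps:
        raise ValidationError(
            f"expected {n_probes * n_snps} records (snp-major), got {len(records)}"
        )

    R = residuals.values  # probes x samples
    codes = genotypes.codes.loc[residuals.sample_ids]
    n_samples = R.shape[1]
    rng = np.random.default_rng(config.seed)

    masks: dict[str, np.ndarray] = {}
    gvecs: dict[str, np.ndarray] = {}
    obs_r2 = np.zeros((n_snps, n_probes))
    active = np.zeros(n_snps, dtype=bool)
    for s, snp_id in enumerate(snp_ids):
        g = codes[snp_id].to_numpy(dtype=float)
        mask = ~np.isnan(g)
        gm = g[mask]
        if gm.size >= 3 and np.ptp(gm) > 0:
            masks[snp_id] = mask
            gvecs[snp_id] = gm
            obs_r2[s] = _r2_matrix(R[:, mask], gm)
            active[s] = True

    counts = np.zeros((n_snps, n_probes), dtype=np.int64)
    if config.scheme == SCHEME_JOINT:
        for _ in range(config.B):
            perm = rng.permutation(n_samples)
            Rp = R[:, perm]
            for s, snp_id in enumerate(snp_ids):
                if not active[s]:
                    continue
                r2b = _r2_matrix(Rp[:, masks[snp_id]], gvecs[snp_id])
                counts[s] += r2b >= obs_r2[s] - R2_TIE_TOL
    else:  # per_pair: independent relabelings for every pair
        for s, snp_id in enumerate(snp_ids):
            if not active[s]:
                continue
            mask, gm = masks[snp_id], gvecs[snp_id]
            Rm = R[:, mask]
            for j in range(n_probes):
                y = Rm[j]
                perms = np.array([rng.permutation(y) for _ in range(config.B)])
                r2b = _r2_matrix(perms, gm)
                counts[s, j] += (r2b >= obs_r2[s, j] - R2_TIE_TOL).sum()

    if config.pseudocount == PSEUDOCOUNT_NONE:
        perm_p = counts / config.B
    else:
        perm_p = (counts + 1) / (config.B + 1)

    for idx, rec in enumerate(records):
        s, j = divmod(idx, n_probes)
        if rec.snp_id != snp_ids[s] or rec.probe_id != probe_ids[j]:
            raise ValidationError(
                f"record {idx} ({rec.snp_id}, {rec.probe_id}) out of snp-major order"
            )
        rec.perm_p = 1.0 if (rec.degenerate or not active[s]) else float(perm_p[s, j])

    logger.info(
        "permutation scan: B=%d, scheme=%s, pseudocount=%s, %d pairs",
        config.B, config.scheme, config.pseudocount, len(records),
    )
    return records


def exact_permutation_oracle(
    residual_vector: np.ndarray, genotype_vector: np.ndarray
) -> float:
    """Exact permutation P by enumerating all n! relabelings (n <= 8).

    Counts the fraction of relabelings whose r-squared ties or beats the
    observed one; the identity relabeling always counts, so the result is
    at least 1/n!. A constant residual or genotype vector returns 1.
    """
    y = np.asarray(residual_vector, dtype=float)
    g = np.asarray(genotype_vector, dtype=float)
    if y.shape != g.shape or y.ndim != 1:
        raise ValidationError("vectors must be 1-D and equal length")
    n = y.size
    if n > 8:
        raise ValidationError(f"exact enumeration limited to n <= 8, got {n}")
    if np.ptp(y) == 0 or np.ptp(g) == 0:
        return 1.0

    def r2(yv: np.ndarray) -> float:
        r = np.corrcoef(yv, g)[0, 1]
        return r * r

    observed = r2(y)
    hits = sum(
        1
        for perm in itertools.permutations(range(n))
        if r2(y[list(perm)]) >= observed - R2_TIE_TOL
    )
    return hits / math.factorial(n)
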