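"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a small case/control expression-genetics cohort:
Hardy-Weinberg genotypes at specified minor-allele frequencies for a
handful of candidate SNPs, uniform ages within per-group ranges, and
log2-scale expression built from the same linear model the analysis fits —

    y_gi = mu_g + beta_age * age_i + beta_status * case_i
           + sum_planted beta_s * G_si + eps,   eps ~ N(0, noise_sd^2)

so that planted SNP effects have a known population variance fraction and
probes without planted effects are exact nulls for every SNP. Detection
P-values are two-point (0.01 pass / 0.5 fail) because only the >0.05
threshold matters to the QC filter.

Defaults mirror the study cohort this pipeline was built around: 74 cases
(ages 21-85) and 47 controls (ages 26-89) genotyped at seven ovarian-cancer
risk SNPs; default per-SNP frequencies pool the published case and control
MAFs weighted by group size.

Genotypes are independent across SNPs by default; an optional ``ld_pairs``
knob plants pairwise linkage disequilibrium (haplotype sampling at a given
allelic correlation r) to emulate co-inherited variants at one locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assocscan import GenotypeTable
from .covadjust import CovariateTable
from .qcnorm import SCALE_LOG2, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

#: Published case/control MAFs for the seven genotyped risk SNPs.
CASE_CONTROL_MAFS: dict[str, tuple[float, float]] = {
    "rs3814113": (0.346, 0.298),
    "rs2072590": (0.300, 0.368),
    "rs2665390": (0.081, 0.060),
    "rs10088218": (0.149, 0.107),
    "rs1516982": (0.167, 0.119),
    "rs10098821": (0.127, 0.071),
    "rs2363956": (0.432, 0.488),
}

N_CASES_DEFAULT = 74
N_CONTROLS_DEFAULT = 47


def _pooled_mafs() -> dict[str, float]:
    n, m = N_CASES_DEFAULT, N_CONTROLS_DEFAULT
    return {
        snp: round((n * ca + m * co) / (n + m), 4)
        for snp, (ca, co) in CASE_CONTROL_MAFS.items()
    }


@dataclass
class SimulationConfig:
    """Cohort-level knobs; defaults reproduce the reference study design."""

    n_cases: int = N_CASES_DEFAULT
    n_controls: int = N_CONTROLS_DEFAULT
    snp_mafs: dict[str, float] = field(default_factory=_pooled_mafs)
    planted_effects: list[tuple[str, int, float]] = field(default_factory=list)
    age_range_cases: tuple[float, float] = (21.0, 85.0)
    age_range_controls: tuple[float, float] = (26.0, 89.0)
    covariate_betas: tuple[float, float] = (0.005, 0.1)  # per year, case offset
    noise_sd: float = 1.0
    n_probes: int = 500
    detection_miss_rate: float = 0.0
    ld_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError(
                f"group sizes must be positive (got {self.n_cases} cases, "
                f"{self.n_controls} controls)"
            )
        if self.n_cases + self.n_controls < 3:
            raise ValidationError("need at least 3 samples in total")
        for snp, p in self.snp_mafs.items():
            if not 0.0 <= p <= 0.5:
                raise ValidationError(f"MAF for {snp} must be in [0, 0.5], got {p}")
        for snp, probe, f in self.planted_effects:
            if not 0.0 <= f < 1.0:
                raise ValidationError(
                    f"variance fraction for ({snp}, probe {probe}) must be in [0, 1), got {f}"
                )
            if snp not in self.snp_mafs:
                raise ValidationError(f"planted effect references unknown SNP {snp!r}")
            if not 0 <= probe < self.n_probes:
                raise ValidationError(
                    f"planted probe index {probe} out of range [0, {self.n_probes})"
                )
        for lo, hi in (self.age_range_cases, self.age_range_controls):
            if not lo < hi:
                raise ValidationError(f"age range must have min < max, got ({lo}, {hi})")
        if self.noise_sd <= 0:
            raise ValidationError(f"noise_sd must be positive, got {self.noise_sd}")
        if not 0.0 <= self.detection_miss_rate <= 1.0:
            raise ValidationError("detection_miss_rate must be in [0, 1]")
        for a, b, r in self.ld_pairs:
            if a not in self.snp_mafs or b not in self.snp_mafs:
                raise ValidationError(f"LD pair ({a}, {b}) references unknown SNP")
            if not -1.0 < r < 1.0:
                raise ValidationError(f"LD correlation must be in (-1, 1), got {r}")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def sample_ids(self) -> list[str]:
        return [f"case{i + 1:03d}" for i in range(self.n_cases)] + [
            f"ctrl{i + 1:03d}" for i in range(self.n_controls)
        ]

    @property
    def probe_ids(self) -> list[str]:
        return [f"probe{i:05d}" for i in range(self.n_probes)]


def _haplotype_pair(pa: float, pb: float, r: float, n: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes for two SNPs with allelic (haplotype) correlation r."""
    d = r * np.sqrt(pa * (1 - pa) * pb * (1 - pb))
    p11 = pa * pb + d          # haplotype carrying both minor alleles
    p10 = pa * (1 - pb) - d
    p01 = (1 - pa) * pb - d
    p00 = (1 - pa) * (1 - pb) + d
    probs = np.array([p11, p10, p01, p00])
    if np.any(probs < -1e-12):
        raise ValidationError(
            f"LD correlation {r} infeasible for MAFs ({pa}, {pb})"
        )
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    haps = rng.choice(4, size=(n, 2), p=probs)
    a = (haps < 2).sum(axis=1).astype(float)          # minor allele of SNP a
    b = np.isin(haps, (0, 2)).sum(axis=1).astype(float)
    return a, b


def simulate_genotypes(config: SimulationConfig) -> GenotypeTable:
    """Hardy-Weinberg genotypes: code ~ Binomial(2, MAF) per sample per SNP."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_samples
    codes = pd.DataFrame(index=config.sample_ids, columns=list(config.snp_mafs),
                         dtype=float)
    ld_members = {s for a, b, _ in config.ld_pairs for s in (a, b)}
    for snp, p in config.snp_mafs.items():
        if snp in ld_members:
            continue
        codes[snp] = rng.binomial(2, p, size=n).astype(float)
    for a, b, r in config.ld_pairs:
        ga, gb = _haplotype_pair(config.snp_mafs[a], config.snp_mafs[b], r, n, rng)
        codes[a], codes[b] = ga, gb
    logger.info("simulated genotypes: %d samples x %d SNPs", n, len(config.snp_mafs))
    return GenotypeTable(codes=codes)


def simulate_covariates(config: SimulationConfig) -> CovariateTable:
    """Uniform ages within each group's range; status fixed by group."""
    rng = np.random.default_rng([config.seed, 1])
    ages = np.concatenate([
        rng.uniform(*config.age_range_cases, size=config.n_cases),
        rng.uniform(*config.age_range_controls, size=config.n_controls),
    ])
    status = ["case"] * config.n_cases + ["control"] * config.n_controls
    table = pd.DataFrame({"age": ages, "status": status},
                         index=pd.Index(config.sample_ids, name="sample_id"))
    return CovariateTable(table=table)


def effect_size_to_beta(variance_fraction: float, maf: float,
                        residual_sd: float) -> float:
    """Slope that makes a planted additive effect explain a target R^2.

    Under Hardy-Weinberg the genotype variance is 2p(1-p), so a slope
    beta explains beta^2 * 2p(1-p) of the total variance
    beta^2 * 2p(1-p) + residual_sd^2. Solving for the slope whose
    population coefficient of determination equals ``variance_fraction`` f:

        beta = residual_sd * sqrt( f / ((1 - f) * 2p(1-p)) )
    """
    if not 0.0 <= variance_fraction < 1.0:
        raise ValidationError(f"variance fraction must be in [0, 1), got {variance_fraction}")
    if residual_sd <= 0:
        raise ValidationError(f"residual_sd must be positive, got {residual_sd}")
    if variance_fraction == 0.0:
        return 0.0
    if not 0.0 < maf <= 0.5:
        raise ValidationError(
            f"MAF must be in (0, 0.5] for a nonzero planted effect, got {maf}"
        )
    geno_var = 2.0 * maf * (1.0 - maf)
    return residual_sd * np.sqrt(
        variance_fraction / ((1.0 - variance_fraction) * geno_var)
    )


def simulate_expression(
    genotypes: GenotypeTable,
    covariates: CovariateTable,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """log2-scale expression from the additive model, plus detection P-values.

    Probe baselines are drawn uniform in [6, 12] (typical log2 intensity
    range for expression arrays). Probes without planted effects are exact
    nulls for every SNP. Detection P-values are 0.01 except for cells
    failed at ``detection_miss_rate`` (set to 0.5, i.e. above the 0.05
    threshold), exercising the QC filter.
    """
    if list(genotypes.sample_ids) != list(covariates.sample_ids):
        raise ValidationError("genotype and covariate sample sets differ")
    rng = np.random.default_rng([config.seed, 2])
    n = config.n_samples
    beta_age, beta_status = config.covariate_betas

    mu = rng.uniform(6.0, 12.0, size=config.n_probes)
    y = np.tile(mu[:, None], (1, n))
    y += beta_age * covariates.age + beta_status * covariates.status_indicator

    for snp, probe_idx, f in config.planted_effects:
        beta = effect_size_to_beta(f, config.snp_mafs[snp], config.noise_sd)
        y[probe_idx] += beta * genotypes.codes[snp].to_numpy(dtype=float)

    y += rng.normal(0.0, config.noise_sd, size=y.shape)

    detection = np.full(y.shape, 0.01)
    if config.detection_miss_rate > 0:
        fails = rng.random(y.shape) < config.detection_miss_rate
        detection[fails] = 0.5

    index = pd.Index(config.probe_ids, name="probe_id")
    logger.info(
        "simulated expression: %d probes x %d samples, %d planted effects",
        config.n_probes, n, len(config.planted_effects),
    )
    return ExpressionMatrix(
        intensities=pd.DataFrame(y, index=index, columns=config.sample_ids),
        detection_p=pd.DataFrame(detection, index=index, columns=config.sample_ids),
        scale_flag=SCALE_LOG2,
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GenotypeTable, CovariateTable]:
    """Genotypes, covariates and expression for one synthetic cohort."""
    genotypes = simulate_genotypes(config)
    covariates = simulate_covariates(config)
    expression = simulate_expression(genotypes, covariates, config)
    return expression, genotypes, covariates
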