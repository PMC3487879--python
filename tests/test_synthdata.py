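"""Generator statistics: Hardy-Weinberg, covariate structure, planted effects."""

import numpy as np
import pytest

from candeqtl import (
    SimulationConfig,
    ValidationError,
    effect_size_to_beta,
    simulate_covariates,
    simulate_expression,
    simulate_genotypes,
)
from candeqtl.assocscan import regress_pair


def _config(**kwargs):
    defaults = dict(n_probes=5, seed=1)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestGenotypes:
    def test_maf_zero_gives_all_reference(self):
        cfg = _config(snp_mafs={"s": 0.0}, n_cases=74, n_controls=47)
        table = simulate_genotypes(cfg)
        assert (table.codes["s"] == 0).all()

    def test_maf_half_mean_dosage_near_one(self):
        cfg = _config(snp_mafs={"s": 0.5}, n_cases=5000, n_controls=5000)
        codes = simulate_genotypes(cfg).codes["s"].to_numpy()
        se = np.sqrt(2 * 0.5 * 0.5 / codes.size)  # SD of mean dosage
        assert abs(codes.mean() - 1.0) < 3 * se

    def test_hardy_weinberg_heterozygote_fraction(self):
        # 2pq at p=0.127 is 0.2217; check at n=100,000
        p = 0.127
        cfg = _config(snp_mafs={"s": p}, n_cases=50_000, n_controls=50_000)
        codes = simulate_genotypes(cfg).codes["s"].to_numpy()
        het = 2 * p * (1 - p)
        se = np.sqrt(het * (1 - het) / codes.size)
        assert abs((codes == 1).mean() - het) < 3 * se

    def test_codes_in_allowed_set_and_deterministic(self):
        cfg = _config(snp_mafs={"a": 0.2, "b": 0.4}, n_cases=100, n_controls=50)
        t1 = simulate_genotypes(cfg)
        t2 = simulate_genotypes(cfg)
        assert t1.codes.equals(t2.codes)
        assert t1.codes.isin([0.0, 1.0, 2.0]).all().all()

    def test_maf_out_of_range_names_snp(self):
        with pytest.raises(ValidationError, match="rs_bad"):
            _config(snp_mafs={"rs_bad": 0.7})

    def test_ld_pair_recovers_allelic_correlation(self):
        cfg = _config(
            snp_mafs={"a": 0.3, "b": 0.3},
            ld_pairs=[("a", "b", 0.8)],
            n_cases=10_000,
            n_controls=10_000,
        )
        codes = simulate_genotypes(cfg).codes
        r = np.corrcoef(codes["a"], codes["b"])[0, 1]
        assert abs(r - 0.8) < 0.05
        # marginal MAFs preserved under LD sampling
        assert abs(codes["a"].mean() / 2 - 0.3) < 0.01

    def test_infeasible_ld_rejected(self):
        cfg = _config(snp_mafs={"a": 0.05, "b": 0.45}, ld_pairs=[("a", "b", 0.95)])
        with pytest.raises(ValidationError, match="infeasible"):
            simulate_genotypes(cfg)


class TestCovariates:
    def test_cohort_composition(self):
        cov = simulate_covariates(_config(n_cases=74, n_controls=47))
        assert len(cov.table) == 121
        assert cov.n_cases == 74
        assert cov.n_controls == 47

    def test_ages_within_group_ranges(self):
        cfg = _config(n_cases=200, n_controls=200,
                      age_range_cases=(21, 85), age_range_controls=(26, 89))
        cov = simulate_covariates(cfg)
        cases = cov.table[cov.table["status"] == "case"]["age"]
        controls = cov.table[cov.table["status"] == "control"]["age"]
        assert cases.between(21, 85).all()
        assert controls.between(26, 89).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            _config(n_cases=0, n_controls=47)

    def test_bad_age_range_rejected(self):
        with pytest.raises(ValidationError):
            _config(age_range_cases=(85, 21))


class TestEffectSizeToBeta:
    def test_zero_fraction_gives_zero_slope(self):
        assert effect_size_to_beta(0.0, 0.127, 1.0) == 0.0

    def test_closed_form_at_half(self):
        # f=0.5, p=0.5: beta = sqrt(0.5 / (0.5 * 2*0.25)) = sqrt(2)
        assert effect_size_to_beta(0.5, 0.5, 1.0) == pytest.approx(np.sqrt(2))

    def test_large_sample_r2_matches_target(self):
        rng = np.random.default_rng(5)
        f, p = 0.13, 0.127
        beta = effect_size_to_beta(f, p, 1.0)
        g = rng.binomial(2, p, 100_000).astype(float)
        y = beta * g + rng.normal(0, 1.0, g.size)
        r2 = np.corrcoef(g, y)[0, 1] ** 2
        assert abs(r2 - f) < 0.01

    def test_no_genotype_variance_rejected(self):
        with pytest.raises(ValidationError):
            effect_size_to_beta(0.2, 0.0, 1.0)


class TestExpression:
    def test_shape_and_determinism(self):
        cfg = _config(n_probes=12, n_cases=10, n_controls=8)
        geno = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg)
        e1 = simulate_expression(geno, cov, cfg)
        e2 = simulate_expression(geno, cov, cfg)
        assert e1.intensities.shape == (12, 18)
        assert e1.intensities.equals(e2.intensities)
        assert e1.detection_p.equals(e2.detection_p)

    def test_zero_miss_rate_all_probes_detected(self):
        cfg = _config(n_probes=10, n_cases=10, n_controls=8, detection_miss_rate=0.0)
        geno, cov = simulate_genotypes(cfg), simulate_covariates(cfg)
        expr = simulate_expression(geno, cov, cfg)
        assert (expr.detection_p.to_numpy() == 0.01).all()

    def test_miss_rate_produces_failures(self):
        cfg = _config(n_probes=200, n_cases=30, n_controls=30,
                      detection_miss_rate=0.3)
        geno, cov = simulate_genotypes(cfg), simulate_covariates(cfg)
        expr = simulate_expression(geno, cov, cfg)
        frac = (expr.detection_p.to_numpy() > 0.05).mean()
        assert abs(frac - 0.3) < 0.02

    def test_planted_effect_recovered_in_regression(self):
        cfg = _config(
            n_probes=5, n_cases=2000, n_controls=2000,
            snp_mafs={"s": 0.3}, planted_effects=[("s", 2, 0.2)],
            covariate_betas=(0.0, 0.0),
        )
        geno, cov = simulate_genotypes(cfg), simulate_covariates(cfg)
        expr = simulate_expression(geno, cov, cfg)
        g = geno.codes["s"].to_numpy()
        planted = regress_pair(expr.intensities.iloc[2].to_numpy(), g)
        null = regress_pair(expr.intensities.iloc[0].to_numpy(), g)
        assert abs(planted.r2 - 0.2) < 0.03
        assert null.r2 < 0.01

    def test_planted_probe_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="out of range"):
            _config(n_probes=5, planted_effects=[("rs10098821", 9, 0.1)])

    def test_mismatched_samples_rejected(self):
        cfg_a = _config(n_cases=10, n_controls=8)
        cfg_b = _config(n_cases=9, n_controls=8)
        geno = simulate_genotypes(cfg_a)
        cov = simulate_covariates(cfg_b)
        with pytest.raises(ValidationError):
            simulate_expression(geno, cov, cfg_a)
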