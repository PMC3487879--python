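"""Permutation engine vs exact enumeration, determinism, null behavior."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from candeqtl import (
    GenotypeTable,
    PermutationConfig,
    ResidualMatrix,
    ValidationError,
    exact_permutation_oracle,
    permutation_scan,
    scan_all,
)


def _setup(values, codes_dict):
    """ResidualMatrix + GenotypeTable + fresh scan records."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = [f"s{i}" for i in range(values.shape[1])]
    resid = ResidualMatrix(
        residuals=pd.DataFrame(
            values, index=[f"p{i}" for i in range(values.shape[0])], columns=samples
        )
    )
    geno = GenotypeTable(codes=pd.DataFrame(codes_dict, index=samples, dtype=float))
    return resid, geno, scan_all(resid, geno)


Y6 = [1.0, 0.8, 2.1, 1.9, 3.2, 2.9]
G6 = [0.0, 0, 1, 1, 2, 2]


class TestExactOracle:
    def test_n3_brute_force(self):
        # independent enumeration with corrcoef, written out by hand
        y = np.array([1.0, 2.0, 5.0])
        g = np.array([0.0, 1.0, 2.0])
        obs = np.corrcoef(y, g)[0, 1] ** 2
        hits = sum(
            np.corrcoef(np.array(p), g)[0, 1] ** 2 >= obs - 1e-12
            for p in itertools.permutations(y)
        )
        assert exact_permutation_oracle(y, g) == pytest.approx(hits / 6)

    def test_constant_residuals_give_one(self):
        assert exact_permutation_oracle(np.ones(5), np.arange(5.0)) == 1.0

    def test_includes_identity_so_never_below_one_over_nfact(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=6)
        assert exact_permutation_oracle(y, np.array(G6)) >= 1 / math.factorial(6)

    def test_perfectly_separated_counts_grouping_preserving_relabelings(self):
        # residuals equal the codes: |r|=1 only for relabelings that keep
        # the three dosage groups intact: (2!)^3 * 3! orderings... of which
        # only those mapping equal values together reproduce r^2 = 1.
        g = np.array(G6)
        p = exact_permutation_oracle(g.astype(float), g)
        hits = sum(
            abs(np.corrcoef(np.array(perm), g)[0, 1]) >= 1 - 1e-12
            for perm in itertools.permutations(g.astype(float))
        )
        assert p == pytest.approx(hits / math.factorial(6))

    def test_refuses_large_n(self):
        with pytest.raises(ValidationError, match="n <= 8"):
            exact_permutation_oracle(np.arange(9.0), np.arange(9.0))


class TestPermutationScan:
    def test_monte_carlo_matches_exact_enumeration(self):
        resid, geno, records = _setup(Y6, {"snp": G6})
        exact = exact_permutation_oracle(np.array(Y6), np.array(G6))
        permutation_scan(resid, geno, records, PermutationConfig(B=10_000, seed=9))
        mc = records[0].perm_p
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(mc - exact) < 3 * se

    def test_same_seed_identical_different_seed_not_required(self):
        resid, geno, r1 = _setup(np.random.default_rng(0).normal(size=(10, 20)),
                                 {"a": np.tile([0, 1, 2, 1], 5)})
        _, _, r2 = _setup(resid.values, {"a": np.tile([0, 1, 2, 1], 5)})
        cfg = PermutationConfig(B=500, seed=123)
        permutation_scan(resid, geno, r1, cfg)
        permutation_scan(resid, geno, r2, cfg)
        assert [x.perm_p for x in r1] == [x.perm_p for x in r2]

    def test_pseudocount_add_one_strictly_positive(self):
        resid, geno, records = _setup(Y6, {"snp": G6})
        permutation_scan(
            resid, geno, records,
            PermutationConfig(B=100, seed=2, pseudocount="add_one"),
        )
        for rec in records:
            assert rec.perm_p > 0
            assert (rec.perm_p * 101) == pytest.approx(round(rec.perm_p * 101))

    def test_perm_p_on_count_over_b_grid(self):
        resid, geno, records = _setup(np.random.default_rng(1).normal(size=(4, 12)),
                                      {"a": np.tile([0, 1, 2], 4)})
        B = 250
        permutation_scan(resid, geno, records, PermutationConfig(B=B, seed=5))
        for rec in records:
            assert rec.perm_p * B == pytest.approx(round(rec.perm_p * B))
            assert 0.0 <= rec.perm_p <= 1.0

    def test_degenerate_snp_gets_perm_p_one(self):
        resid, geno, records = _setup(Y6, {"mono": [1] * 6})
        permutation_scan(resid, geno, records, PermutationConfig(B=50, seed=1))
        assert records[0].perm_p == 1.0

    def test_schemes_agree_on_strong_signal(self):
        rng = np.random.default_rng(6)
        g = np.tile([0.0, 1, 2], 10)
        y = 2.0 * g + rng.normal(0, 0.5, 30)
        for scheme in ("joint", "per_pair"):
            resid, geno, records = _setup(y, {"snp": g})
            permutation_scan(resid, geno, records,
                             PermutationConfig(B=2000, seed=3, scheme=scheme))
            assert records[0].perm_p < 0.01

    def test_invariant_to_monotone_transform_of_statistic(self):
        # perm_p depends on residual/genotype values only through r^2
        # ranks; doubling all residuals cannot change it
        resid, geno, records = _setup(Y6, {"snp": G6})
        resid2, geno2, records2 = _setup(2.0 * np.array(Y6), {"snp": G6})
        cfg = PermutationConfig(B=1000, seed=17)
        permutation_scan(resid, geno, records, cfg)
        permutation_scan(resid2, geno2, records2, cfg)
        assert records[0].perm_p == records2[0].perm_p

    def test_bad_b_rejected(self):
        with pytest.raises(ValidationError, match="B"):
            PermutationConfig(B=0)

    def test_record_order_mismatch_detected(self):
        resid, geno, records = _setup(np.random.default_rng(0).normal(size=(3, 6)),
                                      {"snp": G6})
        records.reverse()
        with pytest.raises(ValidationError, match="order"):
            permutation_scan(resid, geno, records, PermutationConfig(B=10, seed=0))


class TestNullCalibration:
    def test_null_perm_p_roughly_uniform(self):
        # 200 null probes, one SNP: empirical CDF at 0.2/0.5/0.8 within
        # 3 binomial SE of uniform
        rng = np.random.default_rng(13)
        n, n_probes = 60, 200
        g = rng.binomial(2, 0.3, n).astype(float)
        resid, geno, records = _setup(rng.normal(size=(n_probes, n)), {"snp": g})
        permutation_scan(resid, geno, records, PermutationConfig(B=400, seed=13))
        pp = np.array([r.perm_p for r in records])
        for q in (0.2, 0.5, 0.8):
            se = np.sqrt(q * (1 - q) / n_probes)
            assert abs((pp < q).mean() - q) < 3 * se
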