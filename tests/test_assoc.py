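from fractions import Fraction
from math import comb

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import kstest
from sklearn.metrics import silhouette_score

from mitocohort.assoc import (
    GenotypeMatrix,
    filter_genotypes,
    genotype_pca,
    glm_scan,
    hwe_exact_p,
    select_mt_phenotypes,
    significance_thresholds,
)
from mitocohort.mt_variants import MtVariantCall
from mitocohort.synthetic_data import gen_assoc_dataset


def exact_hwe_fraction(n_AA, n_Aa, n_aa):
    """Independent oracle via exact rational arithmetic over het counts."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa
    nA = 2 * n - na
    rare = min(na, nA)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = (2 * n - rare - h) // 2
        # multinomial count of genotype configurations times allele weight
        probs[h] = Fraction(2**h * comb(n, hr) * comb(n - hr, h), 1)
    total = sum(probs.values())
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


class TestHweExact:
    def test_perfect_hwe_p_one(self):
        assert hwe_exact_p(25, 50, 25) == pytest.approx(1.0)

    def test_tiny_case_full_enumeration(self):
        # alleles 2A/2a over 2 diploids: het counts {0, 2} with probs {1/3, 2/3}
        assert hwe_exact_p(1, 0, 1) == pytest.approx(1 / 3)
        assert hwe_exact_p(0, 2, 0) == pytest.approx(1.0)

    def test_monomorphic_p_one(self):
        assert hwe_exact_p(10, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts", [(3, 2, 1), (5, 5, 5), (10, 1, 4), (2, 8, 2), (7, 0, 7)]
    )
    def test_matches_rational_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(exact_hwe_fraction(*counts), rel=1e-9)

    def test_extreme_het_deficit_tiny_p(self):
        assert hwe_exact_p(50, 0, 50) < 1e-6

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 0, 0)


class TestFilterGenotypes:
    def mk(self, dosages):
        d = np.asarray(dosages, dtype=float)
        return GenotypeMatrix(
            samples=[f"S{i}" for i in range(d.shape[0])],
            variant_ids=[f"v{j}" for j in range(d.shape[1])],
            dosages=d,
        )

    def test_low_call_rate_variant_dropped(self):
        col = np.ones((20, 1))
        col[:4] = np.nan  # 80% variant call rate; sample call rates stay > 0.9
        good = np.tile(np.tile([0, 1, 2, 1], 5).reshape(20, 1), (1, 10))
        g = self.mk(np.hstack([col, good]))
        out, log = filter_genotypes(g, min_maf=0.0)
        assert "v0" not in out.variant_ids and "v1" in out.variant_ids
        assert ("v0", "variant", "call_rate") in list(log.itertuples(index=False, name=None))

    def test_maf_counting(self):
        # dosages [0,1,2,2]: alt freq 0.625, MAF 0.375 -> kept
        g = self.mk(np.array([[0], [1], [2], [2]]))
        out, _ = filter_genotypes(g, min_hwe_p=0.0)
        assert out.variant_ids == ["v0"]

    def test_monomorphic_dropped_by_maf(self):
        g = self.mk(np.ones((10, 1)) * 2)
        out, log = filter_genotypes(g)
        assert out.variant_ids == []
        assert log.reason.tolist() == ["maf"]

    def test_hwe_outlier_dropped(self):
        # 50/0/50: p << 1e-6 per exact test
        col = np.array([0] * 50 + [2] * 50, dtype=float).reshape(-1, 1)
        g = self.mk(col)
        out, log = filter_genotypes(g)
        assert out.variant_ids == [] and log.reason.tolist() == ["hwe"]

    def test_all_samples_dropped_is_error(self):
        g = self.mk(np.full((3, 2), np.nan))
        with pytest.raises(ValueError):
            filter_genotypes(g)


class TestSelectMtPhenotypes:
    def call(self, sample, vaf, pos=750):
        level = "homoplasmic" if vaf >= 0.95 else "heteroplasmic"
        return MtVariantCall(sample, pos, "A", "G", vaf, 500, level)

    def test_common_variant_selected_with_zeros_for_noncarriers(self):
        samples = [f"S{i}" for i in range(50)]
        calls = [self.call(f"S{i}", 0.8) for i in range(3)]  # 6% of samples
        df = select_mt_phenotypes(calls, samples, min_freq=0.05)
        assert list(df.columns) == ["m.750A>G"]
        assert df.iloc[0, 0] == 0.8 and df.iloc[10, 0] == 0.0

    def test_rare_variant_excluded(self):
        samples = [f"S{i}" for i in range(100)]
        calls = [self.call("S0", 1.0)]
        df = select_mt_phenotypes(calls, samples, min_freq=0.05)
        assert df.shape[1] == 0


class TestGenotypePca:
    def test_two_population_structure_recovered(self):
        gmat, _, truth = gen_assoc_dataset(
            n=300, n_snps=300, n_causal=0, two_populations=True, pop_shift=0.3, seed=9
        )
        gmat, _ = filter_genotypes(gmat, min_maf=0.01)
        pcs = genotype_pca(gmat, k=2)
        sil = silhouette_score(pcs[:, :1], truth.extras["pop"][: len(gmat.samples)])
        assert sil > 0.8

    def test_zero_k_empty_block(self):
        gmat, _, _ = gen_assoc_dataset(n=50, n_snps=20, seed=1)
        assert genotype_pca(gmat, k=0).shape == (50, 0)

    def test_identical_samples_error(self):
        g = GenotypeMatrix(["a", "b"], ["v0"], np.array([[1.0], [1.0]]))
        with pytest.raises(ValueError):
            genotype_pca(g, k=1)

    def test_k_exceeding_rank_error(self):
        gmat, _, _ = gen_assoc_dataset(n=5, n_snps=50, seed=2)
        with pytest.raises(ValueError):
            genotype_pca(gmat, k=20)


class TestThresholds:
    def test_published_divisors(self):
        primary, stringent = significance_thresholds(0.05, 5e-8, 93)
        assert primary == pytest.approx(0.05 / 93)
        assert stringent == pytest.approx(5e-8 / 93)
        # two-significant-figure presentation
        assert float(f"{primary:.1e}") == 5.4e-4
        assert float(f"{stringent:.1e}") == 5.4e-10

    def test_single_phenotype_identity(self):
        assert significance_thresholds(0.05, 5e-8, 1) == (0.05, 5e-8)

    def test_zero_alpha(self):
        assert significance_thresholds(0.0, 0.0, 10) == (0.0, 0.0)

    def test_zero_phenotypes_error(self):
        with pytest.raises(ValueError):
            significance_thresholds(n_mt=0)


class TestGlmScan:
    def test_matches_statsmodels_ols(self):
        gmat, y, _ = gen_assoc_dataset(n=300, n_snps=10, n_causal=2, seed=4)
        cov = np.random.default_rng(0).normal(size=(300, 3))
        results = glm_scan(y, gmat, covariates=cov, n_mt=1)
        for j in (0, 3, 7):
            X = sm.add_constant(np.column_stack([gmat.dosages[:, j], cov]))
            fit = sm.OLS(y, X).fit()
            assert results[j].beta == pytest.approx(fit.params[1], rel=1e-8)
            assert results[j].se == pytest.approx(fit.bse[1], rel=1e-8)
            assert results[j].p_value == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_no_covariates_equals_simple_regression_closed_form(self):
        gmat, y, _ = gen_assoc_dataset(n=200, n_snps=5, n_causal=1, seed=6)
        results = glm_scan(y, gmat, covariates=None, n_mt=1)
        for j, r in enumerate(results):
            x = gmat.dosages[:, j]
            xc, yc = x - x.mean(), y - y.mean()
            beta = (xc * yc).sum() / (xc**2).sum()
            assert r.beta == pytest.approx(beta, rel=1e-10)

    def test_planted_beta_recovered_within_3se(self):
        gmat, y, truth = gen_assoc_dataset(
            n=2000, n_snps=50, n_causal=3, beta=0.1, noise_sd=0.05, seed=8
        )
        results = {r.ndna_variant: r for r in glm_scan(y, gmat, n_mt=1)}
        for vid, beta in truth.assoc_betas.items():
            r = results[vid]
            assert abs(r.beta - beta) < 3 * r.se

    def test_permuted_phenotype_p_uniform(self):
        gmat, y, _ = gen_assoc_dataset(n=500, n_snps=1200, n_causal=0, seed=10)
        rng = np.random.default_rng(11)
        y_perm = rng.permutation(y)
        results = glm_scan(y_perm, gmat, n_mt=1)
        ps = np.array([r.p_value for r in results if not np.isnan(r.p_value)])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_dosage_flagged_na(self):
        g = GenotypeMatrix(
            [f"S{i}" for i in range(30)],
            ["const", "ok"],
            np.column_stack([np.ones(30), np.tile([0, 1, 2], 10)]),
        )
        y = np.random.default_rng(3).normal(size=30)
        results = glm_scan(y, g, n_mt=1)
        assert np.isnan(results[0].beta) and not results[0].significant_primary
        assert not np.isnan(results[1].beta)

    def test_bh_qvalues_monotone_in_p(self):
        gmat, y, _ = gen_assoc_dataset(n=200, n_snps=100, n_causal=5, seed=12)
        results = glm_scan(y, gmat, n_mt=1)
        rows = sorted(
            [(r.p_value, r.q_value) for r in results if not np.isnan(r.p_value)]
        )
        qs = [q for _, q in rows]
        assert qs == sorted(qs)
        assert all(q >= p for p, q in rows)

    def test_confounded_scan_calibrated_only_with_covariates(self):
        gmat, y, truth = gen_assoc_dataset(
            n=600, n_snps=400, n_causal=0, two_populations=True,
            pop_shift=0.25, confound=0.1, seed=13,
        )
        gmat, _ = filter_genotypes(gmat, min_maf=0.01)
        naive = glm_scan(y, gmat, n_mt=1)
        pcs = genotype_pca(gmat, k=2)
        adj = glm_scan(y, gmat, covariates=pcs, n_mt=1)
        frac = lambda rs: np.mean([r.p_value <= 0.05 for r in rs if not np.isnan(r.p_value)])
        assert frac(naive) > 0.15          # inflation under stratification
        assert abs(frac(adj) - 0.05) < 0.04  # restored calibration
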