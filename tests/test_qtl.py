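import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apaqtl import qtl
from apaqtl.qtl import (CovariateSet, call_snp_level, compute_hidden_factors,
                        filter_snps, genomic_inflation, map_cis,
                        permutation_calibrate, storey_qvalues)


def _snp_frame(m):
    return pd.DataFrame({"snp": [f"rs{j}" for j in range(m)], "chrom": "chr1",
                         "pos": np.arange(m) * 1000 + 1})


class TestHiddenFactors:
    def test_rank_one_matrix_recovers_generating_vector(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(50)
        v = rng.standard_normal(30)
        vals = pd.DataFrame(np.outer(v, u))  # transcripts x samples
        f = compute_hidden_factors(vals, 1)[:, 0]
        r = abs(np.corrcoef(f, u)[0, 1])
        assert r > 0.999

    def test_factors_are_orthonormal(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.standard_normal((40, 60)))
        F = compute_hidden_factors(vals, 3)
        assert np.allclose(F.T @ F, np.eye(3), atol=1e-8)

    def test_planted_batch_shift_captured_by_first_factor(self):
        rng = np.random.default_rng(2)
        batch = np.repeat([0.0, 1.0], 50)
        X = rng.normal(0.5, 0.02, size=(80, 100))
        X += 0.3 * batch[None, :]  # same shift in every transcript
        f1 = compute_hidden_factors(pd.DataFrame(X), 1)[:, 0]
        assert abs(np.corrcoef(f1, batch)[0, 1]) > 0.9

    def test_invalid_k_rejected(self):
        vals = pd.DataFrame(np.ones((5, 5)))
        with pytest.raises(ValueError):
            compute_hidden_factors(vals, 0)


class TestSnpFilters:
    def test_single_heterozygote_removed_by_allele_count(self):
        dos = np.zeros((200, 1), dtype=np.int8)
        dos[0, 0] = 1  # one allele copy < 10
        kept, _ = filter_snps(dos, _snp_frame(1))
        assert kept.shape[1] == 0

    def test_maf_exactly_at_threshold_retained(self):
        # 500 diploids, 10 alt copies: MAF = 0.01 exactly and count = 10
        dos = np.zeros((500, 1), dtype=np.int8)
        dos[:10, 0] = 1
        kept, meta = filter_snps(dos, _snp_frame(1))
        assert kept.shape[1] == 1

    def test_monomorphic_removed(self):
        dos = np.full((100, 2), 2, dtype=np.int8)
        dos[:, 1] = np.tile([0, 1], 50)
        kept, meta = filter_snps(dos, _snp_frame(2))
        assert list(meta["snp"]) == ["rs1"]


class TestMapCis:
    def test_matches_normal_equations_solver(self):
        """beta/se/p equal a brute-force OLS on the full design to 1e-8."""
        rng = np.random.default_rng(3)
        n, m = 60, 5
        G = rng.integers(0, 3, size=(n, m)).astype(float)
        cov = rng.standard_normal((n, 2))
        y = 0.1 * G[:, 2] + cov @ [0.3, -0.2] + rng.standard_normal(n)
        recs = map_cis(y, G, _snp_frame(m), CovariateSet(known=cov),
                       min_samples=10).set_index("snp")
        for j in range(m):
            X = np.column_stack([np.ones(n), cov, G[:, j]])
            bhat = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ bhat
            df = n - X.shape[1]
            sigma2 = resid @ resid / df
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1])
            t = bhat[-1] / se
            p = 2 * stats.t.sf(abs(t), df)
            row = recs.loc[f"rs{j}"]
            assert np.isclose(row["beta"], bhat[-1], atol=1e-8)
            assert np.isclose(row["se"], se, atol=1e-8)
            assert np.isclose(row["p"], p, rtol=1e-6)

    def test_perfect_linear_relation_recovered(self):
        rng = np.random.default_rng(4)
        G = rng.integers(0, 3, size=(50, 3)).astype(float)
        y = 0.1 * G[:, 0]
        recs = map_cis(y, G, _snp_frame(3), min_samples=10)
        lead = recs.iloc[0]
        assert lead["snp"] == "rs0"
        assert np.isclose(lead["beta"], 0.1, atol=1e-10)
        assert lead["p"] <= np.finfo(float).tiny * 10

    def test_orthogonal_covariate_leaves_beta_unchanged(self):
        rng = np.random.default_rng(5)
        n = 80
        G = rng.integers(0, 3, size=(n, 4)).astype(float)
        y = rng.standard_normal(n)
        base = map_cis(y, G, _snp_frame(4), min_samples=10).set_index("snp")
        # build a covariate orthogonal to y, the intercept and every SNP
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), y, G]))
        c = rng.standard_normal(n)
        c -= Q @ (Q.T @ c)
        with_cov = map_cis(y, G, _snp_frame(4), CovariateSet(known=c[:, None]),
                           min_samples=10).set_index("snp")
        assert np.allclose(base["beta"], with_cov.loc[base.index, "beta"],
                           atol=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            map_cis(np.ones(10), np.ones((10, 1)), _snp_frame(1))


class TestPermutation:
    def test_pseudocount_floor_when_observed_beats_all(self):
        rng = np.random.default_rng(6)
        n = 100
        G = rng.integers(0, 3, size=(n, 5)).astype(float)
        y = 0.5 * G[:, 0] + 0.01 * rng.standard_normal(n)
        res = permutation_calibrate(y, G, _snp_frame(5), n_perm=1000, seed=1)
        assert np.isclose(res.empirical_p, 1.0 / 1001.0)
        assert res.lead_snp == "rs0"

    def test_null_empirical_p_is_uniform(self):
        """Permutation exchangeability: null genes give uniform empirical p."""
        rng = np.random.default_rng(7)
        n = 60
        emp = []
        for g in range(200):
            G = rng.integers(0, 3, size=(n, 8)).astype(float)
            y = rng.standard_normal(n)
            emp.append(permutation_calibrate(y, G, _snp_frame(8), n_perm=100,
                                             seed=g).empirical_p)
        ks = stats.kstest(emp, "uniform")
        assert ks.pvalue > 0.01

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError):
            permutation_calibrate(np.ones(30), np.ones((30, 1)), _snp_frame(1),
                                  n_perm=50)


class TestCalls:
    def test_bh_oracle_on_constructed_pvalues(self):
        # hand-computed: at FDR 0.05, m = 10, BH line i*0.005
        ps = [0.001, 0.004, 0.014, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70]
        recs = pd.DataFrame({"gene": "g", "snp": [f"rs{i}" for i in range(10)],
                             "p": ps})
        kept = call_snp_level(recs)
        assert sorted(kept["snp"]) == ["rs0", "rs1", "rs2"]

    def test_single_nominal_pass(self):
        recs = pd.DataFrame({"gene": ["g"], "snp": ["rs0"], "p": [0.04]})
        assert len(call_snp_level(recs)) == 1

    def test_all_ones_empty(self):
        recs = pd.DataFrame({"gene": "g", "snp": [f"rs{i}" for i in range(5)],
                             "p": np.ones(5)})
        assert call_snp_level(recs).empty

    def test_storey_qvalues_monotone_and_bounded(self):
        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(size=400), rng.uniform(0, 1e-4, 20)])
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))
        assert (q[p < 1e-4] < 0.05).all()


class TestGenomicInflation:
    def test_uniform_pvalues_give_lambda_one(self):
        rng = np.random.default_rng(9)
        lam = genomic_inflation(rng.uniform(size=10000))
        assert abs(lam - 1.0) < 0.05

    def test_median_p_half_is_exactly_one(self):
        assert np.isclose(genomic_inflation(np.full(200, 0.5)), 1.0)

    def test_signal_contamination_inflates_lambda(self):
        rng = np.random.default_rng(10)
        p = np.concatenate([rng.uniform(size=9000), np.full(1000, 1e-6)])
        assert genomic_inflation(p) > 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.array([]))


class TestScanIntegration:
    def test_planted_effect_found_by_lead_or_tag(self, small_cohort, small_pdui):
        """The scan's lead SNP is the causal SNP or a tight LD tag of it."""
        from apaqtl import quantify
        cfg, geno, truth, _ = small_cohort
        est = quantify.split_condition(small_pdui, "baseline")
        cov = CovariateSet(hidden=compute_hidden_factors(est, 5))
        res = qtl.scan_condition(est, geno.dosages, geno.snps,
                                 truth.genes[["gene", "chrom", "utr_start",
                                              "utr_end"]],
                                 cov, n_perm=200, seed=0)
        active = truth.genes[truth.genes["is_aqtl"] & ~truth.genes["is_response"]]
        found = 0
        for _, g in active.iterrows():
            row = res.genes[res.genes["gene"] == g["gene"]]
            if not len(row) or not bool(row["significant"].iloc[0]):
                continue
            lead = row["lead_snp"].iloc[0]
            li = int(np.flatnonzero(geno.snps["snp"] == lead)[0])
            r = np.corrcoef(geno.dosages[:, li],
                            geno.dosages[:, int(g["causal_snp"])])[0, 1]
            if r**2 > 0.8:
                found += 1
        assert found / len(active) >= 0.75
        assert 0.9 <= res.lambda_gc <= 1.1
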