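"""QC, kinship, mixed-model scan, FDR and variance-explained behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlcross import assoc
from eqtlcross.experiments import design_covariates, grid_gls_wald, _oracle_population
from eqtlcross.simulate import SimConfig, simulate_population
from eqtlcross.types import GenotypeMatrix, SNPMap, ValidationError


def snp_map_for(m, chrom="1"):
    return SNPMap(
        pd.DataFrame(
            {"snp_id": [f"s{j}" for j in range(m)], "chrom": [chrom] * m,
             "pos": np.arange(1, m + 1) * 1000}
        )
    )


class TestSnpQc:
    def test_boundaries(self):
        n = 100
        dosage = np.zeros((n, 3))
        dosage[:4, 0] = 2.0  # MAF 0.04 -> removed
        dosage[:30, 1] = 1.0  # MAF 0.15, no missing -> kept
        dosage[:30, 2] = 1.0
        dosage[:5, 2] = np.nan  # exactly 5% missing -> kept (inclusive)
        geno = GenotypeMatrix([f"i{k}" for k in range(n)], dosage)
        kept, kmap, report = assoc.snp_qc(geno, snp_map_for(3))
        assert list(kmap.snp_ids) == ["s1", "s2"]
        assert report.n_removed_maf == 1

        dosage2 = dosage.copy()
        dosage2[:6, 2] = np.nan  # 6% missing -> removed
        geno2 = GenotypeMatrix([f"i{k}" for k in range(n)], dosage2)
        _, kmap2, _ = assoc.snp_qc(geno2, snp_map_for(3))
        assert list(kmap2.snp_ids) == ["s1"]

    def test_matches_brute_force_filter(self, rng):
        n, m = 80, 500
        dosage = rng.integers(0, 3, size=(n, m)).astype(float)
        dosage[rng.random((n, m)) < 0.04] = np.nan
        geno = GenotypeMatrix([f"i{k}" for k in range(n)], dosage)
        _, kmap, _ = assoc.snp_qc(geno, snp_map_for(m))
        expected = []
        for j in range(m):
            col = dosage[:, j]
            obs = col[~np.isnan(col)]
            p = obs.mean() / 2
            maf = min(p, 1 - p)
            miss = np.isnan(col).mean()
            if maf >= 0.05 and miss <= 0.05:
                expected.append(f"s{j}")
        assert list(kmap.snp_ids) == expected


class TestGrm:
    def test_duplicated_individual_matches_diagonal(self, rng):
        dosage = rng.integers(0, 3, size=(10, 200)).astype(float)
        dosage[1] = dosage[0]
        geno = GenotypeMatrix([f"i{k}" for k in range(10)], dosage)
        K = assoc.compute_grm(geno)
        assert K[0, 1] == pytest.approx(K[0, 0], rel=1e-12)
        assert K[0, 1] == pytest.approx(K[1, 1], rel=1e-12)

    def test_unrelated_individuals_near_zero(self, rng):
        n, m = 60, 2000
        p = rng.uniform(0.1, 0.9, m)
        dosage = rng.binomial(2, p, size=(n, m)).astype(float)
        K = assoc.compute_grm(GenotypeMatrix([f"i{k}" for k in range(n)], dosage))
        off = K[np.triu_indices(n, 1)]
        # sample-mean centering makes every row of K sum to zero, so the mean
        # off-diagonal is exactly -trace/(n(n-1)) ~ -1/n, i.e. near zero
        assert off.mean() == pytest.approx(-np.trace(K) / (n * (n - 1)), abs=1e-10)
        assert abs(off.mean()) < 0.05

    def test_full_sibs_near_half(self):
        cfg = SimConfig(
            n_per_backcross=(60, 60, 60), snps_per_chromosome=400,
            n_chromosomes=1, chromosome_lengths_bp=(200_000_000,),
            n_genes=1, effects=[], shared_freqs=True, seed=11,
        )
        sim = simulate_population(cfg)
        geno, _, _ = assoc.snp_qc(sim.genotypes, sim.snp_map)
        K = assoc.compute_grm(geno)
        ped = sim.offspring_pedigree().table
        idx = {ind: i for i, ind in enumerate(geno.individuals)}
        pairs = []
        for (s, d), fam in ped.groupby(["sire", "dam"]):
            ids = [idx[i] for i in fam["individual"]]
            pairs += [(a, b) for k, a in enumerate(ids) for b in ids[k + 1:]]
        mean_kin = np.mean([K[a, b] for a, b in pairs])
        assert mean_kin == pytest.approx(0.5, abs=0.05)

    def test_zero_variance_snp_rejected(self):
        dosage = np.ones((10, 3))
        with pytest.raises(ValidationError):
            assoc.compute_grm(GenotypeMatrix([f"i{k}" for k in range(10)], dosage))


class TestScanGene:
    def test_identity_kinship_reduces_to_ols(self, rng):
        import statsmodels.api as sm

        sim, geno, fmap, K, W = _oracle_population(3, n=40, n_snps=25)
        n = geno.n_individuals
        y = rng.standard_normal(n)
        scan = assoc.scan_gene(y, W, geno, fmap, 1.6 * np.eye(n))
        X = assoc.mean_impute(geno.dosage)
        k = W.shape[1] + 1
        for j, row in scan.iterrows():
            fit = sm.OLS(y, np.column_stack([W, X[:, j]])).fit()
            stat = fit.tvalues[-1] ** 2 * n / (n - k)
            assert row["p"] == pytest.approx(stats.chi2.sf(stat, 1), abs=1e-10)

    def test_matches_grid_gls_oracle(self, rng):
        sim, geno, fmap, K, W = _oracle_population(5, n=40, n_snps=15)
        n = geno.n_individuals
        s, U = np.linalg.eigh(K)
        s = np.clip(s, 0, None)
        y = U @ (rng.standard_normal(n) * np.sqrt(0.5 * s)) + rng.standard_normal(n)
        scan = assoc.scan_gene(y, W, geno, fmap, K)
        X = assoc.mean_impute(geno.dosage)
        for j, row in scan.iterrows():
            wald = (row["beta"] / row["se"]) ** 2
            oracle, _ = grid_gls_wald(y, W, X[:, j], K)
            assert abs(wald - oracle) / max(abs(oracle), 1e-2) < 1e-6

    def test_allele_flip_invariance(self, rng):
        sim, geno, fmap, K, W = _oracle_population(9, n=40, n_snps=10)
        y = rng.standard_normal(geno.n_individuals)
        scan = assoc.scan_gene(y, W, geno, fmap, K)
        flipped = GenotypeMatrix(geno.individuals, 2.0 - geno.dosage, geno.alleles)
        scan_f = assoc.scan_gene(y, W, flipped, fmap, K)
        np.testing.assert_allclose(scan_f["beta"], -scan["beta"], rtol=1e-8)
        np.testing.assert_allclose(scan_f["p"], scan["p"], rtol=1e-8)

    def test_deterministic(self, rng):
        sim, geno, fmap, K, W = _oracle_population(13, n=40, n_snps=8)
        y = rng.standard_normal(geno.n_individuals)
        s1 = assoc.scan_gene(y, W, geno, fmap, K)
        s2 = assoc.scan_gene(y, W, geno, fmap, K)
        pd.testing.assert_frame_equal(s1, s2)

    def test_high_missingness_snp_skipped(self, rng, caplog):
        sim, geno, fmap, K, W = _oracle_population(17, n=40, n_snps=6)
        dosage = geno.dosage.copy()
        dosage[:10, 2] = np.nan  # 25% missing at scan stage
        geno2 = GenotypeMatrix(geno.individuals, dosage, geno.alleles)
        y = rng.standard_normal(geno.n_individuals)
        scan = assoc.scan_gene(y, W, geno2, fmap, K)
        assert fmap.snp_ids[2] not in set(scan["snp_id"])
        assert len(scan) == geno.n_snps - 1

    def test_loco_scan_finds_planted_signal(self):
        from eqtlcross.simulate import PlantedEffect

        causal = "snp_c2_00010"
        cfg = SimConfig(
            n_per_backcross=(40, 40, 40), snps_per_chromosome=20,
            n_chromosomes=2, chromosome_lengths_bp=(60_000_000, 60_000_000),
            n_genes=1, effects=[PlantedEffect("G01", causal, "additive_cis", 0.5)],
            forced_freqs={causal: {"IB": 0.8, "LD": 0.2, "DU": 0.2, "PI": 0.2}},
            seed=5,
        )
        sim = simulate_population(cfg)
        geno, fmap, _ = assoc.snp_qc(sim.genotypes, sim.snp_map)
        W = design_covariates(sim.offspring_pedigree().table)
        y = np.log2(sim.abundance.loc["G01"].to_numpy())
        scan = assoc.scan_gene_loco(y, W, geno, fmap, gene="G01")
        assert scan.loc[scan["p"].idxmin(), "snp_id"] == causal
        assert (scan["q"] < 0.05).any()

    def test_mean_impute(self):
        d = np.array([[0.0, np.nan], [2.0, 1.0], [np.nan, 1.0]])
        out = assoc.mean_impute(d)
        assert out[2, 0] == pytest.approx(1.0)
        assert out[0, 1] == pytest.approx(1.0)


class TestFdr:
    def test_hand_stepup(self):
        q = assoc.bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_trivial_cases(self):
        assert assoc.bh_qvalues(np.array([0.37]))[0] == pytest.approx(0.37)
        np.testing.assert_allclose(assoc.bh_qvalues(np.ones(5)), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            assoc.bh_qvalues(np.array([0.5, 1.5]))

    def test_monotone_in_sorted_p(self, rng):
        p = rng.random(200)
        q = assoc.bh_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(1000):
            p = rng.random(rng.integers(1, 60))
            q = assoc.bh_qvalues(p)
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_sm, atol=1e-12)

    def test_storey_never_exceeds_bh(self, rng):
        p = rng.random(500)
        assert (assoc.storey_qvalues(p) <= assoc.bh_qvalues(p) + 1e-12).all()


class TestVarianceExplained:
    def test_exact_fit_gives_one(self, rng):
        x = rng.integers(0, 3, 50).astype(float)
        y = (x - x.mean()) / x.std()
        assert assoc.variance_explained(y, None, x) == pytest.approx(1.0)

    def test_null_snp_near_zero(self, rng):
        n = 100
        vals = [
            assoc.variance_explained(
                rng.standard_normal(n), None, rng.integers(0, 3, n).astype(float)
            )
            for _ in range(200)
        ]
        assert np.mean(vals) <= 2.0 / n

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValidationError):
            assoc.variance_explained(np.ones(10), None, np.arange(10.0))
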