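"""Generator contracts: founder frequencies, meiosis, expression, qPCR, truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlcross import assoc
from eqtlcross.simulate import (
    PlantedEffect,
    SimConfig,
    build_snp_map,
    draw_breed_frequencies,
    simulate_founders,
    simulate_meiosis,
    simulate_population,
    simulate_qpcr,
)
from eqtlcross.types import ValidationError


class TestFounders:
    def test_forced_half_frequency_is_realized(self, rng):
        cfg = SimConfig(
            snps_per_chromosome=30, n_chromosomes=1, chromosome_lengths_bp=(50_000_000,),
            n_sires_per_backcross=40, n_genes=1, effects=[],
            forced_freqs={"snp_c1_00010": {b: 0.5 for b in ("IB", "LD", "DU", "PI")}},
        )
        snp_map = build_snp_map(cfg)
        founders, _ = simulate_founders(cfg, snp_map, rng)
        haps = np.concatenate(
            [h.ravel() for h in founders.dam_haps.values()]
        )  # many Bernoulli draws pooled across loci; check the forced locus only
        j = 10
        dam_alleles = np.concatenate([h[:, j] for h in founders.dam_haps.values()])
        p = dam_alleles.mean()
        se = np.sqrt(0.25 / len(dam_alleles))
        assert abs(p - 0.5) < 4 * se

    def test_fixed_difference_forces_heterozygous_f1(self, rng):
        cfg = SimConfig(
            snps_per_chromosome=10, n_chromosomes=1, chromosome_lengths_bp=(10_000_000,),
            n_sires_per_backcross=25, n_genes=1, effects=[],
            forced_freqs={"snp_c1_00005": {"IB": 1.0, "LD": 0.0, "DU": 0.0, "PI": 0.0}},
        )
        snp_map = build_snp_map(cfg)
        founders, _ = simulate_founders(cfg, snp_map, rng)
        f1 = founders.f1_dosage()
        assert (f1[5] == 1).all()  # every F1 sire heterozygous, forced by Mendel

    def test_frequency_spectrum_matches_beta_spec(self, rng):
        cfg = SimConfig(
            snps_per_chromosome=2000, n_chromosomes=1,
            chromosome_lengths_bp=(200_000_000,), n_genes=1, effects=[],
        )
        snp_map = build_snp_map(cfg)
        freqs = draw_breed_frequencies(cfg, snp_map, rng)
        a, b = cfg.breed_allele_freq_spec["LD"]
        reference = np.clip(rng.beta(a, b, size=2000), 0.02, 0.98)
        ks = stats.ks_2samp(freqs["LD"], reference)
        assert ks.pvalue > 0.01


class TestMeiosis:
    def test_zero_length_chromosome_transmits_intact(self, rng):
        haps = np.array([[1, 1, 1, 1], [0, 0, 0, 0]], dtype=np.int8)
        pos = np.array([1, 2, 3, 4])  # ~0 Morgans: no crossover possible
        chroms = np.array(["1"] * 4)
        for _ in range(20):
            gamete, phase = simulate_meiosis(haps, pos, chroms, rng)
            assert len(set(phase)) == 1
            np.testing.assert_array_equal(gamete, haps[phase[0]])

    def test_one_morgan_chromosome_mean_crossovers(self, rng):
        m = 200
        pos = np.linspace(1, 100_000_000, m).astype(int)  # 1 Morgan at 1 cM/Mb
        chroms = np.array(["1"] * m)
        haps = np.vstack([np.ones(m, np.int8), np.zeros(m, np.int8)])
        switches = 0
        n_gametes = 10_000
        for _ in range(n_gametes):
            _, phase = simulate_meiosis(haps, pos, chroms, rng)
            switches += int(np.abs(np.diff(phase)).sum())
        mean = switches / n_gametes
        se = np.sqrt(1.0 / n_gametes)  # Poisson(1) variance
        assert abs(mean - 1.0) < 3 * se + 0.01  # small allowance for double COs

    def test_homozygous_parent_gamete_identical(self, rng):
        m = 50
        hap = rng.integers(0, 2, m).astype(np.int8)
        haps = np.vstack([hap, hap])
        pos = np.linspace(1, 80_000_000, m).astype(int)
        gamete, _ = simulate_meiosis(haps, pos, np.array(["1"] * m), rng)
        np.testing.assert_array_equal(gamete, hap)


class TestExpression:
    def test_no_effects_variance_equals_residual(self):
        cfg = SimConfig(
            n_per_backcross=(200, 200, 200), snps_per_chromosome=30,
            n_chromosomes=1, chromosome_lengths_bp=(50_000_000,),
            n_genes=3, effects=[], polygenic_h2=0.0,
            sex_affected_fraction=0.0, backcross_affected_fraction=0.0,
            residual_sd=0.30, seed=77,
        )
        sim = simulate_population(cfg)
        logv = np.log(sim.abundance.to_numpy()).var(axis=1, ddof=1)
        tol = 3 * 0.09 * np.sqrt(2 / 600)
        assert np.all(np.abs(logv - 0.09) < tol)

    def test_planted_pve_half_is_recovered(self):
        causal = "snp_c1_00015"
        master = np.random.default_rng(404)
        r2 = []
        for _ in range(200):
            cfg = SimConfig(
                n_per_backcross=(60, 60, 60), snps_per_chromosome=30,
                n_chromosomes=1, chromosome_lengths_bp=(50_000_000,),
                n_genes=1,
                effects=[PlantedEffect("G01", causal, "additive_cis", 0.50)],
                forced_freqs={causal: {"IB": 0.75, "LD": 0.30, "DU": 0.30, "PI": 0.30}},
                polygenic_h2=0.0, seed=int(master.integers(2**31)),
            )
            sim = simulate_population(cfg)
            y = np.log(sim.abundance.loc["G01"].to_numpy())
            from eqtlcross.experiments import design_covariates

            W = design_covariates(sim.offspring_pedigree().table)
            j = list(sim.snp_map.snp_ids).index(causal)
            r2.append(assoc.variance_explained(y, W, sim.genotypes.dosage[:, j]))
        assert abs(np.mean(r2) - 0.50) < 0.05

    def test_imprinted_group_means_follow_paternal_model(self, desk_sim):
        sim = desk_sim
        eff = [e for e in sim.truth.effects if e.mode == "imprinted_paternal"][0]
        j = sim.truth.snp_ids.index(eff.snp_id)
        pat = sim.truth.paternal_hap[:, j]
        mat = sim.truth.maternal_hap[:, j]
        nq = sim.abundance.loc[eff.gene].to_numpy()
        means = {
            grp: nq[(pat == p) & (mat == m)].mean()
            for grp, p, m in [("AA", 1, 1), ("ApGm", 1, 0), ("AmGp", 0, 1), ("GG", 0, 0)]
        }
        assert min(means["AA"], means["ApGm"]) > max(means["AmGp"], means["GG"])

    def test_infeasible_pve_budget_rejected(self):
        cfg = SimConfig(
            snps_per_chromosome=20, n_chromosomes=1, chromosome_lengths_bp=(30_000_000,),
            n_genes=1,
            effects=[PlantedEffect("G01", "snp_c1_00010", "additive_cis", 0.95)],
            polygenic_h2=0.1,
        )
        with pytest.raises(ValidationError, match="residual"):
            simulate_population(cfg)


class TestQpcr:
    def _flat_config(self):
        return SimConfig(
            snps_per_chromosome=10, n_chromosomes=1, chromosome_lengths_bp=(10_000_000,),
            n_genes=1, effects=[], qpcr_efficiency_range=(1.0, 1.0),
        )

    def test_perfect_doubling_gives_delta_cq_minus_one(self, rng):
        cfg = self._flat_config()
        abundance = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        cq = simulate_qpcr(abundance, cfg, rng, noise_sd=0.0)
        samples = cq[~cq["is_standard"]].set_index("sample")["Cq"]
        assert samples["b"] - samples["a"] == pytest.approx(-1.0, abs=1e-12)

    def test_quantity_at_standard_point_matches_its_cq(self, rng):
        cfg = self._flat_config()
        abundance = pd.DataFrame([[0.0625]], index=["g"], columns=["a"])  # 4^-2
        cq = simulate_qpcr(abundance, cfg, rng, noise_sd=0.0)
        std = cq[cq["is_standard"] & (cq["standard_quantity"] == 0.0625)]["Cq"].iloc[0]
        sample = cq[~cq["is_standard"]]["Cq"].iloc[0]
        assert sample == pytest.approx(std, abs=1e-12)

    def test_noise_free_round_trip_recovers_abundance(self, rng):
        from eqtlcross import qpcr

        cfg = SimConfig(
            snps_per_chromosome=10, n_chromosomes=1, chromosome_lengths_bp=(10_000_000,),
            n_genes=1, effects=[],
        )
        abundance = pd.DataFrame(
            rng.lognormal(0.0, 0.6, size=(3, 8)),
            index=["g1", "g2", "g3"], columns=[f"s{i}" for i in range(8)],
        )
        cq = simulate_qpcr(abundance, cfg, rng, noise_sd=0.0)
        quantities, _ = qpcr.quantify_assays(cq)
        rel = np.abs(quantities.loc[abundance.index, abundance.columns].to_numpy()
                     - abundance.to_numpy()) / abundance.to_numpy()
        assert rel.max() < 0.02


class TestTruth:
    def test_mendelian_consistency_exhaustive(self, desk_sim):
        sim = desk_sim
        truth = sim.truth
        ped = sim.pedigree.table.set_index("individual")
        for i, ind in enumerate(truth.individuals):
            sire, dam = ped.loc[ind, "sire"], ped.loc[ind, "dam"]
            sire_haps = truth.sire_haps[sire]
            dam_haps = truth.dam_haps[dam]
            assert np.isin(truth.paternal_hap[i], sire_haps).all()
            assert np.isin(truth.maternal_hap[i], dam_haps).all()
            # the transmitted allele is one the parent actually carries, locus by locus
            assert (
                (truth.paternal_hap[i] == sire_haps[0])
                | (truth.paternal_hap[i] == sire_haps[1])
            ).all()

    def test_iberian_fraction_near_quarter(self):
        # default cohort sizes: per-individual fractions average over only a
        # few chromosome-length segments, so the population mean needs the
        # full 180 animals for a +/-2% band
        cfg = SimConfig(snps_per_chromosome=40, n_genes=1, effects=[], seed=314)
        sim = simulate_population(cfg)
        frac = sim.truth.iberian_fraction().mean()
        assert abs(frac - 0.25) < 0.02

    def test_origin_labels_match_phase_rederivation(self, desk_sim):
        truth = desk_sim.truth
        ped = desk_sim.pedigree.table.set_index("individual")
        m = len(truth.snp_ids)
        cols = np.arange(m)
        for i, ind in enumerate(truth.individuals):
            sire, dam = ped.loc[ind, "sire"], ped.loc[ind, "dam"]
            re_pat = truth.sire_haps[sire][truth.sire_phase[i], cols]
            re_mat = truth.dam_haps[dam][truth.dam_phase[i], cols]
            np.testing.assert_array_equal(re_pat, truth.paternal_hap[i])
            np.testing.assert_array_equal(re_mat, truth.maternal_hap[i])
            np.testing.assert_array_equal(
                truth.paternal_is_iberian[i], truth.sire_phase[i] == 0
            )

    def test_genotypes_equal_haplotype_sum(self, desk_sim):
        np.testing.assert_array_equal(
            desk_sim.genotypes.dosage,
            (desk_sim.truth.paternal_hap + desk_sim.truth.maternal_hap).astype(float),
        )

    def test_truth_json_round_trip(self, desk_sim, tmp_path):
        from eqtlcross.simulate import TruthSet

        desk_sim.truth.to_json(tmp_path / "t.json")
        back = TruthSet.from_json(tmp_path / "t.json")
        np.testing.assert_array_equal(back.paternal_hap, desk_sim.truth.paternal_hap)
        assert back.blocks == desk_sim.truth.blocks
        assert [e.snp_id for e in back.effects] == [
            e.snp_id for e in desk_sim.truth.effects
        ]
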