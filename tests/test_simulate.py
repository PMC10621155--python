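"""Synthetic-data generator: determinism, pedigree structure, gene
dropping, true-value covariance, phenotype model and presets."""

import numpy as np
import pandas as pd
import pytest

from hoofgen.pedigree import UNKNOWN, compute_inbreeding
from hoofgen.simulate import (
    PRESET_NAMES,
    SimulationConfig,
    drop_genotypes,
    make_snp_map,
    preset,
    preset_truth,
    simulate,
    simulate_founders,
    simulate_phenotypes,
    simulate_true_values,
    simulate_two_country_pedigree,
)


class TestConfigValidation:
    def test_non_positive_sizes_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(n_founders=0)

    def test_asymmetric_sigma_rejected(self):
        S = np.array([[0.2, 0.1], [0.0, 0.2]])
        with pytest.raises(ValueError, match="symmetric"):
            SimulationConfig(Sigma_a=S)

    def test_non_psd_sigma_rejected(self):
        S = np.array([[0.1, 0.5], [0.5, 0.1]])
        with pytest.raises(ValueError, match="semidefinite"):
            SimulationConfig(Sigma_a=S)

    def test_cross_country_pe_block_must_be_zero(self):
        Q = np.full((4, 4), 0.05)
        with pytest.raises(ValueError, match="cross-country"):
            SimulationConfig(
                Sigma_a=np.eye(4) * 0.2, Q_pe=Q, R_e=np.eye(4) * 0.6
            )

    def test_shared_sires_need_two_countries(self):
        with pytest.raises(ValueError, match="two countries"):
            SimulationConfig(countries=("US",), shared_sire_fraction=0.3)

    def test_thresholds_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            SimulationConfig(score_thresholds=(0.0, 0.0, 1.0, 2.0))


class TestFounders:
    def test_determinism(self):
        smap = make_snp_map(50, 2, 1_000_000, seed=0)
        a = simulate_founders(20, smap, 100_000.0, seed=9)
        b = simulate_founders(20, smap, 100_000.0, seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_zero_ld_strength_independence_floor(self):
        smap = make_snp_map(200, 1, 10_000_000, seed=1)
        f = simulate_founders(250, smap, 0.0, seed=2)
        H = f.haplotypes.astype(float)
        Hc = H - H.mean(0)
        denom = np.sqrt((Hc**2).sum(0))
        C = (Hc.T @ Hc) / np.outer(denom, denom)
        iu, ju = np.triu_indices(200, k=1)
        mean_r2 = np.mean(C[iu, ju] ** 2)
        # E[r^2] under independence ~ 1/n_haplotypes
        assert mean_r2 == pytest.approx(1.0 / 500, rel=0.3)

    def test_ld_decays_with_distance(self):
        smap = make_snp_map(300, 1, 30_000_000, seed=3)
        f = simulate_founders(200, smap, 200_000.0, seed=4)
        from hoofgen.genomics import GenotypeData, ld_statistics

        g = GenotypeData(
            (f.haplotypes[::2] + f.haplotypes[1::2]).astype(float), smap,
            np.array([f"f{i}" for i in range(200)], dtype=object),
            haplotypes=f.haplotypes,
        )
        b = ld_statistics(g, max_distance_bp=5_000_000).binned
        first = b[b.bin_start == 0]["mean_r2"].iloc[0]
        far = b[b.bin_start >= 2_000_000]["mean_r2"].mean()
        assert first > 2 * far

    def test_bad_sizes(self):
        smap = make_snp_map(10, 1, 1000, seed=0)
        with pytest.raises(ValueError):
            simulate_founders(0, smap, 1e5, seed=0)


class TestPedigreeSim:
    def test_no_sharing_disjoint_below_founders(self):
        cfg = SimulationConfig(
            n_founders=60, n_generations=2, animals_per_generation_per_country=40,
            shared_sire_fraction=0.0, seed=3,
        )
        ped = simulate_two_country_pedigree(cfg)
        # every non-founder's sire is of the same country
        for i in range(ped.n):
            s = ped.sire[i]
            if s != UNKNOWN:
                assert ped.country[s] == ped.country[i]

    def test_shared_sire_fraction_realised(self):
        cfg = preset("paper-mc", seed=5)
        ped = simulate_two_country_pedigree(cfg, seed=5)
        min_year = cfg.base_year + cfg.phenotype_from_generation
        phen = [
            i for i in range(ped.n)
            if ped.sire[i] != UNKNOWN and ped.birth_year[i] >= min_year
        ]
        # a shared sire has progeny in both countries
        progeny_countries = {}
        for i in phen:
            progeny_countries.setdefault(ped.sire[i], set()).add(ped.country[i])
        shared = {s for s, cs in progeny_countries.items() if len(cs) > 1}
        frac = {}
        for c in ("US", "AU"):
            idx = [i for i in phen if ped.country[i] == c]
            frac[c] = np.mean([ped.sire[i] in shared for i in idx])
        assert frac["US"] == pytest.approx(0.27, abs=0.07)
        assert frac["AU"] == pytest.approx(0.13, abs=0.06)

    def test_parents_precede_and_sexes_consistent(self):
        ped = simulate_two_country_pedigree(preset("paper-jc", seed=1), seed=2)
        for i in range(ped.n):
            for p, sex in ((ped.sire[i], "M"), (ped.dam[i], "F")):
                if p != UNKNOWN:
                    assert p < i
                    assert ped.sex[p] == sex

    def test_birth_years_support_forward_split(self):
        cfg = preset("paper-wc-us", seed=0)
        ped = simulate_two_country_pedigree(cfg, seed=0)
        years = np.unique(ped.birth_year)
        assert len(years) == cfg.n_generations + 1


@pytest.fixture(scope="module")
def dropped():
    cfg = SimulationConfig(
        n_founders=40, n_generations=2, animals_per_generation_per_country=30,
        n_snps=120, n_chromosomes=2, seed=21,
    )
    ped = simulate_two_country_pedigree(cfg, seed=21)
    smap = make_snp_map(120, 2, 50_000_000, seed=21)
    founders = simulate_founders(40, smap, 150_000.0, seed=22)
    geno = drop_genotypes(ped, founders, seed=23)
    return ped, geno


class TestGeneDropping:

    def test_mendelian_consistency(self, dropped):
        """No offspring dosage incompatible with parental dosages."""
        ped, geno = dropped
        d = geno.dosages
        for i in range(ped.n):
            s, m = ped.sire[i], ped.dam[i]
            if s == UNKNOWN or m == UNKNOWN:
                continue
            # offspring can't be hom for an allele absent in a parent
            bad = ((d[s] == 2) & (d[m] == 2) & (d[i] != 2)) | (
                (d[s] == 0) & (d[m] == 0) & (d[i] != 0)
            )
            assert not bad.any()

    def test_determinism(self, dropped):
        ped, geno = dropped
        smap = geno.snp_map
        founders = simulate_founders(40, smap, 150_000.0, seed=22)
        again = drop_genotypes(ped, founders, seed=23)
        assert np.array_equal(again.dosages, geno.dosages)

    def test_zero_morgans_intact_haplotypes(self):
        cfg = SimulationConfig(
            n_founders=10, n_generations=1, animals_per_generation_per_country=8,
            n_snps=40, seed=5, morgans_per_chrom=0.0,
        )
        ped = simulate_two_country_pedigree(cfg, seed=5)
        smap = make_snp_map(40, 1, 1_000_000, seed=5)
        founders = simulate_founders(10, smap, 0.0, seed=6)
        geno = drop_genotypes(ped, founders, seed=7, morgans_per_chrom=0.0)
        for i in range(ped.n):
            s = ped.sire[i]
            if s == UNKNOWN:
                continue
            gam = geno.haplotypes[2 * i]
            assert np.array_equal(gam, geno.haplotypes[2 * s]) or np.array_equal(
                gam, geno.haplotypes[2 * s + 1]
            )

    def test_mean_offspring_dosage_binomial_oracle(self):
        """Parents 2 x 0 at a locus: offspring dosage is always 1; parents
        1 x 1: mean 1.0 with binomial spread."""
        rng = np.random.default_rng(0)
        # direct mini gene-drop: het x het over many replicates
        ids = ["s", "d"] + [f"k{i}" for i in range(10_000)]
        sire = ["0", "0"] + ["s"] * 10_000
        dam = ["0", "0"] + ["d"] * 10_000
        from hoofgen.pedigree import Pedigree

        ped = Pedigree(ids, sire, dam)
        smap = make_snp_map(2, 1, 1_000_000, seed=1)
        founders = simulate_founders(2, smap, 0.0, seed=1)
        founders.haplotypes[:] = np.array([[1, 1], [0, 0], [1, 0], [0, 1]], dtype=np.int8)
        geno = drop_genotypes(ped, founders, seed=9)
        kids = geno.dosages[2:]
        assert kids[:, 0].mean() == pytest.approx(1.0, abs=0.03)


class TestTrueValues:
    def test_zero_sigma_gives_zero_tbv(self):
        cfg = SimulationConfig(
            n_founders=20, n_generations=1, animals_per_generation_per_country=10,
            Sigma_a=np.zeros((2, 2)), seed=1,
        )
        ped = simulate_two_country_pedigree(cfg, seed=1)
        tv = simulate_true_values(ped, cfg, seed=2)
        assert np.all(tv.a == 0)

    def test_founder_tbv_covariance(self):
        """Founder TBVs reproduce Sigma (law of large numbers)."""
        S = np.array([[0.25, 0.10], [0.10, 0.30]])
        cfg = SimulationConfig(
            n_founders=30_000, n_generations=1,
            animals_per_generation_per_country=1,
            Sigma_a=S, seed=3,
        )
        ped = simulate_two_country_pedigree(cfg, seed=3)
        tv = simulate_true_values(ped, cfg, seed=4)
        founders = [i for i in range(ped.n) if ped.sire[i] == UNKNOWN and ped.dam[i] == UNKNOWN]
        emp = np.cov(tv.a[founders].T)
        np.testing.assert_allclose(emp, S, atol=0.012)

    def test_single_qtl_perfect_correlation(self):
        cfg = preset(
            "paper-mc-genomic", seed=6, n_qtl=1, n_snps=60,
            animals_per_generation_per_country=40, n_founders=40,
        )
        sim = simulate(cfg)
        q = sim.true_values.qtl_indices[0]
        z = sim.genotypes.dosages[:, q]
        for t in range(4):
            c = abs(np.corrcoef(sim.true_values.a[:, t], z)[0, 1])
            assert c == pytest.approx(1.0, abs=1e-10)

    def test_genomic_mode_regression_slope_exactly_one(self):
        cfg = preset(
            "paper-mc-genomic", seed=8, n_snps=200, n_qtl=40,
            animals_per_generation_per_country=50, n_founders=60,
        )
        sim = simulate(cfg)
        tv = sim.true_values
        p = sim.founders.freqs[tv.qtl_indices]
        Z = sim.genotypes.dosages[:, tv.qtl_indices] - 2 * p
        pred = Z @ tv.qtl_effects
        np.testing.assert_allclose(pred, tv.a, atol=1e-12)

    def test_mendelian_sampling_scaled_by_parent_inbreeding(self):
        """Offspring of highly inbred parents have reduced within-family
        TBV spread."""
        from hoofgen.pedigree import Pedigree

        n_kids = 4000
        ids = ["a", "b"] + [f"k{i}" for i in range(n_kids)]
        ped_out = Pedigree(ids, ["0", "0"] + ["a"] * n_kids, ["0", "0"] + ["b"] * n_kids)
        cfg = SimulationConfig(
            n_founders=2, n_generations=1, animals_per_generation_per_country=1,
            Sigma_a=np.eye(2) * 1.0, seed=0,
        )
        tv = simulate_true_values(ped_out, cfg, seed=5)
        kids = tv.a[2:]
        within = np.var(kids[:, 0], ddof=1)
        # non-inbred unrelated parents: Mendelian variance = 0.5
        assert within == pytest.approx(0.5, rel=0.1)

    def test_non_psd_raises_before_sampling(self):
        cfg = SimulationConfig(seed=0)
        cfg.Sigma_a = np.array([[0.1, 0.4], [0.4, 0.1]])  # bypass validate
        ped = simulate_two_country_pedigree(preset("paper-wc-us", seed=0), seed=0)
        with pytest.raises(ValueError, match="semidefinite"):
            simulate_true_values(ped, cfg, seed=1)


class TestPhenotypes:
    def test_pure_tbv_scores(self):
        """All non-genetic variation off: the score is the threshold bin of
        the TBV alone."""
        S = np.array([[0.25, 0.0], [0.0, 0.25]])
        cfg = SimulationConfig(
            n_founders=40, n_generations=1, animals_per_generation_per_country=40,
            Sigma_a=S, Q_pe=np.zeros((2, 2)), R_e=np.zeros((2, 2)),
            cg_sd=0.0, age_slope_per_country={}, repeat_record_fraction=0.0,
            score_thresholds=(-0.6, -0.2, 0.2, 0.6), seed=2,
        )
        ped = simulate_two_country_pedigree(cfg, seed=2)
        tv = simulate_true_values(ped, cfg, seed=3)
        ph = simulate_phenotypes(ped, tv, cfg, seed=4)
        th = np.array(cfg.score_thresholds)
        # latent equals the TBV alone, so scores are its threshold bins
        idx = ped.index_of(ph["animal"])
        np.testing.assert_allclose(
            ph["latent"], tv.a[idx, ph["response"].to_numpy()], atol=1e-12
        )
        centred = ph["latent"] - ph["latent"].mean()
        np.testing.assert_array_equal(ph["score"], 5 + np.digitize(centred, th))

    def test_repeat_fraction_gives_11_mean_records(self):
        cfg = preset("paper-wc-us", seed=9, score_thresholds=None)
        sim = simulate(cfg)
        per_animal = sim.phenotypes.groupby(["animal", "trait"])["score"].size()
        assert per_animal.mean() == pytest.approx(1.1, abs=0.03)

    def test_au_preset_right_skewed_us_more_symmetric(self):
        au = simulate(preset("paper-wc-au", seed=4))
        us = simulate(preset("paper-wc-us", seed=4))
        from scipy.stats import skew

        s_au = skew(au.phenotypes["score"])
        s_us = skew(us.phenotypes["score"])
        assert s_au > 0.2
        assert abs(s_us) < abs(s_au)

    def test_degenerate_thresholds_warn(self):
        cfg = preset("paper-wc-us", seed=1, animals_per_generation_per_country=30,
                     n_founders=20, score_thresholds=(50.0, 60.0, 70.0, 80.0))
        ped = simulate_two_country_pedigree(cfg, seed=1)
        tv = simulate_true_values(ped, cfg, seed=2)
        with pytest.warns(UserWarning, match="thresholds"):
            simulate_phenotypes(ped, tv, cfg, seed=3)


class TestPresets:
    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_presets_valid_and_deterministic(self, name):
        cfg = preset(name, seed=1)
        cfg.validate()

    def test_unknown_preset_lists_valid(self):
        with pytest.raises(ValueError, match="paper-wc-us"):
            preset("nope")

    def test_truth_values_match_published_estimates(self):
        t = preset_truth("paper-wc-us")
        assert t["h2"]["FA"] == pytest.approx(0.22)
        assert t["rep"]["FA"] == pytest.approx(0.32)
        assert t["rg"][("FA", "CS")] == pytest.approx(0.50)
        t = preset_truth("paper-wc-au")
        assert t["h2"]["CS"] == pytest.approx(0.26)
        assert t["rep"]["CS"] == pytest.approx(0.35)
        assert t["rg"][("FA", "CS")] == pytest.approx(0.46)
        t = preset_truth("paper-mc")
        assert t["rg"][("FA_US", "FA_AU")] == pytest.approx(0.61)
        assert t["rg"][("CS_US", "CS_AU")] == pytest.approx(0.76)
        t = preset_truth("paper-mc-genomic")
        assert t["rg"][("FA_US", "FA_AU")] == pytest.approx(0.76)
        assert t["rg"][("CS_US", "CS_AU")] == pytest.approx(0.78)
        t = preset_truth("paper-jc")
        assert t["h2"]["FA"] == pytest.approx(0.24)
        assert t["h2"]["CS"] == pytest.approx(0.25)

    def test_end_to_end_determinism(self):
        a = simulate(preset("paper-mc-genomic", seed=17, n_snps=100,
                            animals_per_generation_per_country=30, n_founders=40))
        b = simulate(preset("paper-mc-genomic", seed=17, n_snps=100,
                            animals_per_generation_per_country=30, n_founders=40))
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
        assert np.array_equal(a.true_values.a, b.true_values.a)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)


class TestVarianceBookkeeping:
    def test_continuous_records_recover_ratios(self):
        """Empirical variance decomposition at large n recovers the preset
        h2 and repeatability (thresholds disabled)."""
        cfg = preset(
            "paper-wc-us", seed=31, score_thresholds=None,
            animals_per_generation_per_country=10_000, n_generations=1,
            n_founders=4000, cg_sd=0.0, age_slope_per_country={},
            repeat_record_fraction=1.0,
        )
        sim = simulate(cfg)
        ph = sim.phenotypes[sim.phenotypes.trait == "FA"]
        ped = sim.pedigree
        uni = ph.drop_duplicates("animal")
        idx = ped.index_of(uni["animal"])
        va = np.var(sim.true_values.a[idx, 0], ddof=1)
        vp = np.var(sim.true_values.pe[idx, 0], ddof=1)
        assert va == pytest.approx(0.22, abs=0.02)
        assert va + vp == pytest.approx(0.32, abs=0.02)
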