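"""Genotype QC, G/H matrices, APY, LD statistics, PCA and pruning."""

import numpy as np
import pandas as pd
import pytest

from hoofgen.genomics import (
    GenotypeData,
    apy_inverse,
    blend_G,
    build_G,
    build_H,
    build_H_inverse,
    ld_prune,
    ld_statistics,
    pca_of_G,
    phase_consistency,
    qc_genotypes,
)
from hoofgen.pedigree import (
    RelationshipMatrix,
    build_A,
    build_A22_inverse,
    build_A_inverse,
)


def make_geno(dosages, bp=None, haplotypes=None):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    snp_map = pd.DataFrame(
        {"snp": [f"s{j}" for j in range(m)], "chrom": 1,
         "bp": bp if bp is not None else np.arange(m) * 1000}
    )
    ids = np.array([f"a{i}" for i in range(dosages.shape[0])], dtype=object)
    return GenotypeData(dosages, snp_map, ids, haplotypes=haplotypes)


class TestQC:
    def test_maf_boundary_is_strict(self):
        # SNP 0 at allele frequency exactly 0.05 -> removed (strictly >)
        n = 20
        col = np.zeros(n)
        col[0] = 1.0  # p = 1/40 < 0.05? make exactly 0.05: 2 of 40 alleles
        col[1] = 1.0
        keep = np.tile([0.0, 1.0], n // 2)  # p = 0.25
        g = make_geno(np.column_stack([col, keep]))
        out, report = qc_genotypes(g)
        assert list(out.snp_map["snp"]) == ["s1"]
        assert report["n_snps_removed_maf"] == 1

    def test_sample_call_rate_boundary(self):
        m = 100
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.5, size=(3, m)).astype(float)
        dos[0, :21] = np.nan  # 79% called -> removed
        dos[1, :19] = np.nan  # 81% called -> kept
        g = make_geno(dos)
        out, report = qc_genotypes(g)
        assert report["n_samples_removed_call_rate"] == 1
        assert "a0" not in out.sample_ids

    def test_toy_counts(self):
        # one monomorphic SNP and one 50%-missing SNP among well-called
        # samples: both SNPs removed, the rest survive
        rng = np.random.default_rng(9)
        dos = rng.binomial(2, 0.5, size=(6, 12)).astype(float)
        dos[:, 0] = 2.0                      # monomorphic
        dos[::2, 1] = np.nan                 # 50% missing
        out, report = qc_genotypes(make_geno(dos))
        assert out.n_snps == 10
        assert report["n_snps_removed"] == 2
        assert report["n_samples_removed_call_rate"] == 0

    def test_all_removed_raises(self):
        g = make_geno(np.full((4, 2), 2.0))
        with pytest.raises(ValueError, match="all SNPs removed"):
            qc_genotypes(g)


class TestG:
    def test_single_snp_arithmetic(self):
        g = make_geno([[0.0], [1.0], [2.0]])
        expected = np.array([[2, 0, -2], [0, 0, 0], [-2, 0, 2]], dtype=float)
        np.testing.assert_allclose(build_G(g).dense(), expected)

    def test_centering_zero_column_means(self):
        rng = np.random.default_rng(1)
        g = make_geno(rng.binomial(2, 0.3, (40, 30)).astype(float))
        p = g.allele_freq()
        Z = g.dosages - 2 * p
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)

    def test_mean_diagonal_near_one_under_hwe(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 2000)
        dos = rng.binomial(2, p, size=(60, 2000)).astype(float)
        G = build_G(make_geno(dos))
        assert np.mean(np.diag(G.dense())) == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_only_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            build_G(make_geno(np.full((4, 3), 1.0) * 2))


class TestBlendAndAPY:
    @pytest.fixture
    def gb(self, random_genotypes):
        G = build_G(random_genotypes)
        A22 = RelationshipMatrix(np.eye(G.matrix.shape[0]), G.ids, "A22")
        return G, A22

    def test_alpha_one_returns_G(self, gb):
        G, A22 = gb
        np.testing.assert_allclose(blend_G(G, A22, 1.0, 0.0).dense(), G.dense())

    def test_alpha_zero_returns_A22(self, gb):
        G, A22 = gb
        np.testing.assert_allclose(blend_G(G, A22, 0.0, 1.0).dense(), A22.dense())

    def test_default_blend_diagonal(self, gb):
        G, A22 = gb
        Gb = blend_G(G, A22)
        np.testing.assert_allclose(
            np.diag(Gb.dense()), 0.9 * np.diag(G.dense()) + 0.1 * np.diag(A22.dense())
        )

    def test_alpha_beta_must_sum_to_one(self, gb):
        G, A22 = gb
        with pytest.raises(ValueError, match="alpha"):
            blend_G(G, A22, 0.9, 0.2)

    def test_apy_full_core_is_exact_inverse(self, gb):
        G, A22 = gb
        Gb = blend_G(G, A22)
        inv = apy_inverse(Gb, core_ids=Gb.ids).dense()
        np.testing.assert_allclose(inv, np.linalg.inv(Gb.dense()), atol=1e-8)

    def test_apy_seeded_core_reproducible(self, gb):
        G, A22 = gb
        Gb = blend_G(G, A22)
        a = apy_inverse(Gb, n_core=20, seed=5)
        b = apy_inverse(Gb, n_core=20, seed=5)
        assert np.array_equal(a.meta["apy_core_ids"], b.meta["apy_core_ids"])
        np.testing.assert_allclose(a.dense(), b.dense())

    def test_apy_gebv_correlation_improves_with_core_size(self, gb):
        """APY GEBVs approach the full-inverse GEBVs as the core grows."""
        G, A22 = gb
        Gb = blend_G(G, A22)
        n = len(Gb.ids)
        rng = np.random.default_rng(3)
        y = rng.standard_normal(n)
        lam = 1.0
        full = np.linalg.solve(np.linalg.inv(Gb.dense()) * lam + np.eye(n), y)
        cors = []
        for frac in (0.2, 0.5, 1.0):
            inv = apy_inverse(Gb, n_core=max(2, int(frac * n)), seed=1).dense()
            gebv = np.linalg.solve(inv * lam + np.eye(n), y)
            cors.append(np.corrcoef(gebv, full)[0, 1])
        assert cors[-1] > 0.9999
        assert cors[0] <= cors[1] + 1e-12 <= cors[2] + 2e-12
        assert cors[0] > 0.9


class TestH:
    def test_H_inverse_matches_dense_H(self, wc_sim):
        """Sparse H^-1 assembly inverts the textbook dense H."""
        ped = wc_sim.pedigree
        rng = np.random.default_rng(0)
        gids = ped.ids[rng.choice(ped.n, 60, replace=False)]
        A = build_A(ped)
        A22 = RelationshipMatrix(A.submatrix(gids), np.asarray(gids, dtype=object), "A22")
        # synthetic G close to A22 keeps the toy well conditioned
        noise = rng.standard_normal((60, 60)) * 0.05
        G = RelationshipMatrix(A22.dense() + noise @ noise.T / 60, A22.ids, "G")
        Gb = blend_G(G, A22)
        H = build_H(A, Gb)
        H_inv = build_H_inverse(
            build_A_inverse(ped),
            build_A22_inverse(ped, gids),
            RelationshipMatrix(np.linalg.inv(Gb.dense()), Gb.ids, "G_blended_inverse"),
        )
        prod = H_inv.dense() @ H.dense()
        assert np.abs(prod - np.eye(ped.n)).max() < 1e-6

    def test_Gb_equal_A22_gives_A_inverse(self, wc_sim):
        ped = wc_sim.pedigree
        gids = ped.ids[:40]
        A = build_A(ped)
        A22 = RelationshipMatrix(A.submatrix(gids), np.asarray(gids, dtype=object), "A22")
        H_inv = build_H_inverse(
            build_A_inverse(ped),
            build_A22_inverse(ped, gids),
            RelationshipMatrix(np.linalg.inv(A22.dense()), A22.ids, "G_blended_inverse"),
        )
        np.testing.assert_allclose(
            H_inv.dense(), build_A_inverse(ped).dense(), atol=1e-6
        )

    def test_genotyped_animal_missing_from_pedigree(self, wc_sim):
        ped = wc_sim.pedigree
        ids = np.array(["ghost1", "ghost2"], dtype=object)
        fake = RelationshipMatrix(np.eye(2), ids, "G_blended_inverse")
        with pytest.raises(KeyError):
            build_H_inverse(build_A_inverse(ped), RelationshipMatrix(np.eye(2), ids, "A22_inverse"), fake)


class TestLD:
    def test_perfect_ld(self):
        # f(AB)=0.5, f(A)=f(B)=0.5 -> D=0.25, r2=1, signed=+1
        H = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8)
        g = make_geno(H[::2] + H[1::2], bp=[0, 1000], haplotypes=H)
        res = ld_statistics(g)
        assert res.pairs["r2"].iloc[0] == pytest.approx(1.0)
        assert res.pairs["signed_ld"].iloc[0] == pytest.approx(1.0)

    def test_derived_arithmetic_example(self):
        # f(AB)=0.4, f(A)=f(B)=0.5 -> D=0.15, r2=0.36, signed=+0.6
        # haplotype counts over 20: AB=8, Ab=2, aB=2, ab=8
        H = np.array([[1, 1]] * 8 + [[1, 0]] * 2 + [[0, 1]] * 2 + [[0, 0]] * 8, dtype=np.int8)
        g = make_geno(H[::2] + H[1::2], bp=[0, 1000], haplotypes=H)
        res = ld_statistics(g)
        assert res.pairs["r2"].iloc[0] == pytest.approx(0.36)
        assert res.pairs["signed_ld"].iloc[0] == pytest.approx(0.6)

    def test_zero_ld_when_independent(self):
        H = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8)
        g = make_geno(H[::2] + H[1::2], bp=[0, 1000], haplotypes=H)
        assert ld_statistics(g).pairs["r2"].iloc[0] == pytest.approx(0.0)

    def test_allele_relabel_flips_sign_preserves_r2(self):
        rng = np.random.default_rng(4)
        H = rng.integers(0, 2, size=(40, 5)).astype(np.int8)
        g1 = make_geno(H[::2] + H[1::2], haplotypes=H)
        H2 = H.copy()
        H2[:, 0] = 1 - H2[:, 0]  # relabel locus 0
        g2 = make_geno(H2[::2] + H2[1::2], haplotypes=H2)
        r1 = ld_statistics(g1).pairs
        r2 = ld_statistics(g2).pairs
        np.testing.assert_allclose(r1["r2"], r2["r2"], atol=1e-12)
        flip = np.where(r1["i"] == 0, -1.0, 1.0)
        np.testing.assert_allclose(r1["signed_ld"] * flip, r2["signed_ld"], atol=1e-12)

    def test_bin_convention_half_open(self):
        H = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 1], [0, 0, 0]], dtype=np.int8)
        g = make_geno(H[::2] + H[1::2], bp=[0, 99_999, 100_000], haplotypes=H)
        res = ld_statistics(g)
        by_pair = dict(zip(zip(res.pairs["i"], res.pairs["j"]), res.pairs["bin_start"]))
        assert by_pair[(0, 1)] == 0        # 99,999 bp
        assert by_pair[(0, 2)] == 100_000  # exactly 100 kb

    def test_unsorted_map_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            make_geno(np.zeros((3, 2)), bp=[1000, 10])


class TestPhaseConsistency:
    def test_population_vs_itself_is_one(self, wc_sim):
        rng = np.random.default_rng(0)
        H = rng.integers(0, 2, size=(60, 40)).astype(np.int8)
        g = make_geno(H[::2] + H[1::2], haplotypes=H,
                      bp=np.sort(rng.choice(5_000_000, 40, replace=False)))
        ld = ld_statistics(g)
        pc = phase_consistency(ld, ld)
        assert np.allclose(pc["consistency"].dropna(), 1.0)

    def test_independent_populations_near_zero(self):
        rng = np.random.default_rng(1)
        bp = np.sort(rng.choice(3_000_000, 150, replace=False))
        out = []
        for s in (1, 2):
            H = np.random.default_rng(s).integers(0, 2, size=(400, 150)).astype(np.int8)
            out.append(ld_statistics(make_geno(H[::2] + H[1::2], bp=bp, haplotypes=H)))
        pc = phase_consistency(out[0], out[1])
        # pair-count-weighted mean consistency over bins is ~0
        c = pc.dropna()
        mean_c = np.average(c["consistency"], weights=c["n_pairs"])
        assert abs(mean_c) < 0.1

    def test_simultaneous_relabel_invariant(self):
        """Relabelling alleles at the same loci in both populations flips
        the same signed-LD signs in both, leaving the per-bin correlation
        essentially unchanged (exactly so up to the bin-mean centring)."""
        rng = np.random.default_rng(2)
        m = 120
        bp = np.sort(rng.choice(1_000_000, m, replace=False))
        H1 = rng.integers(0, 2, size=(400, m)).astype(np.int8)
        H2 = (H1 + (rng.random((400, m)) < 0.2)).astype(np.int8) % 2  # related pops
        g = lambda H: make_geno(H[::2] + H[1::2], bp=bp, haplotypes=H)
        pc0 = phase_consistency(ld_statistics(g(H1)), ld_statistics(g(H2)))
        flip = np.zeros(m, dtype=np.int8)
        flip[::3] = 1
        pc1 = phase_consistency(
            ld_statistics(g(np.abs(H1 - flip))), ld_statistics(g(np.abs(H2 - flip)))
        )
        np.testing.assert_allclose(
            pc0["consistency"].dropna(), pc1["consistency"].dropna(), atol=0.05
        )

    def test_sparse_bins_reported_missing(self):
        rng = np.random.default_rng(3)
        H = rng.integers(0, 2, size=(20, 3)).astype(np.int8)
        g = make_geno(H[::2] + H[1::2], bp=[0, 150_000, 900_000], haplotypes=H)
        ld = ld_statistics(g)
        pc = phase_consistency(ld, ld, min_pairs=3)
        assert pc["consistency"].isna().all()  # <3 pairs per bin


class TestPCA:
    def test_identity_equal_shares(self):
        G = RelationshipMatrix(np.eye(8), [f"a{i}" for i in range(8)], "G")
        vals, vecs, pct = pca_of_G(G, n_pc=8)
        np.testing.assert_allclose(pct, 100.0 / 8, atol=1e-10)

    def test_diverged_populations_separate_on_pc1(self):
        rng = np.random.default_rng(5)
        m = 400
        p1 = rng.uniform(0.1, 0.9, m)
        shift = rng.choice([-0.3, 0.3], m)
        p2 = np.clip(p1 + shift, 0.05, 0.95)
        dos = np.vstack(
            [rng.binomial(2, p1, (30, m)), rng.binomial(2, p2, (30, m))]
        ).astype(float)
        G = build_G(make_geno(dos))
        _, vecs, _ = pca_of_G(G, n_pc=2)
        lab = np.r_[np.zeros(30), np.ones(30)]
        assert abs(np.corrcoef(vecs[:, 0], lab)[0, 1]) > 0.95

    def test_asymmetric_rejected(self):
        M = np.eye(3)
        M[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            pca_of_G(RelationshipMatrix(M, ["a", "b", "c"], "G"))


class TestLDPrune:
    def test_perfectly_correlated_pair_pruned(self):
        rng = np.random.default_rng(6)
        a = rng.binomial(2, 0.5, 50).astype(float)
        b = rng.binomial(2, 0.3, 50).astype(float)
        g = make_geno(np.column_stack([a, a, b]))
        out = ld_prune(g)
        assert out.n_snps == 2

    def test_uncorrelated_unchanged(self):
        rng = np.random.default_rng(7)
        dos = rng.binomial(2, 0.5, size=(200, 8)).astype(float)
        g = make_geno(dos)
        # verify the premise, then prune
        from hoofgen.genomics import _composite_r_dosage

        C = _composite_r_dosage(dos) ** 2
        np.fill_diagonal(C, 0)
        if C.max() <= 0.20:
            assert ld_prune(g).n_snps == 8

    def test_no_violating_pairs_remain(self):
        """Survivor set is clean; removals match a brute-force check."""
        rng = np.random.default_rng(8)
        base = rng.binomial(2, 0.5, size=(80, 4)).astype(float)
        cols = [base[:, 0]]
        for j in range(11):
            src = cols[-1] if j % 3 else base[:, j % 4]
            noisy = np.clip(src + rng.choice([-1, 0, 0, 1], 80), 0, 2)
            cols.append(noisy)
        g = make_geno(np.column_stack(cols))
        out = ld_prune(g)
        from hoofgen.genomics import _composite_r_dosage

        kept = out.dosages
        C = _composite_r_dosage(kept) ** 2
        np.fill_diagonal(C, 0)
        # within any window of 10 kept SNPs no pair exceeds the threshold
        for s in range(max(out.n_snps - 9, 1)):
            w = C[s : s + 10, s : s + 10]
            assert w.max() <= 0.20 + 1e-9
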