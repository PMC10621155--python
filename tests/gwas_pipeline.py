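"""End-to-end ssGWAS pipeline on simulated family data.

Shared by the GWAS unit tests and the acceptance suite/script: simulate a
genotyped population with the package generator, estimate the additive
variance by REML (two-stage, as in routine evaluations), solve the MME,
back-solve SNP effects and compute p-values.
"""

import numpy as np

from hoofgen.genomics import blend_G, build_G, qc_genotypes
from hoofgen.gwas import backsolve_snp_effects, snp_pvalues
from hoofgen.models import ModelSpec, build_design, reml_estimate, solve_mme
from hoofgen.pedigree import RelationshipMatrix, build_A
from hoofgen.simulate import SimulationConfig, simulate


def _cov2(h2):
    S = np.diag([h2, h2])
    R = np.diag([1 - h2, 1 - h2])
    return S, np.zeros((2, 2)), R


def ssgwas_run(seed, n_qtl=0, n_snps=2000, per_gen=150, h2=0.30):
    """Run the full ssGWAS chain; ``n_qtl=0`` gives a polygenic
    (pedigree-mode, no-QTL) null; ``n_qtl>=1`` plants QTL carrying the
    whole additive variance.  Returns (p, effects, geno, qtl_indices)."""
    S, Q, R = _cov2(h2)
    cfg = SimulationConfig(
        countries=("US", "AU"), n_founders=120, n_generations=2,
        animals_per_generation_per_country=per_gen,
        n_snps=n_snps, n_chromosomes=1, chrom_length_bp=100_000_000,
        Sigma_a=S, Q_pe=Q, R_e=R, cg_count_per_country=6, cg_sd=0.2,
        repeat_record_fraction=0.0, score_thresholds=None,
        tbv_mode="pedigree" if n_qtl == 0 else "genomic",
        n_qtl=max(n_qtl, 1), genotyped_fraction=1.0, seed=seed,
    )
    sim = simulate(cfg)
    geno = sim.genotypes.select_samples(sim.genotyped_ids)
    geno, _ = qc_genotypes(geno)
    A = build_A(sim.pedigree)
    A22 = RelationshipMatrix(A.submatrix(geno.sample_ids), geno.sample_ids, "A22")
    G = build_G(geno)
    Gb = blend_G(G, A22, 0.95, 0.05)
    Gb_inv = RelationshipMatrix(np.linalg.inv(Gb.dense()), Gb.ids, "G_blended_inverse")
    # restrict records to genotyped animals: a plain GBLUP evaluation
    ph = sim.phenotypes
    ph = ph[(ph.trait == "FA") & ph.animal.isin(set(geno.sample_ids))]
    design = build_design(ph, ModelSpec(scenario="JC-ST", trait="FA",
                                        countries=("US", "AU")))
    comps = reml_estimate(design, Gb, include_pe=False, tol=1e-6)
    sol = solve_mme(design, Gb_inv, comps)
    ebv_g = sol.ebv["FA"].reindex([str(a) for a in Gb.ids]).to_numpy()
    C_aa = sol.pev_block(list(Gb.ids), 0)
    u = backsolve_snp_effects(ebv_g, geno, Gb)
    p, se, flagged = snp_pvalues(u, geno, Gb, C_aa, comps.Sigma[0, 0])
    qtl = None
    if n_qtl:
        # map original QTL indices through the QC SNP filter
        orig = sim.true_values.qtl_indices
        name = sim.genotypes.snp_map["snp"].to_numpy()[orig]
        qtl = np.flatnonzero(geno.snp_map["snp"].isin(set(name)).to_numpy())
    return p, u, geno, qtl
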