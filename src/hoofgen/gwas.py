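"""Single-step GWAS: SNP effects back-solved from genomic EBVs.

SNP effects are recovered from the genotyped animals' (G)EBVs through the
blended genomic relationship matrix, their sampling variances propagated
from the prediction error (co)variance of the additive effects, and
significance called at fixed strong/moderate p-value thresholds.
Candidate windows of +/-100 kb around significant SNPs are intersected
with a user-supplied gene table (1-based inclusive coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .genomics import GenotypeData
from .pedigree import RelationshipMatrix

__all__ = [
    "GwasResult",
    "CandidateWindow",
    "backsolve_snp_effects",
    "snp_pvalues",
    "call_significance",
    "window_report",
    "genomic_control_lambda",
]

STRONG_P = 1e-6
MODERATE_P = 1e-4


@dataclass
class GwasResult:
    """Per-SNP effects, standard errors, p-values and significance labels."""

    table: pd.DataFrame  # chrom, bp, snp, effect, se, p, label
    trait: str = ""
    population: str = ""


def _centered_Z(geno: GenotypeData) -> tuple[np.ndarray, float]:
    p = geno.allele_freq()
    M = geno.dosages.copy()
    miss = np.isnan(M)
    if miss.any():
        M[miss] = np.broadcast_to(2.0 * p, M.shape)[miss]
    Z = M - 2.0 * p
    k = float(2.0 * np.sum(p * (1.0 - p)))
    return Z, k


def backsolve_snp_effects(
    ebv_g: np.ndarray,
    geno: GenotypeData,
    Gb: RelationshipMatrix,
    k: float | None = None,
) -> np.ndarray:
    """SNP effects u = (1/k) Z' Gb^-1 a_hat with equal SNP weights.

    ``ebv_g`` holds the genomic EBVs of exactly the animals in ``Gb`` (same
    order); ``k`` defaults to the VanRaden scaling constant 2*sum p(1-p)
    recomputed from the genotypes.
    """
    Z, k_default = _centered_Z(geno)
    if k is None:
        k = k_default
    ebv_g = np.asarray(ebv_g, dtype=float)
    if len(ebv_g) != len(Gb.ids) or Z.shape[0] != len(Gb.ids):
        raise ValueError("EBV / genotype / Gb dimensions do not match")
    sol = np.linalg.solve(Gb.dense(), ebv_g)
    return (Z.T @ sol) / k


def snp_pvalues(
    effects: np.ndarray,
    geno: GenotypeData,
    Gb: RelationshipMatrix,
    C_aa: np.ndarray,
    sigma_a2: float,
    k: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """P-values of back-solved SNP effects.

    Var(u_j) = (1/k^2) z_j' Gb^-1 (sigma_a^2 Gb - C_aa) Gb^-1 z_j, where
    ``C_aa`` is the prediction error (co)variance block of the genotyped
    animals' additive effects (from the inverted MME coefficient matrix);
    p = 2 (1 - Phi(|u_j| / sqrt(Var u_j))).  SNPs with non-positive
    variance (e.g. zero dosage variance) get p = 1 and a flag.

    Returns (p_values, standard_errors, flagged).
    """
    Z, k_default = _centered_Z(geno)
    if k is None:
        k = k_default
    Gb_d = Gb.dense()
    Gb_inv = np.linalg.inv(Gb_d)
    B = Gb_inv @ (sigma_a2 * Gb_d - C_aa) @ Gb_inv
    var_u = np.einsum("ij,jk,ik->i", Z.T, B, Z.T) / (k * k)
    flagged = var_u <= 1e-14
    se = np.sqrt(np.clip(var_u, 0.0, None))
    p = np.ones_like(se)
    ok = ~flagged
    zstat = np.zeros_like(se)
    zstat[ok] = np.abs(effects[ok]) / se[ok]
    p[ok] = 2.0 * norm.sf(zstat[ok])
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return p, se, flagged


def subsample_genotyped(
    sample_ids: np.ndarray,
    country: np.ndarray | None,
    per_country: int,
    seed: int | None = None,
) -> np.ndarray:
    """Seeded subsample of genotyped animals, at most ``per_country`` from
    each country (mirroring the routine practice of capping the genotyped
    set before inverting the full coefficient matrix for p-values)."""
    rng = np.random.default_rng(seed)
    sample_ids = np.asarray(sample_ids, dtype=object)
    if country is None:
        k = min(per_country, len(sample_ids))
        return sample_ids[np.sort(rng.choice(len(sample_ids), k, replace=False))]
    out = []
    for c in pd.unique(pd.Series(country)):
        idx = np.flatnonzero(np.asarray(country) == c)
        k = min(per_country, len(idx))
        out.append(sample_ids[np.sort(rng.choice(idx, k, replace=False))])
    return np.concatenate(out)


def call_significance(p_values: np.ndarray) -> np.ndarray:
    """Strong (p < 1e-6) / moderate (p < 1e-4) / none labels."""
    p = np.asarray(p_values)
    out = np.full(p.shape, "none", dtype=object)
    out[p < MODERATE_P] = "moderate"
    out[p < STRONG_P] = "strong"
    return out


def genomic_control_lambda(p_values: np.ndarray) -> float:
    """Inflation factor: median chi-square of the p-values over its
    theoretical median (0.4549); ~1 under a well-calibrated null."""
    q = chi2.isf(np.asarray(p_values), df=1)
    return float(np.median(q) / chi2.ppf(0.5, df=1))


def run_gwas(
    ebv_g: np.ndarray,
    geno: GenotypeData,
    Gb: RelationshipMatrix,
    C_aa: np.ndarray,
    sigma_a2: float,
    trait: str = "",
    population: str = "",
) -> GwasResult:
    """Back-solve, test and label every SNP; convenience wrapper."""
    u = backsolve_snp_effects(ebv_g, geno, Gb)
    p, se, flagged = snp_pvalues(u, geno, Gb, C_aa, sigma_a2)
    table = pd.DataFrame(
        {
            "chrom": geno.snp_map["chrom"].to_numpy(),
            "bp": geno.snp_map["bp"].to_numpy(),
            "snp": geno.snp_map["snp"].to_numpy(),
            "effect": u,
            "se": se,
            "p": p,
            "label": call_significance(p),
            "flagged": flagged,
        }
    )
    return GwasResult(table=table, trait=trait, population=population)


@dataclass
class CandidateWindow:
    snp: str
    chrom: object
    bp: int
    window_start: int
    window_end: int
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        assert self.window_end - self.window_start + 1 <= 200_001


def window_report(
    significant: pd.DataFrame,
    gene_table: pd.DataFrame,
    flank: int = 100_000,
) -> list[CandidateWindow]:
    """Genes within +/-``flank`` bp of each significant SNP.

    ``significant`` needs columns chrom, bp, snp; ``gene_table`` needs
    chrom, start, end, gene with 1-based inclusive coordinates.  Intervals
    intersect inclusively on both ends; windows are clipped at position 1.
    An empty overlap still yields a window entry.
    """
    sig_chroms = set(np.asarray(significant["chrom"]).tolist())
    gene_chroms = set(np.asarray(gene_table["chrom"]).tolist())
    if sig_chroms and gene_chroms and not (sig_chroms & gene_chroms):
        import warnings

        warnings.warn(
            "no shared chromosome names between SNPs and gene table; assembly mismatch?"
        )
    out = []
    for _, row in significant.iterrows():
        lo = max(1, int(row["bp"]) - flank)
        hi = int(row["bp"]) + flank
        sub = gene_table[
            (gene_table["chrom"] == row["chrom"])
            & (gene_table["start"] <= hi)
            & (gene_table["end"] >= lo)
        ].reset_index(drop=True)
        out.append(
            CandidateWindow(
                snp=str(row["snp"]), chrom=row["chrom"], bp=int(row["bp"]),
                window_start=lo, window_end=hi, genes=sub,
            )
        )
    return out
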