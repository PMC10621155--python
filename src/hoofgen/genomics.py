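"""Genomic relationship machinery and marker statistics.

Genotype QC, the VanRaden method-1 genomic relationship matrix ``G``,
blending with the pedigree block ``A22``, the APY sparse inverse, the
single-step ``H`` matrix (dense forward form and sparse inverse), linkage
disequilibrium decay, signed-LD gametic-phase consistency between
populations, PCA of ``G`` and LD pruning.

Dosages are 0/1/2 with ``nan`` for missing.  Where the simulator retains
true phase, LD uses haplotype frequencies; for unphased input a
dosage-based composite correlation is used and labelled as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import RelationshipMatrix

__all__ = [
    "GenotypeData",
    "LDResult",
    "qc_genotypes",
    "build_G",
    "blend_G",
    "apy_inverse",
    "build_H",
    "build_H_inverse",
    "ld_statistics",
    "phase_consistency",
    "pca_of_G",
    "ld_prune",
]


@dataclass
class GenotypeData:
    """Allele dosages with a SNP map and sample metadata.

    ``dosages``: (n_samples, n_snps) float array, values 0/1/2 or nan.
    ``snp_map``: DataFrame with columns ``snp``, ``chrom``, ``bp`` (bp sorted
    within chromosome).  ``haplotypes`` (2*n_samples, n_snps, int8) is kept
    when true phase is known (simulated data); row 2i and 2i+1 belong to
    sample i.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: np.ndarray
    country: np.ndarray | None = None
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_map)):
            raise ValueError("dosage matrix shape does not match ids/map")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(bp < 0) or np.any(np.diff(bp) < 0):
                raise ValueError("SNP map bp must be non-negative and sorted within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeData":
        g = self
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            hap = None
            if g.haplotypes is not None:
                hrows = np.stack([2 * sample_idx, 2 * sample_idx + 1], axis=1).ravel()
                hap = g.haplotypes[hrows]
            g = GenotypeData(
                g.dosages[sample_idx],
                g.snp_map,
                g.sample_ids[sample_idx],
                None if g.country is None else g.country[sample_idx],
                hap,
            )
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            g = GenotypeData(
                g.dosages[:, snp_idx],
                g.snp_map.iloc[snp_idx].reset_index(drop=True),
                g.sample_ids,
                g.country,
                None if g.haplotypes is None else g.haplotypes[:, snp_idx],
            )
        return g

    def select_samples(self, ids: Iterable) -> "GenotypeData":
        index = {a: i for i, a in enumerate(self.sample_ids)}
        return self.subset(sample_idx=[index[str(a)] for a in ids])


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_genotypes(
    geno: GenotypeData,
    maf_threshold: float = 0.05,
    snp_call_rate: float = 0.90,
    sample_call_rate: float = 0.80,
) -> tuple[GenotypeData, dict]:
    """Marker and sample quality control.

    Samples with call rate strictly above ``sample_call_rate`` are kept
    first; then SNPs with minor allele frequency strictly above
    ``maf_threshold`` and call rate strictly above ``snp_call_rate``.
    Returns the filtered data and a report of counts removed per rule.
    """
    called = ~np.isnan(geno.dosages)
    samp_cr = called.mean(axis=1)
    keep_samples = samp_cr > sample_call_rate
    g = geno.subset(sample_idx=np.flatnonzero(keep_samples))

    called = ~np.isnan(g.dosages)
    snp_cr = called.mean(axis=0)
    p = g.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    low_maf = ~(maf > maf_threshold)
    low_cr = ~(snp_cr > snp_call_rate)
    keep_snps = ~(low_maf | low_cr)
    if not keep_snps.any():
        raise ValueError("all SNPs removed by QC")
    out = g.subset(snp_idx=np.flatnonzero(keep_snps))
    report = {
        "n_samples_in": geno.n_samples,
        "n_samples_removed_call_rate": int((~keep_samples).sum()),
        "n_snps_in": geno.n_snps,
        "n_snps_removed_maf": int(low_maf.sum()),
        "n_snps_removed_call_rate": int(low_cr.sum()),
        "n_snps_removed": int((~keep_snps).sum()),
        "n_samples_out": out.n_samples,
        "n_snps_out": out.n_snps,
    }
    return out, report


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def build_G(geno: GenotypeData) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G = Z Z' / (2 sum p_j (1-p_j)) with Z = M - 2P, allele frequencies from
    the observed data and missing dosages mean-imputed at 2p.
    """
    p = geno.allele_freq()
    k = float(2.0 * np.sum(p * (1.0 - p)))
    if k <= 0:
        raise ValueError("all SNPs monomorphic; G scaling constant is zero")
    M = geno.dosages.copy()
    miss = np.isnan(M)
    if miss.any():
        M[miss] = np.broadcast_to(2.0 * p, M.shape)[miss]
    Z = M - 2.0 * p
    G = (Z @ Z.T) / k
    return RelationshipMatrix(G, geno.sample_ids, "G", meta={"k": k, "p": p})


def blend_G(
    G: RelationshipMatrix, A22: RelationshipMatrix, alpha: float = 0.90, beta: float = 0.10
) -> RelationshipMatrix:
    """G_b = alpha*G + beta*A22 (defaults 0.90/0.10) on matching id indices."""
    if abs(alpha + beta - 1.0) > 1e-12:
        raise ValueError("alpha + beta must equal 1")
    if len(G.ids) != len(A22.ids) or np.any(G.ids != A22.ids):
        raise ValueError("G and A22 id indices do not match")
    Gb = alpha * G.dense() + beta * A22.dense()
    meta = dict(G.meta)
    meta.update(alpha=alpha, beta=beta)
    return RelationshipMatrix(Gb, G.ids, "G_blended", meta=meta)


def apy_inverse(
    Gb: RelationshipMatrix,
    core_ids: Iterable | None = None,
    n_core: int | None = None,
    seed: int | None = None,
) -> RelationshipMatrix:
    """APY (algorithm of proven and young) approximate inverse of G_b.

    Core animals are either supplied or sampled uniformly (seeded).  The
    non-core block is diagonal with per-animal conditional variances
    m_ii = g_ii - g_ic Gcc^-1 g_ci computed exactly.  With the core equal to
    the whole set this is the direct inverse.
    """
    ids = Gb.ids
    n = len(ids)
    if core_ids is None:
        if n_core is None:
            raise ValueError("supply core_ids or n_core")
        rng = np.random.default_rng(seed)
        core_idx = np.sort(rng.choice(n, size=min(n_core, n), replace=False))
    else:
        core_idx = np.sort(Gb.index_of(core_ids))
    mask = np.zeros(n, dtype=bool)
    mask[core_idx] = True
    non_idx = np.flatnonzero(~mask)
    M = Gb.dense()
    Gcc = M[np.ix_(core_idx, core_idx)]
    try:
        Gcc_inv = np.linalg.inv(Gcc)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular core block; blend G with A22 (e.g. 0.90G + 0.10A22) first"
        ) from exc
    out = np.zeros_like(M)
    if len(non_idx) == 0:
        out = Gcc_inv
    else:
        Gcn = M[np.ix_(core_idx, non_idx)]
        W = Gcc_inv @ Gcn  # (c, n)
        mdiag = M[non_idx, non_idx] - np.einsum("cn,cn->n", Gcn, W)
        if np.any(mdiag <= 0):
            raise np.linalg.LinAlgError(
                "non-positive APY conditional variance; blend G with A22 first"
            )
        minv = 1.0 / mdiag
        out[np.ix_(core_idx, core_idx)] = Gcc_inv + (W * minv) @ W.T
        out[np.ix_(core_idx, non_idx)] = -W * minv
        out[np.ix_(non_idx, core_idx)] = (-W * minv).T
        out[non_idx, non_idx] = minv
    return RelationshipMatrix(
        out, ids, "G_blended_inverse",
        meta={"apy_core_ids": ids[core_idx], "apy": len(core_idx) < n},
    )


def build_H(
    A: RelationshipMatrix, Gb: RelationshipMatrix
) -> RelationshipMatrix:
    """Dense single-step H by the textbook forward formula (desk scale).

    With genotyped block indices 2 and the rest 1:
    H11 = A11 + A12 A22i (Gb - A22) A22i A21,  H12 = A12 A22i Gb,  H22 = Gb.
    Used as the REML relationship for ssGBLUP fits and as the oracle for the
    sparse H^-1 assembly.
    """
    gidx = A.index_of(Gb.ids)
    n = len(A.ids)
    mask = np.zeros(n, dtype=bool)
    mask[gidx] = True
    nidx = np.flatnonzero(~mask)
    Ad = A.dense()
    A22 = Ad[np.ix_(gidx, gidx)]
    A22i = np.linalg.inv(A22)
    Gbd = Gb.dense()
    H = Ad.copy()
    A12 = Ad[np.ix_(nidx, gidx)]
    T = A12 @ A22i  # (n1, n2)
    H[np.ix_(nidx, nidx)] = Ad[np.ix_(nidx, nidx)] + T @ (Gbd - A22) @ T.T
    H12 = T @ Gbd
    H[np.ix_(nidx, gidx)] = H12
    H[np.ix_(gidx, nidx)] = H12.T
    H[np.ix_(gidx, gidx)] = Gbd
    return RelationshipMatrix(H, A.ids, "H", meta={"genotyped_ids": Gb.ids})


def build_H_inverse(
    A_inv: RelationshipMatrix,
    A22_inv: RelationshipMatrix,
    Gb_inv: RelationshipMatrix,
) -> RelationshipMatrix:
    """Sparse H^-1 = A^-1 + [[0,0],[0, Gb^-1 - A22^-1]] on the genotyped block."""
    if len(A22_inv.ids) != len(Gb_inv.ids) or np.any(A22_inv.ids != Gb_inv.ids):
        raise ValueError("A22^-1 and Gb^-1 id indices do not match")
    gidx = A_inv.index_of(Gb_inv.ids)  # raises if a genotyped id is absent
    n = len(A_inv.ids)
    delta = Gb_inv.dense() - A22_inv.dense()
    corr = sp.coo_matrix(
        (
            delta.ravel(),
            (
                np.repeat(gidx, len(gidx)),
                np.tile(gidx, len(gidx)),
            ),
        ),
        shape=(n, n),
    )
    Am = A_inv.matrix if sp.issparse(A_inv.matrix) else sp.csr_matrix(A_inv.matrix)
    H_inv = (Am + corr.tocsr()).tocsr()
    return RelationshipMatrix(H_inv, A_inv.ids, "H_inverse")


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDResult:
    """Pairwise within-chromosome LD plus a 100-kbp binned summary.

    ``pairs``: DataFrame (chrom, i, j, snp_i, snp_j, dist_bp, r2, signed_ld)
    where i < j index the SNP map.  ``binned``: DataFrame (bin_start,
    mean_r2, mean_signed_ld, n_pairs).  ``method`` is 'haplotype' or
    'dosage' (composite fallback for unphased input).
    """

    pairs: pd.DataFrame
    binned: pd.DataFrame
    bin_width: int
    method: str


def _signed_r_haplotype(H: np.ndarray) -> np.ndarray:
    """Correlation of allele indicators across haplotypes.

    The correlation r = D / sqrt(p(1-p)q(1-q)) already carries the sign of
    D = f(AB) - f(A) f(B); r^2 is the usual LD measure.
    """
    Hc = H - H.mean(axis=0)
    denom = np.sqrt((Hc**2).sum(axis=0))
    denom[denom == 0] = np.nan
    C = (Hc.T @ Hc) / np.outer(denom, denom)
    return C


def _composite_r_dosage(M: np.ndarray) -> np.ndarray:
    Mc = M - np.nanmean(M, axis=0)
    Mc = np.where(np.isnan(Mc), 0.0, Mc)
    denom = np.sqrt((Mc**2).sum(axis=0))
    denom[denom == 0] = np.nan
    return (Mc.T @ Mc) / np.outer(denom, denom)


def ld_statistics(
    geno: GenotypeData,
    max_distance_bp: int | None = None,
    bin_width: int = 100_000,
) -> LDResult:
    """Pairwise r^2 and signed LD within chromosomes, binned by distance.

    Bins are half-open [k*bin_width, (k+1)*bin_width) on |bp_i - bp_j|.
    """
    use_hap = geno.haplotypes is not None
    frames = []
    for chrom, grp in geno.snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        bp = grp["bp"].to_numpy()
        if use_hap:
            C = _signed_r_haplotype(geno.haplotypes[:, idx].astype(float))
        else:
            C = _composite_r_dosage(geno.dosages[:, idx])
        iu, ju = np.triu_indices(len(idx), k=1)
        dist = np.abs(bp[ju] - bp[iu])
        if max_distance_bp is not None:
            keep = dist <= max_distance_bp
            iu, ju, dist = iu[keep], ju[keep], dist[keep]
        r = C[iu, ju]
        ok = np.isfinite(r)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "i": idx[iu[ok]],
                    "j": idx[ju[ok]],
                    "snp_i": grp["snp"].to_numpy()[iu[ok]],
                    "snp_j": grp["snp"].to_numpy()[ju[ok]],
                    "dist_bp": dist[ok],
                    "r2": r[ok] ** 2,
                    "signed_ld": r[ok],
                }
            )
        )
    pairs = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "i", "j", "snp_i", "snp_j", "dist_bp", "r2", "signed_ld"]
    )
    pairs["bin_start"] = (pairs["dist_bp"] // bin_width).astype(int) * bin_width
    binned = (
        pairs.groupby("bin_start")
        .agg(mean_r2=("r2", "mean"), mean_signed_ld=("signed_ld", "mean"), n_pairs=("r2", "size"))
        .reset_index()
    )
    return LDResult(pairs=pairs, binned=binned, bin_width=bin_width,
                    method="haplotype" if use_hap else "dosage")


def phase_consistency(
    ld_pop1: LDResult, ld_pop2: LDResult, mode: str = "per-pair", min_pairs: int = 3
) -> pd.DataFrame:
    """Gametic-phase consistency between two populations.

    Default ('per-pair'): for each distance bin, the Pearson correlation of
    per-pair signed LD between the populations over SNP pairs present in
    both; bins with fewer than ``min_pairs`` shared pairs are reported as
    missing.  Mode 'binned-curve' instead returns the single Pearson
    correlation of the two binned mean-signed-LD curves.
    """
    key = ["chrom", "i", "j"]
    merged = ld_pop1.pairs.merge(
        ld_pop2.pairs[key + ["signed_ld"]], on=key, suffixes=("_1", "_2")
    )
    if mode == "binned-curve":
        b = merged.groupby("bin_start")[["signed_ld_1", "signed_ld_2"]].mean()
        r = float(np.corrcoef(b["signed_ld_1"], b["signed_ld_2"])[0, 1])
        return pd.DataFrame({"bin_start": [0], "consistency": [r], "n_pairs": [len(b)]})
    rows = []
    for bin_start, grp in merged.groupby("bin_start"):
        if len(grp) < min_pairs:
            rows.append((bin_start, np.nan, len(grp)))
            continue
        r = float(np.corrcoef(grp["signed_ld_1"], grp["signed_ld_2"])[0, 1])
        rows.append((bin_start, r, len(grp)))
    return pd.DataFrame(rows, columns=["bin_start", "consistency", "n_pairs"])


# ---------------------------------------------------------------------------
# PCA and pruning
# ---------------------------------------------------------------------------

def pca_of_G(G: RelationshipMatrix, n_pc: int = 10):
    """Top eigenpairs of G by exact symmetric eigendecomposition.

    Returns (eigenvalues desc, eigenvectors columns, pct_variance) where
    pct_variance_i = lambda_i / trace(G) * 100.
    """
    M = G.dense()
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("G must be symmetric")
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1][:n_pc]
    vals_top = vals[order]
    pct = 100.0 * vals_top / np.trace(M)
    return vals_top, vecs[:, order], pct


def ld_prune(
    geno: GenotypeData, r2_threshold: float = 0.20, window: int = 10
) -> GenotypeData:
    """Greedy sliding-window LD pruning (window of SNPs, step 1).

    In each window, for every pair with r^2 > threshold the SNP with the
    lower MAF is removed (tie: the later map position); windows are rescanned
    until no violating pair remains among the survivors.
    """
    p = geno.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    keep = np.ones(geno.n_snps, dtype=bool)
    M = geno.dosages
    for chrom, grp in geno.snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        changed = True
        while changed:
            changed = False
            alive = idx[keep[idx]]
            for start in range(0, max(len(alive) - 1, 0)):
                w = alive[start : start + window]
                w = w[keep[w]]
                if len(w) < 2:
                    continue
                C = _composite_r_dosage(M[:, w])
                iu, ju = np.triu_indices(len(w), k=1)
                bad = (C[iu, ju] ** 2) > r2_threshold
                for a, b in zip(iu[bad], ju[bad]):
                    sa, sb = w[a], w[b]
                    if not (keep[sa] and keep[sb]):
                        continue
                    if maf[sa] < maf[sb]:
                        drop = sa
                    elif maf[sb] < maf[sa]:
                        drop = sb
                    else:
                        drop = max(sa, sb)  # tie: later map position
                    keep[drop] = False
                    changed = True
    return geno.subset(snp_idx=np.flatnonzero(keep))
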