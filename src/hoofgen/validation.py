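"""Forward validation of (genomic) breeding values.

Implements the whole/partial forward design and the LR-method statistics —
bias, dispersion and accuracy of GEBVs — plus exact per-animal theoretical
accuracies from prediction error variances, and proven-sire rank
correlations across evaluation scenarios.

The *whole* dataset contains all phenotypes; the *partial* dataset masks
the phenotypes of the target animals (genotyped-and-phenotyped animals
born in the per-country target years) and additionally drops the records
of non-genotyped animals born in those years so they cannot leak target
information into the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .pedigree import Pedigree

__all__ = [
    "ValidationSplit",
    "LRResult",
    "make_forward_split",
    "lr_metrics",
    "theoretical_accuracy",
    "sire_correlations",
]


@dataclass
class ValidationSplit:
    target_ids: np.ndarray
    whole: pd.DataFrame
    partial: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        overlap = set(self.partial["animal"]) & set(self.target_ids)
        if overlap:
            raise AssertionError("partial dataset leaks target phenotypes")


def make_forward_split(
    phenotypes: pd.DataFrame,
    genotyped_ids,
    target_years_by_country: dict,
) -> ValidationSplit:
    """Split phenotypes into whole and partial sets for forward validation.

    ``target_years_by_country`` maps country to an iterable of birth years
    (e.g. ``{"US": [2020], "AU": [2019, 2020]}``).  Targets must be
    genotyped and phenotyped; phenotyped-but-not-genotyped animals born in
    a target year are removed from the partial data entirely.
    """
    gset = {str(g) for g in genotyped_ids}
    df = phenotypes
    in_target_year = np.zeros(len(df), dtype=bool)
    for c, years in target_years_by_country.items():
        years = set(int(y) for y in years)
        in_target_year |= (
            (df["country"].astype(str) == str(c))
            & df["birth_year"].astype(int).isin(years)
        ).to_numpy()
    is_geno = df["animal"].astype(str).isin(gset).to_numpy()
    target_ids = np.unique(df["animal"].to_numpy()[in_target_year & is_geno])
    if len(target_ids) == 0:
        raise ValueError("no target animals: nothing genotyped+phenotyped in the target years")
    drop = in_target_year  # targets masked; non-genotyped same-year animals removed
    partial = df[~drop].reset_index(drop=True)
    counts = (
        df[in_target_year & is_geno]
        .groupby(["country", "birth_year"])["animal"]
        .nunique()
        .rename("n_target")
        .reset_index()
    )
    return ValidationSplit(
        target_ids=target_ids, whole=df.reset_index(drop=True),
        partial=partial, counts=counts,
    )


@dataclass
class LRResult:
    """LR-method statistics over one target group.

    bias is in GEBV units (partial minus whole mean); dispersion is the
    regression of whole on partial GEBVs (1 = no over/under-dispersion);
    accuracy = sqrt(cov(partial, whole) / ((1 - F_bar) sigma_u^2)) for the
    default denominator, or with (1 + F_bar - 2 f_bar) V_g for the
    'original' variant.  Accuracy is undefined (nan) when the covariance
    is non-positive.
    """

    bias: float
    dispersion: float
    accuracy: float
    n_target: int
    F_bar: float
    sigma_u2: float
    denominator: str


def lr_metrics(
    gebv_partial: pd.Series,
    gebv_whole: pd.Series,
    F_bar: float,
    sigma_u2: float,
    denominator: str = "paper",
    f_bar: float | None = None,
) -> LRResult:
    """Bias, dispersion and accuracy of partial vs whole GEBVs.

    The two series are aligned on their index (target animal ids);
    ``sigma_u2`` is the additive genetic variance from the whole-data fit.
    """
    joined = pd.concat(
        [gebv_partial.rename("p"), gebv_whole.rename("w")], axis=1, join="inner"
    ).dropna()
    if len(joined) < 2:
        raise ValueError("need at least two aligned target animals")
    p = joined["p"].to_numpy()
    w = joined["w"].to_numpy()
    bias = float(p.mean() - w.mean())
    var_p = float(np.var(p, ddof=1))
    cov = float(np.cov(p, w, ddof=1)[0, 1])
    dispersion = cov / var_p if var_p > 0 else np.nan
    if denominator == "paper":
        denom = (1.0 - F_bar) * sigma_u2
    elif denominator == "original":
        if f_bar is None:
            raise ValueError("original denominator needs f_bar (mean relationship)")
        denom = (1.0 + F_bar - 2.0 * f_bar) * sigma_u2
    else:
        raise ValueError("denominator must be 'paper' or 'original'")
    accuracy = float(np.sqrt(cov / denom)) if cov > 0 and denom > 0 else np.nan
    return LRResult(
        bias=bias, dispersion=float(dispersion), accuracy=accuracy,
        n_target=len(joined), F_bar=float(F_bar), sigma_u2=float(sigma_u2),
        denominator=denominator,
    )


def theoretical_accuracy(
    pev: np.ndarray, F: np.ndarray, sigma_a2: float
) -> np.ndarray:
    """Individual accuracies r_i = sqrt(1 - PEV_i / ((1 + F_i) sigma_a^2)).

    PEVs exceeding the full additive variance (numerically possible for
    animals with no information) clip the accuracy at 0 with a warning.
    """
    denom = (1.0 + np.asarray(F)) * sigma_a2
    ratio = 1.0 - np.asarray(pev) / denom
    if np.any(ratio < -1e-8):
        import warnings

        warnings.warn("PEV exceeded (1+F) sigma_a^2 for some animals; accuracy set to 0")
    return np.sqrt(np.clip(ratio, 0.0, None))


def sire_correlations(
    solutions: dict,
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    min_progeny: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Pearson/Spearman correlations of proven sires' EBVs across scenarios.

    ``solutions`` maps scenario name -> Series of EBVs indexed by animal
    id.  Proven sires have *more than* ``min_progeny`` progeny with
    phenotypic records.  Returns (pearson, spearman, sire_ids).
    """
    if len(solutions) < 2:
        raise ValueError("need at least two scenarios")
    recorded = set(phenotypes["animal"].astype(str))
    rec_idx = [i for i in range(pedigree.n) if str(pedigree.ids[i]) in recorded]
    sire_count: dict = {}
    for i in rec_idx:
        s = pedigree.sire[i]
        if s >= 0:
            sid = str(pedigree.ids[s])
            sire_count[sid] = sire_count.get(sid, 0) + 1
    proven = sorted(s for s, k in sire_count.items() if k > min_progeny)
    if len(proven) < 3:
        raise ValueError(
            f"fewer than 3 sires with more than {min_progeny} recorded progeny"
        )
    names = list(solutions)
    mat = pd.DataFrame(
        {name: solutions[name].reindex(proven) for name in names}
    ).dropna()
    pear = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    spear = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            pear.loc[a, b] = pear.loc[b, a] = pearsonr(mat[a], mat[b])[0]
            spear.loc[a, b] = spear.loc[b, a] = spearmanr(mat[a], mat[b])[0]
    return pear, spear, np.asarray(proven, dtype=object)
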