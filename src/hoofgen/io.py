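"""Phenotype preparation filters and file readers/writers.

Tabular interchange is TSV/CSV with headers; genotypes additionally go
through PLINK text formats (.ped/.map) and a plain dosage TSV.  The
phenotype filters implement the published editing rules: scores restricted
to 5-9, recording ages within [320, 5475] days, and contemporary-group
cells required to keep at least 20 records spanning at least two score
categories (per trait, applied once, no cascade).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import GenotypeData
from .pedigree import Pedigree

__all__ = [
    "filter_phenotypes",
    "filter_contemporary_groups",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
    "write_plink",
    "read_plink",
    "write_dosage_tsv",
    "read_dosage_tsv",
]

SCORE_MIN, SCORE_MAX = 5, 9
AGE_MIN, AGE_MAX = 320, 5475


def filter_phenotypes(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep scores 5-9 and ages 320-5475 days (inclusive boundaries).

    Returns the filtered table and a report of counts removed per rule;
    removed-plus-kept always equals the input count (score rule applied
    first, then age).
    """
    n_in = len(table)
    score = table["score"].to_numpy()
    ok_score = (score >= SCORE_MIN) & (score <= SCORE_MAX)
    age = table["age_days"].to_numpy()
    ok_age = (age >= AGE_MIN) & (age <= AGE_MAX)
    keep = ok_score & ok_age
    report = {
        "n_in": n_in,
        "n_removed_score": int((~ok_score).sum()),
        "n_removed_age": int((ok_score & ~ok_age).sum()),
        "n_kept": int(keep.sum()),
    }
    return table[keep].reset_index(drop=True), report


def filter_contemporary_groups(
    table: pd.DataFrame, min_records: int = 20, min_categories: int = 2
) -> tuple[pd.DataFrame, dict]:
    """Drop CG-by-trait cells with too few records or score categories.

    A cell is kept when it has at least ``min_records`` records *and* at
    least ``min_categories`` distinct scores.  Applied once after
    :func:`filter_phenotypes`; no cascading re-check.
    """
    n_in = len(table)
    stats = table.groupby(["cg", "trait"])["score"].agg(["size", "nunique"])
    bad = stats[(stats["size"] < min_records) | (stats["nunique"] < min_categories)]
    bad_cells = set(bad.index)
    keep = ~table.set_index(["cg", "trait"]).index.isin(bad_cells)
    out = table[keep].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("contemporary-group filter removed every record")
    report = {
        "n_in": n_in,
        "n_cells_removed": len(bad_cells),
        "n_removed": int(n_in - len(out)),
        "n_kept": int(len(out)),
    }
    return out, report


# ---------------------------------------------------------------------------
# tabular files
# ---------------------------------------------------------------------------

def read_pedigree_csv(path) -> Pedigree:
    """Pedigree CSV with columns id,sire,dam[,birth_year,country,sex];
    '0' or empty marks an unknown parent."""
    df = pd.read_csv(path, dtype=str).fillna("0")
    if "birth_year" in df.columns:
        df["birth_year"] = df["birth_year"].astype(int)
    return Pedigree.from_frame(df)


def write_pedigree_csv(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["animal"] = df["animal"].astype(str)
    return df


def write_phenotypes_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotype files
# ---------------------------------------------------------------------------

def write_plink(geno: GenotypeData, prefix) -> None:
    """PLINK text .ped/.map; missing dosage written as 0 0 alleles.

    Dosage d counts allele '2'; a heterozygote is written '1 2'.  The .map
    carries chromosome, SNP id, 0 cM, and bp.
    """
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in geno.snp_map.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['bp']}\n")
    allele_for = {0.0: "1 1", 1.0: "1 2", 2.0: "2 2"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, animal in enumerate(geno.sample_ids):
            sex = "0"
            calls = [
                allele_for.get(float(d), "0 0") if not np.isnan(d) else "0 0"
                for d in geno.dosages[i]
            ]
            fh.write(f"FAM {animal} 0 0 {sex} -9 " + " ".join(calls) + "\n")


def read_plink(prefix) -> GenotypeData:
    prefix = Path(prefix)
    snp_map = pd.read_csv(
        prefix.with_suffix(".map"), sep="\t", header=None,
        names=["chrom", "snp", "cm", "bp"],
    )[["snp", "chrom", "bp"]]
    ids = []
    rows = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1])
            alleles = parts[6:]
            dos = np.empty(len(alleles) // 2)
            for j in range(0, len(alleles), 2):
                a, b = alleles[j], alleles[j + 1]
                if a == "0" or b == "0":
                    dos[j // 2] = np.nan
                else:
                    dos[j // 2] = (a == "2") + (b == "2")
            rows.append(dos)
    return GenotypeData(
        dosages=np.vstack(rows), snp_map=snp_map,
        sample_ids=np.asarray(ids, dtype=object),
    )


def write_dosage_tsv(geno: GenotypeData, path) -> None:
    df = pd.DataFrame(
        geno.dosages, index=geno.sample_ids, columns=geno.snp_map["snp"]
    )
    df.index.name = "animal"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path, snp_map: pd.DataFrame | None = None) -> GenotypeData:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    if snp_map is None:
        snp_map = pd.DataFrame(
            {"snp": df.columns, "chrom": 1, "bp": np.arange(1, len(df.columns) + 1)}
        )
    return GenotypeData(
        dosages=df.to_numpy(dtype=float), snp_map=snp_map,
        sample_ids=df.index.astype(str).to_numpy(dtype=object),
    )
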