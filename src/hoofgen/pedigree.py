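"""Pedigree relationship algebra.

Numerator (additive) relationship matrices and their inverses for animal
models: the tabular-method ``A``, Henderson's sparse ``A^-1`` accounting for
inbreeding, Meuwissen-Luo inbreeding coefficients, the genotyped-subset
block ``A22`` and its inverse, and ancestor extraction for building
evaluation pedigrees.

Ids are opaque strings; every matrix carries its own id index so that
downstream code never relies on positional conventions.  ``A`` is stored
dense (these analyses run at desk scale), ``A^-1`` always sparse.
Unknown parents contribute founder variance; unknown-parent groups are not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = -1

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "extract_ancestors",
    "compute_inbreeding",
    "build_A",
    "build_A_inverse",
    "build_A22",
    "build_A22_inverse",
]


@dataclass
class RelationshipMatrix:
    """A symmetric relationship matrix together with its id index.

    ``flavor`` distinguishes the algebraic role: one of ``A``, ``A_inverse``,
    ``A22``, ``A22_inverse``, ``G``, ``G_blended``, ``G_blended_inverse``,
    ``H``, ``H_inverse``.  ``meta`` carries construction by-products (e.g.
    the VanRaden scaling constant for ``G``).
    """

    matrix: np.ndarray | sp.spmatrix
    ids: np.ndarray
    flavor: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} ids"
            )
        self._index = {a: i for i, a in enumerate(self.ids)}

    def index_of(self, ids: Iterable) -> np.ndarray:
        """Positions of ``ids`` in this matrix; raises on unknown ids."""
        try:
            return np.array([self._index[a] for a in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"id {exc.args[0]!r} not in {self.flavor} matrix") from exc

    def submatrix(self, ids: Iterable) -> np.ndarray:
        idx = self.index_of(ids)
        m = self.matrix
        if sp.issparse(m):
            m = m.tocsr()[idx][:, idx].toarray()
            return m
        return np.asarray(m)[np.ix_(idx, idx)]

    def dense(self) -> np.ndarray:
        return self.matrix.toarray() if sp.issparse(self.matrix) else np.asarray(self.matrix)


class Pedigree:
    """A topologically ordered pedigree.

    Parameters are parallel sequences: string ids, sire/dam ids (``None``,
    ``""`` or ``"0"`` meaning unknown), and optional birth year, country and
    sex columns.  The constructor validates uniqueness, sorts parents before
    offspring, rejects cycles, and rejects ids used both as sire and as dam.
    """

    def __init__(
        self,
        ids: Sequence,
        sire: Sequence,
        dam: Sequence,
        birth_year: Sequence | None = None,
        country: Sequence | None = None,
        sex: Sequence | None = None,
    ) -> None:
        ids = np.asarray([str(a) for a in ids], dtype=object)
        n = len(ids)
        if len(set(ids)) != n:
            dupes = pd.Series(ids).value_counts()
            raise ValueError(f"duplicate animal ids: {list(dupes[dupes > 1].index)[:5]}")
        index = {a: i for i, a in enumerate(ids)}

        def code(parents):
            out = np.full(n, UNKNOWN, dtype=np.int64)
            for i, p in enumerate(parents):
                if p is None or (isinstance(p, float) and np.isnan(p)):
                    continue
                p = str(p)
                if p in ("", "0", "nan", "NA"):
                    continue
                if p not in index:
                    raise ValueError(f"parent id {p!r} of animal {ids[i]!r} not in pedigree")
                out[i] = index[p]
            return out

        sire_idx = code(sire)
        dam_idx = code(dam)
        used_as_sire = set(sire_idx[sire_idx >= 0])
        used_as_dam = set(dam_idx[dam_idx >= 0])
        both = used_as_sire & used_as_dam
        if both:
            raise ValueError(
                f"ids used both as sire and dam: {[ids[i] for i in sorted(both)][:5]}"
            )

        order = self._topological_order(sire_idx, dam_idx)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = np.arange(n)

        def remap(par):
            out = np.full(n, UNKNOWN, dtype=np.int64)
            for new_i, old_i in enumerate(order):
                p = par[old_i]
                out[new_i] = UNKNOWN if p == UNKNOWN else rank[p]
            return out

        self.ids = ids[order]
        self.sire = remap(sire_idx)
        self.dam = remap(dam_idx)
        take = lambda col, dtype: (
            None if col is None else np.asarray(col, dtype=dtype)[order]
        )
        self.birth_year = take(birth_year, np.int64)
        self.country = take(country, object)
        self.sex = take(sex, object)
        self._index = {a: i for i, a in enumerate(self.ids)}

    @staticmethod
    def _topological_order(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
        n = len(sire)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i in range(n):
            for p in (sire[i], dam[i]):
                if p != UNKNOWN:
                    children[p].append(i)
                    indeg[i] += 1
        from collections import deque

        queue = deque(i for i in range(n) if indeg[i] == 0)
        order: list[int] = []
        while queue:
            i = queue.popleft()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != n:
            raise ValueError("pedigree contains a cycle (an animal is its own ancestor)")
        return np.asarray(order, dtype=np.int64)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, animal) -> bool:
        return str(animal) in self._index

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Iterable) -> np.ndarray:
        try:
            return np.array([self._index[str(a)] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"animal id {exc.args[0]!r} not in pedigree") from exc

    # -- I/O -----------------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        cols = {c.lower(): c for c in df.columns}
        get = lambda name: df[cols[name]].to_numpy() if name in cols else None
        return cls(
            df[cols["id"]].to_numpy(),
            df[cols["sire"]].to_numpy(),
            df[cols["dam"]].to_numpy(),
            birth_year=get("birth_year"),
            country=get("country"),
            sex=get("sex"),
        )

    def to_frame(self) -> pd.DataFrame:
        parent = lambda idx: np.where(idx >= 0, self.ids[np.maximum(idx, 0)], "0")
        data = {"id": self.ids, "sire": parent(self.sire), "dam": parent(self.dam)}
        if self.birth_year is not None:
            data["birth_year"] = self.birth_year
        if self.country is not None:
            data["country"] = self.country
        if self.sex is not None:
            data["sex"] = self.sex
        return pd.DataFrame(data)


def extract_ancestors(ped: Pedigree, base_ids: Iterable, n_generations: int) -> Pedigree:
    """Subset ``ped`` to ``base_ids`` plus ancestors up to ``n_generations`` back.

    Parent links pointing outside the retained subset are set to unknown,
    mirroring how evaluation pedigrees are cut (e.g. "four generations of
    ancestors" from the phenotyped animals).  Idempotent at fixed depth.
    """
    base = ped.index_of(base_ids)
    keep = set(base.tolist())
    frontier = set(base.tolist())
    for _ in range(int(n_generations)):
        nxt = set()
        for i in frontier:
            for p in (ped.sire[i], ped.dam[i]):
                if p != UNKNOWN and p not in keep:
                    nxt.add(int(p))
        keep |= nxt
        frontier = nxt
        if not frontier:
            break
    keep_sorted = sorted(keep)
    in_keep = {i: True for i in keep_sorted}
    ids = ped.ids[keep_sorted]
    parent_col = lambda par: [
        str(ped.ids[par[i]]) if par[i] != UNKNOWN and par[i] in in_keep else "0"
        for i in keep_sorted
    ]
    sub = lambda col: None if col is None else col[keep_sorted]
    return Pedigree(
        ids,
        parent_col(ped.sire),
        parent_col(ped.dam),
        birth_year=sub(ped.birth_year),
        country=sub(ped.country),
        sex=sub(ped.sex),
    )


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Meuwissen-Luo inbreeding coefficients in pedigree order.

    Founders (and animals with an unknown parent) get F consistent with
    unknown parents being unrelated, non-inbred founders.  F_i equals half
    the additive relationship between the parents.
    """
    sire, dam = ped.sire, ped.dam
    F = np.zeros(ped.n)
    cache: dict[tuple[int, int], float] = {}

    def kin(a: int, b: int) -> float:
        # kinship (coancestry) = A/2; relies on topological order so that
        # F of any animal older than the current one is already final.
        if a == UNKNOWN or b == UNKNOWN:
            return 0.0
        if a < b:
            a, b = b, a
        key = (a, b)
        hit = cache.get(key)
        if hit is not None:
            return hit
        if a == b:
            val = 0.5 * (1.0 + F[a])
        else:
            val = 0.5 * (kin(sire[a], b) + kin(dam[a], b))
        cache[key] = val
        return val

    for i in range(ped.n):
        if sire[i] == UNKNOWN or dam[i] == UNKNOWN:
            F[i] = 0.0
        else:
            F[i] = kin(sire[i], dam[i])
    return F


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method numerator relationship matrix (dense, desk scale)."""
    n = ped.n
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        if s != UNKNOWN and d != UNKNOWN:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
    return RelationshipMatrix(A, ped.ids, "A")


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> RelationshipMatrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    The Mendelian-sampling variance d_i uses the parents' inbreeding:
    d_i = 0.5 - 0.25 (F_s + F_d) with both parents known, 0.75 - 0.25 F_p
    with one, and 1 with none.
    """
    if F is None:
        F = compute_inbreeding(ped)
    n = ped.n
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        d = 1.0 - sum(0.25 * (1.0 + F[p]) for p in parents)
        alpha = 1.0 / d
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * alpha, -0.5 * alpha]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * alpha)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(Ainv, ped.ids, "A_inverse")


def build_A22(ped: Pedigree, genotyped_ids: Iterable) -> RelationshipMatrix:
    """Pedigree relationship block among the genotyped animals."""
    gids = [str(g) for g in genotyped_ids]
    A = build_A(ped)
    sub = A.submatrix(gids)
    return RelationshipMatrix(sub, np.asarray(gids, dtype=object), "A22")


def build_A22_inverse(ped: Pedigree, genotyped_ids: Iterable) -> RelationshipMatrix:
    """Direct inverse of the genotyped-subset block of A (desk scale)."""
    a22 = build_A22(ped, genotyped_ids)
    m = a22.dense()
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"A22 is numerically singular (condition estimate {cond:.3g}); "
            "duplicated or identical animals in the genotyped set?"
        )
    inv = np.linalg.inv(m)
    inv = 0.5 * (inv + inv.T)
    return RelationshipMatrix(inv, a22.ids, "A22_inverse", meta={"cond": cond})
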