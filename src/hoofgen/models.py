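"""Multi-trait repeatability animal models.

Design construction, variance-component estimation by AI-REML (with EM
steps), and mixed-model-equation solving for all scenario families:

* WC (within-country), MC (multi-country, country-specific correlated
  traits), JC (joint countries pooled as one population), each in
  single-trait (``-ST``) and two-trait (``-TT``) form, plus AC
  (across-country: the MC structure with one country's phenotypes masked
  in training — the masking itself lives in :mod:`hoofgen.validation`).
* relationship source: pedigree ``A`` or single-step ``H``.

The model for each record is ``y = Xb + Z a + W pe + e`` with
``a ~ N(0, Sigma (x) K)``, ``pe ~ N(0, Q (x) I)`` and event-wise residual
covariance ``R``; in multi-country scenarios the cross-country blocks of
``Q`` and ``R`` are structural zeros and never enter the parameter vector.

REML runs on the dense phenotype covariance ``V`` (desk scale): the
gradient and average-information matrix are exact, EM update steps are
available in closed form from the same quantities, and the resulting
estimates are identical to MME-based AI-REML.  Prediction (EBVs, PEV) uses
the sparse mixed-model equations with ``K^-1`` in ``{A^-1, H^-1}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "DesignData",
    "VarianceComponents",
    "MMESolution",
    "build_design",
    "reml_estimate",
    "solve_mme",
    "derive_parameters",
    "DerivedParameters",
]

SCENARIOS = ("WC-ST", "WC-TT", "MC-ST", "MC-TT", "JC-ST", "JC-TT", "AC")


@dataclass
class ModelSpec:
    """Names the scenario family, traits, countries and relationship source.

    ``trait`` picks the analysed trait for single-trait scenarios.  For WC
    scenarios ``countries`` holds the single analysed country; for MC/JC/AC
    the (ordered) pair.
    """

    scenario: str = "WC-TT"
    traits: tuple = ("FA", "CS")
    trait: str | None = None
    countries: tuple = ("US",)
    relationship: str = "pedigree"  # or "ssgblup"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; valid: {SCENARIOS}")
        if self.scenario.endswith("-ST") and self.trait is None:
            self.trait = self.traits[0]

    @property
    def response_labels(self) -> list[tuple[str, str | None]]:
        sc = self.scenario
        if sc in ("WC-TT", "JC-TT"):
            return [(t, None) for t in self.traits]
        if sc in ("WC-ST", "JC-ST"):
            return [(self.trait, None)]
        if sc in ("MC-TT", "AC"):
            return [(t, c) for c in self.countries for t in self.traits]
        if sc == "MC-ST":
            return [(self.trait, c) for c in self.countries]
        raise AssertionError(sc)

    @property
    def nests_age_in_country(self) -> bool:
        return self.scenario.startswith("JC")


def _label(lab: tuple[str, str | None]) -> str:
    t, c = lab
    return t if c is None else f"{t}_{c}"


@dataclass
class DesignData:
    """One row per phenotypic record, mapped onto model responses.

    ``resp`` indexes ``resp_labels``; ``animal_codes`` indexes
    ``animal_ids`` (the recorded animals); ``event_codes`` groups records
    scored at the same visit (shared residual draw).  ``q_blocks`` /
    ``r_blocks`` partition responses into blocks with free
    permanent-environment / residual (co)variances; covariances across
    blocks are structural zeros.
    """

    y: np.ndarray
    resp: np.ndarray
    animal_codes: np.ndarray
    animal_ids: np.ndarray
    event_codes: np.ndarray
    X: np.ndarray
    fixed_labels: list
    resp_labels: list
    q_blocks: list
    r_blocks: list
    records: pd.DataFrame | None = None

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_responses(self) -> int:
        return len(self.resp_labels)

    @property
    def labels(self) -> list[str]:
        return [_label(lab) for lab in self.resp_labels]


def build_design(phenotypes: pd.DataFrame, spec: ModelSpec) -> DesignData:
    """Incidence structures for one scenario.

    Fixed effects are contemporary-group dummies per response plus a linear
    age covariate per response (nested within country for JC scenarios, in
    which case there is one age column per response-country cell).  Records
    are sorted by (animal, event, response) so that within-animal and
    within-event runs are contiguous.
    """
    labels = spec.response_labels
    df = phenotypes.copy()
    df["country"] = df["country"].astype(str)
    keep_countries = set(spec.countries)
    df = df[df["country"].isin(keep_countries)]
    if spec.scenario.endswith("-ST"):
        df = df[df["trait"] == spec.trait]
    # map each record to its response index
    lab_index = {}
    for k, (t, c) in enumerate(labels):
        lab_index[(t, c)] = k
    def resp_of(row_trait, row_country):
        if (row_trait, row_country) in lab_index:
            return lab_index[(row_trait, row_country)]
        return lab_index.get((row_trait, None), -1)
    resp = np.array(
        [resp_of(t, c) for t, c in zip(df["trait"], df["country"])], dtype=np.int64
    )
    ok = resp >= 0
    df, resp = df[ok], resp[ok]
    if len(df) == 0:
        raise ValueError("no records match the model specification")
    order = np.lexsort((resp, df["event"].to_numpy(), df["animal"].to_numpy()))
    df = df.iloc[order]
    resp = resp[order]

    animal_ids, animal_codes = np.unique(df["animal"].to_numpy(), return_inverse=True)
    ev_key = df["animal"].astype(str) + "#" + df["event"].astype(str)
    _, event_codes = np.unique(ev_key.to_numpy(), return_inverse=True)

    # fixed effects: CG within response, age within response(xcountry for JC)
    cg_key = pd.Series(
        [f"{_label(labels[r])}|{cg}" for r, cg in zip(resp, df["cg"])], index=df.index
    )
    cg_levels, cg_codes = np.unique(cg_key.to_numpy(), return_inverse=True)
    empty_cg = pd.Series(cg_codes).value_counts()
    if (empty_cg < 1).any():  # pragma: no cover - unique() cannot produce this
        raise ValueError("empty contemporary group")
    n = len(df)
    age = df["age_days"].to_numpy(dtype=float)
    age_c = (age - age.mean()) / 1000.0
    if spec.nests_age_in_country:
        age_key = [f"age|{_label(labels[r])}|{c}" for r, c in zip(resp, df["country"])]
    else:
        age_key = [f"age|{_label(labels[r])}" for r in resp]
    age_levels, age_codes = np.unique(np.asarray(age_key), return_inverse=True)
    X = np.zeros((n, len(cg_levels) + len(age_levels)))
    X[np.arange(n), cg_codes] = 1.0
    X[np.arange(n), len(cg_levels) + age_codes] = age_c
    fixed_labels = list(cg_levels) + list(age_levels)

    # response blocks for pe and residual: grouped by country label
    blocks: dict = {}
    for k, (t, c) in enumerate(labels):
        blocks.setdefault(c, []).append(k)
    block_list = list(blocks.values())
    return DesignData(
        y=df["score"].to_numpy(dtype=float),
        resp=resp,
        animal_codes=animal_codes,
        animal_ids=animal_ids,
        event_codes=event_codes,
        X=X,
        fixed_labels=fixed_labels,
        resp_labels=labels,
        q_blocks=block_list,
        r_blocks=[list(b) for b in block_list],
        records=df.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """REML estimates of the additive (Sigma), permanent-environment (Q)
    and residual (R) covariance matrices with standard errors.

    Structural zeros (cross-country blocks of Q and R) are exactly zero and
    carry zero SE.  ``param_cov`` is the inverse average-information matrix
    mapped to the original phenotype scale; ``param_index`` names its rows
    as (matrix, i, j) triplets.
    """

    Sigma: np.ndarray
    Q: np.ndarray | None
    R: np.ndarray
    se_Sigma: np.ndarray | None = None
    se_Q: np.ndarray | None = None
    se_R: np.ndarray | None = None
    resp_labels: list = field(default_factory=list)
    q_blocks: list = field(default_factory=list)
    r_blocks: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    loglik: float = np.nan
    loglik_path: list = field(default_factory=list)
    param_index: list = field(default_factory=list)
    param_cov: np.ndarray | None = None
    method: str = "ai"

    @property
    def labels(self) -> list[str]:
        return [_label(lab) for lab in self.resp_labels]


class _ParamMap:
    """Maps the free (co)variance elements to a flat parameter vector.

    The optimiser works on the Cholesky factors of the free blocks (PSD by
    construction, so boundary estimates need no projection); scores and
    the AI matrix are computed on the covariance scale and transformed by
    the Jacobian of the Cholesky map.  ``entries`` lists the covariance
    elements; ``blocks`` records the contiguous block layout.
    """

    def __init__(self, T: int, q_blocks, r_blocks, include_pe: bool):
        self.T = T
        self.entries: list[tuple[str, int, int]] = []
        self.blocks: list[tuple[str, list, int]] = []  # (matrix, indices, entry offset)
        self.blocks.append(("S", list(range(T)), 0))
        for i in range(T):
            for j in range(i, T):
                self.entries.append(("S", i, j))
        if include_pe:
            for blk in q_blocks:
                self.blocks.append(("Q", list(blk), len(self.entries)))
                for a in range(len(blk)):
                    for b in range(a, len(blk)):
                        self.entries.append(("Q", blk[a], blk[b]))
        for blk in r_blocks:
            self.blocks.append(("R", list(blk), len(self.entries)))
            for a in range(len(blk)):
                for b in range(a, len(blk)):
                    self.entries.append(("R", blk[a], blk[b]))
        self.include_pe = include_pe
        self.chol_diag_pos = np.array(
            [k for k, (_, i, j) in enumerate(self.entries) if i == j], dtype=int
        )

    # boundary components pin at a small positive Cholesky diagonal instead
    # of crawling asymptotically towards an exactly singular block
    CHOL_DIAG_FLOOR = 1e-3

    def clamp(self, lvec: np.ndarray) -> np.ndarray:
        out = lvec.copy()
        dp = self.chol_diag_pos
        out[dp] = np.maximum(np.abs(out[dp]), self.CHOL_DIAG_FLOOR)
        return out

    def to_vec(self, S, Q, R) -> np.ndarray:
        src = {"S": S, "Q": Q, "R": R}
        return np.array([src[m][i, j] for m, i, j in self.entries])

    def from_vec(self, vec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        T = self.T
        S = np.zeros((T, T))
        Q = np.zeros((T, T))
        R = np.zeros((T, T))
        dst = {"S": S, "Q": Q, "R": R}
        for v, (m, i, j) in zip(vec, self.entries):
            dst[m][i, j] = v
            dst[m][j, i] = v
        return S, Q, R

    # -- Cholesky parameterisation ------------------------------------------
    def _block_mats(self, S, Q, R):
        src = {"S": S, "Q": Q, "R": R}
        for m, blk, off in self.blocks:
            yield m, blk, off, src[m][np.ix_(blk, blk)]

    def chol_vec(self, S, Q, R) -> np.ndarray:
        out = np.empty(len(self.entries))
        for m, blk, off, B in self._block_mats(S, Q, R):
            k = len(blk)
            ev_min = float(np.min(np.linalg.eigvalsh(B))) if k > 1 else float(B[0, 0])
            jitter = max(0.0, 1e-10 - ev_min)
            L = np.linalg.cholesky(B + jitter * np.eye(k))
            pos = off
            for a in range(k):
                for b in range(a, k):
                    out[pos] = L[b, a]  # sigma entry (a,b) <-> L entry (b,a)
                    pos += 1
        return out

    def from_chol(self, lvec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        T = self.T
        S = np.zeros((T, T))
        Q = np.zeros((T, T))
        R = np.zeros((T, T))
        dst = {"S": S, "Q": Q, "R": R}
        for m, blk, off in self.blocks:
            k = len(blk)
            L = np.zeros((k, k))
            pos = off
            for a in range(k):
                for b in range(a, k):
                    L[b, a] = lvec[pos]
                    pos += 1
            B = L @ L.T
            dst[m][np.ix_(blk, blk)] = B
        return S, Q, R

    def chol_jacobian(self, lvec) -> np.ndarray:
        """d(sigma)/d(l), block diagonal; rows follow ``entries``."""
        p = len(self.entries)
        J = np.zeros((p, p))
        for m, blk, off in self.blocks:
            k = len(blk)
            L = np.zeros((k, k))
            pairs = []
            pos = off
            for a in range(k):
                for b in range(a, k):
                    L[b, a] = lvec[pos]
                    pairs.append((a, b))
                    pos += 1
            # sigma_(a,b) = sum_m L[a,m] L[b,m]; d/dL[c,d] = delta_ac L[b,d] + delta_bc L[a,d]
            for r_loc, (a, b) in enumerate(pairs):
                for c_loc, (d_col, c_row) in enumerate(pairs):
                    # column entry is L[c_row, d_col] with c_row >= d_col
                    val = 0.0
                    if a == c_row:
                        val += L[b, d_col]
                    if b == c_row:
                        val += L[a, d_col]
                    J[off + r_loc, off + c_loc] = val
        return J


def _project_psd(M: np.ndarray, floor: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(M)
    if vals.min() >= floor:
        return M
    vals = np.clip(vals, floor, None)
    return vecs @ np.diag(vals) @ vecs.T


def _project_blocks(S, Q, R, q_blocks, r_blocks, floor, include_pe):
    S = _project_psd(S, floor)
    if include_pe:
        for blk in q_blocks:
            ix = np.ix_(blk, blk)
            Q[ix] = _project_psd(Q[ix], floor)
    for blk in r_blocks:
        ix = np.ix_(blk, blk)
        R[ix] = _project_psd(R[ix], max(floor, 1e-4))
    return S, Q, R


class _RemlWork:
    """Precomputed index structures and per-iteration REML quantities."""

    def __init__(self, design: DesignData, K_sub: np.ndarray, include_pe: bool):
        d = design
        self.d = d
        self.include_pe = include_pe
        self.T = d.n_responses
        n = d.n_records
        self.n = n
        self.A = K_sub[np.ix_(d.animal_codes, d.animal_codes)]
        self.n_animals = len(d.animal_ids)
        self.n_events = int(d.event_codes.max()) + 1
        T = self.T
        self.M = np.zeros((n, T))
        self.M[np.arange(n), d.resp] = 1.0
        # ordered index pairs of records sharing an animal / an event
        self.an_pairs = self._pairs(d.animal_codes)
        self.ev_pairs = self._pairs(d.event_codes)
        self.an_code_rs = d.resp[self.an_pairs[0]] * T + d.resp[self.an_pairs[1]]
        self.ev_code_rs = d.resp[self.ev_pairs[0]] * T + d.resp[self.ev_pairs[1]]
        # animals/events per country block
        self.block_animals = []
        for blk in d.q_blocks:
            in_blk = np.isin(d.resp, blk)
            self.block_animals.append(len(np.unique(d.animal_codes[in_blk])))
        self.block_events = []
        for blk in d.r_blocks:
            in_blk = np.isin(d.resp, blk)
            self.block_events.append(len(np.unique(d.event_codes[in_blk])))

    @staticmethod
    def _pairs(codes: np.ndarray):
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        starts = np.flatnonzero(np.r_[True, np.diff(sorted_codes) != 0])
        bounds = np.r_[starts, len(codes)]
        rr, ss = [], []
        for a, b in zip(bounds[:-1], bounds[1:]):
            grp = order[a:b]
            rr.append(np.repeat(grp, len(grp)))
            ss.append(np.tile(grp, len(grp)))
        return np.concatenate(rr), np.concatenate(ss)

    # -- V assembly ---------------------------------------------------------
    def build_V(self, S, Q, R) -> np.ndarray:
        d = self.d
        V = S[np.ix_(d.resp, d.resp)] * self.A
        pr, ps = self.an_pairs
        if self.include_pe:
            V[pr, ps] += Q.ravel()[self.an_code_rs]
        er, es = self.ev_pairs
        V[er, es] += R.ravel()[self.ev_code_rs]
        return V

    def loglik(self, S, Q, R) -> float:
        V = self.build_V(S, Q, R)
        try:
            c, low = sla.cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf
        X, y = self.d.X, self.d.y
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        ViX = sla.cho_solve((c, low), X, check_finite=False)
        Viy = sla.cho_solve((c, low), y, check_finite=False)
        XtViX = X.T @ ViX
        try:
            cx = sla.cho_factor(XtViX, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf
        logdetX = 2.0 * np.sum(np.log(np.diag(cx[0])))
        beta = sla.cho_solve(cx, X.T @ Viy, check_finite=False)
        yPy = float(y @ Viy - (X.T @ Viy) @ beta)
        return -0.5 * (logdetV + logdetX + yPy)

    def iteration(self, S, Q, R):
        """Log-likelihood, exact score vector, AI matrix and the sufficient
        cross-products for an EM update, all at the current parameters."""
        d = self.d
        T = self.T
        V = self.build_V(S, Q, R)
        c, low = sla.cho_factor(V, lower=True, check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv, info = sla.lapack.dpotri(c, lower=1)
        if info != 0:  # pragma: no cover
            raise np.linalg.LinAlgError("dpotri failed")
        Vinv = np.tril(Vinv) + np.tril(Vinv, -1).T
        X, y = d.X, d.y
        ViX = Vinv @ X
        XtViX = X.T @ ViX
        cx = sla.cho_factor(XtViX, lower=True, check_finite=False)
        logdetX = 2.0 * np.sum(np.log(np.diag(cx[0])))
        XtViy = ViX.T @ y
        beta = sla.cho_solve(cx, XtViy, check_finite=False)
        P = Vinv - ViX @ sla.cho_solve(cx, ViX.T, check_finite=False)
        w = Vinv @ y - ViX @ beta  # = P y
        loglik = -0.5 * (logdetV + logdetX + float(y @ w))

        # trace pieces tr(P dV)
        PA = P * self.A
        S_A = self.M.T @ PA @ self.M
        pr, ps = self.an_pairs
        S_Q = np.bincount(
            self.an_code_rs, weights=P[pr, ps], minlength=T * T
        ).reshape(T, T)
        er, es = self.ev_pairs
        S_R = np.bincount(
            self.ev_code_rs, weights=P[er, es], minlength=T * T
        ).reshape(T, T)

        # quadratic pieces w' dV w and working vectors for the AI matrix
        Gmat = w[:, None] * self.M  # (n, T)
        Hmat = self.A @ Gmat
        q_A = Gmat.T @ Hmat
        Wa = np.zeros((self.n_animals, T))
        np.add.at(Wa, (d.animal_codes, d.resp), w)
        q_Q = Wa.T @ Wa
        We = np.zeros((self.n_events, T))
        np.add.at(We, (d.event_codes, d.resp), w)
        q_R = We.T @ We

        return {
            "loglik": loglik, "P": P, "w": w,
            "S_A": S_A, "S_Q": S_Q, "S_R": S_R,
            "q_A": q_A, "q_Q": q_Q, "q_R": q_R,
            "Hmat": Hmat, "Wa": Wa, "We": We, "beta": beta,
        }

    def score_and_ai(self, pm: _ParamMap, it: dict):
        d = self.d
        T = self.T
        n = self.n
        p = len(pm.entries)
        score = np.zeros(p)
        U = np.zeros((n, p))
        rows = [np.flatnonzero(d.resp == t) for t in range(T)]
        for k, (m, i, j) in enumerate(pm.entries):
            if m == "S":
                tr = it["S_A"][i, j]
                qd = it["q_A"][i, j]
                U[rows[i], k] += it["Hmat"][rows[i], j]
                if i != j:
                    U[rows[j], k] += it["Hmat"][rows[j], i]
            elif m == "Q":
                tr = it["S_Q"][i, j]
                qd = it["q_Q"][i, j]
                U[rows[i], k] += it["Wa"][d.animal_codes[rows[i]], j]
                if i != j:
                    U[rows[j], k] += it["Wa"][d.animal_codes[rows[j]], i]
            else:
                tr = it["S_R"][i, j]
                qd = it["q_R"][i, j]
                U[rows[i], k] += it["We"][d.event_codes[rows[i]], j]
                if i != j:
                    U[rows[j], k] += it["We"][d.event_codes[rows[j]], i]
            mult = 2.0 if i != j else 1.0
            score[k] = -0.5 * mult * (tr - qd)
        PU = it["P"] @ U
        AI = 0.5 * (U.T @ PU)
        return score, AI

    def em_update(self, S, Q, R, it: dict):
        """Closed-form EM-REML update from the iteration cross-products."""
        n_an = self.n_animals
        S_new = S + S @ (it["q_A"] - it["S_A"]) @ S / n_an
        Q_new = None
        if self.include_pe:
            Q_new = np.zeros_like(Q)
            for blk, nb in zip(self.d.q_blocks, self.block_animals):
                ix = np.ix_(blk, blk)
                Qb = Q[ix]
                Q_new[ix] = Qb + Qb @ (it["q_Q"][ix] - it["S_Q"][ix]) @ Qb / nb
        R_new = np.zeros_like(R)
        for blk, ne in zip(self.d.r_blocks, self.block_events):
            ix = np.ix_(blk, blk)
            Rb = R[ix]
            R_new[ix] = Rb + Rb @ (it["q_R"][ix] - it["S_R"][ix]) @ Rb / ne
        return S_new, Q_new, R_new


def reml_estimate(
    design: DesignData,
    K: RelationshipMatrix,
    method: str = "ai",
    init=None,
    tol: float = 1e-8,
    max_iter: int = 500,
    include_pe: bool = True,
    verbose: bool = False,
) -> VarianceComponents:
    """REML variance components for a multi-trait repeatability model.

    ``method='ai'`` takes average-information Newton steps with
    step-halving and PSD projection, falling back to an EM step whenever
    the AI proposal fails to improve the restricted likelihood;
    ``method='em'`` iterates the closed-form EM update (monotone in the
    likelihood, slower near the optimum).  Standard errors come from the
    inverse AI matrix at convergence.

    ``K`` must cover every recorded animal; it is the additive relationship
    source (pedigree ``A`` or single-step ``H``).
    """
    if method not in ("ai", "em"):
        raise ValueError("method must be 'ai' or 'em'")
    d = design
    T = d.n_responses
    # standardise per response; refit scale restored on output
    sd = np.ones(T)
    for t in range(T):
        m = d.resp == t
        if m.sum() > 1:
            sd[t] = max(np.std(d.y[m]), 1e-8)
    y_std = d.y / sd[d.resp]
    X = d.X
    d_std = DesignData(
        y=y_std, resp=d.resp, animal_codes=d.animal_codes, animal_ids=d.animal_ids,
        event_codes=d.event_codes, X=X, fixed_labels=d.fixed_labels,
        resp_labels=d.resp_labels, q_blocks=d.q_blocks, r_blocks=d.r_blocks,
    )
    K_sub = K.submatrix(d.animal_ids)
    work = _RemlWork(d_std, K_sub, include_pe)
    pm = _ParamMap(T, d.q_blocks, d.r_blocks, include_pe)

    if init is None:
        S0 = 0.30 * (np.full((T, T), 0.3) + 0.7 * np.eye(T))
        Q0 = np.zeros((T, T))
        R0 = np.zeros((T, T))
        for blk in d.q_blocks:
            ix = np.ix_(blk, blk)
            k = len(blk)
            Q0[ix] = 0.10 * (np.full((k, k), 0.2) + 0.8 * np.eye(k))
        for blk in d.r_blocks:
            ix = np.ix_(blk, blk)
            k = len(blk)
            R0[ix] = 0.60 * (np.full((k, k), 0.2) + 0.8 * np.eye(k))
        S, Q, R = S0, Q0, R0
    else:
        S, Q, R = (np.array(m, dtype=float) for m in init)
        # move to standardised scale
        D = np.outer(sd, sd)
        S, Q, R = S / D, Q / D, R / D
    floor = 1e-6

    it = work.iteration(S, Q, R)
    loglik = it["loglik"]
    path = [loglik]
    converged = False
    n_iter = 0
    lam = 1e-8
    for n_iter in range(1, max_iter + 1):
        vec = pm.to_vec(S, Q, R)
        if method == "em":
            S_new, Q_new, R_new = work.em_update(S, Q, R, it)
            if not include_pe:
                Q_new = Q
            S_new, Q_new, R_new = _project_blocks(
                S_new, Q_new, R_new, d.q_blocks, d.r_blocks, floor, include_pe
            )
        else:
            score, AI = work.score_and_ai(pm, it)
            lvec = pm.chol_vec(S, Q, R)
            J = pm.chol_jacobian(lvec)
            score_l = J.T @ score
            AI_l = J.T @ AI @ J
            scale_l = max(np.trace(AI_l) / len(AI_l), 1.0)
            # Levenberg-Marquardt damping: boundary estimates make the
            # transformed AI singular; raise the damping until the proposed
            # step improves the restricted likelihood.
            S_new = Q_new = R_new = None
            best_ll = -np.inf
            for _ in range(10):
                try:
                    delta_l = np.linalg.solve(
                        AI_l + lam * scale_l * np.eye(len(AI_l)), score_l
                    )
                except np.linalg.LinAlgError:
                    delta_l = score_l / (lam * scale_l)
                Sc, Qc, Rc = pm.from_chol(pm.clamp(lvec + delta_l))
                if not include_pe:
                    Qc = Q
                ll = work.loglik(Sc, Qc, Rc)
                if ll >= loglik - 1e-9:
                    S_new, Q_new, R_new = Sc, Qc, Rc
                    best_ll = ll
                    lam = max(lam / 10.0, 1e-10)
                    break
                lam *= 10.0
            if S_new is None:
                # EM fallback step: cannot decrease the restricted likelihood
                S_new, Q_new, R_new = work.em_update(S, Q, R, it)
                if not include_pe:
                    Q_new = Q
                S_new, Q_new, R_new = _project_blocks(
                    S_new, Q_new, R_new, d.q_blocks, d.r_blocks, floor, include_pe
                )
        new_vec = pm.to_vec(S_new, Q_new, R_new)
        rel_change = np.max(np.abs(new_vec - vec) / (np.abs(vec) + 0.1))
        S, Q, R = S_new, Q_new, R_new
        it = work.iteration(S, Q, R)
        new_ll = it["loglik"]
        if verbose:  # pragma: no cover
            print(f"iter {n_iter}: logL={new_ll:.6f} max-change={rel_change:.2e}")
        dll = new_ll - loglik
        loglik = new_ll
        path.append(loglik)
        if rel_change < tol or (n_iter > 3 and abs(dll) < 1e-8):
            converged = True
            break
    if not converged:
        warnings.warn(f"REML did not converge in {max_iter} iterations")
    if np.any(np.diag(S) <= 2 * floor):
        warnings.warn("an additive variance was pinned at the small positive floor")

    # standard errors from the AI matrix at the optimum
    score, AI = work.score_and_ai(pm, it)
    try:
        ai_inv = np.linalg.inv(AI)
    except np.linalg.LinAlgError:  # pragma: no cover
        ai_inv = np.full((len(pm.entries), len(pm.entries)), np.nan)
    # back to original scale
    scale = np.array([sd[i] * sd[j] for _, i, j in pm.entries])
    param_cov = ai_inv * np.outer(scale, scale)
    D = np.outer(sd, sd)
    S_out, Q_out, R_out = S * D, Q * D, R * D
    se = {m: np.zeros((T, T)) for m in ("S", "Q", "R")}
    for k, (m, i, j) in enumerate(pm.entries):
        s = np.sqrt(max(param_cov[k, k], 0.0))
        se[m][i, j] = se[m][j, i] = s
    return VarianceComponents(
        Sigma=S_out, Q=Q_out if include_pe else None, R=R_out,
        se_Sigma=se["S"], se_Q=se["Q"] if include_pe else None, se_R=se["R"],
        resp_labels=d.resp_labels, q_blocks=d.q_blocks, r_blocks=d.r_blocks,
        converged=converged, n_iter=n_iter, loglik=loglik, loglik_path=path,
        param_index=list(pm.entries), param_cov=param_cov, method=method,
    )


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------

@dataclass
class MMESolution:
    """Solutions of the mixed-model equations.

    ``ebv`` is animals x responses over every animal of the relationship
    matrix (genetic effects are predicted for non-recorded relatives too).
    When solved directly, the sparse factorisation is retained so that
    prediction error (co)variances can be extracted column by column.
    """

    beta: np.ndarray
    fixed_labels: list
    ebv: pd.DataFrame
    pe: pd.DataFrame | None
    resp_labels: list
    animal_offset: int
    n_rel: int
    C: sp.spmatrix | None = None
    _lu: object | None = None

    @property
    def labels(self) -> list[str]:
        return [_label(lab) for lab in self.resp_labels]

    def _col(self, animal, resp_idx) -> int:
        k = self.ebv.index.get_loc(str(animal))
        return self.animal_offset + resp_idx * self.n_rel + k

    def pev(self, animals: Sequence, resp_idx: int) -> np.ndarray:
        """Prediction error variances of the additive effects of
        ``animals`` for one response (direct solver only)."""
        if self._lu is None:
            raise ValueError("PEV requires the direct solver")
        out = np.empty(len(animals))
        ncol = self.C.shape[0]
        for k, a in enumerate(animals):
            col = self._col(a, resp_idx)
            e = np.zeros(ncol)
            e[col] = 1.0
            out[k] = self._lu.solve(e)[col]
        return out

    def pev_block(self, animals: Sequence, resp_idx: int) -> np.ndarray:
        """Dense PEV covariance block for ``animals`` at one response."""
        if self._lu is None:
            raise ValueError("PEV requires the direct solver")
        cols = [self._col(a, resp_idx) for a in animals]
        ncol = self.C.shape[0]
        E = np.zeros((ncol, len(cols)))
        for k, c in enumerate(cols):
            E[c, k] = 1.0
        sol = self._lu.solve(E)
        return sol[cols, :]


def solve_mme(
    design: DesignData,
    K_inv: RelationshipMatrix,
    components: VarianceComponents,
    method: str = "direct",
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> MMESolution:
    """Solve Henderson's mixed-model equations.

    ``K_inv`` is the inverse relationship over *all* animals to evaluate
    (``A^-1`` or ``H^-1``); every recorded animal must be present.  The
    coefficient matrix is ``[X Z W]' R^-1 [X Z W]`` plus
    ``Sigma^-1 (x) K^-1`` on the additive block and ``Q_b^-1 (x) I`` on
    each permanent-environment block.  ``method='pcg'`` uses conjugate
    gradients with a Jacobi preconditioner and relative-residual stop
    ``tol``; the direct solver keeps its factorisation for PEV queries.
    """
    d = design
    T = d.n_responses
    rel_ids = K_inv.ids
    n_rel = len(rel_ids)
    rec_pos = K_inv.index_of(d.animal_ids)  # raises if missing
    n = d.n_records
    p_fix = d.X.shape[1]

    Sigma = components.Sigma
    Sigma_inv = np.linalg.inv(Sigma)
    Kmat = K_inv.matrix if sp.issparse(K_inv.matrix) else sp.csr_matrix(K_inv.matrix)
    Ga_inv = sp.kron(sp.csr_matrix(Sigma_inv), Kmat, format="csr")

    # permanent environment columns per country block
    use_pe = components.Q is not None and not np.allclose(components.Q, 0)
    pe_cols: dict = {}
    pe_prec_blocks = []
    pe_labels = []
    offset = 0
    if use_pe:
        for blk in d.q_blocks:
            in_blk = np.isin(d.resp, blk)
            animals_b = np.unique(d.animal_codes[in_blk])
            amap = {a: k for k, a in enumerate(animals_b)}
            nb = len(animals_b)
            Qb = components.Q[np.ix_(blk, blk)]
            Qb_inv = np.linalg.inv(Qb)
            pe_prec_blocks.append(sp.kron(sp.csr_matrix(Qb_inv), sp.eye(nb), format="csr"))
            for r in blk:
                for a in animals_b:
                    pe_labels.append((r, d.animal_ids[a]))
            pe_cols[tuple(blk)] = (offset, amap, nb)
            offset += len(blk) * nb
    n_pe = offset

    # R^-1 as a sparse block-diagonal over events
    er, es = _RemlWork._pairs(d.event_codes)
    rinv_vals = np.empty(len(er))
    # group events and invert per observed pattern
    order = np.argsort(d.event_codes, kind="stable")
    codes_sorted = d.event_codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(codes_sorted) != 0])
    bounds = np.r_[starts, n]
    pat_cache: dict = {}
    rows_l, cols_l, vals_l = [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        grp = order[a:b]
        pat = tuple(d.resp[grp])
        inv = pat_cache.get(pat)
        if inv is None:
            Rb = components.R[np.ix_(list(pat), list(pat))]
            inv = np.linalg.inv(Rb)
            pat_cache[pat] = inv
        k = len(grp)
        rows_l.append(np.repeat(grp, k))
        cols_l.append(np.tile(grp, k))
        vals_l.append(inv.ravel())
    R_inv = sp.coo_matrix(
        (np.concatenate(vals_l), (np.concatenate(rows_l), np.concatenate(cols_l))),
        shape=(n, n),
    ).tocsr()

    # incidence [X | Za | Wpe]
    rows = np.arange(n)
    Za = sp.coo_matrix(
        (np.ones(n), (rows, d.resp * n_rel + rec_pos[d.animal_codes])),
        shape=(n, T * n_rel),
    )
    mats = [sp.csr_matrix(d.X), Za.tocsr()]
    if use_pe and n_pe:
        pe_r, pe_c = [], []
        for blk in d.q_blocks:
            off, amap, nb = pe_cols[tuple(blk)]
            in_blk = np.flatnonzero(np.isin(d.resp, blk))
            local_r = {r: k for k, r in enumerate(blk)}
            for rec in in_blk:
                pe_r.append(rec)
                pe_c.append(
                    p_fix * 0 + off + local_r[d.resp[rec]] * nb + amap[d.animal_codes[rec]]
                )
        Wpe = sp.coo_matrix(
            (np.ones(len(pe_r)), (pe_r, pe_c)), shape=(n, n_pe)
        ).tocsr()
        mats.append(Wpe)
    D = sp.hstack(mats, format="csr")
    C = (D.T @ R_inv @ D).tolil()
    a0 = p_fix
    C[a0 : a0 + T * n_rel, a0 : a0 + T * n_rel] = (
        C[a0 : a0 + T * n_rel, a0 : a0 + T * n_rel] + Ga_inv
    )
    if use_pe and n_pe:
        q0 = a0 + T * n_rel
        off = 0
        for blk_mat in pe_prec_blocks:
            k = blk_mat.shape[0]
            C[q0 + off : q0 + off + k, q0 + off : q0 + off + k] = (
                C[q0 + off : q0 + off + k, q0 + off : q0 + off + k] + blk_mat
            )
            off += k
    C = C.tocsc()
    rhs = D.T @ (R_inv @ d.y)

    lu = None
    if method == "direct":
        lu = spla.splu(C)
        theta = lu.solve(rhs)
    elif method == "pcg":
        dg = C.diagonal()
        dg[dg == 0] = 1.0
        M = spla.LinearOperator(C.shape, matvec=lambda v: v / dg)
        theta, info = spla.cg(C, rhs, rtol=tol, maxiter=max_iter, M=M)
        if info != 0:
            raise RuntimeError(f"PCG did not converge (info={info})")
    else:
        raise ValueError("method must be 'direct' or 'pcg'")

    beta = theta[:p_fix]
    a_hat = theta[a0 : a0 + T * n_rel].reshape(T, n_rel).T
    ebv = pd.DataFrame(
        a_hat, index=[str(x) for x in rel_ids],
        columns=[_label(lab) for lab in d.resp_labels],
    )
    pe_df = None
    if use_pe and n_pe:
        q0 = a0 + T * n_rel
        pe_df = pd.DataFrame(
            {"resp": [r for r, _ in pe_labels],
             "animal": [a for _, a in pe_labels],
             "solution": theta[q0 : q0 + n_pe]}
        )
    return MMESolution(
        beta=beta, fixed_labels=d.fixed_labels, ebv=ebv, pe=pe_df,
        resp_labels=d.resp_labels, animal_offset=a0, n_rel=n_rel,
        C=C, _lu=lu,
    )


# ---------------------------------------------------------------------------
# derived genetic parameters
# ---------------------------------------------------------------------------

@dataclass
class DerivedParameters:
    h2: dict
    rep: dict
    rg: dict
    se_h2: dict
    se_rep: dict
    se_rg: dict

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for lab in self.h2:
            rows.append(
                (lab, self.h2[lab], self.se_h2.get(lab, np.nan),
                 self.rep.get(lab, np.nan), self.se_rep.get(lab, np.nan))
            )
        return pd.DataFrame(rows, columns=["response", "h2", "se_h2", "rep", "se_rep"])


def derive_parameters(components: VarianceComponents) -> DerivedParameters:
    """Heritability, repeatability and genetic correlations with
    delta-method standard errors from the AI covariance of the estimates.

    h2 = sa^2 / (sa^2 + spe^2 + se^2); rep = (sa^2 + spe^2) / total;
    r_g(i,j) = sa(ij) / sqrt(sa^2(i) sa^2(j)).
    """
    T = components.Sigma.shape[0]
    labels = components.labels
    Q = components.Q if components.Q is not None else np.zeros((T, T))

    def derived_vec(pvec):
        Smat = np.zeros((T, T))
        Qmat = np.zeros((T, T))
        Rmat = np.zeros((T, T))
        dst = {"S": Smat, "Q": Qmat, "R": Rmat}
        for v, (m, i, j) in zip(pvec, components.param_index):
            dst[m][i, j] = v
            dst[m][j, i] = v
        tot = np.diag(Smat) + np.diag(Qmat) + np.diag(Rmat)
        if np.any(tot <= 0):
            raise ValueError("zero total variance")
        out = list(np.diag(Smat) / tot)
        out += list((np.diag(Smat) + np.diag(Qmat)) / tot)
        d = np.sqrt(np.clip(np.diag(Smat), 1e-12, None))
        for i in range(T):
            for j in range(i + 1, T):
                out.append(Smat[i, j] / (d[i] * d[j]))
        return np.array(out)

    pvec = np.array(
        [
            {"S": components.Sigma, "Q": Q, "R": components.R}[m][i, j]
            for m, i, j in components.param_index
        ]
    )
    vals = derived_vec(pvec)
    # numeric delta method
    se_vals = np.full(len(vals), np.nan)
    if components.param_cov is not None and np.all(np.isfinite(components.param_cov)):
        J = np.zeros((len(vals), len(pvec)))
        for k in range(len(pvec)):
            h = 1e-6 * max(abs(pvec[k]), 1e-3)
            up, dn = pvec.copy(), pvec.copy()
            up[k] += h
            dn[k] -= h
            J[:, k] = (derived_vec(up) - derived_vec(dn)) / (2 * h)
        cov = J @ components.param_cov @ J.T
        se_vals = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    h2 = dict(zip(labels, vals[:T]))
    rep = dict(zip(labels, vals[T : 2 * T]))
    se_h2 = dict(zip(labels, se_vals[:T]))
    se_rep = dict(zip(labels, se_vals[T : 2 * T]))
    rg, se_rg = {}, {}
    k = 2 * T
    for i in range(T):
        for j in range(i + 1, T):
            rg[(labels[i], labels[j])] = vals[k]
            se_rg[(labels[i], labels[j])] = se_vals[k]
            k += 1
    return DerivedParameters(h2=h2, rep=rep, rg=rg, se_h2=se_h2, se_rep=se_rep, se_rg=se_rg)
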