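"""Scenario orchestration: simulate -> QC -> relationships -> REML ->
solve -> validate (-> GWAS), with every artifact stamped by config hash
and seed.

The run configuration is a flat mapping (YAML on disk) naming a generator
preset, a model scenario and the knobs that matter: relationship source,
blending weights, APY core size, REML settings, validation years and the
global seed.  Everything downstream consumes explicit sub-seeds derived
from the global one.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genomics, io as hio, models, simulate as sim_mod, validation
from .pedigree import build_A, build_A_inverse, build_A22_inverse

__all__ = ["RunConfig", "run_scenario", "relationship_matrices"]


@dataclass
class RunConfig:
    preset: str = "paper-wc-us"
    scenario: str = "WC-TT"
    trait: str | None = None
    ac_eset: str | None = None  # AC training country; targets = the rest
    relationship: str = "pedigree"  # or "ssgblup"
    alpha: float = 0.90
    beta: float = 0.10
    apy_n_core: int | None = None
    reml_method: str = "ai"
    reml_tol: float = 1e-8
    reml_max_iter: int = 500
    target_years: dict | None = None
    continuous: bool = False
    run_gwas: bool = False
    seed: int = 1
    outdir: str = "hoofgen-run"
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def relationship_matrices(sim, spec: models.ModelSpec, cfg: RunConfig):
    """The dense relationship for REML and its sparse inverse for the MME.

    Pedigree source: tabular A and Henderson's A^-1.  ssGBLUP: G (VanRaden
    method 1) on the QC'd genotyped subset, blended alpha*G + beta*A22,
    H dense for REML and sparse H^-1 (APY inverse of G_b when
    ``apy_n_core`` is set) for the MME.
    """
    ped = sim.pedigree
    A = build_A(ped)
    A_inv = build_A_inverse(ped)
    if spec.relationship == "pedigree":
        return A, A_inv
    if sim.genotypes is None or sim.genotyped_ids is None:
        raise ValueError("ssGBLUP requested but the dataset has no genotypes")
    geno = sim.genotypes.select_samples(sim.genotyped_ids)
    geno, _ = genomics.qc_genotypes(geno)
    G = genomics.build_G(geno)
    from .pedigree import RelationshipMatrix

    A22 = RelationshipMatrix(A.submatrix(geno.sample_ids), geno.sample_ids, "A22")
    Gb = genomics.blend_G(G, A22, cfg.alpha, cfg.beta)
    H = genomics.build_H(A, Gb)
    A22_inv = build_A22_inverse(ped, geno.sample_ids)
    if cfg.apy_n_core is not None:
        Gb_inv = genomics.apy_inverse(Gb, n_core=cfg.apy_n_core, seed=cfg.seed)
    else:
        Gb_inv = RelationshipMatrix(
            np.linalg.inv(Gb.dense()), Gb.ids, "G_blended_inverse"
        )
    H_inv = genomics.build_H_inverse(A_inv, A22_inv, Gb_inv)
    return H, H_inv


def run_scenario(cfg: RunConfig) -> dict:
    """Execute one scenario end to end and write artifacts to ``outdir``.

    Returns a summary dict (also written as run_log.json).  Any stage
    failure raises with the stage name prefixed.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    t0 = time.time()

    def stage(name):
        def deco(fn):
            try:
                t = time.time()
                res = fn()
                log["stages"][name] = round(time.time() - t, 3)
                return res
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return deco

    overrides = dict(cfg.overrides)
    if cfg.continuous:
        overrides["score_thresholds"] = None
    sim_cfg = sim_mod.preset(cfg.preset, seed=cfg.seed, **overrides)

    sim = stage("simulate")(lambda: sim_mod.simulate(sim_cfg))
    hio.write_pedigree_csv(sim.pedigree, out / "pedigree.csv")

    def _filter():
        phen = sim.phenotypes
        if not cfg.continuous:
            phen, rep1 = hio.filter_phenotypes(phen)
            phen, rep2 = hio.filter_contemporary_groups(phen)
            log["filter_reports"] = {"phenotype": rep1, "contemporary_group": rep2}
        return phen

    phen = stage("qc")(_filter)
    hio.write_phenotypes_csv(phen, out / "phenotypes.csv")

    countries = tuple(sim_cfg.countries) if cfg.scenario.startswith(("MC", "JC", "AC")) \
        else (sim_cfg.countries[0],)
    spec = models.ModelSpec(
        scenario=cfg.scenario, trait=cfg.trait, countries=countries,
        relationship=cfg.relationship,
    )
    design = stage("design")(lambda: models.build_design(phen, spec))
    K, K_inv = stage("relationships")(lambda: relationship_matrices(sim, spec, cfg))
    components = stage("reml")(
        lambda: models.reml_estimate(
            design, K, method=cfg.reml_method, tol=cfg.reml_tol,
            max_iter=cfg.reml_max_iter,
        )
    )
    derived = models.derive_parameters(components)
    derived.as_frame().to_csv(out / "genetic_parameters.tsv", sep="\t", index=False)

    solution = stage("solve")(lambda: models.solve_mme(design, K_inv, components))
    sol_out = solution.ebv.copy()
    sol_out.index.name = "animal"
    sol_out.to_csv(out / "solutions.tsv", sep="\t")

    def _validate():
        years = cfg.target_years
        if years is None:
            last = int(sim.pedigree.birth_year.max())
            years = {c: [last] for c in sim_cfg.countries}
        genotyped = (
            sim.genotyped_ids if sim.genotyped_ids is not None
            else phen["animal"].unique()
        )
        split = validation.make_forward_split(phen, genotyped, years)
        partial = split.partial
        if cfg.scenario == "AC":
            if cfg.ac_eset is None:
                raise ValueError("AC scenario needs ac_eset (the training country)")
            # across-country: the training set holds only the estimation
            # country's phenotypes; every other country is target-only
            partial = partial[partial["country"] == cfg.ac_eset].reset_index(drop=True)
        part_design = models.build_design(partial, spec)
        part_sol = models.solve_mme(part_design, K_inv, components)
        from .pedigree import compute_inbreeding

        Fall = compute_inbreeding(sim.pedigree)
        target_ids = split.target_ids
        if cfg.scenario == "AC":
            country_of = dict(zip(sim.pedigree.ids, sim.pedigree.country))
            target_ids = np.asarray(
                [a for a in target_ids if country_of[str(a)] != cfg.ac_eset],
                dtype=object,
            )
            if len(target_ids) == 0:
                raise ValueError("AC scenario found no target animals outside the Eset")
        split = validation.ValidationSplit(
            target_ids=target_ids, whole=split.whole, partial=partial,
            counts=split.counts,
        ) if cfg.scenario == "AC" else split
        tpos = sim.pedigree.index_of(split.target_ids)
        rows = []
        for r, lab in enumerate(design.labels):
            sigma_u2 = components.Sigma[r, r]
            res = validation.lr_metrics(
                part_sol.ebv[lab].reindex([str(a) for a in split.target_ids]),
                solution.ebv[lab].reindex([str(a) for a in split.target_ids]),
                F_bar=float(Fall[tpos].mean()),
                sigma_u2=sigma_u2,
            )
            rows.append((cfg.scenario, lab, res.n_target, res.bias,
                         res.dispersion, res.accuracy))
        return pd.DataFrame(
            rows, columns=["scenario", "response", "n_target", "bias",
                           "dispersion", "accuracy"],
        )

    lr = stage("validate")(_validate)
    lr.to_csv(out / "lr_report.tsv", sep="\t", index=False)
    log["lr"] = lr.to_dict(orient="records")
    log["components"] = {
        "Sigma": components.Sigma.tolist(),
        "Q": None if components.Q is None else components.Q.tolist(),
        "R": components.R.tolist(),
        "converged": components.converged,
        "n_iter": components.n_iter,
    }
    log["derived"] = {
        "h2": derived.h2, "rep": derived.rep,
        "rg": {f"{a}~{b}": v for (a, b), v in derived.rg.items()},
    }
    log["runtime_s"] = round(time.time() - t0, 3)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=float)
    return log
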