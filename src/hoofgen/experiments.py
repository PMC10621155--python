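"""Reproduction workflows: parameter-recovery and population-structure
experiments on the named presets.

Each function simulates data under a preset's study conditions (continuous
records, since the recovery contracts are on the latent scale), fits the
matching model, and returns the derived quantities.  These workflows back
the package's reproduction script and acceptance suite; sizes default to
desk scale and are overridable.
"""

from __future__ import annotations

import numpy as np

from . import validation
from .genomics import (
    blend_G,
    build_G,
    build_H,
    ld_statistics,
    phase_consistency,
    qc_genotypes,
)
from .models import (
    ModelSpec,
    build_design,
    derive_parameters,
    reml_estimate,
    solve_mme,
)
from .pedigree import RelationshipMatrix, build_A, build_A_inverse
from .simulate import preset, simulate

__all__ = [
    "fit_preset",
    "recovery_experiment",
    "phase_consistency_at",
    "sire_correlation_mc_vs_jc",
    "lr_forward_comparison",
]

SCENARIO_FOR_PRESET = {
    "paper-wc-us": "WC-TT",
    "paper-wc-au": "WC-TT",
    "paper-mc": "MC-TT",
    "paper-mc-genomic": "MC-ST",
    "paper-jc": "JC-ST",
}


def _model_spec(preset_name: str, cfg, scenario: str | None, trait: str | None):
    scenario = scenario or SCENARIO_FOR_PRESET[preset_name]
    countries = tuple(cfg.countries) if scenario[0] in ("M", "J", "A") else (
        cfg.countries[0],
    )
    relationship = "ssgblup" if preset_name == "paper-mc-genomic" else "pedigree"
    return ModelSpec(
        scenario=scenario, trait=trait, countries=countries,
        relationship=relationship,
    )


def _relationship_for_reml(sim, spec, alpha=0.90, beta=0.10):
    A = build_A(sim.pedigree)
    if spec.relationship == "pedigree":
        return A
    geno = sim.genotypes.select_samples(sim.genotyped_ids)
    geno, _ = qc_genotypes(geno)
    G = build_G(geno)
    A22 = RelationshipMatrix(A.submatrix(geno.sample_ids), geno.sample_ids, "A22")
    Gb = blend_G(G, A22, alpha, beta)
    return build_H(A, Gb)


def fit_preset(
    preset_name: str,
    seed: int,
    scenario: str | None = None,
    trait: str | None = None,
    sizes: dict | None = None,
    tol: float = 1e-4,
    max_iter: int = 40,
):
    """Simulate one replicate of a preset and fit the matching model.

    Returns (derived_parameters, components, sim).
    """
    overrides = dict(sizes or {})
    overrides["score_thresholds"] = None
    cfg = preset(preset_name, seed=seed, **overrides)
    sim = simulate(cfg)
    spec = _model_spec(preset_name, cfg, scenario, trait)
    design = build_design(sim.phenotypes, spec)
    K = _relationship_for_reml(sim, spec)
    comps = reml_estimate(design, K, tol=tol, max_iter=max_iter)
    return derive_parameters(comps), comps, sim


def recovery_experiment(
    preset_name: str,
    quantities: list,
    seeds,
    scenario: str | None = None,
    trait: str | None = None,
    sizes: dict | None = None,
    tol: float = 1e-4,
    max_iter: int = 40,
) -> dict:
    """Replicate a preset over seeds and summarise derived quantities.

    ``quantities`` are ("h2", label), ("rep", label) or ("rg", (l1, l2))
    pairs.  Returns {quantity: {"mean", "sd", "se", "values", "n"}}.
    """
    values = {q: [] for q in quantities}
    for seed in seeds:
        der, _, _ = fit_preset(
            preset_name, seed, scenario=scenario, trait=trait, sizes=sizes,
            tol=tol, max_iter=max_iter,
        )
        for q in quantities:
            kind, key = q
            store = getattr(der, kind)
            if kind == "rg" and key not in store:
                key = (key[1], key[0])
            values[q].append(float(store[key]))
    out = {}
    for q, v in values.items():
        v = np.asarray(v)
        out[q] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
            "se": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan"),
            "values": v.tolist(),
            "n": len(v),
        }
    return out


def phase_consistency_at(
    seed: int, distance_bp: int = 5_000_000, sizes: dict | None = None
) -> float:
    """Signed-LD consistency between the two popstruct populations at the
    bin containing ``distance_bp``."""
    cfg = preset("paper-popstruct", seed=seed, **(sizes or {}))
    sim = simulate(cfg)
    geno = sim.genotypes.select_samples(sim.genotyped_ids)
    max_d = distance_bp + 2_000_000
    lds = {}
    for c in cfg.countries:
        sub = geno.subset(sample_idx=np.flatnonzero(geno.country == c))
        lds[c] = ld_statistics(sub, max_distance_bp=max_d)
    pc = phase_consistency(lds[cfg.countries[0]], lds[cfg.countries[1]])
    row = pc[pc.bin_start == (distance_bp // 100_000) * 100_000]
    return float(row["consistency"].iloc[0])


def _true_components(cfg, spec, design):
    """Assumed (true-by-construction) covariance matrices on the model's
    response scale.

    Country-specific model responses map directly onto the config's
    responses; country-pooled responses (WC with one country, or JC) take
    the within-country entries of the config truth, averaged over the
    analysed countries when the truth is country-specific.
    """
    from .models import VarianceComponents

    labels = spec.response_labels
    T = len(labels)
    cfg_idx = {lab: k for k, lab in enumerate(cfg.response_labels)}

    def entry(M, li, lj):
        ti, ci = labels[li]
        tj, cj = labels[lj]
        if cfg.n_responses == 2:
            i = 0 if ti == "FA" else 1
            j = 0 if tj == "FA" else 1
            return M[i, j]
        if ci is not None and cj is not None:
            return M[cfg_idx[(ti, ci)], cfg_idx[(tj, cj)]]
        # pooled responses: average the within-country entries
        vals = [
            M[cfg_idx[(ti, c)], cfg_idx[(tj, c)]] for c in spec.countries
        ]
        return float(np.mean(vals))

    def reduce(M):
        out = np.zeros((T, T))
        for i in range(T):
            for j in range(T):
                out[i, j] = entry(M, i, j)
        return out

    return VarianceComponents(
        Sigma=reduce(cfg.Sigma_a), Q=reduce(cfg.Q_pe), R=reduce(cfg.R_e),
        resp_labels=labels, q_blocks=design.q_blocks, r_blocks=design.r_blocks,
        param_index=[("S", i, j) for i in range(T) for j in range(i, T)],
    )


def _solve_scenario(sim, spec, phenotypes=None, components=None):
    ph = sim.phenotypes if phenotypes is None else phenotypes
    design = build_design(ph, spec)
    if components is None:
        components = _true_components(sim.config, spec, design)
    A_inv = build_A_inverse(sim.pedigree)
    sol = solve_mme(design, A_inv, components)
    return sol, design, components


def sire_correlation_mc_vs_jc(seed: int, sizes: dict | None = None,
                              min_progeny: int = 50):
    """Spearman correlation of proven-sire EBVs (foot angle) between the
    multi-country and joint-country single-trait models on one paper-mc
    replicate, using the preset's true variance components for both solves.
    """
    overrides = dict(sizes or {})
    overrides.setdefault("progeny_per_sire", 80)
    overrides.setdefault("animals_per_generation_per_country", 550)
    overrides.setdefault("n_shared_sires", 4)
    overrides["score_thresholds"] = None
    cfg = preset("paper-mc", seed=seed, **overrides)
    sim = simulate(cfg)
    mc_spec = ModelSpec(scenario="MC-ST", trait="FA", countries=tuple(cfg.countries))
    jc_spec = ModelSpec(scenario="JC-ST", trait="FA", countries=tuple(cfg.countries))
    sol_mc, _, _ = _solve_scenario(sim, mc_spec)
    sol_jc, _, _ = _solve_scenario(sim, jc_spec)
    ped = sim.pedigree
    # MC: take each sire's own-country trait EBV
    country_of = {str(ped.ids[i]): str(ped.country[i]) for i in range(ped.n)}
    import pandas as pd

    mc_ebv = pd.Series(
        {
            a: sol_mc.ebv.loc[a, f"FA_{country_of[a]}"]
            for a in sol_mc.ebv.index
            if f"FA_{country_of[a]}" in sol_mc.ebv.columns
        }
    )
    jc_ebv = sol_jc.ebv["FA"]
    pear, spear, sires = validation.sire_correlations(
        {"MC-ST": mc_ebv, "JC-ST": jc_ebv}, ped, sim.phenotypes,
        min_progeny=min_progeny,
    )
    return float(spear.loc["MC-ST", "JC-ST"]), len(sires)


def lr_forward_comparison(seeds, sizes: dict | None = None) -> dict:
    """Forward LR validation: within-country vs joint evaluations.

    For each seed, simulates a paper-mc replicate, runs whole/partial
    solves (true components) for WC-TT (US data only) and JC-TT (both
    countries), and records the LR accuracy of the US target group under
    each.  Returns per-seed accuracies and the count of seeds where the
    joint evaluation is at least as accurate.
    """
    from .pedigree import compute_inbreeding

    overrides = dict(sizes or {})
    overrides.setdefault("animals_per_generation_per_country", 250)
    overrides.setdefault("n_founders", 150)
    overrides["score_thresholds"] = None
    rows = []
    for seed in seeds:
        cfg = preset("paper-mc", seed=seed, **overrides)
        sim = simulate(cfg)
        ped = sim.pedigree
        last = int(ped.birth_year.max())
        ph = sim.phenotypes
        genotyped = ph["animal"].unique()  # all phenotyped eligible as targets
        split = validation.make_forward_split(ph, genotyped, {"US": [last]})
        F = compute_inbreeding(ped)
        tpos = ped.index_of(split.target_ids)
        F_bar = float(F[tpos].mean())
        accs = {}
        for name, spec in (
            ("WC", ModelSpec(scenario="WC-TT", countries=("US",))),
            ("JC", ModelSpec(scenario="JC-TT", countries=tuple(cfg.countries))),
        ):
            whole_sol, design, comps = _solve_scenario(sim, spec)
            part_sol, _, _ = _solve_scenario(sim, spec, phenotypes=split.partial,
                                             components=comps)
            lab = "FA"
            idx = [str(a) for a in split.target_ids]
            sigma_u2 = comps.Sigma[0, 0]
            res = validation.lr_metrics(
                part_sol.ebv[lab].reindex(idx), whole_sol.ebv[lab].reindex(idx),
                F_bar=F_bar, sigma_u2=sigma_u2,
            )
            accs[name] = res.accuracy
        rows.append(accs)
    joint_wins = sum(r["JC"] >= r["WC"] - 1e-9 for r in rows)
    return {"per_seed": rows, "joint_at_least_wc": joint_wins, "n": len(rows)}
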