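"""End-to-end orchestration of the temperature-sensitive CI pipeline.

Stages run in method order: simulate -> hatch model (filter, ZIB-GLMM fit,
odds-ratio contrasts, type-II Wald tests) -> density/expression linear
models -> development-time resampling -> within-strain concordance ->
phylogenetic regression.  Every stage reads and writes only its documented
files inside the output directory, so the pipeline is restartable stage by
stage, and a machine-readable JSON summary aggregates the headline numbers.

The default configuration IS the emulated study design: eight Wolbachia
strains at up to four rearing temperatures (18-26 C; wTei lacks 18 C, wTri
lacks 18 and 20 C), three cross types, ~14 egg-lay replicates per cell with
~24 eggs each, half the strains with temperature-sensitive CI profiles.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import hatch, linmod, phylo, relquant, resampling, simulate

log = logging.getLogger("citherm.pipeline")

STAGES = ("simulate", "hatch", "densities", "expression", "devtime",
          "concordance", "phylo")

SENSITIVE_CI_PROFILE = {
    # per-strain CI-cross logit hatch probabilities by temperature
    "wMel": {18.0: -3.7, 20.0: -4.9, 23.0: -2.1, 26.0: -3.3},
    "wRi": {18.0: -7.0, 20.0: -7.0, 23.0: -3.5, 26.0: -7.0},
    "wHa": {18.0: -5.0, 20.0: -3.0, 23.0: -6.0, 26.0: -6.5},
    "wTei": {20.0: -0.3, 23.0: -5.3, 26.0: -0.2},
    "wSeg": {18.0: -5.0, 20.0: -5.0, 23.0: -5.0, 26.0: -5.0},
    "wCha": {18.0: -6.5, 20.0: -6.5, 23.0: -6.5, 26.0: -6.5},
    "wBic": {18.0: -4.5, 20.0: -4.5, 23.0: -4.5, 26.0: -4.5},
    "wTri": {23.0: -5.5, 26.0: -5.5},
}


def default_config() -> dict:
    return {
        "stages": {name: True for name in STAGES},
        "design": {
            "strains": ["wMel", "wTei", "wSeg", "wCha", "wBic", "wRi",
                        "wHa", "wTri"],
            "temperatures": [18.0, 20.0, 23.0, 26.0],
            "cross_types": list(simulate.CROSS_TYPES),
            "replicates_per_cell": 14,
            "unavailable_cells": [["wTei", 18.0], ["wTri", 18.0],
                                  ["wTri", 20.0]],
        },
        "sim": {
            "olre_sigma": 0.8,
            "zi_prob": 0.05,
            "egg_count_mean": 24.4,
            "egg_count_dispersion": 5.0,
            "devtime_base": 13.0,
            "devtime_temp_slope": -1.5,
            "devtime_cyto_effect": -0.5,
            "devtime_sd": 1.0,
            "cq_ref_mean": 22.0,
            "cq_noise_sd": 0.2,
            "ddpcr_log_mean": 5.0,
            "ddpcr_log_sd": 0.3,
        },
        "devtime_vials_per_cell": 8,
        "cq_samples_per_cell": 3,
        "ddpcr_replicates": 10,
        "analysis": {
            "min_eggs": 10,
            "quad_order": 25,
            "n_perm_permanova": 9999,
            "n_perm_pairwise": 10000,
            "n_boot": 10000,
            "n_mc": 10000,
            "chains": 4,
            "iters": 8000,
            "warmup": 2000,
        },
        "seed": 0,
    }


def load_config(path=None, overrides=None) -> dict:
    config = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(config, user)
    if overrides:
        _deep_update(config, overrides)
    return config


def _deep_update(base, extra):
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val


# ---------------------------------------------------------------------------
# True molecular profiles for the synthetic study
# ---------------------------------------------------------------------------

def _density_true_log2(design):
    """True log2 Wolbachia and Wovirus densities per strain x temperature.

    Strain identity dominates (as in testes qPCR data); half the strains
    get a thermal trend in density, the other half are flat.
    """
    out = {}
    for i, s in enumerate(design.strains):
        base = 1.0 + (i % 4)
        slope = 0.25 if i % 2 == 0 else 0.0
        for (s2, t) in design.strain_temp_cells():
            if s2 != s:
                continue
            out[(s, t, "ftsZ")] = base + slope * (t - 23.0)
            # one or two prophage variants per strain, relative to ftsZ
            out[(s, t, "sr1")] = -1.0 + 0.1 * (t - 23.0) * (1 if i % 2 else 0)
            if i % 3 == 0:
                out[(s, t, "sr2")] = -2.0
    return out


def _expression_true_log2():
    """True log2 cifB-transcript abundance per variant x treatment.

    Four of five variants are more highly expressed at the cool
    temperature; one is temperature-insensitive.
    """
    cool_excess = {"cifB_wMel_T1": 1.15, "cifB_wRi_T1": 2.5,
                   "cifB_wRi_T2": 1.9, "cifB_wHa_T1-1": 1.65,
                   "cifB_wHa_T1-2": 0.0}
    out = {}
    for i, (variant, excess) in enumerate(sorted(cool_excess.items())):
        warm = -2.0 + 0.8 * i
        out[(variant, "warm")] = warm
        out[(variant, "cool")] = warm + excess
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config, outdir: Path):
    design = simulate.build_design(config["design"])
    params = simulate.SimParams.from_mapping(
        dict(config["sim"], seed=config["seed"]))
    params.cell_logit_mean = simulate.default_cell_logits(
        design, ci_profile=SENSITIVE_CI_PROFILE)
    crosses = simulate.simulate_crosses(design, params)
    simulate.crosses_frame(crosses).to_csv(outdir / "crosses.csv", index=False)
    dev = simulate.simulate_devtimes(
        design, params, vials_per_cell=config["devtime_vials_per_cell"])
    simulate.devtimes_frame(dev).to_csv(outdir / "devtime.csv", index=False)
    cq = simulate.simulate_cq(design, params, _density_true_log2(design),
                              samples_per_cell=config["cq_samples_per_cell"])
    simulate.cq_frame(cq).to_csv(outdir / "cq.csv", index=False)
    ddpcr = simulate.simulate_ddpcr(design, params, _expression_true_log2(),
                                    replicates=config["ddpcr_replicates"])
    simulate.ddpcr_frame(ddpcr).to_csv(outdir / "ddpcr.csv", index=False)
    (outdir / "chronogram.nwk").write_text(
        simulate.simulate_chronogram(design.strains, params.seed) + "\n")
    return {"n_crosses": len(crosses), "n_devtime": len(dev),
            "n_cq": len(cq), "n_ddpcr": len(ddpcr)}


def stage_hatch(config, outdir: Path):
    ana = config["analysis"]
    table = pd.read_csv(outdir / "crosses.csv")
    kept = hatch.filter_min_eggs(table, ana["min_eggs"])
    log.info("min-egg filter: %d of %d replicates kept",
             len(kept), len(table))
    for rid in table.loc[table["eggs_total"] < ana["min_eggs"],
                         "replicate_id"]:
        log.info("excluded replicate %s (fewer than %d embryos)",
                 rid, ana["min_eggs"])
    fit = hatch.fit_zib_glmm(kept, quad_order=ana["quad_order"])

    strains = sorted({c[0] for c in fit.cells})
    temps_by_strain = {
        s: sorted({c[1] for c in fit.cells if c[0] == s}) for s in strains}

    or_ci, or_r, or_cit = [], [], []
    for s in strains:
        for t in temps_by_strain[s]:
            comp = (s, t, "compatible")
            if (s, t, "ci") in fit.cell_coef and comp in fit.cell_coef:
                or_ci.append(hatch.odds_ratio_contrast(
                    fit, (s, t, "ci"), comp, label=f"OR_CI {s} {t:g}C"))
            if (s, t, "rescue") in fit.cell_coef and comp in fit.cell_coef:
                or_r.append(hatch.odds_ratio_contrast(
                    fit, (s, t, "rescue"), comp, label=f"OR_R {s} {t:g}C"))
        temps = temps_by_strain[s]
        for i in range(len(temps)):
            for j in range(i + 1, len(temps)):
                tc, tw = temps[i], temps[j]
                cells = [(s, tc, "ci"), (s, tc, "compatible"),
                         (s, tw, "ci"), (s, tw, "compatible")]
                if all(c in fit.cell_coef for c in cells):
                    or_cit.append(hatch.ratio_of_odds_ratios(
                        fit, (cells[0], cells[1]), (cells[2], cells[3]),
                        label=f"OR_CI,T {s} {tc:g}/{tw:g}C"))
    for family in (or_ci, or_r, or_cit):
        hatch.adjust_family(family)

    contrasts = or_ci + or_r + or_cit
    pd.DataFrame([
        dict(label=c.label, ratio=c.ratio, ci_low=c.ci_low,
             ci_high=c.ci_high, p_raw=c.p_raw, p_adj=c.p_adj, scale=c.scale)
        for c in contrasts
    ]).to_csv(outdir / "contrasts.tsv", sep="\t", index=False)

    tests = hatch.typeII_wald_tests(fit)
    rows = [dict(term=t.term, chisq=t.chisq, df=t.df, p=t.p,
                 eta_sq_p=hatch.partial_eta_sq(t.chisq, fit.n_obs))
            for t in tests]
    pd.DataFrame(rows).to_csv(outdir / "anova_hatch.tsv", sep="\t",
                              index=False)

    emms = hatch.emm_cells(fit)
    pd.DataFrame([
        dict(strain=m.cell[0], temperature_c=m.cell[1], cross=m.cell[2],
             estimate=m.estimate, se=m.se) for m in emms
    ]).to_csv(outdir / "emm_hatch.tsv", sep="\t", index=False)

    with open(outdir / "fit.json", "w") as fh:
        json.dump({
            "coefficients": {" | ".join(map(str, c)): v
                             for c, v in sorted(fit.cell_coef.items())},
            "olre_sigma": fit.olre_sigma,
            "zi_prob": fit.zi_prob,
            "loglik": fit.loglik,
            "n_obs": fit.n_obs,
            "converged": fit.converged,
            "zero_inflated": fit.zero_inflated,
            "capped_cells": [" | ".join(map(str, c))
                             for c in fit.capped_cells],
        }, fh, indent=1, sort_keys=True)
    cross_term = next(t for t in tests if t.term == "cross")
    return {"n_kept": int(fit.n_obs), "sigma": fit.olre_sigma,
            "pi": fit.zi_prob, "loglik": fit.loglik,
            "converged": fit.converged,
            "cross_chisq": cross_term.chisq,
            "cross_eta_sq_p": hatch.partial_eta_sq(cross_term.chisq,
                                                   fit.n_obs),
            "n_or_ci": len(or_ci), "n_or_cit": len(or_cit)}


def stage_densities(config, outdir: Path):
    cq = pd.read_csv(outdir / "cq.csv")
    dens = relquant.densities_from_cq(cq)
    dens.to_csv(outdir / "densities.csv", index=False)
    summary = {}
    anova_rows, rr_rows = [], []
    for metric, sub in dens.groupby("metric", sort=True):
        sub = sub.copy()
        sub["temperature_c"] = sub["temperature_c"].astype(str)
        fit = linmod.fit_factorial_ols(sub, "log2_fold",
                                       ["strain", "temperature_c"])
        for row in linmod.typeII_anova_F(fit):
            anova_rows.append(dict(metric=metric, term=row.term, ss=row.ss,
                                   df=row.df, F=row.F, p=row.p,
                                   omega_sq_p=row.omega_sq_p))
            if row.term == "strain":
                summary[f"{metric}_strain_omega_sq_p"] = row.omega_sq_p
        family = []
        for s in sorted(sub["strain"].unique()):
            family.extend(linmod.emm_pairwise_rr(fit, within=s,
                                                 across="temperature_c"))
        hatch.adjust_family(family)
        rr_rows.extend(dict(metric=metric, label=c.label, ratio=c.ratio,
                            ci_low=c.ci_low, ci_high=c.ci_high,
                            p_raw=c.p_raw, p_adj=c.p_adj)
                       for c in family)
    pd.DataFrame(anova_rows).to_csv(outdir / "anova_densities.tsv", sep="\t",
                                    index=False)
    pd.DataFrame(rr_rows).to_csv(outdir / "rr_contrasts.tsv", sep="\t",
                                 index=False)
    return summary


def stage_expression(config, outdir: Path):
    ddpcr = pd.read_csv(outdir / "ddpcr.csv")
    ab = relquant.abundance_table_from_ddpcr(ddpcr)
    fit = linmod.fit_factorial_ols(ab, "value_log2", ["variant", "treatment"])
    anova = linmod.typeII_anova_F(fit)
    pd.DataFrame([
        dict(term=r.term, ss=r.ss, df=r.df, F=r.F, p=r.p,
             omega_sq_p=r.omega_sq_p) for r in anova
    ]).to_csv(outdir / "anova_expression.tsv", sep="\t", index=False)
    family = []
    for v in sorted(ab["variant"].unique()):
        family.extend(linmod.emm_pairwise_rr(fit, within=v,
                                             across="treatment"))
    hatch.adjust_family(family)
    pd.DataFrame([
        dict(label=c.label, ratio=c.ratio, ci_low=c.ci_low,
             ci_high=c.ci_high, p_raw=c.p_raw, p_adj=c.p_adj)
        for c in family
    ]).to_csv(outdir / "expression_rr.tsv", sep="\t", index=False)
    variant_term = next(r for r in anova if r.term == "variant")
    return {"variant_omega_sq_p": variant_term.omega_sq_p,
            "n_measurements": int(fit.n_obs)}


def stage_devtime(config, outdir: Path):
    ana = config["analysis"]
    seed = config["seed"]
    table = pd.read_csv(outdir / "devtime.csv")
    table["temperature_c"] = table["temperature_c"].astype(str)
    terms = ["strain", "cytotype", "temperature_c",
             "strain:cytotype", "strain:temperature_c",
             "cytotype:temperature_c", "strain:cytotype:temperature_c"]
    rows = resampling.permanova_seq(
        table["emergence_day"].to_numpy(float), table, terms,
        n_perm=ana["n_perm_permanova"], seed=seed)
    pd.DataFrame([r.__dict__ for r in rows]).to_csv(
        outdir / "permanova.tsv", sep="\t", index=False)

    pair_rows = []
    family = []
    for i, ((s, t), grp) in enumerate(
            table.groupby(["strain", "temperature_c"], sort=True)):
        apo = grp.loc[grp["cytotype"] == "aposymbiotic",
                      "emergence_day"].to_numpy(float)
        sym = grp.loc[grp["cytotype"] == "symbiotic",
                      "emergence_day"].to_numpy(float)
        if apo.size == 0 or sym.size == 0:
            continue
        res = resampling.permutation_diff_test(
            sym, apo, n_perm=ana["n_perm_pairwise"], seed=seed + i + 1)
        ci = {}
        for name, vals in (("sym", sym), ("apo", apo)):
            if vals.size >= 2 and np.ptp(vals) > 0:
                lo, hi, _ = resampling.bootstrap_percentile_ci(
                    vals, n_boot=ana["n_boot"], seed=seed + i + 1)
                ci[name] = (lo, hi)
        pair_rows.append(dict(strain=s, temperature_c=t,
                              delta_t=res.observed_diff, p_raw=res.p,
                              n_perm=res.n_perm,
                              sym_ci_low=ci.get("sym", (np.nan, np.nan))[0],
                              sym_ci_high=ci.get("sym", (np.nan, np.nan))[1]))
        family.append(res.p)
    adj = hatch.bh_fdr(family)
    for row, a in zip(pair_rows, adj):
        row["p_adj"] = float(a)
    pd.DataFrame(pair_rows).to_csv(outdir / "pairwise_permutation.tsv",
                                   sep="\t", index=False)
    temp_r2 = next(r.r2 for r in rows if r.term == "temperature_c")
    return {"temperature_r2": temp_r2,
            "n_obs": int(len(table)),
            "min_delta_t": float(min((r["delta_t"] for r in pair_rows),
                                     default=np.nan))}


def _hatch_emm_tables(outdir: Path):
    """Log OR_CI estimate and SE per strain x temperature from contrasts."""
    con = pd.read_csv(outdir / "contrasts.tsv", sep="\t")
    ci = con.loc[con["label"].str.startswith("OR_CI ")].copy()
    parts = ci["label"].str.split(expand=True)
    ci["strain"] = parts[1]
    ci["temperature_c"] = parts[2].str.rstrip("C").astype(float)
    ci["log_or"] = np.log(ci["ratio"])
    # Wald SE back from the CI: (log hi - log lo) / (2 * 1.96)
    ci["se"] = (np.log(ci["ci_high"]) - np.log(ci["ci_low"])) / (2 * 1.959963984540054)
    return ci[["strain", "temperature_c", "log_or", "se"]]


def _density_emm_tables(outdir: Path, metric="wolbachia_per_host"):
    dens = pd.read_csv(outdir / "densities.csv")
    sub = dens.loc[dens["metric"] == metric]
    grp = sub.groupby(["strain", "temperature_c"])["log2_fold"]
    emm = grp.mean().rename("mean").reset_index()
    emm["se"] = grp.sem().to_numpy()
    return emm


def stage_concordance(config, outdir: Path):
    ana = config["analysis"]
    or_tab = _hatch_emm_tables(outdir).rename(columns={"se": "se_or"})
    dens_tab = _density_emm_tables(outdir).rename(columns={"se": "se_dens"})
    merged = or_tab.merge(dens_tab, on=["strain", "temperature_c"])
    rows = []
    for s, grp in merged.groupby("strain", sort=True):
        if len(grp) < 2:
            continue
        res = conc.mc_concordance(
            grp["log_or"].to_numpy(), grp["se_or"].to_numpy(),
            grp["mean"].to_numpy(), grp["se_dens"].to_numpy(),
            n_mc=ana["n_mc"], seed=config["seed"])
        rows.append(dict(pair=f"OR_CI~density {s}", tau=res.tau,
                         p_d=res.p_d, n_conditions=res.n_conditions))
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    return {"n_strains": len(rows),
            "mean_abs_tau": float(out["tau"].abs().mean()) if len(out) else np.nan}


def stage_phylo(config, outdir: Path):
    ana = config["analysis"]
    chrono = phylo.parse_newick_chronogram(
        (outdir / "chronogram.nwk").read_text())
    cov = phylo.phylo_covariance(chrono)
    or_tab = _hatch_emm_tables(outdir)
    dens_tab = _density_emm_tables(outdir)
    merged = or_tab.merge(dens_tab, on=["strain", "temperature_c"])
    summary = phylo.fit_phylo_mixed_model(
        merged["log_or"].to_numpy(), merged["mean"].to_numpy(),
        list(merged["strain"]), cov,
        chains=ana["chains"], iters=ana["iters"], warmup=ana["warmup"],
        seed=config["seed"])
    payload = dict(beta_mean=summary.beta_mean, ci_low=summary.ci_low,
                   ci_high=summary.ci_high, bayes_r2=summary.bayes_r2,
                   p_d=summary.p_d, rhat_max=summary.rhat_max,
                   n_draws=summary.n_draws, n_obs=int(len(merged)))
    with open(outdir / "posterior.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return payload


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "hatch": stage_hatch,
    "densities": stage_densities,
    "expression": stage_expression,
    "devtime": stage_devtime,
    "concordance": stage_concordance,
    "phylo": stage_phylo,
}

_STAGE_INPUTS = {
    "simulate": [],
    "hatch": ["crosses.csv"],
    "densities": ["cq.csv"],
    "expression": ["ddpcr.csv"],
    "devtime": ["devtime.csv"],
    "concordance": ["contrasts.tsv", "densities.csv"],
    "phylo": ["chronogram.nwk", "contrasts.tsv", "densities.csv"],
}


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict, outdir) -> dict:
    """Run every enabled stage in order; return the summary mapping.

    Missing input files for any enabled stage abort before the first stage
    executes.  The summary is also written to ``summary.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if config["stages"].get(s, False)]
    produced = set()
    for stage in enabled:
        if stage == "simulate":
            produced.update(["crosses.csv", "devtime.csv", "cq.csv",
                             "ddpcr.csv", "chronogram.nwk"])
            continue
        if stage == "hatch":
            produced.update(["contrasts.tsv", "fit.json"])
        if stage == "densities":
            produced.add("densities.csv")
        missing = [f for f in _STAGE_INPUTS[stage]
                   if f not in produced and not (outdir / f).exists()]
        if missing:
            raise FileNotFoundError(
                f"stage {stage!r} requires missing inputs: {missing}")
    summary = {"seed": config["seed"], "stages_run": enabled}
    for stage in enabled:
        log.info("running stage %s", stage)
        try:
            summary[stage] = _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:  # re-raise with the stage named
            raise StageError(stage, exc) from exc
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
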