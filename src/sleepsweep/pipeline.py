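"""End-to-end orchestration: simulate -> score sleep -> selection QG ->
CMH scan -> logistic filter -> drift thresholds/verdicts -> LD -> diallel,
driven by one config mapping and emitting a machine-readable report."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, afc, drift, ld, selection, sleep
from . import diallel as diallel_mod
from . import io as ssio
from .simulate import (ActivitySpec, ExperimentConfig, MafSpectrum,
                       generate_founder_panel, simulate_activity,
                       simulate_diallel)
from .simulate.experiment import simulate_experiment

log = logging.getLogger("sleepsweep")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "sleepsweep_out",
    "founders": {"n_lines": 10, "n_sites_per_chrom": 200,
                 "chrom_labels": ["2L", "2R", "3L", "3R", "X"],
                 "maf_spectrum": {"kind": "uniform", "a": 0.1, "b": 0.9}},
    "experiment": {"n_generations": 13, "n_measured_per_sex": 50,
                   "selection_fraction": 0.25, "census": 100,
                   "coverage_mean": 80.0, "env_sd": 100.0,
                   "n_qtls": 20, "qtl_effect": 12.0},
    "activity": {"n_flies_per_group": 30, "night_means": {"long": 650.0,
                 "short": 100.0, "control": 450.0}, "day_mean": 200.0},
    "scan": {"alpha": None, "min_coverage": 10, "max_coverage": 2000,
             "pairs": [[0, 1], [1, 2], [2, 5], [5, 8], [8, 10], [10, 12]]},
    "drift": {"n_reps": 2000, "quantile": 0.999},
    "ld": {"n_per_chrom": 50, "r2_min": 0.8},
    "diallel": {"n_parents": 3, "gca_sd": 20.0, "noise_sd": 5.0,
                "n_per_cross": 2},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(cfg: dict, out_dir=None) -> dict:
    """Execute every stage on synthetic inputs; returns the report dict.

    Identical configs (and therefore seeds) give identical reports.
    Artifacts (TSV/CSV + report.json) land in ``out_dir``.
    """
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    seed = int(cfg["seed"])
    report: dict = {"version": __version__, "config_hash": chash, "seed": seed}

    # --- stage: simulate -------------------------------------------------
    fc = cfg["founders"]
    panel = generate_founder_panel(
        n_lines=fc["n_lines"], n_sites_per_chrom=fc["n_sites_per_chrom"],
        chrom_labels=fc["chrom_labels"],
        maf_spectrum=MafSpectrum(**fc["maf_spectrum"]), seed=seed)
    ec = cfg["experiment"]
    rng = np.random.default_rng(seed + 1)
    n_sites = panel.n_sites
    qtl_sites = rng.choice(n_sites, size=min(ec["n_qtls"], n_sites), replace=False)
    signs = rng.choice([-1.0, 1.0], size=qtl_sites.size)
    effects = {int(s): float(ec["qtl_effect"] * sg)
               for s, sg in zip(qtl_sites, signs)}
    exp_cfg = ExperimentConfig(
        n_generations=ec["n_generations"],
        n_measured_per_sex=ec["n_measured_per_sex"],
        selection_fraction=ec["selection_fraction"], census=ec["census"],
        qtl_effects=effects, env_sd=ec["env_sd"],
        coverage_mean=ec["coverage_mean"], seed=seed + 2)
    result = simulate_experiment(panel, exp_cfg)
    ssio.write_sync(result.counts, out / "counts.sync", chash, {"simulate": seed})
    ssio.write_long_counts(result.counts, out / "counts.tsv", chash,
                           {"simulate": seed})
    ssio.write_founders_tsv(panel, out / "founders.tsv")
    report["simulate"] = {"n_sites": n_sites,
                          "n_samples": result.counts.n_samples,
                          "n_qtls": int(qtl_sites.size)}

    # --- stage: sleep scoring -------------------------------------------
    ac = cfg["activity"]
    traits_frames = []
    state_fracs = {}
    act_rng = np.random.default_rng(seed + 3)
    for scheme, night_mean in ac["night_means"].items():
        traces = [
            simulate_activity(night_mean, ac["day_mean"],
                              ActivitySpec(mean_bout_length=60.0),
                              seed=act_rng, fly_id=f"{scheme}_{k}")
            for k in range(ac["n_flies_per_group"])
        ]
        scored = [sleep.score_traits(t) for t in traces]
        traits_frames.append(sleep.traits_frame(
            scored, scheme=scheme, fly_id=[t.fly_id for t in traces]))
        states = [sleep.classify_states(t) for t in traces]
        state_fracs[scheme] = float(
            sleep.population_state_fractions(states)["sleep"].mean())
    traits = pd.concat(traits_frames, ignore_index=True)
    ssio.TraitTableIO.write(traits, out / "sleep_traits.csv", chash,
                            {"activity": seed})
    report["sleep"] = {
        "mean_night_sleep": {
            scheme: float(grp["night_sleep"].mean())
            for scheme, grp in traits.groupby("scheme")},
        "sleep_fraction": state_fracs,
    }

    # --- stage: selection quantitative genetics -------------------------
    summaries = result.summaries
    h2_rows = []
    for pop, grp in summaries.groupby("population"):
        series = selection.cumulative_series(grp)
        est = selection.realized_heritability(series)
        h2_rows.append({"population": pop,
                        "scheme": grp["scheme"].iloc[0],
                        "h2": est.h2, "se": est.se, "p": est.p_value})
    h2_df = pd.DataFrame(h2_rows)
    h2_df.to_csv(out / "realized_h2.csv", index=False)
    final = summaries[summaries["generation"] == exp_cfg.n_generations]
    div = selection.divergence(
        final.loc[final["scheme"] == "long", "mean"],
        final.loc[final["scheme"] == "short", "mean"])
    report["selection"] = {
        "divergence_minutes": float(div),
        "h2": {r["population"]: r["h2"] for r in h2_rows},
    }

    # --- stage: allele-frequency scan -----------------------------------
    sc = cfg["scan"]
    counts = afc.coverage_filter(result.counts, sc["min_coverage"],
                                 sc["max_coverage"])
    assignment = afc.define_minor_allele(counts)
    alpha = sc["alpha"] or 0.05 / counts.n_sites
    pairs = [tuple(p) for p in sc["pairs"]]
    scan_res = afc.scan(counts, assignment, pairs, alpha=alpha)
    pops = result.populations
    sig = {s: {p: scan_res.significant[p]
               for p in pops.loc[pops["scheme"] == s, "name"]}
           for s in ("long", "short", "control")}
    candidates = afc.overlap_filter(sig["long"], sig["short"], sig["control"])
    logit = afc.logistic_filter(counts, assignment, candidates)
    logit.to_csv(out / "logistic_filter.tsv", sep="\t", index=False)
    survivors = sorted(logit.loc[logit["passed"], "site"].astype(int))
    report["scan"] = {
        "alpha": float(alpha),
        "n_significant": {p: len(s) for p, s in scan_res.significant.items()},
        "n_candidates": len(candidates),
        "n_logistic_pass": len(survivors),
    }

    # --- stage: drift ----------------------------------------------------
    control_pops = pops.loc[pops["scheme"] == "control", "name"]
    t_final = max(g for g in exp_cfg.sequenced_generations)
    q0_list, qt_list = [], []
    for pop in control_pops:
        idx0 = counts.sample_index(population=pop, generation=0)
        idxt = counts.sample_index(population=pop, generation=t_final)
        tot0 = counts.total[:, idx0].sum(axis=1)
        tott = counts.total[:, idxt].sum(axis=1)
        minor = afc.minor_counts(counts, assignment)
        with np.errstate(invalid="ignore", divide="ignore"):
            q0_list.append(np.where(tot0 > 0, minor[:, idx0].sum(1) / tot0, np.nan))
            qt_list.append(np.where(tott > 0, minor[:, idxt].sum(1) / tott, np.nan))
    ne_est = drift.binned_ne(np.concatenate(q0_list), np.concatenate(qt_list),
                             t=t_final)
    ne = int(round(ne_est.median_ne)) if np.isfinite(ne_est.median_ne) else 50
    ne = max(ne, 2)
    dc = cfg["drift"]
    tables = {
        mode: drift.drift_threshold_table(
            ne, t=t_final, n_reps=dc["n_reps"], quantile=dc["quantile"],
            chrom_mode=mode, seed=seed + 4)
        for mode in ("autosome", "X")
    }
    tables["autosome"].table.to_csv(out / "drift_thresholds.tsv", sep="\t",
                                    index=False)
    cand_rows = []
    minor_all = afc.minor_counts(counts, assignment)
    for site in survivors:
        idx0 = counts.sample_index(generation=0)
        tot0 = counts.total[site, idx0].sum()
        q0 = minor_all[site, idx0].sum() / tot0 if tot0 > 0 else np.nan
        freqs = {}
        for scheme in ("long", "short"):
            idx = counts.sample_index(scheme=scheme, generation=t_final)
            tot = counts.total[site, idx].sum()
            freqs[scheme] = minor_all[site, idx].sum() / tot if tot > 0 else np.nan
        cand_rows.append({
            "site": site, "chrom": counts.sites.at[site, "chrom"], "q0": q0,
            "divergence": abs(freqs["short"] - freqs["long"]),
        })
    verdicts = drift.drift_verdict(
        pd.DataFrame(cand_rows, columns=["site", "chrom", "q0", "divergence"]),
        tables, x_chroms={"X"})
    verdicts.to_csv(out / "candidates.tsv", sep="\t", index=False)
    report["drift"] = {
        "median_ne": float(ne_est.median_ne),
        "n_exceed_drift": int(verdicts["exceeds_drift"].fillna(False).sum())
        if len(verdicts) else 0,
    }

    # --- stage: LD -------------------------------------------------------
    lc = cfg["ld"]
    pair_set = ld.sample_snp_pairs(panel, n_per_chrom=lc["n_per_chrom"],
                                   seed=seed + 5)
    r2_tab = pair_set.r2_table()
    high = r2_tab[r2_tab["r2"] >= lc["r2_min"]].reset_index(drop=True)
    freq_rows = []
    for pop in pops["name"]:
        for gen in exp_cfg.sequenced_generations:
            idx = counts.sample_index(population=pop, generation=gen)
            tot = counts.total[:, idx].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                freq = np.where(tot > 0, minor_all[:, idx].sum(1) / tot, np.nan)
            for site in np.unique(high[["site_a", "site_b"]].to_numpy()):
                if np.isfinite(freq[site]):
                    freq_rows.append({"site": int(site), "population": pop,
                                      "generation": gen,
                                      "freq": float(freq[site])})
    persistence = ld.ld_persistence(high, pd.DataFrame(
        freq_rows, columns=["site", "population", "generation", "freq"]),
        r2_min=lc["r2_min"])
    persistence.to_csv(out / "ld_persistence.tsv", sep="\t", index=False)
    report["ld"] = {
        "n_pairs": int(pair_set.n_pairs),
        "n_high_ld_founders": int(len(high)),
    }

    # --- stage: diallel --------------------------------------------------
    dlc = cfg["diallel"]
    drng = np.random.default_rng(seed + 6)
    n_par = dlc["n_parents"]
    g_true = drng.normal(0, dlc["gca_sd"], n_par)
    g_true -= g_true.mean()
    table = simulate_diallel(g_true, np.zeros((n_par, n_par)),
                             np.zeros((n_par, n_par)), grand_mean=300.0,
                             noise_sd=dlc["noise_sd"],
                             n_per_cross=dlc["n_per_cross"], seed=drng)
    fit = diallel_mod.diallel_anova(table)
    fit.effects.to_csv(out / "diallel_effects.csv", index=False)
    fit.anova.to_csv(out / "diallel_anova.csv", index=False)
    report["diallel"] = {
        "n_crosses": int(table.n ** 2),
        "gca_rmse": float(np.sqrt(np.mean((fit.gca - g_true) ** 2))),
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
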