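"""End-to-end orchestration of the discovery/evaluation pipeline.

Each stage reads and writes the TSV/JSON formats in :mod:`netprog.io`;
``run_all`` chains them on one dataset + network and is deterministic for
a fixed config and seed (all randomness flows through named substreams of
the master seed; all outputs are written in sorted order).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from netprog import io
from netprog._rng import substream
from netprog.config import AnalysisConfig
from netprog.dataset import OmicsDataset
from netprog.discovery import (
    auto_delta,
    discovery_significance,
    exchanged_heat,
    extract_subnetworks,
    insulated_diffusion,
    permuted_heat_ensemble,
    Subnetwork,
)
from netprog.evaluation import (
    assemble_profile,
    monte_carlo_cv,
    permutation_test,
    PrognosticModel,
    rank_models,
)
from netprog.heat import gene_heat, heat_table, survival_gene_set
from netprog.risk import (
    clinical_adjustment,
    fit_final_model,
    snrs,
    stability_select,
    stratify_median,
)
from netprog.screening import collapse_methylation, screen_features, ScreeningResult
from netprog.stratify import compare_strata, nmf_consensus, pool_features

logger = logging.getLogger(__name__)


def run_screen(ds: OmicsDataset, cfg: AnalysisConfig, out: Path) -> ScreeningResult:
    result = screen_features(ds, cfg)
    collapsed = collapse_methylation(result, ds.probe_map)
    io.write_tsv(result.stats.rename_axis("feature").sort_index(), out / "screening.tsv", cfg)
    io.write_tsv(collapsed.stats.rename_axis("feature").sort_index(), out / "screening_collapsed.tsv", cfg)
    return collapsed


def run_score(collapsed: ScreeningResult, cfg: AnalysisConfig, out: Path):
    heats = gene_heat(collapsed)
    io.write_tsv(heat_table(heats), out / "gene_heat.tsv", cfg)
    logger.info("survival-related genes: %d", len(survival_gene_set(heats)))
    return heats


def run_discover(
    net: nx.Graph, heats, cfg: AnalysisConfig, out: Path, network_label: str = "net"
) -> list[Subnetwork]:
    F, nodes = insulated_diffusion(net, cfg.beta_restart)
    E = exchanged_heat(F, nodes, heats)
    if cfg.delta == "auto":
        rng = substream(cfg.seed, "auto_delta")
        ensemble = permuted_heat_ensemble(F, nodes, heats, cfg.auto_delta_perms, rng)
        delta = auto_delta(ensemble, cfg.effective_delta_cap)
    else:
        delta = float(cfg.delta)
    subs = extract_subnetworks(E, nodes, net, delta, cfg.min_subnetwork_size, network_label)
    if subs:
        rng = substream(cfg.seed, "discovery_significance")
        discovery_significance(F, nodes, net, heats, subs, delta, cfg.discovery_n_perm, rng, cfg.min_subnetwork_size)
    rows = [
        {
            "subnetwork": s.subnetwork_id,
            "size": s.size,
            "genes": ",".join(sorted(s.genes)),
            "size_class_p": s.size_class_p,
            "delta": delta,
            "beta": cfg.beta_restart,
        }
        for s in subs
    ]
    io.write_tsv(pd.DataFrame(rows), out / "subnetworks.tsv", cfg, index=False)
    io.write_gmt(subs, out / "subnetworks.gmt")
    logger.info("discovered %d subnetworks (delta=%g)", len(subs), delta)
    return subs


def run_evaluate(
    subs: list[Subnetwork],
    ds: OmicsDataset,
    collapsed: ScreeningResult,
    cfg: AnalysisConfig,
    out: Path,
):
    time = ds.survival_time.to_numpy(float)
    event = ds.event.to_numpy(int)
    models, profiles, cv_rows, sel_rows = [], {}, [], []
    for sub in subs:
        try:
            profile = assemble_profile(sub, ds, collapsed)
        except ValueError as exc:
            logger.warning("skipping %s: %s", sub.subnetwork_id, exc)
            continue
        rng_cv = substream(cfg.seed, f"cv:{sub.subnetwork_id}")
        cv = monte_carlo_cv(profile, time, event, cfg, rng_cv)
        rng_perm = substream(cfg.seed, f"perm:{sub.subnetwork_id}")
        p = permutation_test(profile, time, event, cv.median_c, cfg, rng_perm)
        models.append(
            PrognosticModel(
                subnetwork_id=sub.subnetwork_id,
                median_c=cv.median_c,
                permutation_p=p,
                selection_counts=cv.selection_counts,
            )
        )
        profiles[sub.subnetwork_id] = profile
        cv_rows.extend(
            {"subnetwork": sub.subnetwork_id, "split": i, "c_index": c}
            for i, c in enumerate(cv.c_distribution)
        )
        sel_rows.extend(
            {"subnetwork": sub.subnetwork_id, "feature": f, "count": c}
            for f, c in sorted(cv.selection_counts.items())
        )
    ranked = rank_models(models)
    io.write_tsv(pd.DataFrame(cv_rows), out / "cv_cindex.tsv", cfg, index=False)
    io.write_tsv(
        pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "subnetwork": m.subnetwork_id,
                    "median_c": m.median_c,
                    "permutation_p": m.permutation_p,
                    "passed": m.passed,
                }
                for i, m in enumerate(ranked)
            ]
        ),
        out / "models.tsv",
        cfg,
        index=False,
    )
    io.write_tsv(pd.DataFrame(sel_rows), out / "selection_counts.tsv", cfg, index=False)
    return ranked, profiles


def run_risk(
    ranked: list[PrognosticModel],
    profiles,
    ds: OmicsDataset,
    cfg: AnalysisConfig,
    out: Path,
):
    """snRS for the top-ranked passing model: median split, KM, clinical table."""
    time = ds.survival_time.to_numpy(float)
    event = ds.event.to_numpy(int)
    candidates = [m for m in ranked if m.passed] or ranked
    for model in candidates:
        stable = stability_select(model.selection_counts, cfg.stability_min_count)
        if not stable:
            logger.warning("%s: no stable features; skipping risk model", model.subnetwork_id)
            continue
        X = profiles[model.subnetwork_id].X
        usable = sorted(stable & set(X.columns))
        try:
            risk_model = fit_final_model(usable, X, time, event, model.subnetwork_id)
            scores = snrs(risk_model, X)
            strat = stratify_median(scores, time, event)
        except (ValueError, RuntimeError) as exc:
            logger.warning("%s: risk modelling failed (%s)", model.subnetwork_id, exc)
            continue
        io.write_tsv(
            pd.DataFrame({"snrs": strat.scores, "group": strat.group}).rename_axis("patient"),
            out / "snrs.tsv",
            cfg,
        )
        for grp, tbl in strat.km_tables.items():
            io.write_tsv(tbl, out / f"km_{model.subnetwork_id}_{grp}.tsv", cfg, index=False)
        io.write_json(
            {
                "subnetwork": model.subnetwork_id,
                "cutoff": strat.cutoff,
                "logrank_p": strat.logrank_p,
                "hr": strat.hr,
                "hr_ci": list(strat.hr_ci),
                "features": risk_model.features,
                "coefficients": risk_model.coefficients,
            },
            out / "risk_summary.json",
        )
        adj = clinical_adjustment(scores, ds.clinical, time, event)
        io.write_tsv(adj, out / "clinical_adjustment.tsv", cfg)
        return risk_model, strat
    logger.warning("no subnetwork yielded a risk model")
    return None, None


def run_stratify(
    ranked: list[PrognosticModel],
    ds: OmicsDataset,
    collapsed: ScreeningResult,
    cfg: AnalysisConfig,
    out: Path,
):
    time = ds.survival_time.to_numpy(float)
    event = ds.event.to_numpy(int)
    stability_sets = {
        m.subnetwork_id: stability_select(m.selection_counts, cfg.stability_min_count)
        for m in ranked
    }
    try:
        pooled = pool_features(ranked, stability_sets, ds, collapsed)
        strat = nmf_consensus(pooled, cfg.nmf_k, cfg.nmf_runs, cfg.seed)
        logrank_p, hr, ci = compare_strata(strat.labels, time, event)
    except ValueError as exc:
        logger.warning("stratification skipped: %s", exc)
        return None
    strat.logrank_p, strat.hr, strat.hr_ci = logrank_p, hr, ci
    io.write_tsv(strat.labels.to_frame().rename_axis("patient"), out / "clusters.tsv", cfg)
    io.write_tsv(strat.consensus.rename_axis("patient"), out / "consensus.tsv", cfg)
    io.write_json(
        {"logrank_p": logrank_p, "hr": hr, "hr_ci": list(ci), "n_pooled_features": len(strat.pooled_features)},
        out / "strata_survival.json",
    )
    return strat


def run_all(ds: OmicsDataset, net: nx.Graph, cfg: AnalysisConfig, out: str | Path) -> dict:
    """Full pipeline on one dataset + network; returns a run summary."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    collapsed = run_screen(ds, cfg, out)
    heats = run_score(collapsed, cfg, out)
    subs = run_discover(net, heats, cfg, out)
    summary = {
        "config_hash": cfg.hash(),
        "n_patients": ds.n_patients,
        "n_events": ds.n_events,
        "n_selected_features": int(collapsed.stats["selected"].sum()),
        "n_survival_genes": len(survival_gene_set(heats)),
        "n_subnetworks": len(subs),
    }
    if subs:
        ranked, profiles = run_evaluate(subs, ds, collapsed, cfg, out)
        summary["n_models"] = len(ranked)
        summary["n_passed"] = sum(m.passed for m in ranked)
        if ranked:
            summary["best_median_c"] = ranked[0].median_c
        risk_model, strat = run_risk(ranked, profiles, ds, cfg, out)
        if strat is not None:
            summary["risk_logrank_p"] = strat.logrank_p
            summary["risk_hr"] = strat.hr
        strata = run_stratify(ranked, ds, collapsed, cfg, out)
        if strata is not None:
            summary["strata_logrank_p"] = strata.logrank_p
            summary["strata_hr"] = strata.hr
    io.write_json(summary, out / "run_summary.json")
    return summary
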