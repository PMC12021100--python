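"""End-to-end pipeline chaining: stratify -> stats -> dpa -> select ->
drivers -> network -> flux.

Each stage consumes the in-memory cohort plus upstream stage outputs and
writes one :class:`ResultBundle` (tables + provenance).  Identical config,
seed and inputs give byte-identical tabular outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, bn, dpa as dpa_mod, flux as flux_mod, selection, snf, tableone
from .config import AnalysisConfig
from .layers import ResultBundle, config_hash

log = logging.getLogger("stratomics")

STAGE_ORDER = ["stratify", "stats", "dpa", "select", "drivers", "network", "flux"]
STAGE_DEPS = {
    "stratify": [],
    "stats": ["stratify"],
    "dpa": ["stratify"],
    "select": ["stratify"],
    "drivers": ["select"],
    "network": ["stratify", "dpa"],
    "flux": ["stratify"],
}


def _provenance(config: AnalysisConfig, cohort: dict, stage: str) -> dict:
    return {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config_hash(config.to_dict()),
        "input_digests": {k: cohort[k].digest() for k in
                          ("transcriptomics", "proteomics", "metabolomics")},
    }


def run_pipeline(config: AnalysisConfig, cohort: dict, outdir: str | Path,
                 stages: list[str] | None = None) -> dict[str, ResultBundle]:
    """Run the requested stages in dependency order and write their bundles.

    ``cohort`` holds the three omics layers, the sample table and optionally
    gene sets (the output of :func:`stratomics.synthetic.generate_cohort`, or
    the equivalent loaded from disk).  Requesting a stage without its
    upstream stage is an error naming the missing stage.
    """
    stages = list(stages or STAGE_ORDER)
    for s in stages:
        if s not in STAGE_ORDER:
            raise ValueError(f"unknown stage {s!r}")
        for dep in STAGE_DEPS[s]:
            if dep not in stages:
                raise ValueError(f"stage {s!r} requires upstream stage {dep!r}")
    stages.sort(key=STAGE_ORDER.index)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    bundles: dict[str, ResultBundle] = {}
    for s in stages:
        log.info("running stage %s", s)
        bundle = _STAGE_FN[s](config, cohort, state)
        bundle.provenance.update(_provenance(config, cohort, s))
        bundle.write(outdir)
        bundles[s] = bundle
    return bundles


def _stage_stratify(config: AnalysisConfig, cohort: dict, state: dict) -> ResultBundle:
    layers = [cohort["transcriptomics"], cohort["proteomics"], cohort["metabolomics"]]
    assign = snf.stratify(layers, config.snf, seed=config.seed)
    state["labels"] = np.asarray(assign.labels)
    state["assignment"] = assign
    labels_df = pd.DataFrame({"cluster": assign.labels},
                             index=pd.Index(assign.sample_ids, name="sample"))
    diag = pd.DataFrame({
        "eigengap": pd.Series(assign.eigengap),
        "rotation_cost": pd.Series(assign.rotation_cost),
    }).rename_axis("n_clusters")
    nmi = pd.DataFrame({"nmi": pd.Series(assign.layer_nmi)}).rename_axis("layer")
    fused = pd.DataFrame(assign.fused.matrix, index=assign.sample_ids,
                         columns=assign.sample_ids)
    return ResultBundle("stratify", {"labels": labels_df, "diagnostics": diag,
                                     "nmi": nmi, "fused_affinity": fused},
                        {"n_clusters": assign.n_clusters})


def _stage_stats(config: AnalysisConfig, cohort: dict, state: dict) -> ResultBundle:
    samples = cohort["samples"]
    labels = state["labels"]
    test_map = {}
    for col in samples.covariates.columns:
        if np.issubdtype(samples.covariates[col].dtype, np.number):
            test_map[col] = "continuous-nonnormal"
        else:
            test_map[col] = "categorical"
    table = tableone.build_table_one(samples, labels, test_map)
    return ResultBundle("stats", {"table_one": table})


def _stage_dpa(config: AnalysisConfig, cohort: dict, state: dict) -> ResultBundle:
    samples = cohort["samples"]
    labels = state["labels"]
    covs = config.dpa.covariates if config.dpa.model == 3 else []
    design = dpa_mod.build_design(samples, labels, covs)
    fit = dpa_mod.fit_moderated(cohort["proteomics"], design)
    state["dpa"] = fit.to_frame()
    n_sig = int((fit.fdr < config.dpa.fdr).sum())
    return ResultBundle("dpa", {"proteomics": state["dpa"]},
                        {"model": config.dpa.model, "n_significant": n_sig,
                         "d0": fit.d0, "s0_2": fit.s0_2})


def _stage_select(config: AnalysisConfig, cohort: dict, state: dict) -> ResultBundle:
    prot = cohort["proteomics"]
    labels = state["labels"]
    X = prot.to_frame()
    cfg = config.selection
    if cfg.subset_size > X.shape[1]:
        from dataclasses import replace
        cfg = replace(cfg, subset_size=X.shape[1])
    trace = selection.consensus_select(X, labels, cfg, seed=config.seed)
    state["selected"] = trace.selected
    tables = {"trace": trace.to_frame()}
    prov: dict = {"n_selected": len(trace.selected)}
    if len(trace.selected) >= 2:
        ev = selection.final_evaluate(X[trace.selected], labels, seed=config.seed)
        tables["confusion"] = pd.DataFrame(ev.confusion, index=ev.classes,
                                           columns=ev.classes)
        prov.update({"accuracy": ev.accuracy, "sensitivity": ev.sensitivity,
                     "specificity": ev.specificity, "oob_error": ev.oob_error,
                     "mtry": ev.mtry})
    return ResultBundle("select", tables, prov)


def _stage_drivers(config: AnalysisConfig, cohort: dict, state: dict) -> ResultBundle:
    prot = cohort["proteomics"]
    selected = state.get("selected") or []
    if len(selected) < 3:
        raise ValueError("drivers stage needs >= 3 selected features; "
                         "run the select stage with a stronger signal")
    data = prot.to_frame()[selected]
    model = bn.consensus_dag(data, config.bn.n_starts, config.bn.refine_iters,
                             config.bn.max_parents, seed=config.seed)
    scores = bn.driver_scores(model, data)
    sc = bn.BicScorer(data)
    top = [s for s in scores[: min(5, len(scores))] if s.delta_bic > 0]
    for s in top:
        if len(model.nodes) - len(top) >= 5:
            s.empirical_p = bn.validate_driver(
                s.node, model, data, seed=config.seed,
                candidates=[t.node for t in top], scorer=sc, iters=200)
    edges = pd.DataFrame(model.edges(), columns=["source", "target"])
    drv = pd.DataFrame([{"node": s.node, "delta_bic": s.delta_bic, "rank": s.rank,
                         "empirical_p": s.empirical_p} for s in scores]).set_index("node")
    return ResultBundle("drivers", {"edges": edges, "drivers": drv},
                        {"score": model.score, "n_edges": len(model.edges())})


def _stage_network(config: AnalysisConfig, cohort: dict, state: dict) -> ResultBundle:
    layers = [cohort["transcriptomics"], cohort["proteomics"], cohort["metabolomics"]]
    edges = assoc.consensus_associations(layers, config.network, seed=config.seed)
    tables: dict[str, pd.DataFrame] = {}
    prov: dict = {"n_consensus_pairs": len(edges)}
    if edges:
        net = assoc.finalize_network(edges, layers, config.network.final_fdr,
                                     state.get("dpa"))
        net = assoc.leiden_communities(net, config.network.min_community,
                                       seed=config.seed)
        tables["edges"] = net.edges
        tables["nodes"] = net.nodes.assign(
            community=[net.communities.get(n, -1) for n in net.nodes.index])
        comm = pd.DataFrame({"mean_degree": pd.Series(net.community_mean_degree)})
        comm.index.name = "community"
        tables["communities"] = comm
        prov["most_central"] = net.most_central
        if state.get("dpa") is not None and "gene_sets" in cohort:
            try:
                overlay = assoc.senescence_overlay(state["dpa"], cohort["gene_sets"], net)
                prov["sap_fraction_central"] = overlay.fraction
                prov["sap_significant"] = len(overlay.significant)
            except ValueError:
                pass
    return ResultBundle("network", tables, prov)


def _toy_gene_expression(cohort: dict, mask: np.ndarray) -> dict[str, float]:
    """Bridge cohort transcripts onto the toy model's gene ids.

    The i-th toy gene is mapped to the i-th transcript; expression is the
    group-mean log-CPM rescaled to [0, 1] across genes, a synthetic stand-in
    for TPM integration on a real reconstruction.
    """
    model = flux_mod.toy_cell_model()
    genes = sorted({g for r in model.reactions
                    for g in flux_mod._TOKEN.findall(r.gene_rule)
                    if g not in ("and", "or", "(", ")")})
    tx = dpa_mod.log_cpm(cohort["transcriptomics"])
    means = tx.values[mask].mean(axis=0)
    lo, hi = means.min(), means.max()
    scale = (means - lo) / (hi - lo) if hi > lo else np.ones_like(means)
    return {g: float(scale[i % len(scale)]) for i, g in enumerate(genes)}


def _stage_flux(config: AnalysisConfig, cohort: dict, state: dict) -> ResultBundle:
    labels = state["labels"]
    model = flux_mod.toy_cell_model()
    groups = {"control": None}
    for c in sorted(np.unique(labels)):
        groups[f"cluster{c}"] = labels == c
    metab = cohort["metabolomics"]
    flux_tables: dict[str, pd.Series] = {}
    for name, mask in groups.items():
        if mask is None:
            ctx = model
        else:
            expr = _toy_gene_expression(cohort, mask)
            levels = {"glc": float(np.exp(metab.values[mask, 0].mean() / 4.0)),
                      "trp": float(np.exp(metab.values[mask, 1].mean() / 4.0))}
            try:
                ctx = flux_mod.contextualize(model, expr, levels,
                                             expr_threshold=0.05)
            except flux_mod.TaskFailure:
                ctx = model
        res = flux_mod.fba(ctx)
        flux_tables[name] = res.fluxes
    target = sorted(k for k in flux_tables if k != "control")[-1]
    comparison = flux_mod.group_specific_fluxes(flux_tables, target=target,
                                                flux_eps=config.flux.flux_eps)
    filt = flux_mod.filter_fluxes(flux_tables[target], model,
                                  config.flux.flux_eps, config.flux.display_cut)
    return ResultBundle("flux", {"comparison": comparison, "target_fluxes": filt},
                        {"target": target,
                         "objective": {k: float(v.get("BIOMASS", np.nan))
                                       for k, v in flux_tables.items()}})


_STAGE_FN = {
    "stratify": _stage_stratify,
    "stats": _stage_stats,
    "dpa": _stage_dpa,
    "select": _stage_select,
    "drivers": _stage_drivers,
    "network": _stage_network,
    "flux": _stage_flux,
}
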