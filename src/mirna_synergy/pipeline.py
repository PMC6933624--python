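"""End-to-end orchestration: preprocess -> select -> effects -> network ->
modules -> analytics, with a machine-readable run report.

The pipeline is a pure function of (inputs, config, seed): identical inputs
produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from .analytics import (coexpression_calls, enrich_modules, topology_summary)
from .config import RunConfig
from .datatypes import (BindingNetwork, ExpressionMatrix, GeneList,
                        SurvivalTable)
from .io import write_network
from .modules import enumerate_maximal_bicliques, refine_module
from .preprocess import cox_select, preprocess_pipeline
from .synergy import (build_network, candidate_sets, compare_networks,
                      find_max_synergy_set, sequence_level_pairs)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(mirna_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix,
                 survival: SurvivalTable, binding: BindingNetwork,
                 config: RunConfig, out_dir: str | Path | None = None,
                 disease_genes: GeneList | None = None) -> dict:
    """Run every stage and return the run report dict.

    When ``out_dir`` is given, writes the network edgelist/GraphML, module
    JSON/TSV, topology JSON, comparison JSON, co-expression TSV and the run
    report there.
    """
    report: dict = {"version": __version__, "config": config.to_dict(),
                    "stages": {}, "warnings": []}

    def stage(name):
        def deco(fn):
            try:
                with warnings.catch_warnings(record=True) as wlist:
                    warnings.simplefilter("always")
                    result = fn()
                for w in wlist:
                    report["warnings"].append(f"{name}: {w.message}")
                return result
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return deco

    @stage("preprocess")
    def _pre():
        mi_norm, mi_means = preprocess_pipeline(
            mirna_expr, config.missing_threshold, config.knn_k)
        mr_norm, mr_means = preprocess_pipeline(
            mrna_expr, config.missing_threshold, config.knn_k)
        return mi_norm, mi_means, mr_norm, mr_means

    mi_norm, mi_means, mr_norm, mr_means = _pre
    report["stages"]["preprocess"] = {
        "miRNAs_in": mirna_expr.n_entities, "miRNAs_kept": mi_norm.n_entities,
        "mRNAs_in": mrna_expr.n_entities, "mRNAs_kept": mr_norm.n_entities,
        "samples": mi_norm.n_samples,
    }

    @stage("select")
    def _sel():
        sel_mi = cox_select(mi_norm, survival, config.alpha_cox)
        sel_mr = cox_select(mr_norm, survival, config.alpha_cox)
        return sel_mi, sel_mr

    sel_mi, sel_mr = _sel
    report["stages"]["select"] = {
        "significant_miRNAs": len(sel_mi.kept_ids),
        "significant_mRNAs": len(sel_mr.kept_ids),
        "multiple_testing_correction": "none (raw p < alpha_cox)",
    }
    if not sel_mi.kept_ids or not sel_mr.kept_ids:
        log.warning("no significant %s after selection; empty network",
                    "miRNAs" if not sel_mi.kept_ids else "mRNAs")
        report["stages"]["network"] = {"synergy_sets": 0, "nodes": 0, "edges": 0}
        report["stages"]["modules"] = {"bicliques": 0, "modules": 0}
        report["empty"] = True
        if out_dir is not None:
            _write_outputs(Path(out_dir), report, None, [], None, None, [], [])
        return report

    selected = mi_norm.subset(sel_mi.kept_ids)
    selected_mr = mr_norm.subset(sel_mr.kept_ids)
    data = ExpressionMatrix(pd.concat([selected.values, selected_mr.values]),
                            pd.concat([selected.entity_class,
                                       selected_mr.entity_class]))
    averages = pd.concat([mi_means, mr_means]).to_dict()
    sig_binding = binding.restrict(sel_mi.kept_ids, sel_mr.kept_ids)

    @stage("network")
    def _net():
        cands = candidate_sets(sig_binding, sel_mi.kept_ids, sel_mr.kept_ids)
        sets = []
        for cand in cands:
            s = find_max_synergy_set(cand, data, averages, config)
            if s is not None:
                sets.append(s)
        return cands, sets, build_network(sets)

    cands, synergy_sets, network = _net
    report["stages"]["network"] = {
        "candidate_targets": len(cands),
        "synergy_sets": len(synergy_sets),
        "nodes": len(network.nodes),
        "edges": len(network.edges),
    }

    @stage("compare")
    def _cmp():
        seq = sequence_level_pairs(sig_binding, sel_mi.kept_ids)
        return seq, compare_networks(seq, network)

    seq_pairs, comparison = _cmp
    report["stages"]["compare"] = {
        "sequence_level_pairs": len(seq_pairs),
        **{k: v for k, v in comparison.to_dict().items()
           if k.startswith("n_")},
    }

    @stage("modules")
    def _mod():
        bicliques = enumerate_maximal_bicliques(
            sig_binding, config.min_module_mirnas, config.min_module_mrnas)
        mods = []
        for b in bicliques:
            m = refine_module(b, data, averages, config)
            if m is not None:
                mods.append(m)
        return bicliques, mods

    bicliques, modules = _mod
    report["stages"]["modules"] = {"bicliques": len(bicliques),
                                   "modules": len(modules)}

    enrichment = []
    if disease_genes is not None and modules:
        @stage("enrich")
        def _enr():
            background = GeneList("significant",
                                  set(sel_mi.kept_ids) | set(sel_mr.kept_ids))
            return enrich_modules(modules, disease_genes, background,
                                  config.alpha_enrich)
        enrichment = _enr
        report["stages"]["enrich"] = {
            "modules_tested": len(enrichment),
            "modules_flagged": sum(e.flagged for e in enrichment),
        }

    topo = None
    if network.edges:
        @stage("analyze")
        def _ana():
            return topology_summary(network, config.n_random,
                                    config.random_model, config.seed)
        topo = _ana
        report["stages"]["analyze"] = topo.to_dict()

    coexpr = []
    if network.edges:
        @stage("coexpression")
        def _coe():
            return coexpression_calls(sorted(network.edges), data,
                                      config.alpha_corr)
        coexpr = _coe
        n_co = sum(c.co_expressed for c in coexpr)
        report["stages"]["coexpression"] = {
            "pairs": len(coexpr), "co_expressed": n_co,
            "fraction": (n_co / len(coexpr)) if coexpr else None,
        }

    if out_dir is not None:
        _write_outputs(Path(out_dir), report, network, modules, comparison,
                       topo, enrichment, coexpr)
    return report


def _write_outputs(out: Path, report, network, modules, comparison, topo,
                   enrichment, coexpr) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if network is not None:
        write_network(network, out / "synergy_network.tsv", "edgelist")
        write_network(network, out / "synergy_network.graphml", "graphml")
    with open(out / "modules.json", "w") as fh:
        json.dump([{"miRNAs": m.miRNAs, "mRNAs": m.mRNAs, "score": m.score,
                    "per_mRNA_delta": m.per_mrna_delta,
                    "parent_biclique": {"miRNAs": sorted(m.parent.miRNAs),
                                        "mRNAs": sorted(m.parent.mRNAs)}}
                   for m in modules], fh, indent=1, sort_keys=True)
    with open(out / "modules.tsv", "w") as fh:
        fh.write("module\tmiRNAs\tmRNAs\tscore\n")
        for i, m in enumerate(modules):
            fh.write(f"module_{i + 1}\t{';'.join(m.miRNAs)}\t"
                     f"{';'.join(m.mRNAs)}\t{m.score:.6g}\n")
    if comparison is not None:
        with open(out / "comparison.json", "w") as fh:
            json.dump(comparison.to_dict(), fh, indent=1, sort_keys=True)
    if topo is not None:
        with open(out / "topology.json", "w") as fh:
            json.dump(topo.to_dict(), fh, indent=1, sort_keys=True)
    if enrichment:
        with open(out / "enrichment.tsv", "w") as fh:
            fh.write("module_id\tN\tM\tK\tx\tp_value\tflagged\n")
            for e in enrichment:
                fh.write(f"{e.module_id}\t{e.N}\t{e.M}\t{e.K}\t{e.x}\t"
                         f"{e.p_value:.6g}\t{int(e.flagged)}\n")
    if coexpr:
        with open(out / "coexpression.tsv", "w") as fh:
            fh.write("miRNA_A\tmiRNA_B\tr\tp_value\tco_expressed\n")
            for c in coexpr:
                r = "NA" if c.r is None else f"{c.r:.6g}"
                p = "NA" if c.p_value is None else f"{c.p_value:.6g}"
                fh.write(f"{c.pair[0]}\t{c.pair[1]}\t{r}\t{p}\t"
                         f"{int(c.co_expressed)}\n")
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
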