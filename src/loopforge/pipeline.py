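"""End-to-end Control-vs-KO comparison: orchestration, caching, reporting.

Stage order mirrors the analysis it re-implements: contact maps -> balancing
-> compartments / insulation / TADs -> loop calling -> merged and
non-redundant loop sets -> CTCF peak dynamics -> integration statistics.
Every output table is reproducible bit-for-bit given the seed; stages are
cached by a content hash of inputs + parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import contact, compartments, insulation, loops as loops_mod
from .integrate import (GeneExpression, anchor_overlap_stats,
                        convergent_motif_pairs, anchor_ctcf_enrichment,
                        assign_genes_to_loops, rank_split, rank_group_test,
                        gene_loop_contingency, classify_ep_loops)
from .intervals import GeneModel
from .peaks import classify_peak_dynamics, class_counts
from .simulate import SimulationConfig, SimulatedBundle, simulate_bundle

log = logging.getLogger(__name__)

CONDITIONS = ("Control", "KO")
REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Thresholds of the comparison; defaults follow the analysis conventions."""

    seed: int = 0
    fdr: float = 0.10                 # loop-calling FDR
    ratio: float = 1.5                # loop enrichment ratio
    peak_fc: float = 1.5              # CTCF Up/Down threshold
    fpkm_min: float = 0.5             # expressed-gene filter
    de_q: float = 0.05                # DE call threshold
    promoter_halfwidth: int = 1000    # bp
    insulation_window: int = 1_000_000
    k_ranks: int = 4
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        for name in ("fdr", "ratio", "peak_fc", "fpkm_min", "de_q",
                     "promoter_halfwidth", "insulation_window", "k_ranks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _content_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig,
                 bundle: SimulatedBundle | None = None) -> dict:
    """Run the full comparison on a (simulated) two-condition bundle.

    Returns a JSON-serializable report with one entry per analysis table.
    """
    t0 = time.time()
    results: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                     "parameters": _params_dict(config),
                     "stages": []}

    def stage(name, fn):
        t = time.time()
        try:
            out = fn()
        except Exception as e:  # abort with the stage name attached
            raise StageFailure(name, e) from e
        results["stages"].append({"stage": name,
                                  "elapsed_s": round(time.time() - t, 3)})
        log.info("stage %-22s %6.2fs", name, time.time() - t)
        return out

    if bundle is None:
        cfg = config.simulation
        if cfg.seed != config.seed:
            cfg = SimulationConfig(**{**asdict(cfg), "seed": config.seed})
        bundle = stage("simulate", lambda: simulate_bundle(cfg))

    # --- balancing + O/E per condition ------------------------------------
    norm = {}

    def _normalize():
        for cond in CONDITIONS:
            cmap = bundle.maps[cond]
            w = contact.kr_balance(cmap)
            e = contact.expected_by_distance(cmap, w)
            norm[cond] = (cmap, w, e)
        return norm

    stage("normalize", _normalize)

    # --- compartments ------------------------------------------------------
    def _compartments():
        out = {}
        gene_density = _gene_density(bundle.genes, bundle.maps["Control"])
        for cond in CONDITIONS:
            cmap, w, e = norm[cond]
            oe = contact.oe_matrix(cmap, w, e)
            X = compartments.correlation_matrix(oe, mask=w.mask)
            ev = compartments.compartment_eigenvector(X)
            track = compartments.embed_track(ev, w.mask, cmap.chrom, cmap.resolution)
            out[cond] = compartments.orient_sign(track, gene_density)
        r = compartments.correlate_tracks(out["Control"].values, out["KO"].values,
                                          "pearson")
        results["compartments"] = {
            "pearson_control_vs_ko": r,
            "a_fraction": {c: float(np.nanmean(out[c].values > 0)) for c in CONDITIONS},
        }
        return out

    comp_tracks = stage("compartments", _compartments)

    # --- insulation + TADs --------------------------------------------------
    def _insulation():
        tracks, tadsets = {}, {}
        for cond in CONDITIONS:
            cmap, w, e = norm[cond]
            tr = insulation.insulation_score(cmap, w, config.insulation_window)
            b = insulation.detect_boundaries(tr)
            tadsets[cond] = insulation.call_tads(
                b, (cmap.chrom, 0, cmap.n_bins * cmap.resolution),
                cmap.resolution, tr.scores)
            tracks[cond] = tr
        rho = compartments.correlate_tracks(tracks["Control"].scores,
                                            tracks["KO"].scores, "spearman")
        common, ctrl_only, ko_only = insulation.match_tads(
            tadsets["Control"], tadsets["KO"])
        results["insulation"] = {"spearman_control_vs_ko": rho}
        results["tads"] = {
            "n_control": len(tadsets["Control"]), "n_ko": len(tadsets["KO"]),
            "common": len(common), "control_specific": len(ctrl_only),
            "ko_specific": len(ko_only)}
        return tracks, tadsets

    stage("insulation_tads", _insulation)

    # --- loop calling -------------------------------------------------------
    loop_params = loops_mod.LoopCallParams(fdr=config.fdr, ratio=config.ratio)

    def _call(cond):
        cmap, w, e = norm[cond]
        return loops_mod.call_loops({cmap.resolution: (cmap, w, e)},
                                    loop_params, condition=cond)

    loopsets = {cond: stage(f"loops_{cond}", lambda c=cond: _call(c))
                for cond in CONDITIONS}

    def _loop_sets():
        default = loops_mod.nonredundant_union(loopsets["KO"], loopsets["Control"])
        alt = loops_mod.nonredundant_union(loopsets["Control"], loopsets["KO"])
        for name, ls in (("default", default), ("alt", alt)):
            for cond in CONDITIONS:
                cmap, w, e = norm[cond]
                loops_mod.quantify_loops(ls, cmap, w, e, cond)
        ko_specific = sum(
            1 for L in default
            if not any(loops_mod._both_anchors_overlap(L, c)
                       for c in loopsets["Control"]))
        ctrl_specific = sum(
            1 for L in default
            if not any(loops_mod._both_anchors_overlap(L, k)
                       for k in loopsets["KO"]))
        results["loops"] = {
            "n_control": len(loopsets["Control"]), "n_ko": len(loopsets["KO"]),
            "n_default_nonredundant": len(default),
            "n_alt_nonredundant": len(alt),
            "ko_specific": ko_specific, "control_specific": ctrl_specific}
        return default

    default_set = stage("loop_sets", _loop_sets)

    # --- CTCF peak dynamics -------------------------------------------------
    def _peak_dynamics():
        from .intervals import annotate_peaks, promoter_window
        from .peaks import promoter_enrichment, group_log2fc_test

        annotated = annotate_peaks(bundle.merged_peaks, bundle.genes,
                                   config.promoter_halfwidth)
        dyn = classify_peak_dynamics(annotated, threshold=config.peak_fc)
        results["ctcf_classes"] = class_counts(dyn)
        try:
            results["promoter_enrichment"] = promoter_enrichment(dyn)
        except ValueError as e:
            results["promoter_enrichment"] = f"skipped ({e})"

        # per-class expression shift at promoter-located peaks
        if bundle.expression is not None:
            l2fc = dict(zip(bundle.expression["gene_id"],
                            bundle.expression["log2fc"]))
            groups = {}
            for d in dyn:
                if d.peak.annotation != "promoter-TSS":
                    continue
                for g in bundle.genes:
                    if d.peak.interval.overlaps(
                            promoter_window(g, config.promoter_halfwidth)):
                        groups.setdefault(d.klass, []).append(l2fc[g.gene_id])
                        break
            results["promoter_peak_expression"] = {
                k: group_log2fc_test(v) for k, v in groups.items() if len(v) >= 2}
        return dyn

    dynamics = stage("peak_dynamics", _peak_dynamics)

    # --- integration ----------------------------------------------------------
    def _integration():
        peaks_all = bundle.merged_peaks
        ov = anchor_overlap_stats(default_set, peaks_all)
        conv = sum(1 for L in default_set
                   if convergent_motif_pairs(L, bundle.motifs)[0])
        results["anchors"] = {
            "both_anchor_ctcf": ov,
            "convergent_motif_loops": conv,
            "convergent_motif_percent": round(100.0 * conv / max(1, len(default_set)), 1)}

        fc_loop = loops_mod.loop_fold_changes(default_set)
        ctcf_fc = np.array([
            anchor_ctcf_enrichment(L, bundle.fragments, bundle.library_sizes)["fc"]
            for L in default_set])
        ok = np.isfinite(fc_loop) & np.isfinite(ctcf_fc)
        ranks_ok = ok.sum() >= config.k_ranks
        if ranks_ok:
            coords = [default_set.loops[i].anchor1.start
                      for i in np.flatnonzero(ok)]
            grouping = rank_split(ctcf_fc[ok], config.k_ranks, tiebreak=coords)
            results["ctcf_rank_groups"] = rank_group_test(grouping, fc_loop[ok])
        else:
            results["ctcf_rank_groups"] = "skipped"

        expr = _expression_records(bundle, config)
        if expr is None:
            results["gene_ranks"] = "skipped"
            results["gene_loop_contingency"] = "skipped"
            return
        fc_by_loop = {i: float(fc_loop[i]) for i in range(len(default_set))}
        links = assign_genes_to_loops(expr, default_set,
                                      config.promoter_halfwidth, fc_by_loop)
        anchored = [l for l in links if l.linkage == "anchored"
                    and np.isfinite(l.loop_fc)]
        outside_vals = [l.gene.log2fc for l in links if l.linkage == "outside"]
        if len(anchored) >= config.k_ranks and len(outside_vals) >= 2:
            grouping = rank_split([l.loop_fc for l in anchored], config.k_ranks,
                                  tiebreak=[l.gene.gene.tss for l in anchored])
            results["gene_ranks"] = rank_group_test(
                grouping, [l.gene.log2fc for l in anchored], outside_vals)
            results["gene_ranks_n"] = {
                "anchored_combinations": len(anchored),
                "anchored_genes": len({l.gene.gene.gene_id for l in anchored}),
                "anchored_loops": len({id(l.loop) for l in anchored}),
                "rank0_genes": len(outside_vals)}
        else:
            results["gene_ranks"] = "skipped"
        try:
            results["gene_loop_contingency"] = gene_loop_contingency(
                links, config.de_q)
        except ValueError as e:
            results["gene_loop_contingency"] = f"skipped ({e})"

        enh = [iv for iv, _k in bundle.enhancers]
        ep = classify_ep_loops(default_set, enh, bundle.genes,
                               config.promoter_halfwidth)
        results["ep_loops"] = {"n": int(sum(ep)), "total": len(default_set)}

    stage("integration", _integration)

    results["elapsed_s"] = round(time.time() - t0, 3)
    return results


def _params_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


def _gene_density(genes: list[GeneModel], cmap) -> np.ndarray:
    density = np.zeros(cmap.n_bins)
    for g in genes:
        b = g.tss // cmap.resolution
        if 0 <= b < cmap.n_bins:
            density[b] += 1
    return density


def _expression_records(bundle: SimulatedBundle, config: PipelineConfig):
    if bundle.expression is None:
        log.warning("expression input missing; expression sections skipped")
        return None
    gene_by_id = {g.gene_id: g for g in bundle.genes}
    out = []
    for r in bundle.expression.itertuples():
        fpkms = {"Control": float(r.fpkm_Control), "KO": float(r.fpkm_KO)}
        if max(fpkms.values()) < config.fpkm_min:
            continue  # expressed-gene filter
        out.append(GeneExpression(gene_by_id[r.gene_id], fpkms,
                                  float(r.log2fc), float(min(1.0, r.q))))
    return out


# ---------------------------------------------------------------------------
# report I/O with content-hash caching


def write_report(results: dict, outdir) -> Path:
    """Machine-readable JSON + human TSVs + run log line."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(results, fh, indent=1, default=_json_default, sort_keys=True)
    for key in ("ctcf_rank_groups", "gene_ranks"):
        tab = results.get(key)
        if isinstance(tab, list):
            pd.DataFrame(tab).to_csv(outdir / f"{key}.tsv", sep="\t", index=False)
    with open(outdir / "run.log", "a") as fh:
        fh.write(json.dumps({"schema": results["schema_version"],
                             "params_hash": _content_hash(results["parameters"]),
                             "elapsed_s": results.get("elapsed_s")}) + "\n")
    return path


def run_cached(config: PipelineConfig, outdir,
               bundle: SimulatedBundle | None = None) -> dict:
    """Run the pipeline unless a report for identical parameters exists."""
    outdir = Path(outdir)
    key = _content_hash(_params_dict(config))
    marker = outdir / f".cache_{key}"
    report_path = outdir / "report.json"
    if marker.exists() and report_path.exists():
        log.info("cache hit (%s); reusing report", key)
        with open(report_path) as fh:
            return json.load(fh)
    results = run_pipeline(config, bundle)
    write_report(results, outdir)
    marker.write_text(key + "\n")
    return results


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
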