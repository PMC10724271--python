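"""Loop-peak-motif-gene integration statistics.

Links chromatin loops to CTCF peaks (anchor overlap, convergent motif pairs,
anchor ChIP enrichment), to genes (promoter-anchor overlap), and computes the
rank-group statistics: items ranked by a fold change are split into k
near-equal groups and a response variable is compared across groups with
two-sided Mann-Whitney tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .intervals import (GenomicInterval, GeneModel, MotifSite,
                        promoter_window, overlap_query)
from .loops import LoopCall, LoopSet

log = logging.getLogger(__name__)

EXPRESSED_FPKM = 0.5
DE_Q = 0.05

__all__ = [
    "GeneExpression",
    "RankGrouping",
    "GeneLoopLink",
    "fpkm",
    "anchor_overlap_stats",
    "convergent_motif_pairs",
    "anchor_ctcf_enrichment",
    "assign_genes_to_loops",
    "rank_split",
    "rank_group_test",
    "chi_square_2x2",
    "gene_loop_contingency",
    "classify_ep_loops",
]


@dataclass
class GeneExpression:
    gene: GeneModel
    fpkm_by_condition: dict
    log2fc: float
    q_value: float

    def __post_init__(self):
        if any(v < 0 for v in self.fpkm_by_condition.values()):
            raise ValueError("FPKM must be >= 0")
        if not (0 <= self.q_value <= 1):
            raise ValueError("q must be in [0, 1]")

    @property
    def expressed(self) -> bool:
        return max(self.fpkm_by_condition.values(), default=0.0) >= EXPRESSED_FPKM


@dataclass
class RankGrouping:
    order: np.ndarray              # item indices, ascending by ranking value
    group_of: np.ndarray           # group index (0-based) per item
    k: int

    def group_indices(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.group_of == g)


@dataclass
class GeneLoopLink:
    gene: GeneExpression
    loop: LoopCall | None
    linkage: str                   # anchored | outside
    loop_fc: float = float("nan")


def fpkm(read_pairs_per_transcript: float, transcript_length: int,
         total_mapped_pairs: int) -> float:
    """Fragments per kb of transcript per million mapped read pairs."""
    if transcript_length <= 0:
        raise ValueError("transcript length must be > 0")
    if total_mapped_pairs <= 0:
        raise ValueError("total mapped pairs must be > 0")
    return read_pairs_per_transcript * 1e9 / (transcript_length * total_mapped_pairs)


def anchor_overlap_stats(loop_set: LoopSet, peaks) -> dict:
    """Count loops with BOTH anchors overlapping >= 1 peak; percentage to 1 dp."""
    if len(loop_set) == 0:
        raise ValueError("empty loop set")
    peak_ivs = [p.interval for p in peaks]
    a1 = [L.anchor1 for L in loop_set]
    a2 = [L.anchor2 for L in loop_set]
    hit1 = {i for i, _ in overlap_query(a1, peak_ivs)}
    hit2 = {i for i, _ in overlap_query(a2, peak_ivs)}
    count = len(hit1 & hit2)
    return {"count": count, "total": len(loop_set),
            "percent": round(100.0 * count / len(loop_set), 1)}


def convergent_motif_pairs(loop: LoopCall, motif_sites) -> tuple[bool, int]:
    """Convergent orientation: a '+' motif in the upstream anchor paired with a
    '-' motif in the downstream anchor.  Pair count is the product."""
    plus_a1 = sum(1 for m in motif_sites
                  if m.strand == "+" and m.interval.overlaps(loop.anchor1))
    minus_a2 = sum(1 for m in motif_sites
                   if m.strand == "-" and m.interval.overlaps(loop.anchor2))
    n = plus_a1 * minus_a2
    return n > 0, n


def anchor_ctcf_enrichment(loop: LoopCall, fragments_by_condition: dict,
                           library_sizes: dict,
                           pseudocount_fpm: float = 0.5) -> dict:
    """Per-condition CTCF fragments-per-million over both anchors, and KO/Ctrl FC.

    fragments_by_condition: condition -> sequence of GenomicInterval fragments.
    """
    enr = {}
    for cond, frags in fragments_by_condition.items():
        lib = library_sizes[cond]
        if lib <= 0:
            raise ValueError(f"library size for {cond} must be > 0")
        n = sum(1 for f in frags
                if f.overlaps(loop.anchor1) or f.overlaps(loop.anchor2))
        enr[cond] = n * 1e6 / lib
    conds = list(enr)
    out = {"enrichment": enr}
    if "Control" in enr and "KO" in enr:
        out["fc"] = (enr["KO"] + pseudocount_fpm) / (enr["Control"] + pseudocount_fpm)
    elif len(conds) == 2:
        out["fc"] = (enr[conds[1]] + pseudocount_fpm) / (enr[conds[0]] + pseudocount_fpm)
    return out


def assign_genes_to_loops(genes_expression, loop_set: LoopSet,
                          promoter_halfwidth: int = 1000,
                          fc_by_loop: dict | None = None) -> list[GeneLoopLink]:
    """Link expressed genes to loops whose anchors their promoters overlap.

    One link per (gene, loop) pair -- a gene bridging several loops yields
    several "combinations".  Genes with no overlap get a single "outside" link.
    """
    links: list[GeneLoopLink] = []
    for ge in genes_expression:
        win = promoter_window(ge.gene, promoter_halfwidth)
        hit = False
        for idx, loop in enumerate(loop_set):
            if win.overlaps(loop.anchor1) or win.overlaps(loop.anchor2):
                fc = (fc_by_loop or {}).get(idx, float("nan"))
                links.append(GeneLoopLink(ge, loop, "anchored", fc))
                hit = True
        if not hit:
            links.append(GeneLoopLink(ge, None, "outside"))
    return links


def rank_split(values, k: int = 4, tiebreak=None) -> RankGrouping:
    """Rank items ascending by value and split into k near-equal contiguous groups.

    Ties are broken by ``tiebreak`` (e.g. genomic coordinate) then input order,
    so the split is deterministic.  Larger groups come first; sizes differ by
    at most 1.
    """
    v = np.asarray(list(values), dtype=float)
    n = len(v)
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    if tiebreak is not None:
        tb = np.asarray(list(tiebreak))
        order = np.lexsort((np.arange(n), tb, v))
    else:
        order = np.lexsort((np.arange(n), v))
    base, extra = divmod(n, k)
    sizes = [base + 1 if g < extra else base for g in range(k)]
    group_of = np.empty(n, dtype=int)
    pos = 0
    for g, size in enumerate(sizes):
        group_of[order[pos:pos + size]] = g
        pos += size
    return RankGrouping(order=order, group_of=group_of, k=k)


def rank_group_test(grouping: RankGrouping, response_values,
                    baseline_values=None) -> list[dict]:
    """Per-group summary + two-sided Mann-Whitney p against the baseline.

    Baseline is an external "rank 0" sample when given, else group 1 (the
    lowest rank).  Groups with n < 2 get p = NaN and a flag.
    """
    r = np.asarray(list(response_values), dtype=float)
    results = []
    if baseline_values is not None:
        base = np.asarray(list(baseline_values), dtype=float)
        base = base[np.isfinite(base)]
        base_label = 0
    else:
        base = r[grouping.group_indices(0)]
        base = base[np.isfinite(base)]
        base_label = 1

    if baseline_values is not None:
        results.append(_group_summary(0, base, None, None))
    for g in range(grouping.k):
        x = r[grouping.group_indices(g)]
        x = x[np.isfinite(x)]
        is_base = baseline_values is None and g == 0
        if is_base or len(x) < 2 or len(base) < 2:
            p = u = float("nan")
            if not is_base and (len(x) < 2 or len(base) < 2):
                log.warning("rank group %d: too few observations for MW test", g + 1)
        else:
            u, p = stats.mannwhitneyu(x, base, alternative="two-sided")
        results.append(_group_summary(g + 1, x, float(u) if np.isfinite(u) else u,
                                      float(p) if np.isfinite(p) else p))
    results[0]["baseline"] = base_label
    return results


def _group_summary(label, x, u, p):
    q = np.percentile(x, [25, 50, 75]) if len(x) else [np.nan] * 3
    return {"group": label, "n": int(len(x)), "median": float(q[1]),
            "q1": float(q[0]), "q3": float(q[2]), "U": u, "p": p}


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Chi-square statistic and p for a 2x2 count table (no continuity
    correction by default)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError(f"empty margin in contingency table {t.tolist()}")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return float(chi2), float(p)


def gene_loop_contingency(links, de_q_threshold: float = DE_Q,
                          yates: bool = False) -> dict:
    """2x2 (anchored/outside x up/down) over DE-called genes + chi-square.

    up := q < threshold and log2FC > 0; down := q < threshold and log2FC < 0.
    A gene anchored by any loop counts once as anchored.  Chi-square without
    continuity correction by default.
    """
    anchored_genes, outside_genes = {}, {}
    for link in links:
        gid = link.gene.gene.gene_id
        if link.linkage == "anchored":
            anchored_genes[gid] = link.gene
        else:
            outside_genes[gid] = link.gene
    for gid in anchored_genes:
        outside_genes.pop(gid, None)

    def updown(genes):
        up = sum(1 for g in genes.values()
                 if g.q_value < de_q_threshold and g.log2fc > 0)
        down = sum(1 for g in genes.values()
                   if g.q_value < de_q_threshold and g.log2fc < 0)
        return up, down

    table = np.array([updown(anchored_genes), updown(outside_genes)], dtype=float)
    chi2, p = chi_square_2x2(table, yates=yates)
    return {"table": table.astype(int).tolist(), "chi2": chi2, "p": p, "dof": 1}


def classify_ep_loops(loop_set: LoopSet, enhancers, genes,
                      promoter_halfwidth: int = 1000) -> list[bool]:
    """Flag enhancer-promoter loops.

    EP iff one anchor overlaps a (non-promoter) enhancer interval and the
    other overlaps a promoter window, in either orientation.  Enhancers that
    overlap a promoter window count as promoters (precedence, logged).
    """
    promoters = [promoter_window(g, promoter_halfwidth) for g in genes]

    def is_prom(iv: GenomicInterval) -> bool:
        return any(iv.overlaps(p) for p in promoters)

    clean_enh = []
    for e in enhancers:
        if is_prom(e):
            log.info("enhancer %s:%d-%d overlaps a promoter window; "
                     "treated as promoter", e.chrom, e.start, e.end)
        else:
            clean_enh.append(e)

    def is_enh(iv: GenomicInterval) -> bool:
        return any(iv.overlaps(e) for e in clean_enh)

    flags = []
    for L in loop_set:
        e1, p1 = is_enh(L.anchor1), is_prom(L.anchor1)
        e2, p2 = is_enh(L.anchor2), is_prom(L.anchor2)
        flags.append((e1 and p2) or (e2 and p1))
    return flags
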