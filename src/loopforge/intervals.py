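"""Genomic interval arithmetic and BED/BEDPE/gene-table I/O.

All coordinates are 0-based half-open internally (BED native).  Any 1-based
input is converted at the reader boundary.  Strand affects only TSS position
(minus-strand genes: TSS = gene end), never interval overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

PROMOTER_HALFWIDTH = 1000  # bp each side of the TSS

__all__ = [
    "GenomicInterval",
    "Peak",
    "MotifSite",
    "GeneModel",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "overlap_query",
    "merge_condition_peaks",
    "annotate_peak",
    "read_gene_table",
    "write_gene_table",
    "promoter_window",
]


class BedParseError(ValueError):
    """Malformed record in a BED-family file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Peak:
    interval: GenomicInterval
    id: str = "."
    signal_by_condition: dict = field(default_factory=dict)
    annotation: str | None = None  # promoter-TSS | genic | intergenic

    def __post_init__(self):
        for cond, s in self.signal_by_condition.items():
            if s < 0:
                raise ValueError(f"negative signal {s} for condition {cond!r}")


@dataclass(frozen=True)
class MotifSite:
    interval: GenomicInterval
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    transcript_length: int
    span_start: int | None = None  # optional gene body, for genic annotation
    span_end: int | None = None

    def __post_init__(self):
        if self.transcript_length <= 0:
            raise ValueError("transcript_length must be > 0")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def span(self) -> GenomicInterval:
        """Gene body; defaults to [tss, tss+length) on + / [tss-length, tss) on -."""
        if self.span_start is not None and self.span_end is not None:
            return GenomicInterval(self.chrom, self.span_start, self.span_end)
        if self.strand == "+":
            return GenomicInterval(self.chrom, self.tss, self.tss + self.transcript_length)
        return GenomicInterval(self.chrom, max(0, self.tss - self.transcript_length),
                               max(1, self.tss))


def promoter_window(gene: GeneModel, halfwidth: int = PROMOTER_HALFWIDTH) -> GenomicInterval:
    """TSS +/- halfwidth, clipped at the chromosome origin."""
    return GenomicInterval(gene.chrom, max(0, gene.tss - halfwidth), gene.tss + halfwidth)


# ---------------------------------------------------------------------------
# readers / writers


def read_bed(path, default_condition: str | None = None) -> list[Peak]:
    """Read BED3/BED6 into Peaks (file order preserved).

    Column 5 (score), when present, is stored as the signal for
    ``default_condition`` (key ``"signal"`` if no condition given).
    """
    peaks: list[Peak] = []
    key = default_condition or "signal"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise BedParseError(path, lineno, f"non-integer coordinate: {e}") from None
            try:
                iv = GenomicInterval(fields[0], start, end)
            except ValueError as e:
                raise BedParseError(path, lineno, str(e)) from None
            pid = fields[3] if len(fields) > 3 and fields[3] else "."
            signals = {}
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    signals[key] = float(fields[4])
                except ValueError as e:
                    raise BedParseError(path, lineno, f"bad score: {e}") from None
            peaks.append(Peak(iv, id=pid, signal_by_condition=signals))
    return peaks


def write_bed(peaks: Sequence[Peak], path, condition: str | None = None) -> None:
    key = condition or "signal"
    with open(path, "w") as fh:
        for p in peaks:
            score = p.signal_by_condition.get(key)
            cols = [p.interval.chrom, str(p.interval.start), str(p.interval.end),
                    p.id or "."]
            if score is not None:
                cols.append(repr(float(score)))
            fh.write("\t".join(cols) + "\n")


def read_motifs(path) -> list[MotifSite]:
    """BED6 with strand in column 6."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise BedParseError(path, lineno, "motif BED needs 6 columns (strand)")
            try:
                sites.append(MotifSite(GenomicInterval(f[0], int(f[1]), int(f[2])), f[5]))
            except ValueError as e:
                raise BedParseError(path, lineno, str(e)) from None
    return sites


def write_motifs(sites: Sequence[MotifSite], path) -> None:
    with open(path, "w") as fh:
        for m in sites:
            fh.write(f"{m.interval.chrom}\t{m.interval.start}\t{m.interval.end}"
                     f"\t.\t0\t{m.strand}\n")


def read_bedpe(path) -> list[tuple[GenomicInterval, GenomicInterval, list[str]]]:
    """Read 6+-column BEDPE; cis only; anchors normalized so anchor1 is upstream.

    Returns (anchor1, anchor2, extra_columns) triples in file order.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise BedParseError(path, lineno, f"expected >=6 columns, got {len(f)}")
            if f[0] != f[3]:
                raise BedParseError(
                    path, lineno,
                    f"trans record ({f[0]} vs {f[3]}): pipeline is cis-only")
            try:
                a = GenomicInterval(f[0], int(f[1]), int(f[2]))
                b = GenomicInterval(f[3], int(f[4]), int(f[5]))
            except ValueError as e:
                raise BedParseError(path, lineno, str(e)) from None
            if b.start < a.start or (b.start == a.start and b.end < a.end):
                a, b = b, a
            records.append((a, b, f[6:]))
    return records


def write_bedpe(records, path) -> None:
    """records: iterable of (anchor1, anchor2, extra_cols)."""
    with open(path, "w") as fh:
        for a, b, extra in records:
            if b.start < a.start or (b.start == a.start and b.end < a.end):
                a, b = b, a
            cols = [a.chrom, str(a.start), str(a.end), b.chrom, str(b.start), str(b.end)]
            cols.extend(str(x) for x in extra)
            fh.write("\t".join(cols) + "\n")


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "transcript_length"]


def read_gene_table(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} missing columns {missing}")
    return [
        GeneModel(str(r.gene_id), str(r.chrom), str(r.strand),
                  int(r.tss), int(r.transcript_length))
        for r in df.itertuples()
    ]


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.transcript_length) for g in genes],
        columns=GENE_TABLE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval algebra


def _tree_by_chrom(intervals: Sequence[GenomicInterval]):
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    return trees


def overlap_query(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """Index pairs (i, j) with >= 1 bp overlap between set_a[i] and set_b[j].

    Half-open semantics: [0,10) does not overlap [10,20).  Sorted by (i, j).
    """
    trees = _tree_by_chrom(set_b)
    out: list[tuple[int, int]] = []
    for i, iv in enumerate(set_a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            out.append((i, hit.data))
    out.sort()
    return out


def merge_condition_peaks(
    peaks_control: Sequence[Peak],
    peaks_ko: Sequence[Peak],
    conditions: tuple[str, str] = ("Control", "KO"),
) -> list[Peak]:
    """Merge two condition peak sets into union intervals with both signals.

    Transitive merge: connected components of the overlap graph collapse to
    their union interval (HOMER mergePeaks behaviour).  A condition absent
    from a component contributes signal 0.  Output sorted by (chrom, start).
    """
    ctrl_name, ko_name = conditions
    tagged = [(p, ctrl_name) for p in peaks_control] + [(p, ko_name) for p in peaks_ko]
    by_chrom: dict[str, list[tuple[Peak, str]]] = {}
    for p, cond in tagged:
        by_chrom.setdefault(p.interval.chrom, []).append((p, cond))

    merged: list[Peak] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[0].interval.start, t[0].interval.end))
        # sweep: on a sorted list, transitive components are maximal runs where
        # each next interval starts before the running max end
        component: list[tuple[Peak, str]] = []
        comp_end = -1
        for p, cond in items:
            if component and p.interval.start >= comp_end:
                merged.append(_collapse(chrom, component, conditions))
                component = []
            component.append((p, cond))
            comp_end = max(comp_end, p.interval.end)
        if component:
            merged.append(_collapse(chrom, component, conditions))
    return merged


def _collapse(chrom, component, conditions) -> Peak:
    start = min(p.interval.start for p, _ in component)
    end = max(p.interval.end for p, _ in component)
    signals = {c: 0.0 for c in conditions}
    for p, cond in component:
        for key, val in p.signal_by_condition.items():
            use = key if key in signals else cond
            signals[use] = signals.get(use, 0.0) + val
    ids = [p.id for p, _ in component if p.id and p.id != "."]
    return Peak(GenomicInterval(chrom, start, end),
                id=ids[0] if ids else ".", signal_by_condition=signals)


def annotate_peak(
    peak: Peak,
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
) -> str:
    """Classify a peak as promoter-TSS / genic / intergenic.

    Promoter (TSS +/- halfwidth) takes precedence over gene body.
    """
    iv = peak.interval
    for g in genes:
        if g.chrom != iv.chrom:
            continue
        if iv.overlaps(promoter_window(g, promoter_halfwidth)):
            return "promoter-TSS"
    for g in genes:
        if g.chrom == iv.chrom and iv.overlaps(g.span):
            return "genic"
    return "intergenic"


def annotate_peaks(peaks: Iterable[Peak], genes: Sequence[GeneModel],
                   promoter_halfwidth: int = PROMOTER_HALFWIDTH) -> list[Peak]:
    return [replace_annotation(p, annotate_peak(p, genes, promoter_halfwidth))
            for p in peaks]


def replace_annotation(peak: Peak, annotation: str) -> Peak:
    return Peak(peak.interval, peak.id, dict(peak.signal_by_condition), annotation)
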