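"""Two-condition synthetic fixtures with planted ground truth.

The generator emulates the data model of a cis Hi-C / ChIP-seq / RNA-seq
comparison between a Control and a knock-out (KO) condition:

* contact maps with power-law distance decay, a compartment plaid, TAD
  blocks, and focal loops, with Poisson pixel counts;
* CTCF peaks carrying planted Up/Neutral/Down occupancy classes whose fold
  changes drive the Control->KO change in loop intensity (coupling gamma);
* gene expression whose true log2FC is coupled to the intensity change of
  the anchoring loop.

Every planted object is recorded in a machine-readable truth manifest so
consuming modules can be scored against it.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .contact import ContactMap
from .intervals import (GenomicInterval, Peak, MotifSite, GeneModel,
                        write_bed, write_motifs, write_gene_table)
from .peaks import CoverageTrack, rpgc_normalize

__all__ = ["SimulationConfig", "TruthManifest", "SimulatedBundle",
           "simulate_contact_maps", "simulate_peaks_and_tracks",
           "simulate_expression", "simulate_bundle", "write_fixture_bundle"]

CONDITIONS = ("Control", "KO")


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom: str = "chrS"
    chrom_length: int = 20_000_000
    resolution: int = 25_000
    total_pairs: int = 1_000_000
    decay_alpha: float = 1.0            # power-law exponent of distance decay
    compartment_beta: float = 0.3       # plaid strength
    compartment_block_mean: int = 2_000_000  # bp
    tad_size_bins: tuple[int, int] = (10, 80)
    tad_tau: float = 2.0                # intra-TAD contact multiplier
    n_loops: int = 20
    loop_lambda_range: tuple[float, float] = (3.0, 6.0)
    loop_sep_bins: tuple[int, int] = (10, 80)   # 250 kb - 2 Mb at 25 kb
    ctcf_proportions: tuple[float, float, float] = (0.42, 0.54, 0.04)  # Up/Neutral/Down
    gamma: float = 0.5                  # CTCF log2FC -> loop-intensity log2FC
    loop_noise_sigma: float = 0.2
    expression_delta: float = 0.4       # loop log2FC -> gene log2FC
    expression_sigma: float = 0.2
    n_genes: int = 2000
    anchored_gene_fraction: float = 0.15
    n_background_peaks: int = 160
    peak_depth: float = 50.0            # median ChIP fragments per peak (Control)
    peak_depth_sigma: float = 1.0       # log-sd of per-peak baseline strength
    peak_dispersion: float = 0.1
    n_chip_replicates: int = 2          # biological ChIP replicates per condition
    fc_sigma_up: float = 0.2
    fc_sigma_neutral: float = 0.05
    motif_convergent_fraction: float = 0.6
    track_bin: int = 200
    n_te: int = 60
    n_se: int = 8

    def __post_init__(self):
        if abs(sum(self.ctcf_proportions) - 1.0) > 1e-9:
            raise ValueError("CTCF class proportions must sum to 1")
        if min(self.ctcf_proportions) < 0:
            raise ValueError("proportions must be non-negative")
        for name in ("chrom_length", "resolution", "total_pairs",
                     "n_genes", "track_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_loops < 0:
            raise ValueError("n_loops must be >= 0")

    @property
    def n_bins(self) -> int:
        return math.ceil(self.chrom_length / self.resolution)


@dataclass
class TruthManifest:
    config: dict
    compartments: list           # +1 / -1 per bin
    tad_boundaries: list         # bin indices
    loops: list                  # dicts: i, j, lambda per condition, ctcf log2fc
    peaks: list                  # dicts: id, start, end, class, true_fc, anchor_of
    genes: list                  # dicts: gene_id, tss, anchored_loop, true_log2fc
    enhancers: list              # dicts: start, end, class

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    manifest: TruthManifest
    maps: dict                       # condition -> ContactMap
    peaks: dict                      # condition -> list[Peak] (CTCF)
    merged_peaks: list               # merged CTCF peaks with both signals
    motifs: list
    fragments: dict                  # condition -> list[GenomicInterval]
    library_sizes: dict
    ctcf_tracks: dict                # condition -> CoverageTrack (RPGC)
    atac_track: CoverageTrack
    enhancers: list                  # (GenomicInterval, "SE"/"TE")
    genes: list                      # GeneModel
    expression: "object"             # pandas DataFrame


# ---------------------------------------------------------------------------
# planted structure


def _plant_compartments(cfg: SimulationConfig, rng) -> np.ndarray:
    n = cfg.n_bins
    mean_bins = max(1, cfg.compartment_block_mean // cfg.resolution)
    c = np.empty(n, dtype=np.int8)
    sign = 1 if rng.random() < 0.5 else -1
    i = 0
    while i < n:
        block = 1 + rng.geometric(1.0 / mean_bins)
        c[i:i + block] = sign
        sign = -sign
        i += block
    return c


def _plant_tads(cfg: SimulationConfig, rng) -> list[int]:
    lo, hi = cfg.tad_size_bins
    boundaries = [0]
    while boundaries[-1] < cfg.n_bins:
        boundaries.append(boundaries[-1] + int(rng.integers(lo, hi + 1)))
    boundaries[-1] = cfg.n_bins
    return boundaries


def _plant_loops(cfg: SimulationConfig, comp: np.ndarray,
                 tad_bounds: list[int], rng) -> list[dict]:
    """Place focal loops as intra-TAD, compartment-coherent anchor pairs.

    CTCF loops in mammalian maps are predominantly loop domains: both anchors
    inside one TAD (often at its corner) and in the same compartment state.
    Planting them that way keeps the benchmark realistic -- loop pixels sit on
    the elevated intra-TAD background rather than on depleted cross-domain
    pixels.
    """
    n = cfg.n_bins
    lo, hi = cfg.loop_sep_bins
    tads = [(a, b) for a, b in zip(tad_bounds[:-1], tad_bounds[1:])]
    chosen: set[tuple[int, int]] = set()
    loops = []
    guard = 0
    while len(loops) < cfg.n_loops and guard < 20000:
        guard += 1
        sep = int(rng.integers(lo, hi + 1))
        candidates = [(a, b) for a, b in tads if b - a > sep]
        if not candidates:
            continue
        a, b = candidates[int(rng.integers(0, len(candidates)))]
        i = int(rng.integers(a, b - sep))
        j = i + sep
        if i < 8 or j > n - 8:
            continue
        if comp[i] != comp[j]:
            continue
        # keep peak pixels >= 8 bins apart so clusters stay distinct
        if any(abs(i - p) < 8 and abs(j - q) < 8 for p, q in chosen):
            continue
        chosen.add((i, j))
        lam = float(rng.uniform(*cfg.loop_lambda_range))
        loops.append({"i": i, "j": j, "lambda_Control": lam})
    loops.sort(key=lambda d: (d["i"], d["j"]))
    return loops


def _ctcf_classes(cfg: SimulationConfig, n: int, rng) -> tuple[list[str], np.ndarray]:
    """Draw per-peak true fold changes from the three occupancy-class mixtures.

    The recorded class is the category the realized fold change actually
    belongs to (a draw from the "Up" mixture that lands below the 1.5
    threshold is, by definition of the classes, Neutral), so the manifest is
    self-consistent with the classifier's own semantics.
    """
    from .peaks import classify_fold_change

    group = rng.choice(["Up", "Neutral", "Down"], size=n, p=cfg.ctcf_proportions)
    fc = np.empty(n)
    for k in range(n):
        if group[k] == "Up":
            fc[k] = math.exp(rng.normal(math.log(2.0), cfg.fc_sigma_up))
        elif group[k] == "Down":
            fc[k] = 1.0 / math.exp(rng.normal(math.log(2.0), cfg.fc_sigma_up))
        else:
            fc[k] = math.exp(rng.normal(0.0, cfg.fc_sigma_neutral))
    klass = [classify_fold_change(f) for f in fc]
    return klass, fc


# ---------------------------------------------------------------------------
# contact maps


def _expected_intensity(cfg: SimulationConfig, comp: np.ndarray,
                        tad_bounds: list[int], loops: list[dict],
                        condition: str) -> np.ndarray:
    n = cfg.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mu = (d + 1.0) ** (-cfg.decay_alpha)
    mu *= np.exp(cfg.compartment_beta * np.outer(comp, comp))
    tad_id = np.searchsorted(tad_bounds, np.arange(n), side="right")
    same_tad = np.equal.outer(tad_id, tad_id)
    mu *= np.where(same_tad, cfg.tad_tau, 1.0)
    for L in loops:
        lam = L[f"lambda_{condition}"]
        i, j = L["i"], L["j"]
        for a in range(max(0, i - 1), min(n, i + 2)):
            for b in range(max(0, j - 1), min(n, j + 2)):
                f = lam if (a == i and b == j) else math.sqrt(lam)
                mu[a, b] *= f
                mu[b, a] *= f
    # calibrate so the expected upper-triangle mass equals total_pairs
    upper_mass = np.triu(mu).sum()
    if not np.isfinite(upper_mass) or upper_mass <= 0:
        raise ValueError("infeasible intensity calibration")
    return mu * (cfg.total_pairs / upper_mass)


def simulate_contact_maps(cfg: SimulationConfig, rng=None):
    """Simulate Control and KO maps plus the structural truth.

    Expected pixel intensity: power-law decay x compartment plaid x intra-TAD
    multiplier x loop kernel (lambda at the peak pixel, sqrt(lambda) on its
    8-neighborhood); counts are Poisson.  KO loop strength follows
    log2(lambda_KO) - log2(lambda_Ctrl) = gamma * CTCF-anchor log2FC + noise.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    comp = _plant_compartments(cfg, rng)
    tad_bounds = _plant_tads(cfg, rng)
    loops = _plant_loops(cfg, comp, tad_bounds, rng)

    # planted CTCF classes at the 2 anchors of every loop
    anchor_klass, anchor_fc = _ctcf_classes(cfg, 2 * cfg.n_loops, rng)
    for k, L in enumerate(loops):
        l2 = 0.5 * (math.log2(anchor_fc[2 * k]) + math.log2(anchor_fc[2 * k + 1]))
        L["ctcf_log2fc"] = l2
        noise = rng.normal(0.0, cfg.loop_noise_sigma) if cfg.loop_noise_sigma > 0 else 0.0
        L["lambda_KO"] = float(L["lambda_Control"]
                               * 2.0 ** (cfg.gamma * l2 + noise))
        L["anchor_classes"] = [anchor_klass[2 * k], anchor_klass[2 * k + 1]]
        L["anchor_fcs"] = [float(anchor_fc[2 * k]), float(anchor_fc[2 * k + 1])]

    maps = {}
    for cond in CONDITIONS:
        mu = _expected_intensity(cfg, comp, tad_bounds, loops, cond)
        upper = np.triu(mu)
        counts = rng.poisson(upper)
        maps[cond] = ContactMap(cfg.chrom, cfg.resolution, cfg.n_bins,
                                sp.csr_matrix(np.triu(counts)))
    manifest = TruthManifest(
        config=asdict(cfg),
        compartments=comp.astype(int).tolist(),
        tad_boundaries=[int(b) for b in tad_bounds[1:-1]],
        loops=loops,
        peaks=[], genes=[], enhancers=[],
    )
    return maps["Control"], maps["KO"], manifest


# ---------------------------------------------------------------------------
# ChIP peaks, motifs, fragments, coverage tracks


def _nb_counts(mean: float, dispersion: float, size: int, rng) -> np.ndarray:
    """Gamma-Poisson counts; ``dispersion`` is the gamma-mixing CV.

    var = mean + (dispersion * mean)^2, i.e. NB shape r = dispersion^-2
    (the biological-CV parametrization); dispersion <= 0 is the noiseless
    limit (deterministic rounded mean).
    """
    if dispersion <= 0:
        return np.full(size, round(mean), dtype=int)
    r = dispersion ** -2
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_peaks_and_tracks(cfg: SimulationConfig, manifest: TruthManifest,
                              rng=None):
    """CTCF peaks (anchors + background), motifs, fragments and coverage tracks.

    Fragment counts per peak are negative-binomial around a class-specific
    mean (Control mean = peak_depth; KO mean = peak_depth x true FC).
    Convergent motifs are planted at a fraction of loop anchors.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    res = cfg.resolution
    peak_w = 400

    peaks_meta = []  # (interval, class, true_fc, anchor_of)
    for k, L in enumerate(manifest.loops):
        for side, bin_idx in enumerate((L["i"], L["j"])):
            center = bin_idx * res + res // 2
            iv = GenomicInterval(cfg.chrom, center - peak_w // 2, center + peak_w // 2)
            peaks_meta.append((iv, L["anchor_classes"][side],
                               L["anchor_fcs"][side], k))
    bg_klass, bg_fc = _ctcf_classes(cfg, cfg.n_background_peaks, rng)
    anchor_spans = [m[0] for m in peaks_meta]
    placed = 0
    guard = 0
    while placed < cfg.n_background_peaks and guard < 100000:
        guard += 1
        start = int(rng.integers(0, cfg.chrom_length - peak_w))
        iv = GenomicInterval(cfg.chrom, start, start + peak_w)
        if any(iv.overlaps(a) for a in anchor_spans):
            continue
        peaks_meta.append((iv, bg_klass[placed], float(bg_fc[placed]), None))
        anchor_spans.append(iv)
        placed += 1
    peaks_meta.sort(key=lambda m: m[0].start)

    n_track = cfg.chrom_length // cfg.track_bin
    frag_len = 200
    noiseless = cfg.peak_dispersion <= 0
    fragments = {c: [] for c in CONDITIONS}
    raw_tracks = {c: np.zeros(n_track) for c in CONDITIONS}
    # per-peak baseline occupancy is log-normal (real peak strengths span
    # orders of magnitude); the class fold change acts on top of it.
    # Each condition is measured in n_chip_replicates biological replicates
    # (mirroring duplicate ChIP); the peak signal is the replicate mean and
    # the fragment pool merges the replicates.
    base_depth = cfg.peak_depth * np.exp(
        rng.normal(0.0, cfg.peak_depth_sigma, size=len(peaks_meta)))
    signals = {c: np.empty(len(peaks_meta)) for c in CONDITIONS}
    for idx, (iv, klass, fc, anchor_of) in enumerate(peaks_meta):
        for cond in CONDITIONS:
            mean = base_depth[idx] * (fc if cond == "KO" else 1.0)
            reps = _nb_counts(mean, cfg.peak_dispersion,
                              cfg.n_chip_replicates, rng)
            cnt = int(reps.sum())
            signals[cond][idx] = cnt / cfg.n_chip_replicates
            if noiseless:
                # deterministic placement: fragments tile the peak evenly
                starts = np.linspace(iv.start - frag_len // 2,
                                     iv.end - frag_len // 2, num=cnt,
                                     endpoint=False).astype(int) if cnt else []
            else:
                starts = rng.integers(max(0, iv.start - frag_len // 2),
                                      iv.end - frag_len // 2, size=cnt)
            for s in starts:
                fragments[cond].append(
                    GenomicInterval(cfg.chrom, int(s), int(s) + frag_len))
                b0, b1 = int(s) // cfg.track_bin, (int(s) + frag_len - 1) // cfg.track_bin
                raw_tracks[cond][b0:b1 + 1] += 1

    # flat background coverage so RPGC scaling is well defined off-peak;
    # Poisson-noisy unless the count model is run in its noiseless limit
    for cond in CONDITIONS:
        raw_tracks[cond] += (np.ones(n_track) if noiseless
                             else rng.poisson(1.0, size=n_track))

    tracks = {c: rpgc_normalize(CoverageTrack(cfg.chrom, cfg.track_bin,
                                              raw_tracks[c]))
              for c in CONDITIONS}

    # peak score = replicate-mean fragment count (occupancy on a common
    # scale: per-condition sequencing depth is calibrated equal upstream)
    peak_lists = {c: [] for c in CONDITIONS}
    manifest.peaks = []
    for idx, (iv, klass, fc, anchor_of) in enumerate(peaks_meta):
        pid = f"ctcf_{idx:04d}"
        manifest.peaks.append({"id": pid, "start": iv.start, "end": iv.end,
                               "class": str(klass), "true_fc": float(fc),
                               "anchor_of": anchor_of})
        for cond in CONDITIONS:
            peak_lists[cond].append(Peak(iv, id=pid,
                                         signal_by_condition={
                                             cond: float(signals[cond][idx])}))

    motifs = []
    motif_w = 19
    for k, L in enumerate(manifest.loops):
        if rng.random() < cfg.motif_convergent_fraction:
            for bin_idx, strand in ((L["i"], "+"), (L["j"], "-")):
                pos = bin_idx * res + res // 2
                motifs.append(MotifSite(
                    GenomicInterval(cfg.chrom, pos, pos + motif_w), strand))

    # SE/TE enhancers + ATAC track: SEs are longer and stronger
    atac_raw = rng.poisson(1.0, size=n_track).astype(float)
    enhancers = []
    for n_items, klass, length_range, strength in (
            (cfg.n_te, "TE", (1500, 3000), 2.0),
            (cfg.n_se, "SE", (8000, 16000), 6.0)):
        for _ in range(n_items):
            ln = int(rng.integers(*length_range))
            start = int(rng.integers(0, cfg.chrom_length - ln))
            iv = GenomicInterval(cfg.chrom, start, start + ln)
            enhancers.append((iv, klass))
            b0, b1 = start // cfg.track_bin, (start + ln - 1) // cfg.track_bin
            atac_raw[b0:b1 + 1] += rng.poisson(strength, size=b1 - b0 + 1)
    manifest.enhancers = [{"start": iv.start, "end": iv.end, "class": k}
                          for iv, k in enhancers]

    library_sizes = {c: max(1, len(fragments[c])) for c in CONDITIONS}
    atac_track = rpgc_normalize(CoverageTrack(cfg.chrom, cfg.track_bin, atac_raw))
    return peak_lists, motifs, fragments, library_sizes, tracks, atac_track, enhancers


# ---------------------------------------------------------------------------
# expression


def simulate_expression(cfg: SimulationConfig, manifest: TruthManifest, rng=None):
    """Gene models + expression table (FPKM per condition, log2FC, BH q).

    An ``anchored_gene_fraction`` of genes get their TSS planted inside a loop
    anchor bin; their true log2FC is delta x the anchoring loop's intensity
    log2FC, all other genes have true log2FC 0.  Observed replicate values
    (3 vs 3, log2 scale) add Normal(0, sigma) noise; log2FC and q come from a
    Welch t-test with BH correction across genes.
    """
    import pandas as pd

    rng = rng or np.random.default_rng(cfg.seed + 2)
    res = cfg.resolution
    n_anchored = int(round(cfg.anchored_gene_fraction * cfg.n_genes))
    genes, rows = [], []
    manifest.genes = []

    anchor_bins = []
    for k, L in enumerate(manifest.loops):
        anchor_bins.append((k, L["i"]))
        anchor_bins.append((k, L["j"]))

    loop_l2fc = {k: math.log2(L["lambda_KO"] / L["lambda_Control"])
                 for k, L in enumerate(manifest.loops)}

    # genes enriched 3:1 in the A (+1) compartment so eigenvector sign
    # orientation by gene density is testable
    comp = np.asarray(manifest.compartments)
    bin_w = np.where(comp > 0, 3.0, 1.0)
    bin_p = bin_w / bin_w.sum()

    for g in range(cfg.n_genes):
        gid = f"gene_{g:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if g < n_anchored and anchor_bins:
            k, bin_idx = anchor_bins[g % len(anchor_bins)]
            tss = int(bin_idx * res + rng.integers(0, res))
            anchored_loop = k
            true_l2fc = cfg.expression_delta * loop_l2fc[k]
        else:
            b = int(rng.choice(len(bin_p), p=bin_p))
            tss = int(b * res + rng.integers(0, res))
            anchored_loop = None
            true_l2fc = 0.0
        length = int(rng.integers(1000, 10000))
        genes.append(GeneModel(gid, cfg.chrom, strand, tss, length))

        base = float(rng.lognormal(1.0, 1.0))
        reps = {}
        for cond in CONDITIONS:
            shift = true_l2fc if cond == "KO" else 0.0
            noise = (rng.normal(0.0, cfg.expression_sigma, size=3)
                     if cfg.expression_sigma > 0 else np.zeros(3))
            reps[cond] = math.log2(base) + shift + noise
        t, p = (stats.ttest_ind(reps["KO"], reps["Control"], equal_var=False)
                if cfg.expression_sigma > 0 else (np.nan, 1.0 if true_l2fc == 0 else 0.0))
        rows.append({
            "gene_id": gid,
            "fpkm_Control": float(np.mean(2.0 ** reps["Control"])),
            "fpkm_KO": float(np.mean(2.0 ** reps["KO"])),
            "log2fc": float(np.mean(reps["KO"]) - np.mean(reps["Control"])),
            "pvalue": float(p),
        })
        manifest.genes.append({"gene_id": gid, "tss": tss,
                               "anchored_loop": anchored_loop,
                               "true_log2fc": float(true_l2fc)})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
    return genes, df


# ---------------------------------------------------------------------------
# bundle


def simulate_bundle(cfg: SimulationConfig) -> SimulatedBundle:
    """Run all three generators under one seeded RNG stream."""
    from .intervals import merge_condition_peaks

    rng = np.random.default_rng(cfg.seed)
    ctrl, ko, manifest = simulate_contact_maps(cfg, rng)
    (peak_lists, motifs, fragments, library_sizes,
     ctcf_tracks, atac_track, enhancers) = simulate_peaks_and_tracks(cfg, manifest, rng)
    genes, expression = simulate_expression(cfg, manifest, rng)
    merged = merge_condition_peaks(peak_lists["Control"], peak_lists["KO"])
    return SimulatedBundle(
        config=cfg, manifest=manifest,
        maps={"Control": ctrl, "KO": ko},
        peaks=peak_lists, merged_peaks=merged, motifs=motifs,
        fragments=fragments, library_sizes=library_sizes,
        ctcf_tracks=ctcf_tracks, atac_track=atac_track,
        enhancers=enhancers, genes=genes, expression=expression)


def write_fixture_bundle(cfg: SimulationConfig, outdir) -> SimulatedBundle:
    """Emit all fixture files + truth manifest + a checksum file."""
    from .contact import write_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(cfg)

    for cond in CONDITIONS:
        write_matrix(bundle.maps[cond], outdir / f"matrix_{cond}.tsv",
                     outdir / f"bins_{cond}.bed")
        write_bed(bundle.peaks[cond], outdir / f"ctcf_peaks_{cond}.bed",
                  condition=cond)
        with open(outdir / f"ctcf_fragments_{cond}.bed", "w") as fh:
            for f in bundle.fragments[cond]:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")
        _write_bedgraph(bundle.ctcf_tracks[cond], outdir / f"ctcf_track_{cond}.bedgraph")
    _write_bedgraph(bundle.atac_track, outdir / "atac_track.bedgraph")
    write_motifs(bundle.motifs, outdir / "ctcf_motifs.bed")
    with open(outdir / "enhancers.bed", "w") as fh:
        for iv, klass in bundle.enhancers:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{klass}\n")
    write_gene_table(bundle.genes, outdir / "genes.tsv")
    bundle.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    bundle.manifest.to_json(outdir / "truth_manifest.json")

    sums = []
    for p in sorted(outdir.iterdir()):
        if p.name == "checksums.txt" or p.is_dir():
            continue
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        sums.append(f"{digest}  {p.name}")
    (outdir / "checksums.txt").write_text("\n".join(sums) + "\n")
    return bundle


def _write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            fh.write(f"{track.chrom}\t{i * track.bin_size}"
                     f"\t{(i + 1) * track.bin_size}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# scale-free statistical fixtures (no contact maps involved)


def simulate_loop_coupling(n_loops: int, gamma: float = 0.5, sigma: float = 0.2,
                           rng=None, cfg: SimulationConfig | None = None):
    """Planted (CTCF anchor FC, loop-intensity FC) pairs at arbitrary scale.

    Anchor fold changes are drawn from the CTCF class mixture (two anchors
    per loop, averaged on the log scale) and the loop-intensity log2 FC is
    gamma x that value plus Normal(0, sigma) noise -- the same coupling the
    contact-map generator plants, usable for rank-statistics tests at sizes
    where simulating maps would be pointless.
    """
    cfg = cfg or SimulationConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    _, fc = _ctcf_classes(cfg, 2 * n_loops, rng)
    l2 = np.log2(fc)
    ctcf_l2fc = 0.5 * (l2[0::2] + l2[1::2])
    loop_l2fc = gamma * ctcf_l2fc + rng.normal(0.0, sigma, size=n_loops)
    return 2.0 ** ctcf_l2fc, 2.0 ** loop_l2fc


def synthesize_loop_overlap_sets(n_primary: int, n_secondary: int,
                                 n_secondary_overlapping: int,
                                 n_primary_overlapping: int,
                                 resolution: int = 25_000,
                                 chrom: str = "chrS"):
    """Two LoopSets with exactly the prescribed cross-overlap cardinalities.

    Returns (primary, secondary) where ``n_secondary_overlapping`` secondary
    loops overlap (both anchors) at least one primary loop and
    ``n_primary_overlapping`` primary loops overlap at least one secondary
    loop.  When the two overlap counts differ, the surplus primary loops are
    covered by secondary loops whose wider anchors span two adjacent primary
    anchors.  Within each set no two loops overlap.
    """
    from .loops import LoopCall, LoopSet

    if n_secondary_overlapping > n_secondary:
        raise ValueError("overlapping secondary loops exceed secondary set")
    if n_primary_overlapping > n_primary:
        raise ValueError("overlapping primary loops exceed primary set")
    extra = n_primary_overlapping - n_secondary_overlapping
    if extra < 0:
        raise ValueError("need n_primary_overlapping >= n_secondary_overlapping "
                         "(a secondary loop overlapping k primaries, k >= 1)")
    n_double = extra  # secondary loops that each cover two primaries
    n_single = n_secondary_overlapping - n_double
    if n_single < 0:
        raise ValueError("overlap cardinalities not representable")

    res = resolution
    stride = 8 * res       # anchor1 positions; anchor2 shifted far downstream
    offset = (n_primary + n_secondary + 10) * stride

    def anchors(k, width=1, side_shift=0):
        a1 = GenomicInterval(chrom, k * stride + side_shift * res,
                             k * stride + (side_shift + width) * res)
        a2 = GenomicInterval(chrom, offset + k * stride + side_shift * res,
                             offset + k * stride + (side_shift + width) * res)
        return a1, a2

    def mk(a1, a2, qi):
        i = a1.start // res
        j = a2.start // res
        return LoopCall(chrom, a1, a2, res, (i, j),
                        intensity_by_condition={"called": 1.0}, fdr_q=qi)

    primary = [mk(*anchors(k), 0.001) for k in range(n_primary)]

    secondary = []
    # single-overlap secondary loops sit exactly on primary anchors 0..n_single-1
    for k in range(n_single):
        secondary.append(mk(*anchors(k), 0.002))
    # double-overlap loops span primary pairs (n_single+2t, n_single+2t+1):
    # anchor width stride/res + 1 bins covers both primary anchors
    width = stride // res + 1
    for t in range(n_double):
        k = n_single + 2 * t
        if k + 1 >= n_primary_overlapping + 1 and k + 1 >= n_primary:
            raise ValueError("not enough primary loops for double overlaps")
        secondary.append(mk(*anchors(k, width=width), 0.002))
    # non-overlapping secondary loops: shifted half a stride off any primary
    for k in range(n_secondary - n_single - n_double):
        secondary.append(mk(*anchors(n_primary + 2 + k, side_shift=4), 0.002))
    return (LoopSet(primary, provenance={"condition": "primary"}),
            LoopSet(secondary, provenance={"condition": "secondary"}))
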