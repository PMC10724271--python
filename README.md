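# loopforge

Chromatin-architecture comparison between two conditions (a Control and a
knock-out labelled KO) from cis Hi-C contact maps, CTCF ChIP-seq peaks and
RNA-seq expression tables. The package re-implements, as a tested pipeline,
the analysis pattern in which a chromatin regulator's loss **increases CTCF
binding and chromatin-loop intensity without altering A/B compartments or
TADs**, and quantifies how loop-intensity changes couple to CTCF occupancy
and to the expression of loop-anchored genes.

It is aimed at computational epigenomicists who want each step of that
comparison as an importable, individually tested operation, exercised on
synthetic data with planted ground truth rather than on a specific deposited
dataset.

## What it computes

For a binned symmetric cis contact matrix of observed counts *O*:

* **Knight–Ruiz balancing** — weights *w<sub>i</sub>* such that the balanced
  matrix *B<sub>ij</sub> = w<sub>i</sub> O<sub>ij</sub> w<sub>j</sub>* has
  unit row sums; low-coverage bins are masked first.
* **Observed/expected (loop intensity)** — *B<sub>ij</sub> / E(|i−j|)*,
  with *E(d)* the per-diagonal mean of *B*; by construction every
  diagonal's mean O/E is 1.
* **A/B compartments** — the leading eigenvector of the Pearson correlation
  matrix of the O/E map, sign-oriented by gene density (A := positive).
* **Insulation and TADs** — *I<sub>i</sub>* sums balanced contacts in a
  1-Mb window crossing bin *i*; prominent local minima are boundaries,
  consecutive boundaries delimit TADs, and TADs are matched one-to-one
  across conditions (a TAD is *common* when it overlaps exactly one partner
  TAD, reciprocally, with matching flanking boundary regions).
* **Focal loop calling** — a pixel is enriched when its balanced value
  exceeds, by ≥ 50 %, the local expectation from each of four neighborhoods
  (lower-left, horizontal, vertical, donut) and each Poisson upper-tail
  test passes BH FDR < 10 % (per-neighborhood correction); 8-connected
  enriched pixels cluster into one loop at their max-O/E "peak pixel".
  Loop sets are merged (both-anchors-overlap components) and combined into
  non-redundant unions across conditions.
* **CTCF peak dynamics** — merged two-condition peaks classified Up
  (FC > 1.5), Down (FC < 1/1.5) or Neutral (boundaries inclusive), with
  promoter annotation (TSS ± 1 kb), promoter-enrichment statistics and
  per-class expression tests.
* **Integration** — anchor–peak overlap percentages, convergent CTCF motif
  pairs, anchor ChIP enrichment, loops ranked by CTCF fold change into
  quartile groups (two-sided Mann–Whitney between groups), loop-anchored
  gene assignment (promoter overlaps an anchor), enhancer–promoter loop
  flags, and the anchored/outside × up/down chi-square contingency.
* **Synthetic data** — a generator that plants power-law distance decay,
  a compartment plaid, TAD blocks, intra-TAD focal loops, CTCF peak classes
  whose fold changes drive the Control→KO loop-intensity change (coupling
  γ), and gene expression coupled to the anchoring loop, all recorded in a
  machine-readable truth manifest.

## Worked example

```sh
python analysis/01_simulate_fixtures.py --seed 1   # plant the truth
python analysis/04_call_loops.py --seed 1          # call + quantify loops
```

prints, for the default conditions (20-Mb chromosome, 25-kb bins, 10⁶ cis
pairs per condition, 20 planted loops):

```
Control: 21 loops called
KO: 18 loops called
default non-redundant set (KO primary): 25 loops, median intensity FC 0.89
planted-loop recovery: 19/20 within +-1 bin
```

19 of the 20 planted loops are recovered with their peak pixel within one
bin of the planted position; the called set contains a few extra calls from
merged shoulders and noise at the stated 10 % FDR. Similarly,

```sh
python analysis/03_compartments_insulation_tads.py --seed 1
```

```
eigenvector Control vs KO: Pearson R = 0.933
insulation Control vs KO: Spearman rho = 0.994
A/B assignment vs planted truth: 100.0% of unmasked bins
TADs: 20 Control / 19 KO; 18 common, 2 Control-specific, 1 KO-specific
```

shows the intended contrast: loops differ between conditions while the
compartment eigenvector and insulation profile remain nearly identical.
`analysis/06_integrate_loops_genes.py` demonstrates the rank-group
statistic at published scale — 5027 synthetic loops split into CTCF-FC
quartiles show monotonically increasing median loop-intensity log2 FC
(−0.061, +0.098, +0.245, +0.454) with Mann–Whitney p < 10⁻⁶³ for every
rank against rank 1.

A `loopforge` console script exposes the same steps
(`loopforge simulate / run / call-loops / compartments / insulation`).

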