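#!/usr/bin/env python
"""Loop-CTCF-expression integration: the rank-group analyses.

Runs the full pipeline report (loops -> CTCF anchor enrichment ranks ->
loop-anchored gene ranks -> contingency), then demonstrates the same
rank-group machinery at published scale (5027 synthetic loops with the
planted gamma = 0.5 coupling).  Writes results/report/ and
results/rank_coupling_5027.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from loopforge.integrate import rank_group_test, rank_split
from loopforge.pipeline import PipelineConfig, run_cached
from loopforge.simulate import simulate_loop_coupling

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    res = ROOT / "results"
    report = run_cached(PipelineConfig(seed=args.seed), res / "report")
    print("pipeline report -> results/report/report.json")
    for key in ("loops", "ctcf_classes", "anchors"):
        print(f"  {key}: {report[key]}")
    if isinstance(report.get("gene_ranks"), list):
        meds = [g["median"] for g in report["gene_ranks"]]
        print(f"  gene-rank medians (rank0..4): "
              f"{', '.join(f'{m:+.3f}' for m in meds)}")

    ctcf_fc, loop_fc = simulate_loop_coupling(
        5027, gamma=0.5, sigma=0.2, rng=np.random.default_rng(args.seed))
    grouping = rank_split(ctcf_fc, 4)
    table = rank_group_test(grouping, np.log2(loop_fc))
    df = pd.DataFrame(table)
    df.to_csv(res / "rank_coupling_5027.tsv", sep="\t", index=False)
    print("5027-loop synthetic coupling, ranks by CTCF FC:")
    for g in table:
        p = "baseline" if np.isnan(g["p"]) else f"p={g['p']:.3g}"
        print(f"  rank {g['group']}: n={g['n']} median log2FC "
              f"{g['median']:+.3f} ({p})")


if __name__ == "__main__":
    main()
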