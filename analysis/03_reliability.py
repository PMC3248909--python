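#!/usr/bin/env python
"""Test-retest reliability of the simulated committee.

Produces results/reliability.{json,md}: pair counts, session means,
ICC(3,1) and agreement proportions for weights, scores and per-rater value
estimates, plus per-cluster identical percentages — the same table layout
used to report the case study's agreement analysis. Run
01_simulate_committee.py first.
"""

from pathlib import Path

from mcda_panel.io import RunConfig
from mcda_panel.report import run_reliability, write_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = RunConfig(
        panel=ROOT / "results" / "data" / "panel_simulated.csv",
        out_dir=ROOT / "results",
    )
    report = run_reliability(cfg)
    jpath, mpath = write_report(report, cfg.out_dir, "reliability")
    for col, stats in report["columns"].items():
        pct = "" if stats["pct_same"] is None else f", {stats['pct_same']}% identical"
        print(f"{col}: n={stats['n_pairs']}, ICC(3,1)={stats['icc_3_1']:.3f}{pct}")
    print(f"wrote {jpath} and {mpath}")


if __name__ == "__main__":
    main()
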