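#!/usr/bin/env python
"""Run the MCDA appraisal on the simulated committee.

Produces results/appraisal.{json,md}: weight and score summaries per
criterion, the committee value estimate with per-criterion and per-cluster
contribution shares, and the contextual impact tallies. Run
01_simulate_committee.py first.
"""

from pathlib import Path

from mcda_panel.io import RunConfig
from mcda_panel.report import run_appraisal, write_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = RunConfig(
        panel=ROOT / "results" / "data" / "panel_simulated.csv",
        impacts=ROOT / "results" / "data" / "impacts.csv",
        out_dir=ROOT / "results",
    )
    report = run_appraisal(cfg)
    jpath, mpath = write_report(report, cfg.out_dir, "appraisal")
    v = report["value_estimate"]
    print(f"committee value estimate {v['committee_mean_display']} ± "
          f"{v['committee_sd_display']} "
          f"(range {v['min']:.2f}–{v['max']:.2f}) over {report['n_raters']} raters")
    shares = report["value_estimate"]["cluster_share_pct"]
    top = max(shares, key=shares.get)
    print(f"largest cluster share: {top} ({shares[top]}% of committee value)")
    print(f"wrote {jpath} and {mpath}")


if __name__ == "__main__":
    main()
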