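"""Report assembly: appraisal and reliability results as JSON + Markdown.

The JSON report is the machine-readable record (full-precision numbers plus
the rendered, rounded strings); the Markdown report mirrors the same
numbers for humans. Rendering follows one rounding policy — means/SDs to
1 dp, value estimates to 2 dp, percentages to 1 dp, half-up — applied only
at the rendering boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import __version__
from .contextual import tally_impacts
from .core_model import committee_value_estimate, summarize_matrix
from .criteria import CriteriaSet
from .errors import ConfigurationError
from .io import RunConfig, read_impacts, read_panel
from .reliability import (
    agreement_proportions,
    cluster_agreement,
    icc_3_1,
    pair_sessions,
    value_estimate_reliability,
)
from .rounding import round_half_up

__all__ = ["run_appraisal", "run_reliability", "render_markdown"]


def _r(x: float, nd: int) -> float:
    return round_half_up(x, nd)


def _summary_block(matrix, criteria: CriteriaSet, nd: int, sd_ddof: int) -> list[dict]:
    names = {c.id: c.name for c in criteria.core}
    return [
        {
            "criterion_id": s.criterion_id,
            "name": names.get(s.criterion_id, s.criterion_id),
            "mean": s.mean,
            "sd": s.sd,
            "mean_display": _r(s.mean, nd),
            "sd_display": _r(s.sd, nd),
        }
        for s in summarize_matrix(matrix, sd_ddof=sd_ddof)
    ]


def run_appraisal(config: RunConfig) -> dict:
    """Full appraisal: weight/score summaries, value estimate with
    contribution decomposition, and contextual impact tallies.

    Deterministic for fixed inputs; returns the JSON-serializable report.
    """
    criteria = config.criteria()
    nd_sum = config.rounding["summary"]
    nd_val = config.rounding["value"]
    nd_pct = config.rounding["percent"]

    weights = read_panel(config.panel, role="weight", session="test")
    scores = read_panel(config.panel, role="score", session="test")
    estimate = committee_value_estimate(weights, scores, criteria, sd_ddof=config.sd_ddof)

    report: dict = {
        "tool": {"name": "mcda_panel", "version": __version__},
        "config": config.as_dict(),
        "sd_convention": "sample (n-1)" if config.sd_ddof == 1 else "population (n)",
        "n_raters": weights.n_raters,
        "n_criteria": weights.n_criteria,
        "weight_summary": _summary_block(weights, criteria, nd_sum, config.sd_ddof),
        "score_summary": _summary_block(scores, criteria, nd_sum, config.sd_ddof),
        "value_estimate": {
            "committee_mean": estimate.committee_mean,
            "committee_sd": estimate.committee_sd,
            "committee_mean_display": _r(estimate.committee_mean, nd_val),
            "committee_sd_display": _r(estimate.committee_sd, nd_val),
            "per_rater": {r: v for r, v in estimate.per_rater_value.items()},
            "min": min(estimate.per_rater_value.values()),
            "max": max(estimate.per_rater_value.values()),
            "criterion_contribution_pct": {
                cid: _r(100.0 * c / estimate.committee_mean, nd_pct)
                for cid, c in estimate.criterion_mean_contributions.items()
                if estimate.committee_mean > 0
            },
            "cluster_share_pct": {
                cl: _r(100.0 * share, nd_pct)
                for cl, share in estimate.cluster_shares.items()
            },
        },
    }

    if config.impacts is not None:
        impacts = read_impacts(config.impacts)
        report["impact_tallies"] = [t.as_dict() for t in tally_impacts(impacts)]

    return report


def run_reliability(config: RunConfig) -> dict:
    """Test–retest reliability report mirroring the study's agreement table:
    pair counts, session means, ICC(3,1) and agreement proportions for
    weights, scores and per-rater value estimates, plus per-cluster
    identical percentages."""
    criteria = config.criteria()
    nd_pct = config.rounding["percent"]

    panels = {}
    for role in ("weight", "score"):
        for session in ("test", "retest"):
            panels[(role, session)] = read_panel(config.panel, role=role, session=session)

    report: dict = {
        "tool": {"name": "mcda_panel", "version": __version__},
        "config": config.as_dict(),
        "columns": {},
    }
    for role in ("weight", "score"):
        pairs = pair_sessions(panels[(role, "test")], panels[(role, "retest")])
        agree = agreement_proportions(pairs)
        clusters = cluster_agreement(pairs, criteria)
        result = icc_3_1(pairs, agreement=agree, cluster_pct=clusters)
        pct = agree.percentages()
        report["columns"][role + "s"] = {
            "n_pairs": pairs.n,
            "mean_test": result.mean_test,
            "mean_retest": result.mean_retest,
            "icc_3_1": result.icc,
            "between_ms": result.between_ms,
            "error_ms": result.error_ms,
            "pct_same": _r(pct["same"], nd_pct),
            "pct_diff1": _r(pct["diff1"], nd_pct),
            "pct_diff2": _r(pct["diff2"], nd_pct),
            "pct_diff_gt2": _r(pct["diff_gt2"], nd_pct),
            "cluster_pct_same": {cl: _r(p, nd_pct) for cl, p in clusters.items()},
        }

    vres = value_estimate_reliability(
        panels[("weight", "test")], panels[("score", "test")],
        panels[("weight", "retest")], panels[("score", "retest")],
    )
    report["columns"]["value_estimates"] = {
        "n_pairs": vres.n_units,
        "mean_test": vres.mean_test,
        "mean_retest": vres.mean_retest,
        "icc_3_1": vres.icc,
        "between_ms": vres.between_ms,
        "error_ms": vres.error_ms,
        "pct_same": None,  # point-difference categories do not apply
        "pct_diff1": None,
        "pct_diff2": None,
        "pct_diff_gt2": None,
    }
    return report


def _md_table(headers: list[str], rows: list[list]) -> list[str]:
    lines = ["| " + " | ".join(headers) + " |", "|" + "---|" * len(headers)]
    lines += ["| " + " | ".join(str(c) for c in row) + " |" for row in rows]
    return lines


def render_markdown(report: dict) -> str:
    """Render an appraisal or reliability report as Markdown; numbers are
    the same rounded values carried in the JSON."""
    lines = [f"# MCDA panel report (mcda_panel {report['tool']['version']})", ""]
    if "weight_summary" in report:
        v = report["value_estimate"]
        lines += [
            f"Committee: {report['n_raters']} raters x {report['n_criteria']} criteria; "
            f"SD convention: {report['sd_convention']}.",
            "",
            "## Criterion weights (importance, 1-5)",
            "",
            *_md_table(
                ["Criterion", "Mean", "SD"],
                [[s["name"], s["mean_display"], s["sd_display"]] for s in report["weight_summary"]],
            ),
            "",
            "## Criterion scores (performance, 0-3)",
            "",
            *_md_table(
                ["Criterion", "Mean", "SD"],
                [[s["name"], s["mean_display"], s["sd_display"]] for s in report["score_summary"]],
            ),
            "",
            "## Value estimate",
            "",
            f"Committee value estimate: **{v['committee_mean_display']} ± "
            f"{v['committee_sd_display']}** (individual range "
            f"{_r(v['min'], 2)}–{_r(v['max'], 2)}, scale 0 to 1).",
            "",
            "Cluster shares of the committee value:",
            "",
            *_md_table(
                ["Cluster", "% of value"],
                sorted(v["cluster_share_pct"].items(), key=lambda kv: -kv[1]),
            ),
        ]
        if "impact_tallies" in report:
            lines += [
                "",
                "## Contextual impacts",
                "",
                *_md_table(
                    ["Criterion", "Negative", "Neutral", "Positive", "Missing"],
                    [
                        [t["criterion_id"], t["negative"], t["neutral"], t["positive"], t["missing"]]
                        for t in report["impact_tallies"]
                    ],
                ),
            ]
    if "columns" in report:
        cols = report["columns"]

        def fmt(x, nd=3):
            return "NA" if x is None else _r(x, nd)

        lines += [
            "## Test-retest agreement",
            "",
            *_md_table(
                ["", "Weights", "Scores", "Value estimates"],
                [
                    ["Number of pairs"] + [cols[c]["n_pairs"] for c in ("weights", "scores", "value_estimates")],
                    ["Mean of test data"] + [fmt(cols[c]["mean_test"], 2) for c in ("weights", "scores", "value_estimates")],
                    ["Mean of retest data"] + [fmt(cols[c]["mean_retest"], 2) for c in ("weights", "scores", "value_estimates")],
                    ["ICC(3,1)"] + [fmt(cols[c]["icc_3_1"]) for c in ("weights", "scores", "value_estimates")],
                    ["% no difference"] + [fmt(cols[c]["pct_same"], 1) for c in ("weights", "scores", "value_estimates")],
                    ["% differ by 1 point"] + [fmt(cols[c]["pct_diff1"], 1) for c in ("weights", "scores", "value_estimates")],
                    ["% differ by 2 points"] + [fmt(cols[c]["pct_diff2"], 1) for c in ("weights", "scores", "value_estimates")],
                ],
            ),
        ]
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir: str | Path, stem: str) -> tuple[Path, Path]:
    """Write the JSON and Markdown renderings; returns their paths."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigurationError(f"cannot create output dir {out}: {exc}") from exc
    jpath = out / f"{stem}.json"
    mpath = out / f"{stem}.md"
    jpath.write_text(json.dumps(report, indent=2, sort_keys=False) + "\n")
    mpath.write_text(render_markdown(report))
    return jpath, mpath
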