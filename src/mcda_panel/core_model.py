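"""Linear-additive MCDA value model.

Each rater assigns every core criterion an importance weight ``w_x`` on 1–5
and a performance score ``s_x`` on 0–3. Weights are normalized within rater
(``W_x = w_x / sum w``) and scores rescaled to [0,1] by the scale maximum
(``S_x = s_x / 3``); the rater's value estimate is

    V = sum_x W_x * S_x,      V in [0, 1],

anchored so that V = 0 means no value on every criterion and V = 1 maximum
value on every criterion, regardless of the weights. Each term
``V_x = W_x * S_x`` is the criterion's additive contribution. The committee
estimate is the arithmetic mean of rater values; its dispersion uses the
sample (n-1) convention by default.

The score divisor (the scale maximum, 3) is applied explicitly here: the
[0,1] anchoring requires it, and it is what makes the equal-weights closed
form V = mean(score)/3 hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .criteria import CriteriaSet
from .errors import AlignmentError, IncompletePanelError, ScaleViolationError
from .matrices import RatingMatrix

SCORE_MAX = 3

__all__ = [
    "CriterionSummary",
    "ValueEstimateResult",
    "normalize_weights",
    "rater_value_estimate",
    "committee_value_estimate",
    "summarize_matrix",
    "uniform_weight_value",
    "SCORE_MAX",
]


@dataclass(frozen=True)
class CriterionSummary:
    """Committee-level mean and SD of one criterion's ratings."""

    criterion_id: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class ValueEstimateResult:
    """Per-rater value estimates with contribution decomposition.

    Attributes
    ----------
    per_rater_value : rater_id -> V in [0,1].
    per_rater_contributions : rater_id -> {criterion_id -> V_x}.
    committee_mean, committee_sd : mean and dispersion of rater values.
    criterion_mean_contributions : criterion_id -> mean V_x across raters.
    cluster_shares : cluster_id -> fraction of the committee mean value
        contributed by that cluster's criteria (sums to 1 when mean > 0).
    sd_ddof : delta degrees of freedom used for committee_sd (1 = sample).
    """

    per_rater_value: dict[str, float]
    per_rater_contributions: dict[str, dict[str, float]]
    committee_mean: float
    committee_sd: float
    criterion_mean_contributions: dict[str, float]
    cluster_shares: dict[str, float]
    sd_ddof: int = 1


def normalize_weights(weights: dict[str, float]) -> dict[str, float]:
    """Normalize one rater's raw weights to fractions summing to 1.

    ``W_x = w_x / sum_y w_y``. Raw weights must be positive; the elicitation
    scale is 1–5 but any positive weights are accepted so alternative
    elicitation schemes remain usable.
    """
    if not weights:
        raise IncompletePanelError("no weights supplied")
    for cid, w in weights.items():
        if not (w > 0):
            raise ScaleViolationError(
                f"weight for {cid!r} must be positive, got {w!r}"
            )
    total = float(sum(weights.values()))
    return {cid: float(w) / total for cid, w in weights.items()}


def rater_value_estimate(
    weights: dict[str, float],
    scores: dict[str, float],
    score_max: int = SCORE_MAX,
) -> tuple[float, dict[str, float]]:
    """One rater's value estimate and per-criterion contributions.

    Returns ``(V, {criterion_id: V_x})`` with ``V_x = W_x * s_x / score_max``
    and ``V = sum V_x``.
    """
    if set(weights) != set(scores):
        raise AlignmentError(
            "weight and score criterion sets differ: "
            f"{sorted(set(weights) ^ set(scores))}"
        )
    for cid, s in scores.items():
        if not (0 <= s <= score_max):
            raise ScaleViolationError(
                f"score {s!r} for {cid!r} outside [0, {score_max}]"
            )
    norm = normalize_weights(weights)
    contributions = {cid: norm[cid] * (float(scores[cid]) / score_max) for cid in norm}
    value = float(sum(contributions.values()))
    # the anchors are exact by construction: all-max scores give V = 1 and
    # all-min V = 0 whatever the weights, so float drift there is snapped
    if all(s == score_max for s in scores.values()):
        value = 1.0
    elif all(s == 0 for s in scores.values()):
        value = 0.0
    return min(max(value, 0.0), 1.0), contributions


def committee_value_estimate(
    weights: RatingMatrix,
    scores: RatingMatrix,
    criteria: CriteriaSet | None = None,
    sd_ddof: int = 1,
) -> ValueEstimateResult:
    """Value estimates for a whole committee.

    Each rater's estimate is computed independently from that rater's own
    weights and scores, then averaged across the committee. Cluster shares
    divide the committee mean into the fractions contributed by each
    criterion cluster (requires ``criteria``).
    """
    if weights.role != "weight" or scores.role != "score":
        raise AlignmentError(
            f"expected a weight and a score matrix, got {weights.role!r}/{scores.role!r}"
        )
    weights.check_aligned(scores)
    score_max = scores.scale[1]
    raters = weights.rater_ids

    per_value: dict[str, float] = {}
    per_contrib: dict[str, dict[str, float]] = {}
    for r in raters:
        v, contrib = rater_value_estimate(weights.row(r), scores.row(r), score_max)
        per_value[r] = v
        per_contrib[r] = contrib

    vals = np.array(list(per_value.values()), dtype=float)
    mean = float(vals.mean())
    sd = 0.0 if len(vals) <= sd_ddof else float(vals.std(ddof=sd_ddof))

    crit_ids = weights.criterion_ids
    mean_contrib = {
        cid: float(np.mean([per_contrib[r][cid] for r in raters])) for cid in crit_ids
    }
    cluster_shares: dict[str, float] = {}
    if criteria is not None and mean > 0:
        missing = set(crit_ids) - set(criteria.core_ids)
        if missing:
            raise AlignmentError(
                f"criteria registry lacks panel criteria: {sorted(missing)}"
            )
        for cluster_id, members in criteria.clusters.items():
            share = sum(mean_contrib[m] for m in members if m in mean_contrib)
            cluster_shares[cluster_id] = share / mean

    return ValueEstimateResult(
        per_rater_value=per_value,
        per_rater_contributions=per_contrib,
        committee_mean=mean,
        committee_sd=sd,
        criterion_mean_contributions=mean_contrib,
        cluster_shares=cluster_shares,
        sd_ddof=sd_ddof,
    )


def summarize_matrix(matrix: RatingMatrix, sd_ddof: int = 1) -> list[CriterionSummary]:
    """Per-criterion mean and SD of ratings across raters.

    SD uses the sample (n-1) convention by default and is 0 for a single
    rater. Full precision is retained; rendering rounds to 1 dp.
    """
    n = matrix.n_raters
    out = []
    for cid in matrix.criterion_ids:
        col = matrix.values[cid].to_numpy(dtype=float)
        sd = 0.0 if n <= sd_ddof else float(col.std(ddof=sd_ddof))
        out.append(CriterionSummary(cid, float(col.mean()), sd, n))
    return out


def uniform_weight_value(mean_score: float, score_max: int = SCORE_MAX) -> float:
    """Equal-weights closed form of the value model: V = mean(score)/score_max.

    When every rater weights all criteria equally, the normalized weights are
    all 1/n and the committee value estimate collapses to the grand mean
    score divided by the scale maximum.
    """
    if not (0 <= mean_score <= score_max):
        raise ScaleViolationError(f"mean score {mean_score!r} outside [0, {score_max}]")
    return float(mean_score) / score_max
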