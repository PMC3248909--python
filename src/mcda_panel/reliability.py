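"""Test–retest reliability: ICC(3,1) and exact agreement proportions.

Intra-rater stability of the elicitation is quantified two ways:

* **ICC(3,1)** — the single-measure consistency intraclass correlation from
  a two-way mixed ANOVA (units crossed with the two sessions, the session
  effect fixed):

      ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) * EMS),

  with BMS the between-unit mean square, EMS the residual mean square and
  k = 2 sessions. A constant shift between sessions is absorbed by the
  fixed session effect, so it does not reduce the ICC. For weights and
  scores the unit is a rater x criterion cell pooled across criteria
  (9 raters x 14 criteria = 126 units); for value estimates the unit is a
  rater (9 units).

* **Agreement proportions** — the fractions of paired integer ratings whose
  absolute test–retest difference is 0, 1, 2 or more than 2 points. A >2
  category is possible on the 1–5 weight scale and tracked explicitly.

Negative ICCs are reported as computed (with a warning), never clamped; an
ICC on data with no variance at all is an explicit error rather than a
silent 0 or 1. Inter-rater reliability is deliberately out of scope: the
weights capture individual perspectives that are expected to differ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .core_model import committee_value_estimate
from .criteria import CriteriaSet
from .errors import AlignmentError, ConfigurationError, ScaleViolationError, UndefinedICCError
from .matrices import RatingMatrix

__all__ = [
    "PairedObservations",
    "AgreementProportions",
    "ReliabilityResult",
    "pair_sessions",
    "icc_3_1",
    "agreement_proportions",
    "cluster_agreement",
    "value_estimate_reliability",
]


@dataclass(frozen=True)
class PairedObservations:
    """Complete-case test/retest pairs over uniquely identified units.

    Units are rater x criterion cells for weights/scores and raters for
    value estimates. ``criterion_of`` maps unit_id -> criterion_id when the
    units are cells (used for per-cluster breakdowns).
    """

    unit_ids: tuple[str, ...]
    test: np.ndarray
    retest: np.ndarray
    role: str | None = None
    criterion_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.unit_ids) != len(set(self.unit_ids)):
            raise AlignmentError("unit ids are not unique")
        if not (len(self.unit_ids) == len(self.test) == len(self.retest)):
            raise AlignmentError("test/retest lengths differ from unit count")
        object.__setattr__(self, "test", np.asarray(self.test, dtype=float))
        object.__setattr__(self, "retest", np.asarray(self.retest, dtype=float))

    @property
    def n(self) -> int:
        return len(self.unit_ids)


@dataclass(frozen=True)
class AgreementProportions:
    """Exact counts of |test - retest| in {0, 1, 2, >2} plus percentages.

    Fractions are exact (rational); percentage rendering rounds half-up to
    1 dp downstream.
    """

    n_pairs: int
    count_same: int
    count_diff1: int
    count_diff2: int
    count_diff_gt2: int

    def __post_init__(self):
        total = self.count_same + self.count_diff1 + self.count_diff2 + self.count_diff_gt2
        if total != self.n_pairs:
            raise ValueError("agreement categories do not partition the pairs")

    def fraction(self, category: str) -> Fraction:
        counts = {
            "same": self.count_same,
            "diff1": self.count_diff1,
            "diff2": self.count_diff2,
            "diff_gt2": self.count_diff_gt2,
        }
        return Fraction(counts[category], self.n_pairs)

    def percentages(self) -> dict[str, float]:
        return {
            cat: 100.0 * self.fraction(cat)
            for cat in ("same", "diff1", "diff2", "diff_gt2")
        }


@dataclass(frozen=True)
class ReliabilityResult:
    """ICC(3,1) with its ANOVA mean squares and optional agreement block."""

    icc: float
    between_ms: float
    error_ms: float
    session_ms: float
    n_units: int
    k_sessions: int
    mean_test: float
    mean_retest: float
    agreement: AgreementProportions | None = None
    cluster_agreement: dict[str, float] | None = None


def pair_sessions(test: RatingMatrix, retest: RatingMatrix) -> PairedObservations:
    """Pair rater x criterion cells across the two sessions (complete case).

    Raters present in only one session are excluded with a warning; the
    criterion sets must match exactly. A complete 9 x 14 panel yields 126
    pairs.
    """
    if test.role != retest.role:
        raise AlignmentError(f"role mismatch: {test.role!r} vs {retest.role!r}")
    test.check_aligned(retest, raters=False)
    common = [r for r in test.rater_ids if r in set(retest.rater_ids)]
    dropped = sorted((set(test.rater_ids) | set(retest.rater_ids)) - set(common))
    if dropped:
        warnings.warn(
            f"raters present in only one session excluded from pairing: {dropped}",
            stacklevel=2,
        )
    if not common:
        raise AlignmentError("no raters common to test and retest sessions")
    crits = test.criterion_ids
    unit_ids, tvals, rvals, crit_of = [], [], [], {}
    for r in common:
        for c in crits:
            uid = f"{r}:{c}"
            unit_ids.append(uid)
            crit_of[uid] = c
            tvals.append(int(test.values.at[r, c]))
            rvals.append(int(retest.values.at[r, c]))
    return PairedObservations(
        tuple(unit_ids), np.array(tvals, float), np.array(rvals, float),
        role=test.role, criterion_of=crit_of,
    )


def _two_way_mean_squares(pairs: PairedObservations) -> tuple[float, float, float]:
    """(BMS, session MS, EMS) of the unit x session two-way ANOVA, k = 2."""
    x = np.column_stack([pairs.test, pairs.retest])
    n, k = x.shape
    if n < 2:
        raise UndefinedICCError("ICC needs at least 2 units")
    grand = x.mean()
    unit_means = x.mean(axis=1)
    session_means = x.mean(axis=0)
    ss_units = k * float(((unit_means - grand) ** 2).sum())
    ss_sessions = n * float(((session_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = ss_total - ss_units - ss_sessions
    bms = ss_units / (n - 1)
    jms = ss_sessions / (k - 1)
    ems = max(ss_error, 0.0) / ((n - 1) * (k - 1))
    return bms, jms, ems


def icc_3_1(pairs: PairedObservations, agreement: AgreementProportions | None = None,
            cluster_pct: dict[str, float] | None = None) -> ReliabilityResult:
    """ICC(3,1) = (BMS - EMS) / (BMS + EMS) for k = 2 sessions.

    Raises :class:`UndefinedICCError` when the data carry no variance beyond
    a possible fixed session shift (BMS = EMS = 0); emits a warning for
    negative estimates but reports them unclamped.
    """
    bms, jms, ems = _two_way_mean_squares(pairs)
    k = 2
    denom = bms + (k - 1) * ems
    if math.isclose(denom, 0.0, abs_tol=1e-15):
        raise UndefinedICCError(
            "ICC undefined: no between-unit or residual variance "
            "(all values identical up to a session shift)"
        )
    icc = (bms - ems) / denom
    if icc < 0:
        warnings.warn(f"negative ICC(3,1) = {icc:.4f} reported unclamped", stacklevel=2)
    return ReliabilityResult(
        icc=float(icc), between_ms=bms, error_ms=ems, session_ms=jms,
        n_units=pairs.n, k_sessions=k,
        mean_test=float(pairs.test.mean()), mean_retest=float(pairs.retest.mean()),
        agreement=agreement, cluster_agreement=cluster_pct,
    )


def agreement_proportions(pairs: PairedObservations) -> AgreementProportions:
    """Classify each pair by |test - retest| into 0 / 1 / 2 / >2 points."""
    for arr, name in ((pairs.test, "test"), (pairs.retest, "retest")):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ScaleViolationError(
                f"{name} values must be integers for agreement proportions"
            )
    diffs = np.abs(pairs.test - pairs.retest).astype(int)
    return AgreementProportions(
        n_pairs=pairs.n,
        count_same=int((diffs == 0).sum()),
        count_diff1=int((diffs == 1).sum()),
        count_diff2=int((diffs == 2).sum()),
        count_diff_gt2=int((diffs > 2).sum()),
    )


def cluster_agreement(pairs: PairedObservations, criteria: CriteriaSet) -> dict[str, float]:
    """Percentage of identical test–retest pairs within each criterion cluster."""
    if not pairs.criterion_of:
        raise ConfigurationError("pairs carry no criterion mapping; pair cells, not raters")
    clusters = criteria.clusters
    crit_to_cluster = {c: cl for cl, members in clusters.items() for c in members}
    diffs = np.abs(pairs.test - pairs.retest)
    per_cluster: dict[str, list[float]] = {cl: [] for cl in clusters}
    for i, uid in enumerate(pairs.unit_ids):
        crit = pairs.criterion_of[uid]
        if crit not in crit_to_cluster:
            raise ConfigurationError(f"criterion {crit!r} is not mapped to any cluster")
        per_cluster[crit_to_cluster[crit]].append(diffs[i])
    return {
        cl: 100.0 * float(np.mean(np.array(d) == 0))
        for cl, d in per_cluster.items()
        if d
    }


def value_estimate_reliability(
    test_weights: RatingMatrix,
    test_scores: RatingMatrix,
    retest_weights: RatingMatrix,
    retest_scores: RatingMatrix,
) -> ReliabilityResult:
    """ICC(3,1) of per-rater value estimates across sessions (units = raters).

    Each rater's value estimate is computed per session with the additive
    value model, then the 9-unit, 2-session ANOVA is run on those
    continuous values. Point-difference agreement categories do not apply
    to continuous values and are reported as absent.
    """
    test_weights.check_aligned(retest_weights)
    test = committee_value_estimate(test_weights, test_scores)
    retest = committee_value_estimate(retest_weights, retest_scores)
    raters = sorted(test.per_rater_value)
    pairs = PairedObservations(
        tuple(raters),
        np.array([test.per_rater_value[r] for r in raters]),
        np.array([retest.per_rater_value[r] for r in raters]),
        role=None,
    )
    return icc_3_1(pairs)
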