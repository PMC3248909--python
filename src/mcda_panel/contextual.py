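"""Contextual Tool tallies.

Contextual criteria (ethical, political, system-capacity considerations) are
not weighted or scored: each rater tags each one as having a negative,
neutral or positive impact on the appraisal, and the committee-level output
is simply the distribution of those tags. Impacts stay qualitative — they
modulate the interpretation of the value estimate but never enter it
numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

from .matrices import ImpactMatrix

__all__ = ["ImpactTally", "tally_impacts"]


@dataclass(frozen=True)
class ImpactTally:
    """Distribution of impact tags for one contextual criterion.

    ``negative + neutral + positive + missing`` always equals the number of
    raters; ``responders`` counts the non-missing tags. Missing answers are
    reported, never silently dropped.
    """

    criterion_id: str
    negative: int
    neutral: int
    positive: int
    missing: int
    n_raters: int

    @property
    def responders(self) -> int:
        return self.n_raters - self.missing

    def as_dict(self) -> dict:
        return {
            "criterion_id": self.criterion_id,
            "negative": self.negative,
            "neutral": self.neutral,
            "positive": self.positive,
            "missing": self.missing,
            "responders": self.responders,
            "n_raters": self.n_raters,
        }


def tally_impacts(impacts: ImpactMatrix) -> list[ImpactTally]:
    """Count impact tags per contextual criterion across the committee."""
    n = impacts.n_raters
    tallies = []
    for cid in impacts.criterion_ids:
        col = impacts.values[cid]
        counts = {lvl: int((col == lvl).sum()) for lvl in ("negative", "neutral", "positive", "missing")}
        assert sum(counts.values()) == n  # ImpactMatrix admits only the 4 states
        tallies.append(ImpactTally(cid, counts["negative"], counts["neutral"], counts["positive"], counts["missing"], n))
    return tallies
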