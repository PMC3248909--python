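"""Panel data containers: integer rating matrices and qualitative impacts.

A :class:`RatingMatrix` is a complete rater x criterion rectangle of integer
ratings for one elicitation session — either weights (importance of each
criterion, 1–5) or scores (performance of the intervention on each
criterion, 0–3). An :class:`ImpactMatrix` holds the Contextual Tool output:
one categorical impact (negative/neutral/positive, or missing) per rater and
contextual criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    EmptyPanelError,
    IncompletePanelError,
    ScaleViolationError,
)

WEIGHT_SCALE = (1, 5)
SCORE_SCALE = (0, 3)

IMPACT_LEVELS = ("negative", "neutral", "positive", "missing")
#: accepted input spellings -> canonical level ("none" is the elicitation
#: wording for a neutral impact)
IMPACT_ALIASES = {
    "negative": "negative",
    "neutral": "neutral",
    "none": "neutral",
    "positive": "positive",
    "missing": "missing",
    "": "missing",
}

__all__ = [
    "RatingMatrix",
    "ImpactMatrix",
    "WEIGHT_SCALE",
    "SCORE_SCALE",
    "IMPACT_LEVELS",
    "IMPACT_ALIASES",
    "scale_for_role",
]


def scale_for_role(role: str) -> tuple[int, int]:
    if role == "weight":
        return WEIGHT_SCALE
    if role == "score":
        return SCORE_SCALE
    raise ValueError(f"unknown role {role!r}; expected 'weight' or 'score'")


@dataclass(frozen=True)
class RatingMatrix:
    """Complete rater x criterion integer rating rectangle for one session.

    ``values`` is indexed by rater_id with one column per core criterion;
    dtype is integer after validation. Construction validates completeness,
    integrality and scale bounds, so downstream code can assume a clean
    rectangle.
    """

    values: pd.DataFrame
    role: str  # "weight" | "score"
    session: str = "test"  # "test" | "retest"
    scale: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.role not in ("weight", "score"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.session not in ("test", "retest"):
            raise ValueError(f"unknown session {self.session!r}")
        scale = self.scale or scale_for_role(self.role)
        object.__setattr__(self, "scale", tuple(scale))
        df = self.values
        if df.shape[0] == 0:
            raise EmptyPanelError(f"{self.session} {self.role} panel has no raters")
        if df.shape[1] == 0:
            raise IncompletePanelError(f"{self.session} {self.role} panel has no criteria")
        if df.isna().any().any():
            cells = [
                (str(r), str(c))
                for r in df.index
                for c in df.columns
                if pd.isna(df.at[r, c])
            ]
            raise IncompletePanelError(
                f"{self.session} {self.role} panel has missing cells: {cells[:5]}"
            )
        arr = df.to_numpy()
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ScaleViolationError(f"{self.role} ratings must be integers")
        lo, hi = self.scale
        bad = (arr < lo) | (arr > hi)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ScaleViolationError(
                f"{self.role} {arr[r, c]} for rater {df.index[r]!r}, criterion "
                f"{df.columns[c]!r} outside scale [{lo}, {hi}]"
            )
        object.__setattr__(self, "values", df.astype(np.int64))

    @property
    def rater_ids(self) -> tuple[str, ...]:
        return tuple(str(r) for r in self.values.index)

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.values.columns)

    @property
    def n_raters(self) -> int:
        return self.values.shape[0]

    @property
    def n_criteria(self) -> int:
        return self.values.shape[1]

    def row(self, rater_id: str) -> dict[str, int]:
        """One rater's ratings as criterion_id -> int."""
        return {str(c): int(v) for c, v in self.values.loc[rater_id].items()}

    def check_aligned(self, other: "RatingMatrix", *, raters: bool = True) -> None:
        """Raise AlignmentError if criterion (and optionally rater) sets differ."""
        if set(self.criterion_ids) != set(other.criterion_ids):
            raise AlignmentError(
                "criterion sets differ: "
                f"{sorted(set(self.criterion_ids) ^ set(other.criterion_ids))}"
            )
        if raters and set(self.rater_ids) != set(other.rater_ids):
            raise AlignmentError(
                "rater sets differ: "
                f"{sorted(set(self.rater_ids) ^ set(other.rater_ids))}"
            )

    @classmethod
    def from_dict(
        cls,
        cells: dict[tuple[str, str], int],
        role: str,
        session: str = "test",
        scale: tuple[int, int] | None = None,
    ) -> "RatingMatrix":
        """Build from a {(rater_id, criterion_id): value} mapping."""
        raters = list(dict.fromkeys(r for r, _ in cells))
        crits = list(dict.fromkeys(c for _, c in cells))
        df = pd.DataFrame(index=raters, columns=crits, dtype=float)
        for (r, c), v in cells.items():
            df.at[r, c] = v
        return cls(df, role=role, session=session, scale=scale)


@dataclass(frozen=True)
class ImpactMatrix:
    """Rater x contextual-criterion qualitative impacts.

    Values are one of negative/neutral/positive/missing; ``missing`` is a
    legitimate state (a rater may decline a criterion) and is never dropped.
    """

    values: pd.DataFrame

    def __post_init__(self):
        df = self.values
        if df.shape[0] == 0:
            raise EmptyPanelError("impact panel has no raters")
        norm = df.copy()
        for r in df.index:
            for c in df.columns:
                raw = df.at[r, c]
                key = "" if pd.isna(raw) else str(raw).strip().lower()
                if key not in IMPACT_ALIASES:
                    raise ScaleViolationError(
                        f"unknown impact {raw!r} for rater {r!r}, criterion {c!r}; "
                        f"expected one of {sorted(set(IMPACT_ALIASES) - {''})}"
                    )
                norm.at[r, c] = IMPACT_ALIASES[key]
        object.__setattr__(self, "values", norm.astype(str))

    @property
    def rater_ids(self) -> tuple[str, ...]:
        return tuple(str(r) for r in self.values.index)

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.values.columns)

    @property
    def n_raters(self) -> int:
        return self.values.shape[0]
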