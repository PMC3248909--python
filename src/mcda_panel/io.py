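"""Long-format panel CSV readers/writers and run configuration.

One CSV dialect is used everywhere (comma separated, UTF-8, header row):

* rating panels: ``rater_id,criterion_id,session,role,value`` with strict
  integer values — a single file may hold test and retest, weights and
  scores;
* impact tables: ``rater_id,criterion_id,impact``.

Parsing is strict: duplicate cells, out-of-scale or non-integer values and
unknown labels are rejected with the offending row number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .criteria import CriteriaSet, default_criteria_set, load_criteria_set
from .errors import ConfigurationError, EmptyPanelError, PanelParseError
from .matrices import IMPACT_ALIASES, ImpactMatrix, RatingMatrix, scale_for_role

RATING_COLUMNS = ("rater_id", "criterion_id", "session", "role", "value")
IMPACT_COLUMNS = ("rater_id", "criterion_id", "impact")

__all__ = [
    "RunConfig",
    "read_panel",
    "write_panel",
    "read_impacts",
    "write_impacts",
    "load_run_config",
]


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"panel file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyPanelError(f"panel file {path} is empty") from None
    except Exception as exc:  # malformed CSV
        raise PanelParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelParseError(f"{path} lacks required columns {missing}")
    if df.empty:
        raise EmptyPanelError(f"panel file {path} has a header but no rows")
    return df


def read_panel(path: str | Path, role: str, session: str = "test") -> RatingMatrix:
    """Read one rating matrix from a long-format panel CSV.

    Rows are filtered to the requested ``role`` and ``session``; the
    remaining cells must form a complete rectangle of in-scale integers.
    Row numbers in error messages are 1-based data rows (header excluded).
    """
    scale = scale_for_role(role)
    df = _read_csv(path, RATING_COLUMNS)
    sub = df[(df["role"] == role) & (df["session"] == session)]
    if sub.empty:
        raise EmptyPanelError(
            f"{path} holds no rows with role={role!r}, session={session!r}"
        )
    cells: dict[tuple[str, str], int] = {}
    for idx, row in sub.iterrows():
        rownum = idx + 1
        raw = row["value"].strip()
        try:
            value = int(raw)
        except ValueError:
            raise PanelParseError(
                f"{path} row {rownum}: value {raw!r} is not an integer"
            ) from None
        lo, hi = scale
        if not (lo <= value <= hi):
            raise PanelParseError(
                f"{path} row {rownum}: {role} {value} outside scale [{lo}, {hi}]"
            )
        key = (row["rater_id"], row["criterion_id"])
        if key in cells:
            raise PanelParseError(
                f"{path} row {rownum}: duplicate cell for rater {key[0]!r}, "
                f"criterion {key[1]!r}, session {session!r}"
            )
        cells[key] = value
    return RatingMatrix.from_dict(cells, role=role, session=session, scale=scale)


def write_panel(matrices: list[RatingMatrix], path: str | Path) -> None:
    """Write rating matrices to one long-format CSV (lossless round trip)."""
    rows = []
    for m in matrices:
        for r in m.rater_ids:
            for c in m.criterion_ids:
                rows.append(
                    {
                        "rater_id": r,
                        "criterion_id": c,
                        "session": m.session,
                        "role": m.role,
                        "value": int(m.values.at[r, c]),
                    }
                )
    pd.DataFrame(rows, columns=list(RATING_COLUMNS)).to_csv(path, index=False)


def read_impacts(path: str | Path) -> ImpactMatrix:
    """Read a contextual impact table; unknown labels name the row."""
    df = _read_csv(path, IMPACT_COLUMNS)
    cells: dict[tuple[str, str], str] = {}
    for idx, row in df.iterrows():
        rownum = idx + 1
        label = row["impact"].strip().lower()
        if label not in IMPACT_ALIASES:
            raise PanelParseError(
                f"{path} row {rownum}: unknown impact {row['impact']!r} for rater "
                f"{row['rater_id']!r}, criterion {row['criterion_id']!r}"
            )
        key = (row["rater_id"], row["criterion_id"])
        if key in cells:
            raise PanelParseError(f"{path} row {rownum}: duplicate impact cell {key}")
        cells[key] = IMPACT_ALIASES[label]
    raters = list(dict.fromkeys(r for r, _ in cells))
    crits = list(dict.fromkeys(c for _, c in cells))
    df_out = pd.DataFrame("missing", index=raters, columns=crits, dtype=object)
    for (r, c), v in cells.items():
        df_out.at[r, c] = v
    return ImpactMatrix(df_out)


def write_impacts(impacts: ImpactMatrix, path: str | Path) -> None:
    rows = [
        {"rater_id": r, "criterion_id": c, "impact": impacts.values.at[r, c]}
        for r in impacts.rater_ids
        for c in impacts.criterion_ids
    ]
    pd.DataFrame(rows, columns=list(IMPACT_COLUMNS)).to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one appraisal/reliability run.

    The config is echoed into every report for provenance. ``sd_ddof``
    selects the dispersion convention (1 = sample SD, the default).
    """

    panel: Path
    impacts: Path | None = None
    criteria_config: Path | None = None
    out_dir: Path = Path("results")
    seed: int = 0
    sd_ddof: int = 1
    with_reliability: bool = False
    verbose: bool = False
    rounding: dict[str, int] = field(
        default_factory=lambda: {"summary": 1, "value": 2, "percent": 1}
    )

    def __post_init__(self):
        if not Path(self.panel).exists():
            raise ConfigurationError(f"panel file not found: {self.panel}")
        if self.impacts is not None and not Path(self.impacts).exists():
            raise ConfigurationError(f"impact file not found: {self.impacts}")
        if self.criteria_config is not None and not Path(self.criteria_config).exists():
            raise ConfigurationError(f"criteria config not found: {self.criteria_config}")
        if self.sd_ddof not in (0, 1):
            raise ConfigurationError("sd_ddof must be 0 (population) or 1 (sample)")

    def criteria(self) -> CriteriaSet:
        if self.criteria_config is None:
            return default_criteria_set()
        return load_criteria_set(self.criteria_config)

    def as_dict(self) -> dict:
        return {
            "panel": str(self.panel),
            "impacts": None if self.impacts is None else str(self.impacts),
            "criteria_config": None
            if self.criteria_config is None
            else str(self.criteria_config),
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "sd_ddof": self.sd_ddof,
            "with_reliability": self.with_reliability,
            "rounding": dict(self.rounding),
        }


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"run config not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict) or "panel" not in raw:
        raise ConfigurationError(f"run config {path} must define at least 'panel'")
    kwargs = dict(raw)
    for key in ("panel", "impacts", "criteria_config", "out_dir"):
        if kwargs.get(key) is not None:
            kwargs[key] = Path(kwargs[key])
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"unknown key in run config {path}: {exc}") from exc
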