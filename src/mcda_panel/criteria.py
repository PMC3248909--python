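"""Criteria registry for an EVIDEM-style MCDA appraisal.

The quantitative Core Model carries 14 weighted-and-scored criteria grouped
into six clusters; the qualitative Contextual Tool carries 6 criteria whose
impact on the appraisal is tagged negative/neutral/positive rather than
scored. The registry is fully configuration-driven (JSON or YAML); the
default set below reproduces the framework used in the tramadol appraisal.

Four of the default core criteria are not named explicitly in the study
narrative and are completed from the published EVIDEM framework; they are
flagged ``inferred=True`` so reports can mark them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

CONTEXTUAL_CLUSTER = "contextual"

__all__ = [
    "Criterion",
    "CriteriaSet",
    "default_criteria_set",
    "load_criteria_set",
    "CONTEXTUAL_CLUSTER",
]


@dataclass(frozen=True)
class Criterion:
    """One appraisal criterion.

    Parameters
    ----------
    id : stable short token used in data files.
    name : display text.
    cluster_id : cluster token; contextual criteria use the sentinel
        ``"contextual"``.
    kind : ``"core"`` (weighted and scored) or ``"contextual"``
        (qualitative impact only).
    inferred : True when the criterion identity was completed from the
        parent framework rather than named in the study.
    """

    id: str
    name: str
    cluster_id: str
    kind: str = "core"
    inferred: bool = False

    def __post_init__(self):
        if self.kind not in ("core", "contextual"):
            raise ConfigurationError(f"unknown criterion kind {self.kind!r}")
        if self.kind == "contextual" and self.cluster_id != CONTEXTUAL_CLUSTER:
            raise ConfigurationError(
                f"contextual criterion {self.id!r} must use cluster "
                f"{CONTEXTUAL_CLUSTER!r}, got {self.cluster_id!r}"
            )
        if self.kind == "core" and self.cluster_id == CONTEXTUAL_CLUSTER:
            raise ConfigurationError(
                f"core criterion {self.id!r} cannot live in the contextual cluster"
            )


@dataclass(frozen=True)
class CriteriaSet:
    """Ordered registry of core and contextual criteria with cluster map."""

    core: tuple[Criterion, ...]
    contextual: tuple[Criterion, ...] = ()
    cluster_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [c.id for c in self.core] + [c.id for c in self.contextual]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ConfigurationError(f"duplicate criterion ids: {sorted(dupes)}")
        if not self.core:
            raise ConfigurationError("criteria set has no core criteria")
        for c in self.core:
            if c.kind != "core":
                raise ConfigurationError(f"{c.id!r} listed as core but kind={c.kind!r}")
        for c in self.contextual:
            if c.kind != "contextual":
                raise ConfigurationError(
                    f"{c.id!r} listed as contextual but kind={c.kind!r}"
                )

    @property
    def core_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.core)

    @property
    def contextual_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.contextual)

    @property
    def clusters(self) -> dict[str, tuple[str, ...]]:
        """Mapping cluster_id -> ordered member core-criterion ids."""
        out: dict[str, list[str]] = {}
        for c in self.core:
            out.setdefault(c.cluster_id, []).append(c.id)
        return {k: tuple(v) for k, v in out.items()}

    def cluster_of(self, criterion_id: str) -> str:
        for c in self.core:
            if c.id == criterion_id:
                return c.cluster_id
        raise ConfigurationError(f"criterion {criterion_id!r} not in core registry")

    @property
    def n(self) -> int:
        """Number of core criteria (the n of the additive value model)."""
        return len(self.core)

    def to_dict(self) -> dict:
        return {
            "core": [
                {
                    "id": c.id,
                    "name": c.name,
                    "cluster": c.cluster_id,
                    "inferred": c.inferred,
                }
                for c in self.core
            ],
            "contextual": [{"id": c.id, "name": c.name} for c in self.contextual],
            "cluster_names": dict(self.cluster_names),
        }


def _core(cid, name, cluster, inferred=False):
    return Criterion(cid, name, cluster, "core", inferred)


def _ctx(cid, name):
    return Criterion(cid, name, CONTEXTUAL_CLUSTER, "contextual")


_DEFAULT_CLUSTER_NAMES = {
    "disease_impact": "Disease impact",
    "context_of_intervention": "Context of intervention",
    "intervention_outcomes": "Intervention outcomes",
    "type_of_benefits": "Type of benefits",
    "economics": "Economics",
    "quality_of_evidence": "Quality of evidence",
}


def default_criteria_set() -> CriteriaSet:
    """The default 14 + 6 criteria registry.

    Cluster membership for the four inferred criteria follows the parent
    framework; any alternative 14-item registry can be loaded from config.
    """
    core = (
        _core("disease_severity", "Disease severity", "disease_impact"),
        _core("population_size", "Size of population affected by disease", "disease_impact"),
        _core("comparative_limitations", "Comparative interventions limitations", "context_of_intervention"),
        _core("adherence_requirements", "Adherence to requirements of decisionmaking body", "context_of_intervention", inferred=True),
        _core("efficacy", "Improvement of efficacy/effectiveness", "intervention_outcomes"),
        _core("safety_tolerability", "Improvement of safety & tolerability", "intervention_outcomes"),
        _core("patient_reported_outcomes", "Improvement of patient-reported outcomes", "intervention_outcomes"),
        _core("public_health_interest", "Public health interest", "type_of_benefits"),
        _core("medical_service_type", "Type of medical service", "type_of_benefits"),
        _core("budget_impact", "Budget impact on health plan", "economics", inferred=True),
        _core("cost_effectiveness", "Cost-effectiveness of intervention", "economics", inferred=True),
        _core("other_spending_impact", "Impact on other spending", "economics"),
        _core("evidence_relevance_validity", "Relevance and validity of evidence", "quality_of_evidence"),
        _core("reporting_completeness", "Completeness and consistency of reporting evidence", "quality_of_evidence", inferred=True),
    )
    contextual = (
        _ctx("utility_goal", "Goal of healthcare - utility"),
        _ctx("efficiency_opportunity_cost", "Opportunity cost - efficiency"),
        _ctx("population_priority_fairness", "Population priority and access and fairness"),
        _ctx("system_capacity", "System capacity and appropriate use of intervention"),
        _ctx("political_context", "Political/historical context"),
        _ctx("stakeholder_pressures", "Stakeholders pressures"),
    )
    return CriteriaSet(core, contextual, dict(_DEFAULT_CLUSTER_NAMES))


def load_criteria_set(path: str | Path) -> CriteriaSet:
    """Load a criteria registry from a JSON or YAML config file.

    Expected structure::

        core:
          - {id: ..., name: ..., cluster: ..., inferred: false}
        contextual:
          - {id: ..., name: ...}
        cluster_names: {cluster_id: display name}
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"criteria config not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot parse criteria config {path}: {exc}") from exc
    if not isinstance(raw, dict) or "core" not in raw:
        raise ConfigurationError(f"criteria config {path} lacks a 'core' section")
    try:
        core = tuple(
            _core(d["id"], d.get("name", d["id"]), d["cluster"], bool(d.get("inferred", False)))
            for d in raw["core"]
        )
        contextual = tuple(
            _ctx(d["id"], d.get("name", d["id"])) for d in raw.get("contextual", [])
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed criterion entry in {path}: {exc}") from exc
    return CriteriaSet(core, contextual, dict(raw.get("cluster_names", {})))
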