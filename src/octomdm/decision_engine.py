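"""Rule-based therapeutic proposal engine.

Given a validated patient case the engine either proposes a set of
guideline-derived treatment options or escalates to a face-to-face tumor
board.  Escalation triggers, in order of precedence: tumor relapse, distant
metastasis (M1), and no remaining feasible option after filtering the rule
table by what the patient can actually receive.

The rule table itself is data, not code: a versioned JSON config shipped
with the package (``data/rules.json``) mapping (sublocation, stage class)
to candidate regimens.  Users may supply their own table to ``decide``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .case_model import (
    CaseValidationError,
    Histology,
    MCategory,
    PatientCase,
    StageClass,
    TNMStage,
    TumorSite,
    classify_stage,
    validate_case,
)

__all__ = [
    "Modality",
    "Regimen",
    "DecisionKind",
    "EscalationReason",
    "DecisionSet",
    "RuleTable",
    "load_default_rules",
    "candidate_regimens",
    "filter_feasible",
    "escalation_reasons",
    "decide",
]


class Modality(str, enum.Enum):
    surgery = "surgery"
    radiation = "radiation"
    chemotherapy = "chemotherapy"


class DecisionKind(str, enum.Enum):
    options = "options"
    face_to_face = "face_to_face"


class EscalationReason(str, enum.Enum):
    relapse = "relapse"
    metastatic = "metastatic"
    no_feasible_option = "no_feasible_option"
    non_unanimous = "non_unanimous"


# Concurrent chemoradiation is one treatment however it is written; the
# canonical component order is radiation first.
_CHEMORADIATION = frozenset({Modality.radiation, Modality.chemotherapy})

_RENDER_NAMES = {
    Modality.surgery: "Surgery",
    Modality.radiation: "Radiation",
    Modality.chemotherapy: "Chemotherapy",
}


@dataclass(frozen=True)
class Regimen:
    """An ordered combination of treatment modalities.

    Order is treatment sequence: ``(surgery, radiation)`` is surgery with
    adjuvant radiation, a different treatment from definitive radiation.
    The single exception is chemoradiation, which is delivered concurrently:
    any regimen whose components are exactly {radiation, chemotherapy} is
    normalized to ``(radiation, chemotherapy)`` so the two spellings compare
    equal.
    """

    components: tuple[Modality, ...]

    def __post_init__(self) -> None:
        comps = tuple(Modality(c) for c in self.components)
        if not comps:
            raise ValueError("a regimen must contain at least one modality")
        if len(set(comps)) != len(comps):
            raise ValueError(f"modality repeated in regimen: {comps}")
        if frozenset(comps) == _CHEMORADIATION:
            comps = (Modality.radiation, Modality.chemotherapy)
        object.__setattr__(self, "components", comps)

    def __str__(self) -> str:
        return " + ".join(_RENDER_NAMES[m] for m in self.components)

    @property
    def modality_set(self) -> frozenset[Modality]:
        return frozenset(self.components)

    @classmethod
    def of(cls, *modalities: Modality | str) -> "Regimen":
        return cls(tuple(Modality(m) for m in modalities))


def _sorted_regimens(regimens: Iterable[Regimen]) -> list[Regimen]:
    # Stable rendering order: shorter regimens first, then lexical.
    return sorted(regimens, key=lambda r: (len(r.components), [m.value for m in r.components]))


@dataclass(frozen=True)
class DecisionSet:
    """Engine output: alternative regimens, or a face-to-face escalation."""

    kind: DecisionKind
    alternatives: frozenset[Regimen] = frozenset()
    reasons: tuple[EscalationReason, ...] = ()

    def __post_init__(self) -> None:
        if self.kind is DecisionKind.options:
            if not self.alternatives or self.reasons:
                raise ValueError("an options decision needs alternatives and no reasons")
        else:
            if self.alternatives or not self.reasons:
                raise ValueError("a face-to-face decision needs reasons and no alternatives")

    def __str__(self) -> str:
        if self.kind is DecisionKind.face_to_face:
            return "Face-to-face MDM"
        return " or ".join(str(r) for r in _sorted_regimens(self.alternatives))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "alternatives": [
                [m.value for m in r.components] for r in _sorted_regimens(self.alternatives)
            ],
            "reasons": [r.value for r in self.reasons],
            "text": str(self),
        }


@dataclass(frozen=True)
class RuleTable:
    """Mapping (sublocation, early|locally_advanced) -> candidate regimens.

    Metastatic disease never has an entry: M1 always escalates before the
    table is consulted.
    """

    entries: dict[tuple[TumorSite, StageClass], frozenset[Regimen]]
    version: int = 1
    anchored: dict[tuple[TumorSite, StageClass], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (site, stage), regimens in self.entries.items():
            if stage is StageClass.metastatic:
                raise ValueError(f"rule table may not contain metastatic entries ({site.value})")
            if not regimens:
                raise ValueError(f"empty rule entry for ({site.value}, {stage.value})")
        for site in TumorSite:
            for stage in (StageClass.early, StageClass.locally_advanced):
                if (site, stage) not in self.entries:
                    raise ValueError(f"missing rule entry for ({site.value}, {stage.value})")

    @classmethod
    def from_dict(cls, payload: dict) -> "RuleTable":
        entries: dict[tuple[TumorSite, StageClass], frozenset[Regimen]] = {}
        anchored: dict[tuple[TumorSite, StageClass], bool] = {}
        for entry in payload["entries"]:
            key = (TumorSite(entry["site"]), StageClass(entry["stage_class"]))
            entries[key] = frozenset(Regimen.of(*r) for r in entry["regimens"])
            anchored[key] = bool(entry.get("anchored", True))
        return cls(entries=entries, version=int(payload.get("version", 1)), anchored=anchored)

    @classmethod
    def from_json(cls, path) -> "RuleTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def load_default_rules() -> RuleTable:
    """Load the rule table shipped with the package."""
    payload = json.loads(
        resources.files("octomdm").joinpath("data/rules.json").read_text(encoding="utf-8")
    )
    return RuleTable.from_dict(payload)


_DEFAULT_RULES: Optional[RuleTable] = None


def _default_rules() -> RuleTable:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_default_rules()
    return _DEFAULT_RULES


def candidate_regimens(
    site: TumorSite,
    stage: StageClass,
    histology: Histology,
    rules: Optional[RuleTable] = None,
) -> frozenset[Regimen]:
    """Guideline options before feasibility filtering.

    Histology is part of the call signature for forward compatibility (the
    nasopharynx/UCNT pathway is currently implied by the site) but does not
    yet split any entry.
    """
    if stage is StageClass.metastatic:
        raise ValueError("metastatic disease has no rule-table entry; escalate M1 first")
    rules = rules if rules is not None else _default_rules()
    return rules.entries[(site, stage)]


def filter_feasible(regimens: Iterable[Regimen], feasibility) -> frozenset[Regimen]:
    """Keep only regimens whose every component modality is feasible."""
    allowed = set()
    if feasibility.surgery_feasible:
        allowed.add(Modality.surgery)
    if feasibility.radiation_feasible:
        allowed.add(Modality.radiation)
    if feasibility.chemotherapy_feasible:
        allowed.add(Modality.chemotherapy)
    return frozenset(r for r in regimens if r.modality_set <= allowed)


def escalation_reasons(
    case: PatientCase, rules: Optional[RuleTable] = None
) -> list[EscalationReason]:
    """All face-to-face triggers that apply to a case, in precedence order.

    Empty iff :func:`decide` yields options.  The no-feasible-option check is
    evaluated against the stage class the case would have in the absence of
    distant metastasis, so an M1 case with infeasible local treatment reports
    both triggers.
    """
    reasons: list[EscalationReason] = []
    if case.relapse:
        reasons.append(EscalationReason.relapse)
    if case.tnm.m is MCategory.M1:
        reasons.append(EscalationReason.metastatic)
    local_stage = classify_stage(TNMStage(t=case.tnm.t, n=case.tnm.n, m=MCategory.M0))
    candidates = candidate_regimens(case.site, local_stage, case.histology, rules)
    if not filter_feasible(candidates, case.feasibility):
        reasons.append(EscalationReason.no_feasible_option)
    return reasons


def decide(case: PatientCase, rules: Optional[RuleTable] = None) -> DecisionSet:
    """Automatic therapeutic proposal for a valid case.

    Pure and deterministic.  Raises :class:`CaseValidationError` listing the
    violations if the case is invalid.
    """
    violations = validate_case(case)
    if violations:
        raise CaseValidationError(
            "invalid case: " + "; ".join(str(v) for v in violations)
        )
    reasons = escalation_reasons(case, rules)
    if reasons:
        return DecisionSet(kind=DecisionKind.face_to_face, reasons=tuple(reasons))
    stage = classify_stage(case.tnm)
    options = filter_feasible(
        candidate_regimens(case.site, stage, case.histology, rules), case.feasibility
    )
    return DecisionSet(kind=DecisionKind.options, alternatives=options)
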