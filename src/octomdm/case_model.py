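"""Standard cancer patient file: TNM staging, tumor sites, and case validation.

The case file carries the handful of fields an otolaryngology tumor board
actually decides on: tumor sublocation, TNM stage, histology, per-modality
feasibility (surgery / radiation / chemotherapy), relapse status, and
free-text poor-prognosis factors.  Everything downstream (the decision
engine, the review workflow) consumes this model.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

__all__ = [
    "TCategory",
    "NCategory",
    "MCategory",
    "TNMStage",
    "TumorSite",
    "Histology",
    "StageClass",
    "FeasibilityProfile",
    "PatientCase",
    "CaseValidationError",
    "Violation",
    "parse_tnm",
    "render_tnm",
    "classify_stage",
    "validate_case",
]


class TCategory(str, enum.Enum):
    T1 = "T1"
    T2 = "T2"
    T3 = "T3"
    T4 = "T4"
    T4a = "T4a"
    T4b = "T4b"


class NCategory(str, enum.Enum):
    N0 = "N0"
    N1 = "N1"
    N2 = "N2"
    N2a = "N2a"
    N2b = "N2b"
    N2c = "N2c"
    N3 = "N3"


class MCategory(str, enum.Enum):
    M0 = "M0"
    M1 = "M1"


class TumorSite(str, enum.Enum):
    """Closed enumeration of upper aerodigestive tract sublocations.

    ``nasopharynx`` is the site clinicians often call the cavum; the base of
    tongue is kept distinct from the oral (anterior, mobile) tongue because
    the two carry different treatment plans.
    """

    larynx_glottic = "larynx_glottic"
    larynx_supraglottic = "larynx_supraglottic"
    nasopharynx = "nasopharynx"
    oral_tongue = "oral_tongue"
    floor_of_mouth = "floor_of_mouth"
    oropharynx = "oropharynx"
    tongue_base = "tongue_base"
    hypopharynx = "hypopharynx"


class Histology(str, enum.Enum):
    epidermoid_carcinoma = "epidermoid_carcinoma"
    ucnt = "ucnt"  # undifferentiated carcinoma of nasopharyngeal type
    other = "other"


class StageClass(str, enum.Enum):
    """Coarse stage grouping used to key the rule table."""

    early = "early"
    locally_advanced = "locally_advanced"
    metastatic = "metastatic"


@dataclass(frozen=True, order=True)
class TNMStage:
    """A complete T/N/M stage; no field may be missing or partial."""

    t: TCategory
    n: NCategory
    m: MCategory

    def __str__(self) -> str:
        return render_tnm(self)


@dataclass(frozen=True)
class FeasibilityProfile:
    """Whether each treatment modality is feasible for this patient.

    All three flags are plain booleans — a case with an unknown feasibility
    is not a valid case.
    """

    surgery_feasible: bool
    radiation_feasible: bool
    chemotherapy_feasible: bool


@dataclass
class PatientCase:
    """One standard MDM case file.

    ``submitted_at`` absent (None) marks a draft; drafts are editable by the
    submitting resident, submitted cases are frozen (enforced by the review
    workflow, not here).
    """

    case_id: str
    site: TumorSite
    tnm: TNMStage
    histology: Histology
    feasibility: FeasibilityProfile
    relapse: bool
    poor_prognosis_factors: list[str] = field(default_factory=list)
    submitted_by: str = ""
    submitted_at: Optional[datetime] = None

    @property
    def is_draft(self) -> bool:
        return self.submitted_at is None


class CaseValidationError(ValueError):
    """Raised by parsers on malformed input; names the offending token."""


@dataclass(frozen=True)
class Violation:
    """A single validation failure: which field, and why."""

    field: str
    reason: str

    def __str__(self) -> str:
        return f"{self.field}: {self.reason}"


_TNM_RE = re.compile(
    r"^\s*T(?P<t>[1-4](?:[ab])?)\s*N(?P<n>[0-3](?:[abc])?)\s*M(?P<m>[01])\s*$",
    re.IGNORECASE,
)


def parse_tnm(text: str) -> TNMStage:
    """Parse a compact stage string such as ``"T3N2cM0"``.

    Case-insensitive; surrounding and internal whitespace between the three
    categories is ignored.  Raises :class:`CaseValidationError` naming the
    offending token for anything outside the closed T/N/M enumerations.
    """
    if not text or not text.strip():
        raise CaseValidationError("empty TNM stage string")
    match = _TNM_RE.match(text)
    if match is None:
        # Re-scan token by token so the error names what is actually wrong.
        _diagnose_tnm(text)
        raise CaseValidationError(f"malformed TNM stage string: {text!r}")
    t_tok = "T" + match.group("t").lower()
    n_tok = "N" + match.group("n").lower()
    m_tok = "M" + match.group("m")
    try:
        t = TCategory(t_tok)
    except ValueError:
        raise CaseValidationError(f"unknown T category: {t_tok!r}") from None
    try:
        n = NCategory(n_tok)
    except ValueError:
        raise CaseValidationError(f"unknown N category: {n_tok!r}") from None
    return TNMStage(t=t, n=n, m=MCategory(m_tok))


def _diagnose_tnm(text: str) -> None:
    stripped = text.strip()
    for prefix, enum_cls, name in (
        ("T", TCategory, "T"),
        ("N", NCategory, "N"),
        ("M", MCategory, "M"),
    ):
        m = re.search(rf"{prefix}([0-9][abc]?)", stripped, re.IGNORECASE)
        if m is None:
            raise CaseValidationError(f"missing {name} category in {stripped!r}")
        token = prefix + m.group(1).lower()
        if prefix == "M":
            token = token.upper()
        try:
            enum_cls(token)
        except ValueError:
            raise CaseValidationError(f"unknown {name} category: {token!r}") from None


def render_tnm(stage: TNMStage) -> str:
    """Canonical compact rendering; ``parse_tnm(render_tnm(s)) == s``."""
    return f"{stage.t.value}{stage.n.value}{stage.m.value}"


def classify_stage(tnm: TNMStage) -> StageClass:
    """Map a TNM stage onto the coarse class the rule table is keyed by.

    Metastatic iff M1; otherwise early iff T1/T2 with N0; every other M0
    stage is locally advanced.  N2 subcategories (a/b/c) classify exactly
    like bare N2.  Total over all 84 valid stages.
    """
    if tnm.m is MCategory.M1:
        return StageClass.metastatic
    if tnm.t in (TCategory.T1, TCategory.T2) and tnm.n is NCategory.N0:
        return StageClass.early
    return StageClass.locally_advanced


def validate_case(case: PatientCase) -> list[Violation]:
    """Check every field invariant; returns violations instead of raising.

    An empty list means the case is valid input for the decision engine.
    """
    violations: list[Violation] = []

    def bad(field_name: str, reason: str) -> None:
        violations.append(Violation(field=field_name, reason=reason))

    if not isinstance(case.case_id, str) or not case.case_id.strip():
        bad("case_id", "must be a non-empty string")
    if not isinstance(case.site, TumorSite):
        bad("site", f"unknown tumor sublocation: {case.site!r}")
    if not isinstance(case.tnm, TNMStage):
        bad("tnm", f"not a complete TNM stage: {case.tnm!r}")
    else:
        for part, enum_cls in (
            (case.tnm.t, TCategory),
            (case.tnm.n, NCategory),
            (case.tnm.m, MCategory),
        ):
            if not isinstance(part, enum_cls):
                bad("tnm", f"invalid {enum_cls.__name__} member: {part!r}")
    if not isinstance(case.histology, Histology):
        bad("histology", f"unknown histology: {case.histology!r}")
    if not isinstance(case.feasibility, FeasibilityProfile):
        bad("feasibility", "missing feasibility profile")
    else:
        for flag in ("surgery_feasible", "radiation_feasible", "chemotherapy_feasible"):
            value = getattr(case.feasibility, flag)
            if not isinstance(value, bool):
                bad("feasibility", f"{flag} must be a boolean, got {value!r}")
    if not isinstance(case.relapse, bool):
        bad("relapse", f"must be a boolean, got {case.relapse!r}")
    if not isinstance(case.poor_prognosis_factors, list) or any(
        not isinstance(tag, str) for tag in case.poor_prognosis_factors
    ):
        bad("poor_prognosis_factors", "must be a list of text tags")
    if case.submitted_at is not None and not isinstance(case.submitted_at, datetime):
        bad("submitted_at", f"must be a timestamp or absent, got {case.submitted_at!r}")
    return violations
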