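"""Consensus/validation workflow around the decision engine.

A resident submits a case file; the engine attaches its automatic proposal;
the five consultant roles (otolaryngologist, oncologist, radiotherapist,
radiologist, pathologist) each pick a regimen — one of the engine's options,
a colleague's proposed alternative, or their own — or request an in-person
discussion.  A unanimous regimen validates the case; any split, or any
face-to-face request, escalates it.  Cases whose engine decision is already
face-to-face escalate at submission.

State machine: draft -> pending -> {validated | escalated}, plus
draft -> escalated for immediate escalations.  Validated and escalated are
terminal.  Every file must be reviewed within a configurable window,
15 days by default, matching a biweekly in-person meeting schedule.

All timestamps are injected by the caller; nothing here reads a wall clock,
so every behavior is replayable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional, Union

from .case_model import PatientCase, validate_case
from .decision_engine import (
    DecisionKind,
    DecisionSet,
    EscalationReason,
    Regimen,
    RuleTable,
    decide,
)

__all__ = [
    "MemberRole",
    "CONSULTANT_ROLES",
    "ReviewStatus",
    "FaceToFaceRequest",
    "FACE_TO_FACE_REQUEST",
    "Vote",
    "Message",
    "MessageKind",
    "ReviewRecord",
    "WorkflowError",
    "DEFAULT_REVIEW_WINDOW",
    "submit_case",
    "can_edit",
    "record_vote",
    "resolve",
    "list_overdue",
    "request_opinion",
    "generate_report",
    "render_report_markdown",
    "can_view_report",
    "record_to_dict",
    "record_from_dict",
]

DEFAULT_REVIEW_WINDOW = timedelta(days=15)


class MemberRole(str, enum.Enum):
    otolaryngologist = "otolaryngologist"
    oncologist = "oncologist"
    radiotherapist = "radiotherapist"
    radiologist = "radiologist"
    pathologist = "pathologist"
    resident = "resident"


#: The voting faculty: every role except the resident.
CONSULTANT_ROLES: frozenset[MemberRole] = frozenset(
    r for r in MemberRole if r is not MemberRole.resident
)


class ReviewStatus(str, enum.Enum):
    draft = "draft"
    pending = "pending"
    validated = "validated"
    escalated = "escalated"


class WorkflowError(RuntimeError):
    """An operation attempted outside its legal state."""


class FaceToFaceRequest:
    """Sentinel vote choice: discuss this case in person."""

    _instance: Optional["FaceToFaceRequest"] = None

    def __new__(cls) -> "FaceToFaceRequest":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "FaceToFaceRequest()"


FACE_TO_FACE_REQUEST = FaceToFaceRequest()

VoteChoice = Union[Regimen, FaceToFaceRequest]


@dataclass(frozen=True)
class Vote:
    """One consultant's choice; re-voting replaces the earlier vote."""

    role: MemberRole
    choice: VoteChoice
    cast_at: datetime
    proposed_by: Optional[MemberRole] = None  # set when the regimen is a member proposal


class MessageKind(str, enum.Enum):
    imaging_review = "imaging_review"
    pathology_review = "pathology_review"
    expert_opinion = "expert_opinion"


@dataclass(frozen=True)
class Message:
    from_role: MemberRole
    to_role: MemberRole
    case_ref: str
    kind: MessageKind
    body: str
    sent_at: datetime


@dataclass
class ReviewRecord:
    """Per-case workflow state."""

    case: PatientCase
    engine_decision: DecisionSet
    status: ReviewStatus
    deadline: datetime
    votes: dict[MemberRole, Vote] = field(default_factory=dict)
    outcome: Optional[Union[Regimen, DecisionSet]] = None
    escalation_reasons: tuple[EscalationReason, ...] = ()
    proposed_alternatives: dict[MemberRole, Regimen] = field(default_factory=dict)
    messages: list[Message] = field(default_factory=list)

    @property
    def case_ref(self) -> str:
        return self.case.case_id

    def votable_options(self) -> frozenset[Regimen]:
        """Engine options plus every member-proposed alternative."""
        return self.engine_decision.alternatives | frozenset(
            self.proposed_alternatives.values()
        )


def submit_case(
    case: PatientCase,
    now: datetime,
    rules: Optional[RuleTable] = None,
    review_window: timedelta = DEFAULT_REVIEW_WINDOW,
) -> ReviewRecord:
    """Freeze a draft case, attach the engine decision, start the clock.

    A case whose automatic decision is already face-to-face is escalated
    immediately; otherwise it becomes pending with deadline
    ``now + review_window``.
    """
    violations = validate_case(case)
    if violations:
        raise WorkflowError(
            "cannot submit invalid case: " + "; ".join(str(v) for v in violations)
        )
    if not case.is_draft:
        raise WorkflowError(f"case {case.case_id!r} was already submitted")
    submitted = replace(case, submitted_at=now)
    decision = decide(submitted, rules)
    record = ReviewRecord(
        case=submitted,
        engine_decision=decision,
        status=ReviewStatus.pending,
        deadline=now + review_window,
    )
    if decision.kind is DecisionKind.face_to_face:
        record.status = ReviewStatus.escalated
        record.outcome = decision
        record.escalation_reasons = decision.reasons
    return record


def can_edit(record_or_case, actor_role: MemberRole, actor_id: str) -> bool:
    """Only the submitting resident may edit, and only while still a draft."""
    case = record_or_case.case if isinstance(record_or_case, ReviewRecord) else record_or_case
    status_draft = (
        record_or_case.status is ReviewStatus.draft
        if isinstance(record_or_case, ReviewRecord)
        else case.is_draft
    )
    return (
        actor_role is MemberRole.resident
        and actor_id == case.submitted_by
        and status_draft
    )


def record_vote(record: ReviewRecord, vote: Vote) -> ReviewRecord:
    """Store a consultant vote on a pending record (in place; returns record).

    A regimen the engine did not propose is registered as that member's
    alternative and becomes votable by the others.
    """
    if record.status is not ReviewStatus.pending:
        raise WorkflowError(f"cannot vote on a {record.status.value} record")
    if vote.role not in CONSULTANT_ROLES:
        raise WorkflowError("only the five consultant roles may vote")
    if isinstance(vote.choice, Regimen) and vote.choice not in record.votable_options():
        record.proposed_alternatives[vote.role] = vote.choice
        vote = Vote(
            role=vote.role, choice=vote.choice, cast_at=vote.cast_at, proposed_by=vote.role
        )
    record.votes[vote.role] = vote
    return record


def resolve(record: ReviewRecord) -> ReviewRecord:
    """Close the vote: unanimity on one regimen validates, anything else
    (a split, or any face-to-face request) escalates."""
    if record.status is not ReviewStatus.pending:
        raise WorkflowError(f"cannot resolve a {record.status.value} record")
    missing = CONSULTANT_ROLES - set(record.votes)
    if missing:
        names = ", ".join(sorted(r.value for r in missing))
        raise WorkflowError(f"cannot resolve before all consultants vote (missing: {names})")
    choices = {record.votes[role].choice for role in CONSULTANT_ROLES}
    if len(choices) == 1:
        only = next(iter(choices))
        if isinstance(only, Regimen):
            record.status = ReviewStatus.validated
            record.outcome = only
            return record
    record.status = ReviewStatus.escalated
    record.escalation_reasons = (EscalationReason.non_unanimous,)
    record.outcome = DecisionSet(
        kind=DecisionKind.face_to_face, reasons=(EscalationReason.non_unanimous,)
    )
    return record


def list_overdue(records, now: datetime) -> list[str]:
    """Pending cases strictly past their deadline, earliest deadline first.

    The deadline day itself still counts as on time.
    """
    overdue = [
        r for r in records if r.status is ReviewStatus.pending and now > r.deadline
    ]
    return [r.case_ref for r in sorted(overdue, key=lambda r: r.deadline)]


def request_opinion(
    records: dict[str, ReviewRecord],
    from_role: MemberRole,
    to_role: MemberRole,
    case_ref: str,
    kind: MessageKind,
    body: str,
    now: datetime,
) -> Message:
    """Internal mailing: ask a specific member to review imaging/pathology
    or give an expert opinion on an existing case."""
    if case_ref not in records:
        raise WorkflowError(f"unknown case: {case_ref!r}")
    message = Message(
        from_role=from_role,
        to_role=to_role,
        case_ref=case_ref,
        kind=kind,
        body=body,
        sent_at=now,
    )
    records[case_ref].messages.append(message)
    return message


def can_view_report(record: ReviewRecord, actor_role: MemberRole, actor_id: str) -> bool:
    """Consultants see every report; a resident only their own patients'."""
    if actor_role in CONSULTANT_ROLES:
        return True
    return actor_id == record.case.submitted_by


def generate_report(record: ReviewRecord) -> dict:
    """Final report for a closed (validated or escalated) record.

    Returns a JSON-ready dict; use :func:`render_report_markdown` for the
    human-readable rendering.
    """
    if record.status not in (ReviewStatus.validated, ReviewStatus.escalated):
        raise WorkflowError(f"no final report for a {record.status.value} record")
    case = record.case
    if isinstance(record.outcome, Regimen):
        outcome: dict = {"kind": "regimen", "text": str(record.outcome)}
    else:
        outcome = {"kind": "face_to_face", "text": "Face-to-face MDM"}
    return {
        "case_id": case.case_id,
        "site": case.site.value,
        "tnm": str(case.tnm),
        "histology": case.histology.value,
        "relapse": case.relapse,
        "poor_prognosis_factors": list(case.poor_prognosis_factors),
        "submitted_by": case.submitted_by,
        "submitted_at": case.submitted_at.isoformat() if case.submitted_at else None,
        "engine_decision": record.engine_decision.to_dict(),
        "votes": {
            role.value: {
                "choice": str(vote.choice)
                if isinstance(vote.choice, Regimen)
                else "Face-to-face MDM",
                "cast_at": vote.cast_at.isoformat(),
            }
            for role, vote in sorted(record.votes.items(), key=lambda kv: kv[0].value)
        },
        "status": record.status.value,
        "outcome": outcome,
        "escalation_reasons": [r.value for r in record.escalation_reasons],
        "messages": [
            {
                "from": m.from_role.value,
                "to": m.to_role.value,
                "kind": m.kind.value,
                "body": m.body,
                "sent_at": m.sent_at.isoformat(),
            }
            for m in record.messages
        ],
    }


def record_to_dict(record: ReviewRecord) -> dict:
    """JSON-safe snapshot of a review record (see :func:`record_from_dict`)."""
    from .io_fixtures import case_to_dict

    def choice_payload(choice: VoteChoice):
        if isinstance(choice, Regimen):
            return [m.value for m in choice.components]
        return "face_to_face"

    return {
        "case": case_to_dict(record.case),
        "engine_decision": record.engine_decision.to_dict(),
        "status": record.status.value,
        "deadline": record.deadline.isoformat(),
        "votes": [
            {
                "role": vote.role.value,
                "choice": choice_payload(vote.choice),
                "cast_at": vote.cast_at.isoformat(),
                "proposed_by": vote.proposed_by.value if vote.proposed_by else None,
            }
            for vote in record.votes.values()
        ],
        "outcome": (
            None
            if record.outcome is None
            else [m.value for m in record.outcome.components]
            if isinstance(record.outcome, Regimen)
            else "face_to_face"
        ),
        "escalation_reasons": [r.value for r in record.escalation_reasons],
        "proposed_alternatives": {
            role.value: [m.value for m in regimen.components]
            for role, regimen in record.proposed_alternatives.items()
        },
        "messages": [
            {
                "from_role": m.from_role.value,
                "to_role": m.to_role.value,
                "case_ref": m.case_ref,
                "kind": m.kind.value,
                "body": m.body,
                "sent_at": m.sent_at.isoformat(),
            }
            for m in record.messages
        ],
    }


def record_from_dict(payload: dict) -> ReviewRecord:
    """Rebuild a review record from :func:`record_to_dict` output."""
    from .io_fixtures import case_from_dict

    engine = payload["engine_decision"]
    decision = DecisionSet(
        kind=DecisionKind(engine["kind"]),
        alternatives=frozenset(Regimen.of(*r) for r in engine["alternatives"]),
        reasons=tuple(EscalationReason(r) for r in engine["reasons"]),
    )

    def parse_choice(choice):
        if choice == "face_to_face":
            return FACE_TO_FACE_REQUEST
        return Regimen.of(*choice)

    record = ReviewRecord(
        case=case_from_dict(payload["case"]),
        engine_decision=decision,
        status=ReviewStatus(payload["status"]),
        deadline=datetime.fromisoformat(payload["deadline"]),
        votes={
            MemberRole(v["role"]): Vote(
                role=MemberRole(v["role"]),
                choice=parse_choice(v["choice"]),
                cast_at=datetime.fromisoformat(v["cast_at"]),
                proposed_by=MemberRole(v["proposed_by"]) if v.get("proposed_by") else None,
            )
            for v in payload["votes"]
        },
        escalation_reasons=tuple(
            EscalationReason(r) for r in payload.get("escalation_reasons", [])
        ),
        proposed_alternatives={
            MemberRole(role): Regimen.of(*regimen)
            for role, regimen in payload.get("proposed_alternatives", {}).items()
        },
        messages=[
            Message(
                from_role=MemberRole(m["from_role"]),
                to_role=MemberRole(m["to_role"]),
                case_ref=m["case_ref"],
                kind=MessageKind(m["kind"]),
                body=m["body"],
                sent_at=datetime.fromisoformat(m["sent_at"]),
            )
            for m in payload.get("messages", [])
        ],
    )
    outcome = payload.get("outcome")
    if outcome == "face_to_face":
        record.outcome = DecisionSet(
            kind=DecisionKind.face_to_face,
            reasons=record.escalation_reasons or (EscalationReason.non_unanimous,),
        )
    elif outcome is not None:
        record.outcome = Regimen.of(*outcome)
    return record


def render_report_markdown(report: dict) -> str:
    """Plain-text/markdown rendering of :func:`generate_report` output."""
    lines = [
        f"# MDM final report — case {report['case_id']}",
        "",
        f"- Site: {report['site']}",
        f"- Stage: {report['tnm']}",
        f"- Histology: {report['histology']}",
        f"- Relapse: {'yes' if report['relapse'] else 'no'}",
    ]
    if report["poor_prognosis_factors"]:
        lines.append("- Poor prognosis factors: " + ", ".join(report["poor_prognosis_factors"]))
    lines += [
        f"- Submitted by: {report['submitted_by']} at {report['submitted_at']}",
        "",
        f"Automatic proposal: {report['engine_decision']['text']}",
        "",
    ]
    if report["votes"]:
        lines.append("Votes:")
        for role, vote in report["votes"].items():
            lines.append(f"- {role}: {vote['choice']}")
        lines.append("")
    lines.append(f"Outcome ({report['status']}): {report['outcome']['text']}")
    if report["escalation_reasons"]:
        lines.append("Escalation reasons: " + ", ".join(report["escalation_reasons"]))
    if report["messages"]:
        lines.append("")
        lines.append("Messages:")
        for m in report["messages"]:
            lines.append(f"- {m['from']} -> {m['to']} ({m['kind']}): {m['body']}")
    return "\n".join(lines) + "\n"
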