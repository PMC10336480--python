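import random
from datetime import datetime, timedelta

import pytest

from conftest import make_case
from octomdm.decision_engine import DecisionKind, EscalationReason, Regimen
from octomdm.case_model import TumorSite
from octomdm.mdm_workflow import (
    CONSULTANT_ROLES,
    FACE_TO_FACE_REQUEST,
    MemberRole,
    MessageKind,
    ReviewStatus,
    Vote,
    WorkflowError,
    can_edit,
    can_view_report,
    generate_report,
    list_overdue,
    record_from_dict,
    record_to_dict,
    record_vote,
    render_report_markdown,
    request_opinion,
    resolve,
    submit_case,
)

RT = Regimen.of("radiation")
RT_CT = Regimen.of("radiation", "chemotherapy")


def vote_all(record, regimen, when):
    for role in sorted(CONSULTANT_ROLES, key=lambda r: r.value):
        record_vote(record, Vote(role=role, choice=regimen, cast_at=when))
    return record


class TestSubmit:
    def test_deadline_is_fifteen_days_after_submission(self, draft_case):
        record = submit_case(draft_case, datetime(2023, 1, 1))
        assert record.deadline == datetime(2023, 1, 16)
        assert record.status is ReviewStatus.pending

    def test_immediate_escalation_for_relapse_case(self, t0):
        case = make_case(
            site=TumorSite.hypopharynx,
            tnm="T3N2cM0",
            relapse=True,
            surgery=False,
            radiation=False,
        )
        record = submit_case(case, t0)
        assert record.status is ReviewStatus.escalated
        assert record.outcome.kind is DecisionKind.face_to_face
        assert EscalationReason.relapse in record.escalation_reasons

    def test_resubmission_of_a_submitted_case_is_an_error(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        with pytest.raises(WorkflowError):
            submit_case(record.case, t0)

    def test_invalid_case_cannot_be_submitted(self, draft_case, t0):
        draft_case.site = "sinus"
        with pytest.raises(WorkflowError, match="site"):
            submit_case(draft_case, t0)


class TestCanEdit:
    def test_submitting_resident_may_edit_only_drafts(self, draft_case, t0):
        assert can_edit(draft_case, MemberRole.resident, "res-1")
        record = submit_case(draft_case, t0)
        assert not can_edit(record, MemberRole.resident, "res-1")

    def test_other_resident_may_never_edit(self, draft_case):
        assert not can_edit(draft_case, MemberRole.resident, "res-2")

    def test_consultants_do_not_edit_case_files(self, draft_case):
        assert not can_edit(draft_case, MemberRole.oncologist, "res-1")


class TestVoting:
    def test_engine_option_vote_is_stored(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        record_vote(record, Vote(MemberRole.radiotherapist, RT, t0))
        assert record.votes[MemberRole.radiotherapist].choice == RT

    def test_proposed_alternative_becomes_votable(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        alt = Regimen.of("surgery", "radiation")
        assert alt not in record.votable_options()
        record_vote(record, Vote(MemberRole.oncologist, alt, t0))
        assert alt in record.votable_options()
        assert record.votes[MemberRole.oncologist].proposed_by is MemberRole.oncologist

    def test_resident_votes_are_rejected(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        with pytest.raises(WorkflowError):
            record_vote(record, Vote(MemberRole.resident, RT, t0))

    def test_revoting_replaces_the_earlier_vote(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        record_vote(record, Vote(MemberRole.oncologist, RT, t0))
        record_vote(record, Vote(MemberRole.oncologist, Regimen.of("surgery"), t0))
        assert record.votes[MemberRole.oncologist].choice == Regimen.of("surgery")
        assert len(record.votes) == 1

    def test_voting_on_closed_records_is_an_error(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        vote_all(record, RT, t0)
        resolve(record)
        with pytest.raises(WorkflowError):
            record_vote(record, Vote(MemberRole.oncologist, RT, t0))


class TestResolve:
    def test_unanimous_regimen_validates(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        vote_all(record, RT, t0)
        resolve(record)
        assert record.status is ReviewStatus.validated
        assert record.outcome == RT

    def test_any_split_escalates_as_non_unanimous(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        vote_all(record, RT, t0)
        record_vote(record, Vote(MemberRole.pathologist, Regimen.of("surgery"), t0))
        resolve(record)
        assert record.status is ReviewStatus.escalated
        assert record.escalation_reasons == (EscalationReason.non_unanimous,)

    def test_single_face_to_face_request_forces_escalation(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        vote_all(record, RT, t0)
        record_vote(record, Vote(MemberRole.radiologist, FACE_TO_FACE_REQUEST, t0))
        resolve(record)
        assert record.status is ReviewStatus.escalated

    def test_resolving_before_all_five_votes_is_an_error(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        record_vote(record, Vote(MemberRole.oncologist, RT, t0))
        with pytest.raises(WorkflowError, match="missing"):
            resolve(record)

    def test_resolution_is_invariant_to_vote_arrival_order(self, t0):
        outcomes = []
        for order_seed in range(3):
            record = submit_case(make_case(), t0)
            roles = sorted(CONSULTANT_ROLES, key=lambda r: r.value)
            random.Random(order_seed).shuffle(roles)
            choices = {role: RT for role in roles}
            choices[MemberRole.pathologist] = Regimen.of("surgery")
            for role in roles:
                record_vote(record, Vote(role, choices[role], t0))
            resolve(record)
            outcomes.append(record.status)
        assert outcomes == [ReviewStatus.escalated] * 3


class TestOverdue:
    def test_strictly_past_deadline_is_listed_sorted(self, t0):
        r1 = submit_case(make_case(case_id="a"), t0)
        r2 = submit_case(make_case(case_id="b"), t0 - timedelta(days=5))
        now = r1.deadline + timedelta(days=1)
        assert list_overdue([r1, r2], now) == ["b", "a"]

    def test_deadline_day_itself_is_on_time(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        assert list_overdue([record], record.deadline) == []

    def test_closed_records_never_count(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        vote_all(record, RT, t0)
        resolve(record)
        assert list_overdue([record], record.deadline + timedelta(days=40)) == []


class TestMessaging:
    def test_opinion_request_lands_in_the_message_log(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        records = {record.case_ref: record}
        message = request_opinion(
            records,
            MemberRole.oncologist,
            MemberRole.pathologist,
            record.case_ref,
            MessageKind.pathology_review,
            "please re-grade the biopsy",
            t0,
        )
        assert record.messages == [message]

    def test_unknown_case_ref_is_an_error(self, t0):
        with pytest.raises(WorkflowError):
            request_opinion(
                {},
                MemberRole.oncologist,
                MemberRole.radiologist,
                "ghost",
                MessageKind.imaging_review,
                "?",
                t0,
            )


class TestReports:
    def test_validated_report_contains_the_unanimous_regimen(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        vote_all(record, RT_CT, t0)
        resolve(record)
        report = generate_report(record)
        assert report["outcome"] == {"kind": "regimen", "text": "Radiation + Chemotherapy"}
        assert "Radiation + Chemotherapy" in render_report_markdown(report)

    def test_escalated_report_says_face_to_face(self, t0):
        case = make_case(site=TumorSite.tongue_base, tnm="T4N2cM1")
        record = submit_case(case, t0)
        report = generate_report(record)
        assert report["outcome"]["text"] == "Face-to-face MDM"
        assert "metastatic" in report["escalation_reasons"]

    def test_pending_record_has_no_report(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        with pytest.raises(WorkflowError):
            generate_report(record)

    def test_visibility_rules(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        assert can_view_report(record, MemberRole.resident, "res-1")
        assert not can_view_report(record, MemberRole.resident, "res-2")
        for role in CONSULTANT_ROLES:
            assert can_view_report(record, role, "anyone")

    def test_record_round_trips_through_json_dict(self, draft_case, t0):
        record = submit_case(draft_case, t0)
        record_vote(record, Vote(MemberRole.oncologist, RT, t0))
        record_vote(record, Vote(MemberRole.radiologist, FACE_TO_FACE_REQUEST, t0))
        rebuilt = record_from_dict(record_to_dict(record))
        assert rebuilt.status == record.status
        assert rebuilt.votes[MemberRole.oncologist].choice == RT
        assert rebuilt.votes[MemberRole.radiologist].choice is FACE_TO_FACE_REQUEST
        assert rebuilt.deadline == record.deadline


def test_state_machine_fuzzer_never_breaks_invariants():
    """Random legal operation sequences: the only transitions are
    draft->pending->{validated|escalated} and draft->escalated, terminal
    states never change, and escalations always carry a reason."""
    rng = random.Random(2023)
    sites = sorted(TumorSite, key=lambda s: s.value)
    tnms = ["T1N0M0", "T2N0M0", "T3N1M0", "T4N2cM0", "T2N1M1"]
    choices = [RT, RT_CT, Regimen.of("surgery"), FACE_TO_FACE_REQUEST]
    for trial in range(400):
        case = make_case(
            case_id=f"fuzz-{trial}",
            site=rng.choice(sites),
            tnm=rng.choice(tnms),
            surgery=rng.random() > 0.2,
            radiation=rng.random() > 0.2,
            chemotherapy=rng.random() > 0.2,
            relapse=rng.random() < 0.15,
        )
        t = datetime(2023, 1, 1) + timedelta(hours=trial)
        record = submit_case(case, t)
        assert record.status in (ReviewStatus.pending, ReviewStatus.escalated)
        seen = [record.status]
        for _ in range(rng.randint(0, 25)):
            op = rng.choice(["vote", "resolve", "overdue"])
            if op == "vote" and record.status is ReviewStatus.pending:
                role = rng.choice(sorted(CONSULTANT_ROLES, key=lambda r: r.value))
                record_vote(record, Vote(role, rng.choice(choices), t))
            elif op == "resolve" and record.status is ReviewStatus.pending:
                if CONSULTANT_ROLES <= set(record.votes):
                    resolve(record)
            else:
                list_overdue([record], t + timedelta(days=rng.randint(0, 30)))
            seen.append(record.status)
        for before, after in zip(seen, seen[1:]):
            if before in (ReviewStatus.validated, ReviewStatus.escalated):
                assert after is before
            elif before is ReviewStatus.pending:
                assert after in (
                    ReviewStatus.pending,
                    ReviewStatus.validated,
                    ReviewStatus.escalated,
                )
        if record.status is ReviewStatus.escalated:
            assert record.outcome.kind is DecisionKind.face_to_face
            assert record.escalation_reasons
        if record.status is ReviewStatus.validated:
            assert isinstance(record.outcome, Regimen)
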