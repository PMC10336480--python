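"""Case I/O, packaged validation fixtures, and the seeded case generator.

Case records travel as JSON (one object per case, or a list) or as a CSV
roster; both use the flat schema::

    case_id, site, tnm, histology,
    surgery_feasible, radiation_feasible, chemotherapy_feasible,
    relapse, poor_prognosis_factors, submitted_by, submitted_at

with ``tnm`` as a compact stage string ("T3N2cM0"), booleans as true/false,
``poor_prognosis_factors`` as a semicolon-joined list in CSV, and
timestamps in ISO-8601.

The ten fictitious validation cases ship with the package together with the
raw automatic/expert decision strings; the seeded generator produces
arbitrary numbers of additional valid cases for property testing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .case_model import (
    CaseValidationError,
    FeasibilityProfile,
    Histology,
    PatientCase,
    TumorSite,
    parse_tnm,
    render_tnm,
    validate_case,
)

__all__ = [
    "FixtureCase",
    "GeneratorConfig",
    "load_table1_fixtures",
    "generate_cases",
    "case_to_dict",
    "case_from_dict",
    "read_cases",
    "write_cases",
]

_CSV_COLUMNS = [
    "case_id",
    "site",
    "tnm",
    "histology",
    "surgery_feasible",
    "radiation_feasible",
    "chemotherapy_feasible",
    "relapse",
    "poor_prognosis_factors",
    "submitted_by",
    "submitted_at",
]


@dataclass(frozen=True)
class FixtureCase:
    """A packaged validation case with its two raw decision strings."""

    case: PatientCase
    expected_auto: str
    expected_expert: str


def case_to_dict(case: PatientCase) -> dict:
    return {
        "case_id": case.case_id,
        "site": case.site.value,
        "tnm": render_tnm(case.tnm),
        "histology": case.histology.value,
        "surgery_feasible": case.feasibility.surgery_feasible,
        "radiation_feasible": case.feasibility.radiation_feasible,
        "chemotherapy_feasible": case.feasibility.chemotherapy_feasible,
        "relapse": case.relapse,
        "poor_prognosis_factors": list(case.poor_prognosis_factors),
        "submitted_by": case.submitted_by,
        "submitted_at": case.submitted_at.isoformat() if case.submitted_at else None,
    }


def case_from_dict(payload: dict, where: str = "case") -> PatientCase:
    """Build a case from the flat schema; errors name the offending field."""
    missing = [
        key
        for key in ("case_id", "site", "tnm")
        if key not in payload or payload[key] in (None, "")
    ]
    if missing:
        raise CaseValidationError(f"{where}: missing required field(s): {', '.join(missing)}")
    try:
        site = TumorSite(str(payload["site"]))
    except ValueError:
        raise CaseValidationError(
            f"{where}: unknown tumor sublocation: {payload['site']!r}"
        ) from None
    try:
        histology = Histology(str(payload.get("histology", "other")))
    except ValueError:
        raise CaseValidationError(
            f"{where}: unknown histology: {payload['histology']!r}"
        ) from None
    try:
        tnm = parse_tnm(str(payload["tnm"]))
    except CaseValidationError as exc:
        raise CaseValidationError(f"{where}: {exc}") from None
    submitted_at = payload.get("submitted_at") or None
    if isinstance(submitted_at, str):
        submitted_at = datetime.fromisoformat(submitted_at)
    tags = payload.get("poor_prognosis_factors", [])
    if isinstance(tags, str):
        tags = [t.strip() for t in tags.split(";") if t.strip()]
    return PatientCase(
        case_id=str(payload["case_id"]),
        site=site,
        tnm=tnm,
        histology=histology,
        feasibility=FeasibilityProfile(
            surgery_feasible=_as_bool(payload, "surgery_feasible", where),
            radiation_feasible=_as_bool(payload, "radiation_feasible", where),
            chemotherapy_feasible=_as_bool(payload, "chemotherapy_feasible", where),
        ),
        relapse=_as_bool(payload, "relapse", where),
        poor_prognosis_factors=list(tags),
        submitted_by=str(payload.get("submitted_by", "")),
        submitted_at=submitted_at,
    )


def _as_bool(payload: dict, key: str, where: str) -> bool:
    if key not in payload:
        raise CaseValidationError(f"{where}: missing required field(s): {key}")
    value = payload[key]
    if isinstance(value, bool):
        return value
    if isinstance(value, str) and value.strip().lower() in ("true", "false"):
        return value.strip().lower() == "true"
    raise CaseValidationError(f"{where}: {key} must be true/false, got {value!r}")


def load_table1_fixtures() -> list[FixtureCase]:
    """The ten packaged validation cases, in published row order."""
    payload = json.loads(
        resources.files("octomdm")
        .joinpath("data/table1_cases.json")
        .read_text(encoding="utf-8")
    )
    fixtures = [
        FixtureCase(
            case=case_from_dict(item["case"], where=f"fixture row {i + 1}"),
            expected_auto=item["expected_auto"],
            expected_expert=item["expected_expert"],
        )
        for i, item in enumerate(payload["fixtures"])
    ]
    if len(fixtures) != 10:
        raise RuntimeError(f"packaged fixture file is corrupted: expected 10 cases, found {len(fixtures)}")
    for fixture in fixtures:
        problems = validate_case(fixture.case)
        if problems:
            raise RuntimeError(
                f"packaged fixture {fixture.case.case_id} is corrupted: "
                + "; ".join(str(p) for p in problems)
            )
    return fixtures


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling distribution for synthetic cases.

    Defaults reflect an upper-aerodigestive-tract tumor-board caseload:
    sites uniform over the eight sublocations, a roughly even split of early
    versus locally advanced presentations with a ~10% metastatic fraction,
    each modality independently infeasible 15% of the time (comorbidity,
    prior irradiation, unresectability), and a 10% relapse rate.  Histology
    follows the site: nasopharyngeal cases are UCNT, all others epidermoid
    carcinoma.
    """

    n: int = 100
    seed: int = 0
    site_weights: dict[str, float] = field(default_factory=dict)  # empty = uniform
    stage_weights: tuple[float, float, float] = (0.45, 0.45, 0.10)  # early, adv, M1
    infeasibility_rate: float = 0.15
    relapse_rate: float = 0.10

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not 0.0 <= self.infeasibility_rate <= 1.0:
            raise ValueError("infeasibility_rate must lie in [0, 1]")
        if not 0.0 <= self.relapse_rate <= 1.0:
            raise ValueError("relapse_rate must lie in [0, 1]")
        if len(self.stage_weights) != 3 or any(w < 0 for w in self.stage_weights):
            raise ValueError("stage_weights must be three non-negative numbers")
        if sum(self.stage_weights) <= 0:
            raise ValueError("stage_weights must not all be zero")
        for site, weight in self.site_weights.items():
            TumorSite(site)
            if weight < 0:
                raise ValueError(f"negative site weight for {site}")


_EARLY_T = ["T1", "T2"]
_ADV_T = ["T1", "T2", "T3", "T4", "T4a", "T4b"]
_N_ALL = ["N0", "N1", "N2", "N2a", "N2b", "N2c", "N3"]


def generate_cases(config: GeneratorConfig) -> list[PatientCase]:
    """Draw ``config.n`` valid draft cases; identical seed, identical output.

    One explicit NumPy generator is threaded through all sampling — there is
    no global random state.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sites = sorted(TumorSite, key=lambda s: s.value)
    if config.site_weights:
        weights = np.array([config.site_weights.get(s.value, 0.0) for s in sites])
        if weights.sum() <= 0:
            raise ValueError("site_weights must give positive total mass")
    else:
        weights = np.ones(len(sites))
    site_p = weights / weights.sum()
    stage_p = np.asarray(config.stage_weights, dtype=float)
    stage_p = stage_p / stage_p.sum()

    cases: list[PatientCase] = []
    for i in range(config.n):
        site = sites[rng.choice(len(sites), p=site_p)]
        stage_kind = rng.choice(3, p=stage_p)
        if stage_kind == 0:  # early: T1-T2 N0 M0
            tnm_text = f"{_EARLY_T[rng.integers(len(_EARLY_T))]}N0M0"
        elif stage_kind == 1:  # locally advanced: M0, not (T1-T2 N0)
            while True:
                t = _ADV_T[rng.integers(len(_ADV_T))]
                n = _N_ALL[rng.integers(len(_N_ALL))]
                if not (t in _EARLY_T and n == "N0"):
                    break
            tnm_text = f"{t}{n}M0"
        else:  # metastatic
            tnm_text = f"{_ADV_T[rng.integers(len(_ADV_T))]}{_N_ALL[rng.integers(len(_N_ALL))]}M1"
        histology = Histology.ucnt if site is TumorSite.nasopharynx else Histology.epidermoid_carcinoma
        feasibility = FeasibilityProfile(
            surgery_feasible=bool(rng.random() >= config.infeasibility_rate),
            radiation_feasible=bool(rng.random() >= config.infeasibility_rate),
            chemotherapy_feasible=bool(rng.random() >= config.infeasibility_rate),
        )
        cases.append(
            PatientCase(
                case_id=f"SYN-{config.seed}-{i:05d}",
                site=site,
                tnm=parse_tnm(tnm_text),
                histology=histology,
                feasibility=feasibility,
                relapse=bool(rng.random() < config.relapse_rate),
                poor_prognosis_factors=[],
                submitted_by="synthetic",
                submitted_at=None,
            )
        )
    return cases


def read_cases(path, fmt: Optional[str] = None) -> list[PatientCase]:
    """Read a case roster from JSON or CSV; duplicate case_ids are an error."""
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        records = payload if isinstance(payload, list) else [payload]
        cases = [case_from_dict(rec, where=f"record {i + 1}") for i, rec in enumerate(records)]
    elif fmt == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise CaseValidationError("CSV file has no header row")
            missing = [c for c in _CSV_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise CaseValidationError(
                    "CSV header missing column(s): " + ", ".join(missing)
                )
            cases = [
                case_from_dict(row, where=f"row {i + 2}") for i, row in enumerate(reader)
            ]
    else:
        raise ValueError(f"unknown format: {fmt!r} (expected 'json' or 'csv')")
    seen: set[str] = set()
    for case in cases:
        if case.case_id in seen:
            raise CaseValidationError(f"duplicate case_id: {case.case_id!r}")
        seen.add(case.case_id)
    return cases


def write_cases(cases: Sequence[PatientCase], path, fmt: Optional[str] = None) -> None:
    """Write a case roster as JSON or CSV; ``read_cases`` round-trips it."""
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([case_to_dict(c) for c in cases], fh, indent=2)
            fh.write("\n")
    elif fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for case in cases:
                row = case_to_dict(case)
                row["poor_prognosis_factors"] = ";".join(row["poor_prognosis_factors"])
                row["surgery_feasible"] = str(row["surgery_feasible"]).lower()
                row["radiation_feasible"] = str(row["radiation_feasible"]).lower()
                row["chemotherapy_feasible"] = str(row["chemotherapy_feasible"]).lower()
                row["relapse"] = str(row["relapse"]).lower()
                row["submitted_at"] = row["submitted_at"] or ""
                writer.writerow(row)
    else:
        raise ValueError(f"unknown format: {fmt!r} (expected 'json' or 'csv')")
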