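"""Decision-string canonicalization and Cohen's kappa.

Automatic and expert tumor-board decisions are free-ish text ("Radiation +
chemotherapy", "Radiation and chemotherapy", "Surgery ± radiation",
"Face-to-face MDMs").  To score agreement, both are first reduced to a
canonical form — a set of regimens, or a face-to-face marker — and two
decisions agree iff their canonical forms are equal.  Each distinct
canonical decision is then one nominal category for an unweighted Cohen's
kappa:

    kappa = (p_o - p_e) / (1 - p_e)

with p_o the observed proportion of agreeing pairs and p_e the chance
agreement expected from the two raters' marginal distributions.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Sequence

from .decision_engine import DecisionKind, DecisionSet, Modality, Regimen

__all__ = [
    "CanonicalDecision",
    "AgreementResult",
    "DecisionParseError",
    "canonicalize",
    "canonicalize_decision_set",
    "cohen_kappa",
    "interpret_kappa",
]


class DecisionParseError(ValueError):
    """Raised on an unrecognized token in a decision string."""


@dataclass(frozen=True)
class CanonicalDecision:
    """Equality-comparable form of a decision string.

    ``kind=face_to_face`` carries no alternatives; ``kind=options`` carries a
    non-empty set of regimens.  Two decision strings are "in agreement" iff
    their canonical values compare equal.
    """

    kind: DecisionKind
    alternatives: frozenset[Regimen] = frozenset()

    def __post_init__(self) -> None:
        if self.kind is DecisionKind.options and not self.alternatives:
            raise ValueError("an options decision must carry at least one regimen")
        if self.kind is DecisionKind.face_to_face and self.alternatives:
            raise ValueError("a face-to-face decision carries no regimens")

    def __str__(self) -> str:
        if self.kind is DecisionKind.face_to_face:
            return "Face-to-face MDM"
        rendered = sorted(
            (" + ".join(m.value.capitalize() for m in r.components) for r in self.alternatives),
        )
        return " or ".join(rendered)


FACE_TO_FACE = CanonicalDecision(kind=DecisionKind.face_to_face)

# All the dash/hyphen code points seen in published tables, folded to ASCII.
_DASHES = dict.fromkeys(map(ord, "‐‑‒–—―−"), "-")

_MODALITY_WORDS = {
    "surgery": Modality.surgery,
    "radiation": Modality.radiation,
    "radiotherapy": Modality.radiation,
    "chemotherapy": Modality.chemotherapy,
    "chemo": Modality.chemotherapy,
}

_FTF_RE = re.compile(r"^face\s*-\s*to\s*-\s*face\s+mdms?\.?$")


def _normalize(text: str) -> str:
    text = text.translate(_DASHES).replace(" ", " ")
    return re.sub(r"\s+", " ", text).strip().lower()


def _parse_combination(text: str) -> Regimen:
    # "surgery + radiation" / "radiation and chemotherapy" -> one regimen,
    # component order preserved (order = treatment sequence).
    tokens = [t.strip() for t in re.split(r"\+|\band\b", text) if t.strip()]
    if not tokens:
        raise DecisionParseError(f"empty treatment combination in {text!r}")
    modalities = []
    for token in tokens:
        if token not in _MODALITY_WORDS:
            raise DecisionParseError(f"unrecognized token: {token!r}")
        modalities.append(_MODALITY_WORDS[token])
    return Regimen(tuple(modalities))


def canonicalize(text: str) -> CanonicalDecision:
    """Reduce a raw decision string to its canonical comparable form.

    Grammar of the table dialect: ``or`` separates alternatives; ``+`` and
    ``and`` combine modalities into one regimen; ``X ± Y`` expands to the
    two alternatives ``X`` and ``X + Y``; any capitalization or
    pluralization of "Face-to-face MDM" (with any dash variant) maps to the
    face-to-face marker.  Raises :class:`DecisionParseError` naming the
    first unrecognized token.
    """
    if not text or not text.strip():
        raise DecisionParseError("empty decision string")
    norm = _normalize(text)
    if _FTF_RE.match(norm):
        return FACE_TO_FACE
    alternatives: set[Regimen] = set()
    for alt in norm.split(" or "):
        alt = alt.strip()
        if "±" in alt:
            base_text, _, optional_text = alt.partition("±")
            base = _parse_combination(base_text)
            optional = _parse_combination(optional_text)
            alternatives.add(base)
            alternatives.add(Regimen(base.components + optional.components))
        else:
            alternatives.add(_parse_combination(alt))
    return CanonicalDecision(kind=DecisionKind.options, alternatives=frozenset(alternatives))


def canonicalize_decision_set(decision: DecisionSet) -> CanonicalDecision:
    """Canonical form of an engine output (escalation reasons are dropped)."""
    if decision.kind is DecisionKind.face_to_face:
        return FACE_TO_FACE
    return CanonicalDecision(kind=DecisionKind.options, alternatives=decision.alternatives)


@dataclass(frozen=True)
class AgreementResult:
    """Observed/expected agreement and chance-corrected kappa."""

    p_observed: float
    p_expected: float
    kappa: float
    n_items: int
    label: str

    def to_dict(self) -> dict:
        return {
            "p_observed": self.p_observed,
            "p_expected": self.p_expected,
            "kappa": self.kappa,
            "n_items": self.n_items,
            "label": self.label,
        }


def cohen_kappa(pairs: Sequence[tuple[Hashable, Hashable]]) -> AgreementResult:
    """Unweighted Cohen's kappa over paired ratings.

    Categories are the distinct values observed in either column; any
    hashable labels work (canonical decisions included).  With a single
    shared category (p_e = 1), kappa is defined as 1 under perfect agreement
    and is an error otherwise.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("kappa needs at least 2 rating pairs")
    first = Counter(a for a, _ in pairs)
    second = Counter(b for _, b in pairs)
    p_observed = sum(1 for a, b in pairs if a == b) / n
    categories = set(first) | set(second)
    p_expected = sum(first[c] * second[c] for c in categories) / (n * n)
    if p_expected >= 1.0:
        if p_observed == 1.0:
            kappa = 1.0
        else:
            raise ValueError(
                "kappa undefined: expected agreement is 1 but observed agreement is not"
            )
    else:
        kappa = (p_observed - p_expected) / (1.0 - p_expected)
    return AgreementResult(
        p_observed=p_observed,
        p_expected=p_expected,
        kappa=kappa,
        n_items=n,
        label=interpret_kappa(max(-1.0, min(1.0, kappa))),
    )


_BANDS = (
    (0.0, "poor"),
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost perfect"),
)


def interpret_kappa(kappa: float) -> str:
    """Landis–Koch interpretation band for a kappa in [-1, 1].

    <=0 poor; (0,0.2] slight; (0.2,0.4] fair; (0.4,0.6] moderate;
    (0.6,0.8] substantial; (0.8,1] almost perfect.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    for upper, label in _BANDS:
        if kappa <= upper:
            return label
    return "almost perfect"  # pragma: no cover - unreachable
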