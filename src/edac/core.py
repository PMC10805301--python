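"""The EDAC decision table.

The Emergency Department Avoidability Classification (EDAC) is a deterministic
rule over five chart variables that are routinely recorded in administrative ED
data: patient age, triage acuity (CTAS 1-5), whether a specialist was consulted
in the ED, the main physician intervention (a CCI-style procedure code), and
the visit outcome.  A visit is

* **avoidable** when the patient was 18-70 years old, triaged CTAS 4 or 5
  (less-urgent / non-urgent), saw no specialist, received a main intervention
  that a subacute primary-care setting could deliver (code in the configured
  registry), and was discharged home;
* **potentially avoidable** under the same conjunction but with CTAS 3
  (urgent);
* **not avoidable** in every other case.

The registry of subacute-manageable intervention codes is configuration, not
code: it is supplied by the user as a plain-text list (one code per line) or a
config entry, and membership is tested after canonicalisation (trim +
uppercase).
"""

from __future__ import annotations

import enum
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


class ValidationError(ValueError):
    """A visit record is missing or violates a required criterion field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class EDACClass(enum.IntEnum):
    """The three EDAC classes, ordered for ordinal analyses.

    The integer order NOT_AVOIDABLE < POTENTIALLY_AVOIDABLE < AVOIDABLE is the
    ordinal ranking used by the association analyses (the not-avoidable class
    is the referent).
    """

    NOT_AVOIDABLE = 0
    POTENTIALLY_AVOIDABLE = 1
    AVOIDABLE = 2

    @classmethod
    def from_label(cls, label: str) -> "EDACClass":
        return cls[label.strip().upper().replace("-", "_").replace(" ", "_")]

    @property
    def label(self) -> str:
        return self.name.lower()


#: Visit outcomes recognised by the classifier.
OUTCOMES = ("discharged", "admission", "other")

#: Age window (inclusive on both ends) for the avoidable / potentially
#: avoidable classes.
AGE_MIN, AGE_MAX = 18, 70


@dataclass(frozen=True)
class EDVisit:
    """One ED attendance.

    The five criterion fields (``age``, ``ctas``, ``specialist_consult``,
    ``main_intervention``, ``outcome``) are required; the remaining fields are
    descriptors carried along for cohort summaries and are never used by the
    classifier.
    """

    visit_id: str
    age: int
    ctas: int
    specialist_consult: bool
    main_intervention: str
    outcome: str
    sex: Optional[str] = None
    arrival_mode: Optional[str] = None
    day_of_week: Optional[str] = None
    ed_minutes: Optional[float] = None
    provider_service: Optional[str] = None

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first invalid field.

        Charts lacking any variable required for classification are excluded
        from analysis rather than silently defaulted, so missing or
        out-of-range criterion fields are hard errors.
        """
        if self.visit_id is None or str(self.visit_id) == "":
            raise ValidationError("visit_id", "must be a non-empty identifier")
        if self.age is None or not isinstance(self.age, (int,)) or self.age < 0:
            raise ValidationError("age", f"must be a non-negative integer, got {self.age!r}")
        if self.ctas not in (1, 2, 3, 4, 5):
            raise ValidationError("ctas", f"must be in 1..5, got {self.ctas!r}")
        if not isinstance(self.specialist_consult, bool):
            raise ValidationError(
                "specialist_consult", f"must be boolean, got {self.specialist_consult!r}"
            )
        if self.main_intervention is None or not str(self.main_intervention).strip():
            raise ValidationError("main_intervention", "must be a non-empty code")
        if self.outcome not in OUTCOMES:
            raise ValidationError(
                "outcome", f"must be one of {OUTCOMES}, got {self.outcome!r}"
            )
        if self.ed_minutes is not None and self.ed_minutes < 0:
            raise ValidationError("ed_minutes", "must be non-negative")


def canonicalize_code(code: str) -> str:
    """Canonical form of an intervention code: trimmed, uppercased."""
    return str(code).strip().upper()


@dataclass(frozen=True)
class CodeRegistry:
    """Set of intervention codes accepted as manageable in subacute care.

    The registry contents are configuration (they vary by jurisdiction and
    coding system); membership is an exact string match after
    canonicalisation.
    """

    codes: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "CodeRegistry":
        return cls(frozenset(canonicalize_code(c) for c in codes if str(c).strip()))

    @classmethod
    def from_file(cls, path: str | Path) -> "CodeRegistry":
        """Load a registry from a one-code-per-line text file.

        Blank lines and ``#`` comments are ignored.
        """
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls.from_codes(
            line.split("#", 1)[0] for line in lines if line.split("#", 1)[0].strip()
        )

    def __contains__(self, code: str) -> bool:
        return canonicalize_code(code) in self.codes

    def __len__(self) -> int:
        return len(self.codes)


def classify_visit(visit: EDVisit, registry: CodeRegistry) -> EDACClass:
    """Apply the EDAC decision table to one visit.

    Raises :class:`ValidationError` if any criterion field is missing or out
    of range, and ``ValueError`` if the registry is empty.
    """
    visit.validate()
    if len(registry) == 0:
        raise ValueError("intervention-code registry is empty")

    base = (
        AGE_MIN <= visit.age <= AGE_MAX
        and not visit.specialist_consult
        and visit.main_intervention in registry
        and visit.outcome == "discharged"
    )
    if base and visit.ctas in (4, 5):
        return EDACClass.AVOIDABLE
    if base and visit.ctas == 3:
        return EDACClass.POTENTIALLY_AVOIDABLE
    return EDACClass.NOT_AVOIDABLE


def classify_cohort(
    visits: Iterable[EDVisit], registry: CodeRegistry
) -> tuple[dict[str, EDACClass], Counter]:
    """Classify every visit in a cohort.

    Returns ``(mapping visit_id -> EDACClass, tally Counter over classes)``.
    Duplicate visit ids are an error: the classification is per attendance and
    a cohort must identify each attendance uniquely.
    """
    labels: dict[str, EDACClass] = {}
    tally: Counter = Counter({c: 0 for c in EDACClass})
    for visit in visits:
        if visit.visit_id in labels:
            raise ValueError(f"duplicate visit_id {visit.visit_id!r}")
        cls = classify_visit(visit, registry)
        labels[visit.visit_id] = cls
        tally[cls] += 1
    return labels, tally


def tally_by_class(labels: Mapping[str, EDACClass]) -> Counter:
    """Per-class counts from a label mapping."""
    tally: Counter = Counter({c: 0 for c in EDACClass})
    for cls in labels.values():
        tally[cls] += 1
    return tally
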