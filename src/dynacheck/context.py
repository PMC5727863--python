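"""Patient context: the per-patient field -> typed-value record rules evaluate.

A :class:`ContextSchema` is the field catalogue a model is validated against;
a :class:`PatientContext` is one patient's (partial) record. Missing fields
are first-class: rule evaluation maps them to the truth value ``unknown``
rather than guessing, so a checklist never asserts a patient-specific finding
from absent data.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping

from .errors import TypeMismatchError

#: Declared field kinds. ``date`` values are ``datetime.date``; ``text`` is str.
FIELD_TYPES = ("number", "boolean", "text", "date")


@dataclass(frozen=True)
class FieldSpec:
    """One entry of the field catalogue."""

    name: str
    type: str  # one of FIELD_TYPES
    description: str = ""

    def __post_init__(self):
        if self.type not in FIELD_TYPES:
            raise ValueError(f"unknown field type {self.type!r} for {self.name!r}")


@dataclass(frozen=True)
class ContextSchema:
    """Catalogue of the patient-context fields a model may reference."""

    fields: Mapping[str, FieldSpec] = field(default_factory=dict)

    @classmethod
    def from_specs(cls, specs) -> "ContextSchema":
        return cls(fields={s.name: s for s in specs})

    def __contains__(self, name: str) -> bool:
        return name in self.fields

    def type_of(self, name: str) -> str | None:
        spec = self.fields.get(name)
        return spec.type if spec else None


def value_kind(value) -> str:
    """Runtime kind of a context value, on the FIELD_TYPES scale."""
    if isinstance(value, bool):
        return "boolean"
    if isinstance(value, (int, float)):
        return "number"
    if isinstance(value, _dt.date):
        return "date"
    if isinstance(value, str):
        return "text"
    raise TypeMismatchError(f"unsupported context value {value!r}")


@dataclass(frozen=True)
class PatientContext:
    """A flat field -> value record for one patient.

    ``observed_at`` optionally timestamps individual fields; the engine does
    not interpret it, it is carried for audit trails.
    """

    patient_id: str
    values: Mapping[str, object] = field(default_factory=dict)
    observed_at: Mapping[str, _dt.datetime] = field(default_factory=dict)

    def get(self, name: str):
        return self.values.get(name)

    def has(self, name: str) -> bool:
        return name in self.values and self.values[name] is not None

    def check_against(self, schema: ContextSchema) -> None:
        """Raise TYPE_MISMATCH if any present value contradicts the schema."""
        for name, value in self.values.items():
            if value is None:
                continue
            declared = schema.type_of(name)
            if declared is None:
                continue  # unknown fields are a validation concern, not a type error
            if value_kind(value) != declared:
                raise TypeMismatchError(
                    f"field {name!r}: schema declares {declared}, "
                    f"value {value!r} is {value_kind(value)}"
                )

    def without(self, *names: str) -> "PatientContext":
        """Copy with the given fields removed (used for monotonicity checks)."""
        return PatientContext(
            patient_id=self.patient_id,
            values={k: v for k, v in self.values.items() if k not in names},
            observed_at={k: v for k, v in self.observed_at.items() if k not in names},
        )
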