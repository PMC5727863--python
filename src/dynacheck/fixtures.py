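"""Bundled worked models and a synthetic patient-cohort generator.

Two complete models ship with the package as native bundles (plus their
BPMN exports) under ``dynacheck/data/``:

* **CABG** — a coronary-artery-bypass-graft peri-operative pathway with 19
  clinical tasks across 9 roles (ward, OR, perfusion, ICU, physiotherapy and
  discharge lanes), a three-way parallel preparation block, an exclusive
  complication branch, and one checklist guard per lane. Task and role
  wording is this package's own; the task and role counts are the modelled
  care process's.
* **PCI** — a percutaneous-coronary-intervention pathway with an ad-hoc
  post-procedure observation block and a pre-operative checklist whose rules
  add a red-flagged alert when LVEF is below 50, note renal insufficiency,
  and pre-check documented medication.

Hospital EMR connectivity is out of scope; :func:`generate_patients`
synthesizes seeded cohorts with configurable distributions, prevalences and
missingness so pathway and rule behavior can be exercised at scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .bundle import load_bundle
from .context import PatientContext
from .model import Model


def _data_path(name: str) -> Path:
    return Path(str(resources.files("dynacheck").joinpath("data", name)))


def cabg_fixture() -> Model:
    """The bundled CABG peri-operative model (19 tasks, 9 roles)."""
    return load_bundle(_data_path("cabg"))


def pci_fixture() -> Model:
    """The bundled PCI peri-operative model with the LVEF alert rule."""
    return load_bundle(_data_path("pci"))


def fixture_bpmn(name: str) -> bytes:
    """The shipped BPMN 2.0 export of a bundled pathway ("cabg" or "pci")."""
    return (_data_path(name) / f"{name}.bpmn").read_bytes()


def pci_example_patient() -> PatientContext:
    """The worked-example patient: LVEF 36 (< 50), medication documented."""
    return PatientContext(
        patient_id="example",
        values={
            "lvef": 36,
            "renal_insufficiency": False,
            "antiplatelet_given": True,
            "age": 67,
        },
    )


# ---------------------------------------------------------------------------
# synthetic cohorts


@dataclass(frozen=True)
class FieldDistribution:
    """Sampling spec for one patient-context field.

    kind "uniform": U[low, high); "normal": N(mean, sd) clipped to
    [low, high] when bounds are given; "boolean": Bernoulli(prevalence).
    ``missing`` is the probability the field is absent from a record.
    ``integer`` rounds numeric draws.
    """

    kind: str  # "uniform" | "normal" | "boolean"
    low: float | None = None
    high: float | None = None
    mean: float | None = None
    sd: float | None = None
    prevalence: float | None = None
    missing: float = 0.0
    integer: bool = False

    def __post_init__(self):
        if self.kind not in ("uniform", "normal", "boolean"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "boolean":
            if self.prevalence is None or not 0.0 <= self.prevalence <= 1.0:
                raise ValueError("boolean fields need prevalence in [0, 1]")
        if not 0.0 <= self.missing <= 1.0:
            raise ValueError("missingness must be in [0, 1]")


@dataclass(frozen=True)
class CohortProfile:
    """A seeded recipe for a synthetic patient cohort."""

    n: int
    seed: int
    field_specs: dict[str, FieldDistribution] = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("cohort size must be >= 0")


def generate_patients(profile: CohortProfile) -> list[PatientContext]:
    """Draw exactly ``profile.n`` patient records, deterministic in the seed."""
    rng = np.random.default_rng(profile.seed)
    patients: list[PatientContext] = []
    names = sorted(profile.field_specs)
    for i in range(profile.n):
        values: dict[str, object] = {}
        for name in names:
            spec = profile.field_specs[name]
            if spec.missing and rng.random() < spec.missing:
                continue
            if spec.kind == "boolean":
                values[name] = bool(rng.random() < spec.prevalence)
            elif spec.kind == "uniform":
                v = float(rng.uniform(spec.low, spec.high))
                values[name] = int(round(v)) if spec.integer else v
            else:
                v = float(rng.normal(spec.mean, spec.sd))
                if spec.low is not None or spec.high is not None:
                    v = float(np.clip(v, spec.low, spec.high))
                values[name] = int(round(v)) if spec.integer else v
        patients.append(PatientContext(patient_id=f"p{i:05d}", values=values))
    return patients


def pci_cohort_profile(n: int, seed: int) -> CohortProfile:
    """A realistic elective-PCI cohort for the bundled model's catalogue."""
    return CohortProfile(
        n=n,
        seed=seed,
        field_specs={
            "lvef": FieldDistribution(
                kind="normal", mean=55.0, sd=12.0, low=10, high=80,
                integer=True, missing=0.05,
            ),
            "renal_insufficiency": FieldDistribution(kind="boolean", prevalence=0.15),
            "antiplatelet_given": FieldDistribution(kind="boolean", prevalence=0.9),
            "age": FieldDistribution(
                kind="normal", mean=66.0, sd=10.0, low=30, high=95, integer=True,
            ),
        },
    )


def cabg_cohort_profile(n: int, seed: int) -> CohortProfile:
    """A CABG peri-operative cohort for the bundled model's catalogue."""
    return CohortProfile(
        n=n,
        seed=seed,
        field_specs={
            "complication": FieldDistribution(kind="boolean", prevalence=0.2),
            "renal_insufficiency": FieldDistribution(kind="boolean", prevalence=0.15),
            "diabetes": FieldDistribution(kind="boolean", prevalence=0.3),
            "blood_crossmatch_done": FieldDistribution(kind="boolean", prevalence=0.95),
            "hemoglobin": FieldDistribution(
                kind="normal", mean=13.5, sd=1.8, low=6, high=19, missing=0.05,
            ),
            "age": FieldDistribution(
                kind="normal", mean=68.0, sd=9.0, low=35, high=92, integer=True,
            ),
        },
    )
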