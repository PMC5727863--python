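import pytest

from dynacheck.context import ContextSchema, FieldSpec, PatientContext
from dynacheck.fixtures import cabg_fixture, pci_fixture, pci_example_patient


@pytest.fixture(scope="session")
def cabg():
    return cabg_fixture()


@pytest.fixture(scope="session")
def pci():
    return pci_fixture()


@pytest.fixture(scope="session")
def example_patient():
    return pci_example_patient()


@pytest.fixture
def simple_schema():
    return ContextSchema.from_specs([
        FieldSpec("lvef", "number"),
        FieldSpec("renal_insufficiency", "boolean"),
        FieldSpec("age", "number"),
        FieldSpec("name", "text"),
        FieldSpec("admitted", "date"),
    ])


def make_ctx(**values) -> PatientContext:
    return PatientContext(patient_id="t", values=values)


@pytest.fixture
def ctx_factory():
    return make_ctx
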