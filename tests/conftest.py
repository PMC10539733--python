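import pytest

from fpro import FieldSettings
from fpro.io import load_geometry_table, load_measured_relaxation, load_shift_table


@pytest.fixture(scope="session")
def field():
    """14.1 T (600 MHz ¹H) — the field of all ¹⁹F measurements."""
    return FieldSettings(b0=14.1)


@pytest.fixture(scope="session")
def geometries():
    """Packaged conformer geometries keyed by label."""
    return load_geometry_table()


@pytest.fixture(scope="session")
def exo_major(geometries):
    return geometries["(4R)-exo major"]


@pytest.fixture(scope="session")
def endo_major(geometries):
    return geometries["(4S)-endo major"]


@pytest.fixture(scope="session")
def measured_relaxation():
    return load_measured_relaxation()


@pytest.fixture(scope="session")
def shift_table():
    return load_shift_table()
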