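import numpy as np
import pytest

from prodperm import (
    MembraneProfile, PhysicalSettings, load_fixture, load_parents,
    load_study_catalog,
)


@pytest.fixture(scope="session")
def parents():
    return load_parents()


@pytest.fixture(scope="session")
def cytarabine(parents):
    return parents["cytarabine"]


@pytest.fixture(scope="session")
def study_catalog():
    return load_study_catalog()


@pytest.fixture(scope="session")
def settings():
    return PhysicalSettings(temperature=293.0)


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


def make_flat_profile(span=80.0, layers=81, dG=0.0, D=1.0e-5, snapshot_id=1):
    """Uniform free energy / diffusivity over a symmetric span (A)."""
    z = np.linspace(-span / 2, span / 2, layers)
    z = (z - z[::-1]) / 2
    return MembraneProfile(
        z=z,
        dG=np.full(layers, float(dG)),
        D=np.full(layers, float(D)),
        snapshot_id=snapshot_id,
    )


@pytest.fixture
def flat_profile():
    return make_flat_profile()
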