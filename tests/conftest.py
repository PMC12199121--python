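"""Shared fixtures: synthetic fluids and the canonical 10-well chips.

Simulation fixtures are session-scoped - the reports are read-only and the
loading/evacuation runs are the slowest part of the suite.
"""

import pytest

import capdrop as cd


@pytest.fixture(scope="session")
def water():
    return cd.make_fluid("water")


@pytest.fixture(scope="session")
def oil():
    return cd.make_fluid("oil_span20")


@pytest.fixture(scope="session")
def sweat():
    return cd.make_fluid("sweat_like")


@pytest.fixture(scope="session")
def capdrop10():
    return cd.build_layout("capdrop", 10)


@pytest.fixture(scope="session")
def capdropn10():
    return cd.build_layout("capdrop_n", 10)


@pytest.fixture(scope="session")
def loading_capdrop(capdrop10, water):
    return cd.simulate_loading(capdrop10, water)


@pytest.fixture(scope="session")
def evac_capdrop(capdrop10, water):
    return cd.simulate_evacuation(capdrop10, water)


@pytest.fixture(scope="session")
def evac_capdropn(capdropn10, water):
    return cd.simulate_evacuation(capdropn10, water)


@pytest.fixture(scope="session")
def small_geometry():
    """A short chip that keeps full-workflow sweeps fast."""
    return {"mf_length": "6 cm", "delay_length": "1.5 cm"}
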