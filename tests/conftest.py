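"""Shared fixtures: the two literature scenarios are simulated once per session."""

import dataclasses

import pytest

import surfemit as se


@pytest.fixture(scope="session")
def acetic():
    return se.acetic_acid_floor()


@pytest.fixture(scope="session")
def d5():
    return se.d5_skin()


@pytest.fixture(scope="session")
def acetic_result(acetic):
    return se.simulate(acetic)


@pytest.fixture(scope="session")
def acetic_metrics(acetic_result):
    return se.compute_metrics(acetic_result)


@pytest.fixture(scope="session")
def d5_result(d5):
    return se.simulate(d5)


@pytest.fixture(scope="session")
def d5_metrics(d5_result):
    return se.compute_metrics(d5_result)


@pytest.fixture(scope="session")
def small_scenario():
    """Fast, strongly-absorbing case whose mass split is grid-insensitive
    (the substrate saturates well before depletion), so coarse and fine
    discretizations must agree."""
    return se.Scenario(
        chemical=se.ChemicalProps(name="probe", Ds=1e-9, Koa=1.25e5, Ksa=5.0e2),
        surface=se.SurfaceSpec(Ls=2e-3, A=0.5, Cs0=0.0, n_layers=10),
        room=se.RoomSpec(V=20.0, Q=5e-3, h=9e-4),
        liquid=se.LiquidApplication(Cl=1e9, m0=1e4),
        mode="full",
        t_end=4000.0,
        output_interval=20.0,
    ).resolved()


def impermeable(scenario):
    """Variant with a vanishing substrate diffusion coefficient."""
    return dataclasses.replace(
        scenario, chemical=dataclasses.replace(scenario.chemical, Ds=1e-30)
    )
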