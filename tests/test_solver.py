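"""Solver: discretization, stage stepping, oracle limits and conservation."""

import dataclasses

import numpy as np
import pytest

import surfemit as se
from conftest import impermeable


# ---------------------------------------------------------------------- grid


@pytest.mark.parametrize(
    "Ls, n, dx",
    [(1.9e-2, 10, 1.9e-3), (1e-6, 10, 1e-7), (1.0, 2, 0.5)],
)
def test_grid_spacing_is_thickness_over_layers(Ls, n, dx):
    grid = se.build_grid(se.SurfaceSpec(Ls=Ls, A=1.0, n_layers=n))
    assert grid.dx == pytest.approx(dx)
    assert grid.faces[0] == 0.0 and grid.faces[-1] == pytest.approx(Ls)
    assert len(grid.faces) == n + 1


def test_two_layer_grid_interfaces():
    grid = se.build_grid(se.SurfaceSpec(Ls=1.0, A=1.0, n_layers=2))
    assert grid.faces == pytest.approx([0.0, 0.5, 1.0])


def test_numerics_layer_override(acetic):
    grid = se.build_grid(acetic.surface, se.NumericsConfig(n_layers=20))
    assert grid.n_layers == 20


# --------------------------------------------------------------- single steps


def test_stage1_equilibrium_is_fixed_point(acetic):
    """Substrate at Cl/Kls and air at Cl/Koa with matched supply: nothing moves."""
    s = acetic.resolved()
    ca_eq = s.liquid.Cl / s.chemical.Koa
    s = dataclasses.replace(
        s, room=dataclasses.replace(s.room, Cout=ca_eq, Ca0=ca_eq)
    )
    grid = se.build_grid(s.surface)
    cs_eq = s.liquid.Cl / s.chemical.Kls
    state = se.State(t=0.0, Cs=np.full(grid.n_layers, cs_eq), Ca=ca_eq, ml=s.liquid.m0, stage=1)
    out = se.step_stage1(state, s, grid, dt=100.0)
    assert out.Cs == pytest.approx(state.Cs)
    assert out.Ca == pytest.approx(ca_eq)
    assert out.ml == pytest.approx(s.liquid.m0)


def test_stage1_sealed_substrate_ventilation_only(acetic):
    """h=0 and Ds→0: ml constant, Ca driven by ventilation alone."""
    s = dataclasses.replace(
        impermeable(acetic), room=dataclasses.replace(acetic.room, h=0.0, Ca0=30.0)
    ).resolved()
    grid = se.build_grid(s.surface)
    state = se.State(t=0.0, Cs=np.zeros(grid.n_layers), Ca=30.0, ml=s.liquid.m0, stage=1)
    out = se.step_stage1(state, s, grid, dt=60.0)
    assert out.ml == pytest.approx(s.liquid.m0)
    assert 0 < out.Ca < 30.0  # pure decay toward Cout = 0


def test_stage1_first_step_from_clean_state(acetic):
    """From clean substrate and air, one step raises Ca, loads the surface
    layer toward Cl/Kls ≈ 1.58e8 µg/m³ and depletes the liquid."""
    s = acetic.resolved()
    grid = se.build_grid(s.surface)
    state = se.State(t=0.0, Cs=np.zeros(grid.n_layers), Ca=0.0, ml=s.liquid.m0, stage=1)
    out = se.step_stage1(state, s, grid, dt=60.0)
    assert out.Ca > 0.0
    assert out.ml < s.liquid.m0
    cs_eq = s.liquid.Cl / s.chemical.Kls
    assert cs_eq == pytest.approx(1.58e8, rel=5e-3)
    assert 0.0 < out.Cs[0] < cs_eq
    assert out.Cs[0] > out.Cs[1]  # loading from the surface downward


def test_stage1_truncates_step_at_depletion(acetic):
    s = acetic.resolved()
    tiny = dataclasses.replace(s, liquid=dataclasses.replace(s.liquid, m0=50.0))
    grid = se.build_grid(tiny.surface)
    state = se.State(t=0.0, Cs=np.zeros(grid.n_layers), Ca=0.0, ml=50.0, stage=1)
    out = se.step_stage1(state, tiny, grid, dt=60.0)
    assert out.stage == 2
    assert out.ml == 0.0
    assert 0.0 < out.t < 60.0


def test_stage2_equilibrium_no_flux(d5):
    """Cs/Ksa equal to Ca everywhere: surface flux vanishes."""
    s = d5.resolved()
    grid = se.build_grid(s.surface)
    ca = s.surface.Cs0 / s.chemical.Ksa
    quiet = dataclasses.replace(s, room=dataclasses.replace(s.room, Q=0.0, Ca0=ca))
    state = se.State(t=0.0, Cs=np.full(grid.n_layers, s.surface.Cs0), Ca=ca, ml=0.0, stage=2)
    out = se.step_stage2(state, quiet, grid, dt=10.0)
    assert out.Cs == pytest.approx(state.Cs)
    assert out.Ca == pytest.approx(ca)


def test_stage2_first_step_emits_from_loaded_skin(d5):
    """Loaded skin over clean air: Cs0/Ksa ≈ 2.69e6 µg/m³ drives Ca upward."""
    s = d5.resolved()
    assert s.surface.Cs0 / s.chemical.Ksa == pytest.approx(2.69e6, rel=5e-3)
    grid = se.build_grid(s.surface)
    state = se.State(t=0.0, Cs=np.full(grid.n_layers, s.surface.Cs0), Ca=0.0, ml=0.0, stage=2)
    out = se.step_stage2(state, s, grid, dt=5.0)
    assert out.Ca > 0.0
    assert out.Cs[0] < s.surface.Cs0  # surface layer drains first


@pytest.mark.parametrize("stepper, stage", [(se.step_stage1, 1), (se.step_stage2, 2)])
def test_steps_reject_nonpositive_dt(acetic, stepper, stage):
    s = acetic.resolved()
    grid = se.build_grid(s.surface)
    state = se.State(t=0.0, Cs=np.zeros(grid.n_layers), Ca=0.0, ml=1.0, stage=stage)
    with pytest.raises(ValueError):
        stepper(state, s, grid, dt=0.0)


# ------------------------------------------------------------- oracle limits


def test_impermeable_stage1_matches_closed_form(acetic):
    """With Ds→0 the stage-1 air history is the one-box ODE solution."""
    s = impermeable(acetic)
    r = se.simulate(s)
    probes = np.linspace(600.0, 0.9 * r.depletion_time, 20)
    idx = np.searchsorted(r.times, probes)
    expected = se.analytic_stage1_impermeable(s, r.times[idx])
    assert r.Ca_series[idx] == pytest.approx(expected, rel=5e-3)
    assert se.compute_metrics(r).f_liquid_to_air == pytest.approx(1.0, abs=1e-6)


def test_stage2_with_no_film_transfer_is_ventilation_decay(d5):
    s = dataclasses.replace(d5, room=dataclasses.replace(d5.room, h=0.0, Ca0=50.0))
    r = se.simulate(s)
    expected = se.analytic_ventilation_decay(50.0, s.room, r.times)
    mask = expected > 1e-12 * 50.0
    assert r.Ca_series[mask] == pytest.approx(expected[mask], rel=1e-3)


def test_ventilation_decay_closed_form_limits():
    room = se.RoomSpec(V=20.0, Q=5e-3, h=0.0)
    assert se.analytic_ventilation_decay(7.0, room, 0.0) == pytest.approx(7.0)
    assert se.analytic_ventilation_decay(7.0, room, 20.0 / 5e-3) == pytest.approx(7.0 / np.e)
    sealed = se.RoomSpec(V=20.0, Q=0.0, h=0.0)
    assert se.analytic_ventilation_decay(7.0, sealed, 1e6) == pytest.approx(7.0)


def test_impermeable_closed_form_limits(acetic):
    s = impermeable(acetic).resolved()
    assert se.analytic_stage1_impermeable(s, 0.0) == pytest.approx(0.0)
    hA = s.room.h * s.surface.A
    steady = hA * s.liquid.Cl / s.chemical.Koa / (s.room.Q + hA)
    assert se.analytic_stage1_impermeable(s, 1e9) == pytest.approx(steady)
    tau = s.room.V / (s.room.Q + hA)
    assert se.analytic_stage1_impermeable(s, tau) == pytest.approx(steady * (1 - 1 / np.e))


def _explicit_reference(s, n_layers, dt):
    """Naive forward-Euler finite-volume reference, coded independently of
    the package's implicit solver."""
    c, surf, room, liq = s.chemical, s.surface, s.room, s.liquid
    dx = surf.Ls / n_layers
    C = np.zeros(n_layers)
    Ca, ml, t = 0.0, liq.m0, 0.0
    cd = liq.Cl / c.Kls
    hA = room.h * surf.A
    liquid_to_air = 0.0
    stage, t_dep = 1, None
    c_peak = 0.0
    while t < s.t_end:
        dC = np.zeros(n_layers)
        dC[1:-1] = c.Ds * (C[:-2] - 2 * C[1:-1] + C[2:]) / dx**2
        dC[-1] = c.Ds * (C[-2] - C[-1]) / dx**2
        if stage == 1:
            flux_in = 2 * c.Ds / dx * (cd - C[0])
            dC[0] = (flux_in - c.Ds * (C[0] - C[1]) / dx) / dx
            f_air = hA * (liq.Cl / c.Koa - Ca)
            dml = -(f_air + surf.A * flux_in)
            step = dt if ml + dt * dml >= 0 else ml / -dml
            C += step * dC
            Ca += step * (-room.Q * Ca + f_air) / room.V
            liquid_to_air += step * f_air
            ml += step * dml
            t += step
            if step < dt:
                stage, t_dep, ml = 2, t, 0.0
        else:
            alpha = 2 * c.Ds / dx
            g = room.h * alpha / (alpha + room.h / c.Ksa)
            J = g * (C[0] / c.Ksa - Ca)
            dC[0] = (-J - c.Ds * (C[0] - C[1]) / dx) / dx
            C += dt * dC
            Ca += dt * (-room.Q * Ca + surf.A * J) / room.V
            t += dt
        c_peak = max(c_peak, Ca)
    return {"t_dep": t_dep, "C_peak": c_peak, "f_liquid_to_air": liquid_to_air / liq.m0}


def test_brute_force_fine_grid_oracle(small_scenario):
    """A 40-layer explicit run with a ~100x smaller step agrees with the
    implicit 10-layer solver on the peak and the final mass split."""
    r = se.simulate(small_scenario)
    m = se.compute_metrics(r)
    dx40 = small_scenario.surface.Ls / 40
    dt = min(r.dt_stage2 / 100, 0.2 * dx40**2 / (2 * small_scenario.chemical.Ds))
    ref = _explicit_reference(small_scenario, n_layers=40, dt=dt)
    assert m.C_peak == pytest.approx(ref["C_peak"], rel=0.01)
    assert r.depletion_time == pytest.approx(ref["t_dep"], rel=0.01)
    assert m.f_liquid_to_air == pytest.approx(ref["f_liquid_to_air"], rel=0.01)


# ------------------------------------------------- conservation & invariants


def test_mass_conservation_on_fixtures(acetic_result, d5_result):
    assert acetic_result.max_mass_balance_residual < 1e-10
    assert d5_result.max_mass_balance_residual < 1e-10


def test_monotonic_series(acetic_result):
    ml = acetic_result.ml_series
    assert np.all(np.diff(ml) <= 1e-12 * ml[0])
    assert np.all(np.diff(acetic_result.exhaust_cumulative) >= 0.0)
    assert np.all(acetic_result.Ca_series >= 0.0)
    assert np.all(acetic_result.substrate_mass_series >= 0.0)


def test_stage_transition_happens_once(acetic_result):
    stages = acetic_result.stage_series
    assert stages[0] == 1 and stages[-1] == 2
    assert np.all(np.diff(stages) >= 0)
    assert int(np.sum(np.diff(stages))) == 1
    assert acetic_result.depletion_time is not None


def test_state_continuity_across_transition(acetic):
    """Air concentration and substrate mass do not jump at depletion beyond
    one reporting interval's worth of change."""
    r = se.simulate(acetic)
    k = int(np.searchsorted(r.times, r.depletion_time))
    for series in (r.Ca_series, r.substrate_mass_series):
        local = np.abs(np.diff(series[max(k - 3, 0) : k + 3]))
        typical = np.median(np.abs(np.diff(series[: max(k - 3, 1)]))) + 1e-300
        assert local.max() < 50 * typical


def test_grid_doubling_insensitivity(acetic, d5):
    """10 → 20 layers moves times and peak by <2% and fractions by <2 points."""
    for scenario in (acetic, d5):
        m1 = se.compute_metrics(se.simulate(scenario))
        m2 = se.compute_metrics(se.simulate(scenario, se.NumericsConfig(n_layers=20)))
        assert m2.C_peak == pytest.approx(m1.C_peak, rel=0.02)
        assert m2.t_peak == pytest.approx(m1.t_peak, rel=0.02)
        if m1.depletion_time is not None:
            assert m2.depletion_time == pytest.approx(m1.depletion_time, rel=0.02)
            assert abs(m2.f_liquid_to_air - m1.f_liquid_to_air) < 0.02
            assert abs(m2.f_liquid_to_substrate - m1.f_liquid_to_substrate) < 0.02
        assert abs(m2.f_substrate_to_air - m1.f_substrate_to_air) < 0.02


def test_degenerate_tiny_source_completes(acetic):
    s = dataclasses.replace(acetic, liquid=dataclasses.replace(acetic.liquid, m0=1e-6))
    r = se.simulate(s)
    assert r.depletion_time < 1.0
    assert r.C_peak < 1e-3
    assert r.max_mass_balance_residual < 1e-8


def test_simulation_is_deterministic(acetic):
    a = se.simulate(acetic)
    b = se.simulate(acetic)
    assert np.array_equal(a.Ca_series, b.Ca_series)
    assert a.depletion_time == b.depletion_time


def test_simulate_rejects_invalid_scenario(acetic):
    broken = dataclasses.replace(acetic, liquid=None)
    with pytest.raises(se.ScenarioError):
        se.simulate(broken)


def test_nonconvergence_raises_with_deltas(acetic):
    with pytest.raises(se.ConvergenceError) as err:
        se.simulate(acetic, se.NumericsConfig(max_refinements=1, convergence_rtol=1e-12))
    assert err.value.deltas  # carries the last refinement deltas
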