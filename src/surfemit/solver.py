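"""Finite-volume integration of the coupled substrate/liquid/air system.

The substrate (applied material or skin) is a 1-D slab of thickness ``Ls``
divided into ``n_layers`` equal layers.  Chemical transport in it is pure
Fickian diffusion, ``∂Cs/∂t = Ds ∂²Cs/∂x²``, with a zero-flux condition at
the backed side ``x = Ls``.  The surface condition at ``x = 0`` switches
with the emission stage:

* **stage 1** (liquid film present): the surface is pinned at the
  liquid/substrate equilibrium value ``Cl/Kls`` (Dirichlet), the room air
  receives a convective flux ``h·A·(Cl/Koa − Ca)`` directly from the
  liquid, and the liquid chemical mass ``ml`` is decremented by both the
  liquid→air flux and the substrate uptake;
* **stage 2** (film depleted): the surface exchanges with room air through
  a flux-matching (Robin) condition ``Ds ∂Cs/∂x = h (Cs/Ksa − Ca)``.

The room is a single well-mixed zone, ``V dCa/dt = Q (Cout − Ca) + A·J``
with ``J`` the surface flux of the active stage.

Unknowns live at the layer (cell) centers; boundary conditions are applied
at the surface *interface*, which makes the scheme exactly conservative:
the discrete change of ``ml + A·Δx·ΣCs + V·Ca + ∫Q·Ca dt − ∫Q·Cout dt`` is
zero to round-off at every step, so the mass-balance audit is a genuine
bug detector rather than a discretization-error meter.  Time integration
is θ-weighted (Crank–Nicolson by default) with a convergence-by-halving
refinement loop on the peak air concentration and the final mass
fractions.  The solver is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .core import (
    MODE_FULL,
    MODE_STAGE2_ONLY,
    RoomSpec,
    Scenario,
    State,
    SurfaceSpec,
    require_valid,
)

__all__ = [
    "NumericsConfig",
    "Grid",
    "SimulationResult",
    "SolverError",
    "ConvergenceError",
    "build_grid",
    "step_stage1",
    "step_stage2",
    "simulate",
    "analytic_stage1_impermeable",
    "analytic_ventilation_decay",
]


class SolverError(RuntimeError):
    """Raised when an integration pass produces an unusable solution."""


class ConvergenceError(SolverError):
    """Raised when time-step halving fails to converge.

    Carries the last two refinement deltas in ``deltas``.
    """

    def __init__(self, message, deltas):
        super().__init__(message)
        self.deltas = deltas


@dataclass(frozen=True)
class NumericsConfig:
    """Numerical controls for :func:`simulate`.

    ``n_layers`` overrides the scenario's spatial layer count (default 10).
    ``dt_init`` is the starting time step in seconds; when ``None`` it is
    derived from the horizon, the stiffest linear rate of the system and an
    a-priori depletion-time estimate.  The step is halved (and the run
    repeated) until the peak air concentration and the final mass fractions
    change by less than ``convergence_rtol`` between refinements, up to
    ``max_refinements`` halvings (``max_refinements=0`` accepts the first
    pass unconditionally).  ``theta`` is the implicitness weight of the
    time scheme: 0.5 is Crank–Nicolson, 1.0 backward Euler.
    """

    n_layers: Optional[int] = None
    dt_init: Optional[float] = None
    convergence_rtol: float = 1e-3
    theta: float = 0.5
    max_refinements: int = 8


@dataclass(frozen=True)
class Grid:
    """Uniform 1-D grid over the substrate thickness.

    ``faces`` holds the ``n_layers + 1`` layer-interface positions, with
    ``faces[0] = 0`` the surface in contact with the liquid/air and
    ``faces[-1] = Ls`` the backed side.  Unknowns live at the layer
    centers, ``centers``.
    """

    faces: np.ndarray

    @property
    def n_layers(self) -> int:
        return len(self.faces) - 1

    @property
    def dx(self) -> float:
        return float(self.faces[1] - self.faces[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.faces[1:] + self.faces[:-1])


def build_grid(surface: SurfaceSpec, numerics: NumericsConfig = NumericsConfig()) -> Grid:
    """Build the uniform grid: ``n_layers + 1`` interfaces, ``Δx = Ls/n_layers``."""
    n = numerics.n_layers if numerics.n_layers is not None else surface.n_layers
    if n < 2:
        raise ValueError(f"n_layers must be >= 2, got {n}")
    return Grid(faces=np.linspace(0.0, surface.Ls, n + 1))


# ---------------------------------------------------------------------------
# discrete operators


def _diffusion_matrix(n: int, lam: float) -> np.ndarray:
    """Interior diffusion stencil with a zero-flux backed side (rows 1..n-1)."""
    L = np.zeros((n, n))
    for i in range(1, n - 1):
        L[i, i - 1] = lam
        L[i, i] = -2.0 * lam
        L[i, i + 1] = lam
    L[n - 1, n - 2] = lam
    L[n - 1, n - 1] = -lam
    return L


def _stage1_operator(sc: Scenario, grid: Grid):
    """Substrate operator and source for stage 1 (surface pinned at Cl/Kls)."""
    c = sc.chemical
    n, dx = grid.n_layers, grid.dx
    lam = c.Ds / dx**2
    cd = sc.liquid.Cl / c.Kls  # liquid/substrate equilibrium at the surface
    L = _diffusion_matrix(n, lam)
    L[0, 0] = -3.0 * lam  # half-cell Dirichlet + full-cell interior face
    L[0, 1] = lam
    b = np.zeros(n)
    b[0] = 2.0 * lam * cd
    return L, b


def _stage2_coupling(sc: Scenario, grid: Grid) -> float:
    """Series-resistance surface conductance g (m/s): J = g (C0/Ksa − Ca).

    Combines the air-side film ``h`` with the half-layer diffusive
    resistance; vanishes with either ``h`` or ``Ds`` (an impermeable
    substrate emits nothing in stage 2).
    """
    c = sc.chemical
    alpha = 2.0 * c.Ds / grid.dx
    beta = sc.room.h / c.Ksa
    if sc.room.h == 0.0 or alpha + beta == 0.0 or alpha == 0.0:
        return 0.0
    return sc.room.h * alpha / (alpha + beta)


def _stage2_operator(sc: Scenario, grid: Grid):
    """Coupled operator over [Cs(0..n-1), Ca] for stage 2."""
    c, room = sc.chemical, sc.room
    n, dx = grid.n_layers, grid.dx
    lam = c.Ds / dx**2
    g = _stage2_coupling(sc, grid)
    A = sc.surface.A
    L = np.zeros((n + 1, n + 1))
    L[:n, :n] = _diffusion_matrix(n, lam)
    L[0, 0] = -lam - g / (dx * c.Ksa)
    L[0, 1] = lam
    L[0, n] = g / dx
    L[n, 0] = A * g / (room.V * c.Ksa)
    L[n, n] = -(room.Q + A * g) / room.V
    b = np.zeros(n + 1)
    b[n] = room.Q * room.Cout / room.V
    return L, b


def _theta_system(L: np.ndarray, b: np.ndarray, theta: float, dt: float):
    """Return (M_implicit, M_explicit, dt*b) of the θ-weighted update."""
    n = L.shape[0]
    eye = np.eye(n)
    return eye - theta * dt * L, eye + (1.0 - theta) * dt * L, dt * b


# ---------------------------------------------------------------------------
# single steps (public, shared with the integrator)


def _air_step_stage1(sc: Scenario, theta: float, dt: float, Ca: float):
    """θ-update of the stage-1 air balance; returns (Ca_new, Ca_theta)."""
    room, liq, chem = sc.room, sc.liquid, sc.chemical
    hA = room.h * sc.surface.A
    a = (room.Q + hA) / room.V
    c = (room.Q * room.Cout + hA * liq.Cl / chem.Koa) / room.V
    Ca_new = (Ca * (1.0 - (1.0 - theta) * a * dt) + dt * c) / (1.0 + theta * a * dt)
    return Ca_new, theta * Ca_new + (1.0 - theta) * Ca


def step_stage1(state: State, s: Scenario, grid: Grid,
                numerics: NumericsConfig = NumericsConfig(), dt: float = 1.0) -> State:
    """Advance one θ-weighted stage-1 step.

    Substrate diffuses under the pinned surface value ``Cl/Kls``, the air
    follows the stage-1 room balance, and ``ml`` is decremented by the
    liquid→air flux plus the substrate uptake (evaluated as the change of
    the substrate mass integral, which keeps the bookkeeping exact).  If
    the step would drive ``ml`` below zero it is truncated by linear
    interpolation to the depletion instant and the returned state has
    ``stage = 2`` and ``ml = 0``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if state.stage != 1:
        raise ValueError("step_stage1 requires state.stage == 1")
    if not state.ml > 0:
        raise ValueError("step_stage1 requires ml > 0")
    sc = require_valid(s)
    theta = numerics.theta
    L, b = _stage1_operator(sc, grid)
    cellw = sc.surface.A * grid.dx

    def trial(step_dt):
        M_im, M_ex, db = _theta_system(L, b, theta, step_dt)
        Cs_new = np.linalg.solve(M_im, M_ex @ state.Cs + db)
        Ca_new, Ca_th = _air_step_stage1(sc, theta, step_dt, state.Ca)
        flux_air = sc.room.h * sc.surface.A * (sc.liquid.Cl / sc.chemical.Koa - Ca_th)
        ml_new = state.ml - step_dt * flux_air - cellw * (Cs_new.sum() - state.Cs.sum())
        return Cs_new, Ca_new, ml_new

    Cs_new, Ca_new, ml_new = trial(dt)
    if ml_new >= 0.0:
        return State(t=state.t + dt, Cs=Cs_new, Ca=Ca_new, ml=ml_new, stage=1)
    # truncate to the depletion instant (secant on the nearly linear ml(dt))
    step = dt * state.ml / (state.ml - ml_new)
    for _ in range(5):
        if step <= 0.0:
            step = 0.0
            Cs_new, Ca_new, ml_new = state.Cs.copy(), state.Ca, state.ml
            break
        Cs_new, Ca_new, ml_new = trial(step)
        if abs(ml_new) <= 1e-9 * max(state.ml, 1.0):
            break
        step = min(dt, max(0.0, step * state.ml / (state.ml - ml_new)))
    return State(t=state.t + step, Cs=Cs_new, Ca=Ca_new, ml=0.0, stage=2)


def step_stage2(state: State, s: Scenario, grid: Grid,
                numerics: NumericsConfig = NumericsConfig(), dt: float = 1.0) -> State:
    """Advance one θ-weighted stage-2 step (Robin surface, coupled air)."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if state.stage != 2:
        raise ValueError("step_stage2 requires state.stage == 2")
    sc = require_valid(s)
    L, b = _stage2_operator(sc, grid)
    M_im, M_ex, db = _theta_system(L, b, numerics.theta, dt)
    u = np.append(state.Cs, state.Ca)
    u_new = np.linalg.solve(M_im, M_ex @ u + db)
    return State(t=state.t + dt, Cs=u_new[:-1], Ca=float(u_new[-1]), ml=state.ml, stage=2)


# ---------------------------------------------------------------------------
# closed-form oracles (never used by the main path)


def analytic_stage1_impermeable(s: Scenario, t):
    """Stage-1 air concentration for an impermeable substrate (Ds → 0).

    With no substrate uptake, Cout = 0 and Ca0 = 0, the air balance is the
    linear ODE ``V dCa/dt = −(Q + hA) Ca + hA Cl/Koa`` with solution
    ``Ca(t) = [hA Cl/Koa / (Q + hA)] (1 − exp(−(Q + hA) t / V))``.
    Degenerates to ``hA Cl/Koa · t / V`` when ``Q + hA = 0``.
    """
    sc = require_valid(s)
    if sc.room.Cout != 0 or sc.room.Ca0 != 0:
        raise ValueError("closed form assumes Cout = 0 and Ca0 = 0")
    t = np.asarray(t, dtype=float)
    hA = sc.room.h * sc.surface.A
    source = hA * sc.liquid.Cl / sc.chemical.Koa
    drain = sc.room.Q + hA
    if drain == 0.0:
        return source * t / sc.room.V
    return source / drain * (1.0 - np.exp(-drain * t / sc.room.V))


def analytic_ventilation_decay(Ca0: float, room: RoomSpec, t):
    """Pure ventilation decay ``Ca0 · exp(−Q t / V)`` (h = 0, Cout = 0)."""
    if room.Cout != 0:
        raise ValueError("closed form assumes Cout = 0")
    t = np.asarray(t, dtype=float)
    return Ca0 * np.exp(-room.Q * t / room.V)


# ---------------------------------------------------------------------------
# full simulation


@dataclass
class SimulationResult:
    """Reported time series plus derived events and audit totals.

    Series share the reporting grid ``times`` (s).  ``t_peak``/``C_peak``
    are tracked at every internal solver step, so their resolution is the
    time step, not the reporting interval.  ``liquid_to_air_mass`` is the
    stage-1 cumulative liquid→air transfer (µg).
    """

    times: np.ndarray
    Ca_series: np.ndarray
    ml_series: np.ndarray
    substrate_mass_series: np.ndarray
    exhaust_cumulative: np.ndarray
    intake_cumulative: np.ndarray
    stage_series: np.ndarray
    depletion_time: Optional[float]
    t_peak: float
    C_peak: float
    liquid_to_air_mass: Optional[float]
    substrate_mass_at_depletion: Optional[float]
    scenario: Scenario
    n_layers: int
    dt_stage1: Optional[float]
    dt_stage2: float
    refinements: int
    convergence_deltas: dict

    @property
    def initial_total_mass(self) -> float:
        sc = self.scenario
        m0 = sc.liquid.m0 if sc.liquid is not None else 0.0
        return m0 + self.substrate_mass_series[0] + sc.room.V * self.Ca_series[0]

    def mass_balance_residuals(self) -> np.ndarray:
        """|closed-system total(t) − total(0)| / total(0) at each reported time."""
        total = (
            self.ml_series
            + self.substrate_mass_series
            + self.scenario.room.V * self.Ca_series
            + self.exhaust_cumulative
            - self.intake_cumulative
        )
        ref = max(self.initial_total_mass, 1e-300)
        return np.abs(total - ref) / ref

    @property
    def max_mass_balance_residual(self) -> float:
        return float(self.mass_balance_residuals().max())


def _snap_dt(dt: float, interval: float) -> float:
    """Largest step <= dt that divides the reporting interval exactly."""
    return interval / math.ceil(interval / dt - 1e-12)


def _default_dt(sc: Scenario, grid: Grid, stage: int) -> float:
    """Heuristic starting step: resolve the horizon, keep the θ update
    factors non-negative for the stiffest linear rate, and (stage 1)
    resolve an a-priori depletion-time estimate."""
    room, chem = sc.room, sc.chemical
    n, dx = grid.n_layers, grid.dx
    lam = chem.Ds / dx**2
    dt = sc.t_end / 2048.0
    if stage == 1:
        hA = room.h * sc.surface.A
        rate = 4.0 * lam + (room.Q + hA) / room.V
        cd = sc.liquid.Cl / chem.Kls
        cs_mean = float(np.mean(_initial_profile(sc, n)))
        drain = hA * max(sc.liquid.Cl / chem.Koa - room.Ca0, 0.0)
        drain += sc.surface.A * 2.0 * chem.Ds / dx * max(cd - cs_mean, 0.0)
        if drain > 0.0:
            dt = min(dt, sc.liquid.m0 / drain / 32.0)
    else:
        g = _stage2_coupling(sc, grid)
        rate = 4.0 * lam + g / (dx * chem.Ksa) + (room.Q + sc.surface.A * g) / room.V
    if rate > 0.0:
        dt = min(dt, 2.0 / rate)
    return min(dt, sc.output_interval)


def _initial_profile(sc: Scenario, n: int) -> np.ndarray:
    if sc.surface.Cs0_profile is not None:
        return np.asarray(sc.surface.Cs0_profile, dtype=float)
    return np.full(n, float(sc.surface.Cs0))


class _Pass:
    """One integration pass at fixed (dt1, dt2)."""

    def __init__(self, sc: Scenario, grid: Grid, theta: float, dt1, dt2):
        self.sc, self.grid, self.theta = sc, grid, theta
        self.dt1, self.dt2 = dt1, dt2
        self.cellw = sc.surface.A * grid.dx
        self.Cs = _initial_profile(sc, grid.n_layers)
        self.Ca = float(sc.room.Ca0)
        self.ml = sc.liquid.m0 if sc.liquid is not None else 0.0
        self.stage = 1 if sc.mode == MODE_FULL else 2
        self.exhaust = 0.0
        self.intake = 0.0
        self.liquid_to_air = 0.0
        self.t_peak, self.C_peak = 0.0, self.Ca
        self.min_Ca, self.max_Ca = self.Ca, self.Ca
        self.min_Cs = float(self.Cs.min())
        self.max_Cs = float(self.Cs.max())
        self.depletion_time = None
        self.substrate_mass_at_depletion = None
        self._fact_cache = {}
        if self.stage == 1:
            self.L1, self.b1 = _stage1_operator(sc, grid)
        self.L2, self.b2 = _stage2_operator(sc, grid)

    # -- matrix/factorization helpers -------------------------------------
    def _sys(self, stage: int, dt: float):
        key = (stage, dt)
        hit = self._fact_cache.get(key)
        if hit is None:
            L, b = (self.L1, self.b1) if stage == 1 else (self.L2, self.b2)
            M_im, M_ex, db = _theta_system(L, b, self.theta, dt)
            hit = (lu_factor(M_im), M_ex, db)
            if len(self._fact_cache) < 16:
                self._fact_cache[key] = hit
        return hit

    # -- accepted-step bookkeeping -----------------------------------------
    def _track(self, t_after: float):
        if self.Ca > self.C_peak:
            self.C_peak, self.t_peak = self.Ca, t_after
        self.min_Ca = min(self.min_Ca, self.Ca)
        self.max_Ca = max(self.max_Ca, self.Ca)
        lo = float(self.Cs.min())
        hi = float(self.Cs.max())
        self.min_Cs = min(self.min_Cs, lo)
        self.max_Cs = max(self.max_Cs, hi)

    def _step1_trial(self, dt: float):
        fact, M_ex, db = self._sys(1, dt)
        Cs_new = lu_solve(fact, M_ex @ self.Cs + db)
        Ca_new, Ca_th = _air_step_stage1(self.sc, self.theta, dt, self.Ca)
        flux_air = (
            self.sc.room.h
            * self.sc.surface.A
            * (self.sc.liquid.Cl / self.sc.chemical.Koa - Ca_th)
        )
        ml_new = self.ml - dt * flux_air - self.cellw * (Cs_new.sum() - self.Cs.sum())
        return Cs_new, Ca_new, Ca_th, flux_air, ml_new

    def _accept1(self, dt, Cs_new, Ca_new, Ca_th, flux_air, ml_new, t_after):
        room = self.sc.room
        self.exhaust += room.Q * Ca_th * dt
        self.intake += room.Q * room.Cout * dt
        self.liquid_to_air += dt * flux_air
        self.Cs, self.Ca, self.ml = Cs_new, float(Ca_new), ml_new
        self._track(t_after)

    def advance_stage1(self, t_start: float, duration: float):
        """Advance stage 1 by ``duration``; returns the depletion offset
        within the chunk, or None if the liquid survives it."""
        k = max(1, round(duration / self.dt1))
        dt = duration / k
        for j in range(k):
            trial = self._step1_trial(dt)
            ml_new = trial[4]
            if ml_new >= 0.0:
                self._accept1(dt, *trial, t_after=t_start + (j + 1) * dt)
                continue
            # depletion inside this step: secant truncation on ml(Δ)=0
            offset = j * dt
            step = dt * self.ml / (self.ml - ml_new)
            for _ in range(5):
                if step <= 0.0:
                    step = 0.0
                    trial = (self.Cs.copy(), self.Ca, self.Ca, 0.0, self.ml)
                    break
                trial = self._step1_trial(step)
                if abs(trial[4]) <= 1e-9 * max(self.ml, 1.0):
                    break
                step = min(dt, max(0.0, step * self.ml / (self.ml - trial[4])))
            if step > 0.0:
                self._accept1(step, *trial, t_after=t_start + offset + step)
            residual = self.ml  # sliver left by the secant truncation
            self.liquid_to_air += residual
            self.ml = 0.0
            self.stage = 2
            self.depletion_time = t_start + offset + step
            self.substrate_mass_at_depletion = self.cellw * float(self.Cs.sum())
            return offset + step
        return None

    def advance_stage2(self, t_start: float, duration: float):
        k = max(1, math.ceil(duration / self.dt2 - 1e-12))
        dt = duration / k
        fact, M_ex, db = self._sys(2, dt)
        room = self.sc.room
        u = np.append(self.Cs, self.Ca)
        for j in range(k):
            u_new = lu_solve(fact, M_ex @ u + db)
            Ca_th = self.theta * u_new[-1] + (1.0 - self.theta) * u[-1]
            self.exhaust += room.Q * Ca_th * dt
            self.intake += room.Q * room.Cout * dt
            u = u_new
            self.Cs, self.Ca = u[:-1], float(u[-1])
            self._track(t_start + (j + 1) * dt)

    def substrate_mass(self) -> float:
        return self.cellw * float(self.Cs.sum())


def _run_pass(sc: Scenario, grid: Grid, theta: float, dt1, dt2) -> _Pass:
    """Integrate the full horizon, recording at the reporting grid."""
    oi = sc.output_interval
    n_full = int(math.floor(sc.t_end / oi + 1e-9))
    boundaries = [k * oi for k in range(1, n_full + 1)]
    if sc.t_end - n_full * oi > 1e-9 * oi:
        boundaries.append(sc.t_end)

    p = _Pass(sc, grid, theta, dt1, dt2)
    rec = {
        "times": [0.0],
        "Ca": [p.Ca],
        "ml": [p.ml],
        "sub": [p.substrate_mass()],
        "exh": [0.0],
        "intake": [0.0],
        "stage": [p.stage],
    }
    t_prev = 0.0
    for t_next in boundaries:
        chunk = t_next - t_prev
        if p.stage == 1:
            offset = p.advance_stage1(t_prev, chunk)
            if offset is not None:  # liquid depleted mid-chunk
                rest = chunk - offset
                if rest > 1e-12 * oi:
                    p.advance_stage2(t_prev + offset, rest)
        else:
            p.advance_stage2(t_prev, chunk)
        rec["times"].append(t_next)
        rec["Ca"].append(p.Ca)
        rec["ml"].append(p.ml)
        rec["sub"].append(p.substrate_mass())
        rec["exh"].append(p.exhaust)
        rec["intake"].append(p.intake)
        rec["stage"].append(p.stage)
        t_prev = t_next
    p.record = rec
    return p


def _pass_summary(p: _Pass, sc: Scenario) -> dict:
    """Quantities monitored by the refinement loop."""
    out = {"C_peak": p.C_peak}
    if sc.mode == MODE_FULL:
        m0 = sc.liquid.m0
        sub0 = p.record["sub"][0]
        sub_end = p.record["sub"][-1]
        out["f_liquid_to_air"] = p.liquid_to_air / m0
        if p.depletion_time is not None:
            sub_dep = p.substrate_mass_at_depletion
            out["f_liquid_to_substrate"] = (sub_dep - sub0) / m0
            out["f_substrate_to_air"] = (sub_dep - sub_end) / m0
        else:
            out["f_liquid_to_substrate"] = (sub_end - sub0) / m0
            out["f_substrate_to_air"] = 0.0
    else:
        sub0 = p.record["sub"][0]
        out["f_substrate_to_air"] = (sub0 - p.record["sub"][-1]) / max(sub0, 1e-300)
    return out


def _rel_delta(a: float, b: float, floor: float = 0.0) -> float:
    scale = max(abs(a), abs(b), floor)
    return 0.0 if scale < 1e-30 else abs(a - b) / scale


#: fractions are O(1) by construction; differences below this are round-off
_FRACTION_FLOOR = 1e-9


def simulate(s: Scenario, numerics: NumericsConfig = NumericsConfig()) -> SimulationResult:
    """Run the two-stage (or stage-2-only) simulation with refinement.

    The scenario is validated first; blocking findings raise
    :class:`~surfemit.core.ScenarioError`.  The time step starts at
    ``dt_init`` (or a scenario-derived default) and is halved, rerunning
    the whole horizon, until the peak air concentration and the final mass
    fractions move by less than ``convergence_rtol``; exceeding
    ``max_refinements`` raises :class:`ConvergenceError` carrying the last
    deltas.  After convergence, reported concentrations more negative than
    ``−convergence_rtol`` times their scale fail the run; smaller
    undershoots are clamped to zero.
    """
    sc = require_valid(s)
    grid = build_grid(sc.surface, numerics)
    theta = numerics.theta
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    if numerics.dt_init is not None and numerics.dt_init <= 0:
        raise ValueError(f"dt_init must be > 0, got {numerics.dt_init}")

    if numerics.dt_init is not None:
        base1 = base2 = numerics.dt_init
    else:
        base1 = _default_dt(sc, grid, 1) if sc.mode == MODE_FULL else None
        base2 = _default_dt(sc, grid, 2)

    prev = None
    deltas: dict = {}
    p = None
    for r in range(numerics.max_refinements + 1):
        scale = 2.0**r
        dt1 = _snap_dt(base1 / scale, sc.output_interval) if base1 is not None else None
        dt2 = _snap_dt(base2 / scale, sc.output_interval)
        p = _run_pass(sc, grid, theta, dt1, dt2)
        summary = _pass_summary(p, sc)
        if prev is not None:
            deltas = {
                k: _rel_delta(summary[k], prev[k], _FRACTION_FLOOR if k.startswith("f_") else 0.0)
                for k in summary
            }
            if max(deltas.values()) < numerics.convergence_rtol:
                break
        prev = summary
    else:
        if numerics.max_refinements > 0:
            raise ConvergenceError(
                f"time-step refinement did not converge within "
                f"{numerics.max_refinements} halvings (last deltas: {deltas})",
                deltas,
            )

    # negative-value policy: clamp only after convergence, fail on real blow-ups
    ca_scale = max(p.max_Ca, abs(p.min_Ca), 1e-300)
    cs_scale = max(p.max_Cs, abs(p.min_Cs), 1e-300)
    if p.min_Ca < -numerics.convergence_rtol * ca_scale:
        raise SolverError(
            f"air concentration undershoot {p.min_Ca:.3g} exceeds tolerance "
            f"(scale {ca_scale:.3g}); the scheme is unstable for this step"
        )
    if p.min_Cs < -numerics.convergence_rtol * cs_scale:
        raise SolverError(
            f"substrate concentration undershoot {p.min_Cs:.3g} exceeds tolerance "
            f"(scale {cs_scale:.3g}); the scheme is unstable for this step"
        )

    rec = p.record
    return SimulationResult(
        times=np.asarray(rec["times"]),
        Ca_series=np.clip(np.asarray(rec["Ca"]), 0.0, None),
        ml_series=np.clip(np.asarray(rec["ml"]), 0.0, None),
        substrate_mass_series=np.clip(np.asarray(rec["sub"]), 0.0, None),
        exhaust_cumulative=np.asarray(rec["exh"]),
        intake_cumulative=np.asarray(rec["intake"]),
        stage_series=np.asarray(rec["stage"], dtype=int),
        depletion_time=p.depletion_time,
        t_peak=p.t_peak,
        C_peak=max(p.C_peak, 0.0),
        liquid_to_air_mass=p.liquid_to_air if sc.mode == MODE_FULL else None,
        substrate_mass_at_depletion=p.substrate_mass_at_depletion,
        scenario=sc,
        n_layers=grid.n_layers,
        dt_stage1=dt1,
        dt_stage2=dt2,
        refinements=r,
        convergence_deltas=deltas,
    )
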