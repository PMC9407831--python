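"""Domain types, unit conventions and scenario validation.

Units are fixed package-wide: mass in µg, length in m, time in s, so every
concentration (liquid, substrate and air phase) is in µg/m³.  All partition
coefficients are dimensionless ratios of equilibrium concentrations on that
common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

__all__ = [
    "ChemicalProps",
    "SurfaceSpec",
    "RoomSpec",
    "LiquidApplication",
    "Scenario",
    "State",
    "Finding",
    "ScenarioError",
    "resolve_chemical",
    "validate_scenario",
]


class ScenarioError(ValueError):
    """Raised when a scenario with blocking validation errors is used."""

    def __init__(self, findings):
        self.findings = list(findings)
        msgs = "; ".join(f"{f.field}: {f.message}" for f in self.findings)
        super().__init__(f"invalid scenario: {msgs}")


class Finding(NamedTuple):
    """One validation finding.  ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    field: str
    message: str


@dataclass(frozen=True)
class ChemicalProps:
    """Transport and partitioning constants of the target chemical.

    Parameters
    ----------
    Ds : float
        Diffusion coefficient in the substrate (material or skin), m²/s.
    Koa : float
        Octanol/gas partition coefficient (dimensionless).  Octanol serves
        as the surrogate for the product liquid, so ``Cl/Koa`` is the
        gas-phase concentration in equilibrium with the liquid.
    Ksa : float
        Substrate(material)/gas partition coefficient (dimensionless).
    Kls : float, optional
        Liquid/substrate partition coefficient.  When omitted it is
        resolved as ``Koa/Ksa`` by :func:`resolve_chemical`.
    """

    name: str
    Ds: float
    Koa: float
    Ksa: float
    Kls: Optional[float] = None


def resolve_chemical(props: ChemicalProps) -> ChemicalProps:
    """Return ``props`` with ``Kls`` filled in as ``Koa/Ksa`` when absent.

    An explicitly supplied ``Kls`` is never overwritten.  Idempotent.
    Raises :class:`ScenarioError` naming the offending field for
    non-positive coefficients.
    """
    bad = [
        Finding("error", f"chemical.{name}", f"{name} must be > 0, got {value!r}")
        for name, value in (("Ds", props.Ds), ("Koa", props.Koa), ("Ksa", props.Ksa))
        if not (isinstance(value, (int, float)) and value > 0)
    ]
    if props.Kls is not None and not props.Kls > 0:
        bad.append(Finding("error", "chemical.Kls", f"Kls must be > 0, got {props.Kls!r}"))
    if bad:
        raise ScenarioError(bad)
    if props.Kls is not None:
        return props
    return replace(props, Kls=props.Koa / props.Ksa)


@dataclass(frozen=True)
class SurfaceSpec:
    """Substrate geometry and initial loading.

    ``Cs0`` is the uniform initial chemical concentration in the substrate
    (µg/m³).  ``Cs0_profile`` optionally overrides it with one value per
    discretization layer (surface layer first).
    """

    Ls: float
    A: float
    Cs0: float = 0.0
    n_layers: int = 10
    Cs0_profile: Optional[tuple] = None


@dataclass(frozen=True)
class RoomSpec:
    """Well-mixed room air: volume, ventilation and surface film transfer.

    ``h`` is the convective mass-transfer coefficient (m/s) of the air
    boundary layer over the applied surface.
    """

    V: float
    Q: float
    h: float
    Cout: float = 0.0
    Ca0: float = 0.0


@dataclass(frozen=True)
class LiquidApplication:
    """Applied product liquid: chemical concentration and initial mass."""

    Cl: float
    m0: float


MODE_FULL = "full"
MODE_STAGE2_ONLY = "stage2_only"


@dataclass(frozen=True)
class Scenario:
    """A complete simulation case.

    ``mode="full"`` runs stage 1 (liquid present) until depletion, then
    stage 2 (substrate re-emission).  ``mode="stage2_only"`` starts from a
    loaded substrate with no liquid, as in re-emission-only studies.
    """

    chemical: ChemicalProps
    surface: SurfaceSpec
    room: RoomSpec
    liquid: Optional[LiquidApplication] = None
    mode: str = MODE_FULL
    t_end: float = 12 * 3600.0
    output_interval: float = 60.0

    def resolved(self) -> "Scenario":
        """Return a copy with the chemical's ``Kls`` resolved."""
        return replace(self, chemical=resolve_chemical(self.chemical))


@dataclass
class State:
    """Instantaneous solver state.

    ``Cs`` holds the substrate concentration profile at the layer (cell)
    centers, surface layer first.  ``ml`` is the chemical mass remaining in
    the liquid film (0 in stage 2).
    """

    t: float
    Cs: "object"  # numpy array, shape (n_layers,)
    Ca: float
    ml: float
    stage: int


def _positive(findings, field_name, value, allow_zero=False):
    ok = value >= 0 if allow_zero else value > 0
    if not ok:
        bound = ">= 0" if allow_zero else "> 0"
        findings.append(Finding("error", field_name, f"must be {bound}, got {value!r}"))
        return False
    return True


def validate_scenario(s: Scenario) -> list:
    """Check a scenario for consistency.

    Returns a list of :class:`Finding`.  ``"error"`` findings block
    simulation; ``"warning"`` findings (e.g. an implausible air change
    rate) do not.  An empty list means the scenario is fully consistent.
    """
    f: list = []
    c, surf, room = s.chemical, s.surface, s.room

    _positive(f, "chemical.Ds", c.Ds)
    _positive(f, "chemical.Koa", c.Koa)
    _positive(f, "chemical.Ksa", c.Ksa)
    if c.Kls is not None:
        _positive(f, "chemical.Kls", c.Kls)

    _positive(f, "surface.Ls", surf.Ls)
    _positive(f, "surface.A", surf.A)
    _positive(f, "surface.Cs0", surf.Cs0, allow_zero=True)
    if surf.n_layers < 2:
        f.append(Finding("error", "surface.n_layers", f"grid needs >= 2 layers, got {surf.n_layers}"))
    if surf.Cs0_profile is not None:
        if len(surf.Cs0_profile) != surf.n_layers:
            f.append(
                Finding(
                    "error",
                    "surface.Cs0_profile",
                    f"profile length {len(surf.Cs0_profile)} != n_layers {surf.n_layers}",
                )
            )
        elif any(v < 0 for v in surf.Cs0_profile):
            f.append(Finding("error", "surface.Cs0_profile", "profile values must be >= 0"))

    _positive(f, "room.V", room.V)
    _positive(f, "room.Q", room.Q, allow_zero=True)
    _positive(f, "room.h", room.h, allow_zero=True)
    _positive(f, "room.Cout", room.Cout, allow_zero=True)
    _positive(f, "room.Ca0", room.Ca0, allow_zero=True)

    if s.mode not in (MODE_FULL, MODE_STAGE2_ONLY):
        f.append(Finding("error", "mode", f"unknown mode {s.mode!r}"))
    if s.mode == MODE_FULL:
        if s.liquid is None:
            f.append(Finding("error", "liquid", "mode=full requires a liquid application"))
        else:
            _positive(f, "liquid.Cl", s.liquid.Cl)
            _positive(f, "liquid.m0", s.liquid.m0)
    elif s.mode == MODE_STAGE2_ONLY:
        if s.liquid is not None:
            f.append(Finding("error", "liquid", "mode=stage2_only must not have a liquid application"))
        loaded = surf.Cs0 > 0 or (
            surf.Cs0_profile is not None and any(v > 0 for v in surf.Cs0_profile)
        )
        if not loaded:
            f.append(Finding("error", "surface.Cs0", "mode=stage2_only requires an initially loaded substrate (Cs0 > 0)"))

    if not s.t_end > 0:
        f.append(Finding("error", "t_end", f"must be > 0, got {s.t_end!r}"))
    if not (s.output_interval > 0 and s.output_interval <= s.t_end):
        f.append(
            Finding("error", "output_interval", f"must be in (0, t_end], got {s.output_interval!r}")
        )

    if room.V > 0 and room.Q >= 0:
        ach = room.Q / room.V * 3600.0
        if not (0.01 <= ach <= 100.0) and room.Q > 0:
            f.append(
                Finding(
                    "warning",
                    "room.Q",
                    f"air change rate {ach:.3g} h⁻¹ is outside the typical 0.01–100 h⁻¹ range",
                )
            )
    return f


def require_valid(s: Scenario) -> Scenario:
    """Resolve the chemical and raise :class:`ScenarioError` on any error finding."""
    s = s.resolved()
    errors = [x for x in validate_scenario(s) if x.severity == "error"]
    if errors:
        raise ScenarioError(errors)
    return s
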