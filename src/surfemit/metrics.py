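"""Emission/exposure summary quantities derived from a simulation result.

The headline quantities of a two-stage run are the peak indoor air
concentration and its timing, and the three-way split of the applied
chemical mass: the fraction volatilized directly liquid→air during stage 1,
its complement absorbed into the substrate, and the fraction subsequently
re-emitted substrate→air during stage 2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Optional, Tuple

import numpy as np

from .core import MODE_FULL, Scenario
from .solver import SimulationResult

__all__ = ["EmissionMetrics", "peak", "mass_fractions", "stage2_duration", "compute_metrics"]

#: fraction of the peak concentration taken as the "background" band when
#: measuring how long the stage-2 tail lasts (scale-free, explicit choice).
BACKGROUND_BAND = 0.01


@dataclass
class EmissionMetrics:
    """Summary of one simulated emission event.

    Fractions are relative to the initial liquid chemical mass ``m0``
    (full mode) or to the initial substrate-held mass (stage-2-only mode,
    where only ``f_substrate_to_air`` is defined).  ``stage2_duration`` is
    the time from liquid depletion (or t = 0 in stage-2-only mode) until
    the air concentration first falls below ``BACKGROUND_BAND · C_peak``;
    ``None`` when the horizon ends before that happens.
    """

    t_peak: float
    C_peak: float
    f_liquid_to_air: Optional[float]
    f_liquid_to_substrate: Optional[float]
    f_substrate_to_air: Optional[float]
    stage2_duration: Optional[float]
    depletion_time: Optional[float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def peak(result: SimulationResult) -> Tuple[float, float]:
    """First time at which the maximum of the reported air series is attained.

    Ties break to the earliest time; an all-zero series returns ``(0, 0)``
    with a warning.
    """
    ca = np.asarray(result.Ca_series)
    if ca.size == 0:
        raise ValueError("empty concentration series")
    idx = int(np.argmax(ca))  # argmax returns the first maximizer
    c_peak = float(ca[idx])
    if c_peak == 0.0:
        warnings.warn("air concentration series is identically zero", stacklevel=2)
        return 0.0, 0.0
    return float(result.times[idx]), c_peak


def mass_fractions(result: SimulationResult, s: Optional[Scenario] = None) -> dict:
    """Mass split of the emission event.

    Full mode: ``f_liquid_to_air`` integrates the liquid→air convective
    flux over stage 1 and divides by ``m0``; ``f_liquid_to_substrate`` is
    the substrate mass gained by depletion over ``m0``; and
    ``f_substrate_to_air`` is the substrate mass *decrease* from depletion
    to the end of the horizon over ``m0`` (unambiguous, no provenance split
    of the exhaust integral).  Raises if the liquid never depleted.

    Stage-2-only mode: only ``f_substrate_to_air`` is returned, relative to
    the initial substrate-held mass.
    """
    sc = s if s is not None else result.scenario
    sub = result.substrate_mass_series
    if sc.mode == MODE_FULL:
        if result.depletion_time is None:
            raise ValueError(
                "liquid never depleted within the horizon; stage-1 mass "
                "fractions are undefined (extend t_end)"
            )
        m0 = sc.liquid.m0
        sub_dep = result.substrate_mass_at_depletion
        return {
            "f_liquid_to_air": result.liquid_to_air_mass / m0,
            "f_liquid_to_substrate": (sub_dep - sub[0]) / m0,
            "f_substrate_to_air": (sub_dep - sub[-1]) / m0,
        }
    sub0 = sub[0]
    return {
        "f_liquid_to_air": None,
        "f_liquid_to_substrate": None,
        "f_substrate_to_air": (sub0 - sub[-1]) / max(sub0, 1e-300),
    }


def stage2_duration(result: SimulationResult, band: float = BACKGROUND_BAND) -> Optional[float]:
    """Time from depletion (or 0) until Ca first drops below ``band·C_peak``.

    Uses the reported series, scanning only times after the peak; returns
    ``None`` if the series never re-enters the band within the horizon.
    """
    t_peak, c_peak = result.t_peak, result.C_peak
    if c_peak <= 0.0:
        return None
    t0 = result.depletion_time if result.depletion_time is not None else 0.0
    after = (result.times > t_peak) & (result.Ca_series < band * c_peak)
    if not after.any():
        return None
    return float(result.times[np.argmax(after)]) - t0


def compute_metrics(result: SimulationResult, s: Optional[Scenario] = None,
                    band: float = BACKGROUND_BAND) -> EmissionMetrics:
    """Bundle peak, mass-fraction and duration metrics for one result.

    The peak uses the solver's step-resolution cache rather than the
    reporting grid, so coarse ``output_interval`` does not blur it.
    """
    fr = mass_fractions(result, s)
    return EmissionMetrics(
        t_peak=result.t_peak,
        C_peak=result.C_peak,
        f_liquid_to_air=fr["f_liquid_to_air"],
        f_liquid_to_substrate=fr["f_liquid_to_substrate"],
        f_substrate_to_air=fr["f_substrate_to_air"],
        stage2_duration=stage2_duration(result, band),
        depletion_time=result.depletion_time,
    )
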