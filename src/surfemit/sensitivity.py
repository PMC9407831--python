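"""One-at-a-time parameter sweeps over emission scenarios.

A sweep varies a single scenario parameter (addressed by a dotted path
such as ``chemical.Ds`` or ``room.Q``) or the coupled octanol/gas +
substrate/gas partition-coefficient pair over an explicit list of values,
runs an independent simulation per value, and tabulates the emission
metrics.  The coupled pair is varied at a constant ``Koa/Ksa`` ratio so
the liquid/substrate partition coefficient — and hence the substrate
uptake — stays fixed while the volatility changes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dataclass_fields, replace
from typing import Optional, Sequence, Tuple

import pandas as pd

from .core import Scenario
from .metrics import EmissionMetrics, compute_metrics
from .solver import NumericsConfig, simulate

__all__ = [
    "KOA_KSA_FIXED_RATIO",
    "SweepSpec",
    "SweepRow",
    "SweepResult",
    "sweep",
    "summarize_extremes",
    "decade_grid",
    "coupled_partition_grid",
]

#: parameter marker for varying Koa and Ksa together at fixed ratio
KOA_KSA_FIXED_RATIO = "koa_ksa_fixed_ratio"

_METRIC_NAMES = [f.name for f in dataclass_fields(EmissionMetrics)]


def decade_grid(start: float, stop: float) -> tuple:
    """Inclusive grid with one value per decade from ``start`` to ``stop``.

    Both printed endpoints are included exactly; intermediate values step
    by factors of 10 in the direction of ``stop``.
    """
    if start <= 0 or stop <= 0:
        raise ValueError("decade_grid needs positive endpoints")
    values = [start]
    factor = 10.0 if stop > start else 0.1
    v = start
    # walk until within half a decade of the far endpoint
    while (stop / v > 10.0**0.5) if stop > start else (v / stop > 10.0**0.5):
        v *= factor
        values.append(v)
    if values[-1] != stop:
        values[-1] = stop
    return tuple(values)


def coupled_partition_grid(koa_start: float, koa_stop: float, ratio: float) -> tuple:
    """(Koa, Ksa) decade pairs with ``Ksa = Koa/ratio`` held exactly."""
    return tuple((koa, koa / ratio) for koa in decade_grid(koa_start, koa_stop))


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep request.

    ``parameter`` is a dotted path into the scenario or the
    :data:`KOA_KSA_FIXED_RATIO` marker, in which case ``values`` holds
    ``(Koa, Ksa)`` pairs whose ratio must be constant to machine precision.
    """

    base: Scenario
    parameter: str
    values: tuple
    numerics: NumericsConfig = NumericsConfig()


@dataclass
class SweepRow:
    value: object
    metrics: Optional[EmissionMetrics]
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.metrics is not None


@dataclass
class SweepResult:
    """Rows in request order plus provenance of the sweep."""

    parameter: str
    rows: list
    base_hash: str
    numerics: NumericsConfig

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {}
            if self.parameter == KOA_KSA_FIXED_RATIO:
                rec["Koa"], rec["Ksa"] = row.value
            else:
                rec[self.parameter] = row.value
            for name in _METRIC_NAMES:
                rec[name] = getattr(row.metrics, name) if row.ok else None
            rec["error"] = row.error
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17e")

    def to_json(self, path=None):
        payload = {
            "parameter": self.parameter,
            "base_hash": self.base_hash,
            "rows": json.loads(self.to_dataframe().to_json(orient="records")),
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _scenario_hash(s: Scenario) -> str:
    from .io import scenario_to_dict  # local import to avoid a cycle

    blob = json.dumps(scenario_to_dict(s), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _set_by_path(s: Scenario, path: str, value) -> Scenario:
    parts = path.split(".")
    if len(parts) == 1:
        (name,) = parts
        if name not in {f.name for f in dataclass_fields(Scenario)}:
            raise KeyError(f"unknown scenario field {path!r}")
        return replace(s, **{name: value})
    if len(parts) != 2:
        raise KeyError(f"cannot address {path!r}")
    section, name = parts
    if section not in {f.name for f in dataclass_fields(Scenario)}:
        raise KeyError(f"unknown scenario section {section!r}")
    sub = getattr(s, section)
    if sub is None or name not in {f.name for f in dataclass_fields(type(sub))}:
        raise KeyError(f"unknown scenario field {path!r}")
    return replace(s, **{section: replace(sub, **{name: value})})


def _row_scenarios(spec: SweepSpec):
    base = spec.base.resolved()
    if spec.parameter == KOA_KSA_FIXED_RATIO:
        pairs = [tuple(map(float, v)) for v in spec.values]
        if not pairs:
            raise ValueError("sweep needs at least one value")
        ratios = [koa / ksa for koa, ksa in pairs]
        ref = ratios[0]
        if any(abs(r - ref) > 1e-12 * abs(ref) for r in ratios):
            raise ValueError("Koa/Ksa ratio must be constant across the coupled sweep")
        for koa, ksa in pairs:
            chem = replace(base.chemical, Koa=koa, Ksa=ksa)
            yield (koa, ksa), replace(base, chemical=chem)
    else:
        if not spec.values:
            raise ValueError("sweep needs at least one value")
        if any(v <= 0 for v in spec.values):
            raise ValueError("sweep values must be positive")
        # fail fast on a bad path before any simulation runs
        _set_by_path(base, spec.parameter, spec.values[0])
        for v in spec.values:
            yield v, _set_by_path(base, spec.parameter, float(v))


def sweep(spec: SweepSpec) -> SweepResult:
    """Run one independent simulation per requested value.

    Rows preserve request order; a failing row records its error and does
    not abort the sweep.  An unknown parameter path raises before any
    simulation starts.
    """
    rows = []
    for value, scenario in _row_scenarios(spec):
        try:
            result = simulate(scenario, spec.numerics)
            rows.append(SweepRow(value=value, metrics=compute_metrics(result)))
        except Exception as exc:  # per-row failure, recorded not raised
            rows.append(SweepRow(value=value, metrics=None, error=f"{type(exc).__name__}: {exc}"))
    return SweepResult(
        parameter=spec.parameter,
        rows=rows,
        base_hash=_scenario_hash(spec.base.resolved()),
        numerics=spec.numerics,
    )


def summarize_extremes(result: SweepResult, metric: str) -> Tuple[tuple, tuple]:
    """((min value, row), (max value, row)) over successful rows.

    Ties break to the first occurrence in request order; rows whose metric
    is ``None`` (e.g. undefined stage-2 duration) are skipped.
    """
    if metric not in _METRIC_NAMES:
        raise KeyError(f"unknown metric {metric!r}")
    scored = [
        (getattr(row.metrics, metric), row)
        for row in result.rows
        if row.ok and getattr(row.metrics, metric) is not None
    ]
    if not scored:
        raise ValueError(f"no successful rows with metric {metric!r}")
    lo = min(scored, key=lambda vr: vr[0])
    hi = max(scored, key=lambda vr: vr[0])
    return lo, hi
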