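"""Derived quantities: branch-flow tables, lumen pressure differences,
normalized true-lumen area, and AC-vs-AFC percent changes.

Conventions: human-facing tables are in L/min and mmHg; the normalized
true-lumen area is A* = 100 * A1/A0 with A0 the undeformed true-lumen
cross-section at a station (planar: gap height x out-of-plane depth) and A1
its deformed counterpart.  Pressures at a station are area-averaged over
the lumen cross-section (the planar segment, uniform in depth); percent
changes round half away from zero to integers, with the raw value retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator

from .coupling import SimulationResult
from .fluid_solver import branch_mass_flux
from .geometry import measurement_station

__all__ = [
    "BranchFlowTable",
    "LumenPressureRecord",
    "FlapDeformationRecord",
    "branch_flow_table",
    "lumen_pressure_difference",
    "true_lumen_area_ratio",
    "percent_increase",
    "round_half_away",
    "MMHG_PER_PA",
]

MMHG_PER_PA = 1.0 / 133.322


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class BranchFlowTable:
    """Per-branch flow rows keyed by (scenario, total_flow), L/min; inlet
    branches flagged per row."""

    data: pd.DataFrame  # columns: branch names; index: (scenario, total_flow)
    inlets: dict  # (scenario, total_flow) -> tuple of inlet branch names

    def row(self, scenario: str, total_flow: float) -> pd.Series:
        key = (scenario, float(total_flow))
        if key not in self.data.index:
            raise KeyError(f"no row for {key}")
        return self.data.loc[key]

    def row_imbalance(self, scenario: str, total_flow: float) -> float:
        """|sum of outflows - sum of inflows| for one row, L/min."""
        r = self.row(scenario, total_flow)
        inl = self.inlets[(scenario, float(total_flow))]
        q_in = sum(r[b] for b in inl)
        q_out = sum(r[b] for b in r.index if b not in inl)
        return abs(q_out - q_in)


@dataclass(frozen=True)
class LumenPressureRecord:
    station: str
    fl: float  # false-lumen pressure, mmHg
    tl: float  # true-lumen pressure, mmHg

    @property
    def diff(self) -> float:
        return self.fl - self.tl


@dataclass(frozen=True)
class FlapDeformationRecord:
    station: str
    A0: float  # undeformed true-lumen area, mm^2
    A1: float  # deformed true-lumen area, mm^2

    @property
    def A_star(self) -> float:
        return 100.0 * self.A1 / self.A0


def _require_converged(result: SimulationResult, force: bool):
    if not result.converged and not force:
        raise ValueError(
            "simulation result is flagged non-converged; pass force=True to "
            "post-process it anyway"
        )


def branch_flow_table(results, force: bool = False) -> BranchFlowTable:
    """Tabulate branch flows (L/min, at the desk-scale operating flows) from
    one or more coupled results, one row per (scenario, nominal flow)."""
    if isinstance(results, SimulationResult):
        results = [results]
    rows = {}
    inlets = {}
    for res in results:
        _require_converged(res, force)
        spec = res.meshes.spec
        names = [b.name for b in spec.branches]
        key = (res.scenario.mode, float(res.scenario.total_flow))
        vals = {}
        for name in names:
            q = branch_mass_flux(res.flow, res.fluid_mesh_deformed, name)
            vals[name] = abs(q) if name in res.flow.bcs.inflow else q
        rows[key] = vals
        inlets[key] = tuple(t for t in res.flow.bcs.inflow)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["scenario", "total_flow"])
    return BranchFlowTable(data=df, inlets=inlets)


def _flap_surface(result: SimulationResult, side: str):
    solid = result.meshes.solid
    nodes = np.unique(solid.edge_tags[f"interface_{side}"].ravel())
    x = solid.nodes[nodes, 0]
    order = np.argsort(x)
    return x[order], result.solid_displacement[nodes][order]


def lumen_pressure_difference(
    result_or_pair,
    station: str = "CA",
    n_sample: int = 24,
    force: bool = False,
) -> LumenPressureRecord | float:
    """False-minus-true lumen pressure difference (mmHg) at a branch station.

    Accepts either a coupled :class:`SimulationResult` (pressures sampled
    and area-averaged on the deformed cross-section) or a ``(fl, tl)`` pair
    already in mmHg (replica arithmetic), in which case the plain
    difference is returned.
    """
    if isinstance(result_or_pair, (tuple, list)) and len(result_or_pair) == 2:
        fl, tl = float(result_or_pair[0]), float(result_or_pair[1])
        return fl - tl
    result = result_or_pair
    _require_converged(result, force)
    spec = result.meshes.spec
    xs = measurement_station(spec, station)
    x0, x1 = spec.flap_span
    if not (x0 <= xs <= x1):
        raise ValueError(f"station {station!r} lies outside the flap extent")
    xb, ub = _flap_surface(result, "tl")
    xt, ut = _flap_surface(result, "fl")
    y_tl_top = spec.flap_bottom + np.interp(xs, xb, ub[:, 1])
    y_fl_bot = spec.flap_top + np.interp(xs, xt, ut[:, 1])
    H = spec.channel_height

    mesh = result.fluid_mesh_deformed
    pts = mesh.points * result.flow.scale
    interp = LinearNDInterpolator(pts, result.flow.pressure)
    scale = result.flow.scale

    def seg_mean(y0, y1):
        eps = 1e-4 * (y1 - y0)
        ys = np.linspace(y0 + eps, y1 - eps, n_sample)
        vals = interp(np.column_stack([np.full(n_sample, xs * scale), ys * scale]))
        if np.any(np.isnan(vals)):  # points just outside hull: nearest fallback
            from scipy.interpolate import NearestNDInterpolator

            nearest = NearestNDInterpolator(pts, result.flow.pressure)
            bad = np.isnan(vals)
            vals[bad] = nearest(
                np.column_stack([np.full(bad.sum(), xs * scale), ys[bad] * scale])
            )
        return float(np.mean(vals))

    p_tl = seg_mean(0.0, y_tl_top) * MMHG_PER_PA
    p_fl = seg_mean(y_fl_bot, H) * MMHG_PER_PA
    return LumenPressureRecord(station=station, fl=p_fl, tl=p_tl)


def true_lumen_area_ratio(
    result: SimulationResult, station: str = "CA", force: bool = False
) -> FlapDeformationRecord:
    """Normalized true-lumen area A* (%) at a branch station from the
    deformed flap surface."""
    _require_converged(result, force)
    spec = result.meshes.spec
    xs = measurement_station(spec, station)
    xb, ub = _flap_surface(result, "tl")
    gap = spec.flap_bottom + np.interp(xs, xb, ub[:, 1])
    depth = spec.out_of_plane_depth
    return FlapDeformationRecord(
        station=station,
        A0=spec.flap_bottom * depth,
        A1=gap * depth,
    )


def percent_increase(
    table: BranchFlowTable,
    scenarios: tuple[str, str],
    total_flow: float,
    branch_set,
) -> tuple[int, float]:
    """Percent change of the summed flow through ``branch_set`` between two
    scenarios at one total flow: 100 * (sum_b - sum_a) / sum_a for
    ``scenarios = (a, b)``.  Returns (rounded, raw)."""
    a, b = scenarios
    ra = table.row(a, total_flow)
    rb = table.row(b, total_flow)
    sa = float(sum(ra[x] for x in branch_set))
    sb = float(sum(rb[x] for x in branch_set))
    if sa == 0:
        raise ZeroDivisionError(f"zero reference flow for {a} at {total_flow} L/min")
    raw = 100.0 * (sb - sa) / sa
    return round_half_away(raw), raw
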