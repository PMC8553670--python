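"""Experiment battery: case runs, spreading sweeps, parameter sweeps.

Thin orchestration over :mod:`yaptaz3d.solver`: each experiment builds the
geometry for the requested spreading radius, runs one case per
configuration and tabulates the YAP/TAZ nuclear fraction (YTNF) and
nuclear concentration.  "Steady-state YTNF" always means the solver's
declared criterion (|dYTNF/dt| below tolerance sustained over a window, or
the configured horizon, whichever comes first); the horizon reached is
recorded in every output row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import (
    DEFAULT_GRID,
    CellGeometry,
    MOLECULES_PER_UM3_PER_UM as CONV,
    build_cell_shape,
    voxelize,
)
from .model_core import (
    ActivationProtocol,
    CaseConfig,
    ModelError,
    ParameterSet,
    SpeciesState,
    case_config,
)
from .solver import SimulationResult, SolverSettings, run_simulation

__all__ = [
    "SweepSpec",
    "ytnf",
    "run_case_experiment",
    "spreading_sweep",
    "parameter_sweep",
    "sustained_activation_experiment",
]

STANDARD_RADII = (14.0, 16.0, 18.0, 20.0)


def ytnf(obj, geometry: Optional[CellGeometry] = None) -> float:
    """YAP/TAZ nuclear fraction: n / (c + ci + n), all in molecules.

    Accepts a :class:`SimulationResult` (final recorded value), a
    :class:`SpeciesState` together with its geometry, or a triple
    ``(n, c, ci)`` of molecule counts.
    """
    if isinstance(obj, SimulationResult):
        return obj.final_ytnf
    if isinstance(obj, SpeciesState):
        if geometry is None:
            raise ModelError("ytnf(state) requires the geometry")
        vv = geometry.voxel_volume
        c = float(obj.vol["YTc"].sum()) * vv * CONV
        ci = float(obj.vol["YTci"].sum()) * vv * CONV
        n = obj.ytn
    else:
        n, c, ci = (float(x) for x in obj)
    total = n + c + ci
    if total <= 0:
        raise ModelError("total YAP/TAZ is zero")
    return n / total


def _build_geometry(base_radius: float, grid_dims=DEFAULT_GRID,
                    activation_area_fraction: Optional[float] = None) -> CellGeometry:
    kwargs = {}
    if activation_area_fraction is not None:
        kwargs["activation_area_fraction"] = activation_area_fraction
    return voxelize(build_cell_shape(base_radius, **kwargs), grid_dims)


def run_case_experiment(
    case_id: int,
    base_radius: float = 16.0,
    protocol: Optional[ActivationProtocol] = None,
    overrides: Optional[dict] = None,
    grid_dims=DEFAULT_GRID,
    settings: Optional[SolverSettings] = None,
) -> Tuple[SimulationResult, dict]:
    """Run one case and return the result plus a standardized report."""
    protocol = protocol or ActivationProtocol()
    params = ParameterSet().with_overrides(**(overrides or {}))
    geometry = _build_geometry(base_radius, grid_dims)
    case = case_config(case_id)
    settings = settings or SolverSettings()
    result = run_simulation(geometry, case, protocol, params, settings)
    i100 = int(np.searchsorted(result.times, 100.0))
    i100 = min(i100, len(result.times) - 1)
    report = {
        "case": case_id,
        "base_radius_um": base_radius,
        "protocol": protocol.mode,
        "ytnf_100s": float(result.ytnf[i100]),
        "nuclear_conc_100s_uM": float(result.nuclear_conc[i100]),
        "ytnf_final": result.final_ytnf,
        "nuclear_conc_final_uM": float(result.nuclear_conc[-1]),
        "t_final_s": float(result.times[-1]),
        "steady_state_time_s": result.steady_state_time,
        "max_conservation_drift": max(result.conservation_drift.values()),
        "point_locations": result.point_locations,
    }
    return result, report


def _steady_settings(settings: Optional[SolverSettings]) -> SolverSettings:
    if settings is not None:
        return settings
    return SolverSettings(t_end=3000.0, detect_steady_state=True)


def spreading_sweep(
    case_id: int,
    radii: Sequence[float] = STANDARD_RADII,
    protocol: Optional[ActivationProtocol] = None,
    overrides: Optional[dict] = None,
    grid_dims=DEFAULT_GRID,
    settings: Optional[SolverSettings] = None,
) -> pd.DataFrame:
    """Steady-state YTNF as a function of the spreading radius."""
    protocol = protocol or ActivationProtocol()
    params = ParameterSet().with_overrides(**(overrides or {}))
    settings = _steady_settings(settings)
    rows = []
    for radius in radii:
        geometry = _build_geometry(radius, grid_dims)
        result = run_simulation(geometry, case_config(case_id), protocol,
                                params, settings)
        rows.append({
            "case": case_id,
            "base_radius_um": radius,
            "ytnf_steady": result.final_ytnf,
            "t_final_s": float(result.times[-1]),
            "steady_state_time_s": result.steady_state_time,
        })
    return pd.DataFrame(rows)


@dataclass
class SweepSpec:
    """One swept parameter over a list of values, cases and radii."""

    parameter: str                     # ParameterSet field or "base_radius"
    values: Sequence[float]
    cases: Sequence[int] = (3, 4, 5)
    radii: Sequence[float] = (16.0,)
    protocol: ActivationProtocol = field(default_factory=ActivationProtocol)
    grid_dims: tuple = DEFAULT_GRID
    settings: Optional[SolverSettings] = None
    overrides: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.parameter != "base_radius":
            ParameterSet().with_overrides(**{self.parameter: 1.0})  # validates name


def parameter_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Steady-state YTNF per (case, radius, parameter value)."""
    settings = _steady_settings(spec.settings)
    rows = []
    for case_id in spec.cases:
        for radius in spec.radii:
            for value in spec.values:
                overrides = dict(spec.overrides)
                if spec.parameter == "base_radius":
                    geometry = _build_geometry(value, spec.grid_dims)
                else:
                    overrides[spec.parameter] = value
                    geometry = _build_geometry(radius, spec.grid_dims)
                params = ParameterSet().with_overrides(**overrides)
                result = run_simulation(geometry, case_config(case_id),
                                        spec.protocol, params, settings)
                rows.append({
                    "case": case_id,
                    "base_radius_um": radius,
                    "parameter": spec.parameter,
                    "value": value,
                    "ytnf_steady": result.final_ytnf,
                    "t_final_s": float(result.times[-1]),
                    "steady_state_time_s": result.steady_state_time,
                })
    return pd.DataFrame(rows)


def sustained_activation_experiment(
    cases: Sequence[int] = (4, 5),
    radii: Sequence[float] = STANDARD_RADII,
    stiffness_E: Optional[float] = None,
    overrides: Optional[dict] = None,
    grid_dims=DEFAULT_GRID,
    settings: Optional[SolverSettings] = None,
) -> Tuple[pd.DataFrame, Dict[tuple, SimulationResult]]:
    """Sustained (stiffness-dependent) FAK activation for 100 s.

    Only the membrane-bound-FAK cases support this protocol; case 4 starts
    with all inactive FAK at the membrane (signaling starts earlier) while
    case 5 must first bind cytosolic FAK to the membrane.
    """
    for case_id in cases:
        if case_config(case_id).fak_compartment != "membrane":
            raise ModelError("sustained activation requires membrane-bound FAK")
    protocol = ActivationProtocol(mode="sustained_rate", stiffness_E=stiffness_E)
    params = ParameterSet().with_overrides(**(overrides or {}))
    settings = _steady_settings(settings)
    rows, series = [], {}
    for case_id in cases:
        for radius in radii:
            geometry = _build_geometry(radius, grid_dims)
            result = run_simulation(geometry, case_config(case_id), protocol,
                                    params, settings)
            series[(case_id, radius)] = result
            rows.append({
                "case": case_id,
                "base_radius_um": radius,
                "ytnf_steady": result.final_ytnf,
                "t_final_s": float(result.times[-1]),
                "steady_state_time_s": result.steady_state_time,
            })
    return pd.DataFrame(rows), series
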