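"""Compartmental (well-mixed) ODE reduction of the 3D model.

Each species is a single scalar per compartment: cytosol (volume V),
membrane (total face area A, with the FAK pool confined to the activation
footprint A_act), and nucleus.  The right-hand side is a deliberately
*separate* transcription of the reaction equations and boundary conditions
from the spatial modules, so that transcription errors cannot cancel when
the PDE solver is verified against this oracle; with all diffusion terms
dropped, every volumetric reaction appears once and every boundary flux is
scaled by the area it acts on over the cytosol volume.

Used as a brute-force verification oracle for the finite-volume solver
(the spatial solution must converge to these trajectories as diffusion
becomes fast) and as a fast exploration tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import CellGeometry, MOLECULES_PER_UM3_PER_UM as CONV
from .model_core import (
    SURFACE_UNIT,
    ActivationProtocol,
    CaseConfig,
    ModelError,
    ParameterSet,
)

__all__ = ["CompartmentModel", "OracleResult", "reduce", "solve", "compare"]


@dataclass
class CompartmentModel:
    """Scalar reduction of the 3D model for one case."""

    case: CaseConfig
    params: ParameterSet
    protocol: ActivationProtocol
    V: float        # cytosol volume, um^3
    A: float        # membrane area used for surface pooling, um^2
    A_act: float    # basal activation footprint area, um^2
    N: float        # V/A conversion factor used in the flux laws, um
    A_nuc: float    # smooth nuclear membrane area, um^2
    nuclear_volume: float
    species: List[str]  # state-vector layout

    def index(self, name: str) -> int:
        return self.species.index(name)


@dataclass
class OracleResult:
    """Trajectories of the reduced model (totals in molecules)."""

    times: np.ndarray
    totals: Dict[str, np.ndarray]   # per species, molecules
    ytnf: np.ndarray
    nuclear_conc: np.ndarray        # uM in the nuclear volume
    model: CompartmentModel


def reduce(
    geometry: CellGeometry,
    case: CaseConfig,
    params: ParameterSet,
    protocol: Optional[ActivationProtocol] = None,
) -> CompartmentModel:
    """Build the compartment model mirroring the case's species placement."""
    protocol = protocol or ActivationProtocol()
    species = ["FAKci", "RhoAci", "ROCK", "ROCKi", "mDia", "mDiai",
               "Myo", "Myoi", "LIMK", "LIMKi", "Cof", "Cofi",
               "Fcyto", "Gactin", "YTc", "YTci", "YTn"]
    if case.fak_compartment == "cytosol":
        species.append("FAK_v")
    else:
        species += ["FAK_s", "FAKmi_s"]
    if case.rhoa_compartment == "cytosol":
        species.append("RhoA_v")
    else:
        species += ["RhoA_s", "RhoAmi_s"]
    return CompartmentModel(
        case=case,
        params=params,
        protocol=protocol,
        V=geometry.cytosol_volume,
        A=geometry.membrane_area_staircase,
        A_act=geometry.activation_area,
        N=geometry.N,
        A_nuc=geometry.nuclear_area,
        nuclear_volume=geometry.nucleus_volume,
        species=species,
    )


def _initial_vector(m: CompartmentModel) -> np.ndarray:
    y = np.zeros(len(m.species))
    ix = m.index
    for name in ("RhoAci", "ROCKi", "mDiai", "Myoi", "LIMKi", "Cofi", "YTci", "Fcyto"):
        y[ix(name)] = 1.0
    prot, case = m.protocol, m.case
    if prot.mode == "initial_amount":
        y[ix("FAKci")] = prot.initial_inactive_FAK / (CONV * m.V)
        if case.fak_compartment == "cytosol":
            # case 2's band collapses onto the cytosol pool in the reduction
            y[ix("FAK_v")] = prot.initial_active_FAK / (CONV * m.V)
        else:
            y[ix("FAK_s")] = prot.initial_active_FAK / (SURFACE_UNIT * m.A_act)
    elif prot.mode == "sustained_rate":
        if case.fak_compartment != "membrane":
            raise ModelError("sustained activation requires membrane-bound FAK")
        if case.fak_exchange:
            y[ix("FAKci")] = prot.total_FAK / (CONV * m.V)
        else:
            y[ix("FAKmi_s")] = prot.total_FAK / (SURFACE_UNIT * m.A_act)
    else:
        raise ModelError(f"unknown activation mode {prot.mode!r}")
    return y


def _rhs(t: float, y: np.ndarray, m: CompartmentModel) -> np.ndarray:
    p, case = m.params, m.case
    ix = m.index
    d = np.zeros_like(y)

    def g(name):
        return y[ix(name)]

    a_over_v = m.A / m.V          # whole-membrane fluxes -> volumetric rate
    aact_over_v = m.A_act / m.V   # activation-footprint fluxes

    # ---- FAK ----------------------------------------------------------
    if case.fak_compartment == "cytosol":
        fak = g("FAK_v")
        d[ix("FAK_v")] -= p.K_df * fak
        d[ix("FAKci")] += p.K_df * fak
    else:
        fak = g("FAK_s")
        d[ix("FAK_s")] -= p.K_df * fak
        d[ix("FAKmi_s")] += p.K_df * fak
        if case.fak_exchange:
            j = p.KF_on * g("FAKci") - m.N * p.KF_off * g("FAKmi_s")
            d[ix("FAKmi_s")] += j
            d[ix("FAKci")] -= j * aact_over_v * (SURFACE_UNIT / CONV)
        if m.protocol.mode == "sustained_rate" and t < m.protocol.sustain_duration:
            E = m.protocol.stiffness_E if m.protocol.stiffness_E is not None else p.E
            rate = p.K_sf * E / (p.C * p.LD + E)
            d[ix("FAKmi_s")] -= rate * g("FAKmi_s")
            d[ix("FAK_s")] += rate * g("FAKmi_s")

    # ---- RhoA ---------------------------------------------------------
    if case.rhoa_compartment == "cytosol":
        rho = g("RhoA_v")
        if case.case_id == 1:
            act = p.K_frho * fak**2 * g("RhoAci")
        else:  # case 3: membrane flux on the activation footprint
            act = (m.N * p.K_frho * fak**2 * g("RhoAci") * aact_over_v
                   * (SURFACE_UNIT / CONV))
        d[ix("RhoA_v")] += act - p.K_drho * rho
        d[ix("RhoAci")] += p.K_drho * rho - act
        rock_act = p.K_rrho * rho * g("ROCKi")
        mdia_act = p.K_mrho * rho * g("mDiai")
    else:
        j = p.K_on * g("RhoAci") - m.N * p.K_off * g("RhoAmi_s")
        d[ix("RhoAmi_s")] += j
        d[ix("RhoAci")] -= j * a_over_v * (SURFACE_UNIT / CONV)
        if case.fak_compartment == "membrane":
            # FAK only occupies the footprint: it meets that area fraction
            # of the (uniform) membrane-inactive RhoA pool
            act = p.K_frho * fak**2 * g("RhoAmi_s") * (m.A_act / m.A)
        else:  # case 2
            act = p.K_frho * fak**2 * g("RhoAmi_s")
        rho_m = g("RhoA_s")
        d[ix("RhoA_s")] += act - p.K_drho * rho_m
        d[ix("RhoAmi_s")] += p.K_drho * rho_m - act
        rock_act = m.N * p.K_rrho * rho_m * g("ROCKi") * a_over_v * (SURFACE_UNIT / CONV)
        mdia_act = m.N * p.K_mrho * rho_m * g("mDiai") * a_over_v * (SURFACE_UNIT / CONV)

    # ---- ROCK / mDia --------------------------------------------------
    d[ix("ROCK")] += rock_act - p.Kd_rock * g("ROCK")
    d[ix("ROCKi")] += p.Kd_rock * g("ROCK") - rock_act
    d[ix("mDia")] += mdia_act - p.K_dm * g("mDia")
    d[ix("mDiai")] += p.K_dm * g("mDia") - mdia_act

    t_rock = max(g("ROCK") - p.ROCK_b, 0.0)
    t_mdia = max(g("mDia") - p.mDia_b, 0.0)

    myo = p.K_my * p.epsilon * t_rock * g("Myoi")
    d[ix("Myo")] += myo - p.K_dmy * g("Myo")
    d[ix("Myoi")] += p.K_dmy * g("Myo") - myo

    limk = p.K_lr * p.tau * t_rock * g("LIMKi")
    d[ix("LIMK")] += limk - p.K_dl * g("LIMK")
    d[ix("LIMKi")] += p.K_dl * g("LIMK") - limk

    cof = p.K_turnover * g("Cofi") - p.K_cl * g("LIMK") ** 2 * g("Cof")
    d[ix("Cof")] += cof
    d[ix("Cofi")] -= cof

    assembly = p.K_f * p.alpha * t_mdia * g("Gactin")
    if p.eq14_literal_mdia:
        assembly *= g("mDia")
    f_net = assembly - (p.K_dep + p.K_dfc * g("Cof")) * g("Fcyto")
    d[ix("Fcyto")] += f_net
    d[ix("Gactin")] -= f_net

    yt_act = p.K_cy * g("Fcyto") * g("Myo") * g("YTci")
    # nuclear import is a bare surface flux over the (small) nuclear area
    imp = p.K_CN * g("YTc") * m.A_nuc / m.V
    d[ix("YTc")] += yt_act - p.K_dcy * g("YTc") - imp
    d[ix("YTci")] += p.K_dcy * g("YTc") - yt_act
    d[ix("YTn")] += imp * CONV * m.V
    return d


def _totals(m: CompartmentModel, Y: np.ndarray) -> Dict[str, np.ndarray]:
    """Per-species molecule totals from the state matrix (n_species, n_t)."""
    out = {}
    for i, name in enumerate(m.species):
        if name == "YTn":
            out["YTn"] = Y[i]
        elif name.endswith("_s"):
            area = m.A_act if name.startswith("FAK") else m.A
            out[name.replace("_s", "")] = Y[i] * SURFACE_UNIT * area
        else:
            out[name.replace("_v", "")] = Y[i] * CONV * m.V
    return out


def solve(
    model: CompartmentModel,
    t_end: float,
    t_eval: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> OracleResult:
    """Integrate the stiff reduced system with an implicit solver."""
    y0 = _initial_vector(model)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, max(int(t_end) + 1, 2))
    sol = solve_ivp(
        _rhs, (0.0, float(t_end)), y0, args=(model,), method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=atol, max_step=np.inf,
    )
    if not sol.success:
        raise RuntimeError(f"oracle integration failed: {sol.message}")
    totals = _totals(model, sol.y)
    yt_all = totals["YTc"] + totals["YTci"] + totals["YTn"]
    ytnf = totals["YTn"] / yt_all
    nuclear_conc = totals["YTn"] / (CONV * model.nuclear_volume)
    return OracleResult(sol.t, totals, ytnf, nuclear_conc, model)


def compare(pde_result, ode_result: OracleResult, threshold: Optional[float] = None):
    """Per-species max relative deviation of molecule totals over time.

    The PDE result must have been recorded at the same times.  Deviations
    are normalized by the family's maximum total so that species passing
    through zero do not blow up the ratio.  Returns a dict; if
    ``threshold`` is given, adds a ``"pass"`` entry.
    """
    if not np.allclose(pde_result.times, ode_result.times):
        raise ModelError("results were recorded at different times")
    report = {}
    worst = 0.0
    for name, ode_tot in ode_result.totals.items():
        pde_tot = pde_result.totals.get(name)
        if pde_tot is None:
            continue
        scale = max(float(np.max(np.abs(ode_tot))), 1e-300)
        dev = float(np.max(np.abs(pde_tot - ode_tot))) / scale
        report[name] = dev
        worst = max(worst, dev)
    report["max"] = worst
    if threshold is not None:
        report["pass"] = worst <= threshold
    return report
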