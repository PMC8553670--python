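"""Species, parameters, case logic, kinetics and boundary fluxes.

The signaling cascade is FAK -> RhoA -> {ROCK, mDia} -> {myosin, LIMK/cofilin,
F-actin} -> YAP/TAZ.  Every protein has an active and an inactive form that
exchange through activation/deactivation terms, so each family's total
molecule count is conserved; G-actin is the inactive form of F-actin and the
nucleus accumulates YAP/TAZ without export.

Units
-----
Volumetric concentrations are carried in uM; membrane-bound species as
raw surface densities in molecules/um^2 (``SURFACE_UNIT`` = 1 molecule
per um^2 per numeric unit), the native membrane representation of
finite-volume cell simulators, and the printed rate constants act on
these numbers directly (several printed units are internally
inconsistent as dimensions and are honored as numeric values; see
docs/methods.md).  Documented uM figures for membrane pools are displays,
molecules/(602.214*area): the standard 58,104.35 active FAK molecules
read 0.035 uM spread through the cytosol but 147 molecules/um^2
(0.24 uM-equivalent) on the 402-um^2 contact disk.  On the raw density
scale the membrane reactions are effectively saturated while FAK is
dense — which is exactly what makes membrane localization decisive —
and boundary fluxes convert to the volumetric scale with 602.214
molecules/um^3 per uM, so every exchange conserves molecules exactly.
Nuclear import carries no such conversion: it is the bare surface flux
K_CN * YAPTAZ_c over the small nuclear membrane, the bottleneck that
sets the translocation timescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from .geometry import CellGeometry, MOLECULES_PER_UM3_PER_UM as CONV

__all__ = [
    "ParameterSet",
    "CaseConfig",
    "ActivationProtocol",
    "SpeciesState",
    "case_config",
    "threshold",
    "volumetric_rates",
    "boundary_fluxes",
    "nuclear_import",
    "initialize_state",
    "sustained_activation_rate",
    "family_totals",
    "FAMILIES",
]


class ModelError(ValueError):
    """Configuration or state inconsistent with the requested case."""


#: molecules per um^2 corresponding to one numeric unit of a surface field
#: (surface species are carried as raw densities in molecules/um^2)
SURFACE_UNIT = 1.0


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants and diffusion coefficients (printed values).

    Rates in s^-1 unless the printed unit says otherwise; diffusion in
    um^2 s^-1; thresholds and C in uM; E in kPa.
    """

    K_frho: float = 9.0            # FAK-dependent RhoA activation
    mDia_b: float = 0.13           # mDia threshold
    K_drho: float = 0.625          # RhoA deactivation
    ROCK_b: float = 0.26           # ROCK threshold
    LD: float = 2.0                # ligand density (dimensionless)
    C: float = 45.0                # stiffness half-saturation scale
    K_df: float = 0.035            # FAK deactivation
    K_sf: float = 0.3795           # integrin-driven FAK activation
    K_rrho: float = 2.2            # RhoA-dependent ROCK activation
    Kd_rock: float = 0.8           # ROCK deactivation
    K_lr: float = 0.07             # ROCK-dependent LIMK activation
    K_dl: float = 2.0              # LIMK deactivation
    tau: float = 200.0             # LIMK activation amplification
    K_dm: float = 1.0              # mDia deactivation
    K_mrho: float = 1.0            # RhoA-dependent mDia activation
    K_my: float = 0.015            # myosin activation
    K_dmy: float = 0.067           # myosin deactivation
    epsilon: float = 40.0          # myosin activation amplification
    E: float = 1.0e6               # substrate stiffness (kPa)
    K_turnover: float = 0.04       # cofilin dephosphorylation (activation)
    K_cl: float = 0.7              # LIMK-dependent cofilin phosphorylation
    alpha: float = 40.0            # mDia-dependent F-actin amplification
    K_dep: float = 3.5             # F-actin depolymerization
    K_dfc: float = 8.0             # cofilin-dependent F-actin severing
    K_f: float = 0.4               # F-actin polymerization
    K_CN: float = 0.4              # YAP/TAZ nuclear import
    K_cy: float = 20.0             # YAP/TAZ activation
    K_dcy: float = 0.1             # YAP/TAZ deactivation
    KF_on: float = 0.029           # FAK membrane binding
    KF_off: float = 0.017          # FAK membrane unbinding
    K_on: float = 20.0             # RhoA membrane binding
    K_off: float = 0.5             # RhoA membrane unbinding
    # diffusion coefficients
    D_FAKci: float = 15.96         # inactive (and active) cytosolic FAK
    D_FAKmi: float = 0.0           # membrane-bound inactive FAK
    D_FAK: float = 0.0             # membrane-bound active FAK (sweepable)
    D_RhoAci: float = 28.03        # inactive cytosolic RhoA
    D_RhoAmi: float = 0.06         # membrane-bound inactive RhoA
    D_RhoA: float = 0.06           # active RhoA (membrane, or cytosolic in case 3)
    D_ROCK: float = 11.39
    D_m: float = 15.16             # mDia
    D_my: float = 9.76             # myosin
    D_LIMK: float = 18.82
    D_c: float = 29.44             # cofilin
    D_Fcyto: float = 0.001
    D_Gactin: float = 22.58
    D_YAPTAZc: float = 20.71
    #: use the literal extra mDia factor in the F-actin assembly term
    eq14_literal_mdia: bool = False

    def with_overrides(self, **overrides) -> "ParameterSet":
        unknown = set(overrides) - set(self.__dataclass_fields__)
        if unknown:
            raise ModelError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **overrides)


@dataclass(frozen=True)
class CaseConfig:
    """Which compartments FAK and RhoA occupy and which exchanges run."""

    case_id: int
    fak_compartment: str   # "cytosol" | "membrane"
    rhoa_compartment: str  # "cytosol" | "membrane"
    fak_exchange: bool     # FAKci <-> FAKmi binding/unbinding (case 5)
    rhoa_exchange: bool    # RhoAci <-> RhoAmi binding/unbinding (cases 2,4,5)


_CASES = {
    1: CaseConfig(1, "cytosol", "cytosol", False, False),
    2: CaseConfig(2, "cytosol", "membrane", False, True),
    3: CaseConfig(3, "membrane", "cytosol", False, False),
    4: CaseConfig(4, "membrane", "membrane", False, True),
    5: CaseConfig(5, "membrane", "membrane", True, True),
}


def case_config(case_id: int) -> CaseConfig:
    try:
        return _CASES[case_id]
    except KeyError:
        raise ModelError(f"unknown case id {case_id!r}") from None


@dataclass(frozen=True)
class ActivationProtocol:
    """How the cascade is triggered.

    ``initial_amount``: a fixed number of active FAK molecules at t = 0
    (identical across cases and radii).  ``sustained_rate``: no active FAK
    initially; inactive membrane-bound FAK in the activation footprint is
    activated at the stiffness-dependent rate for ``sustain_duration``
    seconds, with the total FAK amount equal to active+inactive of the
    other mode.
    """

    mode: str = "initial_amount"
    initial_active_FAK: float = 58104.35      # molecules
    initial_inactive_FAK: float = 1260018.86  # molecules
    sustain_duration: float = 100.0           # s
    stiffness_E: Optional[float] = None       # kPa; None -> ParameterSet.E

    @property
    def total_FAK(self) -> float:
        return self.initial_active_FAK + self.initial_inactive_FAK


#: conserved families: (volume species, surface species, counts nucleus?)
FAMILIES = {
    "FAK": (("FAKci", "FAK"), ("FAK", "FAKmi"), False),
    "RhoA": (("RhoAci", "RhoA"), ("RhoA", "RhoAmi"), False),
    "ROCK": (("ROCK", "ROCKi"), (), False),
    "mDia": (("mDia", "mDiai"), (), False),
    "Myo": (("Myo", "Myoi"), (), False),
    "LIMK": (("LIMK", "LIMKi"), (), False),
    "Cofilin": (("Cof", "Cofi"), (), False),
    "Actin": (("Fcyto", "Gactin"), (), False),
    "YAPTAZ": (("YTc", "YTci"), (), True),
}


@dataclass
class SpeciesState:
    """Fields of the coupled volume/surface/nucleus system.

    ``vol`` maps species name -> array over packed cytosol voxels (uM);
    ``surf`` maps name -> array over membrane faces (molecules/um^2);
    ``ytn`` is the well-mixed nuclear YAP/TAZ amount in molecules.
    """

    vol: Dict[str, np.ndarray]
    surf: Dict[str, np.ndarray]
    ytn: float = 0.0

    def copy(self) -> "SpeciesState":
        return SpeciesState(
            {k: v.copy() for k, v in self.vol.items()},
            {k: v.copy() for k, v in self.surf.items()},
            self.ytn,
        )

    def validate(self, tol: float = 1e-8) -> None:
        for table in (self.vol, self.surf):
            for name, arr in table.items():
                if not np.all(np.isfinite(arr)):
                    raise ModelError(f"non-finite values in species {name}")
                if arr.min() < -tol:
                    raise ModelError(
                        f"negative concentration in species {name}: {arr.min()}"
                    )


def family_totals(state: SpeciesState, geometry: CellGeometry) -> Dict[str, float]:
    """Total molecules per conserved family (volume + surface + nucleus)."""
    vv = geometry.voxel_volume
    out = {}
    for fam, (vol_names, surf_names, with_nucleus) in FAMILIES.items():
        total = 0.0
        for name in vol_names:
            if name in state.vol:
                total += float(state.vol[name].sum()) * vv * CONV
        for name in surf_names:
            if name in state.surf:
                total += float((state.surf[name] * geometry.mem_area).sum()) * SURFACE_UNIT
        if with_nucleus:
            total += state.ytn
        out[fam] = total
    return out


def threshold(value, base: float):
    """T function: max(0, value - base), elementwise."""
    if base < 0:
        raise ModelError("threshold base must be nonnegative")
    return np.maximum(np.asarray(value) - base, 0.0)


def volumetric_rates(
    state: SpeciesState,
    params: ParameterSet,
    case: CaseConfig,
    validate: bool = True,
) -> Dict[str, np.ndarray]:
    """Pointwise reaction rates (uM/s) on cytosol voxels.

    Contains every purely volumetric reaction; membrane-coupled terms live
    in :func:`boundary_fluxes`.  Each activation/deactivation term appears
    with opposite signs on the active and inactive partner, so summed
    molecule rates vanish per family.
    """
    if validate:
        state.validate()
    p = params
    v = state.vol
    r: Dict[str, np.ndarray] = {name: np.zeros_like(arr) for name, arr in v.items()}

    # FAK: active form decays; volumetric only when FAK is cytosolic
    if case.fak_compartment == "cytosol":
        decay = p.K_df * v["FAK"]
        r["FAK"] -= decay
        r["FAKci"] += decay

    # RhoA
    if case.case_id == 1:
        act = p.K_frho * v["FAK"] ** 2 * v["RhoAci"]
        deact = p.K_drho * v["RhoA"]
        r["RhoA"] += act - deact
        r["RhoAci"] += deact - act
    elif case.case_id == 3:
        # activation happens as a boundary flux; deactivation is volumetric
        deact = p.K_drho * v["RhoA"]
        r["RhoA"] -= deact
        r["RhoAci"] += deact

    # ROCK / mDia: deactivation always volumetric; activation volumetric
    # only when active RhoA is cytosolic (cases 1 and 3)
    rock_deact = p.Kd_rock * v["ROCK"]
    mdia_deact = p.K_dm * v["mDia"]
    r["ROCK"] -= rock_deact
    r["ROCKi"] += rock_deact
    r["mDia"] -= mdia_deact
    r["mDiai"] += mdia_deact
    if case.rhoa_compartment == "cytosol":
        rock_act = p.K_rrho * v["RhoA"] * v["ROCKi"]
        mdia_act = p.K_mrho * v["RhoA"] * v["mDiai"]
        r["ROCK"] += rock_act
        r["ROCKi"] -= rock_act
        r["mDia"] += mdia_act
        r["mDiai"] -= mdia_act

    t_rock = threshold(v["ROCK"], p.ROCK_b)
    t_mdia = threshold(v["mDia"], p.mDia_b)

    myo_act = p.K_my * p.epsilon * t_rock * v["Myoi"]
    myo_deact = p.K_dmy * v["Myo"]
    r["Myo"] += myo_act - myo_deact
    r["Myoi"] += myo_deact - myo_act

    limk_act = p.K_lr * p.tau * t_rock * v["LIMKi"]
    limk_deact = p.K_dl * v["LIMK"]
    r["LIMK"] += limk_act - limk_deact
    r["LIMKi"] += limk_deact - limk_act

    cof_act = p.K_turnover * v["Cofi"]
    cof_deact = p.K_cl * v["LIMK"] ** 2 * v["Cof"]
    r["Cof"] += cof_act - cof_deact
    r["Cofi"] += cof_deact - cof_act

    assembly = p.K_f * p.alpha * t_mdia * v["Gactin"]
    if p.eq14_literal_mdia:
        assembly = assembly * v["mDia"]
    disassembly = (p.K_dep + p.K_dfc * v["Cof"]) * v["Fcyto"]
    r["Fcyto"] += assembly - disassembly
    r["Gactin"] += disassembly - assembly

    yt_act = p.K_cy * v["Fcyto"] * v["Myo"] * v["YTci"]
    yt_deact = p.K_dcy * v["YTc"]
    r["YTc"] += yt_act - yt_deact
    r["YTci"] += yt_deact - yt_act
    return r


def sustained_activation_rate(params: ParameterSet, E: Optional[float] = None) -> float:
    """Stiffness-modulated FAK activation rate K_sf * E / (C*LD + E).

    Saturates to K_sf on rigid substrates (the standard E = 1e6 kPa) and
    equals K_sf/2 at E = C*LD.
    """
    E_val = params.E if E is None else E
    if E_val < 0:
        raise ModelError("substrate stiffness must be nonnegative")
    c_eff = params.C * params.LD
    return params.K_sf * E_val / (c_eff + E_val)


def boundary_fluxes(
    state: SpeciesState,
    params: ParameterSet,
    case: CaseConfig,
    geometry: CellGeometry,
    t: float = 0.0,
    protocol: Optional[ActivationProtocol] = None,
    include_exchange: bool = True,
):
    """Membrane-coupled rate contributions.

    ``include_exchange=False`` omits the linear binding/unbinding fluxes
    (the solver integrates those exactly with a separate propagator).

    Returns ``(vol_rates, surf_rates)``: volumetric contributions (uM/s,
    dense over cytosol voxels) and surface contributions
    (molecules/um^2/s over membrane faces).  Every exchange is written
    symmetrically so molecules crossing a face balance exactly: a surface
    rate ``j`` on face area ``A_f`` pairs with a volumetric rate
    ``-j * A_f / (V_voxel * 602.214)`` on the adjacent voxel.
    """
    p = params
    g = geometry
    n_cyt = g.n_cytosol
    voxvol = g.voxel_volume
    fvox = g.mem_voxel
    farea = g.mem_area
    act = g.activation_faces
    N = g.N

    vol_rates: Dict[str, np.ndarray] = {}
    surf_rates: Dict[str, np.ndarray] = {name: np.zeros_like(arr)
                                         for name, arr in state.surf.items()}

    def add_vol(name, face_mask_or_idx, per_face_rate):
        """Accumulate a per-face volumetric contribution onto voxels."""
        arr = vol_rates.setdefault(name, np.zeros(n_cyt))
        arr += np.bincount(fvox[face_mask_or_idx],
                           weights=per_face_rate * farea[face_mask_or_idx] / voxvol,
                           minlength=n_cyt)

    # ---- FAK on the membrane: decay and (case 5) exchange -------------
    if case.fak_compartment == "membrane":
        fak = state.surf["FAK"]
        decay = p.K_df * fak
        surf_rates["FAK"] -= decay
        surf_rates["FAKmi"] += decay
        if case.fak_exchange and include_exchange:
            c_adj = state.vol["FAKci"][fvox[act]]
            j = p.KF_on * c_adj - N * p.KF_off * state.surf["FAKmi"][act]
            surf_rates["FAKmi"][act] += j
            add_vol("FAKci", act, -j * (SURFACE_UNIT / CONV))
        if protocol is not None and protocol.mode == "sustained_rate":
            if t < protocol.sustain_duration:
                rate = sustained_activation_rate(p, protocol.stiffness_E)
                burst = rate * state.surf["FAKmi"] * act
                surf_rates["FAKmi"] -= burst
                surf_rates["FAK"] += burst
    elif protocol is not None and protocol.mode == "sustained_rate":
        raise ModelError("sustained activation requires membrane-bound FAK")

    # ---- RhoA exchange (cases 2, 4, 5) over the whole membrane --------
    if case.rhoa_exchange:
        if include_exchange:
            c_adj = state.vol["RhoAci"][fvox]
            j = p.K_on * c_adj - N * p.K_off * state.surf["RhoAmi"]
            surf_rates["RhoAmi"] += j
            add_vol("RhoAci", slice(None), -j * (SURFACE_UNIT / CONV))
    elif case.rhoa_compartment == "membrane":
        raise ModelError("membrane RhoA without exchange is not a valid case")

    # ---- RhoA activation ----------------------------------------------
    if case.rhoa_compartment == "membrane":
        # surface reaction RhoAmi -> RhoA, driven by active FAK
        if case.fak_compartment == "membrane":
            fak_sq = state.surf["FAK"] ** 2
        else:  # case 2: adjacent cytosolic active FAK
            fak_sq = state.vol["FAK"][fvox] ** 2
        act_rate = p.K_frho * fak_sq * state.surf["RhoAmi"]
        deact = p.K_drho * state.surf["RhoA"]
        surf_rates["RhoA"] += act_rate - deact
        surf_rates["RhoAmi"] += deact - act_rate
        # membrane activation of ROCK / mDia (boundary sink of inactive,
        # matched source of active, at the face)
        rho_m = state.surf["RhoA"]
        j_rock = N * p.K_rrho * rho_m * state.vol["ROCKi"][fvox]
        j_mdia = N * p.K_mrho * rho_m * state.vol["mDiai"][fvox]
        add_vol("ROCKi", slice(None), -j_rock * (SURFACE_UNIT / CONV))
        add_vol("ROCK", slice(None), j_rock * (SURFACE_UNIT / CONV))
        add_vol("mDiai", slice(None), -j_mdia * (SURFACE_UNIT / CONV))
        add_vol("mDia", slice(None), j_mdia * (SURFACE_UNIT / CONV))
    elif case.case_id == 3:
        # boundary activation of cytosolic RhoA by membrane FAK: with the
        # dense surface FAK this is a near-perfect absorber for inactive
        # RhoA at the footprint (diffusion-limited activation)
        fak_sq = state.surf["FAK"][act] ** 2
        j = N * p.K_frho * fak_sq * state.vol["RhoAci"][fvox[act]]
        add_vol("RhoAci", act, -j * (SURFACE_UNIT / CONV))
        add_vol("RhoA", act, j * (SURFACE_UNIT / CONV))

    return vol_rates, surf_rates


def nuclear_import(state: SpeciesState, params: ParameterSet, geometry: CellGeometry):
    """Irreversible YAP/TAZ import across the nuclear membrane.

    Returns ``(vol_rate, ytn_rate)``: the sink on cytosol voxels adjacent to
    nuclear faces (uM/s) and the matched gain of nuclear molecules per
    second.  The flux is the bare surface flux ``K_CN * YTc`` (uM um/s) over
    the nuclear membrane — unlike the plasma-membrane conditions, nuclear
    import carries no N conversion factor, which makes the small nuclear
    surface the rate-limiting bottleneck of translocation (effective
    whole-cell rate K_CN * A_nuc / V ~ 0.02 1/s).  Staircase face areas are
    rescaled so the total flux corresponds to the smooth nuclear area.
    """
    g = geometry
    j = params.K_CN * state.vol["YTc"][g.nuc_voxel]
    area_eff = g.nuc_area * (g.nuclear_area / g.nuclear_area_staircase)
    vol_rate = -np.bincount(g.nuc_voxel, weights=j * area_eff / g.voxel_volume,
                            minlength=g.n_cytosol)
    ytn_rate = float((j * area_eff).sum()) * CONV
    return vol_rate, ytn_rate


def initialize_state(
    geometry: CellGeometry,
    case: CaseConfig,
    protocol: ActivationProtocol,
    params: ParameterSet,
) -> SpeciesState:
    """Initial fields: inactive pools at 1 uM, F-actin 1 uM, FAK per protocol.

    The active/inactive FAK molecule counts are identical across cases and
    radii; the activation region determines where (and at what numeric
    concentration) the active amount is placed.
    """
    g = geometry
    n_cyt = g.n_cytosol
    n_face = g.n_membrane_faces
    voxvol = g.voxel_volume

    ones = np.ones(n_cyt)
    vol = {
        "RhoAci": ones.copy(),
        "ROCK": np.zeros(n_cyt), "ROCKi": ones.copy(),
        "mDia": np.zeros(n_cyt), "mDiai": ones.copy(),
        "Myo": np.zeros(n_cyt), "Myoi": ones.copy(),
        "LIMK": np.zeros(n_cyt), "LIMKi": ones.copy(),
        "Cof": np.zeros(n_cyt), "Cofi": ones.copy(),
        "Fcyto": ones.copy(), "Gactin": np.zeros(n_cyt),
        "YTc": np.zeros(n_cyt), "YTci": ones.copy(),
    }
    surf: Dict[str, np.ndarray] = {}

    if case.rhoa_compartment == "cytosol":
        vol["RhoA"] = np.zeros(n_cyt)
    else:
        surf["RhoA"] = np.zeros(n_face)
        surf["RhoAmi"] = np.zeros(n_face)

    act = g.activation_faces
    act_area = g.activation_area
    if protocol.mode == "initial_amount":
        m_act = protocol.initial_active_FAK
        if case.fak_compartment == "cytosol":
            vol["FAK"] = np.zeros(n_cyt)
            if case.case_id == 1:
                vol["FAK"][:] = m_act / (CONV * g.cytosol_volume)
            else:  # case 2: thin basal band over the activation footprint
                band = g.cyt_index[g.band_mask]
                if band.size == 0:
                    raise ModelError("activation band has zero measure")
                vol["FAK"][band] = m_act / (CONV * band.size * voxvol)
            surf.pop("FAKmi", None)
        else:
            surf["FAK"] = np.zeros(n_face)
            surf["FAK"][act] = m_act / (SURFACE_UNIT * act_area)
            surf["FAKmi"] = np.zeros(n_face)
        vol["FAKci"] = np.full(
            n_cyt, protocol.initial_inactive_FAK / (CONV * g.cytosol_volume)
        )
    elif protocol.mode == "sustained_rate":
        if case.fak_compartment != "membrane":
            raise ModelError("sustained activation requires membrane-bound FAK")
        surf["FAK"] = np.zeros(n_face)
        surf["FAKmi"] = np.zeros(n_face)
        total = protocol.total_FAK
        if case.fak_exchange:  # case 5: all FAK starts cytosolic
            vol["FAKci"] = np.full(n_cyt, total / (CONV * g.cytosol_volume))
        else:  # case 4: all inactive FAK already at the membrane
            vol["FAKci"] = np.zeros(n_cyt)
            surf["FAKmi"][act] = total / (SURFACE_UNIT * act_area)
    else:
        raise ModelError(f"unknown activation mode {protocol.mode!r}")

    return SpeciesState(vol=vol, surf=surf, ytn=0.0)
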