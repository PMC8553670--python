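# Methods

## Model

`yaptaz3d` solves a 3D reaction–diffusion model of mechanotransduction from
focal adhesion kinase (FAK) to nuclear YAP/TAZ inside a voxelized cell:

FAK → RhoA → {ROCK, mDia} → {myosin, LIMK → cofilin, F-actin} → YAP/TAZ.

Every protein has an active and an inactive form that exchange through
first-order (or mass-action) activation/deactivation terms; G-actin is the
inactive form of F-actin, and cofilin is the one species activated by
*de*phosphorylation.  Volumetric species obey

∂S/∂t = Q_Si·S_i − d_S·S + D_S ∇²S,

with the matching inactive equation of opposite reaction sign, so each
family's total molecule count is invariant.  The cascade kinetics are:

- RhoA activation: K_frho · FAK² · RhoA_inactive, deactivation K_drho · RhoA.
- ROCK / mDia activation: K_rrho · RhoA · ROCK_i and K_mrho · RhoA · mDia_i;
  deactivation Kd_rock, K_dm.
- Myosin: K_my · ε · T_ROCK · Myo_i − K_dmy · Myo.
- LIMK: K_lr · τ · T_ROCK · LIMK_i − K_dl · LIMK.
- Cofilin: K_turnover · Cof_i − K_cl · LIMK² · Cof.
- F-actin: K_f · α · T_mDia · G-actin − K_dep · F − K_dfc · Cof · F.
- YAP/TAZ: K_cy · F · Myo · YAPTAZ_ci − K_dcy · YAPTAZ_c, with irreversible
  nuclear import (no export; the nuclear pool only grows) as the bare
  surface flux K_CN · YAPTAZ_c across the nuclear membrane.  Unlike the
  plasma-membrane boundary conditions, the import carries no volume-to-
  surface conversion factor, so the small nuclear area (~121 um²) makes
  import the rate-limiting step (effective whole-cell rate
  K_CN·A_nuc/V ≈ 0.017 s⁻¹) — the reason K_CN is the parameter that was
  fitted to set the steady nuclear fraction, and the reason steady YTNF
  stays below 1 even when the upstream cascade saturates.

T_x = max(0, x − x_B) are threshold functions: ROCK and mDia must exceed
x_B (0.26 and 0.13 uM) before they drive the cytoskeletal layer.  These
thresholds are what makes membrane localization decisive: compartment
averages stay subthreshold for every activation modality, and only the
locally elevated concentrations produced by membrane-confined reactions
cross them.

There is no baseline (FAK-independent) activation of RhoA, myosin, LIMK or
F-actin, no LATS branch, and no YAP/TAZ export or constitutive import —
the cascade is driven purely by the FAK input.  Consequently a run without
FAK activation provably yields zero nuclear YAP/TAZ, and the nuclear
fraction YTNF = YAPTAZ_n / (YAPTAZ_c + YAPTAZ_ci + YAPTAZ_n) (all in
molecules) is non-decreasing in time and confined to [0, 1].

## Activation modalities (cases 1–5)

| case | FAK | RhoA | exchange |
|------|-----|------|----------|
| 1 | cytosolic | cytosolic | none |
| 2 | cytosolic, activated in a 0.5-um basal band | membrane | RhoA on/off |
| 3 | membrane-bound, immobile | cytosolic | none |
| 4 | membrane-bound, immobile | membrane | RhoA on/off |
| 5 | membrane-bound | membrane | RhoA and FAK on/off |

Membrane-bound active RhoA activates ROCK/mDia through boundary fluxes on
the membrane (cases 2, 4, 5); cytosolic active RhoA does so volumetrically
(cases 1, 3).  In case 3 RhoA is activated by membrane FAK through a
boundary flux on the activation footprint.  Binding/unbinding follows
K_on·c − N·K_off·m (RhoA, all membrane faces) and KF_on·c − N·KF_off·m
(FAK, basal footprint only, case 5), where N = V/A converts volume to
membrane units.

Two trigger protocols are provided.  *Initial amount*: 58,104.35 active and
1,260,018.86 inactive FAK molecules at t = 0, held constant across cases
and radii; under this protocol cases 4 and 5 coincide exactly because the
FAK (un)binding path is bypassed.  *Sustained rate*: zero initial active
FAK and the same total; membrane-bound inactive FAK in the footprint is
activated for 100 s at the stiffness-dependent rate
r(E) = K_sf · E / (C·LD + E), which is K_sf/2 at E = C·LD and saturates to
K_sf = 0.3795 1/s on rigid substrates (E = 1e6 kPa).  The saturating form
on the stiffness axis scaled by the ligand-density factor LD is this
package's closure of an interface that is otherwise only pinned at those
two points; both C and LD are overridable.

## Units and the membrane numeric convention

Volumetric concentrations are carried in uM and surface species as raw
densities in molecules/um² — the native membrane representation of
finite-volume cell simulators.  The printed rate constants act on these
numbers directly; several printed units (K_frho in s⁻², K_off and KF_off
in um⁻¹s⁻¹) are internally inconsistent as dimensions and are honored as
numeric values.  Documented uM figures for membrane pools are displays
(molecules/(602.214·area)): the same 58,104.35 active-FAK molecules read
0.035 uM spread through the cytosol (case 1), ≈0.5 uM in the thin basal
band (case 2) and 147 molecules/um² (0.24 uM-equivalent) on the 402-um²
contact disk (cases 3–5).

This scale has a strong dynamical consequence: with FAK² of order 2e4 on
the contact disk, the membrane reactions K_frho·FAK²·(…) are effectively
*saturated* while membrane FAK is dense — inactive RhoA reaching the
footprint is converted on contact.  Case 3's activation is then
diffusion-limited (the cytosolic RhoA pool is absorbed at the base almost
immediately), cases 4–5's active RhoA grows at the pace of membrane
binding (K_on-limited, over hundreds of seconds), and the firing window
depends only logarithmically on the FAK density — which is why the
steady-state nuclear fraction varies only mildly across spreading radii.
Meanwhile the *cytosolic* FAK of cases 1–2 acts on the uM scale (0.035
after dilution), far too weak to push ROCK or mDia over threshold: the
silent/signaling dichotomy between cytosolic and membrane activation is
a direct consequence of the representation.  Nuclear import, the one
boundary condition without a conversion factor, caps how fast the
nuclear pool can fill regardless of how hard the cascade fires.

## Geometry

The cell is an axisymmetric dome z(r) = H(1 − (r/r_c)²)^p over a
substrate-contact disk of radius r_c = R·√f, where R ∈ {14, 16, 18, 20}
um is the nominal spreading ("base") radius, the contact-area fraction
defaults to f = 1/2, and H is solved so the volume is exactly 2925 um³.
With the parabolic profile p = 1 the standard R = 16 cell is ~14.6 um
tall with a 402-um² contact disk and ~1.2e3 um² of membrane.  These
proportions — not a flat pancake over the full πR² disk — are the ones
jointly consistent with the documented 402-um² FAK activation area, the
documented initial membrane-FAK concentrations, and a 125-um³ nucleus
whose lowest point sits 4 um above the substrate.  The nucleus is a
sphere wherever it fits under the dome (R ≤ 18) and an equal-volume
oblate spheroid otherwise, mirroring nuclear flattening in strongly
spread cells.  FAK activation and (un)binding occur on the full basal
contact disk; `contact_area_fraction` is configurable (1.0 makes the
contact disk the full πR²).

Voxelization samples the shape with 3³ sub-samples per voxel on a regular
grid (default 80×33×25, matching the reference discretization); boundary
faces form a closed staircase surface with axis-aligned outward normals.
Two area measures coexist deliberately: the conversion factor N = V/A in
the flux laws uses the smooth (quadrature) membrane area — N is a
physical property of the cell, not of the mesh — while per-face transfers
use the actual staircase face areas so that every exchange conserves
molecules exactly.  Voxelized volumes agree with the analytic targets to
well under 1% at the default grid for all radii.

## Numerics

- **Spatial discretization**: conservative finite volumes; 7-point
  Laplacian on cytosol voxels, edge-graph Laplacian on the staircase
  surface (faces sharing a geometric edge coupled by l_edge/(d·A)).  Row
  sums vanish; uniform fields are stationary; zero-flux outer boundaries.
- **Time stepping**: Strang splitting R(dt/2) D(dt) R(dt/2) with the outer
  step on a discrete ladder dt_max/4^k (dt_max = 0.1 s, dt_min = 2 ms),
  shrunk while the largest relative field change per step exceeds 1% —
  the signaling onset is the only phase that needs sub-0.1-s steps.
  Diffusion uses prefactorized implicit solves with dimensional splitting
  (three tridiagonal solves per species: fill-free, unconditionally
  stable, mass-conserving, uniform fields stationary).
- **Reactions**: the network consists entirely of activation/deactivation
  pairs whose coefficients depend on other, more slowly varying fields;
  each pair is advanced by its exact exponential solution under frozen
  coefficients, composed palindromically (second order).  The updates are
  unconditionally stable, positivity-preserving and exactly
  molecule-conserving, which matters because membrane reactions reach
  stiffnesses no explicit substep could resolve.  Membrane
  binding/unbinding (a voxel and its boundary faces form a
  constant-coefficient linear cluster) and nuclear import use precomputed
  matrix exponentials.
- **Conservation**: every reaction and flux is written as an exactly
  paired transfer, so family totals drift only at rounding level
  (observed ~1e-13 relative over full runs, against a 1e-4 requirement).
- **Thresholds**: T_x = max(0, x − x_B) is continuous with a kink; the
  variable outer step resolves threshold-crossing fronts, which is where
  fixed dt = 0.1 s shows visible (first-order) splitting error.
- **Steady state**: |dYTNF/dt| < 1e-6 s⁻¹ sustained for 50 s, or t_end
  (default horizon 3000 s for sweeps), whichever comes first; sweep tables
  record the horizon actually reached.
- **Determinism**: no randomness anywhere; serial summation order.

## Well-mixed oracle

`wellmixed_oracle` is a deliberately independent transcription of the same
kinetics reduced to cytosol/membrane/nucleus compartments (diffusion
dropped, boundary fluxes scaled by the areas they act on, the membrane FAK
pool confined to the activation footprint).  At any spatially uniform
state its right-hand side equals the volume/area-weighted sum of the 3D
rate fields to machine precision — the central anti-transcription-error
check — and the 3D solver must converge to its trajectories when all
diffusivities are scaled ×10³.  Because the two transcriptions are
separate, a kinetics error cannot cancel between them.

## Parameter notes

All kinetic constants and Stokes–Einstein-derived diffusion coefficients
are taken as printed (see `ParameterSet`); K_CN = 0.4 s⁻¹ is the fitted
nuclear import rate.  Membrane-bound FAK does not diffuse by default
(D_FAK = D_FAKmi = 0); membrane-bound inactive RhoA defaults to the active
membrane value 0.06 um²/s, preserving the 500× cytosol/membrane mobility
ratio.  Active cytosolic RhoA (case 3) also uses D_RhoA = 0.06 um²/s.  The
F-actin assembly term is implemented as K_f·α·T_mDia·G-actin, the
dimensionally consistent reading; `eq14_literal_mdia=True` switches to the
literal extra ×mDia factor.

## Problem sizes used in the tests

The test suite runs the full physics on reduced grids chosen as the
package's own accuracy/runtime tradeoff: 40×17×13 for solver unit tests,
32×13×21 for the 100-s transient acceptance checks, 24×11×13 for
steady-state levels and 20×9×11 for sweep and monotonicity runs (the
acceptance checks also relax the outer-step change target to 2%).  The
default 80×33×25 grid is exercised by the geometry tests and by
`scripts/acceptance.py`.  In the saturated membrane regime the reported
quantities depend only weakly on resolution (the firing window is
logarithmic in the surface density), and reduced-grid values agree with
the default grid within a few percent.

## Limitations

- The analytic cell outline is a reconstruction (dome with p = 2), not the
  original mesh; absolute transient concentrations inherit a geometry
  sensitivity of order 10%.
- The staircase membrane biases local surface-to-volume ratios even though
  global areas are corrected; near-membrane layer concentrations are
  resolution-dependent, as in any regular-grid treatment of this model.
- Focal adhesions are a continuous footprint, not discrete structures;
  geometry does not deform; the nucleus is rigid and well-mixed.
- Production/degradation of protein is neglected (short timescales).
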