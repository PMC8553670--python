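"""Voxelized cell geometry for the YAP/TAZ reaction-diffusion model.

The cell is an axisymmetric dome sitting on the substrate plane z = 0,

    z_surface(r) = H * (1 - (r/r_c)**2)**p,

whose substrate-contact disk has radius r_c = base_radius * sqrt(f) with
contact-area fraction f = 1/2 by default: a "base radius" of 16 um (the
14-20 um spreading series) yields a contact area of pi R^2 / 2 ~ 402 um^2.
The apex height H is solved numerically so the enclosed volume equals the
prescribed cell volume (2925 um^3), giving a tall dome (H ~ 15 um at
R = 16 with the default parabolic profile p = 1) whose total membrane
area is ~1.05e3 um^2.  The nucleus is an axisymmetric spheroid of fixed
volume (125 um^3) whose lowest point sits ``nucleus_base_gap`` (4 um)
above the substrate; it is a sphere whenever a sphere fits under the dome
and is flattened into an oblate spheroid of equal volume otherwise
(strongly spread cells flatten their nuclei).

Voxelization samples the shape on a regular grid (default 80 x 33 x 25
cells) and produces boolean cytosol/nucleus masks, staircase boundary-face
lists with axis-aligned outward normals, areas, volumes, and the
volume-to-surface conversion factor N = cytosol volume / membrane area used
by the membrane flux boundary conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

#: molecules per um^3 corresponding to a 1 uM solution
MOLECULES_PER_UM3_PER_UM = 602.214076

#: axis labels for face bookkeeping
_AXES = ("x", "y", "z")

DEFAULT_GRID = (80, 33, 25)
STANDARD_CELL_VOLUME = 2925.0  # um^3
STANDARD_NUCLEAR_VOLUME = 125.0  # um^3
STANDARD_NUCLEUS_GAP = 4.0  # um
#: substrate-contact area as a fraction of pi * base_radius^2
#: (pi R^2 / 2 = 402 um^2 at R = 16 um); the FAK activation footprint is
#: the full contact disk
DEFAULT_CONTACT_AREA_FRACTION = 0.5


class GeometryError(ValueError):
    """Raised when a cell shape or voxelization request is infeasible."""


@dataclass(frozen=True)
class CellShapeSpec:
    """Analytic description of the dome-shaped cell and its nucleus.

    All lengths in um, volumes in um^3.
    """

    base_radius: float
    cell_volume: float = STANDARD_CELL_VOLUME
    nuclear_volume: float = STANDARD_NUCLEAR_VOLUME
    nucleus_base_gap: float = STANDARD_NUCLEUS_GAP
    profile_exponent: float = 1.0
    dome_height: float = 0.0  # solved by build_cell_shape
    nucleus_semiaxis_xy: float = 0.0
    nucleus_semiaxis_z: float = 0.0
    contact_area_fraction: float = DEFAULT_CONTACT_AREA_FRACTION

    @property
    def contact_radius(self) -> float:
        """Radius of the substrate-contact disk."""
        return self.base_radius * np.sqrt(self.contact_area_fraction)

    def surface_height(self, r):
        """Dome height z_surface(r); zero outside the contact disk."""
        r = np.asarray(r, dtype=float)
        u = 1.0 - (r / self.contact_radius) ** 2
        return self.dome_height * np.where(u > 0.0, u, 0.0) ** self.profile_exponent

    @property
    def nucleus_center_z(self) -> float:
        return self.nucleus_base_gap + self.nucleus_semiaxis_z

    @property
    def activation_radius(self) -> float:
        """Radius of the basal activation footprint (the contact disk)."""
        return self.contact_radius

    def lateral_area(self) -> float:
        """Area of the curved dome surface (surface of revolution)."""
        R, H, p = self.contact_radius, self.dome_height, self.profile_exponent

        def integrand(r):
            u = 1.0 - (r / R) ** 2
            ds = -2.0 * H * p * r / R**2 * u ** (p - 1.0) if u > 0 else 0.0
            return 2.0 * np.pi * r * np.hypot(1.0, ds)

        area, _ = quad(integrand, 0.0, R, limit=200)
        return area

    def membrane_area(self) -> float:
        """Total smooth membrane area: dome plus contact disk."""
        return self.lateral_area() + np.pi * self.contact_radius**2

    def nuclear_area(self) -> float:
        """Smooth surface area of the (possibly oblate) nuclear spheroid."""
        a, c = self.nucleus_semiaxis_xy, self.nucleus_semiaxis_z
        if abs(a - c) < 1e-9 * a:
            return 4.0 * np.pi * a**2
        e = np.sqrt(1.0 - (c / a) ** 2)  # oblate: a > c
        return 2.0 * np.pi * a**2 * (1.0 + (1.0 - e**2) / e * np.arctanh(e))


def _dome_volume(radius: float, height: float, p: float) -> float:
    """Enclosed volume of z = height*(1-(r/radius)^2)^p over the contact disk."""
    integrand = lambda r: 2.0 * np.pi * r * height * (1.0 - (r / radius) ** 2) ** p
    vol, _ = quad(integrand, 0.0, radius, limit=200)
    return vol


def _fit_nucleus(radius, height, p, gap, nuclear_volume, clearance=0.2):
    """Semi-axes (a, c) of an equal-volume spheroid that fits under the dome.

    Starts from a sphere and flattens (preserving volume, a^2 c = r_n^3)
    until the top of the nucleus clears the dome surface evaluated at the
    nucleus' lateral extent.
    """
    r_n = (3.0 * nuclear_volume / (4.0 * np.pi)) ** (1.0 / 3.0)

    def fits(c):
        a = np.sqrt(r_n**3 / c)
        if a >= 0.95 * radius:
            return False
        rr = np.linspace(0.0, a, 64)
        z_top = gap + c + c * np.sqrt(np.clip(1.0 - (rr / a) ** 2, 0.0, None))
        u = np.clip(1.0 - (rr / radius) ** 2, 0.0, None)
        dome = height * u**p
        return bool(np.all(z_top + clearance <= dome))

    if fits(r_n):
        return r_n, r_n
    for c in np.linspace(r_n, 0.3, 200):
        if fits(c):
            return float(np.sqrt(r_n**3 / c)), float(c)
    raise GeometryError(
        f"nucleus of volume {nuclear_volume} um^3 cannot be placed {gap} um above "
        f"the base under a dome of height {height:.2f} um (radius {radius} um)"
    )


def build_cell_shape(
    base_radius: float,
    cell_volume: float = STANDARD_CELL_VOLUME,
    nuclear_volume: float = STANDARD_NUCLEAR_VOLUME,
    nucleus_base_gap: float = STANDARD_NUCLEUS_GAP,
    profile_exponent: float = 1.0,
    contact_area_fraction: float = DEFAULT_CONTACT_AREA_FRACTION,
) -> CellShapeSpec:
    """Solve the dome height for the requested volume and place the nucleus.

    Raises
    ------
    GeometryError
        If the requested volumes are unachievable for this radius.
    """
    if base_radius <= 0:
        raise GeometryError("base_radius must be positive")
    if cell_volume <= 0 or nuclear_volume <= 0:
        raise GeometryError("volumes must be positive")
    if nuclear_volume >= cell_volume:
        raise GeometryError("nuclear volume must be smaller than cell volume")

    p = profile_exponent
    r_c = base_radius * np.sqrt(contact_area_fraction)
    # closed form H = (p+1) V / (pi r_c^2) exists; solve numerically so the
    # volume constraint holds for any profile exponent
    h_guess = (p + 1.0) * cell_volume / (np.pi * r_c**2)
    f = lambda h: _dome_volume(r_c, h, p) - cell_volume
    height = brentq(f, 0.25 * h_guess, 4.0 * h_guess, xtol=1e-10 * h_guess)
    if abs(_dome_volume(r_c, height, p) - cell_volume) > 1e-3 * cell_volume:
        raise GeometryError("dome height solve failed to reach requested volume")

    a, c = _fit_nucleus(r_c, height, p, nucleus_base_gap, nuclear_volume)
    return CellShapeSpec(
        base_radius=base_radius,
        cell_volume=cell_volume,
        nuclear_volume=nuclear_volume,
        nucleus_base_gap=nucleus_base_gap,
        profile_exponent=p,
        dome_height=height,
        nucleus_semiaxis_xy=a,
        nucleus_semiaxis_z=c,
        contact_area_fraction=contact_area_fraction,
    )


@dataclass
class CellGeometry:
    """Voxelized cell: masks, boundary faces, areas, volumes, N factor.

    Faces are staircase boundary faces of the regular grid.  Each face is
    stored by the flat index of its cytosol voxel (into the packed cytosol
    arrays), its axis (0, 1, 2) and side (-1 or +1, the outward direction).
    """

    shape: CellShapeSpec
    grid_dims: tuple
    voxel_size: tuple  # (dx, dy, dz) um
    origin: tuple  # coordinates of grid corner (um)
    cytosol_mask: np.ndarray  # (nx, ny, nz) bool
    nucleus_mask: np.ndarray
    band_mask: np.ndarray  # cytosol voxels with z < 0.5 um over the footprint
    cyt_index: np.ndarray  # (nx,ny,nz) int, -1 outside, else packed index
    cyt_coords: np.ndarray  # (n_cyt, 3) voxel-center coordinates
    # membrane faces
    mem_voxel: np.ndarray  # packed cytosol index adjacent to each face
    mem_axis: np.ndarray
    mem_side: np.ndarray
    mem_area: np.ndarray
    mem_center: np.ndarray  # (n_faces, 3)
    basal: np.ndarray  # bool, substrate-contact subset of membrane faces
    activation_faces: np.ndarray  # bool, basal faces within the footprint
    # nuclear faces
    nuc_voxel: np.ndarray
    nuc_area: np.ndarray
    # derived scalars
    cytosol_volume: float = 0.0
    nucleus_volume: float = 0.0
    membrane_area: float = 0.0  # smooth estimate (quadrature on the shape)
    membrane_area_staircase: float = 0.0
    basal_area: float = 0.0
    activation_area: float = 0.0
    nuclear_area_staircase: float = 0.0
    nuclear_area: float = 0.0  # smooth spheroid area
    N: float = 0.0  # cytosol volume / membrane area (um)
    N_nuclear: float = 0.0  # cytosol volume / staircase nuclear area (um)

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    @property
    def N_staircase(self) -> float:
        """V/A with the discrete staircase membrane area.

        Used inside the flux laws so that the well-mixed reduction of the
        membrane boundary conditions is exact on the discrete grid; the
        smooth-surface ``N`` is the physically reported factor.
        """
        return self.cytosol_volume / self.membrane_area_staircase

    @property
    def n_cytosol(self) -> int:
        return int(self.cytosol_mask.sum())

    @property
    def n_membrane_faces(self) -> int:
        return self.mem_voxel.size

    def summary(self) -> dict:
        """Scalar geometry summary (JSON-friendly)."""
        return {
            "base_radius_um": self.shape.base_radius,
            "dome_height_um": self.shape.dome_height,
            "grid_dims": list(self.grid_dims),
            "voxel_size_um": list(self.voxel_size),
            "n_cytosol_voxels": self.n_cytosol,
            "n_nucleus_voxels": int(self.nucleus_mask.sum()),
            "n_membrane_faces": self.n_membrane_faces,
            "cytosol_volume_um3": self.cytosol_volume,
            "nucleus_volume_um3": self.nucleus_volume,
            "membrane_area_um2": self.membrane_area,
            "membrane_area_staircase_um2": self.membrane_area_staircase,
            "basal_area_um2": self.basal_area,
            "activation_area_um2": self.activation_area,
            "N_um": self.N,
            "N_nuclear_um": self.N_nuclear,
        }


def _inside_fractions(shape: CellShapeSpec, centers, voxel_size, n_sub=3):
    """Fraction of sub-samples of each voxel inside cell / nucleus."""
    xc, yc, zc = centers
    dx, dy, dz = voxel_size
    offs = (np.arange(n_sub) + 0.5) / n_sub - 0.5
    cell_hits = np.zeros(xc.shape, dtype=np.int32)
    nuc_hits = np.zeros(xc.shape, dtype=np.int32)
    a, c = shape.nucleus_semiaxis_xy, shape.nucleus_semiaxis_z
    z0 = shape.nucleus_center_z
    for ox in offs:
        for oy in offs:
            x = xc + ox * dx
            y = yc + oy * dy
            r2 = x**2 + y**2
            r = np.sqrt(r2)
            zs = shape.surface_height(r)
            for oz in offs:
                z = zc + oz * dz
                cell_hits += (z >= 0.0) & (z <= zs)
                nuc_hits += (r2 / a**2 + (z - z0) ** 2 / c**2) <= 1.0
    n3 = n_sub**3
    return cell_hits / n3, nuc_hits / n3


def voxelize(
    shape: CellShapeSpec,
    grid_dims: tuple = DEFAULT_GRID,
    padding: float = 0.5,
    band_height: float = 0.5,
) -> CellGeometry:
    """Voxelize the analytic shape on a regular grid.

    The grid bounding box is fitted to the shape plus ``padding`` um
    laterally and on top; the substrate plane z = 0 coincides with the
    bottom of the grid so that bottom faces of layer k = 0 are basal
    (substrate-contact) membrane faces.
    """
    nx, ny, nz = grid_dims
    R, H = shape.contact_radius, shape.dome_height
    x0, x1 = -(R + padding), R + padding
    z1 = H + padding
    dx, dy = (x1 - x0) / nx, (x1 - x0) / ny
    dz = z1 / nz
    xs = x0 + (np.arange(nx) + 0.5) * dx
    ys = x0 + (np.arange(ny) + 0.5) * dy
    zs = (np.arange(nz) + 0.5) * dz
    xc, yc, zc = np.meshgrid(xs, ys, zs, indexing="ij")

    cell_frac, nuc_frac = _inside_fractions(shape, (xc, yc, zc), (dx, dy, dz))
    cell_mask = cell_frac >= 0.5
    nucleus_mask = cell_mask & (nuc_frac >= 0.5)
    cytosol_mask = cell_mask & ~nucleus_mask

    if not nucleus_mask.any():
        raise GeometryError("grid too coarse to resolve the nucleus")
    if not cytosol_mask.any():
        raise GeometryError("grid does not resolve the cytosol")

    r_c = np.sqrt(xc**2 + yc**2)
    r_act = shape.activation_radius
    # at least one voxel layer: the band is the thinnest resolvable
    # near-membrane region when the grid is coarser than band_height
    band_mask = cytosol_mask & (zc < max(band_height, dz)) & (r_c <= r_act)

    n_cyt = int(cytosol_mask.sum())
    cyt_index = np.full(grid_dims, -1, dtype=np.int64)
    cyt_index[cytosol_mask] = np.arange(n_cyt)
    cyt_coords = np.column_stack(
        [xc[cytosol_mask], yc[cytosol_mask], zc[cytosol_mask]]
    )

    face_areas = {0: dy * dz, 1: dx * dz, 2: dx * dy}
    half = {0: 0.5 * dx, 1: 0.5 * dy, 2: 0.5 * dz}

    mem_voxel, mem_axis, mem_side, mem_area, mem_center = [], [], [], [], []
    nuc_voxel, nuc_area = [], []
    for axis in range(3):
        for side in (-1, 1):
            shifted = np.roll(cell_mask, -side, axis=axis)
            # rolling wraps around; voxels on the grid edge face the exterior
            edge = [slice(None)] * 3
            edge[axis] = -1 if side == 1 else 0
            shifted[tuple(edge)] = False
            exterior = cytosol_mask & ~shifted
            nuc_neighbor = np.roll(nucleus_mask, -side, axis=axis)
            nuc_neighbor[tuple(edge)] = False
            to_nucleus = cytosol_mask & nuc_neighbor
            exterior &= ~to_nucleus

            for mask, is_nuc in ((exterior, False), (to_nucleus, True)):
                idx = np.nonzero(mask)
                if idx[0].size == 0:
                    continue
                packed = cyt_index[idx]
                centers = np.column_stack([xc[idx], yc[idx], zc[idx]])
                centers[:, axis] += side * half[axis]
                if is_nuc:
                    nuc_voxel.append(packed)
                    nuc_area.append(np.full(packed.size, face_areas[axis]))
                else:
                    mem_voxel.append(packed)
                    mem_axis.append(np.full(packed.size, axis, dtype=np.int8))
                    mem_side.append(np.full(packed.size, side, dtype=np.int8))
                    mem_area.append(np.full(packed.size, face_areas[axis]))
                    mem_center.append(centers)

    mem_voxel = np.concatenate(mem_voxel)
    mem_axis = np.concatenate(mem_axis)
    mem_side = np.concatenate(mem_side)
    mem_area = np.concatenate(mem_area)
    mem_center = np.vstack(mem_center)
    nuc_voxel = np.concatenate(nuc_voxel) if nuc_voxel else np.empty(0, dtype=np.int64)
    nuc_area = np.concatenate(nuc_area) if nuc_area else np.empty(0)

    basal = (mem_axis == 2) & (mem_side == -1) & (np.abs(mem_center[:, 2]) < 1e-9)
    r_face = np.hypot(mem_center[:, 0], mem_center[:, 1])
    activation_faces = basal & (r_face <= r_act)
    if not activation_faces.any():
        raise GeometryError("no basal activation faces resolved")

    voxvol = dx * dy * dz
    geom = CellGeometry(
        shape=shape,
        grid_dims=tuple(grid_dims),
        voxel_size=(dx, dy, dz),
        origin=(x0, x0, 0.0),
        cytosol_mask=cytosol_mask,
        nucleus_mask=nucleus_mask,
        band_mask=band_mask,
        cyt_index=cyt_index,
        cyt_coords=cyt_coords,
        mem_voxel=mem_voxel,
        mem_axis=mem_axis,
        mem_side=mem_side,
        mem_area=mem_area,
        mem_center=mem_center,
        basal=basal,
        activation_faces=activation_faces,
        nuc_voxel=nuc_voxel,
        nuc_area=nuc_area,
    )
    geom.cytosol_volume = n_cyt * voxvol
    geom.nucleus_volume = float(nucleus_mask.sum()) * voxvol
    geom.membrane_area = shape.membrane_area()
    geom.membrane_area_staircase = float(mem_area.sum())
    geom.basal_area = float(mem_area[basal].sum())
    geom.activation_area = float(mem_area[activation_faces].sum())
    geom.nuclear_area_staircase = float(nuc_area.sum())
    geom.nuclear_area = shape.nuclear_area()
    geom.N = geom.cytosol_volume / geom.membrane_area
    geom.N_nuclear = geom.cytosol_volume / geom.nuclear_area_staircase
    return geom


def molecules_to_concentration(count: float, volume_um3: float) -> float:
    """Convert a molecule count in a volume (um^3) to a concentration in uM."""
    if volume_um3 <= 0:
        raise GeometryError("volume must be positive")
    return count / (MOLECULES_PER_UM3_PER_UM * volume_um3)


def concentration_to_molecules(conc_um: float, volume_um3: float) -> float:
    """Inverse of :func:`molecules_to_concentration`."""
    if volume_um3 <= 0:
        raise GeometryError("volume must be positive")
    return conc_um * MOLECULES_PER_UM3_PER_UM * volume_um3


def activation_region(geometry: CellGeometry, case_id: int):
    """Region where the initial/sustained FAK activation lives.

    Case 1: the full cytosol mask; case 2: the thin basal band mask;
    cases 3-5: the boolean selector of basal activation faces.
    """
    if case_id == 1:
        return geometry.cytosol_mask
    if case_id == 2:
        if not geometry.band_mask.any():
            raise GeometryError("activation band resolved to zero voxels")
        return geometry.band_mask
    if case_id in (3, 4, 5):
        return geometry.activation_faces
    raise GeometryError(f"unknown case id {case_id!r}")
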