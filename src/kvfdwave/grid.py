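"""Axisymmetric staggered grid, material rasterisation and PML profiles.

The torsional problem is posed on an r-z plane outside a cylindrical lumen:
the radial coordinate starts at the lumen wall r = ru (there is no axis
singularity because the domain excludes r = 0).  Displacement nodes sit at

    (ru + i dr, j dz),            i = 0 .. Nr-1, j indexed over the z span,

the r-theta stress/strain components at the radial half nodes
(ru + (i+1/2) dr, j dz) and the theta-z components at the axial half nodes
(ru + i dr, (j+1/2) dz).

Absorbing collars (PML) of ``n_pml`` nodes are appended on the three edges
away from the lumen wall: beyond the outer radius and beyond both ends of
the z span.  Interior z coordinates therefore run from 0 to zd while the
full grid spans [-n_pml dz, zd + n_pml dz].

Materials are assigned per cell (the rectangle between four displacement
nodes); stress half nodes take the arithmetic mean of the two flanking
cells and densities the mean of the surrounding cells, so homogeneous
regions are represented exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .rheology import KVFDMaterial

__all__ = [
    "GridSpec",
    "MaterialMap",
    "PMLProfile",
    "build_grid",
    "add_circular_inclusion",
    "half_node_materials",
    "build_pml",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Staggered axisymmetric grid geometry.

    ``n_r`` / ``n_z`` count interior displacement nodes; ``nr_tot`` /
    ``nz_tot`` include the PML collars (outer r, both z ends).
    """

    dr: float
    dz: float
    n_r: int
    n_z: int
    r0: float          # radial coordinate of the lumen-wall column (= ru)
    n_pml: int

    def __post_init__(self) -> None:
        if self.dr <= 0 or self.dz <= 0:
            raise ValueError("dr and dz must be > 0")
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0 (domain excludes the axis)")
        if self.n_r < 2 or self.n_z < 1:
            raise ValueError("need at least 2 radial and 1 axial node")
        if self.n_pml < 0:
            raise ValueError("n_pml must be >= 0")

    # -- total extents (interior + PML collars) ---------------------------
    @property
    def nr_tot(self) -> int:
        return self.n_r + self.n_pml

    @property
    def nz_tot(self) -> int:
        # z PML on both ends unless the grid is a thin periodic strip
        return self.n_z + (2 * self.n_pml if self.n_z > 1 else 0)

    @property
    def j0(self) -> int:
        """Index of the interior z = 0 node."""
        return self.n_pml if self.n_z > 1 else 0

    # -- coordinates -------------------------------------------------------
    @property
    def r_nodes(self) -> np.ndarray:
        """Radial coordinates of displacement columns (length nr_tot)."""
        return self.r0 + self.dr * np.arange(self.nr_tot)

    @property
    def r_half(self) -> np.ndarray:
        """Radial coordinates of r-theta half nodes (length nr_tot - 1)."""
        return self.r0 + self.dr * (np.arange(self.nr_tot - 1) + 0.5)

    @property
    def z_nodes(self) -> np.ndarray:
        """Axial coordinates of displacement rows (length nz_tot)."""
        return self.dz * (np.arange(self.nz_tot) - self.j0)

    @property
    def z_half(self) -> np.ndarray:
        return self.dz * (np.arange(self.nz_tot - 1) - self.j0 + 0.5)

    def r_index(self, r: float) -> int:
        """Nearest displacement-column index for a radial coordinate."""
        return int(round((r - self.r0) / self.dr))

    def z_index(self, z: float) -> int:
        """Nearest displacement-row index for an axial coordinate."""
        return int(round(z / self.dz)) + self.j0

    # -- cell-centre coordinates (material rasterisation) ------------------
    @property
    def cell_r(self) -> np.ndarray:
        return self.r_half

    @property
    def cell_z(self) -> np.ndarray:
        return self.z_half

    def interior_r_slice(self) -> slice:
        return slice(0, self.n_r)

    def interior_z_slice(self) -> slice:
        return slice(self.j0, self.j0 + self.n_z)


def build_grid(rd: float, zd: float, ru: float, dr: float, dz: float, n_pml: int) -> GridSpec:
    """Build the staggered grid for an annular domain of radial depth ``rd``
    and axial extent ``zd`` outside a lumen of radius ``ru``.

    Node counts are n_r = round(rd/dr) + 1 and n_z = round(zd/dz) + 1; if
    the extents are not integer multiples of the steps they are rounded to
    the nearest node with a logged warning.
    """
    if rd <= 0 or zd <= 0:
        raise ValueError("rd and zd must be > 0")
    if dr > rd or dz > zd:
        raise ValueError("spatial steps must not exceed the domain extents")
    n_r = int(round(rd / dr)) + 1
    n_z = int(round(zd / dz)) + 1
    for name, extent, step, n in (("rd", rd, dr, n_r), ("zd", zd, dz, n_z)):
        actual = (n - 1) * step
        if not np.isclose(actual, extent, rtol=1e-9, atol=0.0):
            log.warning(
                "%s = %.6g m is not a multiple of the step; grid spans %.6g m",
                name, extent, actual,
            )
    return GridSpec(dr=dr, dz=dz, n_r=n_r, n_z=n_z, r0=ru, n_pml=n_pml)


@dataclass
class MaterialMap:
    """Per-cell material fields on a grid.

    ``mu``, ``eta``, ``alpha``, ``rho`` have shape (nr_tot-1, nz_tot-1)
    (one entry per cell).  PML-collar cells replicate the background (or
    nearest interior) material so outgoing waves see no impedance step.
    """

    grid: GridSpec
    mu: np.ndarray
    eta: np.ndarray
    alpha: np.ndarray
    rho: np.ndarray
    background: KVFDMaterial

    @classmethod
    def homogeneous(cls, grid: GridSpec, material: KVFDMaterial) -> "MaterialMap":
        shape = (grid.nr_tot - 1, max(grid.nz_tot - 1, 1))
        return cls(
            grid=grid,
            mu=np.full(shape, material.shear_elastic),
            eta=np.full(shape, material.shear_viscous),
            alpha=np.full(shape, material.fractional_order),
            rho=np.full(shape, material.density),
            background=material,
        )

    def copy(self) -> "MaterialMap":
        return MaterialMap(
            grid=self.grid,
            mu=self.mu.copy(),
            eta=self.eta.copy(),
            alpha=self.alpha.copy(),
            rho=self.rho.copy(),
            background=self.background,
        )


def add_circular_inclusion(
    mat_map: MaterialMap,
    center: tuple[float, float],
    diameter: float,
    material: KVFDMaterial,
) -> MaterialMap:
    """Rasterise a circular inclusion: every cell whose centre lies inside
    the circle takes the inclusion material.  Returns a new map.

    The inclusion must lie fully inside the interior domain (not in the PML
    collars and not across the lumen wall).
    """
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    grid = mat_map.grid
    rc, zc = center
    rad = diameter / 2.0
    r_in_lo, r_in_hi = grid.r0, grid.r0 + (grid.n_r - 1) * grid.dr
    z_in_lo, z_in_hi = 0.0, (grid.n_z - 1) * grid.dz
    if (rc - rad < r_in_lo or rc + rad > r_in_hi
            or zc - rad < z_in_lo or zc + rad > z_in_hi):
        raise ValueError(
            "inclusion extends outside the interior domain (into the lumen "
            "or the PML collars)"
        )
    out = mat_map.copy()
    if diameter == 0:
        return out
    rr, zz = np.meshgrid(grid.cell_r, grid.cell_z, indexing="ij")
    inside = (rr - rc) ** 2 + (zz - zc) ** 2 <= rad**2
    out.mu[inside] = material.shear_elastic
    out.eta[inside] = material.shear_viscous
    out.alpha[inside] = material.fractional_order
    out.rho[inside] = material.density
    return out


def half_node_materials(mat_map: MaterialMap):
    """Average per-cell mu/eta/alpha onto the stress half-node locations and
    rho onto displacement nodes.

    Returns a dict with arrays:

    - ``mu_rt``, ``eta_rt``, ``alpha_rt`` at r-theta half nodes,
      shape (nr_tot-1, nz_tot);
    - ``mu_tz``, ``eta_tz``, ``alpha_tz`` at theta-z half nodes,
      shape (nr_tot, nz_tot-1);
    - ``rho`` at displacement nodes, shape (nr_tot, nz_tot).

    Arithmetic means of the flanking cells are used (exact in homogeneous
    regions); edges replicate the single adjacent cell.
    """
    grid = mat_map.grid

    def _pad_mean_axis(a: np.ndarray, axis: int) -> np.ndarray:
        # mean of adjacent cells along `axis`, replicating the edge cells
        pad = [(0, 0), (0, 0)]
        pad[axis] = (1, 1)
        ap = np.pad(a, pad, mode="edge")
        sl0 = [slice(None), slice(None)]
        sl1 = [slice(None), slice(None)]
        sl0[axis] = slice(0, a.shape[axis] + 1)
        sl1[axis] = slice(1, a.shape[axis] + 2)
        return 0.5 * (ap[tuple(sl0)] + ap[tuple(sl1)])

    out = {}
    # r-theta half nodes: same radial index as the cell, average over z
    for key, a in (("mu_rt", mat_map.mu), ("eta_rt", mat_map.eta)):
        out[key] = _pad_mean_axis(a, axis=1)
    # theta-z half nodes: same axial index as the cell, average over r
    for key, a in (("mu_tz", mat_map.mu), ("eta_tz", mat_map.eta)):
        out[key] = _pad_mean_axis(a, axis=0)
    # alpha is per material region: take the flanking value without
    # averaging across an interface (the cell with the larger mu wins,
    # irrelevant when alpha is uniform as in the presets)
    out["alpha_rt"] = _nearest_alpha(mat_map.alpha, mat_map.mu, axis=1)
    out["alpha_tz"] = _nearest_alpha(mat_map.alpha, mat_map.mu, axis=0)
    # density at displacement nodes: mean over the surrounding cells
    rho = _pad_mean_axis(_pad_mean_axis(mat_map.rho, axis=0), axis=1)
    out["rho"] = rho
    if grid.nz_tot == 1:
        out["rho"] = out["rho"][:, :1]
        out["mu_rt"] = out["mu_rt"][:, :1]
        out["eta_rt"] = out["eta_rt"][:, :1]
        out["alpha_rt"] = out["alpha_rt"][:, :1]
    return out


def _nearest_alpha(alpha: np.ndarray, mu: np.ndarray, axis: int) -> np.ndarray:
    pad = [(0, 0), (0, 0)]
    pad[axis] = (1, 1)
    ap = np.pad(alpha, pad, mode="edge")
    mp = np.pad(mu, pad, mode="edge")
    n = alpha.shape[axis]
    sl0 = [slice(None), slice(None)]
    sl1 = [slice(None), slice(None)]
    sl0[axis] = slice(0, n + 1)
    sl1[axis] = slice(1, n + 2)
    a0, a1 = ap[tuple(sl0)], ap[tuple(sl1)]
    m0, m1 = mp[tuple(sl0)], mp[tuple(sl1)]
    return np.where(m1 > m0, a1, a0)


@dataclass(frozen=True)
class PMLProfile:
    """Graded absorption profiles for the three absorbing collars, in 1/s.

    The damping follows the polynomial grading
    sigma(x) = sigma_max (x/delta)^m with
    sigma_max = -(m+1) c_ref ln(R0) / (2 delta): zero at the interior
    interface and monotone increasing towards the outer edge.  A
    complex-frequency-shift profile alpha(x) = alpha_max (1 - x/delta)
    accompanies it (largest at the interface, zero at the edge), which
    moves the absorber pole off dc and suppresses the late-time /
    grazing-incidence reflections a purely real stretching leaves behind.
    Profiles are sampled at both full- and half-node locations so each of
    the four stretched spatial-derivative terms uses its own.
    """

    sigma_r_nodes: np.ndarray   # (nr_tot,)
    sigma_r_half: np.ndarray    # (nr_tot - 1,)
    sigma_z_nodes: np.ndarray   # (nz_tot,)
    sigma_z_half: np.ndarray    # (nz_tot - 1,) or empty
    alpha_r_nodes: np.ndarray
    alpha_r_half: np.ndarray
    alpha_z_nodes: np.ndarray
    alpha_z_half: np.ndarray
    m: float
    R0: float
    alpha_max: float


def build_pml(grid: GridSpec, reference_velocity: float, m: float = 2.0,
              R0: float = 1e-6, alpha_max: float | None = None) -> PMLProfile:
    """Construct the PML absorption profiles for a grid.

    ``reference_velocity`` is the wave speed used to scale sigma_max
    (typically the elastic shear velocity of the background tissue).
    ``alpha_max`` is the complex-frequency shift at the interior interface;
    the customary choice is pi times the dominant source frequency, and the
    default corresponds to the 700 Hz band centre of the packaged
    scenarios.  With ``n_pml = 0`` all profiles are zero (reflecting box).
    """
    n_pml = grid.n_pml
    if alpha_max is None:
        alpha_max = np.pi * 700.0

    def _profiles(coords: np.ndarray, lo: float, hi: float, delta: float):
        sig = np.zeros_like(coords)
        alp = np.zeros_like(coords)
        if n_pml == 0 or delta == 0:
            return sig, alp
        smax = -(m + 1) * reference_velocity * np.log(R0) / (2 * delta)
        for mask, depth in (
            (coords < lo, lo - coords), (coords > hi, coords - hi)
        ):
            frac = np.clip(depth / delta, 0.0, 1.0)
            sig[mask] = smax * frac[mask] ** m
            alp[mask] = alpha_max * (1.0 - frac[mask])
        return sig, alp

    r_hi = grid.r0 + (grid.n_r - 1) * grid.dr     # last interior column
    z_lo, z_hi = 0.0, (grid.n_z - 1) * grid.dz
    delta_r = n_pml * grid.dr
    delta_z = n_pml * grid.dz
    sigma_r_nodes, alpha_r_nodes = _profiles(grid.r_nodes, grid.r0, r_hi, delta_r)
    sigma_r_half, alpha_r_half = _profiles(grid.r_half, grid.r0, r_hi, delta_r)
    if grid.nz_tot > 1:
        sigma_z_nodes, alpha_z_nodes = _profiles(grid.z_nodes, z_lo, z_hi, delta_z)
        sigma_z_half, alpha_z_half = _profiles(grid.z_half, z_lo, z_hi, delta_z)
    else:
        sigma_z_nodes = alpha_z_nodes = np.zeros(1)
        sigma_z_half = alpha_z_half = np.zeros(0)
    return PMLProfile(
        sigma_r_nodes=sigma_r_nodes,
        sigma_r_half=sigma_r_half,
        sigma_z_nodes=sigma_z_nodes,
        sigma_z_half=sigma_z_half,
        alpha_r_nodes=alpha_r_nodes,
        alpha_r_half=alpha_r_half,
        alpha_z_nodes=alpha_z_nodes,
        alpha_z_half=alpha_z_half,
        m=m,
        R0=R0,
        alpha_max=float(alpha_max),
    )
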