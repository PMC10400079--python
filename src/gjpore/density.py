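"""Time-averaged ion occupancy on a 3D grid inside a cylindrical pore
region, axial density profiles, and voxel-emptiness accessible-area
profiles.

The grid follows the analysis protocol for the channel simulations: ions
within a cylinder of radius 10 A around the pore axis are binned onto a
3D grid spaced every 1 A; the per-voxel occupancies are time averages,
and the axial density profile is the integral (sum) of the grid over
each z-slab.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import AxisFrame, SelectionError, Trajectory
from .geometry import RadiusProfile

__all__ = [
    "GridSpec",
    "Grid3D",
    "DensityProfile",
    "accumulate_density",
    "axial_profile",
    "combine_replicates",
    "accessible_area_profile",
]


@dataclass
class GridSpec:
    """Cylindrical binning region around the pore axis."""

    z_range: tuple[float, float]
    spacing: float = 1.0
    cylinder_radius: float = 10.0
    axis: AxisFrame = field(
        default_factory=lambda: AxisFrame(origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]))
    )

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder_radius must be positive")
        if self.z_range[0] >= self.z_range[1]:
            raise ValueError("z_range must be increasing")

    @property
    def n_xy(self) -> int:
        return int(np.ceil(2 * self.cylinder_radius / self.spacing))

    @property
    def n_z(self) -> int:
        return int(np.ceil((self.z_range[1] - self.z_range[0]) / self.spacing))

    def z_centers(self) -> np.ndarray:
        return self.z_range[0] + self.spacing * (np.arange(self.n_z) + 0.5)


@dataclass
class Grid3D:
    """Mean per-voxel ion occupancy (dimensionless), time-averaged."""

    spec: GridSpec
    counts: np.ndarray  # (n_xy, n_xy, n_z)
    n_frames: int
    species: str

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("grid counts must be non-negative")


@dataclass
class DensityProfile:
    """Axial ion density: mean ions per z-slab and replicate spread."""

    z_centers: np.ndarray
    rho: np.ndarray
    sigma_rho: np.ndarray
    species: str
    n_replicates: int = 1

    def __post_init__(self):
        self.z_centers = np.asarray(self.z_centers, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.sigma_rho = np.asarray(self.sigma_rho, dtype=float)
        if not (len(self.z_centers) == len(self.rho) == len(self.sigma_rho)):
            raise ValueError("z_centers, rho and sigma_rho must have equal length")
        if np.any(self.sigma_rho < 0):
            raise ValueError("sigma_rho must be non-negative")


def _bin_indices(coords: np.ndarray, spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """(mask of in-region ions, their (ix, iy, iz)) for axis-frame coords."""
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    r = np.hypot(x, y)
    inside = (r <= spec.cylinder_radius) & (z >= spec.z_range[0]) & (z < spec.z_range[1])
    s = spec.spacing
    ix = np.floor((x[inside] + spec.cylinder_radius) / s).astype(int)
    iy = np.floor((y[inside] + spec.cylinder_radius) / s).astype(int)
    iz = np.floor((z[inside] - spec.z_range[0]) / s).astype(int)
    # an ion exactly on the high cylinder edge lands one voxel outside
    ix = np.clip(ix, 0, spec.n_xy - 1)
    iy = np.clip(iy, 0, spec.n_xy - 1)
    return inside, np.stack([ix, iy, iz], axis=1)


def accumulate_density(traj: Trajectory, spec: GridSpec, species: str) -> Grid3D:
    """Bin one species onto the cylindrical 3D grid, time-averaged.

    Voxels are half-open on the low edge; ions exactly on the cylinder
    boundary are included.  Wrapped coordinates are used as stored (the
    grid is a density, not a path).  The total grid occupancy equals
    the mean number of in-cylinder ions per frame.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory is empty")
    coords = traj.ion_coords(species)  # raises SelectionError if absent
    nf, ni, _ = coords.shape
    if ni == 0:
        raise SelectionError(f"species {species!r} has no ions")
    flat = spec.axis.to_frame(coords.reshape(-1, 3))
    counts = np.zeros((spec.n_xy, spec.n_xy, spec.n_z))
    inside, idx = _bin_indices(flat, spec)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    return Grid3D(spec=spec, counts=counts / nf, n_frames=nf, species=species)


def axial_profile(grid: Grid3D) -> DensityProfile:
    """Integrate the grid over x,y: mean ions per z-slab."""
    rho = grid.counts.sum(axis=(0, 1))
    return DensityProfile(
        z_centers=grid.spec.z_centers(),
        rho=rho,
        sigma_rho=np.zeros_like(rho),
        species=grid.species,
        n_replicates=1,
    )


def combine_replicates(profiles: list[DensityProfile]) -> DensityProfile:
    """Per-bin mean and sample SD (n-1) across replicate profiles."""
    if not profiles:
        raise ValueError("need at least one profile")
    z0 = profiles[0].z_centers
    for p in profiles[1:]:
        if len(p.z_centers) != len(z0) or not np.allclose(p.z_centers, z0):
            raise ValueError("replicate profiles have mismatched z bins")
    stack = np.stack([p.rho for p in profiles])
    n = len(profiles)
    sigma = stack.std(axis=0, ddof=1) if n > 1 else np.zeros(len(z0))
    return DensityProfile(
        z_centers=z0,
        rho=stack.mean(axis=0),
        sigma_rho=sigma,
        species=profiles[0].species,
        n_replicates=n,
    )


def accessible_area_profile(
    traj: Trajectory,
    spec: GridSpec,
    atom_radii: np.ndarray | None = None,
) -> RadiusProfile:
    """Solvent-accessible radius profile by empty-voxel counting.

    Per frame and z-slab, a voxel (inside the cylinder) is empty iff no
    heavy-atom centre lies within that atom's van der Waals radius of
    the voxel centre (a centre exactly at the vdW distance occupies the
    voxel).  Only the empty region 4-connected to the pore axis counts
    as lumen — pockets outside the wall but inside the analysis
    cylinder are not solvent-accessible from the pore.  The accessible
    area is A(z) = N_lumen(z) * spacing^2 and the effective radius
    r(z) = sqrt(A(z)/pi); the profile is the time mean with SD over
    frames as the fluctuation.

    ``atom_radii`` gives the per-atom vdW radii matching the trajectory
    protein atom order; required when protein coordinates are present.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory is empty")
    if traj.frames[0].protein_positions.shape[0] == 0:
        # no wall at all: the whole cylinder cross-section is accessible
        area = np.pi * spec.cylinder_radius**2
        r = np.full(spec.n_z, np.sqrt(area / np.pi))
        return RadiusProfile(
            z_centers=spec.z_centers(),
            radius=r,
            radius_sd=np.zeros(spec.n_z),
            method="voxel_emptiness",
            structure_id="",
        )
    if atom_radii is None:
        raise ValueError("atom_radii required when protein coordinates are present")
    atom_radii = np.asarray(atom_radii, dtype=float)

    from scipy import ndimage

    s = spec.spacing
    half = spec.cylinder_radius
    xy = -half + s * (np.arange(spec.n_xy) + 0.5)
    gx, gy = np.meshgrid(xy, xy, indexing="ij")
    in_cyl = (gx**2 + gy**2) <= half**2
    centers_xy = np.stack([gx[in_cyl], gy[in_cyl]], axis=1)
    axis_voxel = np.unravel_index(np.argmin(gx**2 + gy**2), gx.shape)
    zc = spec.z_centers()
    n_empty = np.zeros((traj.n_frames, spec.n_z))
    rmax = float(atom_radii.max())
    four_conn = ndimage.generate_binary_structure(2, 1)
    for fi, frame in enumerate(traj.frames):
        pos = frame.protein_positions
        if len(pos) != len(atom_radii):
            raise ValueError("atom_radii length does not match protein atom count")
        pos = spec.axis.to_frame(pos)
        tree = cKDTree(pos)
        for zi, z in enumerate(zc):
            centers = np.column_stack(
                [centers_xy[:, 0], centers_xy[:, 1], np.full(len(centers_xy), z)]
            )
            neighbours = tree.query_ball_point(centers, rmax)
            empty_flat = np.empty(len(centers), dtype=bool)
            for k, (c, nb) in enumerate(zip(centers, neighbours)):
                if not nb:
                    empty_flat[k] = True
                    continue
                d = np.linalg.norm(pos[nb] - c, axis=1)
                empty_flat[k] = bool(np.all(d > atom_radii[nb]))
            empty = np.zeros(gx.shape, dtype=bool)
            empty[in_cyl] = empty_flat
            if not empty[axis_voxel]:
                n_empty[fi, zi] = 0
                continue
            labels, _ = ndimage.label(empty, structure=four_conn)
            n_empty[fi, zi] = int(np.sum(labels == labels[axis_voxel]))
    area = n_empty * s**2
    radius = np.sqrt(area / np.pi)
    sd = radius.std(axis=0, ddof=0) if traj.n_frames > 1 else np.zeros(spec.n_z)
    return RadiusProfile(
        z_centers=zc,
        radius=radius.mean(axis=0),
        radius_sd=sd,
        method="voxel_emptiness",
        structure_id="",
    )
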