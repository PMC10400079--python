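"""Synthetic ion trajectories and pore structures with known ground
truth.

Ions are non-interacting Brownian particles in a cylindrically
symmetric pore: an axial potential U(z) (flat, Gaussian barrier, or a
sum of Gaussian barriers), an optional constant axial field E_z acting
on the species charge, a reflecting radial wall, and a periodic axial
boundary.  The overdamped Langevin (Euler-Maruyama) update per
coordinate is

    z <- z + (D / kT) F dt + sqrt(2 D dt) N(0, 1),

with F = -dU/dz + q E_z on the axial coordinate and pure diffusion in
the plane.  At equilibrium the axial density converges to the Boltzmann
distribution of U_eff(z) = U(z) - q E_z z, which makes every downstream
stage (density, free energy, permeation) testable against an analytic
target.  Ideal-gas (non-interacting) statistics are intentional: the
analysis contract is about counting and binning, not ion-ion
correlations.

Identical seeds give bit-identical trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .constants import DEFAULT_T, KCAL_PER_E_MV, kT
from .core import AtomRecord, Frame, SimulationMeta, StructureModel, Trajectory

__all__ = [
    "GeneratorSpec",
    "AxialPotential",
    "simulate_ions",
    "simulate_replicates",
    "make_pore_structure",
    "IonPath",
    "script_trajectory",
]


@dataclass
class AxialPotential:
    """Named axial potential U(z) in kcal/mol.

    forms: ``flat``; ``gaussian_barrier`` with (height, center, width);
    ``double_barrier`` with parallel lists of heights/centers/widths.
    ``width`` is the Gaussian sigma in A.
    """

    form: str = "flat"
    height: float | list[float] = 0.0
    center: float | list[float] = 0.0
    width: float | list[float] = 1.0

    def _terms(self):
        if self.form == "flat":
            return []
        h, c, w = self.height, self.center, self.width
        if self.form == "gaussian_barrier":
            return [(float(h), float(c), float(w))]
        if self.form == "double_barrier":
            return list(zip(h, c, w))
        raise ValueError(f"unknown potential form {self.form!r}")

    def energy(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        for h, c, w in self._terms():
            u += h * np.exp(-((z - c) ** 2) / (2 * w**2))
        return u

    def force(self, z: np.ndarray) -> np.ndarray:
        """-dU/dz (the axial force on a particle in this potential)."""
        z = np.asarray(z, dtype=float)
        f = np.zeros_like(z)
        for h, c, w in self._terms():
            f += h * (z - c) / w**2 * np.exp(-((z - c) ** 2) / (2 * w**2))
        return f


@dataclass
class GeneratorSpec:
    """Conditions for one synthetic Brownian-dynamics run."""

    potential: AxialPotential = dc_field(default_factory=AxialPotential)
    E_z: float = 0.0  # mV/A, constant axial field
    species_charges: dict[str, float] = dc_field(
        default_factory=lambda: {"K+": 1.0, "Cl-": -1.0}
    )
    diffusion_coeff: dict[str, float] | float = 0.2  # A^2/ps, aqueous K+/Cl- scale
    n_ions: dict[str, int] = dc_field(default_factory=lambda: {"K+": 50, "Cl-": 50})
    R_wall: float = 10.0  # A, reflecting radial wall
    box: tuple[float, float, float] = (30.0, 30.0, 120.0)
    dt: float = 1.0  # ps
    n_steps: int = 10000
    sample_every: int = 10
    temperature: float = DEFAULT_T
    seed: int = 0
    replicates: int = 1
    init: str = "uniform"  # "uniform" | "equilibrium" (rejection-sampled Boltzmann start)
    n_equil: int = 0  # burn-in steps run before the first recorded frame

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        dvals = (
            self.diffusion_coeff.values()
            if isinstance(self.diffusion_coeff, dict)
            else [self.diffusion_coeff]
        )
        if any(d < 0 for d in dvals):
            raise ValueError("diffusion coefficients must be non-negative")

    def D_of(self, species: str) -> float:
        if isinstance(self.diffusion_coeff, dict):
            return self.diffusion_coeff[species]
        return float(self.diffusion_coeff)


def _boltzmann_sample_z(spec, species, n, half_z, beta, rng) -> np.ndarray:
    """Rejection-sample axial positions from the equilibrium target
    exp(-beta * (U(z) - q E_z z)) on the box."""
    q = spec.species_charges.get(species, 0.0)

    def u_eff(z):
        return spec.potential.energy(z) - q * spec.E_z * KCAL_PER_E_MV * z

    zg = np.linspace(-half_z, half_z, 2001)
    u_min = u_eff(zg).min()
    out = np.empty(n)
    filled = 0
    while filled < n:
        cand = rng.uniform(-half_z, half_z, 4 * (n - filled))
        acc = rng.uniform(0, 1, len(cand)) < np.exp(-beta * (u_eff(cand) - u_min))
        take = cand[acc][: n - filled]
        out[filled : filled + len(take)] = take
        filled += len(take)
    return out


def simulate_ions(spec: GeneratorSpec, replicate: int = 0) -> Trajectory:
    """Run one replicate of the overdamped Langevin generator.

    The replicate seed is ``spec.seed + replicate``; metadata records
    the seed, temperature and the voltage implied by E_z over the box
    (V = E_z * box_z).
    """
    rng = np.random.default_rng(spec.seed + replicate)
    beta = 1.0 / kT(spec.temperature)
    box = np.asarray(spec.box, dtype=float)
    half_z = box[2] / 2.0
    for sp in spec.n_ions:
        step = np.sqrt(2 * spec.D_of(sp) * spec.dt)
        if step > 1.0:
            warnings.warn(
                f"{sp}: diffusive step {step:.2f} A per dt exceeds 1 A; "
                "reduce dt for a faithful equilibrium",
                stacklevel=2,
            )
    # state per species
    state: dict[str, np.ndarray] = {}
    for sp, n in spec.n_ions.items():
        r = spec.R_wall * np.sqrt(rng.uniform(0, 1, n))
        phi = rng.uniform(0, 2 * np.pi, n)
        if spec.init == "equilibrium":
            z = _boltzmann_sample_z(spec, sp, n, half_z, beta, rng)
        elif spec.init == "uniform":
            z = rng.uniform(-half_z, half_z, n)
        else:
            raise ValueError(f"unknown init mode {spec.init!r}")
        state[sp] = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

    frames: list[Frame] = []

    def record(step_idx: int):
        ions = {}
        for sp, pos in state.items():
            wrapped = pos.copy()
            wrapped[:, 2] = (wrapped[:, 2] + half_z) % box[2] - half_z
            ions[sp] = wrapped
        frames.append(
            Frame(
                time=step_idx * spec.dt,
                ion_positions=ions,
                protein_positions=np.empty((0, 3)),
                box=box,
            )
        )

    def advance():
        for sp, pos in state.items():
            D = spec.D_of(sp)
            if D == 0:
                continue
            q = spec.species_charges.get(sp, 0.0)
            zw = (pos[:, 2] + half_z) % box[2] - half_z  # force uses wrapped z
            F = spec.potential.force(zw) + q * spec.E_z * KCAL_PER_E_MV
            noise = rng.standard_normal(pos.shape)
            pos[:, 0] += np.sqrt(2 * D * spec.dt) * noise[:, 0]
            pos[:, 1] += np.sqrt(2 * D * spec.dt) * noise[:, 1]
            pos[:, 2] += D * beta * F * spec.dt + np.sqrt(2 * D * spec.dt) * noise[:, 2]
            # reflecting radial wall
            r = np.hypot(pos[:, 0], pos[:, 1])
            out = r > spec.R_wall
            if np.any(out):
                scale = (2 * spec.R_wall - r[out]) / r[out]
                scale = np.maximum(scale, 0.0)
                pos[out, 0] *= scale
                pos[out, 1] *= scale

    for _ in range(spec.n_equil):
        advance()
    record(0)
    for step_idx in range(1, spec.n_steps + 1):
        advance()
        if step_idx % spec.sample_every == 0:
            record(step_idx)

    meta = SimulationMeta(
        temperature=spec.temperature,
        applied_voltage=spec.E_z * box[2],
        replicate_id=f"rep{replicate}",
        seed=spec.seed + replicate,
        species_charges=dict(spec.species_charges),
    )
    return Trajectory(frames=frames, meta=meta)


def simulate_replicates(spec: GeneratorSpec) -> list[Trajectory]:
    """All replicates of a spec, seeds ``seed + k`` for k in 0..n-1."""
    return [simulate_ions(spec, replicate=k) for k in range(spec.replicates)]


# ---------------------------------------------------------------------------
# pseudo-atom pore structures
# ---------------------------------------------------------------------------


def make_pore_structure(
    kind: str,
    inner_radius,
    length: float,
    atom_spacing: float = 1.0,
    vdw: float = 1.5,
) -> StructureModel:
    """Deterministic pseudo-atom pore wall.

    ``kind``: ``cylinder`` (constant atom-centre radius ``inner_radius``),
    ``hourglass`` (two cones; ``inner_radius`` is (waist_radius,
    end_radius), waist at z = 0), or ``ring_stack`` (``inner_radius`` is
    a sequence of per-ring radii, rings evenly spaced over the length).
    Walls are stacks of atom rings centred on the z axis, spanning
    z in [-length/2, +length/2].
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if atom_spacing <= 0:
        raise ValueError("atom_spacing must be positive")

    if kind == "cylinder":
        r0 = float(inner_radius)
        radius_of = lambda z: r0
        n_rings = max(int(np.floor(length / atom_spacing)) + 1, 2)
    elif kind == "hourglass":
        waist, end = float(inner_radius[0]), float(inner_radius[1])
        slope = (end - waist) / (length / 2.0)
        radius_of = lambda z: waist + slope * abs(z)
        n_rings = max(int(np.floor(length / atom_spacing)) + 1, 2)
    elif kind == "ring_stack":
        radii = [float(r) for r in inner_radius]
        n_rings = len(radii)
        if n_rings < 1:
            raise ValueError("ring_stack needs at least one radius")
        radius_of = None
    else:
        raise ValueError(f"unknown pore kind {kind!r}")

    zs = np.linspace(-length / 2.0, length / 2.0, n_rings)
    atoms: list[AtomRecord] = []
    atom_id = 0
    for ring_i, z in enumerate(zs):
        r = radius_of(z) if radius_of is not None else radii[ring_i]
        if atom_spacing > r:
            raise ValueError(
                f"atom_spacing {atom_spacing} exceeds ring radius {r} at z={z:.1f}"
            )
        n_in_ring = max(int(np.ceil(2 * np.pi * r / atom_spacing)), 3)
        for j in range(n_in_ring):
            phi = 2 * np.pi * j / n_in_ring
            atom_id += 1
            atoms.append(
                AtomRecord(
                    atom_id=atom_id,
                    element="X",
                    name="PSD",
                    residue_name="WAL",
                    residue_seq=ring_i + 1,
                    chain_id="W",
                    position=np.array([r * np.cos(phi), r * np.sin(phi), z]),
                    vdw_radius=vdw,
                )
            )
    return StructureModel(atoms=atoms, chains=["W"], title=f"synthetic_{kind}")


# ---------------------------------------------------------------------------
# scripted trajectories for event-detection fixtures
# ---------------------------------------------------------------------------


@dataclass
class IonPath:
    """Piecewise-linear z(t) path of one ion; x,y held fixed."""

    species: str
    times: list[float]  # ps, strictly increasing
    z: list[float]  # A, one per time
    xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if len(self.times) != len(self.z):
            raise ValueError("times and z must have equal length")
        if any(t1 >= t2 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("path times must be strictly increasing (no overlaps)")


def script_trajectory(
    paths: list[IonPath],
    box: tuple[float, float, float] = (30.0, 30.0, 200.0),
    dt: float = 1.0,
) -> Trajectory:
    """Exact noise-free frames interpolated from hand-written ion paths.

    Frames run at spacing ``dt`` over the union of all path time
    ranges; a path is clamped to its end values outside its own range.
    """
    if not paths:
        raise ValueError("need at least one path")
    t0 = min(p.times[0] for p in paths)
    t1 = max(p.times[-1] for p in paths)
    times = np.arange(t0, t1 + dt / 2, dt)
    by_species: dict[str, list[IonPath]] = {}
    for p in paths:
        by_species.setdefault(p.species, []).append(p)
    frames = []
    for t in times:
        ions = {}
        for sp, plist in sorted(by_species.items()):
            coords = np.empty((len(plist), 3))
            for i, p in enumerate(plist):
                coords[i] = [p.xy[0], p.xy[1], np.interp(t, p.times, p.z)]
            ions[sp] = coords
        frames.append(
            Frame(time=float(t), ion_positions=ions, protein_positions=np.empty((0, 3)), box=np.asarray(box))
        )
    return Trajectory(frames=frames)
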