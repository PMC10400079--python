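"""Data model and I/O for structures, trajectories and pore-axis frames.

The in-memory objects here are deliberately thin: a structure is a list
of atom records, a trajectory is an ordered list of frames holding ion
and (optionally) protein coordinates plus simulation metadata.  Binary
trajectory formats (XTC/TRR/DCD) are read through MDAnalysis; structures
come in through gemmi (PDB and mmCIF); ``frames_tsv`` is a small
self-describing plain-text fixture format used by the synthetic
generator and the test suite.

Axis convention: the pore/diffusion axis is z in an :class:`AxisFrame`
whose origin sits at the junction midplane; z grows from the cytosol of
hemichannel 1 (HC1) towards the cytosol of hemichannel 2 (HC2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import DEFAULT_SPECIES_MAP, DEFAULT_T, vdw_radius

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Frame",
    "Trajectory",
    "SimulationMeta",
    "AxisFrame",
    "CompartmentSpec",
    "read_structure",
    "read_trajectory",
    "write_frames_tsv",
    "define_pore_axis",
    "define_compartments",
    "unwrapped_z",
]


class FormatError(ValueError):
    """A file does not parse under the named standard."""


class StructuralError(ValueError):
    """Inconsistent sizes/ordering between related inputs."""


class SelectionError(ValueError):
    """A residue/chain selection resolves to nothing."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue context and position (A)."""

    atom_id: int
    element: str
    name: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray  # shape (3,), A
    vdw_radius: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError(f"atom {self.atom_id}: element must be non-empty")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.atom_id}: vdw_radius must be positive")


@dataclass
class StructureModel:
    """An ordered collection of atoms grouped into chains."""

    atoms: list[AtomRecord]
    chains: list[str]
    title: str = ""

    def __post_init__(self):
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom_ids must be unique")
        present = {a.chain_id for a in self.atoms}
        for c in self.chains:
            if c not in present:
                raise ValueError(f"chain {c!r} listed but has no atoms")

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms]) if self.atoms else np.empty((0, 3))

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def select(
        self,
        chain_id: str | None = None,
        residue_range: tuple[int, int] | None = None,
        atom_names: Iterable[str] | None = None,
        heavy_only: bool = False,
    ) -> list[int]:
        """Indices (into ``atoms``) matching the selection."""
        names = set(atom_names) if atom_names is not None else None
        out = []
        for i, a in enumerate(self.atoms):
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if residue_range is not None and not (
                residue_range[0] <= a.residue_seq <= residue_range[1]
            ):
                continue
            if names is not None and a.name not in names:
                continue
            if heavy_only and a.element.upper() == "H":
                continue
            out.append(i)
        return out


@dataclass
class SimulationMeta:
    """Simulation conditions attached to a trajectory."""

    temperature: float = DEFAULT_T  # K
    applied_voltage: float = 0.0  # mV, signed
    replicate_id: str = "rep0"
    seed: int | None = None
    species_charges: dict[str, float] = field(
        default_factory=lambda: {"K+": 1.0, "Cl-": -1.0}
    )

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class Frame:
    """Coordinates at one time point (A, ps)."""

    time: float
    ion_positions: dict[str, np.ndarray]  # species -> (n_ions, 3)
    protein_positions: np.ndarray  # (n_atoms, 3) or (0, 3)
    box: np.ndarray  # (3,) box lengths, A

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box components must be positive")
        self.ion_positions = {
            sp: np.asarray(p, dtype=float).reshape(-1, 3)
            for sp, p in self.ion_positions.items()
        }
        self.protein_positions = np.asarray(self.protein_positions, dtype=float).reshape(-1, 3)


@dataclass
class Trajectory:
    frames: list[Frame]
    meta: SimulationMeta = field(default_factory=SimulationMeta)

    def __post_init__(self):
        times = [f.time for f in self.frames]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise StructuralError("frame times must be strictly increasing")
        if self.frames:
            species = set(self.frames[0].ion_positions)
            for f in self.frames[1:]:
                if set(f.ion_positions) != species:
                    raise StructuralError("all frames must share the same species set")

    @property
    def species(self) -> list[str]:
        return sorted(self.frames[0].ion_positions) if self.frames else []

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def ion_coords(self, species: str) -> np.ndarray:
        """Stacked coordinates for one species, shape (n_frames, n_ions, 3)."""
        if not self.frames or species not in self.frames[0].ion_positions:
            raise SelectionError(f"species {species!r} not present in trajectory")
        return np.stack([f.ion_positions[species] for f in self.frames])


@dataclass
class AxisFrame:
    """Rigid frame with the pore axis as z and origin at the junction midplane."""

    origin: np.ndarray
    axis: np.ndarray
    orientation: str = "hc1_negative"  # which side of the midplane HC1 sits on

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("axis must have unit norm (normalize before construction)")

    def basis(self) -> np.ndarray:
        """Orthonormal 3x3 basis whose third column is the axis."""
        z = self.axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, z)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        x = ref - np.dot(ref, z) * z
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        return np.column_stack([x, y, z])

    def to_frame(self, coords: np.ndarray) -> np.ndarray:
        """Map lab-frame coordinates into this axis frame."""
        coords = np.asarray(coords, dtype=float)
        return (coords - self.origin) @ self.basis()


@dataclass
class CompartmentSpec:
    """Axial compartment boundaries of the gap-junction channel (A).

    ``z_cyt1``/``z_cyt2`` are the cytosolic boundaries of the two
    hemichannels, ``z_mid`` the junction midplane.  ``hysteresis`` is
    the half-width of the buffer band used by crossing detection;
    ``ntd_z`` are the axial centres of the N-terminal-domain gate
    regions of the two hemichannels.
    """

    z_cyt1: float
    z_mid: float
    z_cyt2: float
    hysteresis: float = 2.0
    ntd_z: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self):
        if not self.z_cyt1 < self.z_mid < self.z_cyt2:
            raise ValueError("need z_cyt1 < z_mid < z_cyt2")
        if self.hysteresis < 0:
            raise ValueError("hysteresis must be non-negative")
        lo, hi = self.ntd_z
        if not math.isnan(lo) and not (self.z_cyt1 <= lo < self.z_mid):
            raise ValueError("ntd_z[0] must lie inside HC1")
        if not math.isnan(hi) and not (self.z_mid < hi <= self.z_cyt2):
            raise ValueError("ntd_z[1] must lie inside HC2")


# ---------------------------------------------------------------------------
# structure reading
# ---------------------------------------------------------------------------


def _guess_structure_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    return "pdb"


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Atoms are kept in file order; for multi-model files only model 1 is
    used.  Van der Waals radii are assigned from the element table in
    :mod:`gjpore.constants`.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _guess_structure_format(path, format)
    try:
        if fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        elif fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            raise ValueError(f"unknown structure format {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown structure format" in str(exc):
            raise
        raise FormatError(f"{path}: not a valid {fmt} file ({exc})") from exc

    if len(st) == 0:
        raise FormatError(f"{path}: no models found")
    model = st[0]
    atoms: list[AtomRecord] = []
    chains: list[str] = []
    atom_id = 0
    for chain in model:
        if chain.name not in chains:
            chains.append(chain.name)
        for residue in chain:
            for atom in residue:
                atom_id += 1
                element = atom.element.name if atom.element.name else atom.name[0]
                atoms.append(
                    AtomRecord(
                        atom_id=atom.serial if atom.serial else atom_id,
                        element=element,
                        name=atom.name,
                        residue_name=residue.name,
                        residue_seq=residue.seqid.num,
                        chain_id=chain.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        vdw_radius=vdw_radius(element),
                    )
                )
    chains = [c for c in chains if any(a.chain_id == c for a in atoms)]
    return StructureModel(atoms=atoms, chains=chains, title=st.name or path.stem)


# ---------------------------------------------------------------------------
# trajectory reading / writing
# ---------------------------------------------------------------------------

_TSV_HEADER = "frame\ttime_ps\tspecies\tatom_id\tx\ty\tz\tbox_x\tbox_y\tbox_z"
#: species label used for protein atoms in frames_tsv rows
PROTEIN_LABEL = "protein"


def write_frames_tsv(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the plain-text ``frames_tsv`` format.

    One row per particle per frame; output is bit-identical for
    identical inputs (fixed float formatting, fixed ordering).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_TSV_HEADER + "\n")
        for i, frame in enumerate(traj.frames):
            bx, by, bz = frame.box
            for sp in sorted(frame.ion_positions):
                for j, p in enumerate(frame.ion_positions[sp]):
                    fh.write(
                        f"{i}\t{frame.time:.6f}\t{sp}\t{j}\t"
                        f"{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\t"
                        f"{bx:.6f}\t{by:.6f}\t{bz:.6f}\n"
                    )
            for j, p in enumerate(frame.protein_positions):
                fh.write(
                    f"{i}\t{frame.time:.6f}\t{PROTEIN_LABEL}\t{j}\t"
                    f"{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\t"
                    f"{bx:.6f}\t{by:.6f}\t{bz:.6f}\n"
                )


def _read_frames_tsv(path: Path, meta: SimulationMeta | None) -> Trajectory:
    frames: dict[int, dict] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise FormatError(f"{path}: bad frames_tsv header: {header!r}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 10:
                raise FormatError(f"{path}:{lineno}: expected 10 fields, got {len(parts)}")
            fidx = int(parts[0])
            rec = frames.setdefault(
                fidx,
                {"time": float(parts[1]), "box": np.array([float(parts[7]), float(parts[8]), float(parts[9])]), "ions": {}, "protein": []},
            )
            sp = parts[2]
            pos = [float(parts[4]), float(parts[5]), float(parts[6])]
            if sp == PROTEIN_LABEL:
                rec["protein"].append((int(parts[3]), pos))
            else:
                rec["ions"].setdefault(sp, []).append((int(parts[3]), pos))

    frame_objs = []
    for fidx in sorted(frames):
        rec = frames[fidx]
        ions = {
            sp: np.array([p for _, p in sorted(rows)])
            for sp, rows in rec["ions"].items()
        }
        protein = (
            np.array([p for _, p in sorted(rec["protein"])])
            if rec["protein"]
            else np.empty((0, 3))
        )
        frame_objs.append(Frame(time=rec["time"], ion_positions=ions, protein_positions=protein, box=rec["box"]))
    return Trajectory(frames=frame_objs, meta=meta or SimulationMeta())


def _read_binary(
    path: Path,
    topology: StructureModel,
    species_map: Mapping[str, str],
    meta: SimulationMeta | None,
) -> Trajectory:
    import MDAnalysis as mda

    if topology is None:
        raise StructuralError("binary trajectory formats require a topology StructureModel")
    # Build a minimal MDAnalysis Universe from the in-memory structure.
    n = len(topology.atoms)
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", [a.name for a in topology.atoms])
    u.add_TopologyAttr("resnames")
    u.load_new(str(path))
    species_of = []
    for a in topology.atoms:
        species_of.append(species_map.get(a.residue_name.upper()))
    frames = []
    for ts in u.trajectory:
        if ts.n_atoms != n:
            raise StructuralError(
                f"trajectory frame has {ts.n_atoms} atoms, topology has {n}"
            )
        coords = np.asarray(ts.positions, dtype=float)
        ions: dict[str, list] = {}
        protein = []
        for sp, xyz in zip(species_of, coords):
            if sp is None:
                protein.append(xyz)
            else:
                ions.setdefault(sp, []).append(xyz)
        box = np.asarray(ts.dimensions[:3], dtype=float)
        frames.append(
            Frame(
                time=float(ts.time),
                ion_positions={sp: np.array(v) for sp, v in ions.items()},
                protein_positions=np.array(protein) if protein else np.empty((0, 3)),
                box=box,
            )
        )
    times = [f.time for f in frames]
    if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
        raise StructuralError("non-monotonic frame times in trajectory")
    return Trajectory(frames=frames, meta=meta or SimulationMeta())


def read_trajectory(
    path: str | Path,
    topology: StructureModel | None = None,
    format: str = "auto",
    species_map: Mapping[str, str] | None = None,
    meta: SimulationMeta | None = None,
) -> Trajectory:
    """Read a trajectory (XTC/TRR/DCD via MDAnalysis, or frames_tsv).

    Coordinates are in A, times in ps.  For binary formats ion species
    are identified from the topology residue names through
    ``species_map`` (defaults cover CHARMM and AMBER K+/Cl- names);
    atoms with unmapped residue names are treated as protein.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format
    if fmt == "auto":
        suffix = path.suffix.lower().lstrip(".")
        fmt = suffix if suffix in {"xtc", "trr", "dcd"} else "frames_tsv"
    if fmt == "frames_tsv":
        return _read_frames_tsv(path, meta)
    if fmt in {"xtc", "trr", "dcd"}:
        return _read_binary(path, topology, species_map or DEFAULT_SPECIES_MAP, meta)
    raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# axis and compartments
# ---------------------------------------------------------------------------


def define_pore_axis(
    structure: StructureModel,
    mode: str = "principal",
    explicit: AxisFrame | None = None,
    hc1_chains: Sequence[str] | None = None,
) -> AxisFrame:
    """Determine the pore (diffusion) axis of a channel structure.

    ``mode="principal"`` places the origin at the centre of geometry and
    takes the principal axis of the atom cloud with the largest extent
    (a membrane-spanning channel is longest along its pore axis); the
    sign is chosen so that the declared HC1 chains have negative mean z.
    ``mode="explicit"`` normalizes and echoes the supplied frame.
    """
    if mode == "explicit":
        if explicit is None:
            raise ValueError("explicit mode requires an AxisFrame")
        axis = np.asarray(explicit.axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("explicit axis must be non-zero")
        return AxisFrame(origin=explicit.origin, axis=axis / n, orientation=explicit.orientation)
    if mode != "principal":
        raise ValueError(f"unknown mode {mode!r}")
    coords = structure.positions()
    if len(coords) == 0:
        raise ValueError("structure is empty")
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[-1], 1.0):
        raise ValueError("degenerate atom cloud: rank < 3")
    axis = evecs[:, -1]  # largest-variance direction = pore axis
    if hc1_chains:
        sel = [i for i, a in enumerate(structure.atoms) if a.chain_id in hc1_chains]
        if sel and np.mean(centered[sel] @ axis) > 0:
            axis = -axis
    elif axis[2] < 0:  # fall back to a reproducible sign convention
        axis = -axis
    return AxisFrame(origin=center, axis=axis / np.linalg.norm(axis))


def define_compartments(
    structure: StructureModel,
    axis: AxisFrame,
    ntd_residues: tuple[int, int] = (2, 21),
    margin: float = 10.0,
    hysteresis: float = 2.0,
    hc1_chains: Sequence[str] | None = None,
) -> CompartmentSpec:
    """Derive compartment boundaries from the NTD gate positions.

    The NTD-region centre of each hemichannel is the mean axial
    coordinate of the selected NTD residues on that side of the
    midplane; the cytosolic boundaries are placed ``margin`` A outside
    the NTD centres.
    """
    z = axis.to_frame(structure.positions())[:, 2]
    sel = structure.select(residue_range=ntd_residues)
    if hc1_chains is not None:
        hc1_sel = [i for i in sel if structure.atoms[i].chain_id in hc1_chains]
        hc2_sel = [i for i in sel if structure.atoms[i].chain_id not in hc1_chains]
    else:
        hc1_sel = [i for i in sel if z[i] < 0]
        hc2_sel = [i for i in sel if z[i] >= 0]
    if not hc1_sel:
        raise SelectionError("NTD selection empty for hemichannel 1")
    if not hc2_sel:
        raise SelectionError("NTD selection empty for hemichannel 2")
    ntd1 = float(np.mean(z[hc1_sel]))
    ntd2 = float(np.mean(z[hc2_sel]))
    return CompartmentSpec(
        z_cyt1=ntd1 - margin,
        z_mid=0.0,
        z_cyt2=ntd2 + margin,
        hysteresis=hysteresis,
        ntd_z=(ntd1, ntd2),
    )


# ---------------------------------------------------------------------------
# periodic unwrapping
# ---------------------------------------------------------------------------


def unwrapped_z(traj: Trajectory, species: str, axis: AxisFrame | None = None) -> np.ndarray:
    """Per-ion unwrapped axial coordinates, shape (n_frames, n_ions).

    A minimum-image step is applied between consecutive frames, so each
    ion's z becomes a continuous path; displacements larger than half
    the box length per frame would alias and cannot be recovered.
    Crossing detection requires these continuous paths, while density
    binning uses the wrapped coordinates as stored.
    """
    coords = traj.ion_coords(species)
    if axis is not None:
        nf, ni, _ = coords.shape
        coords = axis.to_frame(coords.reshape(-1, 3)).reshape(nf, ni, 3)
    z = coords[:, :, 2].copy()
    box_z = np.array([f.box[2] for f in traj.frames])[:, None]
    dz = np.diff(z, axis=0)
    shift = np.round(dz / box_z[1:])
    z[1:] -= np.cumsum(shift * box_z[1:], axis=0)
    return z
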