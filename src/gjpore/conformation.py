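"""Rigid superposition and RMSD machinery for conformational analysis.

Covers whole-complex stability RMSD, region RMSD without refitting
(superpose on a core selection, measure a region under that transform),
per-chain N-terminal-domain RMSD traces over a trajectory, and
classification of the NTD gate into closed / intermediate / open states
by RMSD thresholds.

The superposition is the closed-form least-squares (Kabsch) solution:
given paired point sets A and B it returns the proper rotation U and
translation t minimizing sum |U a_i + t - b_i|^2, with any
reflection-requiring case resolved to det(U) = +1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StructureModel, Trajectory

__all__ = [
    "SuperpositionResult",
    "StateTrace",
    "kabsch_superpose",
    "rmsd_nofit",
    "region_rmsd_after_global_fit",
    "per_chain_rmsd_trace",
    "classify_states",
]

STATES = ("closed", "intermediate", "open")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, A
    rmsd: float  # A, over the paired atoms after the transform
    n_atoms: int
    selection_a: str = ""
    selection_b: str = ""

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class StateTrace:
    """Per-frame NTD RMSD of one chain with threshold-derived states."""

    chain_id: str
    times: np.ndarray  # ps
    rmsd: np.ndarray  # A
    state: list[str]
    thresholds: tuple[float, float]


def _paired(coords_a, coords_b, pairing):
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if pairing is not None:
        ia = [p[0] for p in pairing]
        ib = [p[1] for p in pairing]
        a, b = a[ia], b[ib]
    if len(a) != len(b):
        raise ValueError(f"paired sets differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty pairing")
    return a, b


def kabsch_superpose(
    coords_a, coords_b, pairing=None, selection_a: str = "", selection_b: str = ""
) -> SuperpositionResult:
    """Optimal rigid superposition of A onto B over paired atoms.

    Requires at least 3 non-collinear pairs; the rotation is always a
    proper rotation (det +1).
    """
    a, b = _paired(coords_a, coords_b, pairing)
    if len(a) < 3:
        raise ValueError("need at least 3 atom pairs for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinearity check: rank of the centred cloud
    if np.linalg.matrix_rank(a0, tol=1e-8 * max(1.0, np.abs(a0).max())) < 2:
        raise ValueError("degenerate (collinear) coordinates: rotation not unique")
    H = a0.T @ b0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = a0 @ R.T - b0
    rmsd = float(np.sqrt((diff**2).sum() / len(a)))
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_atoms=len(a),
        selection_a=selection_a,
        selection_b=selection_b,
    )


def rmsd_nofit(coords_a, coords_b, pairing=None) -> float:
    """Root-mean-square of paired inter-atom distances, no fitting."""
    a, b = _paired(coords_a, coords_b, pairing)
    return float(np.sqrt(((a - b) ** 2).sum() / len(a)))


_SUBSET_NAMES = {
    "CA": {"CA"},
    "backbone": {"N", "CA", "C", "O"},
    "heavy": None,
}


def _subset_indices(struct: StructureModel, residue_range, atom_subset: str) -> list[int]:
    names = _SUBSET_NAMES[atom_subset]
    return struct.select(
        residue_range=residue_range,
        atom_names=names,
        heavy_only=(atom_subset == "heavy"),
    )


def _pair_by_residue_order(struct_a, idx_a, struct_b, idx_b):
    """Pair atoms across structures by (residue order, atom name)."""
    def keyed(struct, idx):
        return {
            (struct.atoms[i].chain_id, struct.atoms[i].residue_seq, struct.atoms[i].name): i
            for i in idx
        }
    ka, kb = keyed(struct_a, idx_a), keyed(struct_b, idx_b)
    # match by position in the sorted residue sequence, name by name
    ra = sorted({(c, r) for c, r, _ in ka})
    rb = sorted({(c, r) for c, r, _ in kb})
    if len(ra) != len(rb):
        raise ValueError(
            f"selections pair {len(ra)} vs {len(rb)} residues; "
            "unpaired residues: "
            + str(ra[len(rb):] if len(ra) > len(rb) else rb[len(ra):])
        )
    pairs = []
    for (ca_, ra_), (cb_, rb_) in zip(ra, rb):
        names_a = {n for (c, r, n) in ka if (c, r) == (ca_, ra_)}
        names_b = {n for (c, r, n) in kb if (c, r) == (cb_, rb_)}
        for n in sorted(names_a & names_b):
            pairs.append((ka[(ca_, ra_, n)], kb[(cb_, rb_, n)]))
    if not pairs:
        raise ValueError("selections share no atoms after pairing")
    return pairs


def region_rmsd_after_global_fit(
    struct_a: StructureModel,
    struct_b: StructureModel,
    global_sel: tuple[int, int],
    region_sel_a: tuple[int, int],
    region_sel_b: tuple[int, int],
    atom_subset: str = "CA",
) -> float:
    """Superpose on a global selection, then measure a region RMSD
    without refitting (the rms_cur-style comparison).

    Residue ranges are author numbering; atoms are paired by residue
    order and atom name within the chosen subset.
    """
    ga = _subset_indices(struct_a, global_sel, atom_subset)
    gb = _subset_indices(struct_b, global_sel, atom_subset)
    pairs_g = _pair_by_residue_order(struct_a, ga, struct_b, gb)
    pa = struct_a.positions()
    pb = struct_b.positions()
    sup = kabsch_superpose(pa, pb, pairing=pairs_g)
    ra = _subset_indices(struct_a, region_sel_a, atom_subset)
    rb = _subset_indices(struct_b, region_sel_b, atom_subset)
    pairs_r = _pair_by_residue_order(struct_a, ra, struct_b, rb)
    a_t = sup.transform(pa)
    return rmsd_nofit(a_t, pb, pairing=pairs_r)


def per_chain_rmsd_trace(
    traj: Trajectory,
    ref: StructureModel,
    chain_sel: dict[str, tuple[int, int]],
    fit_sel: tuple[int, int],
    atom_subset: str = "CA",
    thresholds: tuple[float, float] = (3.0, 6.0),
) -> list[StateTrace]:
    """Per-frame, per-chain region RMSD against a reference structure.

    Each frame is first rigidly fitted to the reference on ``fit_sel``
    (e.g. the transmembrane core over all chains), then each chain's
    region in ``chain_sel`` (e.g. the NTD helix) is measured without
    refitting.  The trajectory's protein coordinates must follow the
    reference atom order.
    """
    fit_idx = _subset_indices(ref, fit_sel, atom_subset)
    if len(fit_idx) < 3:
        raise ValueError("fit selection resolves to fewer than 3 atoms")
    region_idx = {}
    for chain, rng in chain_sel.items():
        idx = [
            i
            for i in _subset_indices(ref, rng, atom_subset)
            if ref.atoms[i].chain_id == chain
        ]
        if not idx:
            raise ValueError(f"selection empty for chain {chain!r}")
        region_idx[chain] = np.array(idx)
    ref_pos = ref.positions()
    times = np.array([f.time for f in traj.frames])
    nat = len(ref.atoms)
    rmsds = {c: np.empty(traj.n_frames) for c in chain_sel}
    for fi, frame in enumerate(traj.frames):
        pos = frame.protein_positions
        if pos.shape[0] != nat:
            raise ValueError(
                f"frame {fi} has {pos.shape[0]} protein atoms, reference has {nat}"
            )
        sup = kabsch_superpose(pos[fit_idx], ref_pos[fit_idx])
        fitted = sup.transform(pos)
        for chain, idx in region_idx.items():
            rmsds[chain][fi] = rmsd_nofit(fitted[idx], ref_pos[idx])
    traces = []
    for chain in chain_sel:
        trace = StateTrace(
            chain_id=chain,
            times=times,
            rmsd=rmsds[chain],
            state=[],
            thresholds=thresholds,
        )
        traces.append(classify_states(trace, thresholds))
    return traces


def classify_states(trace: StateTrace, thresholds: tuple[float, float]) -> StateTrace:
    """Fill per-frame gate states: rmsd < t0 -> closed, t0 <= rmsd < t1
    -> intermediate, rmsd >= t1 -> open (boundaries go to the higher
    state)."""
    t0, t1 = thresholds
    if not t0 < t1:
        raise ValueError("thresholds must be increasing")
    state = np.where(trace.rmsd < t0, "closed", np.where(trace.rmsd < t1, "intermediate", "open"))
    trace.state = state.tolist()
    trace.thresholds = (t0, t1)
    return trace
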