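import numpy as np
import pytest

from gjpore import AtomRecord, AxisFrame, StructureModel


@pytest.fixture
def z_axis() -> AxisFrame:
    return AxisFrame(origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]))


def make_atoms(positions, element="C", chain_id="A", vdw=1.7, names=None,
               residue_seqs=None) -> StructureModel:
    """Small helper to build a StructureModel from bare coordinates."""
    atoms = []
    for i, p in enumerate(positions):
        atoms.append(
            AtomRecord(
                atom_id=i + 1,
                element=element,
                name=names[i] if names else "CA",
                residue_name="GLY",
                residue_seq=residue_seqs[i] if residue_seqs else i + 1,
                chain_id=chain_id,
                position=np.asarray(p, dtype=float),
                vdw_radius=vdw,
            )
        )
    return StructureModel(atoms=atoms, chains=[chain_id])


@pytest.fixture
def four_atom_pdb(tmp_path):
    """Hand-written 4-atom PDB fixture."""
    text = (
        "TITLE     TINY FIXTURE\n"
        "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       2.000   3.000   4.000  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1       3.000   4.000   5.000  1.00  0.00           C\n"
        "ATOM      4  O   ALA A   1       4.000   5.000   6.000  1.00  0.00           O\n"
        "END\n"
    )
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
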