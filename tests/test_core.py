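"""Structure/trajectory I/O, pore-axis and compartment construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gjpore import (
    AxisFrame,
    CompartmentSpec,
    Frame,
    SimulationMeta,
    Trajectory,
    define_compartments,
    define_pore_axis,
    read_structure,
    read_trajectory,
    unwrapped_z,
    write_frames_tsv,
)
from gjpore.core import SelectionError, StructuralError

from conftest import make_atoms, random_rotation


# ---------------------------------------------------------------------------
# structure reading
# ---------------------------------------------------------------------------


class TestReadStructure:
    def test_file_order_and_fields(self, four_atom_pdb):
        st_ = read_structure(four_atom_pdb)
        assert len(st_.atoms) == 4
        assert [a.name for a in st_.atoms] == ["N", "CA", "C", "O"]
        np.testing.assert_allclose(st_.atoms[0].position, [1.0, 2.0, 3.0])
        assert st_.atoms[1].vdw_radius == pytest.approx(1.70)  # carbon
        assert st_.chains == ["A"]

    def test_pdb_and_mmcif_encodings_agree(self, four_atom_pdb, tmp_path):
        import gemmi

        st_pdb = read_structure(four_atom_pdb, format="pdb")
        doc = gemmi.read_pdb(str(four_atom_pdb))
        cif_path = tmp_path / "tiny.cif"
        doc.setup_entities()
        cif_path.write_text(doc.make_mmcif_document().as_string())
        st_cif = read_structure(cif_path, format="mmcif")
        assert len(st_pdb.atoms) == len(st_cif.atoms)
        for a, b in zip(st_pdb.atoms, st_cif.atoms):
            assert (a.element, a.name, a.residue_name, a.residue_seq) == (
                b.element,
                b.name,
                b.residue_name,
                b.residue_seq,
            )
            np.testing.assert_allclose(a.position, b.position, atol=1e-3)

    def test_unparseable_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure\n")
        with pytest.raises(Exception):
            read_structure(bad, format="mmcif")


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------


def _tiny_traj():
    frames = [
        Frame(
            time=float(t),
            ion_positions={"K+": np.array([[1.0 + t, 2.0, 3.0 * t]])},
            protein_positions=np.empty((0, 3)),
            box=np.array([30.0, 30.0, 100.0]),
        )
        for t in range(2)
    ]
    return Trajectory(frames=frames, meta=SimulationMeta())


class TestFramesTsv:
    def test_read_two_frame_fixture(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_frames_tsv(_tiny_traj(), path)
        traj = read_trajectory(path)
        assert traj.n_frames == 2
        assert traj.species == ["K+"]

    def test_round_trip_coordinates(self, tmp_path):
        traj = _tiny_traj()
        path = tmp_path / "t.tsv"
        write_frames_tsv(traj, path)
        back = read_trajectory(path)
        np.testing.assert_allclose(
            back.ion_coords("K+"), traj.ion_coords("K+"), atol=1e-6
        )

    def test_writer_is_deterministic(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_frames_tsv(_tiny_traj(), p1)
        write_frames_tsv(_tiny_traj(), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_binary_and_tsv_encodings_agree(self, tmp_path):
        """A DCD written via MDAnalysis reads back to the same ion z."""
        import MDAnalysis as mda

        from gjpore import GeneratorSpec, simulate_ions

        traj = simulate_ions(GeneratorSpec(n_ions={"K+": 3}, n_steps=10, sample_every=1, seed=5))
        tsv = tmp_path / "run.tsv"
        write_frames_tsv(traj, tsv)

        n = 3
        u = mda.Universe.empty(n, trajectory=True)
        u.add_TopologyAttr("names", ["K"] * n)
        u.add_TopologyAttr("resnames", ["POT"])
        dcd = tmp_path / "run.dcd"
        with mda.Writer(str(dcd), n) as w:
            for f in traj.frames:
                u.atoms.positions = f.ion_positions["K+"]
                u.dimensions = [*f.box, 90, 90, 90]
                w.write(u.atoms)
        topo = make_atoms(traj.frames[0].ion_positions["K+"], element="K",
                          names=["K"] * n)
        for a in topo.atoms:
            object.__setattr__(a, "residue_name", "POT")
        back = read_trajectory(dcd, topology=topo, format="dcd")
        np.testing.assert_allclose(
            back.ion_coords("K+")[..., 2], traj.ion_coords("K+")[..., 2], atol=1e-3
        )

    def test_nonmonotonic_times_rejected(self):
        f = _tiny_traj().frames
        with pytest.raises(StructuralError):
            Trajectory(frames=[f[1], f[0]])


# ---------------------------------------------------------------------------
# pore axis
# ---------------------------------------------------------------------------


def _cylinder_cloud(radius=8.0, length=60.0, n_rings=30, per_ring=12):
    """Regular ring stack: symmetric, so the principal axis is exact."""
    zs = np.linspace(-length / 2, length / 2, n_rings)
    phi = 2 * np.pi * np.arange(per_ring) / per_ring
    return np.array(
        [[radius * np.cos(p), radius * np.sin(p), z] for z in zs for p in phi]
    )


class TestPoreAxis:
    def test_cylinder_axis_is_z(self):
        st_ = make_atoms(_cylinder_cloud())
        axis = define_pore_axis(st_)
        assert abs(abs(axis.axis[2]) - 1.0) < 1e-6

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_equivariance_under_rotation(self, seed):
        rng = np.random.default_rng(seed)
        R = random_rotation(rng)
        cloud = _cylinder_cloud()
        a0 = define_pore_axis(make_atoms(cloud)).axis
        a1 = define_pore_axis(make_atoms(cloud @ R.T)).axis
        # axis is defined up to sign without an HC1 declaration
        assert min(np.linalg.norm(a1 - R @ a0), np.linalg.norm(a1 + R @ a0)) < 1e-6

    def test_explicit_axis_normalized(self, z_axis):
        raw = AxisFrame.__new__(AxisFrame)
        raw.origin = np.zeros(3)
        raw.axis = np.array([0.0, 0.0, 2.0])
        raw.orientation = "hc1_negative"
        out = define_pore_axis(make_atoms(_cylinder_cloud()), mode="explicit", explicit=raw)
        np.testing.assert_allclose(out.axis, [0, 0, 1], atol=1e-12)

    def test_degenerate_cloud_rejected(self):
        flat = np.column_stack([np.arange(10.0), np.arange(10.0) * 2, np.zeros(10)])
        with pytest.raises(ValueError, match="degenerate"):
            define_pore_axis(make_atoms(flat + np.array([0.0, 0.0, 0.0])))


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------


class TestCompartments:
    def _two_sided_structure(self):
        pos = np.array([[0.0, 1.0, -40.0], [1.0, 0.0, -40.0], [0.0, 1.0, 40.0], [1.0, 0.0, 40.0]])
        return make_atoms(pos, residue_seqs=[5, 6, 5, 6])

    def test_margin_arithmetic(self, z_axis):
        comp = define_compartments(self._two_sided_structure(), z_axis,
                                   ntd_residues=(2, 21), margin=10.0)
        assert comp.z_cyt1 == pytest.approx(-50.0)
        assert comp.z_cyt2 == pytest.approx(50.0)
        assert comp.ntd_z == (pytest.approx(-40.0), pytest.approx(40.0))

    def test_zero_margin(self, z_axis):
        comp = define_compartments(self._two_sided_structure(), z_axis, margin=0.0,
                                   hysteresis=0.0)
        assert comp.z_cyt1 == pytest.approx(comp.ntd_z[0])
        assert comp.z_cyt2 == pytest.approx(comp.ntd_z[1])

    def test_empty_hemichannel_selection(self, z_axis):
        pos = np.array([[0.0, 1.0, -40.0], [1.0, 0.0, -41.0], [0, 2, -39.0], [2, 0, -38.0]])
        with pytest.raises(SelectionError, match="hemichannel"):
            define_compartments(make_atoms(pos), z_axis)

    @given(
        z1=st.floats(-100, -1),
        z2=st.floats(1, 100),
        h=st.floats(0, 5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_spec_invariant_holds_for_valid_inputs(self, z1, z2, h):
        comp = CompartmentSpec(z_cyt1=z1, z_mid=0.0, z_cyt2=z2, hysteresis=h)
        assert comp.z_cyt1 < comp.z_mid < comp.z_cyt2
        assert comp.hysteresis >= 0

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            CompartmentSpec(z_cyt1=10.0, z_mid=0.0, z_cyt2=20.0)


# ---------------------------------------------------------------------------
# unwrapping
# ---------------------------------------------------------------------------


def test_unwrap_recovers_continuous_path():
    """An ion walking steadily past the periodic boundary unwraps to a
    straight line."""
    box = np.array([20.0, 20.0, 50.0])
    true_z = np.linspace(0, 130.0, 40)  # crosses the box twice
    frames = [
        Frame(
            time=float(i),
            ion_positions={"K+": np.array([[0.0, 0.0, ((z + 25) % 50) - 25]])},
            protein_positions=np.empty((0, 3)),
            box=box,
        )
        for i, z in enumerate(true_z)
    ]
    traj = Trajectory(frames=frames)
    z = unwrapped_z(traj, "K+")[:, 0]
    np.testing.assert_allclose(np.diff(z), np.diff(true_z), atol=1e-9)
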