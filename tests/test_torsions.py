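"""Dihedral geometry, phi/psi recovery, Ramachandran statistics,
carbonyl orientation and interhelix torsions."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from channelmd import (
    PoreAxis,
    Selection,
    TorsionTrace,
    Trajectory,
    carbonyl_orientation,
    dihedral,
    helix_axis,
    interhelix_torsion,
    make_helix,
    phi_psi_traces,
    ramachandran_shift,
    ramachandran_summary,
)
from channelmd.errors import FitError, GeometryError
from channelmd.io import AtomRecord, Structure

P1, P2, P3 = np.array([1.0, 1, 0]), np.array([0.0, 1, 0]), np.array([0.0, 0, 0])


def single_frame(structure):
    return Trajectory(structure, structure.coords()[None], 1.0)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral(P1, P2, P3, [1.0, -1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        assert dihedral(P1, P2, P3, [-1.0, -1, 0]) == pytest.approx(180.0)

    def test_right_hand_rotation_sign(self):
        axis = P3 - P2
        axis = axis / np.linalg.norm(axis)
        p4 = Rotation.from_rotvec(np.radians(90) * axis).apply([1.0, -1, 0])
        assert dihedral(P1, P2, P3, p4) == pytest.approx(90.0, abs=1e-9)

    def test_collinear_points_rejected(self):
        with pytest.raises(GeometryError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_rigid_motion_invariance_reversal_and_mirror(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = rng.normal(size=(4, 3))
            d0 = dihedral(*pts)
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(size=3)
            moved = pts @ rot.T + shift
            assert dihedral(*moved) == pytest.approx(d0, abs=1e-9)
            # reversing the point order preserves the signed dihedral
            # (both the viewing direction and the order flip)
            assert dihedral(*pts[::-1]) == pytest.approx(d0, abs=1e-9)
            # a mirror reflection flips the sign
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            if abs(abs(d0) - 180.0) > 1e-9:
                assert dihedral(*mirrored) == pytest.approx(-d0, abs=1e-9)


class TestPhiPsi:
    @pytest.mark.parametrize("phi,psi", [(-57.0, -47.0), (-120.0, 130.0)])
    def test_helix_round_trip(self, phi, psi):
        traj = single_frame(make_helix(10, phi, psi))
        traces = phi_psi_traces(traj, Selection())
        assert traces
        for tr in traces:
            expected = phi if tr.angle_name == "phi" else psi
            np.testing.assert_allclose(tr.values, expected, atol=1e-6)

    def test_random_angles_round_trip(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            phi, psi = rng.uniform(-179, 179, size=2)
            traj = single_frame(make_helix(5, float(phi), float(psi)))
            for tr in phi_psi_traces(traj, Selection()):
                expected = phi if tr.angle_name == "phi" else psi
                np.testing.assert_allclose(tr.values, expected, atol=1e-6)

    def test_terminus_angles_absent(self):
        traj = single_frame(make_helix(6, -57.0, -47.0))
        first = [t.angle_name for t in phi_psi_traces(traj, Selection.of(residues=1))]
        assert first == ["psi"]
        last = [t.angle_name for t in phi_psi_traces(traj, Selection.of(residues=6))]
        assert last == ["phi"]


class TestRamachandran:
    def make_trace(self, values, name):
        return TorsionTrace(1, "A", name, np.asarray(values, dtype=float))

    def test_constant_trace_single_bin(self):
        phi = self.make_trace([-57.0] * 50, "phi")
        psi = self.make_trace([-47.0] * 50, "psi")
        s = ramachandran_summary(phi, psi)
        assert s.occupancy.sum() == pytest.approx(1.0)
        assert (s.occupancy > 0).sum() == 1
        i, j = np.argwhere(s.occupancy > 0)[0]
        assert s.bin_edges[i] <= -57.0 < s.bin_edges[i + 1]
        assert s.bin_edges[j] <= -47.0 < s.bin_edges[j + 1]
        assert s.occupancy[i, j] == pytest.approx(1.0)

    def test_constructed_psi_shift_of_70_degrees(self):
        rng = np.random.default_rng(3)
        base_phi = rng.normal(-57, 5, 2000)
        base_psi = rng.normal(-47, 5, 2000)
        ref = ramachandran_summary(
            self.make_trace(base_phi, "phi"), self.make_trace(base_psi, "psi")
        )
        var = ramachandran_summary(
            self.make_trace(base_phi, "phi"), self.make_trace(base_psi + 70.0, "psi")
        )
        shift = ramachandran_shift(var, ref)
        assert shift["delta_psi"] == pytest.approx(70.0, abs=1.0)
        assert shift["delta_phi"] == pytest.approx(0.0, abs=1.0)

    def test_uniform_noise_flags_unstable_mean(self):
        rng = np.random.default_rng(9)
        phi = self.make_trace(rng.uniform(-180, 180, 5000), "phi")
        psi = self.make_trace(rng.uniform(-180, 180, 5000), "psi")
        s = ramachandran_summary(phi, psi)
        # uniform angles: mean resultant length ~ 1/sqrt(n) -> flagged
        assert not s.phi_mean_reliable
        assert not s.psi_mean_reliable
        # circular variance 1 - R approaches its uniform limit of 1
        assert 1.0 - s.phi_resultant > 0.95

    def test_wraparound_invariance(self):
        vals = np.array([170.0, -170.0, 175.0, -175.0] * 10)
        a = ramachandran_summary(self.make_trace(vals, "phi"), self.make_trace(vals, "psi"))
        b = ramachandran_summary(
            self.make_trace(vals + 360.0, "phi"), self.make_trace(vals - 360.0, "psi")
        )
        np.testing.assert_allclose(a.occupancy, b.occupancy)
        assert a.phi_mean == pytest.approx(b.phi_mean, abs=1e-9)
        assert a.phi_sd == pytest.approx(b.phi_sd, abs=1e-9)


class TestCarbonylOrientation:
    def make(self, o_pos):
        atoms = [
            AtomRecord(1, "C", "VAL", 625, "A", (5.0, 0.0, 0.0), element="C"),
            AtomRecord(2, "O", "VAL", 625, "A", tuple(o_pos), element="O"),
        ]
        return single_frame(Structure(atoms, {"A": "A"}))

    def test_inward_carbonyl(self, z_axis):
        tr = carbonyl_orientation(self.make((3.8, 0.0, 0.0)), 625, "A", z_axis)
        assert tr.state[0] == "in"
        assert tr.radial_projection[0] == pytest.approx(-1.0)

    def test_outward_carbonyl(self, z_axis):
        tr = carbonyl_orientation(self.make((6.2, 0.0, 0.0)), 625, "A", z_axis)
        assert tr.state[0] == "out"
        assert tr.radial_projection[0] == pytest.approx(1.0)

    def test_perpendicular_is_out_by_convention(self, z_axis):
        tr = carbonyl_orientation(self.make((5.0, 1.2, 0.0)), 625, "A", z_axis)
        assert tr.radial_projection[0] == pytest.approx(0.0, abs=1e-12)
        assert tr.state[0] == "out"

    def test_rigid_motion_invariance(self, z_axis):
        traj = self.make((3.8, 0.4, 0.3))
        base = carbonyl_orientation(traj, 625, "A", z_axis)
        rot = Rotation.from_euler("xyz", [25, -40, 60], degrees=True).as_matrix()
        shift = np.array([1.0, -2.0, 3.0])
        moved = traj.roster.with_coords(traj.roster.coords() @ rot.T + shift)
        maxis = PoreAxis(
            tuple(rot @ np.asarray(z_axis.origin) + shift),
            tuple(rot @ np.asarray(z_axis.direction)),
        )
        out = carbonyl_orientation(single_frame(moved), 625, "A", maxis)
        assert out.state == base.state
        assert out.radial_projection[0] == pytest.approx(
            base.radial_projection[0], abs=1e-9
        )


class TestHelixAxisAndInterhelix:
    def test_ideal_helix_axis_matches_screw_axis(self):
        # oracle: the rotation superposing CA(i) onto CA(i+1) is a screw
        # motion whose rotation axis is the true helix axis
        from channelmd.mobility import kabsch_superpose

        helix = make_helix(20, -57.0, -47.0)
        axis = helix_axis(helix, (1, 20), "A")
        ca = np.array([a.position for a in helix.atoms if a.atom_name == "CA"])
        rv = Rotation.from_matrix(
            kabsch_superpose(ca[:-1], ca[1:]).rotation
        ).as_rotvec()
        screw = rv / np.linalg.norm(rv)
        d = np.asarray(axis.direction)
        if screw @ d < 0:
            screw = -screw
        angle = np.degrees(np.arccos(np.clip(d @ screw, -1, 1)))
        assert angle < 2.0

    def test_rotated_helix_rotates_axis(self):
        helix = make_helix(12, -57.0, -47.0)
        d0 = np.asarray(helix_axis(helix, (1, 12), "A").direction)
        rot = Rotation.from_euler("y", 40, degrees=True).as_matrix()
        moved = helix.with_coords(helix.coords() @ rot.T)
        d1 = np.asarray(helix_axis(moved, (1, 12), "A").direction)
        np.testing.assert_allclose(d1, rot @ d0, atol=1e-9)

    def test_three_residue_range_is_fit_error(self):
        helix = make_helix(12, -57.0, -47.0)
        with pytest.raises(FitError):
            helix_axis(helix, (1, 3), "A")

    def make_two_helix_chain(self, rotate_deg=0.0):
        """Two straight 'helices' of CA atoms along x, linked end to end;
        the distal S5 half can be rotated about the linker (x) axis."""
        pts = []
        for i in range(8):  # S4: residues 1-8; distal half offset to y=+2
            pts.append((float(i), 2.0 if i < 4 else 0.0, 0.0))
        for i in range(4):  # linker: residues 9-12 on the x axis
            pts.append((8.0 + float(i), 0.0, 0.0))
        for i in range(8):  # S5: residues 13-20; distal half at y=-2
            pts.append((12.0 + float(i), 0.0 if i < 4 else -2.0, 0.0))
        # proximal-half centroids sit on the x axis, so the dihedral axis
        # is exactly the linker axis
        pts = np.array(pts)
        if rotate_deg:
            rot = Rotation.from_rotvec(np.radians(rotate_deg) * np.array([1.0, 0, 0]))
            pts[16:] = rot.apply(pts[16:])  # distal half of S5
        atoms = [
            AtomRecord(i + 1, "CA", "ALA", i + 1, "A", tuple(p), element="C")
            for i, p in enumerate(pts)
        ]
        return single_frame(Structure(atoms, {"A": "A"}))

    def test_coplanar_trans_construction_is_180(self):
        tr = interhelix_torsion(
            self.make_two_helix_chain(), (1, 8), (9, 12), (13, 20), "A"
        )
        assert abs(tr.values[0]) == pytest.approx(180.0, abs=1e-6)

    def test_rotating_distal_half_shifts_torsion_by_30(self):
        t0 = interhelix_torsion(
            self.make_two_helix_chain(0.0), (1, 8), (9, 12), (13, 20), "A"
        ).values[0]
        t30 = interhelix_torsion(
            self.make_two_helix_chain(30.0), (1, 8), (9, 12), (13, 20), "A"
        ).values[0]
        delta = (t30 - t0 + 180.0) % 360.0 - 180.0
        assert abs(abs(delta) - 30.0) < 1e-6

    def test_static_trajectory_constant_trace(self):
        traj = self.make_two_helix_chain()
        traj5 = Trajectory(traj.roster, np.repeat(traj.frames, 5, axis=0), 1.0)
        tr = interhelix_torsion(traj5, (1, 8), (9, 12), (13, 20), "A", frame_stride=2)
        assert tr.values.shape == (3,)
        assert np.ptp(tr.values) < 1e-12
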