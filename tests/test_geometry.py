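"""Superposition, dihedral, circular-statistics and kink-angle geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gactdyn.geometry import (
    DegenerateFitError,
    InsufficientFramesError,
    MissingAtomError,
    UndefinedDihedralError,
    UndefinedMeanError,
    backbone_dihedral_series,
    circular_mean,
    circular_sd,
    dihedral,
    fit_helix_axis,
    kabsch_superpose,
    prokink_angles,
    rmsd_series,
    rmsf,
    sidechain_chi_series,
)
from gactdyn.model import Selection
from gactdyn.synth import (
    HelixSpec,
    KinkSpec,
    make_backbone_trajectory,
    make_chi_fixture,
    make_ideal_helix,
    make_kinked_helix,
)

from conftest import rigid_transform


def _random_rotation(rng):
    return rigid_transform(rng)[0]


class TestKabsch:
    def test_identity_fit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 3))
        res = kabsch_superpose(x, x)
        assert res.rmsd < 1e-12
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 3))
        Q, t = rigid_transform(rng)
        res = kabsch_superpose(x @ Q.T + t, x)
        assert res.rmsd < 1e-9
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-6

    def test_matches_mdanalysis_rotation(self):
        """Independent oracle: MDAnalysis' QCP rotation gives the same RMSD."""
        mda_align = pytest.importorskip("MDAnalysis.analysis.align")
        rng = np.random.default_rng(2)
        a = rng.normal(size=(12, 3))
        b = a @ _random_rotation(rng).T + rng.normal(scale=0.3, size=(12, 3))
        ours = kabsch_superpose(b, a)
        _R, oracle_rmsd = mda_align.rotation_matrix(b - b.mean(0), a - a.mean(0))
        assert abs(ours.rmsd - oracle_rmsd) < 1e-6

    def test_grid_search_oracle(self):
        """Brute-force small-angle search cannot beat the analytic optimum."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=(5, 3)) * 3
        b = a + rng.normal(scale=0.4, size=(5, 3))
        best = kabsch_superpose(b, a)
        ac, bc = a - a.mean(0), b - b.mean(0)
        grid = np.deg2rad(np.arange(-6, 6.1, 2.0))
        lo = np.inf
        for ax_ in grid:
            for ay in grid:
                for az in grid:
                    cx, sx = np.cos(ax_), np.sin(ax_)
                    cy, sy = np.cos(ay), np.sin(ay)
                    cz, sz = np.cos(az), np.sin(az)
                    R = (np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
                         @ np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
                         @ np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]]))
                    r = np.sqrt(np.mean(np.sum((bc @ (best.rotation @ R).T - ac) ** 2, axis=1)))
                    lo = min(lo, r)
        assert best.rmsd <= lo + 1e-3

    def test_degenerate_inputs(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateFitError):
            kabsch_superpose(line, line)
        with pytest.raises(DegenerateFitError):
            kabsch_superpose(line[:2], line[:2])


class TestRmsdRmsf:
    def test_reference_frame_rmsd_zero(self):
        helix = make_ideal_helix(HelixSpec(10))
        coords = np.repeat(helix.coordinates, 4, axis=0)
        coords[1:] += np.array([1.0, 2.0, 3.0])  # pure translations
        from gactdyn.model import FrameSeries
        frames = FrameSeries(helix.topology, coords, np.arange(4) * 0.1)
        sel = Selection(list(range(10)))
        series = rmsd_series(frames, frames.coordinates[0], sel)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_noise_rmsd_matches_direct_computation(self):
        rng = np.random.default_rng(4)
        base = make_ideal_helix(HelixSpec(20)).coordinates[0]
        sigma = 0.5
        noisy = base[None] + rng.normal(scale=sigma, size=(200, 20, 3))
        from gactdyn.model import FrameSeries
        top = make_ideal_helix(HelixSpec(20)).topology
        frames = FrameSeries(top, noisy, np.arange(200) * 0.1)
        sel = Selection(list(range(20)))
        series = rmsd_series(frames, base, sel)
        # independent oracle: RMSD without superposition bounds the fitted one,
        # and for isotropic noise the two agree closely for n >> 6
        direct = np.sqrt(np.mean(np.sum((noisy - base) ** 2, axis=2), axis=1))
        assert np.all(series <= direct + 1e-12)
        assert abs(series.mean() - direct.mean()) < 0.1

    def test_static_trajectory_rmsf_zero(self):
        helix = make_ideal_helix(HelixSpec(8))
        coords = np.repeat(helix.coordinates, 5, axis=0)
        from gactdyn.model import FrameSeries
        frames = FrameSeries(helix.topology, coords, np.arange(5) * 0.1)
        sel = Selection(list(range(8)))
        prof = rmsf(frames, sel)
        assert all(v < 1e-12 for v in prof.rmsf.values())

    def test_isotropic_jitter_rmsf_sigma_sqrt3(self):
        rng = np.random.default_rng(5)
        base = make_ideal_helix(HelixSpec(30)).coordinates[0]
        sigma = 0.5
        coords = base[None] + rng.normal(scale=sigma, size=(400, 30, 3))
        from gactdyn.model import FrameSeries
        top = make_ideal_helix(HelixSpec(30)).topology
        frames = FrameSeries(top, coords, np.arange(400) * 0.1)
        sel = Selection(list(range(30)))
        prof = rmsf(frames, sel)
        mean_rmsf = np.mean(list(prof.rmsf.values()))
        assert abs(mean_rmsf - sigma * np.sqrt(3)) < 0.08

    def test_single_frame_rejected(self):
        helix = make_ideal_helix(HelixSpec(8))
        with pytest.raises(InsufficientFramesError):
            rmsf(helix, Selection(list(range(8))))


class TestDihedral:
    @pytest.mark.parametrize("points,expected", [
        # planar trans zigzag
        (((0, 0, 0), (1, 0, 0), (2, 1, 0), (3, 1, 0)), 180.0),
        # planar cis
        (((0, 1, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0)), 0.0),
        # right-angle staircase, hand-checked (standard convention, +90)
        (((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)), 90.0),
    ])
    def test_reference_geometries(self, points, expected):
        assert abs(dihedral(*points) - expected) < 1e-9

    def test_brute_force_vector_formula(self):
        """1000 random quadruples against an independent arccos+sign oracle."""
        rng = np.random.default_rng(6)
        for _ in range(1000):
            p = rng.normal(size=(4, 3)) * 5
            b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            if min(np.linalg.norm(n1), np.linalg.norm(n2)) < 1e-6:
                continue
            cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
            mag = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            sign = np.sign(np.dot(np.cross(n1, n2), b2)) or 1.0
            expected = sign * mag
            got = dihedral(*p)
            assert abs((got - expected + 180) % 360 - 180) < 1e-6

    def test_mirror_flips_sign(self):
        rng = np.random.default_rng(7)
        p = rng.normal(size=(4, 3))
        mirrored = p * np.array([1, 1, -1])
        assert abs(dihedral(*p) + dihedral(*mirrored)) < 1e-9

    def test_degenerate_raises(self):
        with pytest.raises(UndefinedDihedralError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (2, 0, 0))
        with pytest.raises(UndefinedDihedralError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestCircularStats:
    def test_wraparound_mean(self):
        mean, r = circular_mean([170.0, -170.0])
        assert mean == pytest.approx(180.0)
        assert r == pytest.approx(np.cos(np.deg2rad(10)))

    def test_plain_mean(self):
        assert circular_mean([10.0, 20.0, 30.0])[0] == pytest.approx(20.0)

    def test_zero_resultant_undefined(self):
        with pytest.raises(UndefinedMeanError):
            circular_mean([0.0, 90.0, 180.0, 270.0])

    def test_matches_scipy(self):
        from scipy.stats import circmean
        rng = np.random.default_rng(8)
        a = rng.uniform(-180, 180, size=50)
        ours, _ = circular_mean(a)
        theirs = np.degrees(circmean(np.radians(a), high=np.pi, low=-np.pi))
        assert abs((ours - theirs + 180) % 360 - 180) < 1e-9

    @given(st.floats(-179, 179), st.floats(1, 20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_concentrated_angles_recover_center(self, center, spread):
        angles = np.array([center - spread, center, center + spread])
        mean, _ = circular_mean(angles)
        assert abs((mean - center + 180) % 360 - 180) < 1e-6
        assert circular_sd(angles) >= 0


class TestBackboneDihedralSeries:
    def test_recovers_construction_angles(self):
        phis = [[-57.0] * 6] * 10
        psis = [[-47.0] * 6] * 10
        frames = make_backbone_trajectory(phis, psis)
        ds_phi = backbone_dihedral_series(frames, 3, "phi")
        ds_psi = backbone_dihedral_series(frames, 3, "psi")
        assert abs(ds_phi.circ_mean - (-57.0)) < 2.0
        assert abs(ds_psi.circ_mean - (-47.0)) < 2.0
        assert ds_phi.circ_sd < 1e-6

    def test_half_split_transition_flag(self):
        first = [[-57.0] * 6, [-47.0] * 6]
        second = [[-57.0] * 6, [-107.0] * 6]  # psi shifted by -60 deg
        phis = [first[0]] * 20
        psis = [first[1]] * 10 + [second[1]] * 10
        frames = make_backbone_trajectory(phis, psis)
        ds = backbone_dihedral_series(frames, 3, "psi")
        m1, m2, flag = ds.half_split
        assert flag
        assert abs(m1 - (-47.0)) < 1.0 and abs(m2 - (-107.0)) < 1.0
        # phi untouched: no transition
        assert not backbone_dihedral_series(frames, 3, "phi").half_split[2]

    def test_terminus_raises(self):
        frames = make_backbone_trajectory([[-57.0] * 4] * 2, [[-47.0] * 4] * 2)
        with pytest.raises(MissingAtomError):
            backbone_dihedral_series(frames, 0, "phi")
        with pytest.raises(MissingAtomError):
            backbone_dihedral_series(frames, 3, "psi")


class TestChiSeries:
    def test_gly_has_no_chi1(self):
        frames = make_chi_fixture("TRP", chi1=-90.0)
        frames.topology.residues[0].name = "GLY"
        with pytest.raises(MissingAtomError):
            sidechain_chi_series(frames, 0, "chi1")

    def test_constructed_trp_chi1(self):
        frames = make_chi_fixture("TRP", chi1=-90.0, n_frames=3)
        ds = sidechain_chi_series(frames, 0, "chi1")
        assert abs(ds.circ_mean - (-90.0)) < 0.1
        assert ds.circ_sd < 1e-6

    def test_chi2(self):
        frames = make_chi_fixture("TRP", chi1=-90.0, chi2=113.5)
        ds = sidechain_chi_series(frames, 0, "chi2")
        assert abs(ds.circ_mean - 113.5) < 0.1


class TestHelixAxis:
    def test_rotated_helix_equivariance(self):
        coords = make_ideal_helix(HelixSpec(10)).coordinates[0]
        rng = np.random.default_rng(9)
        R = _random_rotation(rng)
        rotated = coords @ R.T
        axis = fit_helix_axis(rotated)
        np.testing.assert_allclose(axis.direction, R @ [0, 0, 1], atol=1e-9)

    def test_noisy_helix_within_three_degrees(self):
        rng = np.random.default_rng(10)
        worst = 0.0
        for _ in range(20):
            coords = make_ideal_helix(HelixSpec(12)).coordinates[0]
            noisy = coords + rng.normal(scale=0.3, size=coords.shape)
            axis = fit_helix_axis(noisy)
            ang = np.degrees(np.arccos(np.clip(axis.direction[2], -1, 1)))
            worst = max(worst, ang)
        assert worst < 3.0

    def test_too_few_points(self):
        with pytest.raises(DegenerateFitError):
            fit_helix_axis(np.zeros((3, 3)))


class TestProkink:
    def test_straight_helix_unreliable_wobble(self):
        frames = make_kinked_helix(HelixSpec(14), HelixSpec(14), KinkSpec(0, 0, 0, 13))
        ks = prokink_angles(frames, 13, (0, 13), (14, 27))
        assert ks.avg_bend < 1.0
        assert not ks.wobble_reliable.any()

    def test_reference_kink_recovered(self):
        # bend/wobble/face-shift at the magnitudes typical of the TM6
        # proline kink of an aminergic receptor
        frames = make_kinked_helix(HelixSpec(14), HelixSpec(14),
                                   KinkSpec(34.5, -63.1, 89.3, 13))
        ks = prokink_angles(frames, 13, (0, 13), (14, 27))
        assert abs(ks.avg_bend - 34.5) < 1.0
        assert abs(ks.avg_wobble - (-63.1)) < 1.0
        assert abs(ks.avg_face_shift - 89.3) < 1.0
        assert ks.wobble_reliable.all()

    def test_random_kinks_round_trip(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(25):
            bend = rng.uniform(10, 60)
            wobble = rng.uniform(-180, 180)
            face = rng.uniform(-180, 180)
            frames = make_kinked_helix(HelixSpec(12), HelixSpec(12),
                                       KinkSpec(bend, wobble, face, 11))
            ks = prokink_angles(frames, 11, (0, 11), (12, 23))
            worst = max(worst,
                        abs(ks.avg_bend - bend),
                        abs((ks.avg_wobble - wobble + 180) % 360 - 180),
                        abs((ks.avg_face_shift - face + 180) % 360 - 180))
        assert worst < 1.5

    def test_bend_independent_of_wobble_and_face(self):
        for wobble, face in [(-120.0, 30.0), (45.0, -150.0), (0.0, 0.0)]:
            frames = make_kinked_helix(HelixSpec(12), HelixSpec(12),
                                       KinkSpec(25.0, wobble, face, 11))
            ks = prokink_angles(frames, 11, (0, 11), (12, 23))
            assert abs(ks.avg_bend - 25.0) < 0.5

    def test_rigid_invariance(self):
        frames = make_kinked_helix(HelixSpec(12), HelixSpec(12),
                                   KinkSpec(30.0, 50.0, -40.0, 11))
        rng = np.random.default_rng(12)
        Q, t = rigid_transform(rng)
        from gactdyn.model import FrameSeries
        moved = FrameSeries(frames.topology, frames.coordinates @ Q.T + t,
                            frames.times)
        a = prokink_angles(frames, 11, (0, 11), (12, 23))
        b = prokink_angles(moved, 11, (0, 11), (12, 23))
        assert abs(a.avg_bend - b.avg_bend) < 1e-6
        assert abs(a.avg_wobble - b.avg_wobble) < 1e-6
        assert abs(a.avg_face_shift - b.avg_face_shift) < 1e-6

    def test_short_range_rejected(self):
        frames = make_kinked_helix(HelixSpec(12), HelixSpec(12), KinkSpec(30, 0, 0, 11))
        with pytest.raises(DegenerateFitError):
            prokink_angles(frames, 11, (0, 2), (12, 23))
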