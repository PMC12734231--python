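"""Volumes, volume curves with E/A detection, registration, resampling,
averaging and sequence I/O."""

import numpy as np
import pytest

import lvmech.mesh_kinematics as mk
from lvmech.mesh_kinematics import (
    Landmarks,
    MeshSequence,
    QCWarning,
    average_cohort,
    mesh_volume,
    read_mesh_sequence,
    register,
    resample_cycle,
    volume_curve,
    volume_curve_from_samples,
    write_mesh_sequence,
)
from lvmech.synthetic_cohort import VentricleSpec, generate_ventricle_sequence

CUBE_POINTS = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float
)
# outward-oriented 12-triangle unit cube
CUBE_TRIS = np.array(
    [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7], [0, 1, 5], [0, 5, 4],
     [1, 2, 6], [1, 6, 5], [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]]
)


class TestMeshVolume:
    def test_unit_cube_exact(self):
        assert mesh_volume(CUBE_POINTS * 10.0, CUBE_TRIS) == pytest.approx(1.0, abs=1e-12)

    def test_unit_sphere(self, unit_sphere):
        pts, tris = unit_sphere
        v = mesh_volume(pts * 10.0, tris)  # radius 10 mm -> 4pi/3 mL
        assert v == pytest.approx(4 * np.pi / 3, rel=0.005)

    def test_inward_orientation_rejected(self, unit_sphere):
        pts, tris = unit_sphere
        with pytest.raises(ValueError):
            mesh_volume(pts * 10.0, tris[:, ::-1])
        v = mesh_volume(pts * 10.0, tris[:, ::-1], allow_inverted=True)
        assert v < 0


class TestVolumeCurve:
    def test_ef_matches_generator_spec(self):
        spec = VentricleSpec(edv=66, esv=21, hr=174, systolic_fraction=0.5,
                             e_a_ratio=1.5)
        seq, _, _ = generate_ventricle_sequence(spec)
        vc = volume_curve(seq)
        assert 100 * vc.ejection_fraction == pytest.approx(100 * 45 / 66, abs=1.0)

    def test_two_bump_ratio_by_construction(self):
        # direct synthetic dV/dt with peaks 300 and 50 -> ratio 6
        spec = VentricleSpec(e_a_ratio=6.0)
        from lvmech.synthetic_cohort import VolumeWaveform

        w = VolumeWaveform(spec)
        t = np.linspace(0, w.T, 512, endpoint=False)
        vc = volume_curve_from_samples(t, w.volume(t), w.T)
        assert vc.e_a_ratio == pytest.approx(6.0, rel=0.02)
        assert vc.e_peak > vc.a_peak > 0

    def test_merged_waves_flagged(self):
        # single diastolic bump: E and A indistinguishable
        T, edv, esv = 1.0, 90.0, 40.0
        t = np.linspace(0, T, 256, endpoint=False)
        ts = 0.4
        v = np.where(
            t < ts,
            edv - (edv - esv) * (1 - np.cos(np.pi * t / ts)) / 2,
            esv + (edv - esv) * (1 - np.cos(np.pi * (t - ts) / (T - ts))) / 2,
        )
        vc = volume_curve_from_samples(t, v, T)
        assert vc.merged_filling_waves
        assert np.isnan(vc.e_a_ratio)

    def test_no_filling_raises(self):
        t = np.linspace(0, 1, 64, endpoint=False)
        with pytest.raises(ValueError):
            volume_curve_from_samples(t, np.full(64, 50.0), 1.0)

    def test_low_frame_count_warns(self):
        import contextlib

        spec = VentricleSpec(n_frames=10)
        seq, _, _ = generate_ventricle_sequence(spec)
        short = MeshSequence(seq.vertices[:9], seq.triangles,
                             seq.times[:9], seq.period)
        with pytest.warns(QCWarning):
            with contextlib.suppress(ValueError):  # analysis quality not at stake here
                volume_curve(short)

    def test_dvdt_periodic_integral_zero(self, default_sequence):
        seq, _, _ = default_sequence
        vc = volume_curve(seq)
        assert np.trapezoid(vc.dvdt, vc.times) == pytest.approx(0.0, abs=0.5)


class TestRegister:
    def test_idempotent(self, default_sequence):
        seq, lm, _ = default_sequence
        r1, l1 = register(seq, lm)
        _, _, T = register(r1, l1, return_transform=True)
        np.testing.assert_allclose(T, np.eye(4), atol=1e-10)

    def test_recovers_known_rotation(self, default_sequence):
        seq, lm, _ = default_sequence
        r1, _ = register(seq, lm)
        th = 0.9
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        R = R @ np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0.0]])
        shift = np.array([10.0, -4.0, 2.0])
        moved = MeshSequence(seq.vertices @ R.T + shift, seq.triangles,
                             seq.times, seq.period)
        r2, _ = register(moved, lm.transformed(R, shift))
        np.testing.assert_allclose(r2.vertices, r1.vertices, atol=1e-9)

    def test_volume_invariant(self, default_sequence):
        seq, lm, _ = default_sequence
        r1, _ = register(seq, lm)
        v0 = mesh_volume(seq.frame(0), seq.triangles)
        v1 = mesh_volume(r1.frame(0), r1.triangles)
        assert abs(v1 - v0) / v0 < 1e-12

    def test_aortic_center_lands_on_plus_x(self, default_sequence):
        seq, lm, _ = default_sequence
        _, l1 = register(seq, lm)
        i_ed = 0
        assert l1.aortic_center[i_ed, 0] > 0
        assert abs(l1.aortic_center[i_ed, 1]) < 1e-9

    def test_degenerate_axis_rejected(self, default_sequence):
        seq, lm, _ = default_sequence
        bad = Landmarks(lm.annulus_center, lm.aortic_center, lm.annulus_center)
        with pytest.raises(ValueError):
            register(seq, bad)


class TestResampleAndAverage:
    def test_resample_identity(self, default_sequence):
        seq, _, _ = default_sequence
        out = resample_cycle(seq, seq.n_frames)
        np.testing.assert_allclose(out.vertices, seq.vertices, atol=1e-9)

    def test_band_limited_round_trip(self, spheroid_mesh):
        # single-harmonic motion is exactly representable at 16 frames
        verts, tris = spheroid_mesh
        T = 1.0
        times32 = np.linspace(0, T, 32, endpoint=False)
        motion = lambda t: 0.5 * np.sin(2 * np.pi * t / T)
        seq = MeshSequence(
            verts[None] + motion(times32)[:, None, None] * np.array([0, 0, 1.0]),
            tris, times32, T,
        )
        down = resample_cycle(seq, 16)
        back = resample_cycle(down, 32)
        assert np.abs(back.vertices - seq.vertices).max() < 1e-3

    def test_too_few_output_frames_rejected(self, default_sequence):
        seq, _, _ = default_sequence
        with pytest.raises(ValueError):
            resample_cycle(seq, 8)

    def test_average_of_identical_is_identity(self, default_sequence):
        seq, _, _ = default_sequence
        avg = average_cohort([seq, seq])
        np.testing.assert_allclose(avg.vertices, seq.vertices)

    def test_average_cancels_mirror_perturbation(self, default_sequence):
        seq, _, _ = default_sequence
        d = np.zeros_like(seq.vertices)
        d[:, 7, :] = 0.3
        a = MeshSequence(seq.vertices + d, seq.triangles, seq.times, seq.period)
        b = MeshSequence(seq.vertices - d, seq.triangles, seq.times, seq.period)
        avg = average_cohort([a, b])
        np.testing.assert_allclose(avg.vertices, seq.vertices, atol=1e-12)

    def test_mixed_frame_counts_rejected(self, default_sequence):
        seq, _, _ = default_sequence
        short = resample_cycle(seq, 16)
        with pytest.raises(ValueError):
            average_cohort([seq, short])


class TestSequenceIO:
    def test_round_trip_lossless(self, tmp_path, default_sequence):
        seq, lm, _ = default_sequence
        write_mesh_sequence(tmp_path / "seq", seq, lm, extras=seq.metadata)
        back, lm2 = read_mesh_sequence(tmp_path / "seq")
        np.testing.assert_allclose(back.vertices, seq.vertices, atol=1e-12)
        assert np.array_equal(back.triangles, seq.triangles)
        np.testing.assert_allclose(lm2.apex, lm.apex, atol=1e-12)
        assert back.metadata["av_triangles"] == seq.metadata["av_triangles"]

    def test_low_frame_count_flagged_on_read(self, tmp_path):
        spec = VentricleSpec(n_frames=10)
        seq, lm, _ = generate_ventricle_sequence(spec)
        nine = MeshSequence(seq.vertices[:9], seq.triangles,
                            seq.times[:9], seq.period)
        lm9 = Landmarks(lm.annulus_center[:9], lm.aortic_center[:9], lm.apex[:9])
        write_mesh_sequence(tmp_path / "nine", nine, lm9)
        with pytest.warns(QCWarning):
            back, _ = read_mesh_sequence(tmp_path / "nine")
        assert back.metadata["qc_low_frame_count"]

    def test_permuted_topology_rejected(self, tmp_path, default_sequence):
        import trimesh

        seq, lm, _ = default_sequence
        p = write_mesh_sequence(tmp_path / "bad", seq, lm)
        # rewrite one frame with permuted connectivity
        tris = seq.triangles[::-1]
        m = trimesh.Trimesh(seq.frame(3), tris, process=False)
        (p / "frame_0003.ply").write_bytes(m.export(file_type="ply", encoding="ascii"))
        with pytest.raises(ValueError, match="topology"):
            read_mesh_sequence(p)

    def test_missing_sidecar_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_mesh_sequence(tmp_path / "nothing")
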