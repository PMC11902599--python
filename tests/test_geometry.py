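"""Q-matrix structure, homogeneous reprojection and densification."""

import numpy as np
import pytest

import phytosfm as ps
from phytosfm.features import DisparityField


@pytest.fixture
def rig():
    return ps.CameraIntrinsics(f=8.0, ku=1 / 0.00345, kv=1 / 0.00345,
                               u0=720.0, v0=540.0, s=0.02)


class TestBuildQ:
    def test_structure_and_third_row(self, rig):
        Q = ps.build_Q(rig).entries
        assert np.allclose(Q[0], [1, 0, 0, -720])
        assert np.allclose(Q[1], [0, -1, 0, 540])
        assert Q[2, 2] == pytest.approx(0.02 * 8.0 / 0.00345)  # ≈ 46.376
        assert np.allclose(Q[2], [0, 0, Q[2, 2], 0])
        assert np.allclose(Q[3], [0, 0, 0, 1])

    def test_linearity_in_s(self, rig):
        import dataclasses
        Q1 = ps.build_Q(rig).entries
        Q2 = ps.build_Q(dataclasses.replace(rig, s=0.04)).entries
        assert Q2[2, 2] == pytest.approx(2 * Q1[2, 2])

    def test_rejects_nonpositive_intrinsics(self):
        with pytest.raises(ValueError):
            ps.CameraIntrinsics(f=-8.0)
        with pytest.raises(ValueError):
            ps.CameraIntrinsics(s=0.0)


class TestReprojectPoint:
    def test_principal_ray_maps_to_optical_axis(self, rig):
        Q = ps.build_Q(rig)
        x, y, z = ps.reproject_point(720.0, 540.0, 10.0, Q)
        assert (x, y) == (0.0, 0.0)
        assert z == pytest.approx(rig.s * rig.fku / 10.0)

    def test_explicit_matrix_oracle(self, rig):
        # closed form vs explicit 4×4 multiply + dehomogenization
        Q = ps.build_Q(rig)
        rng = np.random.default_rng(0)
        for _ in range(200):
            u, v = rng.uniform(0, 1440), rng.uniform(0, 1080)
            d = rng.uniform(0.1, 100.0)
            hom = Q.entries @ np.array([u, v, 1.0 / d, 1.0])
            assert hom[3] == 1.0  # W̃ forced to 1 by the last row
            expect = ps.dehomogenize(hom)
            got = ps.reproject_point(u, v, d, Q)
            assert np.allclose(got, expect, rtol=1e-12, atol=0)

    def test_worked_offset_sample(self):
        intr = ps.CameraIntrinsics(u0=720, v0=540)
        Q = ps.build_Q(intr)
        x, y, z = ps.reproject_point(820.0, 440.0, 10.0, Q)
        assert (x, y) == (100.0, 100.0)
        assert z == pytest.approx(intr.s * intr.fku / 10.0)

    def test_nonpositive_disparity_rejected(self, rig):
        Q = ps.build_Q(rig)
        with pytest.raises(ValueError):
            ps.reproject_point(0, 0, 0.0, Q)

    def test_depth_strictly_decreasing_in_disparity(self, rig):
        Q = ps.build_Q(rig)
        ds = np.linspace(0.5, 60, 200)
        zs = [ps.reproject_point(10, 10, d, Q)[2] for d in ds]
        assert np.all(np.diff(zs) < 0)


class TestReprojectField:
    def test_elementwise_equality_with_looped_oracle(self, rig):
        Q = ps.build_Q(rig)
        rng = np.random.default_rng(1)
        samples = np.column_stack([rng.uniform(0, 200, 100),
                                   rng.uniform(0, 150, 100),
                                   rng.uniform(1, 50, 100)])
        field = DisparityField(samples)
        img = ps.SignedChannelImage(rng.uniform(-50, 50, (150, 200)), "exg")
        cloud = ps.reproject_field(field, Q, img)
        assert len(cloud) == 100
        for k, (u, v, d) in enumerate(samples):
            assert np.allclose(cloud.points[k], ps.reproject_point(u, v, d, Q))
            assert cloud.intensity[k] == img.pixels[
                min(int(round(v)), 149), min(int(round(u)), 199)]
        assert not cloud.disease.any()

    def test_constant_disparity_gives_single_depth(self, rig):
        Q = ps.build_Q(rig)
        field = DisparityField(np.array([[10.0, 10, 5], [50, 80, 5], [90, 20, 5]]))
        img = ps.SignedChannelImage(np.zeros((100, 100)), "exg")
        cloud = ps.reproject_field(field, Q, img)
        assert np.ptp(cloud.points[:, 2]) == 0

    def test_empty_field_yields_empty_cloud(self, rig):
        cloud = ps.reproject_field(DisparityField(np.empty((0, 3))),
                                   ps.build_Q(rig),
                                   ps.SignedChannelImage(np.zeros((4, 4)), "exg"))
        assert len(cloud) == 0


class TestDensify:
    def _cloud_on_plane(self, Q, coeffs, n=50, seed=0):
        a, b, c = coeffs
        rng = np.random.default_rng(seed)
        u = rng.uniform(0, 99, n)
        v = rng.uniform(0, 79, n)
        z = a * u + b * v + c
        d = Q.entries[2, 2] / z
        return ps.reproject_field(
            DisparityField(np.column_stack([u, v, d])), Q,
            ps.SignedChannelImage(np.zeros((80, 100)), "exg"))

    def test_single_depth_samples_fill_mask_at_that_depth(self, rig):
        Q = ps.build_Q(rig)
        cloud = self._cloud_on_plane(Q, (0, 0, 500.0))
        mask = np.ones((80, 100), bool)
        dense = ps.densify(cloud, mask, Q,
                           ps.SignedChannelImage(np.zeros((80, 100)), "exg"))
        assert np.allclose(dense.points[:, 2], 500.0)

    def test_linear_method_recovers_depth_plane_inside_hull(self, rig):
        Q = ps.build_Q(rig)
        coeffs = (0.8, -0.3, 600.0)
        cloud = self._cloud_on_plane(Q, coeffs, n=200, seed=2)
        mask = np.zeros((80, 100), bool)
        mask[20:60, 20:80] = True      # well inside the sample hull
        dense = ps.densify(cloud, mask, Q,
                           ps.SignedChannelImage(np.zeros((80, 100)), "exg"))
        u, v = dense.source_pixel.T
        expect = coeffs[0] * u + coeffs[1] * v + coeffs[2]
        assert np.allclose(dense.points[:, 2], expect, atol=1e-6)

    def test_one_point_per_masked_pixel(self, rig):
        Q = ps.build_Q(rig)
        cloud = self._cloud_on_plane(Q, (0, 0, 300.0))
        rng = np.random.default_rng(3)
        mask = rng.random((80, 100)) < 0.3
        dense = ps.densify(cloud, mask, Q,
                           ps.SignedChannelImage(np.zeros((80, 100)), "exg"))
        assert len(dense) == int(mask.sum())

    def test_linear_with_too_few_samples_falls_back_to_nearest(self, rig):
        Q = ps.build_Q(rig)
        field = DisparityField(np.array([[5.0, 5, 2], [20, 30, 2]]))
        img = ps.SignedChannelImage(np.zeros((40, 40)), "exg")
        cloud = ps.reproject_field(field, Q, img)
        dense = ps.densify(cloud, np.ones((40, 40), bool), Q, img, method="linear")
        assert len(dense) == 1600
        assert np.allclose(dense.points[:, 2], Q.entries[2, 2] / 2)


class TestPlyWriter:
    def _cloud(self):
        pts = np.array([[1.0, 2.0, 3.0], [-4.0, 5.0, 6.5]])
        return ps.PlantPointCloud(pts, [10.0, -3.0], [True, False],
                                  [[0, 0], [1, 1]])

    def test_ascii_round_trip(self, tmp_path):
        path = tmp_path / "cloud.ply"
        ps.write_ply(path, self._cloud(), binary=False)
        lines = path.read_text().splitlines()
        assert lines[0] == "ply" and "format ascii 1.0" in lines[1]
        assert "element vertex 2" in lines[2]
        body = [l.split() for l in lines[lines.index("end_header") + 1:]]
        assert [float(x) for x in body[0]] == [1.0, 2.0, 3.0, 10.0, 1]
        assert [float(x) for x in body[1]] == [-4.0, 5.0, 6.5, -3.0, 0]

    def test_binary_payload_parses_back(self, tmp_path):
        path = tmp_path / "cloud.ply"
        cloud = self._cloud()
        ps.write_ply(path, cloud, binary=True)
        raw = path.read_bytes()
        header, _, body = raw.partition(b"end_header\n")
        rec = np.frombuffer(body, dtype=[("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
                                         ("i", "<f4"), ("d", "u1")])
        assert np.allclose(rec["z"], cloud.points[:, 2])
        assert list(rec["d"]) == [1, 0]
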