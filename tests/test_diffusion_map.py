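"""k-means tessellation, per-region inference, region meshes and export."""

import json

import numpy as np
import pytest
import trimesh

from smlmtk import (LandscapeRegion, PointCloud, assign_translocations,
                    build_region_meshes, export_map, infer_map,
                    mle_diffusion_drift, partition_kmeans, save_record,
                    simulate_brownian, simulate_landscape)
from smlmtk.cloud_io import build_trajectories


def two_blob_positions(rng, n=200, sep=20.0):
    a = rng.normal(0, 1, (n, 3))
    b = rng.normal(0, 1, (n, 3)) + [sep, 0, 0]
    return np.vstack([a, b])


class TestPartition:
    def test_two_blobs_recovered(self, rng):
        pos = two_blob_positions(rng)
        part = partition_kmeans(pos, k=2, seed=0)
        truth = np.repeat([0, 1], 200)
        agree = max(np.mean(part.labels == truth),
                    np.mean(part.labels == 1 - truth))
        assert agree == 1.0

    def test_k1_center_is_centroid(self, rng):
        pos = rng.normal(0, 1, (50, 3))
        part = partition_kmeans(pos, k=1, seed=0)
        assert np.allclose(part.centers[0], pos.mean(axis=0), atol=1e-9)

    def test_seed_determinism(self, rng):
        pos = rng.uniform(0, 1, (300, 3))
        a = partition_kmeans(pos, k=5, seed=42)
        b = partition_kmeans(pos, k=5, seed=42)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centers, b.centers)

    def test_points_per_region(self, rng):
        pos = rng.uniform(0, 1, (100, 3))
        part = partition_kmeans(pos, points_per_region=25, seed=0)
        assert part.k == 4

    def test_k_bounds(self, rng):
        with pytest.raises(ValueError):
            partition_kmeans(rng.uniform(size=(5, 3)), k=6)


class TestAssign:
    def test_trajectory_inside_one_region(self, rng):
        pos = two_blob_positions(rng)
        part = partition_kmeans(pos, k=2, seed=0)
        ts = simulate_brownian(1, 20, D=0.01, seed=1)  # stays near origin
        per = assign_translocations(ts, part)
        origin_region = int(part.assign(np.zeros((1, 3)))[0])
        assert len(per[origin_region][0]) == 20
        assert len(per[1 - origin_region][0]) == 0

    def test_step_assigned_to_start_region(self):
        centers_cloud = np.array([[0.0, 0, 0], [10.0, 0, 0],
                                  [0.1, 0, 0], [9.9, 0, 0]])
        part = partition_kmeans(centers_cloud, k=2, seed=0)
        from smlmtk import Trajectory, TrajectorySet
        tr = Trajectory(0.0, np.array([[0.0, 0, 0], [10.0, 0, 0]]),
                        np.array([0.0, 1.0]))
        per = assign_translocations(TrajectorySet([tr]), part)
        start_region = int(part.assign(np.zeros((1, 3)))[0])
        assert len(per[start_region][0]) == 1

    def test_matches_bruteforce_lookup(self, rng):
        ts = simulate_brownian(10, 30, D=0.5, seed=2)
        cloud = ts.to_cloud()
        part = partition_kmeans(cloud.positions, k=6, seed=3)
        per = assign_translocations(ts, part)
        expected = {r: 0 for r in range(6)}
        for tr in ts:
            for p in tr.positions[:-1]:
                d = np.linalg.norm(part.centers - p, axis=1)
                expected[int(np.argmin(d))] += 1
        assert {r: len(per[r][0]) for r in per} == expected


class TestInferMap:
    def test_single_region_equals_pooled_mle(self):
        ts = simulate_brownian(10, 50, D=0.5, seed=4)
        cloud = ts.to_cloud()
        part = partition_kmeans(cloud.positions, k=1, seed=0)
        dmap = infer_map(cloud, ts, part)
        dr, dt = ts.pooled_translocations()
        ref = mle_diffusion_drift(dr, dt)
        est = dmap.estimates[0]
        assert est.D == pytest.approx(ref.D, rel=1e-12)
        assert np.allclose(est.v, ref.v)
        assert est.status == "ok"
        # colour-mapping columns appended
        assert np.all(cloud.columns["region"] == 0)
        assert np.allclose(cloud.columns["D_local"], ref.D)

    def test_insufficient_data_flagged_not_fatal(self, rng):
        ts = simulate_brownian(1, 3, D=0.5, seed=5)
        cloud = PointCloud(np.vstack([ts[0].positions,
                                      rng.normal(50, 1, (30, 3))]))
        part = partition_kmeans(cloud.positions, k=2, seed=0)
        dmap = infer_map(cloud, ts, part, min_translocations=20)
        flagged = [e for e in dmap.estimates if e.status == "insufficient_data"]
        assert len(flagged) == 2  # 3 translocations in one, none in the other
        assert all(e.D is None for e in flagged)

    def test_two_region_landscape_recovery(self):
        # boxes much wider than the diffusion length and many short
        # trajectories keep the k-means boundary near the true interface
        regions = [
            LandscapeRegion(((0, 0, 0), (10, 10, 10)), D=0.1),
            LandscapeRegion(((10, 0, 0), (20, 10, 10)), D=1.0),
        ]
        ts, _ = simulate_landscape(regions, 1000, 10, dt=0.01, seed=6)
        cloud = ts.to_cloud()
        part = partition_kmeans(cloud.positions, k=2, seed=0)
        dmap = infer_map(cloud, ts, part)
        assert all(e.n_translocations >= 2000 for e in dmap.estimates)
        low = int(part.assign(np.array([[5.0, 5.0, 5.0]]))[0])
        d_low = dmap.estimates[low].D
        d_high = dmap.estimates[1 - low].D
        assert d_low == pytest.approx(0.1, rel=0.15)
        assert d_high == pytest.approx(1.0, rel=0.15)

    def test_map_record_deterministic(self, tmp_path):
        ts = simulate_brownian(5, 40, D=0.5, seed=7)
        paths = []
        for run in (0, 1):
            cloud = ts.to_cloud()
            part = partition_kmeans(cloud.positions, k=3, seed=1)
            dmap = infer_map(cloud, ts, part)
            p = tmp_path / f"map{run}.json"
            save_record(dmap.to_record(), p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_bootstrap_se_decreases_with_data(self, rng):
        ts = simulate_brownian(40, 100, D=0.5, dt=0.03, seed=8)
        dr, dt = ts.pooled_translocations()

        def boot_se(m):
            ds = []
            for _ in range(30):
                idx = rng.integers(0, m, m)
                ds.append(mle_diffusion_drift(dr[idx], dt[idx]).D)
            return np.std(ds)

        assert boot_se(4000) < boot_se(200)

    def test_harmonic_well_drift_points_inward(self):
        kT, stiffness = 1.0, 5.0
        box = ((-1.5, -1.5, -1.5), (1.5, 1.5, 1.5))
        regions = [LandscapeRegion(box, D=0.5, well_center=[0.0, 0, 0],
                                   stiffness=stiffness)]
        ts, _ = simulate_landscape(regions, 40, 300, dt=0.01, kT=kT, seed=9)
        cloud = ts.to_cloud()
        part = partition_kmeans(cloud.positions, k=8, seed=2)
        dmap = infer_map(cloud, ts, part)
        inward = 0
        total = 0
        for e in dmap.estimates:
            if e.status != "ok":
                continue
            center = part.centers[e.region]
            radial = np.dot(e.v, center / max(np.linalg.norm(center), 1e-12))
            total += 1
            inward += radial < 0
        assert total >= 6
        assert inward / total >= 0.9


class TestMeshes:
    def _partition_of(self, labels, positions):
        from smlmtk import RegionPartition
        k = int(labels.max()) + 1
        centers = np.array([positions[labels == i].mean(axis=0)
                            for i in range(k)])
        return RegionPartition(k, labels, centers, seed=0)

    def test_tetrahedron_hull(self):
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        cloud = PointCloud(pos)
        part = self._partition_of(np.zeros(4, dtype=int), pos)
        meshes = build_region_meshes(cloud, part, [1.0])
        assert len(meshes[0].vertices) == 4
        assert len(meshes[0].faces) == 4

    def test_unit_cube_volume(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                            for z in (0, 1)], dtype=float)
        cloud = PointCloud(corners)
        part = self._partition_of(np.zeros(8, dtype=int), corners)
        meshes = build_region_meshes(cloud, part, [1.0])
        assert meshes[0].volume == pytest.approx(1.0, abs=1e-9)

    def test_colormap_endpoints(self, rng):
        pos = np.vstack([rng.normal(0, 1, (10, 3)),
                         rng.normal(10, 1, (10, 3)),
                         rng.normal(20, 1, (10, 3))])
        labels = np.repeat([0, 1, 2], 10)
        part = self._partition_of(labels, pos)
        meshes = build_region_meshes(PointCloud(pos), part,
                                     [0.1, 0.5, 1.0], colormap="viridis")
        from matplotlib import colormaps
        lo = tuple(int(round(c * 255)) for c in colormaps["viridis"](0.0)[:3])
        hi = tuple(int(round(c * 255)) for c in colormaps["viridis"](1.0)[:3])
        assert meshes[0].rgba[:3] == lo
        assert meshes[2].rgba[:3] == hi

    def test_degenerate_regions_skipped(self, rng):
        pos = np.vstack([rng.normal(0, 1, (10, 3)),
                         np.column_stack([np.arange(5.0), np.zeros(5),
                                          np.zeros(5)])])  # collinear
        labels = np.repeat([0, 1], [10, 5])
        part = self._partition_of(labels, pos)
        with pytest.warns(UserWarning):
            meshes = build_region_meshes(PointCloud(pos), part, [1.0, 2.0])
        assert len(meshes) == 1

    def test_all_degenerate_raises(self):
        pos = np.zeros((4, 3))
        pos[:, 0] = np.arange(4.0)
        part = self._partition_of(np.zeros(4, dtype=int), pos)
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            build_region_meshes(PointCloud(pos), part, [1.0])


class TestExport:
    def _two_tetra_meshes(self):
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                        [5.0, 0, 0], [6, 0, 0], [5, 1, 0], [5, 0, 1]])
        labels = np.repeat([0, 1], 4)
        from smlmtk import RegionPartition
        centers = np.array([pos[:4].mean(axis=0), pos[4:].mean(axis=0)])
        part = RegionPartition(2, labels, centers, seed=0)
        return build_region_meshes(PointCloud(pos), part, [0.2, 0.9],
                                   transparency=0.5)

    def test_ply_counts_and_colors_roundtrip(self, tmp_path):
        meshes = self._two_tetra_meshes()
        path = tmp_path / "map.ply"
        export_map(meshes, path)
        mesh = trimesh.load(path, process=False)  # independent parser
        assert len(mesh.vertices) == 8
        assert len(mesh.faces) == 8
        colors = np.asarray(mesh.visual.vertex_colors)
        expected = np.repeat([meshes[0].rgba, meshes[1].rgba], 4, axis=0)
        assert np.array_equal(colors, expected)  # RGBA byte-exact

    def test_obj_groups(self, tmp_path):
        meshes = self._two_tetra_meshes()
        path = tmp_path / "map.obj"
        export_map(meshes, path)
        text = path.read_text()
        assert "g region_0" in text and "g region_1" in text
        scene = trimesh.load(path, process=False, group_material=False)
        tm = scene.to_geometry() if hasattr(scene, "to_geometry") else scene
        assert len(tm.vertices) == 8
        assert len(tm.faces) == 8

    def test_empty_raises(self, tmp_path):
        with pytest.raises(ValueError):
            export_map([], tmp_path / "x.ply")
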