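"""Skeletonization, distances and per-spine geometry on the physical grid."""

from __future__ import annotations

import numpy as np
import pytest

import spinemorph as sm

from conftest import SPACING, label_map

DEND, SOMA, HEAD, NECK = 1, 2, 3, 4


def tube_scene(path_pts, radius=0.3, shape=(32, 64, 200), soma=None):
    spec = sm.SceneSpec(
        shape=shape, spacing=SPACING,
        dendrite_path_um=np.asarray(path_pts, dtype=float),
        dendrite_radius_um=radius, soma_center_um=soma, spines=[],
    )
    return sm.generate_scene(spec)[1]


class TestSkeleton:
    def test_straight_cylinder_length_within_5_percent(self):
        m = tube_scene([[2.4, 2.08, 1.5], [2.4, 2.08, 11.5]])
        tree = sm.skeletonize_dendrite(m)
        assert sm.dendrite_length(tree) == pytest.approx(10.0, rel=0.05)

    def test_single_voxel_gives_single_node_zero_length(self):
        labels = np.zeros((5, 5, 5), dtype=np.uint8)
        labels[2, 2, 2] = DEND
        tree = sm.skeletonize_dendrite(label_map(labels))
        assert tree.n_nodes == 1
        assert sm.dendrite_length(tree) == 0.0

    def test_l_shaped_tube_length_within_7_percent(self):
        # two 5 um arms meeting at a right angle
        m = tube_scene(
            [[2.4, 1.3, 1.3], [2.4, 1.3, 6.3], [2.4, 6.3, 6.3]],
            shape=(32, 128, 128),
        )
        tree = sm.skeletonize_dendrite(m)
        assert sm.dendrite_length(tree) == pytest.approx(10.0, rel=0.07)

    def test_length_invariant_under_translation(self):
        m = tube_scene([[2.4, 2.08, 1.5], [2.4, 2.08, 8.5]])
        shifted = label_map(np.roll(m.labels, (2, 5, 7), axis=(0, 1, 2)))
        l0 = sm.dendrite_length(sm.skeletonize_dendrite(m))
        l1 = sm.dendrite_length(sm.skeletonize_dendrite(shifted))
        assert l1 == pytest.approx(l0, rel=0.02)

    def test_empty_dendrite_raises(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            sm.skeletonize_dendrite(label_map(labels))

    def test_root_placed_at_the_soma_when_present(self, straight_scene):
        spec, _, m, _, _ = straight_scene
        tree = sm.skeletonize_dendrite(m)
        root = tree.coords_um[tree.roots[0]]
        assert np.linalg.norm(root - np.asarray(spec.soma_center_um)) <= spec.soma_radius_um + 0.2


class TestSomaDistances:
    def test_spine_on_soma_surface_has_near_zero_geodesic(self):
        labels = np.zeros((16, 32, 32), dtype=np.uint8)
        labels[8, 16, 10:16] = DEND
        labels[6:11, 13:20, 16:23] = SOMA
        labels[8, 17, 9] = HEAD   # near the far dendrite tip
        labels[8, 17, 15] = HEAD  # beside the dendrite voxel touching the soma
        m = label_map(labels)
        instances = sm.attach_all(sm.extract_spine_instances(m), m)
        near = [s for s in instances if tuple(s.voxels[0]) == (8, 17, 15)][0]
        _, geod = sm.soma_distances(near, m)
        assert geod <= np.linalg.norm(np.asarray(SPACING))  # within one voxel step

    def test_straight_dendrite_geodesic_close_to_euclidean(self, analysed_scene):
        *_, records, _ = analysed_scene
        for r in records:
            if r.soma_distance_geodesic_um is None or r.soma_distance_euclid_um < 1.0:
                continue
            assert r.soma_distance_geodesic_um <= 1.10 * r.soma_distance_euclid_um

    def test_geodesic_at_least_euclidean_minus_voxel_diagonal(self, analysed_scene):
        *_, records, _ = analysed_scene
        diag = float(np.linalg.norm(SPACING))
        for r in records:
            if r.soma_distance_geodesic_um is not None:
                assert r.soma_distance_geodesic_um >= r.soma_distance_euclid_um - diag

    def test_u_shaped_dendrite_geodesic_exceeds_euclidean(self):
        v, m, _, gt = sm.generate_scene(sm.u_shaped_scene_spec())
        instances = sm.attach_all(sm.extract_spine_instances(m), m)
        records = sm.measure_spines(instances, m, v)
        r = records[0]
        assert r.soma_distance_geodesic_um > 1.5 * r.soma_distance_euclid_um
        assert r.soma_distance_geodesic_um == pytest.approx(
            gt.geodesic_soma_distance_um[0], rel=0.10
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_graph_shortest_path_oracle_on_small_grids(self, seed):
        # independent oracle: dijkstra over an explicit 26-neighbour graph
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import dijkstra

        rng = np.random.default_rng(seed)
        labels = np.zeros((6, 10, 10), dtype=np.uint8)
        labels[2:4, :, :] = np.where(rng.random((2, 10, 10)) < 0.6, DEND, 0)
        labels[2:4, 4:7, 4:7] = SOMA
        m = label_map(labels)
        dist_map = sm.soma_distance_map(m)

        fg = np.argwhere(labels > 0)
        idx = {tuple(v): i for i, v in enumerate(fg)}
        rows, cols, w = [], [], []
        for i, v in enumerate(fg):
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if (dz, dy, dx) == (0, 0, 0):
                            continue
                        n = (v[0] + dz, v[1] + dy, v[2] + dx)
                        if n in idx:
                            rows.append(i)
                            cols.append(idx[n])
                            w.append(np.linalg.norm(np.array([dz, dy, dx]) * SPACING))
        graph = coo_matrix((w, (rows, cols)), shape=(len(fg), len(fg)))
        soma_nodes = [idx[tuple(v)] for v in np.argwhere(labels == SOMA)]
        oracle = dijkstra(graph, directed=False, indices=soma_nodes).min(axis=0)
        for i, v in enumerate(fg):
            got = dist_map[tuple(v)]
            if np.isinf(oracle[i]):
                assert np.isinf(got)
            else:
                assert got == pytest.approx(oracle[i], abs=1e-9)

    def test_no_soma_yields_missing_distances(self):
        labels = np.zeros((6, 6, 6), dtype=np.uint8)
        labels[3, 3, 1:5] = DEND
        labels[3, 4, 2] = HEAD
        m = label_map(labels)
        s = sm.attach_all(sm.extract_spine_instances(m), m)[0]
        assert sm.soma_distances(s, m) == (None, None)


class TestSpineGeometry:
    def test_spherical_head_width_within_15_percent_of_diameter(self):
        spec = sm.SceneSpec(
            shape=(48, 64, 64), spacing=SPACING,
            dendrite_path_um=np.array([[3.6, 2.08, 0.5], [3.6, 2.08, 3.7]]),
            dendrite_radius_um=0.3,
            soma_center_um=None,
            spines=[sm.SpinePlacement(position_um=2.0, neck_length_um=0.0,
                                      head_radius_um=0.4, direction=(0, 1, 0))],
        )
        v, m, _, _ = sm.generate_scene(spec)
        s = sm.attach_all(sm.extract_spine_instances(m), m)[0]
        _, _, head_width = sm.spine_geometry(s, SPACING)
        assert head_width == pytest.approx(0.8, rel=0.15)

    def test_single_voxel_spine_length_is_one_lateral_step(self):
        labels = np.zeros((6, 6, 6), dtype=np.uint8)
        labels[3, 3, 3] = HEAD
        labels[3, 3, 4] = DEND
        m = label_map(labels)
        s = sm.attach_all(sm.extract_spine_instances(m), m)[0]
        length, neck, _ = sm.spine_geometry(s, SPACING)
        assert length == pytest.approx(0.065)
        assert neck == 0.0  # no neck voxels

    def test_planted_one_micron_neck_recovered_within_15_percent(self):
        spec = sm.SceneSpec(
            shape=(48, 96, 64), spacing=SPACING,
            dendrite_path_um=np.array([[3.6, 1.3, 0.5], [3.6, 1.3, 3.7]]),
            dendrite_radius_um=0.3,
            soma_center_um=None,
            spines=[sm.SpinePlacement(position_um=2.0, neck_length_um=1.0,
                                      head_radius_um=0.3, direction=(0, 1, 0))],
        )
        v, m, _, gt = sm.generate_scene(spec)
        s = sm.attach_all(sm.extract_spine_instances(m), m)[0]
        length, neck, _ = sm.spine_geometry(s, SPACING)
        assert neck == pytest.approx(gt.neck_length_um[0], rel=0.15)
        assert length > neck

    def test_headless_instance_has_missing_head_width(self):
        labels = np.zeros((6, 6, 10), dtype=np.uint8)
        labels[3, 3, 1:5] = NECK
        labels[3, 3, 5] = DEND
        m = label_map(labels)
        s = sm.attach_all(sm.extract_spine_instances(m), m)[0]
        length, neck, head_width = sm.spine_geometry(s, SPACING)
        assert head_width is None
        assert neck > 0


class TestIntensityAndSummary:
    def test_constant_image_stats(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels[1:3, 1:3, 1:3] = HEAD
        m = label_map(labels)
        v = sm.VolumeImage(np.full((1, 4, 4, 4), 7.0), SPACING)
        s = sm.extract_spine_instances(m)[0]
        stats = sm.intensity_stats(s, v)["ch0"]
        assert stats["mean"] == 7.0 and stats["max"] == 7.0

    def test_integrated_intensity_arithmetic(self):
        # 100 voxels of value 2 at the 65x65x150 nm voxel volume
        labels = np.zeros((4, 10, 10), dtype=np.uint8)
        labels[1, :, :] = HEAD
        m = label_map(labels)
        v = sm.VolumeImage(np.full((1, 4, 10, 10), 2.0), SPACING)
        s = sm.extract_spine_instances(m)[0]
        stats = sm.intensity_stats(s, v)["ch0"]
        assert stats["integrated"] == pytest.approx(200 * 6.3375e-4)

    def test_stats_invariant_to_instance_relabelling(self):
        labels = np.zeros((4, 6, 6), dtype=np.uint8)
        labels[1:3, 1:3, 1:3] = HEAD
        m = label_map(labels)
        rng = np.random.default_rng(0)
        v = sm.VolumeImage(rng.random((1, 4, 6, 6)), SPACING)
        s = sm.extract_spine_instances(m)[0]
        from dataclasses import replace

        assert sm.intensity_stats(s, v) == sm.intensity_stats(
            replace(s, instance_id=99), v
        )

    def test_grid_mismatch_rejected(self):
        labels = np.zeros((4, 6, 6), dtype=np.uint8)
        labels[1, 1, 1] = HEAD
        labels[1, 1, 2] = DEND
        m = label_map(labels)
        v = sm.VolumeImage(np.ones((1, 4, 6, 7)), SPACING)
        instances = sm.attach_all(sm.extract_spine_instances(m), m)
        with pytest.raises(ValueError, match="grid"):
            sm.measure_spines(instances, m, v)

    def test_density_arithmetic(self):
        coords = np.zeros((2, 3))
        coords[1] = (0, 0, 20.0)
        tree = sm.SkeletonTree(coords, np.ones(2), np.array([-1, 0]))
        records = [
            sm.SpineRecord(i, 0.1, None, (0, 0, 0), 1.0, 0.5, None, 0.065)
            for i in range(1, 11)
        ]
        summary = sm.summarize(records, tree, "img")
        assert summary.spine_density_per_um == pytest.approx(0.5)

    def test_empty_records_give_zero_count_missing_means(self):
        coords = np.zeros((2, 3))
        coords[1] = (0, 0, 5.0)
        tree = sm.SkeletonTree(coords, np.ones(2), np.array([-1, 0]))
        summary = sm.summarize([], tree, "img")
        assert summary.spine_count == 0
        assert summary.mean_volume_um3 is None

    def test_zero_length_skeleton_gives_missing_density(self):
        tree = sm.SkeletonTree(np.zeros((1, 3)), np.ones(1), np.array([-1]))
        summary = sm.summarize([], tree, "img")
        assert summary.spine_density_per_um is None

    def test_planted_density_recovered_within_10_percent(self):
        # 20 spines over a soma-free straight dendrite
        spec = sm.straight_scene_spec(
            n_spines=20, shape=(48, 160, 400), with_soma=False, seed=5
        )
        v, m, inst, gt = sm.generate_scene(spec)
        instances = sm.attach_all(sm.extract_spine_instances(m), m)
        kept, _ = sm.filter_spines(instances, sm.FilterSpec(), m.spacing)
        records = sm.measure_spines(kept, m, v)
        tree = sm.skeletonize_dendrite(m)
        summary = sm.summarize(records, tree, "img")
        planted = len(spec.spines) / (400 * 0.065)
        assert summary.spine_density_per_um == pytest.approx(planted, rel=0.10)
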