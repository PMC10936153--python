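"""Connected components vs a flood-fill oracle; overlap and linking."""

from collections import deque

import numpy as np
import pandas as pd
import pytest

from hyphacoloc import presets
from hyphacoloc.objects4d import (
    label_components,
    link_objects,
    mask_green_over_red,
    object_overlap,
)
from hyphacoloc.segmentation import segment_green, segment_red
from hyphacoloc.synthetic_scene import make_scene, render, simulate_timeseries
from hyphacoloc.volume_io import ChannelPairVolume

VS = (0.2, 0.1, 0.1)


def _offsets(connectivity):
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_partition(mask, connectivity):
    """Independent BFS labeling; returns frozenset-of-frozensets partition."""
    offs = _offsets(connectivity)
    seen = np.zeros_like(mask, bool)
    parts = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = []
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.append(v)
            for o in offs:
                n = tuple(a + b for a, b in zip(v, o))
                if any(c < 0 or c >= s for c, s in zip(n, mask.shape)):
                    continue
                if mask[n] and not seen[n]:
                    seen[n] = True
                    queue.append(n)
        parts.append(frozenset(comp))
    return frozenset(parts)


def labels_to_partition(labels):
    parts = {}
    for v in zip(*np.nonzero(labels)):
        parts.setdefault(labels[v], []).append(v)
    return frozenset(frozenset(p) for p in parts.values())


class TestLabeling:
    def test_empty_mask_empty_table(self):
        table = label_components(np.zeros((4, 4, 4), bool), VS)
        assert table.n_objects == 0

    def test_two_blocks(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[0:2, 0:2, 0:2] = True
        mask[5:7, 5:7, 5:7] = True
        table = label_components(mask, VS)
        assert table.n_objects == 2
        assert sorted(table.table["volume_vox"]) == [8, 8]
        assert table.table["volume_um3"].iloc[0] == pytest.approx(8 * 0.002)

    def test_centroid_in_physical_units(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 2, 3] = True
        row = label_components(mask, VS).table.iloc[0]
        assert row["centroid_z_um"] == pytest.approx(1.5 * 0.2)
        assert row["centroid_y_um"] == pytest.approx(2.5 * 0.1)
        assert row["centroid_x_um"] == pytest.approx(3.5 * 0.1)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_flood_fill_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 12, 12)) < 0.25
        table = label_components(mask, VS, connectivity)
        assert labels_to_partition(table.labels) == flood_fill_partition(mask, connectivity)

    def test_component_volumes_sum_to_mask(self):
        rng = np.random.default_rng(9)
        mask = rng.random((16, 16, 16)) < 0.3
        table = label_components(mask, VS)
        assert table.table["volume_vox"].sum() == mask.sum()

    def test_vesicle_count_matches_ground_truth(self):
        scene = make_scene(presets.scene_objects_truth(seed=4))
        pair = render(scene, presets.acq_noiseless())
        green = label_components(segment_green(pair.green).mask, VS)
        # all structures carry both fluorophores here: tube + vesicles
        assert green.n_objects == len(scene.vesicles) + 1
        red = label_components(segment_red(pair.red).mask, VS)
        assert red.n_objects == len(scene.vesicles) + 1


class TestObjectOverlap:
    def test_identical_masks_full_overlap(self):
        rng = np.random.default_rng(1)
        mask = rng.random((8, 8, 8)) < 0.3
        t = label_components(mask, VS)
        tr, tg = object_overlap(t, t, mask, mask)
        assert (tr.table["overlap_fraction"] == 1.0).all()
        assert (tg.table["overlap_fraction"] == 1.0).all()

    def test_disjoint_masks_zero_overlap(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[:2], b[4:] = True, True
        tr, tg = object_overlap(label_components(a, VS), label_components(b, VS), a, b)
        assert (tr.table["overlap_fraction"] == 0.0).all()

    def test_volume_weighted_mean_equals_mask_level_overlap(self):
        rng = np.random.default_rng(5)
        mask_r = rng.random((12, 12, 12)) < 0.3
        mask_g = rng.random((12, 12, 12)) < 0.3
        tr, _ = object_overlap(
            label_components(mask_r, VS), label_components(mask_g, VS), mask_r, mask_g)
        df = tr.table
        weighted = (df["overlap_fraction"] * df["volume_vox"]).sum() / df["volume_vox"].sum()
        assert weighted == pytest.approx((mask_r & mask_g).sum() / mask_r.sum(), abs=1e-12)

    def test_adjacent_segregated_vesicles_low_overlap_close_centroids(self):
        # two touching spheres in different channels: object overlap ~0 while
        # centroid distance < 1 um (the micro-segregation regime)
        mask_r = np.zeros((20, 20, 20), bool)
        mask_g = np.zeros((20, 20, 20), bool)
        z, y, x = np.mgrid[:20, :20, :20]
        mask_r[(z - 10) ** 2 + (y - 10) ** 2 + (x - 7) ** 2 <= 9] = True
        mask_g[(z - 10) ** 2 + (y - 10) ** 2 + (x - 13) ** 2 <= 9] = True
        tr, tg = object_overlap(
            label_components(mask_r, VS), label_components(mask_g, VS), mask_r, mask_g)
        assert tr.table["overlap_fraction"].iloc[0] < 0.05
        dr = tr.table.iloc[0]
        dg = tg.table.iloc[0]
        dist = np.sqrt((dr.centroid_z_um - dg.centroid_z_um) ** 2
                       + (dr.centroid_y_um - dg.centroid_y_um) ** 2
                       + (dr.centroid_x_um - dg.centroid_x_um) ** 2)
        assert dist < 1.0


class TestMaskGreenOverRed:
    def test_all_true_mask_keeps_red(self, standard_pair):
        masked, summary = mask_green_over_red(
            standard_pair, np.ones(standard_pair.red.shape, bool))
        assert np.array_equal(masked.red, standard_pair.red)
        assert summary["retained_red_fraction"] == pytest.approx(1.0)

    def test_empty_mask_zeroes_red(self, standard_pair):
        masked, summary = mask_green_over_red(
            standard_pair, np.zeros(standard_pair.red.shape, bool))
        assert not masked.red.any()
        assert summary["retained_red_fraction"] == 0.0

    def test_half_volume_mask_on_uniform_red(self):
        red = np.ones((4, 4, 4))
        pair = ChannelPairVolume(red, red.copy(), VS)
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True
        _, summary = mask_green_over_red(pair, mask)
        assert summary["retained_red_fraction"] == pytest.approx(0.5)


def _table_from_rows(rows, t):
    df = pd.DataFrame(rows, columns=["label_id", "centroid_z_um",
                                     "centroid_y_um", "centroid_x_um"])
    df["t"] = t
    df["volume_vox"] = 1
    labels = np.zeros((1, 1, 1), int)
    from hyphacoloc.objects4d import ObjectTable
    return ObjectTable(df, labels, VS, t=t)


class TestLinking:
    def test_static_objects_one_track_each(self):
        rows = [(1, 0.5, 0.5, 0.5), (2, 2.0, 2.0, 2.0)]
        tables = [_table_from_rows(rows, t) for t in range(3)]
        linked = link_objects(tables, max_step_um=0.5)
        assert linked["track_id"].nunique() == 2
        for _, sub in linked.groupby("track_id"):
            assert len(sub) == 3

    def test_disappearing_object_ends_track(self):
        t0 = _table_from_rows([(1, 0.5, 0.5, 0.5), (2, 2.0, 2.0, 2.0)], 0)
        t1 = _table_from_rows([(1, 0.5, 0.5, 0.5), (2, 2.0, 2.0, 2.0)], 1)
        t2 = _table_from_rows([(1, 0.5, 0.5, 0.5)], 2)
        linked = link_objects([t0, t1, t2], max_step_um=0.5)
        lengths = linked.groupby("track_id").size().sort_values()
        assert list(lengths) == [2, 3]

    def test_far_jump_not_linked(self):
        t0 = _table_from_rows([(1, 0.5, 0.5, 0.5)], 0)
        t1 = _table_from_rows([(1, 5.0, 5.0, 5.0)], 1)
        linked = link_objects([t0, t1], max_step_um=0.5)
        assert linked["track_id"].nunique() == 2

    def test_simulated_motion_tracked_against_ground_truth(self):
        spec = presets.scene_objects_truth(seed=2)
        pair, scenes = simulate_timeseries(
            spec, presets.acq_noiseless(), 10, motion_sd_um=0.1)
        tables = []
        for t in range(10):
            fr = pair.frame(t)
            mask = segment_green(fr.green)
            tables.append(label_components(mask, spec.voxel_size_um, 26,
                                           fr.red, fr.green, t=t))
        linked = link_objects(tables, max_step_um=0.5)

        def truth_id(row):
            scene = scenes[int(row.t)]
            c = np.array([row.centroid_z_um, row.centroid_y_um, row.centroid_x_um])
            cands = [o for o in scene.objects if o.in_green and o.kind != "cytosol"]
            return min(cands, key=lambda o: np.linalg.norm(c - np.array(o.center_zyx_um))).id

        linked["truth"] = [truth_id(r) for r in linked.itertuples()]
        good = total = 0
        for _, sub in linked.groupby("track_id"):
            tr = sub.sort_values("t")["truth"].to_numpy()
            good += int(np.sum(tr[1:] == tr[:-1]))
            total += len(tr) - 1
        assert total > 0
        assert good / total >= 0.95
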