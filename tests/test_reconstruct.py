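import numpy as np
import pytest

from bundlekit3d import phantoms, reconstruct
from bundlekit3d.stackio import FrameMaskSeries, LabelVolume


def series_from_planes(planes):
    return FrameMaskSeries(masks=[np.asarray(p, dtype=np.int32) for p in planes])


def naive_assign(series, min_overlap=1, max_gap=0):
    """Dict-based re-implementation of the documented linking rule.

    Kept deliberately naive (no claim bookkeeping, recomputes everything per
    frame) so it exercises the same rule through different code.
    """
    tracks = {}  # id -> {"last": mask, "last_frame": f, "entries": [...]}
    next_id = 1
    for pos, (frame, plane) in enumerate(zip(series.frame_index, series.masks)):
        dets = {int(l): plane == l for l in np.unique(plane) if l != 0}
        if pos == 0:
            for lid in sorted(dets):
                tracks[next_id] = {"last": dets[lid], "last_frame": frame, "entries": [(frame, lid)]}
                next_id += 1
            continue
        # each detection's preferred track
        prefs = {}
        for lid in sorted(dets):
            best, best_ov = None, 0
            for tid in sorted(tracks):
                if frame - tracks[tid]["last_frame"] > max_gap + 1:
                    continue
                ov = int((dets[lid] & tracks[tid]["last"]).sum())
                if ov >= min_overlap and ov > best_ov:
                    best, best_ov = tid, ov
            prefs[lid] = (best, best_ov)
        winners = {}
        for lid, (tid, ov) in prefs.items():
            if tid is None:
                continue
            cur = winners.get(tid)
            if cur is None or (ov, int(dets[lid].sum()), -lid) > (cur[1], int(dets[cur[0]].sum()), -cur[0]):
                winners[tid] = (lid, ov)
        taken = {lid for lid, _ in winners.values()}
        for tid, (lid, _) in sorted(winners.items()):
            tracks[tid]["last"] = dets[lid]
            tracks[tid]["last_frame"] = frame
            tracks[tid]["entries"].append((frame, lid))
        for lid in sorted(dets):
            if lid in taken:
                continue
            tracks[next_id] = {"last": dets[lid], "last_frame": frame, "entries": [(frame, lid)]}
            next_id += 1
    return {tid: t["entries"] for tid, t in tracks.items()}


class TestOverlapArea:
    def test_identity_and_disjoint(self):
        a = np.zeros((5, 5), bool)
        a[1:3, 1:6] = True
        assert reconstruct.overlap_area(a, a) == a.sum()
        assert reconstruct.overlap_area(a, np.zeros_like(a)) == 0

    def test_shifted_square(self):
        a = np.zeros((5, 5), bool)
        a[1:4, 1:4] = True
        b = np.roll(a, 1, axis=1)
        assert reconstruct.overlap_area(a, b) == 6

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reconstruct.overlap_area(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestAssignTracks:
    def test_single_object_single_track(self):
        plane = np.zeros((8, 8), dtype=np.int32)
        plane[2:5, 2:5] = 1
        ts = reconstruct.assign_tracks(series_from_planes([plane] * 5))
        assert len(ts.tracks) == 1
        assert len(ts.tracks[0].entries) == 5

    def test_two_disjoint_objects_two_tracks(self):
        plane = np.zeros((8, 8), dtype=np.int32)
        plane[0:2, 0:2] = 1
        plane[5:8, 5:8] = 2
        ts = reconstruct.assign_tracks(series_from_planes([plane, plane, plane]))
        assert sorted(len(t.entries) for t in ts.tracks) == [3, 3]

    def test_contested_track_goes_to_largest_overlap(self):
        # frame 0: one 8x8 block; frame 1: A overlaps 40 px, B overlaps 24 px
        f0 = np.zeros((16, 16), dtype=np.int32)
        f0[4:12, 4:12] = 1
        f1 = np.zeros((16, 16), dtype=np.int32)
        f1[4:9, 4:12] = 5   # A: 40-px overlap
        f1[9:12, 4:12] = 9  # B: 24-px overlap
        ts = reconstruct.assign_tracks(series_from_planes([f0, f1]))
        assert len(ts.tracks) == 2
        assert ts.tracks[0].entries == [(0, 1), (1, 5)]  # A joined the track
        assert ts.tracks[1].entries == [(1, 9)]          # B seeded a new one

    def test_min_overlap_gates_linking(self):
        f0 = np.zeros((8, 8), dtype=np.int32)
        f0[0:2, 0:2] = 1
        f1 = np.zeros((8, 8), dtype=np.int32)
        f1[1:3, 1:3] = 1  # overlap = 1 px
        ts = reconstruct.assign_tracks(series_from_planes([f0, f1]), min_overlap=2)
        assert len(ts.tracks) == 2

    def test_max_gap_bridges_single_frame_dropout(self):
        plane = np.zeros((8, 8), dtype=np.int32)
        plane[2:6, 2:6] = 1
        empty = np.zeros_like(plane)
        ts0 = reconstruct.assign_tracks(series_from_planes([plane, empty, plane]), max_gap=0)
        ts1 = reconstruct.assign_tracks(series_from_planes([plane, empty, plane]), max_gap=1)
        assert len(ts0.tracks) == 2
        assert len(ts1.tracks) == 1

    def test_conservation_of_detections(self, rng):
        planes = (rng.integers(0, 4, size=(6, 12, 12))).astype(np.int32)
        series = series_from_planes(list(planes))
        n_dets = sum(len(np.unique(p)) - (0 in p) for p in planes)
        ts = reconstruct.assign_tracks(series)
        assert sum(len(t.entries) for t in ts.tracks) == n_dets
        # no (frame, local id) assigned twice
        seen = set()
        for t in ts.tracks:
            for entry in t.entries:
                assert entry not in seen
                seen.add(entry)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        planes = []
        for _ in range(3):
            plane = np.zeros((10, 10), dtype=np.int32)
            for lid in range(1, int(rng.integers(1, 5)) + 1):
                y, x = rng.integers(0, 7, 2)
                h, w = rng.integers(1, 4, 2)
                patch = plane[y : y + h, x : x + w]
                patch[patch == 0] = lid
            planes.append(plane)
        series = series_from_planes(planes)
        ts = reconstruct.assign_tracks(series)
        got = {t.track_id: t.entries for t in ts.tracks}
        expected = naive_assign(series)
        assert sorted(got.values()) == sorted(expected.values())


class TestLabelVolumeConstruction:
    def test_single_track_paints_all_planes(self):
        plane = np.zeros((6, 6), dtype=np.int32)
        plane[1:3, 1:6] = 4
        series = series_from_planes([plane] * 5)
        ts = reconstruct.assign_tracks(series)
        vol = reconstruct.tracks_to_label_volume(ts, series, (5, 6, 6))
        assert vol.id_set == [1]
        assert int((vol.labels == 1).sum()) == 50

    def test_empty_series_gives_empty_volume(self):
        series = series_from_planes([np.zeros((4, 4), dtype=np.int32)])
        ts = reconstruct.assign_tracks(series)
        vol = reconstruct.tracks_to_label_volume(ts, series, (1, 4, 4))
        assert vol.id_set == []

    def test_noise_free_phantom_roundtrip_iou_one(self, small_phantom):
        from bundlekit3d import evaluate

        _, labels, truth = small_phantom
        series = phantoms.degrade_to_frame_masks(labels, 0.0, 0.0, seed=5)
        vol = reconstruct.reconstruct_volume(series, labels.shape)
        result = evaluate.match_instances(truth.labels, vol, iou_threshold=1.0)
        assert result.fp == result.fn == 0
        assert all(iou == 1.0 for _, _, iou in result.pairs)


class TestFilterComponents:
    def test_zero_thresholds_identity(self, small_phantom):
        _, labels, _ = small_phantom
        out = reconstruct.filter_components(labels, 0, 0)
        np.testing.assert_array_equal(out.labels, labels.labels)

    def test_speck_removed(self):
        labels = np.zeros((4, 8, 8), dtype=np.int64)
        labels[1, 1, 1:4] = 1  # 3 voxels, 1 plane
        labels[0:3, 5:8, 5:8] = 2
        out = reconstruct.filter_components(LabelVolume(labels), min_frames=2, min_voxels=10)
        assert out.id_set == [2]

    def test_depth_threshold_matches_phantom_truth(self):
        from bundlekit3d.phantoms import BundleSpec, PhantomConfig, generate_stack

        cfg = PhantomConfig(
            shape=(14, 128, 128),
            bundles=[
                BundleSpec(peak_y=30, peak_x=36, wing_length_px=25, z_start=2, depth=5),
                BundleSpec(peak_y=30, peak_x=92, wing_length_px=25, z_start=2, depth=10),
            ],
        )
        _, labels, _ = generate_stack(cfg)
        out = reconstruct.filter_components(labels, min_frames=6, min_voxels=0)
        assert out.id_set == [2]
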