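"""3D bundle instances from per-frame 2D masks by overlap tracking.

Per-frame detections (frame-local label images) are linked plane-to-plane by
pixel overlap: each detection joins the active track whose most recent mask
it overlaps the most, or seeds a new track.  Completed tracks become the
instance IDs of the output label volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stackio import FrameMaskSeries, LabelVolume

__all__ = [
    "Track",
    "TrackSet",
    "overlap_area",
    "assign_tracks",
    "tracks_to_label_volume",
    "filter_components",
]


@dataclass
class Track:
    """One growing 3D instance: (frame, frame-local id) entries plus the most
    recent 2D support used for overlap comparison."""

    track_id: int
    entries: list[tuple[int, int]] = field(default_factory=list)
    last_mask: np.ndarray | None = None
    last_frame: int = -1

    def add(self, frame: int, local_id: int, mask: np.ndarray) -> None:
        if self.entries and frame <= self.entries[-1][0]:
            raise ValueError(f"track {self.track_id}: frame {frame} not after {self.entries[-1][0]}")
        self.entries.append((frame, local_id))
        self.last_mask = mask
        self.last_frame = frame


@dataclass
class TrackSet:
    tracks: list[Track] = field(default_factory=list)
    frame_count: int = 0

    def new_track(self, frame: int, local_id: int, mask: np.ndarray) -> Track:
        t = Track(track_id=len(self.tracks) + 1)
        t.add(frame, local_id, mask)
        self.tracks.append(t)
        return t


def overlap_area(mask_a: np.ndarray, mask_b: np.ndarray) -> int:
    """Pixel count of the intersection of two binary supports."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    return int(np.count_nonzero(mask_a & mask_b))


def assign_tracks(series: FrameMaskSeries, min_overlap: int = 1, max_gap: int = 0) -> TrackSet:
    """Greedy overlap tracking across the frame series.

    Every detection in the first frame seeds a track.  In each later frame a
    detection is compared against each eligible track's last mask and joins
    the track with the largest overlap, provided the overlap reaches
    ``min_overlap`` pixels; otherwise it seeds a new track.  When several
    detections claim the same track, the largest-overlap detection wins and
    the losers seed new tracks.  A track stays eligible while the current
    frame is at most ``max_gap + 1`` frames past its last entry, so the
    default ``max_gap=0`` links z-contiguous supports only.

    Ties are deterministic: a detection preferring two tracks equally takes
    the lower track id; two detections tied on a track are ordered by larger
    detection area, then lower frame-local id.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1 pixel")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")

    tracks = TrackSet()
    for pos, (frame, plane) in enumerate(zip(series.frame_index, series.masks)):
        detections = [
            (int(lid), plane == lid) for lid in np.unique(plane) if lid != 0
        ]
        if pos == 0:
            for lid, mask in detections:
                tracks.new_track(frame, lid, mask)
            tracks.frame_count += 1
            continue

        eligible = [t for t in tracks.tracks if frame - t.last_frame <= max_gap + 1]
        # best candidate track per detection
        claims: dict[int, list[tuple[int, int, int, np.ndarray]]] = {}
        unmatched: list[tuple[int, np.ndarray]] = []
        for lid, mask in detections:
            best_track, best_ov = None, 0
            for t in eligible:
                ov = overlap_area(mask, t.last_mask)
                if ov >= min_overlap and (ov > best_ov or (ov == best_ov and best_track is not None and t.track_id < best_track)):
                    best_track, best_ov = t.track_id, ov
            if best_track is None:
                unmatched.append((lid, mask))
            else:
                claims.setdefault(best_track, []).append(
                    (best_ov, int(mask.sum()), lid, mask)
                )

        by_id = {t.track_id: t for t in tracks.tracks}
        for track_id, claimants in claims.items():
            claimants.sort(key=lambda c: (-c[0], -c[1], c[2]))
            _, _, win_lid, win_mask = claimants[0]
            by_id[track_id].add(frame, win_lid, win_mask)
            for _, _, lid, mask in claimants[1:]:
                unmatched.append((lid, mask))
        unmatched.sort(key=lambda c: c[0])
        for lid, mask in unmatched:
            tracks.new_track(frame, lid, mask)
        tracks.frame_count += 1
    return tracks


def tracks_to_label_volume(tracks: TrackSet, series: FrameMaskSeries, shape: tuple[int, int, int]) -> LabelVolume:
    """Paint every track entry into a (z, y, x) label grid.

    IDs follow track creation order.  Valid input guarantees each (frame,
    frame-local id) belongs to one track, so no voxel is claimed twice.
    """
    labels = np.zeros(shape, dtype=np.int64)
    frame_to_plane = {f: m for f, m in zip(series.frame_index, series.masks)}
    for t in tracks.tracks:
        for frame, lid in t.entries:
            if frame >= shape[0]:
                raise ValueError(f"track {t.track_id} entry at frame {frame} exceeds depth {shape[0]}")
            mask = frame_to_plane[frame] == lid
            claimed = labels[frame][mask]
            if np.any(claimed != 0):
                raise AssertionError(
                    f"voxel claimed by tracks {int(claimed[claimed != 0][0])} and {t.track_id}"
                )
            labels[frame][mask] = t.track_id
    return LabelVolume(labels=labels)


def reconstruct_volume(
    series: FrameMaskSeries,
    shape: tuple[int, int, int],
    min_overlap: int = 1,
    max_gap: int = 0,
    min_frames: int = 0,
    min_voxels: int = 0,
) -> LabelVolume:
    """Convenience: assign_tracks → label volume → component filter."""
    tracks = assign_tracks(series, min_overlap=min_overlap, max_gap=max_gap)
    vol = tracks_to_label_volume(tracks, series, shape)
    if min_frames or min_voxels:
        vol = filter_components(vol, min_frames=min_frames, min_voxels=min_voxels)
    return vol


def filter_components(vol: LabelVolume, min_frames: int = 2, min_voxels: int = 20) -> LabelVolume:
    """Remove instances spanning fewer than ``min_frames`` z-planes or fewer
    than ``min_voxels`` voxels; survivors keep their IDs."""
    if min_frames < 0 or min_voxels < 0:
        raise ValueError("thresholds must be >= 0")
    labels = vol.labels.copy()
    for bundle_id in vol.id_set:
        occ = labels == bundle_id
        n_vox = int(occ.sum())
        n_planes = int(occ.any(axis=(1, 2)).sum())
        if n_planes < min_frames or n_vox < min_voxels:
            labels[occ] = 0
    return LabelVolume(labels=labels)
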