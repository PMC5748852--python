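"""Linkage of tracked centroids to segmented voxel data and MFI traces.

Tracking and segmentation may come from different algorithms that assign
different identifiers to the same physical cell.  Because both describe a
cell by its centre of mass, each tracked position is assigned the closest
segmented object carrying voxel information, within a maximum range of
5 µm.  The volumetric mean fluorescence intensity (MFI) of a cell is the
sum of all member-voxel intensities divided by the number of voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .traces import CellTrace
from .volumes import CentroidTrack, SegmentedObject

logger = logging.getLogger(__name__)

__all__ = ["LinkRecord", "object_mfi", "link_tracks_to_objects", "assemble_traces"]

DEFAULT_MAX_RANGE_UM = 5.0


@dataclass(frozen=True)
class LinkRecord:
    """One tracked-position -> segmented-object assignment."""

    track_id: int
    frame_index: int
    object_id: int
    distance_um: float


def object_mfi(obj: SegmentedObject) -> float:
    """Volumetric MFI of a segmented object: intensity sum / voxel count."""
    if obj.voxel_count <= 0:
        raise ValueError(
            f"object {obj.object_id} in frame {obj.frame_index} has no voxels; "
            "MFI is undefined"
        )
    return obj.intensity_sum / obj.voxel_count


def link_tracks_to_objects(
    tracks: Sequence[CentroidTrack],
    objects_by_frame: Mapping[int, Sequence[SegmentedObject]],
    max_range_um: float = DEFAULT_MAX_RANGE_UM,
) -> list[LinkRecord]:
    """Assign to each tracked position the nearest segmented object.

    Per track and frame, the Euclidean-nearest object within
    ``max_range_um`` is linked; positions with no object in range stay
    unlinked.  Distance ties are broken by the lowest ``object_id``.
    Tracks and objects must share frame indexing and micrometre
    coordinates.
    """
    links: list[LinkRecord] = []
    for track in tracks:
        for frame, centroid in zip(track.frame_indices, track.centroids):
            objs = objects_by_frame.get(frame, [])
            if not objs:
                continue
            centers = np.array([o.centroid_um for o in objs])
            dists = np.linalg.norm(centers - np.asarray(centroid), axis=1)
            best = min(
                range(len(objs)), key=lambda k: (dists[k], objs[k].object_id)
            )
            if dists[best] <= max_range_um:
                links.append(
                    LinkRecord(
                        track_id=track.track_id,
                        frame_index=frame,
                        object_id=objs[best].object_id,
                        distance_um=float(dists[best]),
                    )
                )
    return links


def _longest_consecutive_run(frames: np.ndarray) -> tuple[int, int]:
    """Bounds (inclusive positions) of the longest run of consecutive values;
    earliest run wins ties."""
    best = (0, 0)
    start = 0
    for i in range(1, len(frames)):
        if frames[i] != frames[i - 1] + 1:
            if (i - 1) - start > best[1] - best[0]:
                best = (start, i - 1)
            start = i
    if (len(frames) - 1) - start > best[1] - best[0]:
        best = (start, len(frames) - 1)
    return best


def assemble_traces(
    links: Sequence[LinkRecord],
    objects_by_frame: Mapping[int, Sequence[SegmentedObject]],
    frame_interval_min: float = 15.0,
    annotations: Optional[Mapping[int, Mapping]] = None,
) -> list[CellTrace]:
    """Build one MFI trace per track from its object links.

    Each trace is restricted to the track's longest run of consecutively
    linked frames (gaps are not stitched, keeping downstream
    consecutive-frame filters meaningful).  ``annotations`` optionally maps
    ``track_id`` to ``cell_id``/``subset``/``side``/``mitosis_frame``.
    Tracks with zero links are dropped; the count is logged.
    """
    by_object = {
        (o.frame_index, o.object_id): o
        for objs in objects_by_frame.values()
        for o in objs
    }
    by_track: dict[int, list[LinkRecord]] = {}
    for link in links:
        by_track.setdefault(link.track_id, []).append(link)
    annotations = annotations or {}
    traces: list[CellTrace] = []
    n_dropped = 0
    for track_id in sorted(by_track):
        recs = sorted(by_track[track_id], key=lambda r: r.frame_index)
        frames = np.array([r.frame_index for r in recs])
        lo, hi = _longest_consecutive_run(frames)
        recs = recs[lo : hi + 1]
        if not recs:
            n_dropped += 1
            continue
        mfi = np.array(
            [object_mfi(by_object[(r.frame_index, r.object_id)]) for r in recs]
        )
        ann = dict(annotations.get(track_id, {}))
        traces.append(
            CellTrace(
                cell_id=str(ann.get("cell_id", f"track{track_id:04d}")),
                frames=frames[lo : hi + 1],
                mfi=mfi,
                frame_interval_min=frame_interval_min,
                subset=ann.get("subset"),
                side=ann.get("side"),
                mitosis_frame=ann.get("mitosis_frame"),
            )
        )
    if n_dropped:
        logger.info("dropped %d tracks with zero object links", n_dropped)
    return traces
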