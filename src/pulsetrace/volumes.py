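"""Volume I/O, stand-in 3-D segmentation and centroid tracking.

The original analysis used two proprietary tools — an object analyzer for
segmentation/voxel statistics and an object tracker for following cells —
whose algorithms are not published.  This module provides conventional,
fully specified stand-ins: 26-connected thresholding with intensity-weighted
centres of mass, and greedy mutual-nearest-neighbour linking of centroids
between consecutive frames (no gap closing, so downstream "at least N
consecutive frames" filters stay meaningful).  Deconvolution and drift
stabilisation are assumed already applied; :func:`stabilize_series` is a
no-op hook kept for pipeline symmetry.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from scipy import ndimage
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeFrame",
    "SegmentedObject",
    "CentroidTrack",
    "read_volume_series",
    "write_volume_series",
    "stabilize_series",
    "segment_frame",
    "track_centroids",
]

SIDECAR_NAME = "series.json"
SIDECAR_REQUIRED = ("voxel_size_um", "frame_interval_min")


@dataclass
class VolumeFrame:
    """One 3-D intensity volume; axes (z, y, x), voxel sizes (x, y, z) µm."""

    intensity: np.ndarray
    voxel_size_um: tuple[float, float, float]
    frame_index: int  # 1-based
    time_h: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3 or min(self.intensity.shape) < 1:
            raise ValueError("intensity must be a 3-D (z, y, x) array")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be > 0")


@dataclass(frozen=True)
class SegmentedObject:
    """One connected supra-threshold object in one frame.

    The centroid is the intensity-weighted centre of mass of the member
    voxels, in micrometres, ordered (x, y, z).
    """

    object_id: int
    frame_index: int
    centroid_um: tuple[float, float, float]
    voxel_count: int
    intensity_sum: float


@dataclass
class CentroidTrack:
    """An ordered chain of centroids over strictly consecutive frames."""

    track_id: int
    frame_indices: list[int]
    centroids: np.ndarray  # (n, 3) µm, (x, y, z)
    object_ids: list[int]

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(self.frame_indices) != len(self.centroids):
            raise ValueError("frame/centroid length mismatch")
        if len(self.frame_indices) > 1 and np.any(np.diff(self.frame_indices) != 1):
            raise ValueError("track frames must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.frame_indices)


def write_volume_series(
    frames: Sequence[VolumeFrame],
    directory: str | Path,
    frame_interval_min: float | None = None,
) -> Path:
    """Write a volume series as multi-page TIFFs ``t{frame:04d}.tif`` plus a
    JSON sidecar carrying voxel sizes and the frame interval."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if frame_interval_min is None:
        if len(frames) > 1:
            frame_interval_min = (frames[1].time_h - frames[0].time_h) * 60.0
        else:
            frame_interval_min = 15.0
    for fr in frames:
        tifffile.imwrite(
            directory / f"t{fr.frame_index:04d}.tif",
            np.asarray(fr.intensity, dtype=np.float32),
            photometric="minisblack",
        )
    sidecar = {
        "voxel_size_um": list(frames[0].voxel_size_um) if frames else None,
        "frame_interval_min": frame_interval_min,
        "n_frames": len(frames),
    }
    (directory / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2) + "\n")
    return directory


def read_volume_series(
    directory: str | Path, sidecar: str | Path | None = None
) -> list[VolumeFrame]:
    """Read a TIFF volume series written by :func:`write_volume_series`.

    Raises a ``ValueError`` naming any required sidecar field that is
    missing, and on ragged (inconsistent) volume dimensions.
    """
    directory = Path(directory)
    sidecar_path = Path(sidecar) if sidecar is not None else directory / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"sidecar {sidecar_path} not found; required fields: {SIDECAR_REQUIRED}"
        )
    meta = json.loads(sidecar_path.read_text())
    missing = [k for k in SIDECAR_REQUIRED if meta.get(k) is None]
    if missing:
        raise ValueError(f"sidecar {sidecar_path} is missing required fields {missing}")
    voxel_size = tuple(float(v) for v in meta["voxel_size_um"])
    interval = float(meta["frame_interval_min"])
    paths = sorted(directory.glob("t*.tif"))
    if not paths:
        raise FileNotFoundError(f"no t*.tif volumes found in {directory}")
    frames: list[VolumeFrame] = []
    shape = None
    for p in paths:
        m = re.fullmatch(r"t(\d+)\.tif", p.name)
        if not m:
            continue
        idx = int(m.group(1))
        arr = tifffile.imread(p)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"ragged volume series: {p.name} has shape {arr.shape}, expected {shape}"
            )
        frames.append(
            VolumeFrame(
                intensity=arr,
                voxel_size_um=voxel_size,
                frame_index=idx,
                time_h=(idx - 1) * interval / 60.0,
            )
        )
    frames.sort(key=lambda fr: fr.frame_index)
    return frames


def stabilize_series(frames: Sequence[VolumeFrame]) -> list[VolumeFrame]:
    """Drift-stabilisation hook.

    Input volumes are assumed already deconvolved and drift-corrected
    upstream; this hook exists so a correction step can be slotted into the
    pipeline without changing call sites.  Currently the identity.
    """
    return list(frames)


def segment_frame(
    frame: VolumeFrame,
    intensity_threshold: float,
    min_voxels: int = 10,
) -> list[SegmentedObject]:
    """Segment one volume into 26-connected supra-threshold objects.

    Objects are connected components of voxels with intensity strictly
    above ``intensity_threshold`` containing at least ``min_voxels``
    voxels.  ``intensity_sum`` and ``voxel_count`` are computed over member
    voxels only; the centroid is the intensity-weighted centre of mass.
    An empty frame yields an empty list.
    """
    grid = np.asarray(frame.intensity, dtype=float)
    mask = grid > intensity_threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n_labels = ndimage.label(mask, structure=structure)
    if n_labels == 0:
        return []
    idx = np.arange(1, n_labels + 1)
    counts = ndimage.sum_labels(mask, labels, idx)
    keep = idx[counts >= min_voxels]
    if keep.size == 0:
        return []
    sums = ndimage.sum_labels(grid, labels, keep)
    weighted = np.where(mask, grid, 0.0)
    coms = ndimage.center_of_mass(weighted, labels, keep)
    vx, vy, vz = frame.voxel_size_um
    objects = []
    for oid, (label, count, total, com) in enumerate(
        zip(keep, counts[keep - 1], sums, coms), start=1
    ):
        cz, cy, cx = com
        objects.append(
            SegmentedObject(
                object_id=oid,
                frame_index=frame.frame_index,
                centroid_um=(cx * vx, cy * vy, cz * vz),
                voxel_count=int(count),
                intensity_sum=float(total),
            )
        )
    return objects


def track_centroids(
    objects_by_frame: Mapping[int, Sequence[SegmentedObject]],
    max_displacement_um: float = 5.0,
) -> list[CentroidTrack]:
    """Link objects between consecutive frames into centroid tracks.

    Greedy mutual-nearest-neighbour linking: the globally closest open
    track/object pair is linked first, then the next-closest among the
    remainder, and so on; candidate links farther than
    ``max_displacement_um`` are rejected.  Unlinked objects open new
    tracks; there is no gap closing, so a frame with no acceptable partner
    terminates the track.  Each object belongs to at most one track and
    objects from the same frame are never linked to each other.
    """
    frames = sorted(objects_by_frame)
    tracks: list[CentroidTrack] = []
    open_tracks: list[CentroidTrack] = []
    next_id = 1
    for f in frames:
        objs = list(objects_by_frame.get(f, []))
        candidates = [tr for tr in open_tracks if tr.frame_indices[-1] == f - 1]
        assigned_obj = set()
        if candidates and objs:
            prev = np.array([tr.centroids[-1] for tr in candidates])
            cur = np.array([o.centroid_um for o in objs])
            d = cdist(prev, cur)
            while True:
                flat = np.argmin(d)
                i, j = np.unravel_index(flat, d.shape)
                if not np.isfinite(d[i, j]) or d[i, j] > max_displacement_um:
                    break
                tr = candidates[i]
                tr.frame_indices.append(f)
                tr.centroids = np.vstack([tr.centroids, cur[j]])
                tr.object_ids.append(objs[j].object_id)
                assigned_obj.add(j)
                d[i, :] = np.inf
                d[:, j] = np.inf
        for j, obj in enumerate(objs):
            if j in assigned_obj:
                continue
            tracks.append(
                CentroidTrack(
                    track_id=next_id,
                    frame_indices=[f],
                    centroids=np.array([obj.centroid_um]),
                    object_ids=[obj.object_id],
                )
            )
            next_id += 1
        open_tracks = [tr for tr in tracks if tr.frame_indices[-1] >= f - 1]
    tracks.sort(key=lambda tr: tr.track_id)
    return tracks
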