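"""Per-cell intensity traces — the central currency of the pipeline.

A :class:`CellTrace` is a time-ordered series of volumetric mean
fluorescence intensities (MFI) for one tracked cell, with its subset and
dorsoventral annotations.  Traces from the simulator and traces extracted
from image volumes share this container and the same CSV schema, so the
pulse analysis accepts either source interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import SIDES, SUBSETS

__all__ = ["CellTrace", "read_traces_csv", "write_traces_csv"]

TRACE_COLUMNS = ["cell_id", "subset", "side", "frame", "time_h", "mfi", "mitosis_flag"]


@dataclass
class CellTrace:
    """Time-ordered volumetric MFI series of one tracked cell.

    ``frames`` are 1-based, strictly consecutive global movie frame indices;
    times are hours from movie frame 1, ``t = (frame - 1) * interval``.
    """

    cell_id: str
    frames: np.ndarray
    mfi: np.ndarray
    frame_interval_min: float = 15.0
    subset: Optional[str] = None
    side: Optional[str] = None
    mitosis_frame: Optional[int] = None
    drift_suspect: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.mfi = np.asarray(self.mfi, dtype=float)
        if self.frames.ndim != 1 or self.frames.size == 0:
            raise ValueError("frames must be a non-empty 1-D sequence")
        if len(self.mfi) != len(self.frames):
            raise ValueError(
                f"mfi length {len(self.mfi)} != frames length {len(self.frames)}"
            )
        if self.frames[0] < 1:
            raise ValueError("frame indices are 1-based")
        if self.frames.size > 1 and np.any(np.diff(self.frames) != 1):
            raise ValueError("frames must be strictly consecutive")
        if np.any(self.mfi < 0):
            raise ValueError("mfi values must be >= 0")
        if not self.frame_interval_min > 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.subset is not None and self.subset not in SUBSETS:
            raise ValueError(f"subset must be one of {SUBSETS}, got {self.subset!r}")
        if self.side is not None and self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_h(self) -> np.ndarray:
        """Acquisition times in hours from movie frame 1."""
        return (self.frames - 1) * self.frame_interval_min / 60.0

    @property
    def has_mitosis(self) -> bool:
        return self.mitosis_frame is not None


def write_traces_csv(traces: Sequence[CellTrace], path: str | Path) -> Path:
    """Write traces to CSV (one row per cell per frame).

    Schema: cell_id, subset, side, frame, time_h, mfi, mitosis_flag, where
    mitosis_flag is 1 on the frame a division was annotated and 0 elsewhere.
    """
    path = Path(path)
    rows = []
    for tr in traces:
        for f, t, v in zip(tr.frames, tr.times_h, tr.mfi):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "subset": tr.subset if tr.subset is not None else "",
                    "side": tr.side if tr.side is not None else "",
                    "frame": int(f),
                    "time_h": round(float(t), 6),
                    "mfi": float(v),
                    "mitosis_flag": int(tr.mitosis_frame == f)
                    if tr.mitosis_frame is not None
                    else 0,
                }
            )
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)
    return path


def read_traces_csv(path: str | Path, frame_interval_min: Optional[float] = None) -> list[CellTrace]:
    """Read traces written by :func:`write_traces_csv`.

    The frame interval is inferred from the time/frame columns unless given
    explicitly.
    """
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"traces CSV {path} is missing columns {missing}")
    traces: list[CellTrace] = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("frame")
        if frame_interval_min is not None:
            interval = frame_interval_min
        elif len(sub) > 1:
            interval = float(np.diff(sub["time_h"].to_numpy())[0] * 60.0)
        else:
            frame0, t0 = int(sub["frame"].iloc[0]), float(sub["time_h"].iloc[0])
            interval = t0 * 60.0 / (frame0 - 1) if frame0 > 1 and t0 > 0 else 15.0
        mit = sub.loc[sub["mitosis_flag"] == 1, "frame"]
        subset = str(sub["subset"].iloc[0]) or None
        side = str(sub["side"].iloc[0]) or None
        traces.append(
            CellTrace(
                cell_id=str(cell_id),
                frames=sub["frame"].to_numpy(),
                mfi=sub["mfi"].to_numpy(),
                frame_interval_min=interval,
                subset=subset,
                side=side,
                mitosis_frame=int(mit.iloc[0]) if len(mit) else None,
            )
        )
    return traces
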