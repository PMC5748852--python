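"""Inclusion/exclusion rules applied to traces before pulse analysis.

Analysis is limited to cells tracked over at least 10 consecutive frames
that neither divide during the movie nor show a monotone overall intensity
change attributable to the microscope setup (bleaching/drift).  The
original drift criterion was visual; it is operationalised here as a
combined rank-correlation and net-robust-trend rule so that the exclusion
is reproducible.  Thresholds are exposed in :class:`QCConfig` and reported
in run metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .traces import CellTrace

__all__ = [
    "QCConfig",
    "Exclusion",
    "REASON_TOO_SHORT",
    "REASON_MITOSIS",
    "REASON_DRIFT",
    "filter_tracks",
    "flag_drift",
    "mean_mfi_window",
]

REASON_TOO_SHORT = "too_short"
REASON_MITOSIS = "mitosis"
REASON_DRIFT = "drift"


@dataclass(frozen=True)
class QCConfig:
    """Quality-control thresholds.

    ``min_track_frames``: minimum number of consecutive tracked frames
    (default 10).  A trace is drift-suspect when the absolute Spearman rank
    correlation of MFI against time reaches ``drift_rank_corr`` *and* the
    robust (Theil–Sen) end-to-start trend change reaches
    ``drift_abs_change_frac`` of the trace mean.  ``exclude_mitosis`` drops
    cells with an annotated division.
    """

    min_track_frames: int = 10
    drift_abs_change_frac: float = 0.30
    drift_rank_corr: float = 0.8
    exclude_mitosis: bool = True

    def __post_init__(self) -> None:
        if self.min_track_frames < 2:
            raise ValueError("min_track_frames must be >= 2")
        if not 0 < self.drift_rank_corr <= 1:
            raise ValueError("drift_rank_corr must be in (0, 1]")
        if self.drift_abs_change_frac < 0:
            raise ValueError("drift_abs_change_frac must be >= 0")


class Exclusion(NamedTuple):
    trace: CellTrace
    reason: str


def flag_drift(trace: CellTrace, cfg: QCConfig = QCConfig()) -> bool:
    """True when a trace shows a sustained monotone intensity change.

    Requires both a strong rank correlation of MFI with time
    (|Spearman rho| >= ``drift_rank_corr``) and a large net trend change
    (|Theil–Sen slope x duration| >= ``drift_abs_change_frac`` of the trace
    mean).  Invariant to positive rescaling of the trace.  Pulsing traces
    without bleaching fail the rank-correlation arm; small monotone jitter
    fails the net-change arm.
    """
    if len(trace) < 3:
        raise ValueError("drift flagging needs at least 3 frames")
    t = trace.times_h
    y = trace.mfi
    if np.ptp(y) == 0:
        return False
    rho = stats.spearmanr(t, y).statistic
    if not np.isfinite(rho):
        rho = 0.0
    slope = stats.theilslopes(y, t).slope
    net_change = abs(slope * (t[-1] - t[0]))
    return bool(
        abs(rho) >= cfg.drift_rank_corr
        and net_change >= cfg.drift_abs_change_frac * y.mean()
    )


def filter_tracks(
    traces: Sequence[CellTrace], cfg: QCConfig = QCConfig()
) -> tuple[list[CellTrace], list[Exclusion]]:
    """Partition traces into (kept, excluded-with-reason).

    Reasons are checked in order: ``too_short`` (fewer than
    ``min_track_frames`` frames), ``mitosis`` (annotated division, when
    ``exclude_mitosis``), ``drift`` (see :func:`flag_drift`).  Every input
    trace lands in exactly one of the two partitions.
    """
    kept: list[CellTrace] = []
    excluded: list[Exclusion] = []
    for trace in traces:
        if len(trace) < cfg.min_track_frames:
            excluded.append(Exclusion(trace, REASON_TOO_SHORT))
            continue
        if cfg.exclude_mitosis and trace.has_mitosis:
            excluded.append(Exclusion(trace, REASON_MITOSIS))
            continue
        if len(trace) >= 3 and flag_drift(trace, cfg):
            trace.drift_suspect = True
            excluded.append(Exclusion(trace, REASON_DRIFT))
            continue
        kept.append(trace)
    return kept, excluded


def mean_mfi_window(trace: CellTrace, start: int = 3, end: int = 12) -> float:
    """Mean MFI over a window of consecutive track positions.

    ``start``/``end`` are 1-based ordinal positions within the track,
    inclusive (default: 3rd through 12th sample, ten values — the first
    two samples are skipped to avoid settling artefacts at movie start).
    Raises if the trace is shorter than the window, naming the missing
    positions.
    """
    if start < 1 or end < start:
        raise ValueError(f"invalid window [{start}, {end}]")
    if len(trace) < end:
        raise ValueError(
            f"trace {trace.cell_id!r} has {len(trace)} samples; window needs "
            f"positions {start}..{end} (missing {len(trace) + 1}..{end})"
        )
    return float(trace.mfi[start - 1 : end].mean())
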