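"""Synthetic pulsatile-reporter cohorts with known ground truth.

The generator produces per-cell MFI traces (and, optionally, rendered
3D+time image volumes) that emulate the statistical structure of vital
confocal imaging of a short-half-life transcription reporter in the
embryonic aorta: three EHT cell subsets with subset-specific baselines,
pulse periods of roughly 1–3 h and fold amplitudes, a reporter decaying
with a 60–120 min half-life, 15-min sampling over ~12 h, additive Gaussian
detection noise, rare mitosis events (transient intensity dip) and optional
slow photobleaching.

The noiseless trace model is a pulsatile synthesis input passed through a
first-order reporter-decay filter.  For the sinusoid input the filtered
signal stays sinusoidal — attenuated and delayed by ``atan(omega/k)/omega``
— so ground-truth peak times are closed-form.  ``pulse_fold`` always refers
to the peak/trough ratio of the *noiseless trace* (the filter's amplitude
attenuation is absorbed into the requested fold).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    SIDES,
    SUBSETS,
    CellGroundTruth,
    CellSpec,
    CohortConfig,
    PulseKinetics,
)
from .traces import CellTrace
from .volumes import VolumeFrame

logger = logging.getLogger(__name__)

__all__ = ["SimulatedCohort", "simulate_trace", "simulate_cohort", "render_timelapse"]

# depth and width (in frame intervals) of the transient mitosis intensity dip
MITOSIS_DIP_DEPTH = 0.6
MITOSIS_DIP_SIGMA_FRAMES = 1.0

# rendering constants: blob extent (in sigmas), camera gain, read noise
BLOB_SUPPORT_SIGMAS = 2.0
RENDER_BACKGROUND = 2.0
RENDER_GAIN = 5.0
RENDER_READ_NOISE_SD = 0.5
DEFAULT_BLOB_SIGMA_UM = (3.0, 3.0, 2.5)  # (x, y, z)


def _sinusoid_noiseless(kin: PulseKinetics, t_h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless filtered sinusoid and its analytic peak times (hours)."""
    if kin.pulse_fold == 1.0:
        return np.full_like(t_h, kin.baseline_mfi), np.empty(0)
    period = kin.pulse_period_h
    m = kin.modulation
    # output peaks lag the synthesis peaks by the filter delay
    t0 = (kin.phase_rad / (2.0 * math.pi)) * period + kin.peak_lag_h
    y = kin.baseline_mfi * (1.0 + m * np.cos(2.0 * math.pi * (t_h - t0) / period))
    n_lo = math.ceil((t_h[0] - t0) / period - 1e-9)
    n_hi = math.floor((t_h[-1] - t0) / period + 1e-9)
    peaks = t0 + period * np.arange(n_lo, n_hi + 1)
    return y, peaks


def _square_convolved_noiseless(
    kin: PulseKinetics, t_h: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Square synthesis train convolved with the reporter decay filter.

    Solved on a fine grid with exact exponential stepping, then affinely
    rescaled so the sampled noiseless trace has the requested mean and
    peak/trough fold.  Ground-truth peak times are the fine-grid maxima.
    """
    if kin.pulse_fold == 1.0:
        return np.full_like(t_h, kin.baseline_mfi), np.empty(0)
    period = kin.pulse_period_h
    k = kin.decay_rate_per_h
    burn_in = 5.0 / k
    dt = period / 400.0
    t_fine = np.arange(t_h[0] - burn_in, t_h[-1] + dt, dt)
    phase_h = (kin.phase_rad / (2.0 * math.pi)) * period
    on = ((t_fine - phase_h) / period) % 1.0 < 0.5
    s = on.astype(float)
    decay = math.exp(-k * dt)
    u = np.empty_like(t_fine)
    u[0] = 0.5
    for i in range(1, len(t_fine)):
        u[i] = s[i - 1] + (u[i - 1] - s[i - 1]) * decay
    window = t_fine >= t_h[0] - 1e-9
    tw, uw = t_fine[window], u[window]
    u_min, u_max = float(uw.min()), float(uw.max())
    if u_max - u_min < 1e-12:
        return np.full_like(t_h, kin.baseline_mfi), np.empty(0)
    # affine map u -> a + b*u with peak/trough = pulse_fold, then scale to mean
    b = 1.0
    a = (u_max - kin.pulse_fold * u_min) / (kin.pulse_fold - 1.0)
    y_fine = a + b * uw
    interior = (uw[1:-1] >= uw[:-2]) & (uw[1:-1] > uw[2:])
    peaks = tw[1:-1][interior]
    y = np.interp(t_h, tw, y_fine)
    scale = kin.baseline_mfi / y.mean()
    return y * scale, peaks


def simulate_trace(
    spec: CellSpec,
    frame_interval_min: float = 15.0,
    n_frames: int = 48,
    rng: Optional[np.random.Generator] = None,
) -> tuple[CellTrace, CellGroundTruth]:
    """Simulate one cell's MFI trace and its ground truth.

    The observed window is ``spec.start_frame .. min(spec.end_frame,
    n_frames)``; sample times are ``t = (frame - 1) * interval``.  Noise is
    additive Gaussian with SD ``noise_sd_frac`` times the noiseless trace
    mean.  An annotated mitosis produces a transient intensity dip centred
    on ``mitosis_frame``; photobleaching multiplies the noiseless signal by
    a decaying exponential envelope.

    Returns
    -------
    (CellTrace, CellGroundTruth)
        Ground-truth peak times are the analytic maxima of the noiseless
        filtered (un-bleached) signal within the observed window.
    """
    if rng is None:
        rng = np.random.default_rng()
    kin = spec.kinetics
    end = min(spec.end_frame, n_frames)
    if end - spec.start_frame + 1 < 2:
        raise ValueError("a trace needs at least 2 frames")
    frames = np.arange(spec.start_frame, end + 1)
    dt_h = frame_interval_min / 60.0
    t_h = (frames - 1) * dt_h

    if kin.pulse_shape == "sinusoid":
        y, peak_times = _sinusoid_noiseless(kin, t_h)
    else:
        y, peak_times = _square_convolved_noiseless(kin, t_h)
    peak_times = peak_times[(peak_times >= t_h[0] - 1e-9) & (peak_times <= t_h[-1] + 1e-9)]

    if kin.bleach_rate_per_h > 0:
        y = y * np.exp(-kin.bleach_rate_per_h * t_h)
    if spec.mitosis_frame is not None:
        tm = (spec.mitosis_frame - 1) * dt_h
        sigma = MITOSIS_DIP_SIGMA_FRAMES * dt_h
        y = y * (1.0 - MITOSIS_DIP_DEPTH * np.exp(-0.5 * ((t_h - tm) / sigma) ** 2))

    noiseless_mean = float(y.mean())
    if kin.noise_sd_frac > 0:
        y = y + rng.normal(0.0, kin.noise_sd_frac * noiseless_mean, size=y.shape)
    y = np.maximum(y, 1e-6 * kin.baseline_mfi)

    trace = CellTrace(
        cell_id=spec.cell_id,
        frames=frames,
        mfi=y,
        frame_interval_min=frame_interval_min,
        subset=spec.subset,
        side=spec.side,
        mitosis_frame=spec.mitosis_frame,
    )
    truth = CellGroundTruth(
        cell_id=spec.cell_id,
        peak_times_h=peak_times,
        fold_amplitude=kin.pulse_fold,
        subset=spec.subset,
        side=spec.side,
        mitosis_frame=spec.mitosis_frame,
    )
    return trace, truth


@dataclass
class SimulatedCohort:
    """A simulated cohort: traces, per-cell ground truth and annotations."""

    traces: list[CellTrace]
    ground_truth: list[CellGroundTruth]
    specs: list[CellSpec]
    annotations: pd.DataFrame
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.traces)


def _grid_positions(config: CohortConfig, spacing_um: float = 14.0) -> np.ndarray:
    """Candidate blob centres on a jittery 3-D grid inside the volume.

    Keeps simultaneously rendered cells at least ``spacing_um`` apart so
    their blobs do not merge during segmentation.
    """
    nz, ny, nx = config.volume_shape_vox
    vx, vy, vz = config.voxel_size_um
    extent = np.array([(nx - 1) * vx, (ny - 1) * vy, (nz - 1) * vz])
    margin = 8.0
    pts = []
    xs = np.arange(margin, max(extent[0] - margin, margin) + 1e-9, spacing_um)
    ys = np.arange(margin, max(extent[1] - margin, margin) + 1e-9, spacing_um)
    zs = np.arange(margin, max(extent[2] - margin, margin) + 1e-9, spacing_um / 2.0)
    if len(zs) == 0:
        zs = np.array([extent[2] / 2.0])
    for z in zs:
        for y in ys:
            for x in xs:
                pts.append((x, y, min(z, extent[2] - 1.0)))
    return np.array(pts) if pts else np.array([extent / 2.0])


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Draw a full cohort of cells from the per-subset priors.

    Deterministic under a fixed ``(config, seed)``: each cell uses a random
    substream keyed by ``[seed, subset_index, cell_counter]``, so changing
    the cohort size does not reshuffle existing cells.  Requesting zero
    cells yields an empty cohort.
    """
    traces: list[CellTrace] = []
    truths: list[CellGroundTruth] = []
    specs: list[CellSpec] = []
    rows = []
    positions = _grid_positions(config)
    pos_rng = np.random.default_rng([config.seed, 7919])
    order = pos_rng.permutation(len(positions))
    n_total = sum(config.n_cells_per_subset.get(s, 0) for s in SUBSETS)
    if n_total > len(positions):
        logger.warning(
            "cohort of %d cells exceeds %d well-separated rendering positions; "
            "rendered blobs may overlap", n_total, len(positions)
        )
    slot = 0
    lo, hi = config.track_length_range
    for si, subset in enumerate(SUBSETS):
        n_cells = config.n_cells_per_subset.get(subset, 0)
        prior = config.priors.get(subset)
        for i in range(n_cells):
            rng = np.random.default_rng([config.seed, si, i])
            cell_id = f"{subset}_{i:03d}"
            side = "ventral" if rng.random() < prior.ventral_fraction else "dorsal"
            pulsing = rng.random() < prior.pulsing_fraction
            period = float(
                rng.choice(np.asarray(prior.period_choices_h, dtype=float),
                           p=np.asarray(prior.period_weights, dtype=float))
            )
            fold = float(rng.uniform(*prior.fold_range)) if pulsing else 1.0
            baseline = float(max(rng.normal(prior.baseline_mean, prior.baseline_sd), 5.0))
            halflife = float(rng.uniform(*prior.halflife_range_min))
            phase = float(rng.uniform(0.0, 2.0 * math.pi))
            kin = PulseKinetics(
                baseline_mfi=baseline,
                pulse_period_h=period,
                pulse_fold=fold,
                reporter_halflife_min=halflife,
                noise_sd_frac=prior.noise_sd_frac,
                phase_rad=phase,
            )
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(1, config.n_frames - length + 2))
            endf = start + length - 1
            mitosis = None
            if length >= 6 and rng.random() < prior.mitosis_prob:
                mitosis = int(rng.integers(start + 2, endf - 1))
            # slow 3-D random walk from a well-separated grid position
            origin = positions[order[slot % len(positions)]]
            slot += 1
            steps = rng.normal(0.0, 0.4, size=(length, 3))
            steps[0] = 0.0
            path = origin + np.cumsum(steps, axis=0)
            nz, ny, nx = config.volume_shape_vox
            vx, vy, vz = config.voxel_size_um
            upper = np.array([(nx - 1) * vx, (ny - 1) * vy, (nz - 1) * vz]) - 2.0
            path = np.clip(path, 2.0, np.maximum(upper, 2.5))
            spec = CellSpec(
                cell_id=cell_id,
                kinetics=kin,
                subset=subset,
                side=side,
                start_frame=start,
                end_frame=endf,
                mitosis_frame=mitosis,
                centroid_path=path,
            )
            trace, truth = simulate_trace(
                spec, config.frame_interval_min, config.n_frames, rng=rng
            )
            traces.append(trace)
            truths.append(truth)
            specs.append(spec)
            rows.append(
                {
                    "cell_id": cell_id,
                    "subset": subset,
                    "side": side,
                    "start_frame": start,
                    "end_frame": endf,
                    "mitosis_frame": mitosis,
                    "pulsing": pulsing,
                    "true_period_h": period if pulsing else np.nan,
                    "true_fold": fold,
                    "baseline_mfi": baseline,
                    "reporter_halflife_min": halflife,
                }
            )
    annotations = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "subset", "side", "start_frame", "end_frame",
            "mitosis_frame", "pulsing", "true_period_h", "true_fold",
            "baseline_mfi", "reporter_halflife_min",
        ],
    )
    return SimulatedCohort(traces, truths, specs, annotations, config)


def _render_blob(
    grid: np.ndarray,
    center_um: np.ndarray,
    mfi: float,
    voxel_size_um: tuple[float, float, float],
    sigma_um: tuple[float, float, float],
) -> None:
    """Add one anisotropic Gaussian blob to ``grid`` in place.

    The blob amplitude is solved so that (sum of blob intensity) / (number
    of support voxels) equals ``mfi`` exactly over the blob's support
    (voxels within ``BLOB_SUPPORT_SIGMAS`` standard deviations).
    """
    vx, vy, vz = voxel_size_um
    sx, sy, sz = sigma_um
    cx, cy, cz = center_um
    nzv, nyv, nxv = grid.shape
    s = BLOB_SUPPORT_SIGMAS
    ix = np.arange(max(0, math.floor((cx - s * sx) / vx)), min(nxv, math.ceil((cx + s * sx) / vx) + 1))
    iy = np.arange(max(0, math.floor((cy - s * sy) / vy)), min(nyv, math.ceil((cy + s * sy) / vy) + 1))
    iz = np.arange(max(0, math.floor((cz - s * sz) / vz)), min(nzv, math.ceil((cz + s * sz) / vz) + 1))
    if len(ix) == 0 or len(iy) == 0 or len(iz) == 0:
        return
    zz, yy, xx = np.meshgrid(iz, iy, ix, indexing="ij")
    d2 = (
        ((xx * vx - cx) / sx) ** 2
        + ((yy * vy - cy) / sy) ** 2
        + ((zz * vz - cz) / sz) ** 2
    )
    mask = d2 <= s * s
    if not mask.any():
        return
    kernel = np.exp(-0.5 * d2)
    amp = mfi / kernel[mask].mean()
    patch = np.where(mask, amp * kernel, 0.0)
    grid[iz[0]: iz[-1] + 1, iy[0]: iy[-1] + 1, ix[0]: ix[-1] + 1] += patch


def render_timelapse(
    cohort: SimulatedCohort,
    seed: Optional[int] = None,
    blob_sigma_um: tuple[float, float, float] = DEFAULT_BLOB_SIGMA_UM,
    noise: bool = True,
) -> list[VolumeFrame]:
    """Render the cohort as one 3-D intensity volume per time point.

    Each cell becomes an anisotropic Gaussian blob at its centroid-path
    position whose integrated intensity per support voxel equals the cell's
    trace MFI at that frame.  Poisson–Gaussian detection noise is added on
    top of a constant background.  Cells whose centres come closer than one
    blob radius trigger a logged warning (ground truth is still emitted).
    """
    config = cohort.config
    if seed is None:
        seed = config.seed
    frames_out: list[VolumeFrame] = []
    radius = BLOB_SUPPORT_SIGMAS * max(blob_sigma_um)
    dt_h = config.frame_interval_min / 60.0
    for f in range(1, config.n_frames + 1):
        grid = np.full(config.volume_shape_vox, RENDER_BACKGROUND, dtype=float)
        centers = []
        for spec, trace in zip(cohort.specs, cohort.traces):
            if spec.centroid_path is None or not (spec.start_frame <= f <= spec.end_frame):
                continue
            pos = spec.centroid_path[f - spec.start_frame]
            mfi = float(trace.mfi[f - spec.start_frame])
            _render_blob(grid, pos, mfi, config.voxel_size_um, blob_sigma_um)
            centers.append(pos)
        if len(centers) > 1:
            pts = np.asarray(centers)
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < radius:
                logger.warning(
                    "frame %d: cells closer than one blob radius (%.1f um); "
                    "rendered blobs overlap", f, d.min()
                )
        if noise:
            rng = np.random.default_rng([seed, 104729, f])
            grid = rng.poisson(np.clip(grid, 0, None) * RENDER_GAIN) / RENDER_GAIN
            grid = grid + rng.normal(0.0, RENDER_READ_NOISE_SD, size=grid.shape)
        frames_out.append(
            VolumeFrame(
                intensity=grid.astype(np.float32),
                voxel_size_um=config.voxel_size_um,
                frame_index=f,
                time_h=(f - 1) * dt_h,
            )
        )
    return frames_out
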