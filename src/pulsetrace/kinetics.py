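"""Parameter objects for the synthetic pulsatile-reporter cohort.

The simulator emulates vital confocal imaging of a fast-maturing fluorescent
reporter of transcription-factor activity in single aortic cells undergoing
the endothelial-to-hematopoietic transition (EHT).  Cells belong to one of
three phenotypic subsets — hemogenic endothelial cells (HEC), bulging cells
(BC) and intra-aortic hematopoietic cluster cells (IAHC) — on the ventral or
dorsal side of the aorta.  Subset priors are a *qualitative* emulation of the
published group differences (BCs pulse fastest and hardest, IAHCs sit at the
highest baseline, HECs pulse least); they are not estimates of real
parameter distributions.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SUBSETS",
    "SIDES",
    "PULSE_SHAPES",
    "PulseKinetics",
    "CellSpec",
    "SubsetPrior",
    "CohortConfig",
    "CellGroundTruth",
    "default_subset_priors",
]

SUBSETS = ("HEC", "BC", "IAHC")
SIDES = ("ventral", "dorsal")
PULSE_SHAPES = ("sinusoid", "square_convolved")


@dataclass(frozen=True)
class PulseKinetics:
    """Kinetic parameters of one cell's noiseless reporter trace.

    Parameters
    ----------
    baseline_mfi : float
        Mean fluorescence intensity of the trace, arbitrary units.
    pulse_period_h : float
        Period of the transcriptional pulse train, hours.
    pulse_fold : float
        Peak/trough ratio of the noiseless trace (``>= 1``; 1 means no
        pulsing).
    pulse_shape : {"sinusoid", "square_convolved"}
        Shape of the synthesis input.  The sinusoid has closed-form peak
        times; the square train is convolved numerically with the reporter
        decay filter.
    reporter_halflife_min : float
        First-order decay half-life of the fluorescent reporter, minutes.
        Maturation is folded into this single first-order stage.
    noise_sd_frac : float
        SD of additive Gaussian detection noise as a fraction of the
        noiseless trace mean.
    bleach_rate_per_h : float
        Fractional intensity loss per hour (exponential photobleaching
        envelope); 0 disables bleaching.
    phase_rad : float
        Phase offset of the synthesis input, radians.
    """

    baseline_mfi: float = 45.0
    pulse_period_h: float = 2.0
    pulse_fold: float = 1.5
    pulse_shape: str = "sinusoid"
    reporter_halflife_min: float = 90.0
    noise_sd_frac: float = 0.05
    bleach_rate_per_h: float = 0.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if not self.baseline_mfi > 0:
            raise ValueError(f"baseline_mfi must be > 0, got {self.baseline_mfi}")
        if not self.pulse_period_h > 0:
            raise ValueError(f"pulse_period_h must be > 0, got {self.pulse_period_h}")
        if not self.pulse_fold >= 1:
            raise ValueError(f"pulse_fold must be >= 1, got {self.pulse_fold}")
        if self.pulse_shape not in PULSE_SHAPES:
            raise ValueError(
                f"pulse_shape must be one of {PULSE_SHAPES}, got {self.pulse_shape!r}"
            )
        if not self.reporter_halflife_min > 0:
            raise ValueError(
                f"reporter_halflife_min must be > 0, got {self.reporter_halflife_min}"
            )
        if not 0 <= self.noise_sd_frac < 1:
            raise ValueError(
                f"noise_sd_frac must be in [0, 1), got {self.noise_sd_frac}"
            )
        if self.bleach_rate_per_h < 0:
            raise ValueError(
                f"bleach_rate_per_h must be >= 0, got {self.bleach_rate_per_h}"
            )

    @property
    def decay_rate_per_h(self) -> float:
        """First-order reporter decay rate ln(2)/half-life, per hour."""
        return math.log(2.0) / (self.reporter_halflife_min / 60.0)

    @property
    def modulation(self) -> float:
        """Relative modulation depth m with peak/trough = (1+m)/(1-m)."""
        return (self.pulse_fold - 1.0) / (self.pulse_fold + 1.0)

    @property
    def peak_lag_h(self) -> float:
        """Phase lag of the output peaks behind the synthesis peaks.

        A sinusoidal synthesis input passed through a first-order decay
        filter with rate ``k`` emerges delayed by ``atan(omega/k)/omega``.
        """
        omega = 2.0 * math.pi / self.pulse_period_h
        return math.atan2(omega, self.decay_rate_per_h) / omega


@dataclass
class CellSpec:
    """Full specification of one simulated cell.

    ``start_frame``/``end_frame`` are 1-based inclusive global movie frames.
    ``centroid_path`` holds one (x, y, z) position in micrometres per
    observed frame and is only needed when rendering image volumes.
    """

    cell_id: str
    kinetics: PulseKinetics
    subset: Optional[str] = None
    side: Optional[str] = None
    start_frame: int = 1
    end_frame: int = 48
    mitosis_frame: Optional[int] = None
    centroid_path: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.subset is not None and self.subset not in SUBSETS:
            raise ValueError(f"subset must be one of {SUBSETS}, got {self.subset!r}")
        if self.side is not None and self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.start_frame < 1 or self.end_frame < self.start_frame:
            raise ValueError(
                f"need 1 <= start_frame <= end_frame, got "
                f"[{self.start_frame}, {self.end_frame}]"
            )
        if self.mitosis_frame is not None and not (
            self.start_frame <= self.mitosis_frame <= self.end_frame
        ):
            raise ValueError(
                f"mitosis_frame {self.mitosis_frame} outside "
                f"[{self.start_frame}, {self.end_frame}]"
            )
        if self.centroid_path is not None:
            self.centroid_path = np.asarray(self.centroid_path, dtype=float)
            if self.centroid_path.shape != (self.n_frames, 3):
                raise ValueError(
                    f"centroid_path must have shape ({self.n_frames}, 3), "
                    f"got {self.centroid_path.shape}"
                )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class SubsetPrior:
    """Sampling distribution of :class:`PulseKinetics` for one cell subset.

    ``pulsing_fraction`` controls the fraction of cells that pulse at all
    (non-pulsing cells get ``pulse_fold = 1``).  Periods are drawn from a
    categorical prior over whole-hour values, folds and half-lives uniformly
    from their ranges.
    """

    baseline_mean: float
    baseline_sd: float
    pulsing_fraction: float
    period_choices_h: Sequence[float] = (1.0, 2.0, 3.0, 4.0)
    period_weights: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    fold_range: tuple[float, float] = (1.2, 2.0)
    halflife_range_min: tuple[float, float] = (60.0, 120.0)
    noise_sd_frac: float = 0.05
    mitosis_prob: float = 0.0
    ventral_fraction: float = 0.77

    def __post_init__(self) -> None:
        if len(self.period_choices_h) != len(self.period_weights):
            raise ValueError("period_choices_h and period_weights length mismatch")
        if not math.isclose(sum(self.period_weights), 1.0, abs_tol=1e-6):
            raise ValueError("period_weights must sum to 1")
        if not 0 <= self.pulsing_fraction <= 1:
            raise ValueError("pulsing_fraction must be in [0, 1]")


def default_subset_priors() -> dict[str, SubsetPrior]:
    """Default per-subset priors (qualitative emulation of the published
    group structure: HECs pulse least, BCs have the shortest periods and
    largest fold amplitudes, IAHCs the highest baselines)."""
    return {
        "HEC": SubsetPrior(
            baseline_mean=40.0,
            baseline_sd=8.0,
            pulsing_fraction=0.32,
            period_weights=(0.07, 0.30, 0.32, 0.31),
            fold_range=(1.2, 1.8),
            mitosis_prob=0.0,
        ),
        "BC": SubsetPrior(
            baseline_mean=45.0,
            baseline_sd=9.0,
            pulsing_fraction=0.44,
            period_weights=(0.20, 0.43, 0.18, 0.19),
            fold_range=(1.3, 2.2),
            mitosis_prob=0.003,
        ),
        "IAHC": SubsetPrior(
            baseline_mean=50.0,
            baseline_sd=10.0,
            pulsing_fraction=0.51,
            period_weights=(0.13, 0.31, 0.25, 0.31),
            fold_range=(1.2, 1.9),
            mitosis_prob=0.14,
        ),
    }


@dataclass
class CohortConfig:
    """Configuration of a simulated imaging cohort.

    Defaults follow the acquisition geometry of the emulated experiment:
    volumes every 15 min for 12 h (48 frames) with anisotropic voxels
    (z step within 0.7–2.5 µm).  Identical ``(config, seed)`` yields a
    bit-identical cohort; per-cell random substreams are keyed by subset and
    cell counter so growing the cohort does not reshuffle existing cells.
    """

    n_cells_per_subset: Mapping[str, int] = field(
        default_factory=lambda: {"HEC": 30, "BC": 30, "IAHC": 30}
    )
    frame_interval_min: float = 15.0
    n_frames: int = 48
    voxel_size_um: tuple[float, float, float] = (0.76, 0.76, 2.0)  # (x, y, z)
    volume_shape_vox: tuple[int, int, int] = (16, 96, 96)  # (z, y, x)
    seed: int = 0
    priors: Mapping[str, SubsetPrior] = field(default_factory=default_subset_priors)
    track_length_range: Optional[tuple[int, int]] = None  # default (8, n_frames)

    def __post_init__(self) -> None:
        if not self.frame_interval_min > 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for subset in self.n_cells_per_subset:
            if subset not in SUBSETS:
                raise ValueError(f"unknown subset {subset!r}")
            if subset not in self.priors:
                raise ValueError(f"no prior supplied for subset {subset!r}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be > 0")
        if self.track_length_range is None:
            self.track_length_range = (min(8, self.n_frames), self.n_frames)
        lo, hi = self.track_length_range
        if not 2 <= lo <= hi <= self.n_frames:
            raise ValueError(
                f"track_length_range must satisfy 2 <= lo <= hi <= n_frames, "
                f"got {self.track_length_range}"
            )

    def to_dict(self) -> dict:
        """Plain-data representation, round-trippable via YAML/JSON."""
        return {
            "n_cells_per_subset": dict(self.n_cells_per_subset),
            "frame_interval_min": self.frame_interval_min,
            "n_frames": self.n_frames,
            "voxel_size_um": list(self.voxel_size_um),
            "volume_shape_vox": list(self.volume_shape_vox),
            "seed": self.seed,
            "track_length_range": list(self.track_length_range),
            "priors": {
                k: {
                    f: list(val) if isinstance(val, tuple) else val
                    for f, val in dataclasses.asdict(v).items()
                }
                for k, v in self.priors.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        data = dict(data)
        if "priors" in data:
            data["priors"] = {
                k: v if isinstance(v, SubsetPrior) else SubsetPrior(**v)
                for k, v in data["priors"].items()
            }
        for key in ("voxel_size_um", "volume_shape_vox", "track_length_range"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CellGroundTruth:
    """Ground truth of one simulated cell, for recovery testing.

    Peak times are the analytic maxima of the noiseless filtered signal,
    in hours from movie frame 1, restricted to the cell's observed window.
    """

    cell_id: str
    peak_times_h: np.ndarray
    fold_amplitude: float
    subset: Optional[str] = None
    side: Optional[str] = None
    mitosis_frame: Optional[int] = None

    def __post_init__(self) -> None:
        self.peak_times_h = np.asarray(self.peak_times_h, dtype=float)
        if np.any(np.diff(self.peak_times_h) <= 0):
            raise ValueError("ground-truth peak times must be strictly increasing")

    @property
    def periods_h(self) -> np.ndarray:
        """True inter-peak intervals in hours."""
        return np.diff(self.peak_times_h)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times_h)
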