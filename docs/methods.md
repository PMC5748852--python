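# Methods

This note documents the models, conventions and numerical choices behind
`pulsetrace`, and what the synthetic benchmarks do and do not demonstrate
about real imaging data.

## Trace model

A cell's noiseless trace is a pulsatile synthesis input filtered by
first-order reporter decay with rate `k = ln 2 / half-life` (reporter
maturation is folded into this single first-order stage).  For the default
sinusoidal input the filtered output remains sinusoidal, delayed by
`atan(omega/k)/omega` with `omega = 2*pi/period`; ground-truth peak times
are therefore closed-form.  `pulse_fold` always parameterises the
peak/trough ratio of the *noiseless output trace* — the filter's amplitude
attenuation is absorbed into the requested fold, so the half-life affects
peak timing (phase lag), not the realised amplitude.  The alternative
`square_convolved` shape integrates a 50%-duty square synthesis train
through the decay filter on a fine grid (400 steps per period, 5/k burn-in,
exact exponential stepping) and rescales the result affinely to the
requested mean and fold; its ground-truth peaks are fine-grid maxima and
carry ~`period/400` timing quantisation.

Modifiers, applied to the noiseless signal in order:

- **bleaching** — multiplicative envelope `exp(-bleach_rate * t)`; off by
  default (the emulated acquisition showed no confounding bleaching, and
  the QC drift rule exists to *exclude*, not correct, bleached tracks);
- **mitosis** — a transient multiplicative dip, depth 0.6, Gaussian in
  time with SD of one frame interval, centred on the annotated division
  frame (reporter levels drop during division); the dip guarantees a local
  minimum within ±2 frames of the annotation in the noiseless signal;
- **noise** — additive Gaussian with SD = `noise_sd_frac` × noiseless
  trace mean, matching how the detector threshold is referenced to the
  track mean.  Traces are floored at a tiny positive value so fold
  amplitudes stay defined.

## Cohort priors

Per-subset priors are a *qualitative* emulation of the published group
structure, not estimates of real distributions: HECs pulse least
(pulsing fraction 0.32, baseline 40 a.u.), BCs have the shortest periods
and largest folds (0.44, baseline 45, fold up to 2.2), IAHCs the highest
baselines (0.51, baseline 50) and essentially all divisions (mitosis
probability 0.14 vs 0.003 in BCs and 0 in HECs).  Period priors are
categorical over 1–4 h; half-lives uniform in 60–120 min; 77% of cells are
ventral; track lengths uniform in [8, n_frames] frames within a 48-frame
(12 h), 15-min-interval movie; detection noise defaults to 5% of the trace
mean.  All of these are exposed in `SubsetPrior`/`CohortConfig`.

Randomness uses one root seed with per-cell substreams keyed by
`[seed, subset_index, cell_counter]`, so identical configs are
bit-identical and growing a cohort never reshuffles existing cells.

## Rendering

Cells become anisotropic Gaussian blobs (sigma 3, 3, 2.5 µm in x, y, z)
whose support is the 2-sigma ellipsoid; the amplitude is solved so that
integrated blob intensity per support voxel equals the cell's trace MFI
exactly.  Volumes add a flat background (2 a.u.) and Poisson–Gaussian
detection noise (gain 5, read SD 0.5).  Default geometry: 96×96×16 voxels
at 0.76×0.76×2.0 µm.  Rendering positions are drawn from a jittered grid
spaced ≥ 14 µm so blobs stay separable; a cohort larger than the grid
capacity logs a warning because blobs may then overlap.  No optics (PSF,
spectral bleed-through) are simulated: passing end-to-end tests shows the
*pipeline* (segment → track → link → extract) is faithful, not that
segmentation would survive real point-spread functions, debris or
touching cells.

## Segmentation, tracking, linkage

Segmentation is 26-connected components of voxels strictly above the
intensity threshold, with a minimum object size of 10 voxels; centroids
are intensity-weighted centres of mass (robust for blob-like objects and
consistent on both sides of the linkage).  Tracking is greedy
mutual-nearest-neighbour linking between consecutive frames — globally
closest pair first, links beyond 5 µm (default) rejected, no gap closing —
so the "≥ 10 *consecutive* frames" QC filter keeps its meaning.  Each
tracked position is then assigned the closest segmented object within a
maximum range of 5 µm (ties broken by lowest object id), and each track's
trace is restricted to its longest consecutively linked run.  The
volumetric MFI of a cell is the intensity sum over its member voxels
divided by the voxel count.

## QC rules

Kept tracks have ≥ 10 consecutive frames, no annotated division (divisions
are annotations — ground truth in synthetic data, user-supplied for real
data; automatic mitosis detection is out of scope), and no drift.  The
original bleaching/drift criterion was visual; the quantitative stand-in
flags a track when |Spearman rho of MFI vs time| ≥ 0.8 **and** the
Theil–Sen trend change over the track is ≥ 30% of the trace mean.  Both
arms are needed: pulsing alone gives low rank correlation, and monotone
jitter alone gives a small net change.  The rule is invariant to positive
rescaling.  Thresholds are package decisions, exposed in `QCConfig` and
recorded in report metadata, not inferences of the original analysts'
visual judgement.

The windowed expression level `mean_mfi_3_12` averages the 3rd–12th
samples *of the track* (ten values; the first two samples are skipped
against settling artefacts).  Window positions are track-relative so the
quantity is defined for cells first tracked after movie start; tracks
shorter than 12 samples report NaN.

## Peak detector

Delta-threshold alternating-extrema scan with
`delta = threshold_frac × mean(track)`, default 15%.  Semantics: a
candidate maximum is emitted as a peak once the trace falls more than
delta below it, **and** only after a rise of more than delta above the
preceding running minimum — a significant maximum must exceed *both*
neighbouring minima by more than the threshold.  Consequences: track
endpoints are never peaks; a trailing unconfirmed maximum is discarded; on
plateaus the first sample is the extremum; between successive peaks
exactly one minimum is registered.  The preceding trough reported with
each peak is the normative interval minimum (lowest MFI since the previous
peak or track start), which coincides with the scan's registered minimum
under alternation.  Periods are differences of adjacent peak times; the
histogram assigns period p to the nearest whole hour with the boundary
going up (bin h covers [h−0.5, h+0.5); 1.5 h counts as 2 h), bins running
from 1 h upward.  Amplitude is a ratio (fold change), never a difference.

At the default threshold with 3% measurement noise the delta equals 5
noise SDs, which keeps the false-call probability on flat 48-frame traces
near 3% (the one-sided variant that confirms a first peak by its fall
alone triples that rate, which is why the symmetric rule is used).

## Statistics

Group summaries report n, mean, SD and SEM per metric, and period-bin
fractions over cells with ≥ 2 peaks (fractions per group sum to 1).
Comparisons wrap Mann–Whitney U (midranks on ties), two-sample t, and
one-way ANOVA with pairwise t post-tests; Bonferroni adjustment multiplies
each pairwise p by the number of post-hoc pairs, capped at 1.  Groups with
fewer than two observations raise rather than silently falling back.

Period-frequency error bars: cells contributing at least one period are
resampled with replacement (`n_boot` default 2000); per bin the SD of the
resampled frequency is reported and the error bar is 2 × SD.  Cell-level
nonparametric resampling is the primary method; resampling per-cell
residuals around the mean frequency vector is available as
`method="residuals"`, and the method used is recorded in the table's
attrs and in report metadata.  With one period per cell the bootstrap SD
approaches the binomial `sqrt(p(1-p)/n)`, which the tests use as a
closed-form sanity bound.

## Problem sizes and determinism

The test suite and validation script use desk-scale problems chosen to
exercise every code path with comfortable statistical margins: the
detector-validation benchmark uses 200 traces × 48 frames (≈ 1,200
ground-truth peaks); oracle equivalence checks 1,000 random traces of
length ≤ 30 against an exhaustive O(n²) reference; the false-positive
control uses 1,000 flat noisy traces; the end-to-end image test renders a
40-frame 72×72×14-voxel movie.  Every stochastic component takes an
explicit seed (numpy `default_rng` substreams), so all results in the
README are exactly reproducible.

## Known limitations

- Subset priors are placeholders with the right orderings, not fitted
  distributions; group-level numbers from the simulator should never be
  read as predictions of real-tissue values.
- Segmentation/tracking are conventional stand-ins for proprietary tools
  whose parameters were never published; no attempt is made to reproduce
  those tools' exact behaviour.
- No deconvolution, drift correction, PSF simulation, multi-channel
  rendering or tissue geometry; the no-op `stabilize_series` hook marks
  where a correction step would slot in.
- Mitosis and subset identity are annotations, not detected.
- Periodicity is measured only as inter-peak intervals (no spectral or
  autocorrelation estimate, no detrending before detection).
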