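# pulsetrace

Quantification of pulsatile transcription-factor reporter dynamics in
single cells from 3D+time fluorescence imaging.

During the endothelial-to-hematopoietic transition (EHT) in the embryonic
aorta, single cells expressing a fast-maturing fluorescent reporter of
Gata2 transcription (half-life 60–120 min) show pulsatile changes in mean
fluorescence intensity (MFI). `pulsetrace` implements the full desk-side
analysis for such experiments, for imaging labs that track single cells in
confocal time-lapse volumes:

- **synthetic cohorts** (`pulsetrace.synthetic`) — pulsatile reporter
  traces and rendered TIFF volume series with known ground truth, emulating
  three EHT subsets (HEC, BC, IAHC) with subset-specific baselines, pulse
  periods (~1–3 h) and fold amplitudes, 15-min sampling, detection noise,
  rare mitosis dips and optional photobleaching;
- **volumes** (`pulsetrace.volumes`) — TIFF series I/O with a voxel-size
  sidecar, 26-connected 3-D segmentation with intensity-weighted centres of
  mass, and greedy mutual-nearest-neighbour centroid tracking over
  consecutive frames;
- **trace extraction** (`pulsetrace.extraction`) — assignment of each
  tracked position to the closest segmented object within 5 µm, and
  volumetric MFI traces (intensity sum / voxel count per cell per frame);
- **QC** (`pulsetrace.qc`) — the inclusion rules applied before pulse
  analysis: ≥ 10 consecutive tracked frames, exclusion of dividing cells,
  and a quantitative bleaching/drift rule;
- **pulse analysis** (`pulsetrace.pulse`) — delta-threshold peak detection
  and the pulse descriptors; and
- **statistics** (`pulsetrace.stats`) — group summaries, rank-sum / t /
  ANOVA comparisons with Bonferroni post-tests, and cell-level bootstrap
  error bars (2 × SD) for pulse-period frequency distributions.

## The peak detector

For a track with MFI series $y_1,\dots,y_n$ the detector uses an
alternating-extrema scan with
$\delta = f \cdot \overline{y}$, where $\overline{y}$ is the arithmetic
mean of the whole track and $f = 0.15$ by default.  A local maximum is a
significant peak only if it exceeds **both** neighbouring minima by more
than $\delta$: a rise of more than $\delta$ above the preceding running
minimum must be seen before the candidate, and the trace must subsequently
fall more than $\delta$ below it.  Track endpoints are never peaks.  For
each peak, the preceding trough is the lowest MFI since the previous peak
(or the track start), and

- pulse period = time between adjacent peaks (binned to the nearest hour),
- trough-to-peak amplitude = peak MFI / trough MFI (fold change),
- peak counts are normalised to peaks per 10 frames (2.5 h at 15-min
  sampling) to correct for track-length differences.

Because $\delta$ scales with the track mean, peak calls are invariant to
positive rescaling of a trace.

## Worked example

Simulate a 45-cell cohort, run QC + peak detection, and summarise:

```sh
pulsetrace simulate --cells 15,15,15 --seed 4 --out traces.csv
pulsetrace analyze --traces traces.csv --out profiles.csv --exclusions-out excl.csv
pulsetrace report --profiles profiles.csv --group subset --boot 500 --seed 7 --out report
```

which prints

```
wrote 45 traces to traces.csv
profiled 42 cells (3 excluded) -> profiles.csv
```

The three excluded cells are dividing IAHCs (`excl.csv`, reason
`mitosis`).  `profiles.csv` holds one row per cell, e.g.

```
cell_id,subset,side,n_frames,n_peaks,peaks_per_10_frames,mean_mfi_3_12,...
HEC_000,HEC,dorsal,33,1,0.303,45.90,...
```

`report/group_summary.csv` shows the subset structure the simulator's
priors encode and the pipeline recovers: windowed MFI (mean over track
positions 3–12) rises from HECs (40.3) through BCs (44.5) to IAHCs (49.3),
while BCs pulse most (1.19 peaks per 10 frames vs 0.50 in HECs and 0.40 in
IAHCs).  `report/period_frequencies.csv` carries the bootstrap error bars
for the pulse-period histogram (error bar = 2 × bootstrap SD).

The same pipeline runs from image volumes instead of traces:
`pulsetrace simulate --render-dir vols ...` writes a TIFF series, and
`pulsetrace extract --volumes vols --out traces.csv` segments, tracks,
links at 5 µm and extracts MFI traces.

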