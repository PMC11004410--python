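# transcyt

Quantification machinery for lipoprotein transcytosis experiments across
endothelial cells, built around SR-B1-mediated uptake assays: detection of
sub-resolution vesicles in TIRF movies, exocytosis-event calling from
subdiffusive tracks, z-stack internalization and en-face aorta deposition
quantification, equilibrium binding (Kd) fitting, pull-down band ratios,
and a blank-corrected all-pairs fold-change statistic with a binomial
sign-test null. A seeded synthetic-data module generates ground-truth
labeled inputs for every modality, so the whole pipeline is testable
against known answers.

## Who this is for

Groups quantifying receptor-mediated lipoprotein transport from microscopy:
the raw data are TIRF time-lapses (vesicle fusion at the basal membrane),
confocal z-stacks (per-cell internalized fluorescence), dose-response
tables (binding affinity), and band-intensity tables (pull-downs). The
package turns each into calibrated numbers with explicit, configurable
thresholds.

## The core methods

**Exocytosis-event calling.** Each movie frame is background-corrected by
a local median filter and thresholded 15% above its mean intensity;
8-connected components are kept if their mask's equivalent-circle diameter
lies in 60–200 nm and circularity 4πA/P² exceeds 0.2. Detections are
linked frame-to-frame by optimal assignment under the quadratic cost
(Δr/s_r)² + (ΔI/s_I)². Per track, the time-averaged MSD(τ) is fit in
log-log over early lags to get the anomalous exponent α; only subdiffusive
tracks (α < 1, stationary/docked) are eligible. A track is an exocytosis
event when its intensity falls by ≥ 3 SD over its last 5 time points and
no detection reappears near its terminus for 5 frames. Field-of-view
counts are corrected by subtracting the mean count of no-ligand control
movies.

**All-pairs fold-change statistic.** For replicate k with blank (cells
alone), control and condition cells,

    Change_cond_k = { (cond_i − mean(blank_k)) / (ctrl_j − mean(blank_k)) }  over all i, j,

pooled across replicates into Change_cond (Change_ctrl likewise). The
fold change is the cross-division of every Change_cond point by every
Change_ctrl point; its median, 68% and 95% percentile bands are reported.
The p-value is the lower binomial tail P(X ≤ round(f_fail·n_trial)) with
X ~ Bin(n_trial, ½), where f_fail is the fraction of points contradicting
the median's direction and n_trial is the number of independent condition
cells — not the (highly dependent) number of pairs.

**Binding isotherm.** response(c) = baseline + amplitude·c/(Kd + c), fit
by nonlinear least squares with a fixed Hill coefficient of 1; ligand
depletion is negligible at a 50 nM labeled target against micromolar Kd.

## Worked example

`examples/01_tirf_event_detection.py` simulates a 15 s movie with 5
diffusing, 5 docked and 5 exocytosing vesicles at mild camera noise and
runs the full pipeline:

```
simulated 150 frames, 15 vesicles, 5 true exocytosis events
linked 15 tracks, 13 subdiffusive (alpha < 1)
called 5 exocytosis events:
  track 0: fusion at frame 116 (11.6 s), drop 31 SD
  ...
```

All five planted fusion events — and nothing else — are recovered; each
line gives the fusion frame and the intensity drop in units of the track's
baseline SD. The other examples cover the fold-change statistic (a
simulated competitor halving uptake over 6 replicates × 40 cells returns
median 0.49, p ≈ 5e-42), Kd fitting (true 6.87 µM → fitted 6.88 µM on one
noisy 16-point curve), z-stack/aorta quantification, and pull-down ratios.

There is also a thin CLI (`transcyt simulate-tirf`, `transcyt
detect-events`, `transcyt stats-foldchange`, `transcyt fit-kd`, …), each
subcommand writing its artifacts plus a run manifest (config hash, seed,
versions) for reproducibility.

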