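# Methods

This note records the models, parameter choices and numerical conventions
behind `transcyt`, and what the synthetic benchmarks do and do not show
about real data.

## TIRF movie model and event detection

### What the simulator emulates

A TIRF acquisition images ~100 nm above the coverslip, so a cargo vesicle
appears as a diffraction-limited spot that vanishes on fusion with the
basal membrane. `simulate_tirf_movie` renders three vesicle classes as 2D
Gaussians (amplitude 200, PSF σ = 1.5 px, background 100, additive
Gaussian read noise, default σ = 2):

- **diffusing** — Brownian steps with per-axis variance 2D per frame
  (D = 0.05 px²/frame), reflected at the field margin. Expected MSD slope
  α ≈ 1.
- **docked** — independent per-frame jitter about a fixed anchor, clipped
  at the confinement radius (1 px). The MSD saturates at the first lag,
  so α ≈ 0; any confined-motion model with α < 1 would exercise the same
  classifier branch, and the radius is a config knob.
- **exocytosing** — docked motion until a fusion frame drawn uniformly
  from `event_frame_range`; on that frame the emitted amplitude drops to
  25% (one visibly dim detection, completing the drop within 2 frames) and
  is zero afterwards, never returning. Fusion is modeled as an intensity
  extinction, not a kinetic release profile.

Movie geometry defaults to the assay's acquisition: 150 frames at 100 ms
(a 15 s window). Initial positions are dart-thrown with a 14 px minimum
separation so that ground-truth correspondence stays unambiguous; the
seed fixes every draw, and identical seeds give bit-identical movies.

Features of real data deliberately not modeled: photophysics (blinking,
bleaching), Poisson shot noise and camera gain, 3D PSFs, drift, and
vesicle density high enough for frequent occlusions. Passing benchmarks
therefore demonstrate correctness of the *algorithmic chain* — detection,
linking, classification, event logic — under controlled conditions, not
robustness to every nuisance of live-cell imaging.

### Detection cascade

Per frame: (1) local background = median filter over a 15 px window
(spots of ≤ ~8 px diameter occupy a minority of any window and are
ignored by the median; the result is floored at 0); (2) binary mask =
pixels strictly above (1 + 0.15) × mean of the background-subtracted
frame — the mean is taken *after* subtraction, matching the order of the
processing chain; (3) 8-connected components, intensity-weighted sub-pixel
centroids; (4) filters: equivalent-circle diameter of the mask within
60–200 nm and circularity > 0.2.

Two conventions deserve emphasis. The 60–200 nm "size" is below the
diffraction limit, so it is interpreted as the equivalent diameter of the
*thresholded mask* in calibrated units — the only size computable from a
thresholding pipeline — which makes `pixel_size` a required calibration
(simulation default 20 nm/px places masks of typical spots mid-band).
Circularity 4πA/P² depends strongly on the perimeter estimator near the
0.2 cut for thin shapes: the default is the Crofton (4-direction)
perimeter, with the Freeman chain estimator available; values are clamped
at 1.2 because pixelation can push small round masks above 1. A 1-px-wide
line must be ~17 px long before Crofton circularity falls below 0.2.

### Linking and classification

"Most probable" links are realized as the minimum of the Gaussian
log-likelihood cost (Δr/s_r)² + (ΔI_peak/s_I)² over one-to-one frame-pair
assignments (scipy's Hungarian solver), with links beyond 4 px forbidden
via a large sentinel — the optimum therefore maximizes the number of
admissible links, then minimizes cost. Defaults s_r = 1 px and s_I = 20
intensity units are tied to the simulator's calibration (jitter ≲ 1 px,
pixelation-induced peak flicker of a few percent of the 200-unit
amplitude). Linking is per frame pair (no gap closing by default; the
5-frame disappearance logic lives in event calling, not the linker).
Tracks shorter than 10 frames are discarded — twice the 5-point drop
window.

MSD is time-averaged within the track; α is the least-squares slope of
log MSD vs log τ over lags 1–5 (the shortest window consistent with the
minimum track length; the fit is exact on power laws). Lags with MSD below
1e-12 px² are excluded, and fewer than 3 usable points leaves α undefined
(the track is then excluded from event calling). Subdiffusive means
α < 1, which is the operational definition of "stationary / potentially
docked".

### Event criteria

A subdiffusive track yields at most one event. The intensity SD is
computed over the series *excluding* the last 5 points, the drop is
(median of those earlier points) − (final value), and an event requires
drop ≥ 3 SD; a floor of 1e-9 × the series scale keeps noise-free constant
series from dividing by zero. Median-based baselining makes the test
robust to a skewed flicker distribution. The no-reappearance check scans
the 5 frames after the track's end for any detection within 2 px
(2 × s_r) of the terminal position; tracks ending within 5 frames of the
movie end are censored (the check cannot be evaluated), so persistent
docked or diffusing vesicles never contribute events. Whether the decline
must be monotone across the 5 points is not constrained — a net drop is
what is tested.

Per-condition counts subtract the mean raw count of no-ligand control
movies; corrected counts may be negative and are averaged as-is.

## Per-cell fluorescence model and the fold-change statistic

### Generator

Per-cell integrated fluorescence is lognormal. The decades-wide (1e4–1e6)
spread seen in primary cells is split into a between-replicate shift of
the replicate's log10-mean (SD 0.35 — passage-to-passage variability) and
a within-replicate log10 SD of 0.13; blank (autofluorescence) cells sit
two decades below control. This split matters: the statistic works in
within-replicate ratios precisely because replicate-level shifts cancel,
and the generator reproduces both the observed overall span and that
cancellation. Defaults are 6 replicates × 40 cells per group, the scale of
the internalization experiments the statistic was designed for. The
condition multiplies control-law draws by `true_effect` (1 = null).

### Statistic

`change_set` forms, per replicate, all (condition − blank mean) /
(control − blank mean) pairs and pools replicates without reweighting.
Asking for the control's own set includes the i = j pairs, making
Change_ctrl inversion-symmetric with median exactly 1. Pairs with a
non-positive blank-corrected denominator are excluded and counted in the
result's diagnostics (such cells are indistinguishable from
autofluorescence and cannot serve as a denominator).

`pairwise_fold_change` cross-divides the two pooled sets. The full
product is computed exactly up to a cap (default 1e6 points); beyond it,
the cap's worth of pairs is drawn uniformly with a seeded generator —
at 1e5+ points the Monte-Carlo error on the median is far below the
reported precision. Percentile bands are the 2.5/97.5 and 16/84
percentiles of the point set; the "95% CI" of a report is that percentile
band of fold-change points, a descriptive spread, not a sampling CI of
the median.

The binomial p-value uses success probability ½ — the sign-test null that
a fold point is equally likely to fall on either side of 1 — with
k = round(f_fail · n_trial) and the lower tail P(X ≤ k). A
probability-mass mode (`p_mode="pmf"`) is retained for comparison, but
the tail integrates evidence the way a conventional p-value does and is
the default. n_trial is Σ_k Ncells_cond(k): each condition cell is reused
against every control cell, so the pair count wildly overstates the
information content, while the condition-cell count is a defensible
independent-trial count. Median exactly 1 reports direction "none" and
p = 1 by convention.

Display rounding follows the reporting style of the assay: medians and
log2 to two decimals; the fold reduction (1/median) to two decimals below
2 and one decimal at or above 2 (0.51 → 1.96-fold, 0.347 → 2.9-fold). Raw
unrounded values are always carried alongside.

### Calibration benchmarks

Null runs (true_effect = 1, default conditions) must keep the median in
[0.9, 1.1] with p > 0.05 in ≥ 90% of 200 seeded runs; true_effect = 0.5
at 3 replicates × 40 cells must land the median in [0.45, 0.55] with
p < 0.01 in ≥ 95%. Both pass with margin under the generator defaults
above. The benchmark uses a 1e5-point cross-division cap per run to keep
200 runs fast; the cap only adds negligible Monte-Carlo noise to the
median.

## Binding isotherm

Single-site occupancy with a fixed Hill coefficient of 1:
response(c) = baseline + amplitude · c / (Kd + c). Ligand depletion is
ignored — the labeled target is at 50 nM against micromolar Kd, putting
the depletion error below 1% — so the quadratic binding form is out of
scope. Initialization: baseline = min response, amplitude = range, Kd =
concentration nearest the half-range response; the Kd standard error
comes from the fit covariance. Non-convergence returns a flagged fit with
the solver's message rather than any fallback value. The concentration
design mirrors the thermophoresis assay: a 16-point geometric series from
1 nM to 8 µM. Note that a ~7 µM Kd is only ~54% saturated at the top of
that series, so single-curve Kd errors are materially larger than the 2%
response noise — recovery benchmarks therefore test the *median* over 100
curves (within 5% of truth).

## Z-stack, aorta and pull-down quantification

Integrated density is the raw sum over the ROI across all slices, with no
background subtraction at that step. Volume normalization divides by
ROI area × slice count — deliberately the slice *count*, not a physical
z-interval, matching how the source assay computes cell volume; physical
calibration is carried on the stack for callers who want it.

Aorta deposition sums max(0, pixel − background) over all planes of the
LDL channel and divides by the marker-positive (CD31-like) area in
pixels. The background level comes from a no-LDL control acquisition as
mean + k·SD with k = 2 by default (the source procedure says only
"subtract the background"). The tile simulator plants Gaussian deposits
inside a marker band and returns their exact integrated signal, so the
noise-free quantification recovers signal/area to float precision.

Pull-down lanes normalize the captured-protein band by the immobilized
receptor band and then by the input band; a variant's mean normalized
capture over its lanes is divided by the reference's. The ratio is
invariant to rescaling all bands of a blot by a common factor.

## Problem sizes and determinism

Benchmarks run at: 20 noise-free movies (96×96×150) for event recovery
plus a 4-seed noise ladder sharing a scaled unit-noise field; 200 + 200
statistic calibration runs; 100 binding curves per Kd recovery; 1e4-step
random walks for MSD checks. Every stochastic component takes an explicit
seed (numpy `default_rng`); identical seeds give identical results on all
paths, including the subsampled cross-division.

## Known limitations

- Linking is frame-pair-local; no multi-frame global optimization,
  motion-model switching, or gap closing. Dense fields with frequent
  crossings will fragment tracks (fragments without a terminal drop never
  become events, so the failure mode is conservative for event counting).
- The α classifier at 150 frames has ~0.1 sampling spread for genuinely
  Brownian tracks; single diffusing vesicles occasionally dip below 1.
  Event calling tolerates this because persistent tracks are censored.
- The detector measures mask-derived size, which depends on the threshold
  and PSF; it is a filter, not a particle-sizing method.
- The sign-test null treats condition cells as exchangeable across
  replicates after blank correction; strong within-replicate correlation
  beyond the modeled shift would make n_trial optimistic.
- The isotherm assumes one site and no depletion; cooperative or
  depletion-regime data need a different model.
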