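# Methods

This note documents the model, the processing choices, the synthetic
data the package validates itself on, and the places where the design
was genuinely open. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Davis model (`vecmro.davis`)

All quantities are *fractional* changes from baseline; the ratio form
r = 1 + Δx/x₀ is used inside every power term. This is the canonical
Davis/Hoge formulation: with ratios, the forward model and its
inversion are exact algebraic inverses (verified to ≤ 1e-10 over random
parameter triples), and the inversion is regular at Δ = 0. Writing the
power terms on the bare fractional changes instead would make the
inverse singular at zero change and break invertibility.

Constants: α = 0.38 (flow–volume coupling exponent) and β = 1.3
(deoxyhemoglobin susceptibility exponent appropriate at 3 T). Both are
configurable (`DavisParams`) but are never fitted. M is carried as a
fraction internally; percent appears only at reporting boundaries
(`GasSummary.m_percent`, `EvokedMeasures` fields), avoiding
double-scaling bugs.

Domain handling is explicit rather than silent: non-positive ratio
bases raise a domain error naming the offending argument; ΔBOLD ≥ M
(signal above the calibration ceiling) and M ≤ 0 raise calibration
errors; n = ΔCBF/ΔCMRO₂ raises rather than returning infinity when the
denominator is zero.

## Evoked pipeline (`vecmro.evoked`)

Processing order for a task run: despike → surround subtraction
(perfusion echo) / pairwise averaging (BOLD echo) → spatial smoothing →
temporal high-pass → boxcar GLM → ROI selection → Davis inversion.

**Despiking.** Detection compares each sample with a 3-point running
*median*; the residual scale is 1.4826 × median |residual| and points
beyond k = 3 scales (configurable) are replaced by the mean of their
temporal neighbours. A running median rather than a running mean is
used because the mean-based residual is itself contaminated by the
spike on short windows. The median-based rule leaves clean block
designs and clean label/control alternation exactly untouched (their
running-median residuals are zero or uniformly equal), which is what
lets noiseless simulations pass the operator unchanged.

**Surround subtraction.** output_t = s_t · (x_t − (x_{t−1}+x_{t+1})/2)
with the parity sign s_t chosen so output = control − label; endpoints
use their single neighbour. Shared linear drift cancels exactly at
interior points.

**High-pass filter.** Implemented as projection onto the orthogonal
complement of a low-frequency Slepian (DPSS) subspace with
time-half-bandwidth NW = 0.85 · cutoff · N · TR and round(2 NW)
tapers, demeaned so constants pass exactly. For the default 0.0039 Hz
cutoff on a ~600 s run this attenuates sinusoids below ~0.003 Hz by
more than 90 % at every phase while losing < 5 % at the task frequency
(~0.0106 Hz) and above. The subspace is taken slightly narrower than
the nominal cutoff because a finite 600 s window cannot both annihilate
everything up to 0.0039 Hz and leave 0.0106 Hz untouched; the band
edge is a transition region. Any filter satisfying these attenuation
bounds would be interchangeable here.

**Matched regressors.** The GLM design is [intercept, task regressor],
where the task boxcar is passed through the *same* temporal operators
as the data: pairwise averaging for the BOLD echo, the
surround-subtraction resampling for the perfusion echo (label
positions carry u_t, control positions the neighbour mean), and the
same high-pass projection. Because all operators are linear and
constant-preserving, a noiseless simulated run is recovered exactly
(the end-to-end tests require ≤ 1e-6); without regressor matching the
estimates would be biased by a few percent from block-edge mixing.
The boxcar is not convolved with a hemodynamic response function —
block durations (60 s) are long against the HRF and the reference
analysis used a plain boxcar. Percent signal change is
100 · β_task/β_intercept; the t-statistic of β_task feeds ROI ranking
(zero-residual fits get an unbounded t, which the quantile-based ROI
rule handles through inclusive ties).

**ROIs.** Structural ROI = manually drawn occipital mask ∧ grey-matter
partial-volume ≥ 0.80 (inclusive). Task functional ROI = overlap of
the top-5 % BOLD and top-5 % CBF t-values within the structural ROI;
quantile thresholds use inclusive ties, making the rule deterministic.
An empty overlap raises an explicit error telling the caller to relax
the fraction. All volumes must share one voxel grid; registration is
assumed done upstream and a grid mismatch is a hard error. Masks and
indices are 0-based; the slice axis is the third array axis.

**Gas challenge.** Baseline means are taken over the room-air window
and hypercapnic means over the final window after discarding the first
two minutes post-switch (flow stabilisation). One volume adjacent to
every window boundary is additionally dropped because the derived
series mix neighbouring volumes. The ROI is the overlap of the
top-15 % ΔBOLD_hc and ΔCBF_hc voxels within the structural mask,
escalated to 20 % when the overlap is smaller than `min_voxels`
(default 10); an empty overlap at the fallback raises a calibration
failure — the same situation the reference analysis resolved by manual
escalation for one participant. M is computed from the ROI means of
the voxelwise fractional-change maps. The high-pass filter is *not*
applied on the gas path: the hypercapnic step is itself the
low-frequency contrast of interest and window means would be distorted
by any filter at or below the step frequency.

**Evoked measures.** veBOLD/veCBF are ROI means of the percent-change
maps. veCMRO₂ and ve*n* are computed voxelwise inside the ROI and then
averaged (default), with voxels violating ΔBOLD < M or 1 + ΔCBF > 0
skipped and counted; the alternative (average the Δs first, invert
once) is available as `averaging_mode="roi_mean"`. The two agree
exactly on uniform fields and differ in general because a mean of
ratios is not a ratio of means — this is also why a group-level
inversion of group-mean changes does not reproduce the mean of
participant-level veCMRO₂ values. No extra positivity filter is
applied beyond the ROI construction (which already selects positive
task responses); dropping negative-ΔCMRO₂ voxels explicitly was
considered and rejected as an undocumented second filter.

## Lesion metrics (`vecmro.lesions`)

Hyperintensity threshold: per slice (third axis), over in-brain voxels
only, flag intensity ≥ mean + 1.25 SD. Computing the statistics in-brain
matters: zero background would otherwise deflate the mean and corrupt
the threshold. Slices with zero SD flag nothing. The rule is invariant
to per-slice affine intensity rescaling with positive gain.

Distinct lesions are connected components of the mask with volume
≥ 3 mm³; the default connectivity is 26 (faces, edges and corners — so
diagonally touching blobs count as one lesion), configurable to 18
or 6. Burden is |mask| · voxel volume (mm³) and 100 × that over the
uncorrected white-matter volume. Dice κ = 2|A∩B|/(|A|+|B|) quantifies
inter-rater agreement; κ > 0.70 is annotated as excellent agreement in
reports but never used as a gate. Manual false-positive pruning is out
of scope; the API instead accepts rater-edited masks and recomputes
the metrics, which is what enables the Dice comparison.

## Classification (`vecmro.classify`)

Outlier screens are single-pass, per group, with statistics from the
unfiltered group: ± 2 SD from the group mean for plain group
comparisons, ± 3 scaled MADs (consistency constant 1.4826) from the
group median for classification modelling. When the MAD is zero any
value different from the median is removed.

The classifier is binary logistic regression on one predictor,
maximum likelihood via a damped Newton iteration. Complete separation
is detected up front (the classes' supports are disjoint) and replaced
by a deterministic midpoint-threshold rule: the MLE is unbounded under
separation, but every reported statistic is an accuracy, which depends
only on the decision boundary, so the fallback changes nothing
scientifically while keeping the computation finite and reproducible.
Ties at P = 0.5 predict the patient class. The solver is vectorised
over thousands of fits at once (all LOOCV folds of all permutations in
one call), which is what keeps 10⁶-refit resampling runs in seconds;
it is cross-checked against statsmodels and an independent
NLL-optimiser oracle in the tests.

*Within-sample accuracy* gets a stratified BCa bootstrap interval:
resamples draw within each group with replacement, preserving the
exact group sizes (10/13 → 43.5 %/56.5 % composition). The bias
correction z₀ uses the bootstrap CDF at the observed statistic with
ties counted half — accuracy is heavily discrete and a one-sided count
would be systematically biased; the acceleration comes from a
leave-one-out jackknife; interval endpoints are order statistics
(left-continuous inverse CDF) of the bootstrap distribution. A
predictor is significant within-sample when the lower limit exceeds
0.50. If all bootstrap statistics coincide the interval degenerates to
that point.

*Out-of-sample accuracy* is leave-one-out cross-validation; a training
fold containing a single class predicts that class. Its significance
is a label-permutation p-value, p = (#{acc_perm ≥ acc_obs} + 1)/(K+1)
with K = 5,000 by default — the small-sample correction of the
permutation-test literature; "better than" is read inclusively
(configurable to strict, and the raw percentage is available by flag).
The inclusive reading plus the +1 correction make the test
conservative for discrete statistics: under the null its rejection
rate at α = 0.05 sits below 0.05 (the acceptance script measures it at
roughly 0.02–0.06 over 200 null predictors), which is the cost of
never anti-conservative inference at n = 23. Benjamini–Hochberg
adjustment across predictors uses the standard step-up procedure (via
statsmodels). Group comparisons are Welch unequal-variance t-tests
(fractional Satterthwaite df, via scipy) and Cohen's d with the pooled
n−1-weighted SD.

`run_full_screen` drives the whole screen per predictor column,
ranks by within-sample accuracy (name as tie-break), logs skipped
predictors (< 2 per class after filtering), and derives every
predictor's random stream from one root seed, making the output
bit-reproducible.

## Synthetic data (`vecmro.synth`)

The generators define the study conditions the package validates
itself under; their defaults are the study-scale values.

* Task runs: 6 × 60 s visual-stimulation blocks, rest jitters drawn
  from {32, 34, 36, 38, 40} s, TR = 4 s; the run length follows from
  the draws rather than being forced to a fixed duration. The BOLD echo
  is a baseline scaled by (1 + ΔBOLD · boxcar); the perfusion echo is
  an additive control − label difference modulated by (1 + ΔCBF ·
  boxcar). No kinetic ASL model is simulated because the pipeline only
  uses relative change of the difference signal.
* Gas runs: 4 min room air, 6 min hypercapnia; ΔBOLD_hc is derived
  from (M, ΔCBF_hc) through the forward model with unchanged CMRO₂, so
  processing must return exactly the generating M. Signals ramp across
  the discarded two-minute stabilisation window, which the windowing
  must ignore. The default hypercapnic CBF rise is 150 %, in the range
  of the study's group values.
* Noise: additive white Gaussian, parameterised by a contrast-to-noise
  ratio `snr` = (signal-change amplitude)/(noise SD) per echo. The
  referent matters: tying noise to the evoked contrast makes "SNR 20"
  mean the same thing for BOLD and for the much weaker ASL difference
  signal.
* FLAIR phantoms: rectangular lesions at mean + 4 SD over a *bounded*
  two-level (mean ± SD) background texture. A Gaussian background
  would scatter voxels above any ~1 SD threshold and make exact lesion
  recovery impossible by construction; the bounded texture has the
  intended SD while guaranteeing that the 1.25 SD slice rule flags
  exactly the planted lesions. Lesions must not touch (26-neighbour
  sense), or the spec is rejected.
* Predictor tables: per-group normal draws; the default spec carries
  the study-scale cfMRI group means with SD = SEM · √n for n = 10/13
  (e.g. veCMRO₂ 9.59 ± 2.85 vs 17.85 ± 7.10). Equal-mean null
  predictors support calibration tests; a mean/SD-matched log-normal
  option produces the skewed outliers that exercise the MAD screen.

What the generators deliberately do not emulate: motion, physiological
noise spectra, coil inhomogeneity, registration error, partial-volume
mixing, and spatially structured responses. Passing tests therefore
demonstrate correctness of the computation under the stated signal
model, not robustness to every artifact of real acquisitions.

## Problem sizes and numerics

The validation runs use an 8 × 8 × 4 voxel grid (3.44 × 3.44 × 5 mm),
150-volume runs, 100-seed noise studies, 200 null predictors × 500
permutations for the calibration study, and 20,000 bootstrap resamples
for the enumeration comparison — sizes chosen so each stage's property
is sharply testable while the whole suite runs in well under a minute
of compute per module. Exact-recovery assertions use 1e-6 (pipeline)
and 1e-10 (pure algebra) tolerances; quantile thresholds use inclusive
ties; all random streams descend from a single seed via
`numpy.random.SeedSequence`.

## Known limitations

* Absolute CBF quantification (mL/100 g/min) is out of scope; all
  quantities are relative changes, which is all Eqs. of the model use.
* Registration, skull stripping, tissue segmentation, and DTI
  processing are upstream of this package; their outputs enter as
  already-aligned volumes or as numeric predictor columns.
* The permutation test's conservativeness at small n is inherent to
  the inclusive-tie estimator, not a bug; strict counting is available
  but is anti-conservative under heavy ties.
* Only single-predictor models are implemented; multivariable
  combinations are an explicit non-goal.
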