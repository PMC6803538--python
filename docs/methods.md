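# Methods

`neurointent` implements a complete analysis chain for a bimodal
EEG + fNIRS action-observation experiment: three hand–cup interaction
conditions — grasp-to-drink (Sd), grasp-to-move (Sm), and an ambiguous touch
(Su) — each shown with seven cup colors, four repetitions per cell, giving
84 trials in four sessions of 21 (16 s per trial: 6 s pre-rest, 0.5 s cue,
3.5 s observation, 6 s post-rest; 120 s between sessions; 28.4 min total).
Because no recordings of this kind are publicly deposited, the package pairs
the analysis chain with a synthetic-data generator that emulates the
paradigm with known ground truth; every validation statement in the test
suite and the acceptance script is a recovery of something the generator
planted.

## Synthetic recordings

**EEG (64 channels, 1 kHz default).** Background activity is per-channel
1/f^α noise (α = 1, 6 µV), a 10 Hz alpha rhythm with random per-channel
phase (3 µV), and white noise (1 µV). Each trial adds, time-locked to
observation onset:

* a cue-locked negative deflection on the 13 most posterior channels
  (−6 µV Gaussian, center +50 ms, width σ = 35 ms) — the visual response to
  the cue that precedes the observation period by 500 ms, so the trial
  average is negative at t = 0;
* a condition-scaled component (Gaussian at 375 ms, σ = 60 ms) on the 43
  responsive channels (all but the 21 most frontal in layout order;
  identities configurable since only the count is constrained). Window
  means over 350–400 ms are 12 ± 8·`effect_size` µV, i.e. 20/12/4 µV for
  Sd/Sm/Su at the default effect size — deliberately strong effects, sized
  so that planted per-channel F statistics land in the tens, the regime the
  emulated sensor-level analysis reports;
* block-latent factors: channels are partitioned into four blocks, the
  partition depending on condition, and each block receives a shared
  band-limited (1–30 Hz) latent signal (4 µV × `effect_size`) during the
  observation window. This plants condition-specific inter-channel
  covariance — the substrate of the network classification. The factors are
  made zero-sum across blocks so they cancel from the cross-channel mean and
  leave summary waveforms clean.

Two EOG channels carry Poisson blink transients (120 µV) that leak into the
EEG through a fixed exponential-decay mixing matrix (strongest frontally),
so regression-based removal is exactly identifiable.

**fNIRS (48 channels, 27 ms sampling, three wavelengths).** Hemoglobin
dynamics are built in concentration units (mM·mm) and pushed through the
forward Beer–Lambert model (extinction coefficients at 780/805/830 nm from
the standard compiled in-vitro spectra; DPF 6.3/6.0/5.75) to produce strictly
positive light intensities; the recorded quantity is intensity, as acquired.
Per trial, ΔHbO receives:

* a hemodynamic response: the 3.5 s observation boxcar convolved with a
  double-gamma kernel, the whole response delayed by the neurovascular lag
  (default 1700 ms). The kernel's time-to-peak is calibrated by bisection so
  the convolution peaks exactly at 3.0 s post-onset; a high gamma shape
  parameter gives a delayed, sigmoid-like onset, and a 0.4 undershoot gives
  a genuine (not plateau) peak. Peak amplitudes are 0.02 ± 0.01·`effect_size`
  mM·mm (Sd/Sm/Su ordered), scaled by a hemispheric lateralization index
  (left-dominant for Sd/Sm, right-dominant for Su);
* a fast neural-coupled component: a copy of the cross-channel-mean evoked
  waveform (the cue complex at its 13/64 posterior weight plus the
  condition component at its 43/64 responsive weight), delayed by the same
  lag, at 0.0015 mM·mm per µV. This is what makes the lagged ERP–HbO
  correlation surface peak at the planted lag; the copy mirrors the
  *measured* summary ERP's composition because the lag analysis correlates
  exactly that summary against HbO;
* block-latent factors analogous to the EEG ones (partition differs by
  condition, zero-sum across blocks, smoothed white noise, 0.006 mM·mm ×
  `effect_size`) spanning the whole 16 s trial slot so that trial-mean
  variance is uniform across the epoch;
* physiological noise: Mayer waves (0.1 Hz, 0.004), cardiac pulsation
  (1.1 Hz, 0.002), slow random-walk drift (0.008), white noise (0.002).

ΔHbR = −ΔHbO/3 (a common empirical ratio, configurable); ΔHbT follows by
additivity. `noise_scale = 0` switches every stochastic component off, which
the exactness tests use.

**Complementary modality design.** The EEG block partitions are identical
for Sm and Su (EEG networks resolve Sd against the rest), while the fNIRS
partitions are identical for Sd and Sm (fNIRS networks resolve Su). Neither
modality alone can separate all three conditions through its network
structure; their fusion can. `default_ground_truth()` uses the full evoked
amplitudes above; `network_cohort_truth()` keeps the same partitions but
shrinks the evoked contrasts to 12 ± 1 µV and 0.02 ± 0.002 mM·mm (still
strictly ordered). The reason is physical rather than cosmetic: a large
condition-scaled evoked component measurably raises inter-channel
correlations on the responsive set, so with full-size evoked contrasts the
EEG networks decode all three conditions through amplitude differences alone
and the fused set has nothing left to add. The cohort truth is the
configuration under which "complementary network structure" is actually the
planted effect.

## Preprocessing

EEG: 50 Hz zero-phase IIR notch, zero-phase 4th-order Butterworth band-pass
1–30 Hz (forward–backward, so the 350–400 ms component is not delayed;
effective order 8, passband monotone, a 60 Hz tone is attenuated below 1%),
EOG regression (least-squares projection on the blink channels, fit on
mean-centered signals; constant EOG channels are skipped with a warning),
epoching to (−0.7, 3.5) s around observation onset, baseline correction on
(−700, −500) ms. Epoch length is `ceil(duration × rate)` samples — 4,200 for
the EEG window, 445 for the fNIRS window.

fNIRS: MBLL inversion (ΔOD(λ,t) = −log10 I/I_ref; the per-time 3×2 linear
system in [ΔHbO, ΔHbR] is solved by least squares after dividing by the
per-wavelength DPF; output in mM·mm). I_ref defaults to the per-channel
time mean — the reference choice shifts each channel by a constant that the
baseline correction removes. Band-pass 0.01–0.1 Hz for sensor-level waveform
statistics (the conventional hemodynamic band), epochs (−6.5, 5.5) s,
baseline (−6.5, −0.5) s.

Two stages deliberately use wider fNIRS bands: the network stage (0.01–2 Hz)
and the lag analysis (0.01 Hz high-pass only). A 3.5 s observation window
contains barely a third of a cycle at 0.1 Hz, so per-trial Pearson
correlations — and any millisecond-scale lag structure — are undefined
inside the narrow band; the wider bands retain the within-trial fluctuations
those analyses consume. Both bands are configurable.

## Sensor statistics

Per channel, the per-trial mean amplitude over the analysis window
(350–400 ms for ERP, 0–3.5 s for HbO) is submitted to a one-way ANOVA over
the three conditions; pairwise post hoc t-tests are Bonferroni-corrected
over the three comparisons. Significance thresholds default to α = 0.001
(EEG) and α = 0.05 (fNIRS); no correction across channels is applied, per
the reporting convention emulated. The HbO block t-test contrasts, per
channel and probe time t ∈ {1,…,5} s, the trial mean over [t−0.5, t+0.5]
against the trial mean of the baseline block, paired over trials. Topographic
maps use barycentric-linear scattered interpolation on the 2-D layout
(idealized projected coordinates shipped with the package), masked outside
the channel convex hull; interpolation is exact at channel sites and for
linear fields.

## Neurovascular-coupling lag surface

Grand-averaged ERP and HbO are reduced to one summary waveform per condition
(cross-channel mean; a per-channel-pair variant would be a drop-in
replacement). HbO is linearly interpolated onto a 1 ms grid. For every EEG
window length X ∈ [100, 600] ms (1 ms steps) and lag Y ∈ [0, 3000] ms (27 ms
steps — the fNIRS sampling interval), Pearson r is computed between
ERP[0, X] and HbO[Y, Y+X] per condition. The surface of interest is the
minimum over the three conditions; the high-correlation region is where it
exceeds 0.8, and its argmax (ties broken toward the smallest Y, then the
smallest X) estimates the lag. Degenerate (constant) segments yield NaN and
are excluded from region extraction. On default synthetic subjects the
recovered lag sits at 1701 ms (the grid point nearest the planted 1700 ms)
with a peak window length of ≈ 420 ms; short windows (X ≈ 100 ms) have few
effective samples at the fNIRS bandwidth and occasionally produce a spurious
maximum, which is why the validation criterion is a ≥ 90% hit rate over
seeds rather than exact recovery.

## Networks and nodal features

For each trial, pairwise Pearson correlations of the 0–3.5 s observation
window are Fisher-Z transformed (|r| clipped at 1−1e−7), the diagonal
zeroed, and a binary graph formed by proportional thresholding of |Z| at
density 0.3 (ties broken by stable sort on |Z| then node-pair order;
magnitude thresholding keeps strong negative couplings; signed weights are
retained in the weight matrix). Five nodal metrics per channel — degree,
clustering coefficient, betweenness centrality (normalized by
(n−1)(n−2)/2), eigenvector centrality (principal eigenvector of the largest
connected component, non-negative, unit Euclidean norm, zero off-component
and on edgeless graphs), and local efficiency (global efficiency of the
neighbor-induced subgraph) — give 64×5 = 320 EEG and 48×5 = 240 fNIRS
features per trial. Grand-averaged (per-condition) networks are also
computed for visualization. Binary-graph metrics are the default because the
five standard definitions are binary; weighted variants of degree and
clustering would be straightforward extensions.

## Classification

Features are fused by column concatenation (560 columns). All fitting
happens inside training folds: z-scoring, Relief-F ranking (k = 10 nearest
hits and misses per class, Manhattan distance on min–max-normalized
features, all instances sampled; weights are invariant to affine feature
rescaling), selection of the top 60 features (a package default; the
emulated protocol does not fix this number), and an RBF-kernel C-SVC whose (C, γ) are chosen
by an inner stratified 5-fold grid search over C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}
(powers of two, step 2; inner-CV ties resolve to the smallest C, then the
smallest γ). The outer protocol is 10 repetitions of stratified 10-fold
cross-validation — with 84 trials, about 25 training and 3 test trials per
class per fold. Accuracy is averaged over repetitions × folds; confusion
matrices are summed. A modality comparison (one-way ANOVA over
subject × modality accuracy columns with Bonferroni pairwise tests) mirrors
the group-level analysis.

## Validation experiments and problem sizes

`neurointent.experiments` regenerates everything from a seed:

* **Lag recovery**: 20 subjects at the full 84-trial paradigm; EEG is
  synthesized at 250 Hz (the lag analysis interpolates both signals to a
  common 1 ms grid, so the generator rate only sets synthesis cost, and the
  evoked features are band-limited far below 125 Hz).
* **Classification cohort**: 10 subjects (`network_cohort_truth`), reduced
  SVM grid (C ∈ {2^−1, 2^3, 2^7}, γ ∈ {2^−9, 2^−5, 2^−1}), inner 3-fold, and
  2 repetitions of 10-fold CV per modality; the null check (permuted labels)
  runs the full 10×10-fold protocol on one subject.
* **Test-size calibration**: channel ANOVA and block t-test on 500 null
  channels; rejection rates should sit within 2 standard errors of α.
* **Relief-F**: a perfectly separating feature planted among 50 noise
  features across 100 seeds, plus an exactly hand-traced 6-instance example.
* **MBLL**: forward-synthesis/inversion round trip to numerical precision.

## Limitations

The generator emulates signal structure, not biophysics: no photon
transport, no head model, no motion artifacts, no inter-subject variability
in channel identities, and latent "connectivity states" are block-structured
rather than graph-realistic. Passing tests therefore demonstrate that the
pipeline recovers what was planted under the stated noise model — they do
not certify performance on real recordings, where artifact structure,
non-stationarity, and far weaker effects dominate. Headline decoding
accuracies from real subjects are not reproducible from synthetic data and
are not targets; only qualitative orderings (fused ≥ single modality,
EEG > fNIRS) are asserted. EDF and SNIRF adapters are not included; the
native interchange format is plain-text TSV + JSON.
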