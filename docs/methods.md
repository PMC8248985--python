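# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate. Every empirical number
mentioned here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Scope and data model

The package implements the computational chain for identifying
electrophysiological cell classes ("e-types") from extracellular
recordings of a color-based reversal-learning task, and for relating their
firing and spike-LFP synchronization to reinforcement-learning variables.
A session consists of per-unit spike times (seconds), per-unit mean action
potentials sampled at 32 kHz, LFP channels at 1 kHz, and a trial table
with event times, chosen stimulus features (color, location, motion
direction), reward outcome and block identity. All times are seconds on
half-open intervals `[t0, t0 + duration)`. Because no public recording
accession accompanies the source study, every stage is validated by
parameter recovery on synthetic sessions with known ground truth; the
native on-disk layout and a minimal NWB-HDF5 reader are in
`etype_sync.session`.

## Synthetic-data generator

The generator defines the study conditions; its defaults are not tuned per
analysis.

- **Spike trains** are gamma-renewal processes (shape 1 = Poisson), with an
  optional burst mixture: with probability `burst_mix`, a spike is followed
  by a doublet 3 ms later, and the renewal rate is rescaled so the mean
  rate is preserved. Two knobs (shape, burst mixture) span the regular
  (LV < 1) through bursty (LV > 1) regimes of the e-type taxonomy.
- **Waveforms** are two-Gaussian templates (unit-depth trough plus a
  positive repolarization bump). Because the lobes overlap, the bump
  center is calibrated by fixed-point iteration on a 320 kHz grid until
  the realized trough-to-peak time matches the request to within a
  quarter of an interpolated step. `repol_frac` scales the bump width and
  thereby T4R and HR. Double-troughed or degenerate templates raise
  instead of being emitted: combinations whose lobes merge (trough-to-peak
  below ~0.12 ms with the default widths, or a repolarization bump wider
  than the trough-to-peak distance) are flagged, since no single-trough
  action potential has that geometry.
- **LFP** is a sum of cosines with known phase offsets plus 1/f Gaussian
  noise (spectrally shaped white noise). This is deliberately simple:
  stationary, no cross-frequency coupling, no non-sinusoidal waveform
  shape.
- **Phase coupling** moves each spike within one carrier cycle to the time
  at which the cosine phase of the carrier equals a draw from a von Mises
  distribution of concentration kappa. The phase offset of the carrier is
  recovered by projection, so the planted phase distribution is exact and
  the measured PPC can be compared with the analytic resultant
  `(I1(kappa)/I0(kappa))^2`. Coupling restricted to event windows and
  behavioral conditions is available for planting condition-specific
  synchronization.
- **Wideband MUA** is 800-3000 Hz Gaussian noise whose amplitude is
  modulated for 12.5 ms before and after each spike. The post/pre gain
  pair is solved analytically so that, after the *analysis side's*
  per-segment z-scoring (which subtracts the 100 ms segment mean) and the
  5 ms sliding median (which mixes the two gains within 2.5 ms of the
  spike), the (post - pre)/pre ratio over the +/-10 ms windows equals the
  requested SMUM target: `B = A (0.9 + 0.825 s) / (0.9 + 0.075 s)`.
- **Behavior** is played by the attention-augmented Rescorla-Wagner agent
  itself (below) on the two-stimulus color-reversal task: deterministic
  reward for the correct color, pseudo-random binding of location and
  direction each trial, reversal when a block reaches 100 trials or —
  after at least 30 — when the running accuracy over the last 12 trials
  reaches 90%.

What the generator does **not** emulate: spike-sorting artifacts and unit
drift, electrode geometry, non-stationary rates and oscillation bursts,
cross-frequency structure, eye movements, and the error-mode structure of
real monkey behavior. Passing tests therefore demonstrate that the
analysis chain recovers what it claims to measure, not that real cortical
data satisfy the model's assumptions.

## Waveform metrics and the narrow/broad split

Waveforms are trough-aligned, linearly mapped to [-1, 1], and upsampled
10x (cubic spline; the smooth interpolant gives stable threshold
crossings). T2P is the trough-to-peak time with the peak defined as the
most positive sample after the trough; T4R is the time after the peak at
which the voltage falls to 75% of the peak; HR is the reciprocal of the
interval from the last 63%-of-peak crossing before the peak to the peak.
Crossings are located by linear interpolation between samples. Units with
fewer than 50 spikes or double-troughed mean waveforms are excluded;
double troughs are two minima below 80% of the range with prominence of
at least 0.3 (the prominence requirement keeps measurement noise near the
trough from triggering the rule).

Bimodality is assessed with Hartigan's dip statistic, implemented from
scratch: the sample is split at every candidate mode into a convex-left /
concave-right region, the feasibility of a unimodal cdf within a sup-norm
band is reduced to greatest-convex-minorant / least-concave-majorant
violations of the one-sided ecdf corridors, and the minimax split is found
by bisection (splits at tied values, where a unimodal cdf may jump, are
scanned as well). The implementation is verified in the test suite against
a linear-programming oracle on small samples and exact closed-form cases.
The p-value is Monte-Carlo calibrated against uniform nulls of the same
sample size.

The narrow/broad split fits 1- and 2-component Gaussian mixtures (20
restarts, tolerance 1e-8) on the standardized (HR, T4R) plane and each
marginal, compares AIC/BIC, labels by maximum posterior responsibility
when two components are preferred, and calls the larger-HR component
narrow. The first principal component of (HR, T4R) is reported but never
fed to clustering.

## Firing statistics

Rate, CV (population-SD convention, configurable), LV with the factor-3
normalization (so a Poisson train has expectation 1), Fano factor over
non-overlapping 100 ms windows tiling the whole recording (partial last
window dropped), and a burst index — the proportion of ISIs below 5 ms
among ISIs below 100 ms, divided by the same ratio for a Poisson process
of the unit's rate. Statistics are computed over whole sessions without
epoch restriction.

## Spike-triggered MUA modulation (SMUM)

The wideband signal of a *different* electrode is bandpass filtered
800-3000 Hz (4th-order Butterworth, forward-backward), rectified, and
reduced to a 2 kHz envelope by a 5 ms sliding median centered on each
grid point (centering matters: an uncentered median window shifts the
envelope by half the window and contaminates the post-spike mean).
Per-spike +/-50 ms segments are z-scored individually, averaged, and
summarized as SMUM = (post - pre)/pre over the 10 ms windows flanking the
spike, excluding the zero-lag sample from both windows (whether the
source procedure includes it is unstated). Population suppression is
tested by a Wilcoxon signed-rank test of the per-unit ratios against
zero.

## E-type meta-clustering

Features (HR, T4R, LV, CV, FF, rate) are decorrelated (one member of any
pair with |Spearman rho| >= 0.9 dropped, keeping the higher-variance
one), z-scored, rescaled to [0, 1], ranked by variance share, and cut at
90% cumulative variance. The scan stage runs best-of-50 k-means for
k = 1..40 with nine validity indices; Rand, Mirkin and Hubert require two
partitions and are computed here as replicate-stability indices (mean
pairwise value over ten best-of-5 replicate partitions per k — single-init
partitions measured initialization noise rather than structure).

Meta-clustering runs n realizations of best-of-50 k-means for each
k = 5..15, accumulates pairwise co-assignment probabilities per k, and
takes reliable clusters as single-linkage connected components of the
co-assignment graph thresholded at p >= 0.9 with at least five members.
The final k maximizes the fraction of units in reliable clusters; on clean
synthetic data several k tie at 100%, and the tie is broken by the minimum
BIC of a spherical Gaussian mixture evaluated at the k-means solution (the
same information criterion the procedure uses for validation). Units
outside reliable clusters are assigned to the nearest reliable-class
centroid and flagged. Validation uses 200 randomization realizations:
per-class distinctness pools associated vs non-associated realization
centroids across realizations (pooling is essential — a within-realization
shuffle of the association permutes the same distances and cannot serve as
a null), and assignment consistency is compared against shuffled labels.
Classes are named N1..Nk / B1..Bm by narrow/broad majority and ascending
mean LV.

## Reinforcement-learning model

Feature values (two colors, two locations, two directions; V0 = 0.5 at
session start only — the model must discover reversals) update by the
delta rule on the chosen stimulus's features and decay by (1 - omega) on
the unchosen stimulus's features; choices are softmax over beta times the
per-stimulus value sums. The likelihood is maximized by a capped
Nelder-Mead pre-search (20 iterations) followed by L-BFGS-B with eta,
omega in [0, 1] and beta log-parameterized in (0, 50], best of 10 random
starts. Cross-validation splits by blocks 80/20, fitting on training
blocks and scoring held-out trials by running the model over the whole
session (values carry across block boundaries) while summing only
held-out terms. Trialwise outputs are p(choice) of the chosen stimulus
and the positive reward prediction error on rewarded trials,
RPE_pos = R - V(chosen), with V(chosen) the mean of the stimulus's three
feature values so the error lives on the outcome scale.

One consequence of updating *all* chosen features is worth noting: even a
perfect one-shot agent (eta = 1, omega = 1, beta large) is not guaranteed
error-free after the second block trial, because location/direction values
can transiently outweigh the color value; the exact property (the next
choice shares at least two of three features with the last rewarded trial)
is what the tests assert.

## Learning-trial estimator

A Bernoulli observation model on a Gaussian random-walk latent state,
anchored at chance (logit 0) at the block start. The filter uses the
standard Laplace-approximation recursion (Newton per trial), smoothing is
Rauch-Tung-Striebel, and the random-walk variance is estimated by EM
(clipped to [1e-6, 10]). Confidence bounds are the logistic transform of
the smoothed mean +/- 1.96 SD; the learning trial is the earliest trial
whose lower bound exceeds 0.5. All-correct blocks learn at trial 1;
all-error blocks never learn. The estimator is validated by step-change
simulations (0.5 -> 0.95 at trial 10 detected at median trial 10-16;
chance blocks yield no learning trial in >= 90% of runs).

## Spike-LFP synchronization

Spike artifacts are removed by cubic interpolation across +/-2 ms around
each spike (overlapping windows merged; recording edges held) — a
deliberate simplification of Bayesian artifact-removal approaches, whose
spectral fidelity is itself tested (a 10 Hz sine with planted delta
artifacts recovers its power within 5%).

Phases use an adaptive window of five complete cycles (2.5 each side),
Hann taper, cosine convention referenced to the exact spike time (a spike
on a cosine crest has phase 0). PPC is computed through
`(n^2 R^2 - n)/(n(n-1))`, the algebraic identity for the mean over
unordered pairs of cosines of phase differences; it is unbiased by spike
count. Rayleigh p-values use `Z = n R^2` with the standard finite-n
series correction.

Peak detection applies four criteria: Rayleigh p < 0.05, PPC > 0.005,
prominence >= 0.0025, and PPC above 25% of the spectrum's range; the band
is the peak's base (flanking minima) and carries a summed PPC mass. Two
measurement properties matter for interpretation. First, a strongly
locked sinusoidal carrier leaks *upward* in frequency: at measurement
frequency f the 5-cycle window has mainlobe half-width 2f/5, so a 40 Hz
carrier contaminates phases up to roughly 65 Hz while frequencies below
the carrier stay clean; the 25%-of-range criterion is what rejects the
leakage shoulder. Second, the absolute 0.005 PPC floor is approximately
2 SD of the null PPC at 500 spikes but 7 SD at 2000, so uncoupled
controls are only peak-free at session-scale spike counts; the tests
exercise detection at ~500 spikes and the zero-false-peak property at
~2000.

Class peak densities (fraction of units with a peak band covering each
frequency) are compared against the 95% interval of 1000 size-matched
bootstrap samples from the pooled population.

Time-resolved PPC splits trials at the per-session median of the behavior
variable (ties to "low"), pools spikes across trials per +/-350 ms window
stepped by 50 ms, and averages PPC over 500 random 50-spike subsamples,
removing spike-count bias; the normalized variant divides by the -850..0
ms pre-event baseline (ratio; a difference normalization is a
one-argument switch). Group contrasts use label permutations with the
map-wide extreme-5% (max-statistic) threshold — the most extreme 5% of
the null across the whole time-frequency map — which controls the
familywise error exactly under exchangeability, rather than
per-pixel corrections.

## Functional rate statistics

Spike densities use a Gaussian kernel of SD 50 ms truncated at +/-300 ms
(the 600 ms support), normalized to integrate to 1, z-scored per unit to
the -500..0 ms pre-event window. Sliding correlations are Spearman rho of
per-trial rates (windows +/-200 ms, 25 ms steps) against p(choice) or
RPE_pos (rewarded trials only), with per-unit significance at p < 0.05
and class-level curves tested by label shuffles with the extreme-5%
correction. Selectivity proportions use tie-corrected normal-approximation
rank-sum tests, vectorized so that label permutations reduce to one matrix
product over precomputed ranks; because proportions over a finite unit
count are discrete, the corrected randomization p-values count ties as
half (mid-p) — with strict thresholds the familywise error was measurably
conservative (~0.015 at nominal 0.05), with mid-p it sits at ~0.045.
Class effect sizes are mean unsigned
Cohen's d against 1000 size-matched random samples.

E-type decoding uses a one-vs-one RBF SVM (kernel scale 1) over balanced
subsamples (half the minimum class size per class; classes under 5 units
dissolved into the others weighted by size) with stratified k-fold
cross-validation, folds capped so every class appears in every fold. The
confusion matrix is the outcome ratio over all subsample predictions.
Significance of decodable classes is a label-permutation test on the
diagonal accuracies with the extreme-5% correction across classes. The
conventional FDR-corrected binomial test on raw prediction counts is
reported alongside (`pvals_binomial`) but is not the primary criterion:
subsample predictions of one unit are pseudo-replicates, and the count
binomial's empirical familywise error under the null measured here was
~0.9 at nominal 0.05 — even counting each unit once leaves ~0.2, because
chance structure in the data drives all units' predictions jointly. Only
the permutation version is calibrated.

## Circuit motifs

Both motifs are delayed Wilson-Cowan rate models,
`tau_p dr_p/dt = -r_p + F(W r(t - D) + d_p + noise)`, with a logistic
transfer `F` (per-population midpoint and slope), Euler integration at
0.05 ms, and a common synaptic delay. The dominant frequency is the
argmax above 3 Hz of the Welch spectrum (2 s segments, 50% overlap) of
the summed excitatory rate, smoothed over ~4 Hz because noise-driven
resonances are broad. Bands: theta 6-14, beta 20-35, gamma 35-45 Hz.

**E-E-I** (two excitatory pools driving one inhibitory pool that inhibits
both): the inhibitory population is given a high sigmoid midpoint so its
operating-point gain tracks the *total* excitatory drive. With balanced
high drive (240, 240) the loop crosses into a weak limit cycle whose
frequency (~40 Hz) is pinned by the time constants (9, 9, 21 ms) and the
1.2 ms delay — and is therefore robust to weight perturbations; with one
dominant drive of lower total (140, 30) the loop is subcritical and the
noise-driven resonance sits in the beta band. Two design dead-ends are
documented for the record: with a single shared sigmoid the E and I
operating points co-adjust and cancel the drive dependence of the
frequency, and a pure two-population E-I rate loop without delay or
recurrent excitation cannot oscillate at all (its Jacobian trace is
always negative).

**E-I-I** (one excitatory pool reciprocally coupled to a fast and a slow
inhibitory pool, time constants 7.5 vs 130 ms): recurrent excitation
(w_EE = 2) makes the fast subsystem bistable, so when the slow population
is driven it sweeps the circuit through a theta-band relaxation cycle;
driving the fast population instead engages the delayed E-I1 loop at
gamma. The disinhibition preset shifts drive from the slow to the fast
population, switching theta to gamma — the high-prediction-error state.

The pinned parameterizations are versioned as the regression oracle; the
contract is band membership of the two regimes (verified under +/-20%
independent weight perturbations), not exact frequencies.

## Reproducibility and problem sizes

Every stochastic routine takes a seed or Generator; the pipeline derives
per-stage seeds from one master seed, and repeated runs are bit-identical.
Default problem sizes in the tests and the acceptance script (for example
100 meta-clustering realizations, 20 or 8 recovery seeds for the RL fit,
200 learning-trial blocks, 8-unit groups for the time-resolved contrast)
were chosen once as the package's validation scale; larger runs only
shrink Monte-Carlo error.

## Known limitations

- The dip test's Monte-Carlo null is recomputed per call; repeated testing
  at the same n would benefit from caching.
- Selective phase coupling preserves rate only to first order; at very
  high kappa the within-window spike count distribution narrows.
- The evoked-LFP subtraction assumes the evoked component is identical
  across trials; amplitude-varying evoked responses leave a residual.
- The NWB reader covers the common layout (ragged `units/spike_times`,
  `intervals/trials`, acquisition series with rate or timestamps), not
  the full standard.
- Motif frequencies are estimated from finite noisy simulations; runs
  shorter than ~4 s make the dominant-frequency estimate unstable.
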