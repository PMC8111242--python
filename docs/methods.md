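# Methods

This note documents the models and procedures implemented in
`gammastates`, the defaults and why they were chosen, what the synthetic
cohorts do and do not emulate, and the numerical conventions that matter
when comparing results.

## State model

### Time-delay embedding

Let y<sub>t</sub> ∈ R<sup>P</sup> be the band-limited (1–35 Hz),
per-subject z-scored parcel signal. Each sample is replaced by the stacked
window [y<sub>t−L</sub>, …, y<sub>t+L</sub>] with L = 7 lags (±28 ms at
250 Hz), so the embedded vector carries the local autocovariance
structure: a Gaussian distribution over it encodes band-limited power and
cross-parcel phase coupling, not just instantaneous amplitude. The
embedding never crosses segment boundaries; the 2L edge samples of each
segment are masked. The embedded data (width P·(2L+1)) are reduced by PCA
to `pca_dim = 2P` components, a conventional operating point that keeps
the leading spectral structure while making full covariance estimation
tractable. Both L and `pca_dim` are configurable.

### HMM and inference

The reduced data follow a K-state HMM (default K = 4; a config input, with
no automatic selection) with zero-mean full-covariance Gaussian states.
Means are pinned at zero because the data are z-scored and the embedding
makes covariance the carrier of all state structure. Inference is
maximum-likelihood EM (Baum–Welch):

* E-step: exact forward–backward recursions in log space (log-sum-exp,
  numba-compiled), restarted at every segment boundary; probabilities are
  floored at 1e-300 before taking logs.
* M-step: closed-form updates; state covariances receive a ridge
  `cov_reg · (trace/D) · I` (default `cov_reg = 1e-5`).
* Initialization: k-means on (a ≤20k-sample subsample of) the reduced
  data seeds hard responsibilities; a sticky transition matrix (0.9
  self-transition) starts the chain. The best of `n_restarts` runs by
  final log-likelihood is kept (default 5 for library use; the packaged
  recovery presets use 1–2 because the planted states are well separated).
* Convergence: relative log-likelihood change below `tol = 1e-5`, at most
  `max_iter` iterations; non-convergence returns a flagged result after a
  final E-step so posteriors always match the returned parameters.

This is deliberately a maximum-likelihood implementation rather than a
variational-Bayes one: every downstream quantity consumes only the
posteriors γ and the state spectra, which EM provides without priors.
The exactness of the E-step is tested against brute-force enumeration of
all state paths on small instances and against an independent HMM library
with pinned parameters.

Posterior decoding assigns each sample to its most probable state; ties
break to the lowest state index. Samples masked by the embedding edges
carry the uniform posterior 1/K so that the posterior array stays aligned
sample-by-sample with the concatenated data; consumers that must not see
them (FO, spectra) use the accompanying validity mask, while the
pre-stimulus trial weights deliberately keep the alignment (see
limitations).

## State spectra

The state-weighted multitaper estimator computes, per sliding window
(default 2 s, 50% overlap, 3 DPSS tapers with minimal time–bandwidth
(R+1)/2), the tapered cross-spectral matrix, and averages windows into
state k with weight equal to the window mean of

ρ<sub>t,k</sub> = γ<sub>t,k</sub> / (Σ<sub>t</sub> γ<sub>t,k</sub> / T),

the state probability normalized to unit time-mean. The printed form of
this estimator weights Fourier coefficients over the whole series; a
windowed implementation is required for finite-frequency resolution, and
weighting each window's *power* by the window-mean ρ is the variant that
preserves the two defining identities (both tested to tolerance):

* ρ ≡ 1 ⇒ the state spectrum equals the ordinary multitaper spectrum;
* Σ<sub>k</sub> FO<sub>k</sub> · S<sup>(k)</sup>(f) equals the unweighted
  spectrum (FO taken as mean posterior), because
  Σ<sub>k</sub> FO<sub>k</sub> ρ<sub>t,k</sub> = 1.

Low frequencies remain estimable despite ~100 ms state visits because a
state's spectrum pools all windows in proportion to its probability —
what matters is total time credited to the state, not visit length.

Coherence is magnitude-squared coherence of the weighted cross-spectra.
Band maps average power over delta 1–3, theta 4–7, alpha 8–12, beta 13–30
and gamma 60–90 Hz (a `FEATURE_BANDS` preset with delta 1–4 Hz exists for
feature analyses; the two delta conventions coexist deliberately), and are
reported absolutely or relative to the mean over states,
(value − mean)/mean, which averages to zero across states. Because state
inference uses ≤35 Hz data, gamma-band maps are computed on the unfiltered
copy of the recording.

## State dynamics

Fractional occupancy is the fraction of samples assigned to a state
(posterior-mean FO is the default for subject-level statistics, matching
probability averaging over a recording; hard-assignment FO is available).
Lifetimes are maximal runs of the decoded path; runs truncated by a
segment boundary are censored and excluded. Interval times are gaps
between successive visits; a gap is bounded by visits on both sides and
therefore always fully observed, so truncation of the flanking visits does
not bias it. Time-locked FO averages decoded indicators (or posteriors)
across trials at each latency from fixation onset, padding shorter trials
out of the average with coverage counts; per-subject OLS slopes of FO on
time, tested against zero with a one-sample t-test, quantify anticipatory
drifts across the baseline.

## State matching across models

Two independently fitted models are matched by the spatial similarity of
their state power maps: Pearson correlation across parcels, per frequency
band, averaged over bands. For the grouping step, all 2K states enter Ward
hierarchical clustering; each state's feature vector is its row of the
joint 2K × 2K band-averaged correlation matrix over all state maps. This
embedding is invariant to relabeling either model (identical states carry
identical profiles and merge at height ~0) — a property the simpler
"row-vs-column of the cross-model block" embedding lacks, because rows and
columns index different models' states. Matched pairs are read off
greedily by increasing cophenetic merge height with one-to-one removal;
the lowest pair is the best match. Matching on relative (state-mean-
referenced) maps avoids the common 1/f background dominating every
correlation.

## Gamma response quantification

Per-trial induced gamma amplitude: multitaper TF power (40–100 Hz, 300 ms
windows, 2 Slepian tapers), window centers on a nominal 50 ms grid through
stimulus onset with each center rounded to samples independently (50 ms is
12.5 samples at 250 Hz; independent rounding avoids cumulative drift);
percent change per trial and frequency against the mean power of windows
whose centers fall in −0.5…−0.2 s (this window is read in seconds; the
alternative reading in milliseconds is dimensionally impossible given the
300 ms analysis window); subject-level peak = argmax of the trial-averaged
normalized power over the 0.6–2 s response window (ties to the lower
frequency); amplitude = mean over peak ±10 Hz × 0.6–2 s × ROI parcels
(ROI averaging happens at the TF stage; power is linear in parcels, so
order is immaterial for the mean). All averaging steps are linear, so the
mean of per-trial amplitudes equals the amplitude of the trial-averaged
TF — a tested invariant.

## Coupling statistics

* **Between subjects**: Spearman correlation between per-state mean
  probability and trial-averaged gamma amplitude; two-sided permutation
  p = (1 + #{|r<sub>perm</sub>| ≥ |r<sub>obs</sub>|}) / (1 + n_perm) with
  y permuted (default n_perm = 10 000; exact enumeration available for
  n ≤ 9).
* **Within subjects**: per trial, the mean γ over the final
  ⌊0.106 s · fs⌋ = 26 pre-stimulus samples forms a weight row (the 106 ms
  default matches a typical mean state lifetime and is a config value, not
  a constant of nature); weighted state means
  Σ w<sub>k</sub>a / Σ w<sub>k</sub> enter a Friedman test across
  subjects with all pairwise post-hoc comparisons Bonferroni-corrected by
  K(K−1)/2. The post-hoc default is the *paired* signed-rank test because
  the compared values are within-subject; the unpaired rank-sum variant is
  available via `posthoc="rank_sum"` since both appear in practice for
  this design. With K = 2 the omnibus degenerates to the single pairwise
  test and is reported as such.
* **Pseudo-states**: a univariate control replaces state probabilities by
  quantile bins of pre-stimulus Hilbert-envelope band power; ties take the
  bin of their minimum rank (all-equal inputs land in bin 0 with a
  warning).
* **Effect-size comparison**: the trial × K FO matrix (pooled over
  subjects, centered) is reduced to its first principal component, with
  the loading sign fixed so the largest-magnitude loading is positive (PC
  signs are otherwise arbitrary and would flip correlations between
  runs). Subject means of PC1 score and amplitude give the between-subject
  Spearman correlation; pooled within-subject residuals give the
  within-subject correlation (residual subject means vanish by
  construction). 1000 bootstrap draws resample whole subjects with
  replacement — trials travel with their subject — and draws with fewer
  than two distinct subjects are redrawn and counted. Effects are compared
  as the fraction of draws in which one |r| exceeds the other.

## Synthetic cohorts

The generator plants exactly the structures the pipeline is supposed to
find:

* **States**: a Markov chain (default self-transition 0.96 at 250 Hz,
  i.e. ~100 ms mean lifetimes, matching typical electrophysiological state
  durations); state topographies are band-pass-filtered white noise gated
  by the state indicator, one distinct center frequency per state, with
  RMS 1.5× the white-noise floor ("well-separated" topographies for
  recovery testing). The occipital ROI parcels carry alpha in every state
  *except* the enhancing one — planting the occipital-alpha-deficit
  signature of the gamma-enhancing state.
* **Subjects**: transition rows are Dirichlet draws with concentration
  row/jitter. The default jitter 0.002 yields a between-subject FO spread
  of SD ≈ 0.06 with every subject visiting every state — the studied
  regime reports no empirical FO variance, so this is a calibration choice
  for a realistic, non-degenerate cohort, fixed once.
* **Gamma**: Hann-enveloped sinusoidal bursts at a subject-specific peak
  frequency ~ U(42, 74) Hz, 0.6–2.0 s post-stimulus in the ROI parcels.
  Planted trial amplitude = base + coupling_between · (FO<sub>enh</sub> −
  1/K) + coupling_within · 1[pre-stimulus state = enhancing] + subject and
  trial noise, clipped at zero. Defaults (base 1.0, slopes 3.0 and 0.4,
  noise SDs 0.05 and 0.15 RMS units) plant strong couplings, as
  appropriate for recovery tests.
* **Reproducibility**: all randomness flows from one master seed; subject
  s uses `SeedSequence([seed, s])`, and the rest/task/amplitude streams
  are drawn from it in a fixed order, so cohorts are bitwise reproducible.

What the generator does *not* emulate: sensor-space physics (no forward
model, no field spread/leakage, hence no real need for the sign-flipping
step on synthetic data — the implementation is exercised on constructed
instances instead), artifacts (blinks, cardiac), 1/f background spectra,
non-Markovian state dwell times, and gamma responses with latency or
frequency dynamics. Passing tests therefore demonstrate correctness of
the estimators and statistics under the stated generative assumptions,
not robustness to real-data nuisance structure.

## Problem sizes and presets

The packaged recovery presets (`gammastates.presets`) keep the
study-defining conditions — 15 subjects, K = 4, 250 Hz, 2–4 s baselines
with the first second stripped, planted between- and within-subject
coupling — while running at desk scale: 8 parcels, 16 trials/subject, no
rest session, single EM restart with 30 iterations. A full
generate–fit–test cycle takes seconds; full-size cohorts (50 parcels,
~60 trials, 5 min rest) use the same code paths through `CohortConfig`
defaults.

## Numerical conventions and degenerate inputs

* 0-based state labels and parcel indices; half-open sample intervals.
* Argmax ties break to the lowest index everywhere (decoding, peak
  detection uses lowest frequency).
* Pre-stimulus windows take the samples strictly within the window before
  onset: ⌊w · fs⌋ samples.
* Zero-variance parcels fail z-scoring with an error naming subject and
  parcel; states with zero posterior mass fail ρ computation by name;
  all-zero gamma responses raise with advice to supply the peak manually.
* Baselines shorter than the strip, trials shorter than the pre-stimulus
  window, and segments shorter than the lag or spectral window are dropped
  with warnings, not errors.

## Known limitations

* The uniform-posterior fill at embedding edges dilutes pre-stimulus
  trial weights (the last L samples before stimulus onset are masked),
  slightly shrinking within-subject contrasts; the effect is uniform
  across states and leaves rankings intact.
* Sign alignment optimizes a lagged-autocovariance consistency objective
  greedily; it is exhaustively verified only on small instances, and a
  full mirror of one subject is unidentifiable (and harmless) by
  construction.
* EM finds local optima; restarts mitigate but do not eliminate this.
* No out-of-sample prediction: models are characterized on the data they
  were fitted to, matching the scope of the analysis the package
  implements.
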