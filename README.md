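# gammastates

Spontaneous whole-brain network activity below 35 Hz and its influence on
stimulus-induced gamma responses.

Visual stimulation induces narrow-band gamma activity (individual peak
frequencies roughly 42–74 Hz) in occipital cortex, yet the amplitude of
that response varies widely both across people and from trial to trial.
`gammastates` implements an analysis chain that explains part of this
variability through *brain states*: recurring spatio-spectral patterns of
sub-gamma (1–35 Hz) activity inferred from stimulus-free data (rest or
task baseline) with a time-delay-embedded hidden Markov model (TDE-HMM).
The package is aimed at electrophysiologists working with parcel-level
M/EEG time courses, and at methodologists who want a fully testable,
ground-truth-driven reimplementation of this class of analysis.

## What it computes

**State inference.** Parcel time courses are band-passed to 1–35 Hz,
z-scored per subject and concatenated. Each sample is augmented with ±7
lagged copies of all parcels, reduced by PCA to twice the parcel count,
and modelled with a K-state HMM (default K = 4) whose states are zero-mean
Gaussians with full covariance — so each state captures a pattern of
band-limited power and cross-parcel coupling. Inference is maximum-
likelihood EM with an exact log-space forward–backward pass; its output is
the posterior probability γ<sub>t,k</sub> of state *k* at sample *t*.

**State characterization.** State spectra use a state-weighted multitaper
estimator: windowed Slepian-tapered cross-spectra are averaged with weights
ρ<sub>t,k</sub> = γ<sub>t,k</sub> / mean<sub>t</sub>(γ<sub>t,k</sub>), which
have unit time-mean, reduce to the ordinary multitaper spectrum for ρ ≡ 1,
and make the occupancy-weighted mean of state spectra reproduce the
unweighted spectrum. Dynamics are summarized as fractional occupancy (FO),
lifetimes and interval times; states of independently fitted models (rest
vs task baseline) are matched by band-wise Pearson correlation of their
power maps followed by Ward hierarchical clustering.

**Gamma responses.** Induced gamma is quantified per trial by multitaper
time-frequency estimation (40–100 Hz, 300 ms windows, 50 ms steps, 2
Slepian tapers), percent-change normalization against the −0.5…−0.2 s
pre-stimulus baseline, and averaging over the individual gamma peak ±10 Hz,
the 0.6–2 s response window, and the cuneus ROI.

**Coupling statistics.** Between subjects: permutation tests with
Spearman's ρ linking mean state probability to trial-averaged gamma
amplitude. Within subjects: trials are soft-grouped by mean pre-stimulus
(−106…0 ms) state probability, and state-wise weighted mean amplitudes are
compared with a Friedman test plus Bonferroni-corrected post-hoc tests
(with a pseudo-state band-power binning control). Effect sizes are put on
one scale by reducing the trial × state FO matrix to its first principal
component, splitting subject means from within-subject residuals, and
bootstrapping subjects (1000 draws).

**Synthetic cohorts.** Because such recordings are rarely shareable, the
package ships a first-class generator: Markov state sequences with
state-specific narrow-band topographies, subject-specific transition
matrices (Dirichlet-jittered), and Hann-enveloped gamma bursts whose
amplitude is coupled to the states both between subjects (via FO of an
"enhancing" state) and within subjects (via the pre-stimulus state). Every
stage of the pipeline is tested by recovering these planted truths.

## Worked example

```python
import warnings
from gammastates.presets import recovery_cohort_config, recovery_pipeline_config
from gammastates.simulate import generate_cohort
from gammastates.pipeline import analyze_cohort

cohort = generate_cohort(recovery_cohort_config(seed=7))   # 15 subjects
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    analysis = analyze_cohort(cohort, recovery_pipeline_config(7))
print(analysis.summary())
```

prints

```
Cohort analysis
===============
subjects: 15   states: 4

between-subject coupling (state probability vs mean gamma amplitude):
  state 0: Spearman r = -0.025, p = 0.9395 (2000 permutations)
  state 1: Spearman r = -0.275, p = 0.3418 (2000 permutations)
  state 2: Spearman r = -0.268, p = 0.3303 (2000 permutations)
  state 3: Spearman r = 0.571, p = 0.02349 (2000 permutations)

within-subject coupling (pre-stimulus state vs trial amplitude):
  Friedman chi2 = 24.68, p = 1.801e-05 (n = 15 subjects, K = 4)
  state means: [ 705.673  797.178  807.817 1003.988]
  post-hoc (signed_rank, Bonferroni-corrected):
    state 0 vs 1: p = 0.09045
    ...
    state 2 vs 3: p = 0.005127

effect-size comparison:
  between-subject Spearman r = -0.014 (bootstrap median |r| = 0.210, IQR 0.094-0.363)
  within-subject Spearman r = -0.137 (bootstrap median |r| = 0.133, IQR 0.097-0.171)
  P(|between| > |within|) = 0.656 over 1000 draws
```

Inferred state 3 is this cohort's gamma-enhancing state (labels are
arbitrary; `gammastates.pipeline.align_to_truth` maps them onto the
generator's planted labels): subjects who spend more baseline time in it
show larger trial-averaged gamma responses (r = 0.57, permutation p =
0.023), and trials preceded by it show the largest weighted-mean amplitude
(state means are percent change re: pre-stimulus baseline; Friedman
p < 0.001). The fitted model itself is available as `analysis.hmm`
(a results object with `summary()`, the transition matrix, posteriors and
posterior-decoded paths).

The same stages are scriptable from the shell:

```bash
gammastates simulate --config cohort.yaml --out cohort.h5 --seed 1
gammastates preprocess --cohort cohort.h5 --out prep.h5
gammastates fit --prep prep.h5 --states 4 --out hmm.h5
gammastates spectra --prep prep.h5 --hmm hmm.h5 --out spectra.h5
gammastates gamma --cohort cohort.h5 --out gamma.tsv
gammastates stats --cohort cohort.h5 --prep prep.h5 --hmm hmm.h5 \
    --gamma gamma.tsv --out report.json
```

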