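"""End-to-end cohort analysis: states from sub-gamma activity vs gamma responses.

Chains the package's stages the way the study design prescribes:

1. band-pass task baselines to 1-35 Hz, strip the first second of every
   baseline, z-score per subject and concatenate;
2. fit a TDE-HMM (K = 4) to the concatenated baselines (and optionally,
   separately, to the rest recordings);
3. quantify per-trial induced gamma amplitude in the ROI parcels
   (individual peak +-10 Hz, 0.6-2 s, percent change from -0.5..-0.2 s);
4. between subjects: permutation-Spearman of per-state mean probability vs
   trial-averaged gamma amplitude;
5. within subjects: soft trial grouping by pre-stimulus (-106..0 ms) state
   probability, Friedman + Bonferroni post-hoc tests;
6. effect-size comparison: occupancy-PC1 vs amplitude split into subject
   means and residuals, subject-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gamma import GammaQuant, quantify_gamma
from .hmm import TDEHMM, TDEHMMResults
from .preprocess import ConcatenatedData, bandpass, extract_baselines, zscore_concatenate
from .simulate import Cohort
from .stats import (
    CorrelationResult,
    EffectComparison,
    TrialWeights,
    WithinSubjectResult,
    effect_size_comparison,
    friedman_posthoc,
    prestim_weights,
    spearman_permutation,
    weighted_trial_average,
)

__all__ = ["PipelineConfig", "CohortAnalysis", "analyze_cohort", "preprocess_baselines"]


@dataclass
class PipelineConfig:
    """Tunables of the standard analysis chain (defaults = study settings)."""

    band: tuple[float, float] = (1.0, 35.0)
    strip_seconds: float = 1.0
    n_states: int = 4
    n_lags: int = 7
    pca_dim: int | None = None
    cov_reg: float = 1e-5
    max_iter: int = 60
    tol: float = 1e-5
    n_restarts: int = 2
    prestim_window_s: float = 0.106
    epoch: tuple[float, float] = (-0.8, 2.5)
    search_band: tuple[float, float] = (40.0, 100.0)
    response_window: tuple[float, float] = (0.6, 2.0)
    baseline_window: tuple[float, float] = (-0.5, -0.2)
    half_band: float = 10.0
    n_perm: int = 10000
    n_boot: int = 1000
    seed: int = 0


@dataclass
class CohortAnalysis:
    """Everything the standard chain computes for one cohort."""

    config: PipelineConfig
    concat: ConcatenatedData
    hmm: TDEHMMResults
    subject_ids: list[str]
    fo_subject: np.ndarray                  # subjects x K mean state probability
    gamma_by_subject: dict[str, GammaQuant]
    between: list[CorrelationResult]        # per state
    trial_weights: TrialWeights
    weighted_means: np.ndarray              # subjects x K
    within: WithinSubjectResult
    fo_trials: dict[str, np.ndarray]        # per-subject trial x K occupancy
    effects: EffectComparison
    rest_hmm: TDEHMMResults | None = None
    rest_fo_subject: np.ndarray | None = None
    rest_between: list[CorrelationResult] | None = None
    extras: dict = field(default_factory=dict)

    @property
    def mean_amplitude(self) -> np.ndarray:
        return np.array([self.gamma_by_subject[s].amplitude.mean() for s in self.subject_ids])

    def summary(self) -> str:
        lines = [
            "Cohort analysis",
            "===============",
            f"subjects: {len(self.subject_ids)}   states: {self.hmm.n_states}",
            "",
            "between-subject coupling (state probability vs mean gamma amplitude):",
        ]
        for k, res in enumerate(self.between):
            lines.append(f"  state {k}: {res.summary()}")
        lines += ["", "within-subject coupling (pre-stimulus state vs trial amplitude):"]
        lines.append("  " + self.within.summary().replace("\n", "\n  "))
        lines += ["", "effect-size comparison:", "  " + self.effects.summary().replace("\n", "\n  ")]
        return "\n".join(lines)


def preprocess_baselines(cohort: Cohort, cfg: PipelineConfig) -> ConcatenatedData:
    """Filter, strip, z-score and concatenate all subjects' task baselines."""
    recs = []
    for sub in cohort.subjects:
        ts = bandpass(sub.task, cfg.band[0], cfg.band[1])
        recs.append(extract_baselines(ts, sub.events, cfg.strip_seconds))
    return zscore_concatenate(recs)


def _trial_epochs(cohort: Cohort, cfg: PipelineConfig, subject_idx: int) -> tuple[np.ndarray, int]:
    """Cut ROI-parcel epochs around every stimulus onset of one subject."""
    sub = cohort.subjects[subject_idx]
    fs = sub.task.fs
    roi = list(cohort.config.roi_parcels)
    pre = int(round(-cfg.epoch[0] * fs))
    post = int(round(cfg.epoch[1] * fs))
    epochs = []
    for row in sub.events.itertuples():
        s = int(round(row.stim_onset_s * fs))
        epochs.append(sub.task.data[s - pre : s + post, roi])
    return np.stack(epochs), pre


def analyze_cohort(
    cohort: Cohort,
    cfg: PipelineConfig | None = None,
    fit_rest: bool = False,
) -> CohortAnalysis:
    """Run the full chain on a cohort (synthetic or read from disk)."""
    if cfg is None:
        cfg = PipelineConfig()
    sids = cohort.subject_ids
    K = cfg.n_states

    concat = preprocess_baselines(cohort, cfg)
    model = TDEHMM(concat, n_states=K, n_lags=cfg.n_lags, pca_dim=cfg.pca_dim, cov_reg=cfg.cov_reg)
    res = model.fit(max_iter=cfg.max_iter, tol=cfg.tol, n_restarts=cfg.n_restarts, seed=cfg.seed)

    # subject-level mean state probability over the whole baseline recording
    fo_subject = np.vstack(
        [res.gamma[concat.subject_rows(s) & res.valid_mask].mean(axis=0) for s in sids]
    )

    gamma_by_subject: dict[str, GammaQuant] = {}
    for i, sid in enumerate(sids):
        epochs, onset = _trial_epochs(cohort, cfg, i)
        gamma_by_subject[sid] = quantify_gamma(
            epochs,
            cohort.subjects[i].task.fs,
            onset,
            search_band=cfg.search_band,
            response_window=cfg.response_window,
            baseline_window=cfg.baseline_window,
            half_band=cfg.half_band,
        )
    mean_amp = np.array([gamma_by_subject[s].amplitude.mean() for s in sids])

    between = [
        spearman_permutation(fo_subject[:, k], mean_amp, n_perm=cfg.n_perm, seed=cfg.seed + k)
        for k in range(K)
    ]

    weights = prestim_weights(res.gamma, concat, cfg.prestim_window_s)
    weighted_means = np.vstack(
        [
            weighted_trial_average(
                gamma_by_subject[sid].amplitude[
                    weights.index.loc[weights.index["subject_id"] == sid, "trial_id"].to_numpy()
                ],
                weights.for_subject(sid),
            )
            for sid in sids
        ]
    )
    within = friedman_posthoc(weighted_means)

    # per-trial occupancy: mean posterior over each trial's baseline segment
    fo_trials: dict[str, np.ndarray] = {}
    amp_for_effects: dict[str, np.ndarray] = {}
    for sid in sids:
        rows = [
            r
            for r in concat.index.itertuples()
            if r.subject_id == sid and r.label == "baseline"
        ]
        fo_trials[sid] = np.vstack(
            [res.gamma[int(r.start) : int(r.stop)].mean(axis=0) for r in rows]
        )
        amp_for_effects[sid] = gamma_by_subject[sid].amplitude[
            np.array([int(r.segment_id) for r in rows])
        ]
    effects = effect_size_comparison(
        fo_trials, amp_for_effects, n_boot=cfg.n_boot, seed=cfg.seed
    )

    rest_hmm = rest_fo = rest_between = None
    if fit_rest and all(sub.rest is not None for sub in cohort.subjects):
        rest_recs = [bandpass(sub.rest, cfg.band[0], cfg.band[1]) for sub in cohort.subjects]
        rest_concat = zscore_concatenate(rest_recs)
        rest_model = TDEHMM(
            rest_concat, n_states=K, n_lags=cfg.n_lags, pca_dim=cfg.pca_dim, cov_reg=cfg.cov_reg
        )
        rest_hmm = rest_model.fit(
            max_iter=cfg.max_iter, tol=cfg.tol, n_restarts=cfg.n_restarts, seed=cfg.seed + 1
        )
        rest_fo = np.vstack(
            [
                rest_hmm.gamma[rest_concat.subject_rows(s) & rest_hmm.valid_mask].mean(axis=0)
                for s in sids
            ]
        )
        rest_between = [
            spearman_permutation(rest_fo[:, k], mean_amp, n_perm=cfg.n_perm, seed=cfg.seed + 100 + k)
            for k in range(K)
        ]

    return CohortAnalysis(
        config=cfg,
        concat=concat,
        hmm=res,
        subject_ids=sids,
        fo_subject=fo_subject,
        gamma_by_subject=gamma_by_subject,
        between=between,
        trial_weights=weights,
        weighted_means=weighted_means,
        within=within,
        fo_trials=fo_trials,
        effects=effects,
        rest_hmm=rest_hmm,
        rest_fo_subject=rest_fo,
        rest_between=rest_between,
    )


def align_to_truth(analysis: CohortAnalysis, cohort: Cohort) -> tuple[np.ndarray, float]:
    """Map decoded state labels onto the generator's true labels.

    Returns ``(perm, accuracy)`` where ``perm[decoded_label] = true_label``
    maximizes sample-wise agreement on the valid baseline samples, and
    ``accuracy`` is the agreement under that permutation.
    """
    from .hmm import match_labels

    cfg_fs = cohort.subjects[0].task.fs
    true_chunks = []
    events_by = {s.subject_id: s.events for s in cohort.subjects}
    for row in analysis.concat.index.itertuples():
        ev = events_by[row.subject_id]
        r = ev[ev.trial_id == row.segment_id].iloc[0]
        a = int(round((r.baseline_onset_s + analysis.config.strip_seconds) * cfg_fs))
        b = int(round(r.stim_onset_s * cfg_fs))
        true_chunks.append(cohort.ground_truth.state_paths_task[row.subject_id][a:b])
    true_path = np.concatenate(true_chunks)
    dec = analysis.hmm.decode()
    m = analysis.hmm.valid_mask
    perm = match_labels(true_path[m], dec[m], analysis.hmm.n_states)
    acc = float(np.mean(perm[dec[m]] == true_path[m]))
    return perm, acc
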