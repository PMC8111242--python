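"""Inferential links between spontaneous states and gamma responses.

Between subjects, the mean state probability of a recording is correlated
with the trial-averaged gamma amplitude using a non-parametric permutation
test with Spearman's correlation as the base statistic.  Within subjects,
trials are soft-grouped by the mean pre-stimulus state probability (-106 to
0 ms; the window length matches the average state lifetime), state-wise
weighted mean amplitudes are compared with a Friedman omnibus test and
Bonferroni-corrected post-hoc pairwise tests, and a univariate "pseudo
state" control bins trials by pre-stimulus band power instead.  Finally,
between- and within-subject effect sizes are put on one scale by reducing
the trial x state occupancy matrix to its first principal component,
splitting subject means from within-subject residuals, and bootstrapping
subjects to compare the two absolute correlations.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ConcatenatedData, bandpass, ParcelTimeSeries
from scipy.signal import hilbert

__all__ = [
    "CorrelationResult",
    "spearman_permutation",
    "TrialWeights",
    "prestim_weights",
    "weighted_trial_average",
    "WithinSubjectResult",
    "friedman_posthoc",
    "pseudo_state_assign",
    "prestim_band_power",
    "EffectComparison",
    "effect_size_comparison",
    "compare_bootstrap",
]


# ---------------------------------------------------------------------------
# Between-subject permutation correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    """Spearman correlation with a permutation p-value."""

    r: float
    p: float
    n_perm: int
    exact: bool
    seed: int | None

    def summary(self) -> str:
        kind = "exact enumeration" if self.exact else f"{self.n_perm} permutations"
        return f"Spearman r = {self.r:.3f}, p = {self.p:.4g} ({kind})"


def _spearman(xr: np.ndarray, yr: np.ndarray) -> float:
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:  # a constant vector carries no monotone association
        return 0.0
    return float(xc @ yc / denom)


def spearman_permutation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    exact: bool = False,
) -> CorrelationResult:
    """Two-sided permutation test of Spearman's rho.

    Random permutations of ``y`` give p = (1 + #{|r_perm| >= |r_obs|}) /
    (1 + n_perm); with ``exact=True`` all n! permutations are enumerated
    (n <= 9) and p is the exact fraction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    r_obs = _spearman(xr, yr)
    tol = 1e-12
    if exact:
        n = x.size
        if n > 9:
            raise ValueError("exact enumeration limited to n <= 9")
        count = 0
        total = math.factorial(n)
        for perm in itertools.permutations(range(n)):
            if abs(_spearman(xr, yr[list(perm)])) >= abs(r_obs) - tol:
                count += 1
        return CorrelationResult(r_obs, count / total, total, True, None)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(yr, (n_perm, 1)), axis=1)
    xc = xr - xr.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    r_perm = pc @ xc / np.sqrt((pc * pc).sum(axis=1) * (xc @ xc))
    p = (1 + int(np.sum(np.abs(r_perm) >= abs(r_obs) - tol))) / (1 + n_perm)
    return CorrelationResult(r_obs, p, n_perm, False, seed)


# ---------------------------------------------------------------------------
# Within-subject soft trial grouping
# ---------------------------------------------------------------------------


@dataclass
class TrialWeights:
    """Mean pre-stimulus state probabilities per trial (rows sum to 1).

    ``index`` holds one row per retained trial (subject_id, trial_id).
    """

    w: np.ndarray
    index: pd.DataFrame
    window_s: float
    n_window_samples: int

    def for_subject(self, subject_id: str) -> np.ndarray:
        return self.w[(self.index["subject_id"] == subject_id).to_numpy()]


def prestim_weights(
    gamma: np.ndarray,
    data: ConcatenatedData,
    window_s: float = 0.106,
) -> TrialWeights:
    """State-specific trial weights from the pre-stimulus window.

    Baseline segments end at stimulus onset, so the window covers each
    baseline segment's last ``floor(window_s * fs)`` samples (the samples
    strictly within ``window_s`` before onset).  Segments shorter than the
    window are dropped with a warning.
    """
    n_win = int(np.floor(window_s * data.fs + 1e-9))
    if n_win < 1:
        raise ValueError("window shorter than one sample")
    rows, ws = [], []
    for row in data.index.itertuples():
        if row.label != "baseline":
            continue
        if row.stop - row.start < n_win:
            warnings.warn(
                f"trial {row.segment_id} ({row.subject_id}): baseline shorter "
                f"than the {window_s * 1e3:.0f} ms window; trial dropped",
                stacklevel=2,
            )
            continue
        ws.append(gamma[row.stop - n_win : row.stop].mean(axis=0))
        rows.append({"subject_id": row.subject_id, "trial_id": row.segment_id})
    if not ws:
        raise ValueError("no trial covers the pre-stimulus window")
    return TrialWeights(np.asarray(ws), pd.DataFrame(rows), window_s, n_win)


def weighted_trial_average(amplitudes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Soft-assigned state means: sum_i w_ik a_i / sum_i w_ik per state.

    States with zero total weight come back NaN (marked missing).
    """
    a = np.asarray(amplitudes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != a.shape[0]:
        raise ValueError("weights rows must align with trials")
    tot = w.sum(axis=0)
    out = np.full(w.shape[1], np.nan)
    ok = tot > 0
    out[ok] = (w[:, ok] * a[:, None]).sum(axis=0) / tot[ok]
    if not np.all(ok):
        warnings.warn(
            f"state(s) {np.flatnonzero(~ok).tolist()} have zero total weight",
            stacklevel=2,
        )
    return out


@dataclass
class WithinSubjectResult:
    """Friedman omnibus plus Bonferroni-corrected pairwise post-hoc tests."""

    weighted_means: np.ndarray     # subjects x K
    friedman_stat: float
    friedman_p: float
    pairwise_p: np.ndarray         # K x K, symmetric, corrected
    posthoc: str

    @property
    def n_states(self) -> int:
        return self.weighted_means.shape[1]

    def summary(self) -> str:
        lines = [
            f"Friedman chi2 = {self.friedman_stat:.2f}, p = {self.friedman_p:.4g} "
            f"(n = {self.weighted_means.shape[0]} subjects, K = {self.n_states})",
            f"state means: {np.round(np.nanmean(self.weighted_means, axis=0), 3)}",
            f"post-hoc ({self.posthoc}, Bonferroni-corrected):",
        ]
        K = self.n_states
        for i in range(K):
            for j in range(i + 1, K):
                lines.append(f"  state {i} vs {j}: p = {self.pairwise_p[i, j]:.4g}")
        return "\n".join(lines)


def friedman_posthoc(
    weighted_means: np.ndarray, posthoc: str = "signed_rank"
) -> WithinSubjectResult:
    """Friedman test over K related state means, then all pairwise tests.

    ``posthoc`` selects the paired signed-rank test (default: the compared
    values are within-subject) or the unpaired rank-sum test; the
    Bonferroni factor is the number of pairs, K(K-1)/2.  Subjects with any
    missing state value are excluded.
    """
    M = np.asarray(weighted_means, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need a subjects x K matrix with K >= 2")
    keep = ~np.any(np.isnan(M), axis=1)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"excluding {dropped} subject(s) with missing state values", stacklevel=2)
    M = M[keep]
    if M.shape[0] < 3:
        raise ValueError("need at least 3 complete subjects")
    K = M.shape[1]
    if K == 2:
        # the omnibus over two related samples degenerates to the single
        # pairwise comparison; report that test as the omnibus
        if posthoc == "rank_sum":
            stat, p = stats.ranksums(M[:, 0], M[:, 1])
        else:
            res2 = stats.wilcoxon(M[:, 0], M[:, 1])
            stat, p = res2.statistic, res2.pvalue
    else:
        stat, p = stats.friedmanchisquare(*(M[:, k] for k in range(K)))
    n_pairs = K * (K - 1) // 2
    pw = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            if posthoc == "signed_rank":
                res = stats.wilcoxon(M[:, i], M[:, j])
            elif posthoc == "rank_sum":
                res = stats.ranksums(M[:, i], M[:, j])
            else:
                raise ValueError("posthoc must be 'signed_rank' or 'rank_sum'")
            pw[i, j] = pw[j, i] = min(1.0, res.pvalue * n_pairs)
    return WithinSubjectResult(M, float(stat), float(p), pw, posthoc)


def pseudo_state_assign(prestim_power: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Quantile-bin trials by pre-stimulus power (labels 0..n_bins-1).

    Bin b holds trials whose power falls within the b-th quantile quarter
    of the observed values.  Ties are resolved rank-based: tied trials all
    take the bin of their minimum rank (all-equal inputs land in bin 0 with
    a warning).
    """
    x = np.asarray(prestim_power, dtype=float)
    n = x.size
    if n < n_bins:
        raise ValueError("need at least n_bins trials")
    ranks = stats.rankdata(x, method="min")  # 1-based
    labels = ((ranks - 1) * n_bins // n).astype(int)
    if np.all(x == x[0]):
        warnings.warn("all pre-stimulus powers equal; every trial in bin 0", stacklevel=2)
    return labels


def prestim_band_power(
    baselines: list[np.ndarray],
    fs: float,
    band: tuple[float, float],
    window_s: float = 0.106,
) -> np.ndarray:
    """Hilbert-envelope band power in the pre-stimulus window, per trial.

    Each baseline array (samples x parcels, ending at stimulus onset) is
    band-passed, its analytic amplitude averaged over the final
    ``floor(window_s * fs)`` samples and over parcels.
    """
    n_win = int(np.floor(window_s * fs + 1e-9))
    out = []
    for bl in baselines:
        ts = ParcelTimeSeries(np.asarray(bl, dtype=float), fs)
        filt = bandpass(ts, band[0], band[1]).data
        env = np.abs(hilbert(filt, axis=0))
        out.append(env[-n_win:].mean())
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Between vs within effect comparison
# ---------------------------------------------------------------------------


@dataclass
class EffectComparison:
    """Between- vs within-subject coupling of occupancy PC1 and amplitude.

    ``bootstrap`` is n_boot x 2 (|between|, |within| per draw);
    ``p_between_gt_within`` is the fraction of draws with
    |between| > |within|.
    """

    between_r: float
    within_r: float
    pc1_loadings: np.ndarray
    bootstrap: np.ndarray
    p_between_gt_within: float
    n_redrawn: int
    seed: int

    def summary(self) -> str:
        q = np.percentile(self.bootstrap, [25, 50, 75], axis=0)
        return (
            f"between-subject Spearman r = {self.between_r:.3f} "
            f"(bootstrap median |r| = {q[1, 0]:.3f}, IQR {q[0, 0]:.3f}-{q[2, 0]:.3f})\n"
            f"within-subject Spearman r = {self.within_r:.3f} "
            f"(bootstrap median |r| = {q[1, 1]:.3f}, IQR {q[0, 1]:.3f}-{q[2, 1]:.3f})\n"
            f"P(|between| > |within|) = {self.p_between_gt_within:.3f} "
            f"over {self.bootstrap.shape[0]} draws"
        )


def _pc1_scores(fo_stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First principal component of the centered trial x state matrix.

    The loading sign is fixed so that the entry with the largest magnitude
    is positive (PC sign is otherwise arbitrary and would flip correlation
    signs between runs).
    """
    X = fo_stack - fo_stack.mean(axis=0, keepdims=True)
    cov = X.T @ X / max(X.shape[0] - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    if v[int(np.argmax(np.abs(v)))] < 0:
        v = -v
    return X @ v, v


def effect_size_comparison(
    fo_trials: dict[str, np.ndarray],
    amplitudes: dict[str, np.ndarray],
    n_boot: int = 1000,
    seed: int = 0,
) -> EffectComparison:
    """Separate and compare between- and within-subject coupling.

    The trial x K occupancy matrices of all subjects are stacked, reduced
    to their first principal component, and split into subject means plus
    within-subject residuals; amplitudes are split the same way.  Spearman
    correlation of the subject means gives the between-subject effect, of
    the pooled residuals the within-subject effect.  ``n_boot`` bootstrap
    draws resample whole subjects with replacement (draws with fewer than
    two distinct subjects are redrawn and counted).
    """
    sids = list(fo_trials)
    if len(sids) < 2:
        raise ValueError("need at least 2 subjects")
    for sid in sids:
        if fo_trials[sid].shape[0] != amplitudes[sid].shape[0]:
            raise ValueError(f"subject {sid}: occupancy/amplitude trial counts differ")
        if fo_trials[sid].shape[0] < 2:
            raise ValueError(f"subject {sid}: need at least 2 trials")
    stack = np.concatenate([fo_trials[s] for s in sids], axis=0)
    scores, loadings = _pc1_scores(stack)
    bounds = np.cumsum([0] + [fo_trials[s].shape[0] for s in sids])
    score_by = {s: scores[a:b] for s, a, b in zip(sids, bounds[:-1], bounds[1:])}

    def split(vals: dict[str, np.ndarray]):
        means = np.array([vals[s].mean() for s in sids])
        resid = {s: vals[s] - vals[s].mean() for s in sids}
        return means, resid

    amp_by = {s: np.asarray(amplitudes[s], dtype=float) for s in sids}
    s_means, s_resid = split(score_by)
    a_means, a_resid = split(amp_by)

    def spear(u, v):
        return _spearman(stats.rankdata(u), stats.rankdata(v))

    between = spear(s_means, a_means)
    within = spear(
        np.concatenate([s_resid[s] for s in sids]),
        np.concatenate([a_resid[s] for s in sids]),
    )

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 2))
    redrawn = 0
    n_sub = len(sids)
    for b in range(n_boot):
        while True:
            pick = rng.integers(0, n_sub, size=n_sub)
            if np.unique(pick).size >= 2:
                break
            redrawn += 1
        bm_s = s_means[pick]
        bm_a = a_means[pick]
        br = np.concatenate([s_resid[sids[i]] for i in pick])
        ba = np.concatenate([a_resid[sids[i]] for i in pick])
        boot[b, 0] = abs(spear(bm_s, bm_a))
        boot[b, 1] = abs(spear(br, ba))
    p_gt = float(np.mean(boot[:, 0] > boot[:, 1]))
    return EffectComparison(between, within, loadings, boot, p_gt, redrawn, seed)


def compare_bootstrap(boot_a: np.ndarray, boot_b: np.ndarray) -> float:
    """Fraction of bootstrap draws with correlation_a > correlation_b."""
    return float(np.mean(np.asarray(boot_a) > np.asarray(boot_b)))
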