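"""Time-delay-embedded Gaussian hidden Markov model of network states.

Each sample of the (1-35 Hz, z-scored, concatenated) parcel data is
augmented with lagged copies of all parcels (default +-7 lags at 250 Hz,
i.e. a ~60 ms window), reduced by PCA (default 2x the parcel count), and
modelled as a K-state HMM whose states are zero-mean Gaussians with full
covariance.  Because the observation vector contains the local lag
structure, a state's covariance encodes its autocovariance — and hence its
spectral — signature, so states capture patterns of band-limited power and
phase coupling rather than mere instantaneous amplitude.

Inference is maximum-likelihood EM (Baum-Welch) with an exact
forward-backward pass in log space; posteriors gamma_{t,k} and the
posterior-decoded state path feed all downstream analyses.

The public surface follows the model/results convention: build a
:class:`TDEHMM` from a :class:`~gammastates.preprocess.ConcatenatedData`,
call :meth:`TDEHMM.fit`, and read everything off the returned
:class:`TDEHMMResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .preprocess import ConcatenatedData

__all__ = [
    "embed_timedelay",
    "pca_reduce",
    "fit_hmm",
    "posterior_probabilities",
    "decode_states",
    "match_labels",
    "HMMParameters",
    "TDEHMM",
    "TDEHMMResults",
]

_LOG_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# Embedding and reduction
# ---------------------------------------------------------------------------


def lag_window(n_lags: int) -> list[int]:
    """Symmetric lag set -n..+n."""
    return list(range(-n_lags, n_lags + 1))


def embed_timedelay(
    segments: list[np.ndarray], lags: list[int]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Stack lagged copies of every parcel, per segment.

    Returns ``(embedded, masks)``: for each segment an array of valid rows
    (row t holds ``x[t+l]`` for every lag l, parcel-major) and a boolean
    mask over the segment's samples marking which rows are valid.  The
    embedding never crosses segment boundaries; segments shorter than the
    lag window are dropped (empty mask) with a warning.
    """
    lags = sorted(int(l) for l in lags)
    span = lags[-1] - lags[0]
    offsets = [l - lags[0] for l in lags]
    embedded, masks = [], []
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        T, P = seg.shape
        mask = np.zeros(T, dtype=bool)
        if T <= span:
            warnings.warn(
                f"segment of {T} samples shorter than the lag window "
                f"({span + 1}); dropped from embedding",
                stacklevel=2,
            )
            embedded.append(np.empty((0, P * len(lags))))
            masks.append(mask)
            continue
        # sliding_window_view: sw[i, p, j] = seg[i + j, p]
        sw = np.lib.stride_tricks.sliding_window_view(seg, span + 1, axis=0)
        emb = sw[:, :, offsets].reshape(T - span, P * len(lags))
        mask[-lags[0] : T - lags[-1]] = True
        embedded.append(np.ascontiguousarray(emb))
        masks.append(mask)
    return embedded, masks


def pca_reduce(
    embedded: list[np.ndarray], pca_dim: int, seed: int | None = 0
) -> tuple[list[np.ndarray], PCA]:
    """Project embedded segments onto the top ``pca_dim`` principal axes.

    The projection is fitted on the pooled valid rows and returned for
    reuse on held-out data.
    """
    X = np.concatenate([e for e in embedded if e.shape[0]], axis=0)
    if pca_dim > X.shape[1]:
        raise ValueError(f"pca_dim {pca_dim} exceeds embedded width {X.shape[1]}")
    pca = PCA(n_components=pca_dim, svd_solver="auto", random_state=seed)
    pca.fit(X)
    return [pca.transform(e) if e.shape[0] else e for e in embedded], pca


# ---------------------------------------------------------------------------
# Forward-backward (log space, numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fb_pass(logB, logA, logpi):  # pragma: no cover - exercised via wrapper
    T, K = logB.shape
    la = np.empty((T, K))
    lb = np.empty((T, K))
    for k in range(K):
        la[0, k] = logpi[k] + logB[0, k]
    for t in range(1, T):
        for k in range(K):
            m = -np.inf
            for j in range(K):
                v = la[t - 1, j] + logA[j, k]
                if v > m:
                    m = v
            if m == -np.inf:
                la[t, k] = -np.inf
                continue
            s = 0.0
            for j in range(K):
                s += np.exp(la[t - 1, j] + logA[j, k] - m)
            la[t, k] = m + np.log(s) + logB[t, k]
    for k in range(K):
        lb[T - 1, k] = 0.0
    for t in range(T - 2, -1, -1):
        for k in range(K):
            m = -np.inf
            for j in range(K):
                v = logA[k, j] + logB[t + 1, j] + lb[t + 1, j]
                if v > m:
                    m = v
            if m == -np.inf:
                lb[t, k] = -np.inf
                continue
            s = 0.0
            for j in range(K):
                s += np.exp(logA[k, j] + logB[t + 1, j] + lb[t + 1, j] - m)
            lb[t, k] = m + np.log(s)
    # total log-likelihood
    m = -np.inf
    for k in range(K):
        if la[T - 1, k] > m:
            m = la[T - 1, k]
    s = 0.0
    for k in range(K):
        s += np.exp(la[T - 1, k] - m)
    ll = m + np.log(s)

    gamma = np.empty((T, K))
    for t in range(T):
        for k in range(K):
            gamma[t, k] = np.exp(la[t, k] + lb[t, k] - ll)
        # renormalize against accumulated rounding
        rs = 0.0
        for k in range(K):
            rs += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= rs

    xi = np.zeros((K, K))
    for t in range(T - 1):
        for j in range(K):
            for k in range(K):
                xi[j, k] += np.exp(
                    la[t, j] + logA[j, k] + logB[t + 1, k] + lb[t + 1, k] - ll
                )
    return gamma, xi, ll


def _log_gauss_zero_mean(X: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """log N(x_t | 0, Sigma_k) for every sample and state."""
    T, D = X.shape
    K = covs.shape[0]
    logB = np.empty((T, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        z = solve_triangular(L, X.T, lower=True)
        maha = np.sum(z * z, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        logB[:, k] = -0.5 * (D * np.log(2 * np.pi) + logdet + maha)
    return logB


@dataclass
class HMMParameters:
    """Zero-mean Gaussian HMM parameters (observation space = PCA space)."""

    initial: np.ndarray        # (K,)
    transition: np.ndarray     # (K, K) row-stochastic
    covariances: np.ndarray    # (K, D, D) symmetric positive-definite

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]


def posterior_probabilities(
    sequences: list[np.ndarray], params: HMMParameters
) -> tuple[list[np.ndarray], np.ndarray, float]:
    """Exact forward-backward posteriors for fixed parameters.

    Returns per-sequence gamma arrays, the summed transition-count matrix
    xi, and the total log-likelihood.
    """
    logpi = np.log(np.maximum(params.initial, _LOG_FLOOR))
    logA = np.log(np.maximum(params.transition, _LOG_FLOOR))
    gammas, xi_sum, ll_sum = [], np.zeros_like(params.transition), 0.0
    for X in sequences:
        if X.shape[0] == 0:
            gammas.append(np.empty((0, params.n_states)))
            continue
        logB = _log_gauss_zero_mean(X, params.covariances)
        gamma, xi, ll = _fb_pass(logB, logA, logpi)
        gammas.append(gamma)
        xi_sum += xi
        ll_sum += ll
    return gammas, xi_sum, ll_sum


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _regularize(cov: np.ndarray, cov_reg: float) -> np.ndarray:
    D = cov.shape[0]
    ridge = cov_reg * (np.trace(cov) / D + 1e-12)
    return cov + ridge * np.eye(D)


def _m_step(
    sequences: list[np.ndarray],
    gammas: list[np.ndarray],
    xi_sum: np.ndarray,
    cov_reg: float,
) -> HMMParameters:
    K = xi_sum.shape[0]
    D = sequences[0].shape[1]
    first = np.sum([g[0] for g in gammas if g.shape[0]], axis=0)
    initial = first / first.sum()
    rows = xi_sum.sum(axis=1, keepdims=True)
    transition = np.where(rows > 0, xi_sum / np.maximum(rows, 1e-30), 1.0 / K)

    covs = np.empty((K, D, D))
    total = np.zeros(K)
    for k in range(K):
        acc = np.zeros((D, D))
        for X, g in zip(sequences, gammas):
            if X.shape[0] == 0:
                continue
            w = g[:, k]
            acc += (X * w[:, None]).T @ X
            total[k] += w.sum()
        covs[k] = _regularize(acc / max(total[k], 1e-12), cov_reg)
    floor = 2 * D
    weak = np.flatnonzero(total < floor)
    if weak.size:
        warnings.warn(
            f"state(s) {weak.tolist()} carry < {floor} samples of posterior mass",
            stacklevel=3,
        )
    return HMMParameters(initial, transition, covs)


def _init_params(
    sequences: list[np.ndarray], K: int, cov_reg: float, seed: int
) -> HMMParameters:
    """K-means-seeded responsibilities -> initial covariances; sticky A."""
    X = np.concatenate([s for s in sequences if s.shape[0]], axis=0)
    rng = np.random.default_rng(seed)
    sub = X
    if X.shape[0] > 20000:
        sub = X[rng.choice(X.shape[0], 20000, replace=False)]
    km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2**31 - 1)))
    km.fit(sub)
    labels = km.predict(X)
    D = X.shape[1]
    covs = np.empty((K, D, D))
    for k in range(K):
        Xk = X[labels == k]
        if Xk.shape[0] < 2 * D:
            Xk = X[rng.choice(X.shape[0], 2 * D, replace=False)]
        covs[k] = _regularize(Xk.T @ Xk / Xk.shape[0], max(cov_reg, 1e-3))
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9 if K > 1 else 1.0)
    return HMMParameters(np.full(K, 1.0 / K), A, covs)


def fit_hmm(
    sequences: list[np.ndarray],
    n_states: int,
    max_iter: int = 100,
    tol: float = 1e-5,
    n_restarts: int = 5,
    cov_reg: float = 1e-5,
    seed: int = 0,
) -> tuple[HMMParameters, list[np.ndarray], list[float], bool]:
    """Maximum-likelihood EM for the zero-mean Gaussian HMM.

    ``sequences`` are independent chains (the forward-backward recursion is
    restarted at each segment boundary).  The best of ``n_restarts``
    k-means-seeded runs by final log-likelihood is returned as
    ``(params, gammas, loglik_trace, converged)``.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    sequences = [np.ascontiguousarray(s, dtype=float) for s in sequences]
    T_total = sum(s.shape[0] for s in sequences)
    if T_total < n_states * 2 * sequences[0].shape[1]:
        raise ValueError("too few samples for the requested number of states")

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_restarts)]

    best = None
    for restart_seed in child_seeds:
        params = _init_params(sequences, n_states, cov_reg, restart_seed)
        trace: list[float] = []
        converged = False
        gammas: list[np.ndarray] = []
        for _ in range(max_iter):
            gammas, xi_sum, ll = posterior_probabilities(sequences, params)
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
                converged = True
                break
            params = _m_step(sequences, gammas, xi_sum, cov_reg)
        if not converged:
            # one final E-step so posteriors match the returned parameters
            gammas, _, ll = posterior_probabilities(sequences, params)
            trace.append(ll)
            warnings.warn("EM did not converge within max_iter", stacklevel=2)
        if best is None or trace[-1] > best[2][-1]:
            best = (params, gammas, trace, converged)
    return best


def decode_states(gamma: np.ndarray) -> np.ndarray:
    """Posterior decoding: per-sample argmax, ties to the lowest state index."""
    return np.argmax(gamma, axis=1).astype(np.int64)


def match_labels(path_a: np.ndarray, path_b: np.ndarray, K: int) -> np.ndarray:
    """Permutation ``perm`` maximizing agreement of ``perm[path_b]`` with
    ``path_a`` (Hungarian assignment on the confusion matrix)."""
    conf = np.zeros((K, K))
    np.add.at(conf, (path_a, path_b), 1.0)
    rows, cols = linear_sum_assignment(-conf)
    perm = np.empty(K, dtype=np.int64)
    perm[cols] = rows
    return perm


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


class TDEHMM:
    """Time-delay-embedded HMM over a concatenated cohort recording.

    Parameters
    ----------
    data
        Band-limited, per-subject standardized, concatenated parcel data.
    n_states
        Number of hidden states K (default 4).
    n_lags
        Half-width of the symmetric lag window; ``n_lags=7`` embeds 15
        lagged copies of every parcel.  ``n_lags=0`` disables embedding.
    pca_dim
        Dimensionality after PCA of the embedded data (default
        ``2 * n_parcels``; ignored when embedding is disabled and left
        None).
    cov_reg
        Ridge fraction added to state covariances, scaled by the mean
        diagonal (``cov_reg * trace/D``).
    """

    def __init__(
        self,
        data: ConcatenatedData,
        n_states: int = 4,
        n_lags: int = 7,
        pca_dim: int | None = None,
        cov_reg: float = 1e-5,
    ) -> None:
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        self.data = data
        self.n_states = n_states
        self.lags = lag_window(n_lags)
        if pca_dim is None and n_lags > 0:
            pca_dim = 2 * data.n_parcels
        self.pca_dim = pca_dim
        self.cov_reg = cov_reg

    def fit(
        self,
        max_iter: int = 100,
        tol: float = 1e-5,
        n_restarts: int = 5,
        seed: int = 0,
    ) -> "TDEHMMResults":
        segs = [self.data.data[sl] for _, _, sl in self.data.segment_slices()]
        if len(self.lags) > 1:
            embedded, masks = embed_timedelay(segs, self.lags)
        else:
            embedded = [np.asarray(s, dtype=float) for s in segs]
            masks = [np.ones(s.shape[0], dtype=bool) for s in segs]
        pca = None
        if self.pca_dim is not None:
            embedded, pca = pca_reduce(embedded, self.pca_dim, seed=seed)
        kept = [e for e in embedded if e.shape[0]]
        params, gammas, trace, converged = fit_hmm(
            kept,
            self.n_states,
            max_iter=max_iter,
            tol=tol,
            n_restarts=n_restarts,
            cov_reg=self.cov_reg,
            seed=seed,
        )
        # re-expand posteriors to the full concatenated time axis; samples
        # masked out by the embedding edges get the uniform 1/K
        gamma_full = np.full((self.data.n_samples, self.n_states), 1.0 / self.n_states)
        valid = np.zeros(self.data.n_samples, dtype=bool)
        it = iter(gammas)
        for ((_, _, sl), emb, mask) in zip(self.data.segment_slices(), embedded, masks):
            if emb.shape[0] == 0:
                continue
            g = next(it)
            idx = np.flatnonzero(mask) + sl.start
            gamma_full[idx] = g
            valid[idx] = True
        return TDEHMMResults(
            model=self,
            params=params,
            pca=pca,
            gamma=gamma_full,
            valid_mask=valid,
            loglik_trace=np.array(trace),
            converged=converged,
        )


@dataclass
class TDEHMMResults:
    """Fitted TDE-HMM: parameters, posteriors and diagnostics.

    ``gamma`` is aligned sample-by-sample with the model's
    :class:`~gammastates.preprocess.ConcatenatedData` (embedding-edge
    samples hold the uniform posterior and are flagged False in
    ``valid_mask``).
    """

    model: TDEHMM
    params: HMMParameters
    pca: PCA | None
    gamma: np.ndarray
    valid_mask: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    _path: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return self.params.n_states

    @property
    def transition(self) -> np.ndarray:
        return self.params.transition

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def decode(self) -> np.ndarray:
        """Posterior-decoded state path over the concatenated samples."""
        if self._path is None:
            self._path = decode_states(self.gamma)
        return self._path

    def fractional_occupancy(self, soft: bool = True) -> np.ndarray:
        g = self.gamma[self.valid_mask]
        if soft:
            return g.mean(axis=0)
        path = decode_states(g)
        return np.bincount(path, minlength=self.n_states) / path.shape[0]

    def summary(self) -> str:
        fo = self.fractional_occupancy()
        lines = [
            "Time-delay embedded HMM results",
            "===============================",
            f"states: {self.n_states}   lags: {self.model.lags[0]}..{self.model.lags[-1]}"
            f"   pca_dim: {self.model.pca_dim}",
            f"samples: {self.gamma.shape[0]} ({int(self.valid_mask.sum())} valid)",
            f"log-likelihood: {self.loglik:.2f}   EM iterations: {len(self.loglik_trace)}"
            f"   converged: {self.converged}",
            "",
            "state   FO      self-transition",
        ]
        for k in range(self.n_states):
            lines.append(
                f"  {k}    {fo[k]:.3f}      {self.params.transition[k, k]:.4f}"
            )
        return "\n".join(lines)
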