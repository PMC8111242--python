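"""Matching states across independently fitted models.

Two HMMs fitted to different recordings (e.g. rest vs task baseline) have
no shared label space.  States are matched post hoc by the similarity of
their spatial power topographies: per frequency band, the K_A x K_B matrix
of Pearson correlations between state power maps (across parcels) is
computed, the matrices are averaged over bands, and the 2K states are
grouped by agglomerative hierarchical clustering (Ward linkage, Euclidean
metric) on their correlation profiles.  Cross-model pairs that merge at the
lowest heights are the matched states; the pair with the smallest merge
height is the best match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage

from .spectra import BandPowerMap

__all__ = ["MatchResult", "power_map_correlation", "hierarchical_match", "match_states"]


def power_map_correlation(
    maps_a: BandPowerMap, maps_b: BandPowerMap
) -> tuple[np.ndarray, np.ndarray]:
    """Band-wise Pearson correlation of state power maps across parcels.

    Returns ``(corr_per_band, corr_mean)`` with shapes
    (bands, K_A, K_B) and (K_A, K_B); ``corr_mean`` is the arithmetic mean
    of the per-band matrices.  A state map with zero variance in some band
    raises, naming the state and band.
    """
    if maps_a.band_names != maps_b.band_names:
        raise ValueError("band sets differ between the two maps")
    if maps_a.values.shape[1] != maps_b.values.shape[1]:
        raise ValueError("parcel sets differ between the two maps")
    n_bands = len(maps_a.band_names)
    K_a, K_b = maps_a.values.shape[0], maps_b.values.shape[0]
    corr = np.empty((n_bands, K_a, K_b))
    for b, name in enumerate(maps_a.band_names):
        A = maps_a.values[:, :, b]
        B = maps_b.values[:, :, b]
        for label, M in (("A", A), ("B", B)):
            flat = np.flatnonzero(M.std(axis=1) == 0)
            if flat.size:
                raise ValueError(
                    f"model {label} state(s) {flat.tolist()} have a constant "
                    f"power map in band '{name}'"
                )
        Az = (A - A.mean(axis=1, keepdims=True)) / A.std(axis=1, keepdims=True)
        Bz = (B - B.mean(axis=1, keepdims=True)) / B.std(axis=1, keepdims=True)
        corr[b] = Az @ Bz.T / A.shape[1]
    return corr, corr.mean(axis=0)


@dataclass
class MatchResult:
    """Cross-model state pairing derived from power-map similarity.

    ``matched_pairs`` lists (state_a, state_b, merge_height) in ascending
    height order; ``best_match`` is the first entry.  ``linkage`` is the
    scipy linkage matrix over the 2K states (leaves 0..K-1 = model A,
    K..2K-1 = model B).
    """

    corr_per_band: np.ndarray
    corr_mean: np.ndarray
    linkage: np.ndarray
    matched_pairs: list[tuple[int, int, float]]

    @property
    def best_match(self) -> tuple[int, int, float]:
        return self.matched_pairs[0]

    @property
    def pairing(self) -> dict[int, int]:
        """state_a -> state_b for all matched pairs."""
        return {a: b for a, b, _ in self.matched_pairs}


def hierarchical_match(
    corr_mean: np.ndarray,
    corr_per_band: np.ndarray | None = None,
    corr_full: np.ndarray | None = None,
) -> MatchResult:
    """Group the 2K states by hierarchical clustering and pair across models.

    Each of the 2K states is represented by its row of the joint 2K x 2K
    band-averaged correlation matrix over all state maps (``corr_full``;
    leaves 0..K-1 = model A, K..2K-1 = model B), so identical states carry
    identical profiles and merge at height ~0, and the pairing follows any
    relabeling of either model.  When only the cross-model block
    ``corr_mean`` is available the joint matrix is assembled from it with
    unit within-model diagonals (exact whenever the two models' states are
    near-copies of each other).  Ward linkage with Euclidean distances
    builds the tree; cross-model pairs are read off greedily in order of
    increasing cophenetic merge height, removing both partners after each
    match.  Ties break by (state_a, state_b) index order.
    """
    corr_mean = np.asarray(corr_mean, dtype=float)
    if not np.all(np.isfinite(corr_mean)):
        raise ValueError("corr_mean contains non-finite values")
    K_a, K_b = corr_mean.shape
    if K_a != K_b:
        raise ValueError("joint 2K clustering requires equally many states per model")
    K = K_a
    if corr_full is None:
        corr_full = np.block(
            [[np.eye(K), corr_mean], [corr_mean.T, np.eye(K)]]
        )
    features = np.asarray(corr_full, dtype=float)
    if features.shape != (2 * K, 2 * K):
        raise ValueError("corr_full must be 2K x 2K")
    Z = linkage(features, method="ward")
    coph = cophenet(Z)  # condensed over the 2K leaves

    def cdist(i: int, j: int) -> float:
        a, b = min(i, j), max(i, j)
        n = 2 * K
        idx = n * a - a * (a + 1) // 2 + (b - a - 1)
        return float(coph[idx])

    candidates = sorted(
        ((cdist(a, K + b), a, b) for a in range(K) for b in range(K)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for h, a, b in candidates:
        if a in used_a or b in used_b:
            continue
        pairs.append((a, b, h))
        used_a.add(a)
        used_b.add(b)
    return MatchResult(
        corr_per_band if corr_per_band is not None else np.empty((0, K, K)),
        corr_mean,
        Z,
        pairs,
    )


def match_states(maps_a: BandPowerMap, maps_b: BandPowerMap) -> MatchResult:
    """Full matching chain from two band power maps.

    Computes the band-wise cross-model correlations, the joint 2K x 2K
    band-averaged correlation over all state maps, and the hierarchical
    pairing.
    """
    per_band, mean = power_map_correlation(maps_a, maps_b)
    K = maps_a.values.shape[0]
    stacked = BandPowerMap(
        np.concatenate([maps_a.values, maps_b.values], axis=0),
        maps_a.bands,
        maps_a.representation,
    )
    _, full = power_map_correlation(stacked, stacked)
    return hierarchical_match(mean, per_band, corr_full=full)
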