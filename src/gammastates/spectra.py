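"""State-specific power and coherence via state-weighted multitaper spectra.

Ordinary multitaper spectral estimation averages tapered periodograms over
sliding windows.  To obtain *state-specific* spectra from a continuous
recording with soft state assignments, each window's cross-spectral matrix
is weighted by the window-mean of the normalized state probability

    rho_{t,k} = gamma_{t,k} / mean_t(gamma_{t,k}),

which has unit time-mean per state.  A state that is twice as likely as its
average in some window pulls that window into its spectrum with double
weight; with rho identically 1 the estimator reduces exactly to the
ordinary multitaper spectrum, and the occupancy-weighted mean of the state
spectra reproduces the ordinary spectrum.  This makes low frequencies
estimable even though individual state visits are short (~100 ms): what
matters is the total time credited to the state.

Band summaries ("power maps") average power over canonical bands and are
expressed either absolutely or relative to the mean over states,
(value - mean) / mean, matching how state topographies are usually shown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .preprocess import ConcatenatedData

__all__ = [
    "BANDS",
    "FEATURE_BANDS",
    "RhoWeights",
    "StateSpectra",
    "BandPowerMap",
    "compute_rho",
    "weighted_multitaper",
    "band_maps",
    "mean_coupling",
]

#: canonical analysis bands (Hz); gamma is evaluated on unfiltered data
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (60.0, 90.0),
}

#: alternative preset with the wider delta band used for feature analyses
FEATURE_BANDS: dict[str, tuple[float, float]] = {**BANDS, "delta": (1.0, 4.0)}


@dataclass
class RhoWeights:
    """Normalized state weights rho (T x K); each column has time-mean 1."""

    rho: np.ndarray

    @property
    def n_states(self) -> int:
        return self.rho.shape[1]


def compute_rho(gamma: np.ndarray) -> RhoWeights:
    """Posterior probabilities normalized by their time means.

    rho_{t,k} = gamma_{t,k} * T / sum_t gamma_{t,k}.  Raises if a state has
    zero total posterior mass.
    """
    gamma = np.asarray(gamma, dtype=float)
    mass = gamma.sum(axis=0)
    dead = np.flatnonzero(mass <= 0)
    if dead.size:
        raise ValueError(f"state(s) {dead.tolist()} have zero total posterior mass")
    return RhoWeights(gamma * (gamma.shape[0] / mass)[None, :])


@dataclass
class StateSpectra:
    """Per-state multitaper power and coherence.

    ``power`` is K x parcels x freqs; ``coherence`` (optional) is
    K x parcels x parcels x freqs magnitude-squared coherence.
    """

    power: np.ndarray
    coherence: np.ndarray | None
    freqs: np.ndarray
    n_tapers: int
    window_s: float
    overlap: float

    @property
    def n_states(self) -> int:
        return self.power.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.power.shape[1]


def _dpss_tapers(n: int, n_tapers: int) -> np.ndarray:
    """Slepian tapers; time-bandwidth chosen minimally so n_tapers fit
    (NW = (n_tapers + 1) / 2)."""
    nw = (n_tapers + 1) / 2.0
    return windows.dpss(n, nw, Kmax=n_tapers)


def weighted_multitaper(
    data: ConcatenatedData,
    rho: RhoWeights | np.ndarray,
    window_s: float = 2.0,
    overlap: float = 0.5,
    n_tapers: int = 3,
    freq_range: tuple[float, float] = (1.0, 98.0),
    compute_coherence: bool = True,
) -> StateSpectra:
    """Sliding-window multitaper cross-spectra, weighted per state.

    Windows are cut within segments (never across boundaries); each
    window's tapered cross-spectral matrix contributes to state k with
    weight equal to the window-mean rho_k.  Power is the (real) diagonal;
    coherence is |S_pq|^2 / (S_pp S_qq) of the weighted averages.
    """
    if isinstance(rho, np.ndarray):
        rho = RhoWeights(np.asarray(rho, dtype=float))
    if rho.rho.shape[0] != data.n_samples:
        raise ValueError("rho is not aligned with the data samples")
    fs = data.fs
    win = int(round(window_s * fs))
    if win < 2:
        raise ValueError("window too short")
    hop = max(1, int(round(win * (1.0 - overlap))))
    if freq_range[1] > fs / 2:
        raise ValueError(f"freq_range {freq_range} exceeds Nyquist {fs / 2}")

    freqs_all = np.fft.rfftfreq(win, d=1.0 / fs)
    fsel = np.flatnonzero((freqs_all >= freq_range[0]) & (freqs_all <= freq_range[1]))
    freqs = freqs_all[fsel]
    tapers = _dpss_tapers(win, n_tapers)

    K = rho.n_states
    P = data.n_parcels
    F = fsel.size
    acc = np.zeros((K, P, P, F), dtype=complex) if compute_coherence else None
    acc_pow = np.zeros((K, P, F))
    wsum = np.zeros(K)
    n_windows = 0
    longest = 0
    for _, _, sl in data.segment_slices():
        seg = data.data[sl]
        g = rho.rho[sl]
        T = seg.shape[0]
        longest = max(longest, T)
        for start in range(0, T - win + 1, hop):
            x = seg[start : start + win]
            w = g[start : start + win].mean(axis=0)
            # tapered FFTs: (R, P, F)
            X = np.fft.rfft(tapers[:, None, :] * x.T[None, :, :], axis=2)[:, :, fsel]
            if compute_coherence:
                cs = np.einsum("rpf,rqf->pqf", X, np.conj(X)) / n_tapers
                acc += w[:, None, None, None] * cs[None]
            else:
                pw = np.mean(np.abs(X) ** 2, axis=0)  # (P, F)
                acc_pow += w[:, None, None] * pw[None]
            wsum += w
            n_windows += 1
    if n_windows == 0:
        raise ValueError(
            f"window of {win} samples longer than every segment (longest {longest})"
        )

    norm = np.maximum(wsum, 1e-30)[:, None, None]
    power = acc_pow / norm
    coherence = None
    if compute_coherence:
        S = acc / np.maximum(wsum, 1e-30)[:, None, None, None]
        auto = np.real(np.einsum("kppf->kpf", S))
        denom = auto[:, :, None, :] * auto[:, None, :, :]
        coherence = np.abs(S) ** 2 / np.maximum(denom, 1e-300)
        coherence = np.clip(coherence, 0.0, 1.0)
        power = auto
    return StateSpectra(power, coherence, freqs, n_tapers, window_s, overlap)


@dataclass
class BandPowerMap:
    """Band-averaged state power: ``values`` is K x parcels x bands."""

    values: np.ndarray
    bands: dict[str, tuple[float, float]]
    representation: str  # "absolute" | "relative"

    @property
    def band_names(self) -> list[str]:
        return list(self.bands)

    def band(self, name: str) -> np.ndarray:
        """K x parcels slice for one named band."""
        return self.values[:, :, self.band_names.index(name)]


def band_maps(
    spectra: StateSpectra, bands: dict[str, tuple[float, float]] | None = None
) -> tuple[BandPowerMap, BandPowerMap]:
    """Absolute and relative (to the state mean) band power maps.

    The relative map is (value - mean over states) / mean over states, so
    relative maps average to zero across states for every parcel and band.
    Bands that contain no frequency bin raise.
    """
    if bands is None:
        bands = BANDS
    K, P, _ = spectra.power.shape
    vals = np.empty((K, P, len(bands)))
    for b, (name, (lo, hi)) in enumerate(bands.items()):
        sel = (spectra.freqs >= lo) & (spectra.freqs <= hi)
        if not np.any(sel):
            raise ValueError(f"band {name} ({lo}-{hi} Hz) is empty on the frequency grid")
        vals[:, :, b] = spectra.power[:, :, sel].mean(axis=2)
    mean = vals.mean(axis=0, keepdims=True)
    rel = (vals - mean) / np.maximum(mean, 1e-300)
    return (
        BandPowerMap(vals, dict(bands), "absolute"),
        BandPowerMap(rel, dict(bands), "relative"),
    )


def mean_coupling(
    spectra: StateSpectra, bands: dict[str, tuple[float, float]] | None = None
) -> np.ndarray:
    """Average coherence of each parcel with all other parcels, per band.

    Returns K x parcels x bands.
    """
    if spectra.coherence is None:
        raise ValueError("spectra were computed without coherence")
    if bands is None:
        bands = BANDS
    K, P, _, _ = spectra.coherence.shape
    out = np.empty((K, P, len(bands)))
    off = ~np.eye(P, dtype=bool)
    for b, (name, (lo, hi)) in enumerate(bands.items()):
        sel = (spectra.freqs >= lo) & (spectra.freqs <= hi)
        if not np.any(sel):
            raise ValueError(f"band {name} ({lo}-{hi} Hz) is empty on the frequency grid")
        cb = spectra.coherence[:, :, :, sel].mean(axis=3)  # K x P x P
        out[:, :, b] = np.where(off[None], cb, 0.0).sum(axis=2) / (P - 1)
    return out
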