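"""Quick-look plots for fitted models and coupling statistics (matplotlib)."""

from __future__ import annotations

import numpy as np

from .dynamics import TimelockedFO
from .spectra import BandPowerMap
from .stats import EffectComparison

__all__ = ["plot_band_map", "plot_timelocked_fo", "plot_effect_comparison"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_band_map(bmap: BandPowerMap, band: str, parcel_names=None, ax=None):
    """Heatmap of one band's power map (states x parcels)."""
    ax = _axes(ax)
    M = bmap.band(band)
    vmax = np.nanmax(np.abs(M))
    im = ax.imshow(M, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xlabel("parcel")
    ax.set_ylabel("state")
    ax.set_title(f"{band} power ({bmap.representation})")
    if parcel_names is not None:
        ax.set_xticks(range(len(parcel_names)), parcel_names, rotation=90, fontsize=6)
    ax.figure.colorbar(im, ax=ax)
    return ax


def plot_timelocked_fo(tl: TimelockedFO, ax=None):
    """Trial-averaged state probability over the baseline, +-1 SD bands."""
    ax = _axes(ax)
    for k in range(tl.fo.shape[1]):
        ax.plot(tl.times, tl.fo[:, k], label=f"state {k}")
        ax.fill_between(
            tl.times, tl.fo[:, k] - tl.sd[:, k], tl.fo[:, k] + tl.sd[:, k], alpha=0.2
        )
    ax.set_xlabel("time from fixation onset (s)")
    ax.set_ylabel("fractional occupancy")
    ax.legend(fontsize=8)
    return ax


def plot_effect_comparison(effects: EffectComparison, ax=None):
    """Bootstrap distributions of |between| and |within| correlations."""
    ax = _axes(ax)
    ax.boxplot(
        [effects.bootstrap[:, 0], effects.bootstrap[:, 1]],
        tick_labels=["between (subj)", "within (trial)"],
    )
    ax.set_ylabel("|Spearman r| (bootstrap)")
    ax.set_title(f"P(|between| > |within|) = {effects.p_between_gt_within:.2f}")
    return ax
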