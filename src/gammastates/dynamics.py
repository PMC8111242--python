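"""Temporal statistics of state time courses.

Fractional occupancy (FO) is the fraction of samples assigned to a state
(or its mean posterior probability); lifetimes are the durations of
uninterrupted state visits; interval times are the gaps between successive
visits of the same state.  Visits truncated by a segment boundary have
censored durations and are excluded from lifetime statistics; gaps are
bounded by visits on both sides and therefore always fully observed.

Time-locked FO averages state indicators (or posteriors) across trials at
each latency relative to an event — e.g. fixation-cross onset — exposing
systematic drifts of state probability across the baseline period, which
are quantified by per-subject regression slopes and a one-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "fractional_occupancy",
    "lifetimes",
    "interval_times",
    "state_runs",
    "TimelockedFO",
    "timelocked_fo",
    "FOSlopeTest",
    "fo_slope_test",
]


def fractional_occupancy(x: np.ndarray, n_states: int | None = None) -> np.ndarray:
    """FO vector of one unit (recording, trial, ...).

    ``x`` is either a 1-D label path (hard-assignment counts / length) or a
    2-D posterior array (column means).  The result sums to 1.
    """
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("empty unit")
    if x.ndim == 1:
        if n_states is None:
            n_states = int(x.max()) + 1
        return np.bincount(x.astype(int), minlength=n_states) / x.shape[0]
    if x.ndim == 2:
        return x.mean(axis=0)
    raise ValueError("x must be a label path or a posterior matrix")


def state_runs(path: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of identical labels as (state, start, stop) half-open."""
    path = np.asarray(path)
    if path.size == 0:
        return []
    change = np.flatnonzero(np.diff(path) != 0) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [path.size]])
    return [(int(path[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def _iter_segments(path: np.ndarray, segments):
    if segments is None:
        yield path
    else:
        for a, b in segments:
            yield path[a:b]


def lifetimes(
    path: np.ndarray, fs: float, n_states: int | None = None, segments=None
) -> dict[int, np.ndarray]:
    """Durations (s) of complete state visits, per state.

    Runs touching a segment boundary are censored and excluded.
    ``segments`` is an optional list of half-open (start, stop) pairs.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if n_states is None:
        n_states = int(np.max(path)) + 1
    out: dict[int, list[float]] = {k: [] for k in range(n_states)}
    for seg in _iter_segments(np.asarray(path), segments):
        runs = state_runs(seg)
        for k, a, b in runs[1:-1]:  # first and last runs are edge-truncated
            out[k].append((b - a) / fs)
    return {k: np.asarray(v) for k, v in out.items()}


def interval_times(
    path: np.ndarray, fs: float, n_states: int | None = None, segments=None
) -> dict[int, np.ndarray]:
    """Gaps (s) between successive visits of each state, per state.

    A gap is bounded by visits on both sides, so every gap within a segment
    is fully observed (the flanking visits need not be complete).
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if n_states is None:
        n_states = int(np.max(path)) + 1
    out: dict[int, list[float]] = {k: [] for k in range(n_states)}
    for seg in _iter_segments(np.asarray(path), segments):
        ends: dict[int, int] = {}
        for k, a, b in state_runs(seg):
            if k in ends:
                out[k].append((a - ends[k]) / fs)
            ends[k] = b
    return {k: np.asarray(v) for k, v in out.items()}


@dataclass
class TimelockedFO:
    """Trial-averaged state probability locked to an event.

    ``fo`` is time x K (grand mean over subjects), ``sd`` the standard
    deviation over subjects, ``per_subject`` subjects x time x K,
    ``coverage`` the per-subject-and-time trial counts.  Time points not
    covered by any trial of a subject are NaN for that subject.
    """

    times: np.ndarray
    fo: np.ndarray
    sd: np.ndarray
    per_subject: np.ndarray
    coverage: np.ndarray
    subject_ids: list[str]

    def to_frame(self):
        """Long-format (time_s, state, mean, sd) table for export."""
        import pandas as pd

        K = self.fo.shape[1]
        rows = [
            {"time_s": t, "state": k, "mean": self.fo[i, k], "sd": self.sd[i, k]}
            for i, t in enumerate(self.times)
            for k in range(K)
        ]
        return pd.DataFrame(rows)


def timelocked_fo(
    trials_by_subject: dict[str, list[np.ndarray]],
    fs: float,
    n_states: int,
    t_start: float = 0.0,
) -> TimelockedFO:
    """Average state time courses across trials, locked to a common event.

    Each trial array is either a 1-D label path or a 2-D posterior, with
    sample 0 at latency ``t_start`` relative to the event.  Trials of
    different lengths are padded out of the average (NaN-aware mean with a
    coverage count).
    """
    sids = list(trials_by_subject)
    max_len = max(t.shape[0] for ts in trials_by_subject.values() for t in ts)
    n_sub = len(sids)
    per = np.full((n_sub, max_len, n_states), np.nan)
    cov = np.zeros((n_sub, max_len), dtype=int)
    for i, sid in enumerate(sids):
        acc = np.zeros((max_len, n_states))
        for trial in trials_by_subject[sid]:
            trial = np.asarray(trial)
            if trial.ndim == 1:
                ind = np.zeros((trial.shape[0], n_states))
                ind[np.arange(trial.shape[0]), trial.astype(int)] = 1.0
            else:
                ind = trial
            L = ind.shape[0]
            acc[:L] += ind
            cov[i, :L] += 1
        with np.errstate(invalid="ignore"):
            per[i] = acc / np.maximum(cov[i], 1)[:, None]
        per[i, cov[i] == 0] = np.nan
    fo = np.nanmean(per, axis=0)
    sd = np.nanstd(per, axis=0, ddof=1)
    times = t_start + np.arange(max_len) / fs
    return TimelockedFO(times, fo, sd, per, cov, sids)


@dataclass
class FOSlopeTest:
    """Per-subject FO-on-time regression slopes and their group t-test."""

    state: int
    slopes: np.ndarray   # per subject, in FO units per second
    mean_slope: float
    t_stat: float
    p_value: float

    def summary(self) -> str:
        return (
            f"FO slope, state {self.state}: mean = {self.mean_slope:.4f} /s "
            f"(n = {self.slopes.size}), t = {self.t_stat:.2f}, p = {self.p_value:.3g}"
        )


def fo_slope_test(
    tl: TimelockedFO, state: int, window: tuple[float, float] | None = None
) -> FOSlopeTest:
    """OLS slope of time-locked FO on time per subject; t-test against 0.

    ``window`` restricts the fit to latencies in [t0, t1]; NaN time points
    (not covered by a subject's trials) are dropped per subject.
    """
    if tl.per_subject.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    sel = np.ones_like(tl.times, dtype=bool)
    if window is not None:
        sel = (tl.times >= window[0]) & (tl.times <= window[1])
    slopes = []
    for i in range(tl.per_subject.shape[0]):
        y = tl.per_subject[i, sel, state]
        t = tl.times[sel]
        ok = ~np.isnan(y)
        if ok.sum() < 2:
            raise ValueError(f"subject {tl.subject_ids[i]}: too few covered time points")
        slopes.append(np.polyfit(t[ok], y[ok], 1)[0])
    slopes = np.asarray(slopes)
    t_stat, p = stats.ttest_1samp(slopes, 0.0)
    return FOSlopeTest(state, slopes, float(slopes.mean()), float(t_stat), float(p))
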