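"""Preparation of parcel time series for state inference.

Parcel-level recordings are band-pass filtered to the sub-gamma range
(default 1-35 Hz), trial baselines are extracted with the first second
stripped (it carries motor activity from the previous trial's button press),
each subject's data is z-scored using that subject's pooled statistics, and
everything is concatenated in time for group-level state inference.  A
sign-alignment step resolves the arbitrary per-parcel sign of beamformed
source estimates across subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "ParcelTimeSeries",
    "ConcatenatedData",
    "bandpass",
    "extract_baselines",
    "zscore_concatenate",
    "align_signs",
]


@dataclass(frozen=True)
class Segment:
    """Half-open sample interval [start, stop) with a role label.

    ``label`` is one of ``"rest"``, ``"baseline"``, ``"trial"``;
    ``segment_id`` ties baseline segments back to their trial ids.
    """

    start: int
    stop: int
    label: str = "rest"
    segment_id: int = 0

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError(f"empty segment [{self.start}, {self.stop})")

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass
class ParcelTimeSeries:
    """Multichannel parcel signal: ``data`` is samples x parcels at ``fs`` Hz.

    ``segments`` mark the sub-intervals of interest (half-open, 0-based,
    non-overlapping).  When empty, the whole recording counts as a single
    segment.
    """

    data: np.ndarray
    fs: float
    subject_id: str = "S0"
    segments: list[Segment] = field(default_factory=list)
    parcel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be samples x parcels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        n = self.data.shape[0]
        prev_stop = -1
        for seg in sorted(self.segments, key=lambda s: s.start):
            if seg.start < 0 or seg.stop > n:
                raise ValueError(f"segment {seg} out of bounds (T={n})")
            if seg.start < prev_stop:
                raise ValueError(f"segment {seg} overlaps a previous one")
            prev_stop = seg.stop

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    def effective_segments(self) -> list[Segment]:
        """Segments to analyse; the full recording if none were marked."""
        if self.segments:
            return sorted(self.segments, key=lambda s: s.start)
        return [Segment(0, self.n_samples, "rest", 0)]


@dataclass
class ConcatenatedData:
    """Per-subject standardized segments stacked along time.

    ``index`` has one row per concatenated segment with columns
    ``subject_id, segment_id, label, start, stop`` (positions into ``data``).
    """

    data: np.ndarray
    fs: float
    index: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"subject_id", "segment_id", "label", "start", "stop"}
        if not need.issubset(self.index.columns):
            raise ValueError(f"index must have columns {sorted(need)}")
        stops = self.index["stop"].to_numpy()
        starts = self.index["start"].to_numpy()
        if len(self.index):
            if starts[0] != 0 or not np.all(starts[1:] == stops[:-1]):
                raise ValueError("index does not tile the data contiguously")
            if stops[-1] != self.data.shape[0]:
                raise ValueError("index does not cover every sample")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.index["subject_id"]))

    def segment_slices(self) -> list[tuple[str, int, slice]]:
        """(subject_id, segment_id, slice into data) per segment."""
        return [
            (row.subject_id, int(row.segment_id), slice(int(row.start), int(row.stop)))
            for row in self.index.itertuples()
        ]

    def subject_rows(self, subject_id: str) -> np.ndarray:
        """Boolean per-sample mask selecting one subject's samples."""
        mask = np.zeros(self.n_samples, dtype=bool)
        for row in self.index.itertuples():
            if row.subject_id == subject_id:
                mask[int(row.start) : int(row.stop)] = True
        return mask


def _design_bandpass(low: float, high: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if not (0.0 < low < high):
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(
    ts: ParcelTimeSeries, low: float = 1.0, high: float = 35.0, order: int = 4
) -> ParcelTimeSeries:
    """Zero-phase band-pass filter (4th-order Butterworth, forward-backward).

    The default 1-35 Hz band restricts state inference to sub-gamma activity
    so that inferred states cannot be driven by gamma oscillations directly.
    """
    sos = _design_bandpass(low, high, ts.fs, order=order)
    out = signal.sosfiltfilt(sos, ts.data, axis=0)
    return replace(ts, data=out)


def extract_baselines(
    ts: ParcelTimeSeries, events: pd.DataFrame, strip_seconds: float = 1.0
) -> ParcelTimeSeries:
    """Mark pre-stimulus baseline segments, dropping the first ``strip_seconds``.

    ``events`` needs columns ``trial_id, baseline_onset_s, stim_onset_s``.
    Each baseline segment runs from ``baseline_onset + strip_seconds`` to
    ``stim_onset`` (half-open, in samples).  Baselines shorter than the strip
    are dropped with a warning.  Returns a copy of ``ts`` whose ``segments``
    are the retained baselines (segment_id = trial_id).
    """
    if strip_seconds < 0:
        raise ValueError("strip_seconds must be >= 0")
    fs = ts.fs
    segments: list[Segment] = []
    for row in events.itertuples():
        start = int(round((row.baseline_onset_s + strip_seconds) * fs))
        stop = int(round(row.stim_onset_s * fs))
        if stop - start < 1:
            warnings.warn(
                f"trial {row.trial_id}: baseline shorter than strip "
                f"({strip_seconds} s); segment dropped",
                stacklevel=2,
            )
            continue
        segments.append(Segment(start, min(stop, ts.n_samples), "baseline", int(row.trial_id)))
    return replace(ts, segments=segments)


def zscore_concatenate(recordings: list[ParcelTimeSeries]) -> ConcatenatedData:
    """Standardize each subject with pooled segment statistics, then stack.

    All segments belonging to one subject (possibly across several
    recordings) share one mean/SD per parcel, so within-subject amplitude
    dynamics are preserved while between-subject scale differences are
    removed.
    """
    if not recordings:
        raise ValueError("no recordings given")
    fs = recordings[0].fs
    n_parcels = recordings[0].n_parcels
    for ts in recordings:
        if ts.fs != fs or ts.n_parcels != n_parcels:
            raise ValueError("all recordings must share fs and parcel count")

    by_subject: dict[str, list[ParcelTimeSeries]] = {}
    for ts in recordings:
        by_subject.setdefault(ts.subject_id, []).append(ts)

    stats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sid, tss in by_subject.items():
        pooled = np.concatenate(
            [ts.data[seg.start : seg.stop] for ts in tss for seg in ts.effective_segments()]
        )
        mu = pooled.mean(axis=0)
        sd = pooled.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"subject {sid}: zero-variance parcel(s) {bad.tolist()}")
        stats[sid] = (mu, sd)

    chunks: list[np.ndarray] = []
    rows = []
    pos = 0
    for ts in recordings:
        mu, sd = stats[ts.subject_id]
        for seg in ts.effective_segments():
            z = (ts.data[seg.start : seg.stop] - mu) / sd
            chunks.append(z)
            rows.append(
                {
                    "subject_id": ts.subject_id,
                    "segment_id": seg.segment_id,
                    "label": seg.label,
                    "start": pos,
                    "stop": pos + z.shape[0],
                }
            )
            pos += z.shape[0]
    return ConcatenatedData(np.concatenate(chunks), fs, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Sign alignment
# ---------------------------------------------------------------------------


def _lagged_autocov(data: np.ndarray, n_lags: int) -> np.ndarray:
    """Stack of autocovariance matrices C[l] = cov(x_t, x_{t+l}), l = 0..n_lags."""
    x = data - data.mean(axis=0)
    T = x.shape[0]
    mats = []
    for lag in range(n_lags + 1):
        mats.append(x[: T - lag].T @ x[lag:] / (T - lag))
    return np.stack(mats)


def _flip_cov(cov: np.ndarray, flips: np.ndarray) -> np.ndarray:
    return cov * flips[None, :, None] * flips[None, None, :]


def _consistency_objective(covs: list[np.ndarray], flips: np.ndarray) -> float:
    """Sum over subject pairs of correlations between flipped, vectorized
    lagged-autocovariance stacks."""
    vecs = []
    for s, cov in enumerate(covs):
        v = _flip_cov(cov, flips[s]).ravel()
        v = v - v.mean()
        vecs.append(v / np.linalg.norm(v))
    total = 0.0
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            total += float(vecs[i] @ vecs[j])
    return total


def align_signs(
    recordings: list[ParcelTimeSeries],
    n_lags: int = 7,
    max_sweeps: int = 20,
) -> tuple[np.ndarray, list[ParcelTimeSeries]]:
    """Resolve arbitrary per-(subject, parcel) signs across a cohort.

    Beamformed parcel time courses carry an arbitrary sign, which must agree
    across subjects before group-level concatenation.  The objective is the
    sum over subject pairs of the Pearson correlation between their
    vectorized lagged autocovariance stacks (lags 0..n_lags, matching the
    embedding window); it is invariant to flipping any parcel in *all*
    subjects at once, which is exactly the residual ambiguity.  Optimization
    is greedy: sweep over (subject, parcel), keep a flip whenever it
    increases the objective, until a full sweep makes no change.  The result
    never scores below the all-+1 assignment.

    Returns ``(flips, flipped)`` where ``flips`` is subjects x parcels of
    +-1 (subject order = input order) and ``flipped`` are sign-corrected
    copies.
    """
    n_sub = len(recordings)
    if n_sub == 0:
        raise ValueError("no recordings given")
    n_parcels = recordings[0].n_parcels
    flips = np.ones((n_sub, n_parcels))
    if n_sub == 1:
        logger.info("align_signs: single subject, identity flips")
        return flips, [replace(ts) for ts in recordings]

    covs = [_lagged_autocov(ts.data, n_lags) for ts in recordings]
    best = _consistency_objective(covs, flips)
    for _ in range(max_sweeps):
        changed = False
        for s in range(n_sub):
            for p in range(n_parcels):
                flips[s, p] *= -1
                trial = _consistency_objective(covs, flips)
                if trial > best + 1e-12:
                    best = trial
                    changed = True
                else:
                    flips[s, p] *= -1
        if not changed:
            break

    flipped = [
        replace(ts, data=ts.data * flips[s][None, :]) for s, ts in enumerate(recordings)
    ]
    return flips, flipped
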