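"""Synthetic cohort generator with planted state dynamics and gamma coupling.

Generates rest and task sessions for a cohort of subjects in which the
ground truth is known by construction:

* a hidden Markov chain switches between K states (~100 ms lifetimes at the
  default self-transition of 0.96 and 250 Hz);
* each state carries a distinct spatial topography of narrow-band (1-35 Hz)
  oscillatory power, realized as band-pass-filtered white noise gated by
  state visits;
* after each stimulus onset, a narrow-band gamma burst (subject-specific
  peak frequency in 42-74 Hz) with a Hann envelope is added to "cuneus"
  ROI parcels 0.6-2.0 s post-stimulus;
* the burst amplitude is coupled to the states at two levels: between
  subjects (subjects with higher fractional occupancy of the enhancing
  state respond more strongly) and within subjects (trials whose
  pre-stimulus state is the enhancing state respond more strongly).

Every downstream stage of the analysis therefore has a recovery test.
All randomness flows from one master seed: subject s uses
``SeedSequence([master_seed, s])``, and rest/task/amplitude streams are
spawned from it in a fixed order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import ParcelTimeSeries

__all__ = [
    "Oscillator",
    "StateSpec",
    "GammaSpec",
    "CohortConfig",
    "GroundTruth",
    "SubjectRecordings",
    "Cohort",
    "default_state_specs",
    "default_transition",
    "generate_state_sequence",
    "render_recording",
    "generate_task_session",
    "generate_cohort",
]

ANALYSIS_BAND = (1.0, 35.0)


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Oscillator:
    """One narrow-band component of a state's topography.

    ``relative_amplitude`` is the RMS of the oscillation relative to the
    white-noise floor of the recording.
    """

    parcels: tuple[int, ...]
    center_freq: float
    relative_amplitude: float
    bandwidth: float = 2.0


@dataclass(frozen=True)
class StateSpec:
    """Spatial/spectral signature of one hidden state."""

    state_id: int
    oscillators: tuple[Oscillator, ...]
    baseline_noise_sd: float = 1.0

    def validate(self, n_parcels: int) -> None:
        if self.state_id < 0:
            raise ValueError("state_id must be >= 0")
        for osc in self.oscillators:
            if not (ANALYSIS_BAND[0] <= osc.center_freq <= ANALYSIS_BAND[1]):
                raise ValueError(
                    f"center_freq {osc.center_freq} Hz outside the "
                    f"{ANALYSIS_BAND[0]}-{ANALYSIS_BAND[1]} Hz analysis band"
                )
            if len(osc.parcels) == 0:
                raise ValueError("oscillator parcel set is empty")
            if max(osc.parcels) >= n_parcels or min(osc.parcels) < 0:
                raise ValueError("oscillator parcels outside parcel count")
            if not np.isfinite(osc.relative_amplitude) or osc.relative_amplitude < 0:
                raise ValueError("relative_amplitude must be finite and >= 0")


@dataclass(frozen=True)
class GammaSpec:
    """Parameters of the planted stimulus-induced gamma response.

    ``coupling_between`` is the slope of the subject's mean burst amplitude
    on the subject's (centered) fractional occupancy of the enhancing state;
    ``coupling_within`` is the amplitude increment on trials whose
    pre-stimulus state is the enhancing state.
    """

    peak_freq_range: tuple[float, float] = (42.0, 74.0)
    burst_onset: float = 0.6      # s after stimulus onset
    burst_window: float = 1.4     # s (burst spans onset .. onset+window)
    base_amplitude: float = 1.0   # RMS units of the noise floor
    coupling_between: float = 3.0
    coupling_within: float = 0.4
    subject_amp_sd: float = 0.05
    trial_amp_sd: float = 0.15


@dataclass
class CohortConfig:
    """Study-level generator settings.

    Defaults mirror the study conditions: 15 subjects, 50 parcels at
    250 Hz, K=4 states, 2-4 s baselines, ~60 trials per subject, 5 min of
    rest, gamma peaks in 42-74 Hz.
    """

    n_subjects: int = 15
    n_parcels: int = 50
    fs: float = 250.0
    K_true: int = 4
    transition_base: np.ndarray | None = None
    subject_fo_jitter: float = 0.002
    n_trials: int = 60
    baseline_range: tuple[float, float] = (2.0, 4.0)
    post_stim_s: float = 3.0
    rest_duration_s: float = 300.0
    gamma: GammaSpec = field(default_factory=GammaSpec)
    roi_parcels: tuple[int, ...] | None = None
    state_specs: tuple[StateSpec, ...] | None = None
    enhancing_state: int = 1
    prestim_window_s: float = 0.106
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_base is None:
            self.transition_base = default_transition(self.K_true)
        self.transition_base = np.asarray(self.transition_base, dtype=float)
        _check_stochastic(self.transition_base)
        if self.transition_base.shape != (self.K_true, self.K_true):
            raise ValueError("transition_base must be K_true x K_true")
        if self.roi_parcels is None:
            self.roi_parcels = (self.n_parcels - 2, self.n_parcels - 1)
        self.roi_parcels = tuple(int(p) for p in self.roi_parcels)
        if self.state_specs is None:
            self.state_specs = default_state_specs(
                self.n_parcels,
                self.K_true,
                roi_parcels=self.roi_parcels,
                enhancing_state=self.enhancing_state,
            )
        for spec in self.state_specs:
            spec.validate(self.n_parcels)
        if self.baseline_range[0] < 1.0:
            raise ValueError("baseline_range[0] must be >= 1 s (stripped second must leave data)")
        if self.baseline_range[1] < self.baseline_range[0]:
            raise ValueError("baseline_range must be increasing")
        g = self.gamma
        for name in ("coupling_between", "coupling_within", "base_amplitude"):
            if not np.isfinite(getattr(g, name)):
                raise ValueError(f"gamma.{name} must be finite")
        if g.burst_onset + g.burst_window > self.post_stim_s:
            raise ValueError("gamma burst window extends past the trial")
        if not (0 <= self.enhancing_state < self.K_true):
            raise ValueError("enhancing_state out of range")
        if self.subject_fo_jitter < 0:
            raise ValueError("subject_fo_jitter must be >= 0")

    def parcel_names(self) -> list[str]:
        names = [f"parcel_{p:02d}" for p in range(self.n_parcels)]
        roi = list(self.roi_parcels)
        for i, p in enumerate(roi[:2]):
            names[p] = ["cuneus_l", "cuneus_r"][i]
        return names


def default_transition(K: int, self_prob: float = 0.96) -> np.ndarray:
    """Sticky row-stochastic matrix: ~100 ms mean lifetimes at 250 Hz."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return np.ones((1, 1))
    A = np.full((K, K), (1.0 - self_prob) / (K - 1))
    np.fill_diagonal(A, self_prob)
    return A


def default_state_specs(
    n_parcels: int,
    K: int = 4,
    roi_parcels: tuple[int, ...] | None = None,
    enhancing_state: int = 1,
    relative_amplitude: float = 1.5,
) -> tuple[StateSpec, ...]:
    """Well-separated state topographies over the sub-gamma band.

    Each state drives its own parcel group at a distinct frequency.  The
    occipital ROI parcels carry alpha (10 Hz) in every state *except* the
    enhancing one, planting the occipital-alpha deficit that characterizes
    the gamma-enhancing state; the enhancing state instead drives a broad
    central/parietal delta component.
    """
    if roi_parcels is None:
        roi_parcels = (n_parcels - 2, n_parcels - 1)
    roi = set(roi_parcels)
    non_roi = [p for p in range(n_parcels) if p not in roi]
    if len(non_roi) < K:
        raise ValueError("need at least K non-ROI parcels")
    groups = [tuple(int(x) for x in g) for g in np.array_split(np.array(non_roi), K)]
    freqs = [2.5, 6.0, 10.0, 16.0, 21.0, 27.0, 31.0]
    specs = []
    for k in range(K):
        f = freqs[k % len(freqs)]
        oscs = [
            Oscillator(groups[k], f, relative_amplitude, bandwidth=min(2.0, 0.8 * f))
        ]
        if k == enhancing_state:
            # broad low-frequency component reaching beyond its own group
            neighbor = groups[(k + 1) % K]
            oscs.append(Oscillator(neighbor, 2.5, 0.8 * relative_amplitude, bandwidth=1.5))
        else:
            oscs.append(
                Oscillator(tuple(sorted(roi)), 10.0, 0.9 * relative_amplitude, bandwidth=2.0)
            )
        specs.append(StateSpec(k, tuple(oscs)))
    return tuple(specs)


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class TrialTruth:
    """Planted per-trial quantities for one subject's task session."""

    prestim_state: np.ndarray      # modal true state in the pre-stimulus window
    planted_amplitude: np.ndarray  # burst amplitude actually rendered
    peak_freq: float
    subject_amplitude: float       # subject-level mean amplitude component
    fo_baseline: np.ndarray        # K-vector, true FO over baseline samples


@dataclass
class GroundTruth:
    """Planted quantities for a whole cohort, keyed by subject id."""

    enhancing_state: int
    state_paths_task: dict[str, np.ndarray]
    state_paths_rest: dict[str, np.ndarray]
    fo_baseline: dict[str, np.ndarray]
    fo_rest: dict[str, np.ndarray]
    prestim_state: dict[str, np.ndarray]
    planted_amplitude: dict[str, np.ndarray]
    subject_amplitude: dict[str, float]
    peak_freq: dict[str, float]
    transitions: dict[str, np.ndarray]

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            raise TypeError(type(x))

        return json.dumps(asdict(self), default=conv)


@dataclass
class SubjectRecordings:
    subject_id: str
    rest: ParcelTimeSeries | None
    task: ParcelTimeSeries
    events: pd.DataFrame


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectRecordings]
    ground_truth: GroundTruth

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


# ---------------------------------------------------------------------------
# Core generators
# ---------------------------------------------------------------------------


def _check_stochastic(A: np.ndarray, tol: float = 1e-8) -> None:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] < 1:
        raise ValueError("transition matrix must be square, K >= 1")
    if np.any(A < -tol) or not np.allclose(A.sum(axis=1), 1.0, atol=tol):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_state_sequence(
    transition: np.ndarray,
    n_samples: int,
    initial: np.ndarray | int | None = None,
    seed=0,
) -> np.ndarray:
    """Sample a Markov chain path of hidden-state labels (0..K-1).

    ``initial`` may be a starting state index, a probability vector, or None
    (stationary distribution of ``transition``).
    """
    _check_stochastic(transition)
    A = np.asarray(transition, dtype=float)
    K = A.shape[0]
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = _rng(seed)

    if initial is None:
        initial = stationary_distribution(A)
    if np.ndim(initial) == 0:
        s0 = int(initial)
        if not 0 <= s0 < K:
            raise ValueError("initial state out of range")
    else:
        p0 = np.asarray(initial, dtype=float)
        if p0.shape != (K,) or not np.isclose(p0.sum(), 1.0):
            raise ValueError("initial distribution must be a K-simplex vector")
        s0 = int(rng.choice(K, p=p0))

    # inverse-CDF sampling on precomputed row CDFs
    cdf = np.cumsum(A, axis=1)
    cdf[:, -1] = 1.0
    u = rng.random(n_samples)
    states = np.empty(n_samples, dtype=np.int64)
    s = s0
    states[0] = s
    for t in range(1, n_samples):
        s = int(np.searchsorted(cdf[s], u[t], side="right"))
        states[t] = s
    return states


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix at eigenvalue 1, normalized."""
    _check_stochastic(A)
    w, v = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _narrowband_noise(
    rng: np.random.Generator, n_samples: int, n_cols: int, center: float, bw: float, fs: float
) -> np.ndarray:
    """Unit-RMS band-limited noise columns centered at ``center`` Hz."""
    low = max(center - bw / 2.0, 0.05)
    high = min(center + bw / 2.0, fs / 2.0 * 0.99)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal((n_samples, n_cols)), axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def render_recording(
    states: np.ndarray,
    specs: tuple[StateSpec, ...],
    fs: float,
    seed=0,
    n_parcels: int | None = None,
) -> ParcelTimeSeries:
    """Render a label sequence into a samples x parcels signal.

    During visits to state k, the parcels of its oscillators carry elevated
    narrow-band power at the oscillators' center frequencies (band-passed
    white noise gated by the state indicator); white noise at
    ``baseline_noise_sd`` is present throughout.
    """
    states = np.asarray(states)
    labels = np.unique(states)
    spec_by_id = {s.state_id: s for s in specs}
    missing = [int(l) for l in labels if int(l) not in spec_by_id]
    if missing:
        raise ValueError(f"no StateSpec for state label(s) {missing}")
    if n_parcels is None:
        n_parcels = 1 + max(max(o.parcels) for s in specs for o in s.oscillators)
    for s in specs:
        s.validate(n_parcels)
    max_f = max(o.center_freq for s in specs for o in s.oscillators)
    if fs <= 2 * max_f:
        raise ValueError("fs must exceed twice the highest oscillator frequency")

    rng = _rng(seed)
    T = states.shape[0]
    noise_sd = float(np.median([s.baseline_noise_sd for s in specs]))
    data = noise_sd * rng.standard_normal((T, n_parcels)) if noise_sd > 0 else np.zeros((T, n_parcels))
    unit = noise_sd if noise_sd > 0 else 1.0
    for k in labels:
        spec = spec_by_id[int(k)]
        gate = (states == k).astype(float)[:, None]
        for osc in spec.oscillators:
            if osc.relative_amplitude == 0:
                continue
            nb = _narrowband_noise(rng, T, len(osc.parcels), osc.center_freq, osc.bandwidth, fs)
            data[:, list(osc.parcels)] += gate * (osc.relative_amplitude * unit) * nb
    return ParcelTimeSeries(data, fs)


def _modal_state(window: np.ndarray, K: int) -> int:
    counts = np.bincount(window, minlength=K)
    return int(np.argmax(counts))  # ties -> lowest label


def generate_task_session(
    cfg: CohortConfig,
    subject_id: str,
    seed=0,
    transition: np.ndarray | None = None,
    peak_freq: float | None = None,
    subject_amp_noise: float | None = None,
) -> tuple[SubjectRecordings, TrialTruth]:
    """One subject's task session: alternating baselines and stimulus epochs.

    Baseline durations are uniform on ``cfg.baseline_range`` (2-4 s by
    default).  The hidden chain runs continuously through the session; gamma
    bursts are added to the ROI parcels 0.6-2.0 s after each stimulus onset
    with amplitude ``base + coupling_between*(FO_enh - 1/K) + subject noise
    + coupling_within*1[pre-stimulus state = enhancing] + trial noise``.
    """
    rng = _rng(seed)
    fs = cfg.fs
    g = cfg.gamma
    if transition is None:
        transition = cfg.transition_base
    if peak_freq is None:
        peak_freq = float(rng.uniform(*g.peak_freq_range))

    n_bl = rng.uniform(cfg.baseline_range[0], cfg.baseline_range[1], size=cfg.n_trials)
    bl_len = np.round(n_bl * fs).astype(int)
    post_len = int(round(cfg.post_stim_s * fs))
    rows = []
    pos = 0
    for i in range(cfg.n_trials):
        rows.append(
            {
                "trial_id": i,
                "baseline_onset_s": pos / fs,
                "stim_onset_s": (pos + bl_len[i]) / fs,
                "trial_end_s": (pos + bl_len[i] + post_len) / fs,
            }
        )
        pos += bl_len[i] + post_len
    events = pd.DataFrame(rows)
    T = pos

    states = generate_state_sequence(transition, T, seed=rng)
    ts = render_recording(states, cfg.state_specs, fs, seed=rng, n_parcels=cfg.n_parcels)
    ts.subject_id = subject_id
    ts.parcel_names = cfg.parcel_names()

    # --- planted amplitudes -------------------------------------------------
    K = cfg.K_true
    n_win = int(np.floor(cfg.prestim_window_s * fs + 1e-9))
    stim_samp = np.round(events["stim_onset_s"].to_numpy() * fs).astype(int)
    bl_onset_samp = np.round(events["baseline_onset_s"].to_numpy() * fs).astype(int)

    bl_mask = np.zeros(T, dtype=bool)
    for a, b in zip(bl_onset_samp, stim_samp):
        bl_mask[a:b] = True
    fo_baseline = np.bincount(states[bl_mask], minlength=K) / bl_mask.sum()

    prestim = np.array(
        [_modal_state(states[s - n_win : s], K) for s in stim_samp], dtype=int
    )
    if subject_amp_noise is None:
        subject_amp_noise = float(rng.normal(0.0, g.subject_amp_sd))
    subject_amp = (
        g.base_amplitude
        + g.coupling_between * (fo_baseline[cfg.enhancing_state] - 1.0 / K)
        + subject_amp_noise
    )
    amplitudes = (
        subject_amp
        + g.coupling_within * (prestim == cfg.enhancing_state)
        + rng.normal(0.0, g.trial_amp_sd, size=cfg.n_trials)
    )
    amplitudes = np.clip(amplitudes, 0.0, None)

    # --- render the bursts --------------------------------------------------
    burst_len = int(round(g.burst_window * fs))
    env = signal.windows.hann(burst_len, sym=True)
    t_burst = np.arange(burst_len) / fs
    roi = list(cfg.roi_parcels)
    for i, s in enumerate(stim_samp):
        a = s + int(round(g.burst_onset * fs))
        phase = rng.uniform(0, 2 * np.pi, size=len(roi))
        burst = np.sin(2 * np.pi * peak_freq * t_burst[:, None] + phase[None, :])
        # hann envelope has RMS sqrt(3/8); rescale so amplitude is in RMS units
        scale = amplitudes[i] / np.sqrt(3.0 / 8.0 * 0.5)
        ts.data[a : a + burst_len, roi] += scale * env[:, None] * burst

    truth = TrialTruth(
        prestim_state=prestim,
        planted_amplitude=amplitudes,
        peak_freq=peak_freq,
        subject_amplitude=float(subject_amp),
        fo_baseline=fo_baseline,
    )
    rec = SubjectRecordings(subject_id, None, ts, events)
    rec.task_states = states  # type: ignore[attr-defined]
    return rec, truth


def _jitter_transition(
    base: np.ndarray, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Perturb each row with a Dirichlet draw; ``jitter`` ~ row variance knob.

    jitter = 0 returns the base matrix unchanged; larger values spread the
    subject-specific rows (concentration = row/jitter), which in turn spreads
    the subjects' stationary occupancies.
    """
    if jitter == 0:
        return base.copy()
    A = np.empty_like(base)
    floor = 1e-4
    for k in range(base.shape[0]):
        alpha = np.maximum(base[k] / jitter, floor)
        A[k] = rng.dirichlet(alpha)
        A[k] = np.maximum(A[k], floor)
        A[k] /= A[k].sum()
    return A


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate rest + task recordings for the whole cohort.

    Subject-specific transition matrices (Dirichlet-jittered around
    ``transition_base``) induce between-subject FO differences; the planted
    subject mean gamma amplitude increases with the subject's realized FO of
    the enhancing state with slope ``gamma.coupling_between``.
    """
    if cfg.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    subjects: list[SubjectRecordings] = []
    gt = GroundTruth(
        enhancing_state=cfg.enhancing_state,
        state_paths_task={},
        state_paths_rest={},
        fo_baseline={},
        fo_rest={},
        prestim_state={},
        planted_amplitude={},
        subject_amplitude={},
        peak_freq={},
        transitions={},
    )
    K = cfg.K_true
    for s_idx in range(cfg.n_subjects):
        sid = f"S{s_idx:02d}"
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), s_idx]))
        A_s = _jitter_transition(cfg.transition_base, cfg.subject_fo_jitter, rng)
        peak = float(rng.uniform(*cfg.gamma.peak_freq_range))

        rest = None
        if cfg.rest_duration_s > 0:
            T_rest = int(round(cfg.rest_duration_s * cfg.fs))
            rest_states = generate_state_sequence(A_s, T_rest, seed=rng)
            rest = render_recording(
                rest_states, cfg.state_specs, cfg.fs, seed=rng, n_parcels=cfg.n_parcels
            )
            rest.subject_id = sid
            rest.parcel_names = cfg.parcel_names()
            gt.state_paths_rest[sid] = rest_states
            gt.fo_rest[sid] = np.bincount(rest_states, minlength=K) / T_rest

        rec, truth = generate_task_session(cfg, sid, seed=rng, transition=A_s, peak_freq=peak)
        rec.rest = rest
        subjects.append(rec)

        gt.state_paths_task[sid] = rec.task_states  # type: ignore[attr-defined]
        gt.fo_baseline[sid] = truth.fo_baseline
        gt.prestim_state[sid] = truth.prestim_state
        gt.planted_amplitude[sid] = truth.planted_amplitude
        gt.subject_amplitude[sid] = truth.subject_amplitude
        gt.peak_freq[sid] = truth.peak_freq
        gt.transitions[sid] = A_s
    return Cohort(cfg, subjects, gt)
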