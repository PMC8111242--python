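"""Ground-truth properties of the synthetic cohort generator."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import spearmanr

from gammastates.simulate import (
    CohortConfig,
    GammaSpec,
    Oscillator,
    StateSpec,
    default_transition,
    generate_cohort,
    generate_state_sequence,
    generate_task_session,
    render_recording,
    stationary_distribution,
)
from tests.conftest import small_cohort_config


class TestStateSequence:
    def test_absorbing_chain_is_constant(self):
        seq = generate_state_sequence(np.eye(3), 100, initial=2, seed=0)
        assert np.all(seq == 2)

    def test_geometric_mean_lifetime(self):
        A = default_transition(2, self_prob=0.9)
        seq = generate_state_sequence(A, 10**6, seed=1)
        runs = np.diff(np.flatnonzero(np.concatenate([[1], np.diff(seq) != 0, [1]])))
        assert abs(runs.mean() - 10.0) / 10.0 < 0.01

    def test_uniform_chain_stationary_occupancy(self):
        A = np.full((4, 4), 0.25)
        seq = generate_state_sequence(A, 10**6, seed=2)
        fo = np.bincount(seq, minlength=4) / seq.size
        assert np.all((fo > 0.245) & (fo < 0.255))

    def test_reproducible_for_fixed_seed(self):
        A = default_transition(3)
        a = generate_state_sequence(A, 5000, seed=7)
        b = generate_state_sequence(A, 5000, seed=7)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "bad", [np.array([[0.5, 0.4], [0.5, 0.5]]), np.array([[1.2, -0.2], [0.0, 1.0]])]
    )
    def test_non_stochastic_rows_raise(self, bad):
        with pytest.raises(ValueError):
            generate_state_sequence(bad, 10)

    def test_stationary_distribution_matches_long_run(self):
        A = np.array([[0.9, 0.1], [0.3, 0.7]])
        pi = stationary_distribution(A)
        seq = generate_state_sequence(A, 200000, seed=3)
        fo = np.bincount(seq) / seq.size
        assert np.allclose(pi, fo, atol=0.01)


class TestRenderRecording:
    def test_single_oscillator_concentrates_power(self):
        spec = StateSpec(0, (Oscillator((3,), 10.0, 1.0, bandwidth=2.0),), baseline_noise_sd=0.0)
        states = np.zeros(50000, dtype=int)
        ts = render_recording(states, (spec,), 250.0, seed=0, n_parcels=5)
        f, p = sps.periodogram(ts.data[:, 3], fs=250.0)
        in_band = p[(f >= 8.0) & (f <= 12.0)].sum()
        assert in_band / p.sum() > 0.99
        assert np.allclose(ts.data[:, [0, 1, 2, 4]], 0.0)

    def test_zero_amplitude_is_pure_noise(self):
        specs = tuple(
            StateSpec(k, (Oscillator((0,), 10.0 + 5 * k, 0.0),)) for k in range(2)
        )
        states = generate_state_sequence(default_transition(2), 100000, seed=1)
        ts = render_recording(states, specs, 250.0, seed=1, n_parcels=2)
        # band power conditioned on state should be equal within sampling error
        powers = []
        for k in range(2):
            x = ts.data[states == k, 0]
            f, p = sps.welch(x, fs=250.0, nperseg=256)
            powers.append(p[(f >= 5) & (f <= 20)].mean())
        assert abs(powers[0] - powers[1]) / powers[0] < 0.1

    def test_two_state_band_contrast_has_planted_sign(self):
        specs = (
            StateSpec(0, (Oscillator((0,), 10.0, 1.5),)),   # "occipital alpha"
            StateSpec(1, (Oscillator((1,), 2.0, 1.5, bandwidth=1.0),)),  # "centro-parietal delta"
        )
        A = default_transition(2, self_prob=0.99)
        states = generate_state_sequence(A, 200000, seed=2)
        ts = render_recording(states, specs, 250.0, seed=2, n_parcels=2)

        def band_power(x, lo, hi):
            f, p = sps.welch(x, fs=250.0, nperseg=512)
            return p[(f >= lo) & (f <= hi)].mean()

        alpha0 = band_power(ts.data[states == 0, 0], 8, 12)
        alpha1 = band_power(ts.data[states == 1, 0], 8, 12)
        delta0 = band_power(ts.data[states == 0, 1], 1, 3)
        delta1 = band_power(ts.data[states == 1, 1], 1, 3)
        assert alpha0 > alpha1
        assert delta1 > delta0

    def test_missing_spec_raises(self):
        spec = StateSpec(0, (Oscillator((0,), 10.0, 1.0),))
        with pytest.raises(ValueError, match="no StateSpec"):
            render_recording(np.array([0, 1, 0]), (spec,), 250.0, n_parcels=2)


class TestTaskSession:
    def test_no_within_coupling_gives_no_association(self):
        cfg = small_cohort_config(
            n_trials=200, gamma=GammaSpec(coupling_within=0.0, coupling_between=0.0)
        )
        _, truth = generate_task_session(cfg, "S0", seed=5)
        ind = (truth.prestim_state == cfg.enhancing_state).astype(float)
        r = np.corrcoef(ind, truth.planted_amplitude)[0, 1]
        assert abs(r) < 0.15

    def test_within_coupling_shifts_enhancing_trials(self):
        cfg = small_cohort_config(n_trials=200, gamma=GammaSpec(coupling_within=0.5))
        _, truth = generate_task_session(cfg, "S0", seed=6)
        enh = truth.prestim_state == cfg.enhancing_state
        assert enh.sum() > 10 and (~enh).sum() > 10
        diff = truth.planted_amplitude[enh].mean() - truth.planted_amplitude[~enh].mean()
        assert abs(diff - 0.5) < 0.12

    def test_baseline_lengths_within_range(self):
        cfg = small_cohort_config(n_trials=50)
        rec, _ = generate_task_session(cfg, "S0", seed=7)
        lengths = np.round(
            (rec.events.stim_onset_s - rec.events.baseline_onset_s) * cfg.fs
        ).astype(int)
        assert lengths.min() >= 500 and lengths.max() <= 1000

    def test_burst_outside_trial_raises(self):
        with pytest.raises(ValueError, match="burst"):
            small_cohort_config(post_stim_s=1.5, gamma=GammaSpec(burst_onset=0.6, burst_window=1.4))

    def test_baseline_roi_band_power_is_noise_floor(self):
        """Gamma bursts never leak into baseline windows."""
        cfg = small_cohort_config(n_trials=40)
        rec, truth = generate_task_session(cfg, "S0", seed=8)
        quiet = small_cohort_config(
            n_trials=40, gamma=GammaSpec(base_amplitude=0.0, coupling_between=0.0,
                                         coupling_within=0.0, subject_amp_sd=0.0,
                                         trial_amp_sd=0.0)
        )
        rec0, _ = generate_task_session(quiet, "S0", seed=8)
        fs = cfg.fs
        lo, hi = truth.peak_freq - 10, truth.peak_freq + 10

        def baseline_band_power(r):
            chunks = []
            for row in r.events.itertuples():
                a = int(round(row.baseline_onset_s * fs))
                b = int(round(row.stim_onset_s * fs))
                chunks.append(r.task.data[a:b, cfg.roi_parcels[0]])
            x = np.concatenate(chunks)
            f, p = sps.welch(x, fs=fs, nperseg=256)
            return p[(f >= lo) & (f <= hi)].mean()

        ratio = baseline_band_power(rec) / baseline_band_power(rec0)
        assert 0.8 < ratio < 1.25


class TestCohort:
    def test_no_jitter_no_coupling_no_association(self):
        cfg = small_cohort_config(
            n_subjects=12,
            subject_fo_jitter=0.0,
            gamma=GammaSpec(coupling_between=0.0, coupling_within=0.0),
            seed=9,
        )
        cohort = generate_cohort(cfg)
        gt = cohort.ground_truth
        fo = [gt.fo_baseline[s][cfg.enhancing_state] for s in cohort.subject_ids]
        amp = [gt.planted_amplitude[s].mean() for s in cohort.subject_ids]
        assert abs(spearmanr(fo, amp).statistic) < 0.6  # no planted association

    def test_strong_between_coupling_plants_correlation(self):
        hits = 0
        for seed in range(5):
            cfg = small_cohort_config(n_subjects=15, seed=20 + seed)
            cohort = generate_cohort(cfg)
            gt = cohort.ground_truth
            fo = [gt.fo_baseline[s][cfg.enhancing_state] for s in cohort.subject_ids]
            amp = [gt.planted_amplitude[s].mean() for s in cohort.subject_ids]
            if spearmanr(fo, amp).statistic > 0.6:
                hits += 1
        assert hits >= 4

    def test_fixed_seed_bitwise_identical(self):
        cfg_a = small_cohort_config(n_subjects=3, seed=33)
        cfg_b = small_cohort_config(n_subjects=3, seed=33)
        a = generate_cohort(cfg_a)
        b = generate_cohort(cfg_b)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.task.data, sb.task.data)
            assert sa.events.equals(sb.events)
        for sid in a.subject_ids:
            assert np.array_equal(
                a.ground_truth.planted_amplitude[sid], b.ground_truth.planted_amplitude[sid]
            )

    def test_planted_fo_matches_path_tally(self, small_cohort):
        """Planted FO vectors are the generator's own hard-path tallies."""
        gt = small_cohort.ground_truth
        cfg = small_cohort.config
        for sub in small_cohort.subjects:
            states = gt.state_paths_task[sub.subject_id]
            mask = np.zeros(states.size, dtype=bool)
            for row in sub.events.itertuples():
                a = int(round(row.baseline_onset_s * cfg.fs))
                b = int(round(row.stim_onset_s * cfg.fs))
                mask[a:b] = True
            tally = np.bincount(states[mask], minlength=cfg.K_true) / mask.sum()
            assert np.allclose(tally, gt.fo_baseline[sub.subject_id])

    def test_single_subject_cohort_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            generate_cohort(small_cohort_config(n_subjects=1))
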