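"""Epoching, baseline normalization, and the statistics layer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gammamap import epochs as ep
from gammamap import spectral


def events_at(times_ms, speech_offset=None):
    t = np.asarray(times_ms, dtype=float)
    speech = t + speech_offset if speech_offset is not None else np.full(len(t), np.nan)
    return pd.DataFrame(
        {
            "trial": np.arange(len(t)),
            "task": "reading",
            "stim_onset_ms": t,
            "speech_onset_ms": speech,
            "rt_ms": speech - t if speech_offset is not None else np.nan,
            "correct": True,
            "modal": True,
        }
    )


class TestEpoch:
    def test_window_sample_count_is_half_open(self):
        fs = 2000.0
        data = np.zeros((1, int(10 * fs)))
        ev = events_at([2000.0, 5000.0])
        es = ep.epoch(data, fs, ev, "stimulus", (-100.0, 100.0))
        assert es.data.shape == (2, 1, 400)

    def test_constant_channel_gives_constant_epochs(self):
        data = np.full((1, 20000), 5.0)
        es = ep.epoch(data, 1000.0, events_at([3000.0, 8000.0]), "stimulus", (-500.0, 500.0))
        assert (es.data == 5.0).all()

    def test_out_of_bounds_trials_dropped_with_warning(self):
        data = np.zeros((1, 5000))
        ev = events_at([100.0, 2500.0, 4950.0])
        with pytest.warns(UserWarning, match="dropped 2 trials"):
            es = ep.epoch(data, 1000.0, ev, "stimulus", (-500.0, 500.0))
        assert list(es.trial_index) == [1]

    def test_missing_alignment_column_rejected(self):
        ev = events_at([1000.0])  # listening-style: no speech onset
        with pytest.raises(ValueError, match="alignment column"):
            ep.epoch(np.zeros((1, 5000)), 1000.0, ev, "speech", (-100.0, 100.0))

    def test_synthetic_burst_peaks_at_injected_latency(self):
        fs = 1000.0
        n = int(40 * fs)
        onsets = 3000.0 + 3000.0 * np.arange(10)
        env = np.ones((1, n))
        for t0 in onsets:
            i = int((t0 + 300.0) * fs / 1000.0)
            env[0, i - 150 : i + 150] += np.hanning(300)
        es = ep.epoch(env, fs, events_at(onsets), "stimulus", (-500.0, 1000.0))
        peak_ms = es.times_ms[np.argmax(es.data.mean(axis=0)[0])]
        assert abs(peak_ms - 300.0) <= 10.0


class TestPercentChange:
    def make_envelope_epochs(self, value, baseline_value=1.0, fs=1000.0):
        n_t = 1000
        data = np.full((3, 1, n_t), float(baseline_value))
        data[:, :, 600:] = value
        es = ep.EpochSet(
            data=data,
            fs=fs,
            times_ms=-500.0 + np.arange(n_t),
            align="stimulus",
            units="envelope",
            channel_labels=np.array(["ch0"]),
            trial_index=np.arange(3),
        )
        return es

    def test_trace_equal_to_baseline_maps_to_zero(self):
        es = self.make_envelope_epochs(1.0)
        out = ep.percent_change(es, (-400.0, -100.0))
        assert np.allclose(out.data, 0.0)

    def test_doubling_maps_to_plus_100(self):
        es = self.make_envelope_epochs(2.0)
        out = ep.percent_change(es, (-400.0, -100.0))
        assert np.allclose(out.data[:, :, 700:], 100.0)
        assert out.units == "percent"

    def test_nonpositive_baseline_rejected(self):
        es = self.make_envelope_epochs(1.0, baseline_value=0.0)
        with pytest.raises(ValueError, match="baseline"):
            ep.percent_change(es, (-400.0, -100.0))


class TestGroupTimecourse:
    def test_hierarchical_mean_weights_subjects_equally(self):
        traces = np.array([[0.0], [100.0], [50.0]])
        g = ep.group_timecourse(traces, np.array(["A", "A", "B"]), np.array([0.0]))
        assert g.mean[0] == 50.0  # not (0+100+50)/3

    def test_identical_traces_have_zero_se(self):
        traces = np.tile(np.arange(5.0), (4, 1))
        g = ep.group_timecourse(traces, np.array(["A", "B", "C", "D"]), np.arange(5.0))
        assert np.allclose(g.se, 0.0)

    def test_duplicating_an_electrode_within_subject_changes_nothing(self, rng):
        traces = rng.standard_normal((5, 20))
        subj = np.array(["A", "A", "B", "B", "C"])
        g1 = ep.group_timecourse(traces, subj, np.arange(20.0))
        dup = np.vstack([traces, traces[[0]]])
        g2 = ep.group_timecourse(dup, np.append(subj, "A"), np.arange(20.0))
        # subject A's mean shifts, but duplicating an identical electrode does not
        dup2 = np.vstack([traces, traces[[4]]])
        g3 = ep.group_timecourse(dup2, np.append(subj, "C"), np.arange(20.0))
        assert np.allclose(g3.mean, g1.mean)
        assert g2.subject_means.shape == g1.subject_means.shape

    def test_subject_se_scales_as_sigma_over_sqrt_n(self, rng):
        sigma, n = 7.0, 16
        ses = []
        for _ in range(200):
            traces = rng.normal(0, sigma, (n, 1))
            g = ep.group_timecourse(traces, np.arange(n), np.array([0.0]))
            ses.append(g.se[0])
        assert abs(np.mean(ses) - sigma / np.sqrt(n)) < 0.15


def brute_force_bh(pvals, q):
    """Independent step-up oracle: find k* = max{k: p(k) <= k q / m}."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k * q / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask


class TestBhFdr:
    def test_worked_example(self):
        mask = ep.bh_fdr(np.array([0.001, 0.02, 0.03, 0.5]), q=0.05)
        assert list(mask) == [True, True, True, False]

    def test_all_ones_nothing_significant(self):
        assert not ep.bh_fdr(np.ones(10), 0.05).any()

    def test_boundary_all_equal_q_over_m(self):
        m = 8
        mask = ep.bh_fdr(np.full(m, 0.05 / m), q=0.05)
        assert mask.all()

    def test_empty_input(self):
        assert ep.bh_fdr(np.array([]), 0.05).size == 0

    @given(st.integers(min_value=1, max_value=500), st.integers(0, 10_000))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_brute_force_on_random_vectors(self, m, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=m) ** rng.uniform(0.3, 3.0)
        assert np.array_equal(ep.bh_fdr(p, 0.05), brute_force_bh(p, 0.05))


class TestTimepointSignificance:
    def test_plateau_detected_baseline_not(self, rng):
        n_sub, n_t = 8, 100
        traces = 0.5 * rng.standard_normal((n_sub, n_t))
        traces[:, 60:] += 50.0
        g = ep.group_timecourse(traces, np.arange(n_sub), np.arange(n_t, dtype=float))
        mask = ep.timepoint_significance(g, q=0.05)
        assert mask[60:].all()
        assert mask[:60].mean() < 0.1

    def test_single_subject_rejected(self):
        g = ep.group_timecourse(np.zeros((2, 5)), np.array(["A", "A"]), np.arange(5.0))
        with pytest.raises(ValueError, match="3 subjects"):
            ep.timepoint_significance(g)

    def test_zero_variance_zero_mean_flagged(self):
        g = ep.group_timecourse(np.zeros((3, 4)), np.arange(3), np.arange(4.0))
        with pytest.warns(UserWarning, match="zero-variance"):
            mask = ep.timepoint_significance(g)
        assert not mask.any()


class TestWindowZscore:
    def make_epochs(self, data, fs=1000.0):
        n_t = data.shape[2]
        return ep.EpochSet(
            data=data,
            fs=fs,
            times_ms=-500.0 + np.arange(n_t) * 1000.0 / fs,
            align="stimulus",
            units="percent",
            channel_labels=np.array([f"ch{i}" for i in range(data.shape[1])]),
            trial_index=np.arange(data.shape[0]),
        )

    def test_null_window_gives_small_z(self, rng):
        data = rng.standard_normal((100, 3, 1000))
        es = self.make_epochs(data)
        stat = ep.window_zscore(es, (200.0, 400.0), (-400.0, -100.0))
        assert (np.abs(stat["z"]) < 3).all()

    def test_matches_closed_form_arithmetic(self, rng):
        data = rng.standard_normal((40, 1, 1000))
        data[:, :, 700:900] += 2.0
        es = self.make_epochs(data)
        stat = ep.window_zscore(es, (200.0, 400.0), (-400.0, -100.0))
        w = data[:, 0, es.window_idx((200.0, 400.0))].mean(axis=1)
        b = data[:, 0, es.window_idx((-400.0, -100.0))].mean(axis=1)
        z_expected = (w.mean() - b.mean()) / b.std(ddof=1)
        assert abs(stat["z"].iloc[0] - z_expected) < 1e-12
        assert abs(stat["p"].iloc[0] - 2 * stats.norm.sf(abs(z_expected))) < 1e-12

    def test_all_zero_data_guarded(self):
        es = self.make_epochs(np.zeros((10, 1, 1000)))
        with pytest.warns(UserWarning, match="zero baseline"):
            stat = ep.window_zscore(es, (200.0, 400.0), (-400.0, -100.0))
        assert stat["z"].iloc[0] == 0.0
        assert stat["p"].iloc[0] == 1.0

    def test_few_trials_flagged_unstable(self, rng):
        es = self.make_epochs(rng.standard_normal((4, 1, 1000)))
        stat = ep.window_zscore(es, (200.0, 400.0), (-400.0, -100.0))
        assert stat["unstable"].iloc[0]


class TestWilcoxonContrast:
    def test_n6_all_positive_exact_enumeration(self):
        # oracle: enumerate all 2^6 sign assignments of the ranks; the
        # observed W = 21 (all positive) is matched only by itself and its
        # mirror, so two-sided p = 2/64
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        count = 0
        for signs in range(2**6):
            w = sum((i + 1) for i in range(6) if signs >> i & 1)
            if w >= 21 or w <= 0:
                count += 1
        assert count / 2**6 == 2 / 64
        assert ep.wilcoxon_contrast(d) == pytest.approx(2 / 64)

    def test_identical_conditions_return_one_with_warning(self):
        a = np.arange(6.0)
        with pytest.warns(UserWarning, match="zero"):
            assert ep.wilcoxon_contrast(a, a) == 1.0

    def test_swapping_conditions_preserves_p(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        assert ep.wilcoxon_contrast(a, b) == ep.wilcoxon_contrast(b, a)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            ep.wilcoxon_contrast(np.arange(5.0), np.arange(6.0))


class TestTrialFiltering:
    def test_keeps_only_correct_modal_trials(self):
        ev = events_at(np.arange(5) * 1000.0, speech_offset=900.0)
        ev.loc[1, "correct"] = False
        ev.loc[3, "modal"] = False
        kept = ep.filter_trials(ev)
        assert list(kept["trial"]) == [0, 2, 4]


class TestComputeErp:
    def test_evoked_deflection_latency_recovered(self, rng):
        fs = 1000.0
        n = int(60 * fs)
        onsets = 3000.0 + 2000.0 * np.arange(25)
        x = 0.5 * rng.standard_normal((2, n))
        bump = 10.0 * np.exp(-0.5 * ((np.arange(-100, 100)) / 30.0) ** 2)
        for t0 in onsets:
            i = int((t0 + 100.0) * fs / 1000.0)
            x[:, i - 100 : i + 100] += bump
        filt = spectral.erp_filter(x, fs)
        es = ep.epoch(filt, fs, events_at(onsets), "stimulus", (-500.0, 500.0))
        g = ep.compute_erp(es, np.array(["A", "B"]))
        peak_ms = g.times_ms[np.argmax(g.mean)]
        assert abs(peak_ms - 100.0) <= 10.0

    def test_phase_random_gamma_produces_no_evoked_response(self, rng):
        # induced (phase-random) gamma bursts average out in the ERP
        from gammamap import synth

        fs = 1000.0
        n = int(60 * fs)
        onsets = 3000.0 + 2000.0 * np.arange(25)
        carrier = synth._gamma_carrier(n, fs, (70.0, 150.0), 10.0, rng)
        gain = np.ones(n)
        for t0 in onsets:
            i = int((t0 + 100.0) * fs / 1000.0)
            gain[i : i + 300] += 1.0
        x = (carrier * gain)[None, :]
        filt = spectral.erp_filter(x, fs)
        es = ep.epoch(filt, fs, events_at(onsets), "stimulus", (-500.0, 500.0))
        g = ep.compute_erp(es, np.array(["A"]))
        # burst amplitude is 10 uV but the trial-averaged ERP stays small
        assert np.abs(g.mean).max() < 2.0

    def test_zero_input_zero_output(self):
        es = ep.epoch(np.zeros((1, 10000)), 1000.0, events_at([3000.0]), "stimulus",
                      (-500.0, 500.0))
        g = ep.compute_erp(es, np.array(["A"]))
        assert np.allclose(g.mean, 0.0)
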