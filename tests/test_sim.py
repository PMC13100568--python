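import dataclasses

import numpy as np
import pytest

from oculoscope import erp, presets, sim
from oculoscope.sim import (
    EventTrainSpec,
    SimConfig,
    TruncatedNormal,
    make_control_kernel,
    make_kernel,
    sample_events,
    synthesize_trial,
)

from conftest import deterministic_dist

SR = 250.0
DT = 1.0 / SR


class TestTruncatedNormal:
    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            TruncatedNormal(0.3, 0.05, lo=0.5, hi=0.2)
        with pytest.raises(ValueError):
            TruncatedNormal(0.3, 0.05, lo=-0.1, hi=0.2)

    def test_draws_within_bounds(self):
        d = TruncatedNormal(0.3, 0.2, lo=0.1, hi=0.4)
        x = d.draw(np.random.default_rng(0), size=5000)
        assert x.min() >= 0.1 and x.max() <= 0.4

    def test_deterministic(self):
        d = TruncatedNormal(0.3, 0.05, lo=0.1, hi=0.5)
        a = d.draw(np.random.default_rng(42), size=10)
        b = d.draw(np.random.default_rng(42), size=10)
        np.testing.assert_array_equal(a, b)

    def test_expected_close_to_mean_for_symmetric_bounds(self):
        d = TruncatedNormal(0.29, 0.04, lo=0.15, hi=0.43)
        assert abs(d.expected - 0.29) < 1e-3


class TestMakeKernel:
    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_kernel(p1_amp=np.nan)
        with pytest.raises(ValueError):
            make_kernel(n170_amp=+1.0)
        with pytest.raises(ValueError):
            make_kernel(p1_amp=-0.5)
        with pytest.raises(ValueError):
            make_kernel(p1_sigma=0.0)

    def test_degenerate_amplitudes(self):
        k = make_kernel(p1_amp=0.0, n170_amp=-1e-12)
        assert np.max(np.abs(k.waveform)) <= 1e-12
        # argmin at the negative bump centre: 4*p1_sigma + p1_to_trough
        expected = 4 * 0.015 + 0.060
        assert abs(k.trough_offset - expected) <= DT

    def test_default_peak_to_trough_spacing(self):
        k = make_kernel()
        peak_t = k.times[np.argmax(k.waveform)]
        assert abs((k.trough_offset - peak_t) - 0.060) <= DT

    def test_halfmax_to_trough_duration_near_100ms(self):
        # time from first upward half-max crossing of the P1 bump to the trough
        k = make_kernel()
        half = 0.5 * np.max(k.waveform)
        first_cross = k.times[np.flatnonzero(k.waveform >= half)[0]]
        dur = k.trough_offset - first_cross
        assert abs(dur - 0.100) < 0.03

    def test_shape_invariants(self):
        k = make_kernel()
        i_min = np.argmin(k.waveform)
        assert np.sum(k.waveform == k.waveform[i_min]) == 1  # unique global min
        assert np.max(k.waveform[:i_min]) > 0  # positive extremum before it
        assert k.pre_saccade_lag > 0

    def test_lag_stored_unchanged(self):
        k = make_kernel(pre_saccade_lag=0.1337)
        assert k.pre_saccade_lag == 0.1337


class TestSampleEvents:
    def test_vanishing_rate_gives_no_events(self):
        spec = EventTrainSpec(kind="exploratory_saccade",
                              iei_dist=TruncatedNormal(0.3, 0.08, 0.12, 0.8),
                              rate_scale=0.0)
        assert sample_events(spec, (-1.0, 2.0), 0.0, seed=0) == []

    def test_empty_window(self):
        spec = EventTrainSpec(kind="fixation_control",
                              iei_dist=TruncatedNormal(0.105, 0.015, 0.06, 0.2))
        assert sample_events(spec, (1.0, 1.0), 2.0, seed=0) == []

    def test_first_saccade_single_onset(self):
        spec = EventTrainSpec(kind="first_saccade",
                              first_latency_dist=TruncatedNormal(0.29, 0.04, 0.15, 0.45))
        for seed in range(20):
            ev = sample_events(spec, (-1.0, 2.0), 0.0, seed=seed)
            assert len(ev) == 1
            assert 0.15 <= ev[0] <= 0.45

    def test_fixation_control_mean_count(self):
        # renewal-process oracle: expected count over a 4 s fixation window is
        # window / E[interval]
        dist = TruncatedNormal(0.105, 0.015, 0.06, 0.2)
        spec = EventTrainSpec(kind="fixation_control", iei_dist=dist)
        counts = [
            len(sample_events(spec, (-4.0, 1.0), 0.0, seed=s)) for s in range(1000)
        ]
        expected = 4.0 / dist.expected
        assert abs(np.mean(counts) - expected) / expected < 0.05

    def test_exploratory_rate_scaling(self):
        dist = TruncatedNormal(0.3, 0.08, 0.12, 0.8)
        def mean_count(rate):
            spec = EventTrainSpec(kind="exploratory_saccade", iei_dist=dist,
                                  rate_scale=rate)
            return np.mean([
                len(sample_events(spec, (0.0, 60.0), 0.0, seed=s)) for s in range(200)
            ])
        ratio = mean_count(1.0) / mean_count(0.5)
        assert abs(ratio - 2.0) < 0.1

    def test_invalid_distribution_raises(self):
        with pytest.raises(ValueError):
            EventTrainSpec(kind="exploratory_saccade", iei_dist=None)
        with pytest.raises(ValueError):
            EventTrainSpec(kind="nonsense")


def _plain_config(trains, noise_sd=0.0, window=(-0.5, 1.0), **kw):
    return SimConfig(
        kernel=make_kernel(),
        control_kernel=make_control_kernel(),
        trains=trains,
        noise_sd=noise_sd,
        n_trials=1,
        epoch_window=window,
        sample_rate=SR,
        seed=0,
        **kw,
    )


class TestSynthesizeTrial:
    def test_no_events_no_noise_is_zero(self):
        cfg = _plain_config({"c": []})
        trial = synthesize_trial(cfg, "c", 0)
        np.testing.assert_array_equal(trial.eeg, 0.0)

    def test_single_saccade_trough_placement(self):
        # saccade at 0.3 s, lag 0.120 -> argmin at 0.180 s
        cfg = _plain_config(
            {"c": [EventTrainSpec(kind="first_saccade",
                                  first_latency_dist=deterministic_dist(0.3))]}
        )
        trial = synthesize_trial(cfg, "c", 0)
        t_min = trial.times[np.argmin(trial.eeg)]
        assert abs(t_min - 0.180) <= DT

    def test_superposition_is_exact(self):
        # reconstruct the trace from reported ground-truth event times
        cfg = _plain_config(
            {
                "c": [
                    EventTrainSpec(kind="first_saccade",
                                   first_latency_dist=TruncatedNormal(0.29, 0.04, 0.15, 0.45)),
                    EventTrainSpec(kind="exploratory_saccade",
                                   iei_dist=TruncatedNormal(0.3, 0.08, 0.12, 0.8)),
                    EventTrainSpec(kind="fixation_control",
                                   iei_dist=TruncatedNormal(0.105, 0.015, 0.06, 0.2)),
                ]
            },
            window=(-1.0, 1.5),
        )
        trial = synthesize_trial(cfg, "c", 0)
        n = trial.eeg.size
        expect = np.zeros(n)
        t0 = cfg.epoch_window[0]

        def add(wave, start_idx):
            lo, hi = max(start_idx, 0), min(start_idx + wave.size, n)
            if hi > lo:
                expect[lo:hi] += wave[lo - start_idx : hi - start_idx]

        for s in trial.saccade_onsets:
            start = s - cfg.kernel.pre_saccade_lag - cfg.kernel.trough_offset
            add(cfg.kernel.waveform, int(round((start - t0) * SR)))
        for c in trial.ground_truth["control_onsets_with_burnin"]:
            add(cfg.control_kernel.waveform, int(round((c - t0) * SR)))
        np.testing.assert_allclose(trial.eeg, expect, rtol=0, atol=1e-12)

    def test_ground_truth_counts(self):
        cfg = presets.fig_s4(n_trials=1, seed=9)
        trial = synthesize_trial(cfg, "high", 0)
        assert trial.ground_truth["n_saccades"] == len(trial.saccade_onsets)
        assert trial.ground_truth["n_controls"] == len(trial.control_onsets)
        t0, t1 = cfg.epoch_window
        assert all(t0 <= s < t1 for s in trial.saccade_onsets)

    def test_boundary_truncation_flagged(self):
        # saccade so early that the kernel sticks out of the left edge
        cfg = _plain_config(
            {"c": [EventTrainSpec(kind="first_saccade",
                                  first_latency_dist=deterministic_dist(0.02))]},
            window=(-0.05, 0.5),
        )
        trial = synthesize_trial(cfg, "c", 0)
        assert trial.ground_truth["kernel_truncated"]

    def test_balanced_controls_cancel_in_average_but_carry_power(self):
        dist = TruncatedNormal(0.105, 0.015, 0.06, 0.2)
        cfg = dataclasses.replace(
            _plain_config(
                {"c": [EventTrainSpec(kind="fixation_control", iei_dist=dist)]},
                window=(-2.0, 0.5),
            ),
            n_trials=500,
        )
        epochs, _ = sim.simulate_experiment(cfg)
        g = erp.average(epochs)
        pre = g.times < -0.1
        # mean amplitude is far below a single control deflection (0.4 a.u.)
        assert np.abs(g.trace()[pre]).mean() < 3 * g.sem.mean(axis=0)[pre].mean()
        # ... while fixation-interval power peaks at ~1/IEI vs neighbours
        from oculoscope import tfr

        tmap = tfr.tfr_hanning(epochs)
        fix = tmap.times <= -0.25
        spec = tmap.power.mean(axis=(0, 1))[:, fix].mean(axis=1)
        f_peak = 1.0 / dist.expected
        i_peak = np.argmin(np.abs(tmap.freqs - f_peak))
        assert spec[i_peak] > spec[i_peak + 2]
        assert spec[i_peak] > spec[i_peak - 2] or spec[i_peak - 1] > spec[i_peak - 2]

    def test_alternating_controls_cancel_tightly(self):
        dist = TruncatedNormal(0.105, 0.015, 0.06, 0.2)
        base = {"c": [EventTrainSpec(kind="fixation_control", iei_dist=dist)]}
        mk = lambda mode: dataclasses.replace(
            _plain_config(base, window=(-2.0, 0.5), control_sign_mode=mode),
            n_trials=300,
        )
        ep_alt, _ = sim.simulate_experiment(mk("alternate"))
        g = erp.average(ep_alt)
        pre = g.times < -0.1
        # mean amplitude far below a single 0.8 a.u. deflection and within noise
        assert np.abs(g.trace()[pre]).mean() < 3 * g.sem.mean(axis=0)[pre].mean()
        assert np.abs(g.trace()[pre]).mean() < 0.05


class TestSimulateExperiment:
    def test_determinism(self):
        cfg = presets.fig_s4(n_trials=5, seed=123)
        e1, t1 = sim.simulate_experiment(cfg)
        e2, t2 = sim.simulate_experiment(cfg)
        np.testing.assert_array_equal(e1.data, e2.data)
        assert t1.df.equals(t2.df)

    def test_counts_and_meta(self, small_fig_s4):
        cfg, epochs, events = small_fig_s4
        assert epochs.n_trials == cfg.n_trials * 2
        assert set(epochs.meta["condition"]) == {"high", "low"}
        assert len(events.stimulus_onsets()) == epochs.n_trials

    def test_grand_average_shape(self, small_fig_s4):
        # positive-then-negative complex followed by a positive sustained part
        _, epochs, _ = small_fig_s4
        g = erp.average(erp.baseline_correct(epochs))
        tr = g.trace()
        t = g.times
        p1 = tr[(t >= 0.05) & (t < 0.14)].max()
        trough = tr[(t >= 0.14) & (t < 0.22)].min()
        sustained = tr[(t >= 0.4) & (t < 1.0)].mean()
        assert p1 > 0 and trough < 0
        assert sustained > 0

    def test_condition_difference_confined_to_sustained_window(self):
        cfg = dataclasses.replace(presets.fig_s4(n_trials=400, seed=2), noise_sd=0.0)
        epochs, _ = sim.simulate_experiment(cfg)
        by = erp.average(epochs, by="condition")  # no baseline: keep zeros exact
        diff = by["high"].trace() - by["low"].trace()
        t = by["high"].times
        # outside the reach of any first-saccade kernel, conditions are identical
        before_reach = np.abs(diff[t < -0.16]).max()
        assert before_reach == 0.0
        # near stimulus onset only finite-sample latency noise remains; the
        # systematic difference lives in the sustained window
        early = np.abs(diff[(t >= -0.16) & (t < 0.02)]).max()
        late = diff[(t >= 0.4) & (t < 1.0)].mean()
        assert late > 0
        assert early < 0.3 * late

    def test_sustained_monotone_in_rate_scale(self):
        def sustained(rate):
            trains = {
                "c": [
                    EventTrainSpec(kind="first_saccade",
                                   first_latency_dist=presets.FIRST_LATENCY),
                    EventTrainSpec(kind="exploratory_saccade",
                                   iei_dist=presets.EXPLORATORY_IEI,
                                   rate_scale=rate, taper=0.5),
                ]
            }
            cfg = dataclasses.replace(
                presets.fig_s4(n_trials=300, seed=4), trains=trains, noise_sd=0.0
            )
            epochs, _ = sim.simulate_experiment(cfg)
            g = erp.average(erp.baseline_correct(epochs))
            return erp.window_mean(g, (0.4, 1.0))

        values = [sustained(r) for r in (0.4, 0.8, 1.2)]
        assert values[0] <= values[1] <= values[2]

    def test_noise_reproducible_per_trial(self):
        cfg = presets.fig_s4(n_trials=3, seed=77)
        a = synthesize_trial(cfg, "low", 2)
        b = synthesize_trial(cfg, "low", 2)
        np.testing.assert_array_equal(a.eeg, b.eeg)


class TestConfigValidation:
    def test_window_must_contain_zero(self):
        with pytest.raises(ValueError):
            _plain_config({"c": []}, window=(0.1, 1.0))

    def test_sample_rate_floor(self):
        with pytest.raises(ValueError):
            dataclasses.replace(presets.fig_s4(), sample_rate=60.0)

    def test_unknown_condition(self):
        cfg = presets.fig_s4(n_trials=1)
        with pytest.raises(ValueError):
            synthesize_trial(cfg, "nope", 0)
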