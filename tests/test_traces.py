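"""Neuropil correction, ΔF/F baselines, and sparse deconvolution."""

import numpy as np
import pytest

import combicode as cc
from combicode.traces import DegenerateTraceError, reconvolve


class TestContamination:
    @pytest.mark.parametrize(
        "R,N,expected",
        [
            ([4, 2, 6], [2, 2, 2], 1.0),  # min(2,1,3) clamps to 1
            ([1, 3], [2, 2], 0.5),
            ([5, 5, 5], [5, 5, 5], 1.0),  # identical channels
        ],
    )
    def test_min_ratio_examples(self, R, N, expected):
        assert cc.contamination_coefficient(R, N) == pytest.approx(expected)

    def test_negative_ratio_clamps_to_zero(self):
        with pytest.warns(UserWarning):
            assert cc.contamination_coefficient([-1.0, 3.0], [2.0, 2.0]) == 0.0

    def test_no_valid_frames_raises(self):
        with pytest.raises(DegenerateTraceError):
            cc.contamination_coefficient([1.0, 2.0], [0.0, 0.0])

    def test_random_draws_keep_F_nonnegative_and_k_bounded(self):
        # spec invariant: over many random positive traces, k in [0,1] and
        # corrected F >= 0 wherever N > 0
        rng = np.random.default_rng(99)
        for _ in range(1000):
            T = rng.integers(5, 40)
            R = rng.gamma(2.0, 2.0, size=T)
            N = rng.gamma(2.0, 2.0, size=T)
            k = cc.contamination_coefficient(R, N)
            assert 0.0 <= k <= 1.0
            F = R - k * N
            assert np.all(F[N > 1e-9] >= -1e-10)


class TestNeuropilCorrect:
    def test_arithmetic_example(self):
        raw = cc.RawTraceSet(R=[[4.0, 2.0, 6.0]], N=[[2.0, 2.0, 2.0]], frame_rate_hz=10)
        out = cc.neuropil_correct(raw)
        assert out.k[0] == 1.0
        assert out.F[0].tolist() == [2.0, 0.0, 4.0]

    def test_zero_neuropil_flagged_degenerate(self):
        raw = cc.RawTraceSet(R=[[1.0, 2.0, 3.0]], N=[[0.0, 0.0, 0.0]], frame_rate_hz=10)
        out = cc.neuropil_correct(raw)
        assert out.degenerate[0]
        assert out.k[0] == 0.0
        assert np.array_equal(out.F[0], raw.R[0])


def _toy_corrected(F, fr=10.0):
    F = np.atleast_2d(np.asarray(F, float))
    return cc.CorrectedTraceSet(F=F, k=np.zeros(F.shape[0]), frame_rate_hz=fr)


def _toy_trial_table(onsets, catch_flags, stim_s=1.0, iti_s=2.0):
    import pandas as pd
    from combicode.synth import TrialTable

    df = pd.DataFrame(
        {
            "condition_bits": ["00000" if c else "10000" for c in catch_flags],
            "is_catch": catch_flags,
            "onset_frame": onsets,
            "run_speed": np.full(len(onsets), 30.0),
        }
    )
    return TrialTable(df=df, stim_duration_s=stim_s, iti_s=iti_s)


class TestCatchBaseline:
    def test_constant_trace_gives_zero_dff(self):
        table = _toy_trial_table([10, 40], [False, True])
        out = cc.dff_catch_baseline(_toy_corrected(np.full(80, 3.0)), table)
        assert out.f0[0] == pytest.approx(3.0)
        assert np.allclose(out.dff[0], 0.0)

    def test_doubling_during_stimulus_gives_dff_one(self):
        F = np.full(80, 2.0)
        F[10:20] = 4.0  # stimulus window of the first trial
        table = _toy_trial_table([10, 40], [False, True])
        out = cc.dff_catch_baseline(_toy_corrected(F), table)
        assert np.allclose(out.dff[0, 10:20], 1.0)

    def test_nonpositive_baseline_flagged(self):
        table = _toy_trial_table([10, 40], [False, True])
        out = cc.dff_catch_baseline(_toy_corrected(np.zeros(80)), table)
        assert out.invalid[0]
        assert np.all(np.isnan(out.dff[0]))

    def test_requires_catch_trials(self):
        table = _toy_trial_table([10, 40], [False, False])
        with pytest.raises(ValueError):
            cc.dff_catch_baseline(_toy_corrected(np.ones(80)), table)

    def test_recovers_known_baseline_in_noiseless_session(self):
        # zero neuropil, zero noise, ITI long enough for the calcium kernel
        # to decay below float tolerance: the pipeline's f0 matches the
        # configured somatic baseline
        cfg = cc.SessionConfig(
            n_neurons=3, trials_per_condition=2, seed=4, trial_noise_sd=0.0,
            neuropil_baseline=1e-12, neuropil_sd=0.0, baseline_f0=50.0, iti_s=40.0,
        )
        session = cc.generate_session(cfg, mixture=(1.0, 0.0, 0.0), seed=4)
        corrected = cc.neuropil_correct(session.raw)
        assert np.all(corrected.degenerate)  # N ~ 0 -> pass-through
        out = cc.dff_catch_baseline(corrected, session.trial_table)
        assert out.f0 == pytest.approx(np.full(3, 50.0), rel=1e-9)


class TestPercentileBaseline:
    def test_constant_trace(self):
        out = cc.dff_percentile_baseline(_toy_corrected(np.full(200, 5.0)), window_frames=50)
        assert np.allclose(out.dff, 0.0)

    def test_drift_with_transients_near_zero_baseline(self):
        # slow linear drift plus brief transients; baseline frames should stay |dff| < 0.05
        t = np.arange(2000)
        F = 10.0 + 0.001 * t
        transients = np.zeros_like(F)
        for onset in range(100, 2000, 400):
            transients[onset : onset + 5] = 5.0
        out = cc.dff_percentile_baseline(_toy_corrected(F + transients), window_frames=301)
        baseline_frames = transients == 0
        assert np.all(np.abs(out.dff[0, baseline_frames]) < 0.05)

    def test_window_longer_than_trace_warns_and_uses_global(self):
        F = np.linspace(1, 2, 50)
        with pytest.warns(UserWarning):
            out = cc.dff_percentile_baseline(_toy_corrected(F), window_frames=100)
        expected_f0 = np.percentile(F, 20)
        assert np.allclose(out.f0[0], expected_f0)

    def test_matches_hand_computed_windowed_percentile(self):
        rng = np.random.default_rng(0)
        F = rng.uniform(1, 2, size=30)
        out = cc.dff_percentile_baseline(_toy_corrected(F), window_frames=5)
        # centered window of width 5, truncated at edges, type-7 quantiles
        for i in (0, 2, 15, 29):
            lo, hi = max(0, i - 2), min(30, i + 3)
            assert out.f0[0, i] == pytest.approx(np.percentile(F[lo:hi], 20))


def test_dff_gain_invariance():
    # scaling F by c > 0 leaves ΔF/F unchanged under both baseline schemes
    rng = np.random.default_rng(1)
    F = rng.uniform(5, 10, size=120)
    table = _toy_trial_table([10, 40, 70], [False, True, False])
    a = cc.dff_catch_baseline(_toy_corrected(F), table)
    b = cc.dff_catch_baseline(_toy_corrected(3.7 * F), table)
    assert np.allclose(a.dff, b.dff)
    c = cc.dff_percentile_baseline(_toy_corrected(F), window_frames=31)
    d = cc.dff_percentile_baseline(_toy_corrected(3.7 * F), window_frames=31)
    assert np.allclose(c.dff, d.dff, atol=1e-12)


class TestDeconvolve:
    def test_zero_dff_gives_zero_events(self):
        dff = cc.DffTraceSet(dff=np.zeros((1, 100)), f0=np.ones(1), scheme="catch_iti", frame_rate_hz=15.45)
        out = cc.deconvolve(dff)
        assert np.all(out.rates == 0)

    def test_single_kernel_recovered(self):
        fr, tau = 15.45, 1.5
        alpha = np.exp(-1 / (tau * fr))
        T, t0 = 250, 60
        y = np.zeros(T)
        y[t0:] = alpha ** np.arange(T - t0)
        dff = cc.DffTraceSet(dff=y[None], f0=np.ones(1), scheme="catch_iti", frame_rate_hz=fr)
        out = cc.deconvolve(dff, kernel_tau_s=tau, sparsity_weight=1e-4)
        e = out.rates[0] * (1 - alpha)  # undo the rate normalization
        assert e[t0] == pytest.approx(1.0, rel=0.05)
        assert np.delete(e, t0).max() < 0.05

    def test_reconvolution_residual_on_synthetic_session(self):
        cfg = cc.SessionConfig(
            n_neurons=4, trials_per_condition=2, seed=5, trial_noise_sd=0.05,
            neuropil_baseline=1e-12, neuropil_sd=0.0,
        )
        session = cc.generate_session(cfg, mixture=(0.5, 0.5, 0.0), seed=5)
        corrected = cc.neuropil_correct(session.raw)
        dff = cc.dff_catch_baseline(corrected, session.trial_table)
        out = cc.deconvolve(dff, kernel_tau_s=cfg.kernel_tau_s)
        rec = reconvolve(out)
        for i in range(4):
            denom = np.linalg.norm(dff.dff[i])
            if denom > 0:
                assert np.linalg.norm(rec[i] - dff.dff[i]) / denom <= 0.2


def test_dff_and_event_rate_tuning_agree():
    # tuning from deconvolved rates correlates with ΔF/F tuning on
    # well-separated trials
    cfg = cc.SessionConfig(
        n_neurons=5, trials_per_condition=3, seed=9, trial_noise_sd=0.05,
        neuropil_baseline=1e-12, neuropil_sd=0.0,
    )
    session = cc.generate_session(cfg, mixture=(0.5, 0.5, 0.0), seed=9)
    space = session.space()
    corrected = cc.neuropil_correct(session.raw)
    dff = cc.dff_catch_baseline(corrected, session.trial_table)
    events = cc.deconvolve(dff, kernel_tau_s=cfg.kernel_tau_s)
    r_dff = cc.trial_responses(dff.dff, dff.frame_rate_hz, session.trial_table, space)
    r_ev = cc.trial_responses(events.rates, dff.frame_rate_hz, session.trial_table, space, signal_kind="events")
    for i in range(cfg.n_neurons):
        a = cc.tuning_curve(r_dff, i, ci=False).values
        b = cc.tuning_curve(r_ev, i, ci=False).values
        if np.std(a) > 1e-6 and np.std(b) > 1e-6:
            assert np.corrcoef(a, b)[0, 1] > 0.9
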