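"""Kalman filter: literal-recursion oracle, steady state, channel averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgrehab import kalman as kf
from emgrehab import synth_emg as se
from .conftest import FS, single_channel_burst


def literal_recursion(series, Q, R, X0, P0):
    """Independent transcription of the four filter steps, kept brute-force."""
    X_prev, P_prev = X0, P0
    out = []
    for y in series:
        X_kp = X_prev                      # predict state
        P_kp = P_prev + Q                  # predict error
        KG = P_kp / (P_kp + R)             # gain
        X_k = X_kp + KG * (y - X_kp)       # update estimate
        P_k = (1 - KG) * P_kp              # update error
        X_prev, P_prev = X_k, P_k          # recurse
        out.append(X_k)
    return np.array(out)


class TestKalmanStep:
    def test_zero_measurement_noise_passes_through(self):
        state = kf.FilterState(X_prev=3.0, P_prev=1.0)
        _, out = kf.kalman_step(state, 7.0, kf.FilterParams(Q=0.1, R=0.0))
        assert out.KG == 1.0
        assert out.X == 7.0

    def test_perfectly_trusted_prior_never_updates(self):
        params = kf.FilterParams(Q=0.0, R=1.0, X0=2.0, P0=0.0)
        state = kf.FilterState(X_prev=2.0, P_prev=0.0)
        for y in (5.0, -1.0, 100.0):
            state, out = kf.kalman_step(state, y, params)
            assert out.KG == 0.0
            assert out.X == 2.0

    def test_hand_computed_step(self):
        # X_prev=0, P_prev=1, default Q/R, y=1: P_p=1.0001,
        # KG=1.0001/1.59958, X=KG, P=(1-KG)*1.0001 -- worked by hand
        state = kf.FilterState(X_prev=0.0, P_prev=1.0)
        _, out = kf.kalman_step(state, 1.0, kf.FilterParams())
        assert out.KG == pytest.approx(0.625226, abs=1e-6)
        assert out.X == pytest.approx(0.625226, abs=1e-6)
        assert out.P == pytest.approx(0.374811, abs=1e-6)

    def test_non_finite_measurement_rejected(self):
        state = kf.FilterState(X_prev=0.0, P_prev=1.0)
        with pytest.raises(ValueError):
            kf.kalman_step(state, float("nan"), kf.FilterParams())

    def test_negative_variances_rejected_at_construction(self):
        with pytest.raises(ValueError):
            kf.FilterParams(Q=-1.0)
        with pytest.raises(ValueError):
            kf.FilterParams(R=-1.0)
        with pytest.raises(ValueError):
            kf.FilterState(X_prev=0.0, P_prev=-0.1)


class TestKalmanRun:
    def test_constant_series_is_fixed_point(self):
        out = kf.kalman_run(np.full(500, 3.3))
        np.testing.assert_allclose(out, 3.3, atol=1e-12)

    def test_zero_r_reproduces_input(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 2, 300)
        np.testing.assert_array_equal(kf.kalman_run(y, kf.FilterParams(R=0.0)), y)

    def test_rest_variance_reduced(self, burst_activation):
        raw = single_channel_burst(0, 0.5, burst_activation)
        filt = kf.kalman_run(raw)
        rest = slice(0, round(2.0 * FS))  # before the first burst
        assert filt[rest].var() < raw[rest].var()

    def test_oracle_equivalence_on_random_input(self):
        rng = np.random.default_rng(42)
        y = rng.uniform(0, 5, 20_000)
        params = kf.FilterParams()
        ours = kf.kalman_run(y, params)
        ref = literal_recursion(y, params.Q, params.R, X0=y[0], P0=params.R)
        np.testing.assert_allclose(ours, ref, atol=1e-12, rtol=0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            kf.kalman_run([])

    @settings(max_examples=50, derandomize=True)
    @given(
        y=st.lists(st.floats(0, 10), min_size=2, max_size=50),
        q=st.floats(1e-6, 1.0),
        r=st.floats(1e-6, 2.0),
    )
    def test_estimate_is_convex_combination(self, y, q, r):
        """Each X_k lies between X_{k-1} and Y_k; KG and P stay in range."""
        params = kf.FilterParams(Q=q, R=r)
        state = kf.FilterState(X_prev=y[0], P_prev=r)
        for yk in y:
            x_before = state.X_prev
            state, out = kf.kalman_step(state, yk, params)
            assert 0.0 <= out.KG <= 1.0
            assert out.P >= 0.0
            lo, hi = sorted((x_before, yk))
            assert lo - 1e-12 <= out.X <= hi + 1e-12


class TestSteadyState:
    @pytest.mark.parametrize("q, r, expect", [(0.1, 0.0, 1.0), (0.0, 0.5, 0.0)])
    def test_degenerate_limits(self, q, r, expect):
        assert kf.steady_state_gain(q, r) == pytest.approx(expect)

    def test_matches_iterated_covariance_recursion(self):
        # independent oracle: iterate P -> (1 - KG) (P + Q) to convergence
        Q, R = kf.DEFAULT_Q, kf.DEFAULT_R
        P = 1.0
        for _ in range(20_000):
            P_p = P + Q
            P = (1 - P_p / (P_p + R)) * P_p
        kg_iter = (P + Q) / (P + Q + R)
        assert kf.steady_state_gain(Q, R) == pytest.approx(kg_iter, abs=1e-10)
        assert kf.steady_state_gain(Q, R) == pytest.approx(0.012832, abs=1e-6)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            kf.steady_state_gain(0.0, 0.0)

    def test_covariance_converges_for_any_p0(self):
        Q, R = kf.DEFAULT_Q, kf.DEFAULT_R
        P_star = (1 - kf.steady_state_gain(Q, R)) * kf.steady_state_prediction_variance(Q, R)
        for P0 in (0.0, 0.01, 1.0, 100.0):
            params = kf.FilterParams(P0=P0)
            state = kf.FilterState(X_prev=0.0, P_prev=P0)
            gaps = []
            for _ in range(5000):
                state, out = kf.kalman_step(state, 0.0, params)
                gaps.append(abs(out.P - P_star))
            assert gaps[-1] < 1e-12
            # monotone approach to the fixed point
            assert all(g2 <= g1 + 1e-15 for g1, g2 in zip(gaps, gaps[1:]))

    def test_post_burnin_equals_exponential_smoother(self):
        rng = np.random.default_rng(7)
        y = rng.uniform(0, 3, 6000)
        full = kf.kalman_run(y)
        a = kf.steady_state_gain(kf.DEFAULT_Q, kf.DEFAULT_R)
        x = y[0]
        smooth = np.empty_like(y)
        for k, yk in enumerate(y):
            x = x + a * (yk - x)
            smooth[k] = x
        burn = 3000
        assert np.max(np.abs(full[burn:] - smooth[burn:])) < 1e-12

    def test_noise_attenuated_above_one_hertz(self):
        # single-pole magnitude response with the default (Q, R) at 200 Hz:
        # strictly attenuating at 1 Hz and below -10 dB by 2 Hz
        h1 = kf.smoother_frequency_response(1.0, 200.0)
        h2 = kf.smoother_frequency_response(2.0, 200.0)
        assert 20 * np.log10(h1) < 0.0
        assert 20 * np.log10(h2) < -10.0
        freqs = np.linspace(1.0, 99.0, 50)
        hs = [kf.smoother_frequency_response(f, 200.0) for f in freqs]
        assert all(h < 1.0 for h in hs)


class TestControlSignal:
    def test_identical_channels_pass_through(self):
        x = np.abs(np.sin(np.arange(100) / 10.0))
        trace = se.EmgTrace(fs=FS, samples=np.column_stack([x] * 8), kind="filtered")
        np.testing.assert_array_equal(kf.control_signal(trace), x)

    def test_mean_of_two_constant_channels(self):
        trace = se.EmgTrace(
            fs=FS,
            samples=np.column_stack([np.zeros(50), np.full(50, 2.0)]),
            kind="filtered",
        )
        np.testing.assert_array_equal(kf.control_signal(trace), 1.0)

    def test_raw_trace_rejected(self):
        trace = se.EmgTrace(fs=FS, samples=np.ones((10, 8)), kind="raw")
        with pytest.raises(ValueError):
            kf.control_signal(trace)

    def test_noise_sd_shrinks_like_sqrt_channels(self):
        rng = np.random.default_rng(1)
        x = np.abs(rng.normal(1.0, 0.5, (40_000, 8)))
        sd_chan = x.std(axis=0).mean()
        trace = se.EmgTrace(fs=FS, samples=x, kind="filtered")
        assert kf.control_signal(trace).std() == pytest.approx(
            sd_chan / np.sqrt(8), rel=0.05
        )

    def test_filter_then_mean_equals_mean_then_filter(self, burst_activation):
        # the filter is linear time-invariant, so the two orders agree
        trace = se.synthesize_raw_emg(burst_activation, se.default_channels(seed=2))
        a = kf.control_signal(kf.filter_trace(trace))
        b = kf.kalman_run(trace.samples.mean(axis=1))
        np.testing.assert_allclose(a, b, atol=1e-10)
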