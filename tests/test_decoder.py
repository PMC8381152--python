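"""Filter, smoother and EM against independent linear-Gaussian oracles."""

import numpy as np
import pytest

from enerloop.decoder import (
    EMError,
    FilterState,
    filter_series,
    fit_em,
    predict,
    smooth_series,
    update,
)
from enerloop.energy_model import (
    HarmonicCoefficients,
    ObservationTriple,
    forcing,
    simulate_state_and_obs,
)

# ---------------------------------------------------------------------------
# independent oracles: textbook scalar Kalman filter / RTS smoother for the
# two-observation linear model (event channel off)


def kalman_oracle(obs, model, u=None, x0=0.0, var0=None):
    n = len(obs)
    u = np.zeros(n) if u is None else u
    var0 = model.stationary_var if var0 is None else var0
    mp_arr, vp_arr, m_arr, v_arr = (np.empty(n) for _ in range(4))
    m, v = x0, var0
    for k in range(n):
        xp = model.rho * m + forcing(k, model.harmonic) + u[k]
        vp = model.rho**2 * v + model.sigma_eps2
        prec = 1.0 / vp
        num = xp / vp
        if obs[k].R is not None:
            prec += model.r1**2 / model.sigma_v2
            num += model.r1 * (obs[k].R - model.r0) / model.sigma_v2
        if obs[k].S is not None:
            prec += model.s1**2 / model.sigma_w2
            num += model.s1 * (obs[k].S - model.s0) / model.sigma_w2
        m, v = num / prec, 1.0 / prec
        mp_arr[k], vp_arr[k], m_arr[k], v_arr[k] = xp, vp, m, v
    return mp_arr, vp_arr, m_arr, v_arr


def rts_oracle(mp, vp, m, v, rho):
    n = len(m)
    ms, vs = m.copy(), v.copy()
    for k in range(n - 2, -1, -1):
        g = v[k] * rho / vp[k + 1]
        ms[k] = m[k] + g * (ms[k + 1] - mp[k + 1])
        vs[k] = v[k] + g**2 * (vs[k + 1] - vp[k + 1])
    return ms, vs


def linear_obs(model, n, seed):
    """Simulated observations with the event channel stripped."""
    x, obs = simulate_state_and_obs(model, None, n, seed=seed)
    return x, [ObservationTriple(c=None, R=o.R, S=o.S) for o in obs]


# ---------------------------------------------------------------------------


class TestPredict:
    def test_random_walk_grows_by_process_noise(self, default_model):
        model = default_model.with_(rho=0.999999)
        mean, var = predict(2.0, 1.0, model)
        assert mean == pytest.approx(2.0, rel=1e-5)
        assert var == pytest.approx(1.0 * model.rho**2 + model.sigma_eps2)

    def test_memoryless_prior_is_the_input(self, default_model):
        model = default_model.with_(rho=1e-300)
        mean, _ = predict(123.0, 1.0, model, u_k=0.7, i_k=0.3)
        assert mean == pytest.approx(1.0)

    def test_variance_arithmetic(self, default_model):
        model = default_model.with_(rho=0.5, sigma_eps2=1e-300)
        _, var = predict(0.0, 4.0, model)
        assert var == pytest.approx(1.0)


class TestUpdate:
    def test_zero_information_observation_returns_prior(self, default_model):
        model = default_model.with_(gamma1=0.0, r1=1e-300, s1=1e-300)
        st = update(1.5, 2.0, ObservationTriple(c=1, R=50.0, S=-50.0), model)
        assert st.mean_post == pytest.approx(1.5, abs=1e-9)
        assert st.var_post == pytest.approx(2.0, rel=1e-9)

    def test_linear_limit_equals_kalman_two_observation_update(self, default_model):
        """With gamma1=0 the MAP update is the exact conjugate update."""
        model = default_model.with_(gamma1=0.0)
        xp, vp = 0.8, 0.5
        ob = ObservationTriple(c=0, R=15.1, S=4.4)
        st = update(xp, vp, ob, model)
        prec = 1 / vp + model.r1**2 / model.sigma_v2 + model.s1**2 / model.sigma_w2
        num = (
            xp / vp
            + model.r1 * (ob.R - model.r0) / model.sigma_v2
            + model.s1 * (ob.S - model.s0) / model.sigma_w2
        )
        assert st.mean_post == pytest.approx(num / prec, rel=1e-10)
        assert st.var_post == pytest.approx(1 / prec, rel=1e-10)

    def test_informative_update_shrinks_variance(self, default_model):
        st = update(0.0, 1.0, ObservationTriple(c=1, R=14.5, S=4.2), default_model)
        assert st.var_post < st.var_pred

    def test_binary_only_update_moves_mean_toward_event(self, default_model):
        model = default_model.with_(gamma1=2.0)
        st1 = update(0.0, 1.0, ObservationTriple(c=1, R=None, S=None), model)
        st0 = update(0.0, 1.0, ObservationTriple(c=0, R=None, S=None), model)
        assert st1.mean_post > 0 > st0.mean_post

    def test_variance_positivity_validated(self):
        with pytest.raises(ValueError):
            FilterState(mean_pred=0, var_pred=1, mean_post=0, var_post=0)


class TestFilterSeries:
    def test_all_missing_observations_reduce_to_prediction(self, default_model):
        n = 300
        obs = [ObservationTriple(c=None, R=None, S=None)] * n
        traj = filter_series(obs, default_model)
        expected = np.empty(n)
        m = 0.0
        for k in range(n):
            m = default_model.rho * m + forcing(k, default_model.harmonic)
            expected[k] = m
        np.testing.assert_allclose(traj.mean_post, expected, atol=1e-10)

    def test_linear_limit_matches_kalman_oracle(self, default_model):
        model = default_model.with_(gamma1=0.0)
        _, obs = linear_obs(model, 2000, seed=5)
        traj = filter_series(obs, model)
        mp, vp, m, v = kalman_oracle(obs, model)
        np.testing.assert_allclose(traj.mean_post, m, rtol=1e-8)
        np.testing.assert_allclose(traj.var_post, v, rtol=1e-8)

    def test_filtering_beats_prior_mean_on_simulated_data(self, default_model):
        n = 7200
        x, obs = simulate_state_and_obs(default_model, None, n, seed=6)
        traj = filter_series(obs, default_model)
        prior = np.empty(n)
        m = 0.0
        for k in range(n):
            m = default_model.rho * m + forcing(k, default_model.harmonic)
            prior[k] = m
        rmse_filter = np.sqrt(np.mean((traj.mean_post - x) ** 2))
        rmse_prior = np.sqrt(np.mean((prior - x) ** 2))
        assert rmse_filter < rmse_prior

    def test_filter_is_causal(self, default_model):
        """Perturbing a future observation never changes earlier estimates."""
        _, obs = linear_obs(default_model, 400, seed=7)
        traj_a = filter_series(obs, default_model)
        obs_b = list(obs)
        obs_b[300] = ObservationTriple(c=1, R=obs[300].R + 50, S=obs[300].S)
        traj_b = filter_series(obs_b, default_model)
        np.testing.assert_array_equal(traj_a.mean_post[:300], traj_b.mean_post[:300])
        assert traj_a.mean_post[300] != traj_b.mean_post[300]


class TestSmoother:
    def test_boundary_condition_last_state_unchanged(self, default_model):
        _, obs = linear_obs(default_model, 500, seed=8)
        traj = filter_series(obs, default_model)
        sm = smooth_series(traj, default_model)
        assert sm.mean[-1] == traj.mean_post[-1]
        assert sm.var[-1] == traj.var_post[-1]

    def test_linear_limit_matches_rts_oracle(self, default_model):
        model = default_model.with_(gamma1=0.0)
        _, obs = linear_obs(model, 1500, seed=9)
        traj = filter_series(obs, model)
        sm = smooth_series(traj, model)
        mp, vp, m, v = kalman_oracle(obs, model)
        ms, vs = rts_oracle(mp, vp, m, v, model.rho)
        np.testing.assert_allclose(sm.mean, ms, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(sm.var, vs, rtol=1e-8)

    def test_smoothing_never_inflates_variance(self, default_model):
        _, obs = linear_obs(default_model, 1000, seed=10)
        traj = filter_series(obs, default_model)
        sm = smooth_series(traj, default_model)
        assert np.all(sm.var <= traj.var_post + 1e-12)


class TestEM:
    def test_linear_em_matches_reference_iteration(self, default_model):
        """With the event channel off, EM equals a hand-rolled linear EM."""
        model = default_model.with_(gamma1=0.0)
        _, obs = linear_obs(model, 1200, seed=11)
        init = model.with_(rho=0.9, sigma_eps2=0.2, s1=0.4)
        fit, _ = fit_em(
            obs, init=init, max_iter=4, tol=0.0, fit_gamma=False,
            ascent_slack=np.inf,
        )
        ref = init
        for _ in range(4):
            mp, vp, m, v = kalman_oracle(obs, ref)
            ms, vs = rts_oracle(mp, vp, m, v, ref.rho)
            # lag-one covariances for the reference M-step
            n = len(m)
            lag = np.empty(n)
            lag[0] = np.nan
            for k in range(n - 1):
                lag[k + 1] = v[k] * ref.rho / vp[k + 1] * vs[k + 1]
            ref = _reference_m_step(ref, obs, ms, vs, lag)
        assert fit.rho == pytest.approx(ref.rho, abs=1e-6)
        assert fit.s1 == pytest.approx(ref.s1, abs=1e-6)
        assert fit.sigma_v2 == pytest.approx(ref.sigma_v2, rel=1e-6)
        assert fit.sigma_eps2 == pytest.approx(ref.sigma_eps2, rel=1e-6)

    def test_parameter_recovery_on_simulated_data(self, default_model):
        """rho within 0.1 and envelope slopes within 20% across 3 seeds."""
        for seed in (0, 1, 2):
            _, obs = simulate_state_and_obs(default_model, None, 7200, seed=seed)
            fit, trace = fit_em(obs, max_iter=40, tol=1e-6)
            assert abs(fit.rho - default_model.rho) < 0.1
            assert abs(fit.r1 - default_model.r1) / default_model.r1 < 0.2
            assert abs(fit.s1 - default_model.s1) / default_model.s1 < 0.2
            rel_slack = 1e-6 * (1.0 + np.abs(trace[:-1]))
            assert np.all(np.diff(trace) >= -rel_slack)

    def test_ascent_violation_is_flagged(self, default_model):
        _, obs = linear_obs(default_model, 300, seed=12)
        with pytest.raises(EMError):
            fit_em(obs, init=default_model, max_iter=10, ascent_slack=-1.0)


def _reference_m_step(model, obs, m, v, lag):
    """Textbook M-step for the linear two-channel model (r1 anchored)."""
    n = len(m)
    ex2 = v + m**2
    k = np.arange(1, n)
    w = 2 * np.pi * k / 1440
    h = np.column_stack([np.sin(w), np.sin(2 * w), np.cos(w), np.cos(2 * w)])
    lag1 = lag[1:] + m[1:] * m[:-1]
    a = np.zeros((5, 5))
    b = np.zeros(5)
    a[0, 0] = ex2[:-1].sum()
    a[0, 1:] = a[1:, 0] = h.T @ m[:-1]
    a[1:, 1:] = h.T @ h
    b[0] = lag1.sum()
    b[1:] = h.T @ m[1:]
    theta = np.linalg.solve(a, b)
    rho = float(theta[0])
    d = h @ theta[1:]
    sq = (
        ex2[1:] - 2 * rho * lag1 - 2 * d * m[1:] + rho**2 * ex2[:-1]
        + 2 * rho * d * m[:-1] + d**2
    )
    r_arr = np.array([o.R for o in obs])
    s_arr = np.array([o.S for o in obs])
    r0 = float((r_arr - m).mean())
    sv2 = float(((r_arr - r0) ** 2 - 2 * (r_arr - r0) * m + ex2).mean())
    a2 = np.array([[n, m.sum()], [m.sum(), ex2.sum()]])
    b2 = np.array([s_arr.sum(), (s_arr * m).sum()])
    s0, s1 = np.linalg.solve(a2, b2)
    sw2 = float(
        (s_arr**2 - 2 * s_arr * (s0 + s1 * m) + s0**2 + 2 * s0 * s1 * m
         + s1**2 * ex2).mean()
    )
    return model.with_(
        rho=rho,
        sigma_eps2=float(sq.mean()),
        harmonic=HarmonicCoefficients(
            alpha1=float(theta[1]), alpha2=float(theta[2]),
            beta1=float(theta[3]), beta2=float(theta[4]),
        ),
        r0=r0, sigma_v2=sv2, s0=float(s0), s1=float(s1), sigma_w2=sw2,
    )
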