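"""Bayesian decoding of the energy state and offline EM parameter estimation.

The filter alternates a linear prediction step with a maximum-a-posteriori
update that fuses one Bernoulli channel (pulse events, sigmoid link) and two
linear-Gaussian channels (cortisol envelopes).  Because the event
probability p_k depends on the updated mean itself, the update equation is
implicit; it is solved with Newton's method (the posterior log-density is
strictly concave, so the root is unique), with a bisection fallback.

With the event channel switched off (gamma1 = 0) the update reduces exactly
to the two-observation Kalman filter, which serves as an oracle in the test
suite.  Offline parameter estimation runs EM on the Gaussian approximation
of the filtered/smoothed posteriors: closed-form M-steps for the state
recursion and envelope regressions, Newton ascent with Gauss-Hermite
quadrature for the sigmoid parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss

from .energy_model import (
    EnergyStateModel,
    HarmonicCoefficients,
    ObservationTriple,
    forcing,
    pulse_probability,
)

__all__ = [
    "FilterState",
    "FilterTrajectory",
    "SmoothedTrajectory",
    "FilterDivergenceError",
    "EMError",
    "predict",
    "update",
    "filter_series",
    "smooth_series",
    "initial_model_from_obs",
    "fit_em",
]

NEWTON_TOL = 1e-10
NEWTON_MAX_ITER = 50


class FilterDivergenceError(RuntimeError):
    """Raised when the implicit update cannot be solved."""

    def __init__(self, message: str, **diagnostics):
        super().__init__(message)
        self.diagnostics = diagnostics


class EMError(RuntimeError):
    """Raised when the EM surrogate likelihood decreases beyond slack."""


@dataclass(frozen=True)
class FilterState:
    mean_pred: float
    var_pred: float
    mean_post: float
    var_post: float
    p: float = float("nan")  # event probability at the converged mean
    gain: float = float("nan")  # envelope gain A_k

    def __post_init__(self) -> None:
        if self.var_pred <= 0 or self.var_post <= 0:
            raise ValueError("filter variances must be positive")


@dataclass
class FilterTrajectory:
    mean_pred: np.ndarray
    var_pred: np.ndarray
    mean_post: np.ndarray
    var_post: np.ndarray
    p: np.ndarray
    gain: np.ndarray
    loglik: float = 0.0

    def __len__(self) -> int:
        return len(self.mean_post)

    def __getitem__(self, k: int) -> FilterState:
        return FilterState(
            mean_pred=float(self.mean_pred[k]),
            var_pred=float(self.var_pred[k]),
            mean_post=float(self.mean_post[k]),
            var_post=float(self.var_post[k]),
            p=float(self.p[k]),
            gain=float(self.gain[k]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": np.arange(len(self)),
                "mean_pred": self.mean_pred,
                "var_pred": self.var_pred,
                "mean_post": self.mean_post,
                "var_post": self.var_post,
                "p": self.p,
            }
        )


@dataclass
class SmoothedTrajectory:
    mean: np.ndarray
    var: np.ndarray
    lag1: np.ndarray  # lag1[k] = Cov(x_k, x_{k-1} | all data), lag1[0] = nan

    def __len__(self) -> int:
        return len(self.mean)


def predict(
    prev_mean_post: float,
    prev_var_post: float,
    model: EnergyStateModel,
    u_k: float = 0.0,
    i_k: float = 0.0,
) -> tuple[float, float]:
    """One-step-ahead prior from the previous posterior."""
    mean_pred = model.rho * prev_mean_post + i_k + u_k
    var_pred = model.rho**2 * prev_var_post + model.sigma_eps2
    return mean_pred, var_pred


def _obs_terms(obs: ObservationTriple, model: EnergyStateModel):
    """Per-channel (present?, parameters) with missing channels dropped."""
    use_c = obs.c is not None and model.gamma1 != 0.0
    use_r = obs.R is not None
    use_s = obs.S is not None
    return use_c, use_r, use_s


def update(
    mean_pred: float,
    var_pred: float,
    obs: ObservationTriple,
    model: EnergyStateModel,
) -> FilterState:
    """MAP update fusing the Bernoulli event and the two envelope channels.

    Solves the stationarity condition of the posterior log-density

        (x - x_pred)/var_pred = gamma1 (c - p(x))
                              + r1 (R - r0 - r1 x)/sigma_v2
                              + s1 (S - s0 - s1 x)/sigma_w2

    for x by Newton iteration; the posterior variance is the inverse
    curvature at the solution.
    """
    use_c, use_r, use_s = _obs_terms(obs, model)
    g0, g1 = model.gamma0, model.gamma1
    # scalar fast path: this solver runs once per simulated minute
    exp = math.exp
    prior_prec = 1.0 / var_pred
    rr = model.r1 * model.r1 / model.sigma_v2 if use_r else 0.0
    ss = model.s1 * model.s1 / model.sigma_w2 if use_s else 0.0
    r_term = (
        model.r1 * (obs.R - model.r0) / model.sigma_v2 if use_r else 0.0
    )
    s_term = (
        model.s1 * (obs.S - model.s0) / model.sigma_w2 if use_s else 0.0
    )

    def sigmoid(x: float) -> float:
        z = g0 + g1 * x
        if z >= 0:
            return 1.0 / (1.0 + exp(-min(z, 500.0)))
        ez = exp(max(z, -500.0))
        return ez / (1.0 + ez)

    def grad(x: float) -> float:
        g = (x - mean_pred) * prior_prec - r_term + rr * x - s_term + ss * x
        if use_c:
            g -= g1 * (obs.c - sigmoid(x))
        return g

    def curv(x: float) -> float:
        h = prior_prec + rr + ss
        if use_c:
            p = sigmoid(x)
            h += g1 * g1 * p * (1.0 - p)
        return h

    x = mean_pred
    converged = False
    for _ in range(NEWTON_MAX_ITER):
        step = grad(x) / curv(x)
        x -= step
        if abs(step) < NEWTON_TOL:
            converged = True
            break
    if not converged or not np.isfinite(x):
        x = _bisection_root(grad, mean_pred, np.sqrt(var_pred))

    p_hat = sigmoid(x)
    var_post = 1.0 / curv(x)
    gain = _envelope_gain(var_pred, model, use_r, use_s)
    return FilterState(
        mean_pred=mean_pred,
        var_pred=var_pred,
        mean_post=float(x),
        var_post=float(var_post),
        p=float(p_hat),
        gain=gain,
    )


def _envelope_gain(
    var_pred: float, model: EnergyStateModel, use_r: bool, use_s: bool
) -> float:
    """Continuous-channel gain A_k (recorded for diagnostics)."""
    sv2, sw2 = model.sigma_v2, model.sigma_w2
    r1 = model.r1 if use_r else 0.0
    s1 = model.s1 if use_s else 0.0
    denom = sv2 * sw2 + var_pred * (r1**2 * sw2 + s1**2 * sv2)
    return float(var_pred * sv2 * sw2 / denom)


def _bisection_root(grad, center: float, scale: float) -> float:
    """Bracketed fallback; grad is strictly increasing in x."""
    half = 10.0 * max(scale, 1.0)
    for _ in range(60):
        lo, hi = center - half, center + half
        if grad(lo) < 0.0 < grad(hi):
            from scipy.optimize import brentq

            return float(brentq(grad, lo, hi, xtol=1e-12))
        half *= 2.0
    raise FilterDivergenceError(
        "implicit update root not bracketed",
        center=center,
        scale=scale,
        half=half,
    )


# Gauss-Hermite nodes (probabilists') used for Bernoulli expectations.
_GH_NODES, _GH_WEIGHTS = hermegauss(15)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _expected_event_prob(mean: float, var: float, g0: float, g1: float) -> float:
    """E[p(x)] under x ~ N(mean, var), by Gauss-Hermite quadrature."""
    x = mean + np.sqrt(max(var, 0.0)) * _GH_NODES
    return float(np.dot(_GH_WEIGHTS, pulse_probability(x, g0, g1)))


def filter_series(
    obs: list[ObservationTriple],
    model: EnergyStateModel,
    u: np.ndarray | None = None,
    x0: float = 0.0,
    var0: float | None = None,
) -> FilterTrajectory:
    """Causal forward pass over the observation sequence.

    Also accumulates the one-step-ahead predictive log-likelihood used by
    EM as its convergence criterion (Gaussian predictives for the envelope
    channels, quadrature Bernoulli predictive for the event channel).
    """
    n = len(obs)
    if u is None:
        u = np.zeros(n)
    u = np.asarray(u, dtype=float)
    if u.shape != (n,):
        raise ValueError("u must match the observation length")
    if var0 is None:
        var0 = model.stationary_var

    i_all = forcing(np.arange(n), model.harmonic)
    out = FilterTrajectory(
        mean_pred=np.empty(n),
        var_pred=np.empty(n),
        mean_post=np.empty(n),
        var_post=np.empty(n),
        p=np.empty(n),
        gain=np.empty(n),
    )
    ll = 0.0
    m_prev, v_prev = x0, var0
    for k in range(n):
        mean_pred, var_pred = predict(m_prev, v_prev, model, u[k], i_all[k])
        ob = obs[k]
        ll += _predictive_loglik(mean_pred, var_pred, ob, model)
        st = update(mean_pred, var_pred, ob, model)
        out.mean_pred[k] = st.mean_pred
        out.var_pred[k] = st.var_pred
        out.mean_post[k] = st.mean_post
        out.var_post[k] = st.var_post
        out.p[k] = st.p
        out.gain[k] = st.gain
        m_prev, v_prev = st.mean_post, st.var_post
    out.loglik = float(ll)
    return out


def _predictive_loglik(
    mean_pred: float, var_pred: float, obs: ObservationTriple, model: EnergyStateModel
) -> float:
    ll = 0.0
    if obs.R is not None:
        var = model.r1**2 * var_pred + model.sigma_v2
        res = obs.R - model.r0 - model.r1 * mean_pred
        ll += -0.5 * (np.log(2 * np.pi * var) + res**2 / var)
    if obs.S is not None:
        var = model.s1**2 * var_pred + model.sigma_w2
        res = obs.S - model.s0 - model.s1 * mean_pred
        ll += -0.5 * (np.log(2 * np.pi * var) + res**2 / var)
    if obs.c is not None:
        p = _expected_event_prob(mean_pred, var_pred, model.gamma0, model.gamma1)
        p = min(max(p, 1e-12), 1.0 - 1e-12)
        ll += obs.c * np.log(p) + (1 - obs.c) * np.log1p(-p)
    return float(ll)


def smooth_series(
    traj: FilterTrajectory, model: EnergyStateModel
) -> SmoothedTrajectory:
    """Fixed-interval (RTS-form) smoother on the Gaussian approximation."""
    n = len(traj)
    mean = traj.mean_post.copy()
    var = traj.var_post.copy()
    lag1 = np.full(n, np.nan)
    for k in range(n - 2, -1, -1):
        g = traj.var_post[k] * model.rho / traj.var_pred[k + 1]
        mean[k] = traj.mean_post[k] + g * (mean[k + 1] - traj.mean_pred[k + 1])
        var[k] = traj.var_post[k] + g**2 * (var[k + 1] - traj.var_pred[k + 1])
        lag1[k + 1] = g * var[k + 1]
    return SmoothedTrajectory(mean=mean, var=var, lag1=lag1)


def _obs_arrays(obs: list[ObservationTriple]):
    n = len(obs)
    c = np.full(n, np.nan)
    r = np.full(n, np.nan)
    s = np.full(n, np.nan)
    for k, ob in enumerate(obs):
        if ob.c is not None:
            c[k] = ob.c
        if ob.R is not None:
            r[k] = ob.R
        if ob.S is not None:
            s[k] = ob.S
    return c, r, s


def initial_model_from_obs(
    obs: list[ObservationTriple], u: np.ndarray | None = None
) -> EnergyStateModel:
    """Data-driven EM starting point.

    A crude state proxy (the centred envelope midline) anchors the scale;
    the state recursion is initialised by least squares of the proxy on its
    lag and the circadian harmonics, and the sigmoid intercept from the
    marginal event rate.
    """
    c, r, s = _obs_arrays(obs)
    n = len(obs)
    if u is None:
        u = np.zeros(n)
    mid = np.where(np.isnan(s), r, np.where(np.isnan(r), s, 0.5 * (r + s)))
    mid = pd.Series(mid).ffill().bfill().to_numpy()
    proxy = mid - mid.mean()

    # AR(1) + harmonics least squares on the proxy
    k_idx = np.arange(1, n)
    w = 2 * np.pi * k_idx / 1440.0
    design = np.column_stack(
        [proxy[:-1], np.sin(w), np.sin(2 * w), np.cos(w), np.cos(2 * w)]
    )
    target = proxy[1:] - u[1:]
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    rho = float(np.clip(coef[0], -0.995, 0.995))
    resid = target - design @ coef
    sigma_eps2 = float(max(resid.var(), 1e-6))

    r_obs = r[~np.isnan(r)]
    s_obs = s[~np.isnan(s)]
    r0 = float(np.nanmean(r - proxy)) if r_obs.size else 0.0
    s_fit = (
        np.polyfit(proxy[~np.isnan(s)], s_obs, 1) if s_obs.size > 2 else (0.5, 0.0)
    )
    rate = float(np.nanmean(c)) if np.any(~np.isnan(c)) else 0.01
    rate = min(max(rate, 1e-4), 1 - 1e-4)
    scale = proxy.std() if proxy.std() > 0 else 1.0
    return EnergyStateModel(
        rho=rho,
        sigma_eps2=sigma_eps2,
        harmonic=HarmonicCoefficients(
            alpha1=float(coef[1]),
            alpha2=float(coef[2]),
            beta1=float(coef[3]),
            beta2=float(coef[4]),
        ),
        gamma0=float(np.log(rate / (1 - rate))),
        gamma1=float(0.5 / scale),
        r0=r0,
        r1=1.0,
        sigma_v2=float(max(np.nanvar(r - proxy), 1e-4)) if r_obs.size else 1.0,
        s0=float(s_fit[1]),
        s1=float(max(s_fit[0], 1e-3)),
        sigma_w2=float(max(np.nanvar(s - s_fit[0] * proxy), 1e-4))
        if s_obs.size
        else 1.0,
    )


def fit_em(
    obs: list[ObservationTriple],
    init: EnergyStateModel | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    u: np.ndarray | None = None,
    fit_gamma: bool = True,
    ascent_slack: float = 1e-6,
    min_obs_var: float = 0.0,
) -> tuple[EnergyStateModel, np.ndarray]:
    """EM estimation of all model parameters from an observation sequence.

    The latent scale is anchored by holding r1 = 1 throughout (the state is
    measured in upper-envelope units); without an anchor the scale of x,
    gamma1, r1 and s1 are jointly unidentifiable.  Convergence is declared
    when the relative change of the one-step predictive log-likelihood
    falls below ``tol``.  A decrease beyond ``ascent_slack`` (relative)
    raises :class:`EMError`: the surrogate is expected to ascend.

    ``min_obs_var`` floors the envelope noise variances sigma_v2/sigma_w2.
    Envelopes obtained by interpolating through the extrema of a noisy
    measurement carry assay and interpolation error, and letting EM drive
    their variance to zero welds the state to one envelope; the floor keeps
    the channels honest about that error (and, downstream, preserves the
    control input's authority over the state estimate).
    """
    n = len(obs)
    if u is None:
        u = np.zeros(n)
    u = np.asarray(u, dtype=float)
    model = init if init is not None else initial_model_from_obs(obs, u)
    c, r, s = _obs_arrays(obs)
    trace: list[float] = []

    for _ in range(max_iter):
        traj = filter_series(obs, model, u=u)
        smoothed = smooth_series(traj, model)
        ll = traj.loglik
        if trace and ll < trace[-1] - ascent_slack * (1.0 + abs(trace[-1])):
            raise EMError(
                f"surrogate log-likelihood decreased: {trace[-1]:.6f} -> {ll:.6f}"
            )
        done = bool(trace) and abs(ll - trace[-1]) < tol * (1.0 + abs(trace[-1]))
        trace.append(ll)
        if done:
            break
        model = _m_step(
            model, smoothed, c, r, s, u, fit_gamma=fit_gamma, min_obs_var=min_obs_var
        )

    return model, np.asarray(trace)


def _m_step(
    model: EnergyStateModel,
    sm: SmoothedTrajectory,
    c: np.ndarray,
    r: np.ndarray,
    s: np.ndarray,
    u: np.ndarray,
    fit_gamma: bool,
    min_obs_var: float = 0.0,
) -> EnergyStateModel:
    m, v = sm.mean, sm.var
    ex2 = v + m**2
    n = len(m)

    # --- state recursion: regress x_k on (x_{k-1}, harmonics), offset u_k
    k_idx = np.arange(1, n)
    w = 2 * np.pi * k_idx / 1440.0
    h = np.column_stack([np.sin(w), np.sin(2 * w), np.cos(w), np.cos(2 * w)])
    lag = sm.lag1[1:] + m[1:] * m[:-1]  # E[x_k x_{k-1}]
    nh = h.shape[1]
    a = np.empty((1 + nh, 1 + nh))
    b = np.empty(1 + nh)
    a[0, 0] = ex2[:-1].sum()
    a[0, 1:] = a[1:, 0] = h.T @ m[:-1]
    a[1:, 1:] = h.T @ h
    b[0] = (lag - u[1:] * m[:-1]).sum()
    b[1:] = h.T @ (m[1:] - u[1:])
    theta = np.linalg.solve(a, b)
    rho = float(np.clip(theta[0], -0.999, 0.999))
    harm = HarmonicCoefficients(
        alpha1=float(theta[1]),
        alpha2=float(theta[2]),
        beta1=float(theta[3]),
        beta2=float(theta[4]),
    )
    d = u[1:] + h @ theta[1:]
    sq = (
        ex2[1:]
        - 2 * rho * lag
        - 2 * d * m[1:]
        + rho**2 * ex2[:-1]
        + 2 * rho * d * m[:-1]
        + d**2
    )
    sigma_eps2 = float(max(sq.mean(), 1e-10))

    # --- upper envelope: r1 anchored at 1
    var_floor = max(min_obs_var, 1e-10)
    r1 = model.r1
    mask_r = ~np.isnan(r)
    rr, mr, er = r[mask_r], m[mask_r], ex2[mask_r]
    r0 = float((rr - r1 * mr).mean()) if mask_r.any() else model.r0
    sigma_v2 = (
        float(max(((rr - r0) ** 2 - 2 * (rr - r0) * r1 * mr + r1**2 * er).mean(), var_floor))
        if mask_r.any()
        else model.sigma_v2
    )

    # --- lower envelope: full (s0, s1) regression
    mask_s = ~np.isnan(s)
    if mask_s.any():
        ss, ms, es = s[mask_s], m[mask_s], ex2[mask_s]
        a2 = np.array([[mask_s.sum(), ms.sum()], [ms.sum(), es.sum()]])
        b2 = np.array([ss.sum(), (ss * ms).sum()])
        s0, s1 = np.linalg.solve(a2, b2)
        sigma_w2 = float(
            max(
                (ss**2 - 2 * ss * (s0 + s1 * ms) + s0**2 + 2 * s0 * s1 * ms
                 + s1**2 * es).mean(),
                var_floor,
            )
        )
        s0, s1 = float(s0), float(s1)
    else:
        s0, s1, sigma_w2 = model.s0, model.s1, model.sigma_w2

    # --- sigmoid parameters: Newton ascent on the expected log-likelihood
    gamma0, gamma1 = model.gamma0, model.gamma1
    if fit_gamma and np.any(~np.isnan(c)):
        gamma0, gamma1 = _newton_gamma(
            c, m, v, gamma0, gamma1
        )

    return EnergyStateModel(
        rho=rho,
        sigma_eps2=sigma_eps2,
        harmonic=harm,
        gamma0=gamma0,
        gamma1=gamma1,
        r0=r0,
        r1=r1,
        sigma_v2=sigma_v2,
        s0=s0,
        s1=s1,
        sigma_w2=sigma_w2,
    )


def _newton_gamma(
    c: np.ndarray,
    m: np.ndarray,
    v: np.ndarray,
    gamma0: float,
    gamma1: float,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[float, float]:
    """Maximise sum_k E[c_k z - log(1+e^z)], z = g0 + g1 x, x ~ N(m_k, v_k)."""
    mask = ~np.isnan(c)
    cc, mm, vv = c[mask], m[mask], v[mask]
    # quadrature nodes per time step: shape (n, q)
    x = mm[:, None] + np.sqrt(np.maximum(vv, 0.0))[:, None] * _GH_NODES[None, :]
    wq = _GH_WEIGHTS[None, :]
    g = np.array([gamma0, gamma1])
    for _ in range(max_iter):
        z = np.clip(g[0] + g[1] * x, -500, 500)
        p = 1.0 / (1.0 + np.exp(-z))
        ep = (wq * p).sum(axis=1)
        epx = (wq * p * x).sum(axis=1)
        grad = np.array([(cc - ep).sum(), (cc * mm - epx).sum()])
        q = p * (1.0 - p)
        h00 = (wq * q).sum(axis=1).sum()
        h01 = (wq * q * x).sum(axis=1).sum()
        h11 = (wq * q * x * x).sum(axis=1).sum()
        hess = np.array([[h00, h01], [h01, h11]])
        hess += 1e-12 * np.eye(2)
        step = np.linalg.solve(hess, grad)
        g = g + step
        if np.abs(step).max() < tol:
            break
    return float(g[0]), float(g[1])
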