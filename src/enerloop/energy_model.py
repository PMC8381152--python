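"""State-space model linking pulse events and cortisol envelopes to energy.

The latent cognitive energy state x_k follows a first-order autoregression
with a deterministic two-harmonic circadian forcing I_k (period 1440 min)
and an exogenous control input u_k:

    x_k = rho x_{k-1} + u_k + I_k + eps_k,      eps_k ~ N(0, sigma_eps2).

Three observation channels inform x_k each minute:

* a binary pulse event c_k ~ Bernoulli(p_k) with the sigmoid link
  p_k = 1 / (1 + exp(-(gamma0 + gamma1 x_k))),
* the upper cortisol envelope  R_k = r0 + r1 x_k + v_k,  v_k ~ N(0, sigma_v2),
* the lower cortisol envelope  S_k = s0 + s1 x_k + w_k,  w_k ~ N(0, sigma_w2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .virtual_patient import MINUTES_PER_DAY

__all__ = [
    "HarmonicCoefficients",
    "EnergyStateModel",
    "ObservationTriple",
    "forcing",
    "pulse_probability",
    "bernoulli_loglik",
    "envelope_means",
    "simulate_state_and_obs",
]


@dataclass(frozen=True)
class HarmonicCoefficients:
    """sin/cos coefficients of the circadian forcing, fundamentals i=1,2."""

    alpha1: float = 0.0
    alpha2: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.beta1, self.beta2])


@dataclass(frozen=True)
class EnergyStateModel:
    rho: float
    sigma_eps2: float
    harmonic: HarmonicCoefficients
    gamma0: float
    gamma1: float
    r0: float
    r1: float
    sigma_v2: float
    s0: float
    s1: float
    sigma_w2: float

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| < 1 required for stationarity, got {self.rho}")
        for name in ("sigma_eps2", "sigma_v2", "sigma_w2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kwargs) -> "EnergyStateModel":
        return replace(self, **kwargs)

    @property
    def stationary_var(self) -> float:
        """Stationary state variance of the unforced recursion."""
        return self.sigma_eps2 / (1.0 - self.rho**2)


@dataclass(frozen=True)
class ObservationTriple:
    """One minute's observations; any channel may be missing (None)."""

    c: int | None
    R: float | None
    S: float | None

    def __post_init__(self) -> None:
        if self.c is not None and self.c not in (0, 1):
            raise ValueError(f"c must be 0/1 or None, got {self.c}")
        if self.R is not None and self.S is not None and self.R < self.S:
            raise ValueError("upper envelope below lower envelope")


def forcing(k: np.ndarray | int, harmonic: HarmonicCoefficients) -> np.ndarray | float:
    """Two-harmonic circadian drive I_k, exactly 1440-min periodic."""
    w = 2.0 * np.pi * (np.asarray(k) % MINUTES_PER_DAY) / MINUTES_PER_DAY
    out = (
        harmonic.alpha1 * np.sin(w)
        + harmonic.beta1 * np.cos(w)
        + harmonic.alpha2 * np.sin(2 * w)
        + harmonic.beta2 * np.cos(2 * w)
    )
    return float(out) if np.ndim(k) == 0 else out


def pulse_probability(
    x: np.ndarray | float, gamma0: float, gamma1: float
) -> np.ndarray | float:
    """Sigmoid link from state to per-minute pulse probability."""
    z = np.clip(gamma0 + gamma1 * np.asarray(x, dtype=float), -500.0, 500.0)
    p = 1.0 / (1.0 + np.exp(-z))
    return float(p) if np.ndim(x) == 0 else p


def bernoulli_loglik(c: int, p: float) -> float:
    """log P(c | p) for a single binary observation."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    return float(c * np.log(p) + (1 - c) * np.log1p(-p))


def envelope_means(
    x: np.ndarray | float, model: EnergyStateModel
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Conditional means (E[R|x], E[S|x]) of the envelope channels."""
    x = np.asarray(x, dtype=float)
    r = model.r0 + model.r1 * x
    s = model.s0 + model.s1 * x
    if x.ndim == 0:
        return float(r), float(s)
    return r, s


def simulate_state_and_obs(
    model: EnergyStateModel,
    u: np.ndarray | None,
    n: int,
    seed: int,
    x0: float = 0.0,
) -> tuple[np.ndarray, list[ObservationTriple]]:
    """Forward-simulate the state recursion and all three observation channels.

    Used for filter validation and EM parameter-recovery studies; the
    virtual-patient pipeline produces the corresponding quantities from
    simulated cortisol instead.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if u is None:
        u = np.zeros(n)
    u = np.asarray(u, dtype=float)
    if u.shape != (n,):
        raise ValueError("u must have length n")

    i_k = forcing(np.arange(n), model.harmonic)
    eps = rng.normal(0.0, np.sqrt(model.sigma_eps2), size=n)
    x = np.empty(n)
    prev = x0
    for k in range(n):
        prev = model.rho * prev + u[k] + i_k[k] + eps[k]
        x[k] = prev

    p = pulse_probability(x, model.gamma0, model.gamma1)
    c = (rng.random(n) < p).astype(np.int64)
    r = model.r0 + model.r1 * x + rng.normal(0.0, np.sqrt(model.sigma_v2), size=n)
    s = model.s0 + model.s1 * x + rng.normal(0.0, np.sqrt(model.sigma_w2), size=n)
    obs = [
        ObservationTriple(c=int(c[k]), R=max(r[k], s[k]), S=min(r[k], s[k]))
        for k in range(n)
    ]
    return x, obs
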