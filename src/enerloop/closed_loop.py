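"""Open- and closed-loop multi-day runs and the study evaluation metrics.

A run simulates a subject's cortisol profile, derives the observation
triple (pulse events, upper/lower envelopes), fits the state-space model
offline by EM, and filters the energy state in real time.  In closed loop,
from the activation day onward the controller is consulted every minute on
the current state estimate; scheduled doses superpose their bi-exponential
medication responses into the control input u, which feeds back into the
filter's prediction step.

Evaluation follows three circadian-balance criteria, each compared between
the open- and closed-loop runs over the controlled days only:

* day-night difference: mean state 06:00-16:00 minus mean state 22:00-04:00;
* wake growth: state rise across the pre-wake window 04:00-08:00;
* sleep drop: state fall across the pre-sleep window 20:00-24:00.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .actuation import DoseEvent, MedicationModel, _kernel
from .controller import (
    ControllerConfig,
    DailyLedger,
    RuleBase,
    default_action_mfs,
    default_rulebase,
    default_time_mfs,
    defuzzify_centroid,
    mamdani_infer,
    schedule_actuation,
    state_mfs_from_percentiles,
)
from .decoder import filter_series, fit_em, predict, update
from .energy_model import EnergyStateModel, ObservationTriple, forcing
from .virtual_patient import (
    MINUTES_PER_DAY,
    CohortSpec,
    CortisolParams,
    CortisolProfile,
    FlatAmplitudeLaw,
    HarmonicAmplitudeLaw,
    make_cohort_presets,
    sample_pulse_train,
    simulate_cortisol,
)

__all__ = [
    "SubjectConfig",
    "MetricWindows",
    "SimulationRun",
    "Metrics",
    "run_open_loop",
    "run_closed_loop",
    "compute_metrics",
    "run_cohort_study",
    "observations_from_profile",
]

# Hypothetical agents with prompt onset (infusion half-life ~1.4 min) and
# sustained action: the daytime stimulant clears over ~4 h (half-life
# ln2/0.003 = 231 min), the bedtime inhibitor over ~6 h, covering the
# waking day and the night respectively from a single dose.
DEFAULT_EXCITATORY = MedicationModel(theta1=0.5, theta2=0.003, eta=1)
DEFAULT_INHIBITORY = MedicationModel(theta1=0.5, theta2=0.002, eta=-1)


def _derive_seed(seed: int, *tags: int) -> int:
    out = seed & 0x7FFFFFFF
    for t in tags:
        out = (out * 1000003 + t + 1) & 0x7FFFFFFF
    return out


@dataclass(frozen=True)
class SubjectConfig:
    """One virtual subject: cohort statistics plus subject-level jitter.

    ``param_jitter`` applies a reproducible +/-10% multiplicative spread to
    the compartment rates and the amplitude baseline so the ten study
    subjects are not identical copies.
    """

    subject_id: int
    cohort: CohortSpec
    cortisol: CortisolParams = field(default_factory=CortisolParams)
    seed: int = 0
    param_jitter: float = 0.10
    em_max_iter: int = 25
    em_tol: float = 1e-5
    em_ascent_slack: float = 1e-3
    # floor on fitted envelope-noise variances ((ug/dL)^2): envelopes are
    # interpolation artifacts, not exact measurements
    em_min_obs_var: float = 0.25

    def jittered(self) -> tuple[CohortSpec, CortisolParams]:
        """Subject-specific parameters (deterministic in subject_id/seed)."""
        if self.param_jitter == 0:
            return self.cohort, self.cortisol
        rng = np.random.default_rng(_derive_seed(self.seed, self.subject_id, 7))
        f = 1.0 + self.param_jitter * rng.uniform(-1.0, 1.0, size=3)
        law = self.cohort.amplitude_law
        if isinstance(law, HarmonicAmplitudeLaw):
            law = replace(law, baseline=law.baseline * f[2])
        else:
            law = FlatAmplitudeLaw(mean=law.mean * f[2], sd=law.sd)
        cohort = replace(self.cohort, amplitude_law=law)
        cort = CortisolParams(
            zeta1=self.cortisol.zeta1 * f[0],
            zeta2=self.cortisol.zeta2 * f[1],
            sigma_psi2=self.cortisol.sigma_psi2,
        )
        return cohort, cort


@dataclass(frozen=True)
class MetricWindows:
    """Minute-of-day windows for the three balance metrics."""

    day: tuple[int, int] = (360, 960)  # 06:00-16:00
    night: tuple[int, int] = (1320, 240)  # 22:00-04:00, wraps midnight
    wake: tuple[int, int] = (240, 480)  # 04:00-08:00
    sleep: tuple[int, int] = (1200, 1439)  # 20:00-24:00
    endpoint_width: int = 15  # minutes averaged at window endpoints


@dataclass
class SimulationRun:
    subject_id: int
    cohort_name: str
    days: int
    activation_day: int  # first controlled day; > days means never
    seed: int
    model: EnergyStateModel
    profile: CortisolProfile
    x_hat: np.ndarray
    var_hat: np.ndarray
    u: np.ndarray
    doses: list[tuple[DoseEvent, int]]

    def __post_init__(self) -> None:
        n_pre = min(self.activation_day - 1, self.days) * MINUTES_PER_DAY
        if np.any(self.u[:n_pre] != 0.0):
            raise ValueError("control input must vanish before activation")

    @property
    def n(self) -> int:
        return self.days * MINUTES_PER_DAY

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": np.arange(self.n),
                "x_hat": self.x_hat,
                "var_hat": self.var_hat,
                "u": self.u,
                "c": self.profile.c,
                "R": self.profile.R,
                "S": self.profile.S,
            }
        )


@dataclass(frozen=True)
class Metrics:
    day_night_diff_open: float
    day_night_diff_closed: float
    wake_growth_open: float
    wake_growth_closed: float
    sleep_drop_open: float
    sleep_drop_closed: float
    day_night_improvement: float
    wake_growth_improvement: float
    sleep_drop_improvement: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def observations_from_profile(profile: CortisolProfile) -> list[ObservationTriple]:
    return [
        ObservationTriple(
            c=int(profile.c[k]), R=float(profile.R[k]), S=float(profile.S[k])
        )
        for k in range(len(profile))
    ]


def _simulate_and_fit(
    subject: SubjectConfig, days: int, seed: int
) -> tuple[CortisolProfile, list[ObservationTriple], EnergyStateModel]:
    cohort, cort = subject.jittered()
    n = days * MINUTES_PER_DAY
    pulses = sample_pulse_train(cohort, n, _derive_seed(seed, subject.subject_id, 1))
    profile = simulate_cortisol(
        pulses, cort, days, _derive_seed(seed, subject.subject_id, 2)
    )
    obs = observations_from_profile(profile)
    model, _ = fit_em(
        obs,
        max_iter=subject.em_max_iter,
        tol=subject.em_tol,
        ascent_slack=subject.em_ascent_slack,
        min_obs_var=subject.em_min_obs_var,
    )
    return profile, obs, model


def run_open_loop(
    subject: SubjectConfig,
    days: int = 5,
    seed: int | None = None,
    model: EnergyStateModel | None = None,
) -> SimulationRun:
    """Track the energy state with no actuation (u = 0 throughout)."""
    seed = subject.seed if seed is None else seed
    profile, obs, fitted = _simulate_and_fit_cached(subject, days, seed, model)
    traj = filter_series(obs, fitted)
    return SimulationRun(
        subject_id=subject.subject_id,
        cohort_name=subject.cohort.name,
        days=days,
        activation_day=days + 1,
        seed=seed,
        model=fitted,
        profile=profile,
        x_hat=traj.mean_post,
        var_hat=traj.var_post,
        u=np.zeros(len(obs)),
        doses=[],
    )


def _simulate_and_fit_cached(subject, days, seed, model):
    if model is None:
        return _simulate_and_fit(subject, days, seed)
    cohort, cort = subject.jittered()
    n = days * MINUTES_PER_DAY
    pulses = sample_pulse_train(cohort, n, _derive_seed(seed, subject.subject_id, 1))
    profile = simulate_cortisol(
        pulses, cort, days, _derive_seed(seed, subject.subject_id, 2)
    )
    return profile, observations_from_profile(profile), model


def personalized_controller_config(
    reference_x_hat: np.ndarray,
    rulebase: RuleBase | None = None,
) -> ControllerConfig:
    """Controller personalised to a healthy-reference state trajectory.

    Low/Medium/High state sets sit at the 25th/50th/75th percentiles of the
    reference filtered state; the dose ceiling q_max is the reference
    inter-quartile range, so a full-strength dose can move the state by
    about one healthy circadian swing.
    """
    p25, p50, p75 = np.percentile(reference_x_hat, [25, 50, 75])
    if not p25 < p50 < p75:  # degenerate (flat) reference
        spread = max(np.std(reference_x_hat), 1e-3)
        p25, p50, p75 = -spread, 0.0, spread
    q_max = float(p75 - p25)
    cfg = ControllerConfig(
        time_mfs=default_time_mfs(),
        state_mfs=state_mfs_from_percentiles(float(p25), float(p50), float(p75)),
        action_mfs=default_action_mfs(q_max),
        q_max=q_max,
    )
    if rulebase is not None:
        rulebase.validate_against(cfg)
    return cfg


def run_closed_loop(
    subject: SubjectConfig,
    days: int = 5,
    activation_day: int = 3,
    seed: int | None = None,
    controller_config: ControllerConfig | None = None,
    rulebase: RuleBase | None = None,
    excitatory: MedicationModel = DEFAULT_EXCITATORY,
    inhibitory: MedicationModel = DEFAULT_INHIBITORY,
    model: EnergyStateModel | None = None,
) -> SimulationRun:
    """Closed-loop run: open loop before ``activation_day``, control after.

    ``activation_day`` is 1-based: activation_day=3 means days 1-2 are
    open-loop and control starts at the beginning of day 3.  Every minute
    of the controlled period the filter state feeds the fuzzy controller;
    accepted doses add their medication response to u for all later
    minutes, and the filter sees the same u it injected.
    """
    if activation_day < 1:
        raise ValueError("activation_day must be >= 1")
    seed = subject.seed if seed is None else seed
    profile, obs, fitted = _simulate_and_fit_cached(subject, days, seed, model)
    n = len(obs)

    if controller_config is None:
        healthy = replace(
            subject, cohort=make_cohort_presets()["healthy"]
        )
        ref = run_open_loop(healthy, days=days, seed=seed)
        controller_config = personalized_controller_config(ref.x_hat)
    if rulebase is None:
        rulebase = default_rulebase()
    rulebase.validate_against(controller_config)

    u = np.zeros(n)
    x_hat = np.empty(n)
    var_hat = np.empty(n)
    doses: list[tuple[DoseEvent, int]] = []
    ledger = DailyLedger()
    i_all = forcing(np.arange(n), fitted.harmonic)
    first_controlled = (activation_day - 1) * MINUTES_PER_DAY

    m_prev, v_prev = 0.0, fitted.stationary_var
    for k in range(n):
        mean_pred, var_pred = predict(m_prev, v_prev, fitted, u[k], i_all[k])
        st = update(mean_pred, var_pred, obs[k], fitted)
        x_hat[k], var_hat[k] = st.mean_post, st.var_post
        m_prev, v_prev = st.mean_post, st.var_post

        if k >= first_controlled:
            time_min = k % MINUTES_PER_DAY
            day = k // MINUTES_PER_DAY
            mu = mamdani_infer(time_min, x_hat[k], controller_config, rulebase)
            q_star = defuzzify_centroid(mu, controller_config.dose_grid)
            decision = schedule_actuation(
                q_star, time_min, day, ledger, controller_config
            )
            if decision is not None:
                dose, eta = decision
                doses.append((dose, eta))
                med = excitatory if eta > 0 else inhibitory
                lags = np.arange(1, n - k)
                if lags.size:
                    u[k + 1 :] += eta * dose.q * _kernel(
                        med.theta1, med.theta2, lags
                    )

    return SimulationRun(
        subject_id=subject.subject_id,
        cohort_name=subject.cohort.name,
        days=days,
        activation_day=activation_day,
        seed=seed,
        model=fitted,
        profile=profile,
        x_hat=x_hat,
        var_hat=var_hat,
        u=u,
        doses=doses,
    )


def _window_mask(n: int, start_day: int, days: int, window: tuple[int, int]) -> np.ndarray:
    minute = np.arange(n) % MINUTES_PER_DAY
    day = np.arange(n) // MINUTES_PER_DAY
    in_days = (day >= start_day) & (day < days)
    a, b = window
    in_win = (minute >= a) & (minute < b) if a < b else (minute >= a) | (minute < b)
    return in_days & in_win


def _endpoint_mean(x: np.ndarray, day: int, minute: int, width: int) -> float:
    k = day * MINUTES_PER_DAY + minute
    lo = max(k - width // 2, day * MINUTES_PER_DAY)
    hi = min(k + width // 2 + 1, (day + 1) * MINUTES_PER_DAY, len(x))
    return float(x[lo:hi].mean())


def _run_metrics(run: SimulationRun, start_day: int, windows: MetricWindows):
    x = run.x_hat
    n = run.n
    day_mean = x[_window_mask(n, start_day, run.days, windows.day)].mean()
    night_mean = x[_window_mask(n, start_day, run.days, windows.night)].mean()
    growths, drops = [], []
    for d in range(start_day, run.days):
        growths.append(
            _endpoint_mean(x, d, windows.wake[1], windows.endpoint_width)
            - _endpoint_mean(x, d, windows.wake[0], windows.endpoint_width)
        )
        drops.append(
            _endpoint_mean(x, d, windows.sleep[0], windows.endpoint_width)
            - _endpoint_mean(x, d, windows.sleep[1], windows.endpoint_width)
        )
    return float(day_mean - night_mean), float(np.mean(growths)), float(np.mean(drops))


def compute_metrics(
    open_run: SimulationRun,
    closed_run: SimulationRun,
    windows: MetricWindows | None = None,
    eps: float = 1e-9,
) -> Metrics:
    """Balance metrics over the controlled days, open vs. closed loop."""
    if (
        open_run.days != closed_run.days
        or open_run.subject_id != closed_run.subject_id
    ):
        raise ValueError("runs must share subject and horizon")
    windows = windows or MetricWindows()
    start_day = min(closed_run.activation_day - 1, closed_run.days)
    dn_o, wg_o, sd_o = _run_metrics(open_run, start_day, windows)
    dn_c, wg_c, sd_c = _run_metrics(closed_run, start_day, windows)

    def improve(c: float, o: float) -> float:
        return float("nan") if abs(o) < eps else 100.0 * (c - o) / abs(o)

    return Metrics(
        day_night_diff_open=dn_o,
        day_night_diff_closed=dn_c,
        wake_growth_open=wg_o,
        wake_growth_closed=wg_c,
        sleep_drop_open=sd_o,
        sleep_drop_closed=sd_c,
        day_night_improvement=improve(dn_c, dn_o),
        wake_growth_improvement=improve(wg_c, wg_o),
        sleep_drop_improvement=improve(sd_c, sd_o),
    )


def run_cohort_study(
    n_subjects: int = 10,
    seed: int = 0,
    days: int = 5,
    activation_day: int = 3,
    cohorts: tuple[str, ...] = ("cushing_no_circadian", "cushing_circadian"),
    windows: MetricWindows | None = None,
    em_max_iter: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject metrics for the Cushing cohorts plus quartile summary.

    Returns ``(table, summary)``: one row per (subject, cohort) with all
    metric fields, and the median/quartiles of each improvement per cohort.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    presets = make_cohort_presets()
    rows = []
    controller_cache: dict[int, ControllerConfig] = {}
    for cohort_name in cohorts:
        for sid in range(1, n_subjects + 1):
            subject = SubjectConfig(
                subject_id=sid,
                cohort=presets[cohort_name],
                seed=_derive_seed(seed, sid, 100),
                em_max_iter=em_max_iter,
            )
            if sid not in controller_cache:
                healthy = replace(subject, cohort=presets["healthy"])
                ref = run_open_loop(healthy, days=days)
                controller_cache[sid] = personalized_controller_config(ref.x_hat)
            closed = run_closed_loop(
                subject,
                days=days,
                activation_day=activation_day,
                controller_config=controller_cache[sid],
            )
            open_run = run_open_loop(subject, days=days, model=closed.model)
            m = compute_metrics(open_run, closed, windows)
            row = {"subject": sid, "cohort": cohort_name, **m.as_dict()}
            row["n_doses"] = len(closed.doses)
            rows.append(row)
    table = pd.DataFrame(rows)
    improvement_cols = [
        "day_night_improvement",
        "wake_growth_improvement",
        "sleep_drop_improvement",
    ]
    summary = (
        table.groupby("cohort")[improvement_cols]
        .quantile([0.25, 0.5, 0.75])
        .unstack(level=-1)
    )
    return table, summary
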