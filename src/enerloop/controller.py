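"""Mamdani fuzzy controller for intermittent medication scheduling.

Inputs are the time of day (minutes since midnight) and the decoded energy
state; the output is a signed crisp dose on [-q_max, q_max].  Inference is
classical Mamdani: minimum for the AND of the antecedents and for
implication, maximum for rule aggregation, centroid defuzzification of the
aggregated output set on a uniform dose grid.  Positive crisp output
requests an excitatory dose, negative an inhibitory one; a per-day ledger
enforces at most one of each class per calendar day (two doses total), and
each class is structurally confined to its plausible time region (morning
for excitatory, evening for inhibitory).

The default rule base has twelve rules over four active time-of-day labels
(early/late morning, early/late evening) crossed with three state labels
(Low / Medium / High); the Night and Afternoon time labels carry no rules,
so the controller is silent there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .actuation import DoseEvent

__all__ = [
    "MembershipFunction",
    "Rule",
    "RuleBase",
    "ControllerConfig",
    "DailyLedger",
    "fuzzify",
    "mamdani_infer",
    "defuzzify_centroid",
    "schedule_actuation",
    "default_time_mfs",
    "default_action_mfs",
    "state_mfs_from_percentiles",
    "default_rulebase",
]


@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear fuzzy set defined by (value, degree) knots.

    Outside the knot range the membership extends the boundary degree, so
    shoulder sets (boundary degree 1) saturate and ordinary sets (boundary
    degree 0) vanish outside their support.
    """

    label: str
    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(v), float(d)) for v, d in self.breakpoints)
        if len(pts) < 2:
            raise ValueError("membership function needs at least two knots")
        values = [v for v, _ in pts]
        degrees = [d for _, d in pts]
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError(f"{self.label}: knot values must be strictly increasing")
        if any(not 0.0 <= d <= 1.0 for d in degrees):
            raise ValueError(f"{self.label}: degrees must lie in [0, 1]")
        if not any(d == 1.0 for d in degrees):
            raise ValueError(f"{self.label}: a normal fuzzy set needs a degree-1 knot")
        object.__setattr__(self, "breakpoints", pts)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for v, _ in self.breakpoints])

    @property
    def degrees(self) -> np.ndarray:
        return np.array([d for _, d in self.breakpoints])

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return fuzzify(x, self)


def fuzzify(value: np.ndarray | float, mf: MembershipFunction) -> np.ndarray | float:
    """Degree of membership by linear interpolation of the knots."""
    out = np.interp(
        np.asarray(value, dtype=float),
        mf.values,
        mf.degrees,
        left=mf.degrees[0],
        right=mf.degrees[-1],
    )
    return float(out) if np.ndim(value) == 0 else out


@dataclass(frozen=True)
class Rule:
    time_label: str
    state_label: str
    action_label: str


@dataclass(frozen=True)
class RuleBase:
    rules: tuple[Rule, ...]

    def __len__(self) -> int:
        return len(self.rules)

    def validate_against(self, config: "ControllerConfig") -> None:
        time_labels = {mf.label for mf in config.time_mfs}
        state_labels = {mf.label for mf in config.state_mfs}
        action_labels = {mf.label for mf in config.action_mfs}
        for rule in self.rules:
            if rule.time_label not in time_labels:
                raise ValueError(f"unknown time label {rule.time_label!r}")
            if rule.state_label not in state_labels:
                raise ValueError(f"unknown state label {rule.state_label!r}")
            if rule.action_label not in action_labels:
                raise ValueError(f"unknown action label {rule.action_label!r}")


def default_rulebase() -> RuleBase:
    """The twelve-rule knowledge base (time label, state label -> action)."""
    rows = [
        ("early_morning", "High", "PS"),
        ("early_morning", "Low", "PB"),
        ("early_morning", "Medium", "PM"),
        ("late_morning", "High", "Z"),
        ("late_morning", "Low", "PM"),
        ("late_morning", "Medium", "PS"),
        ("early_evening", "High", "NM"),
        ("early_evening", "Low", "Z"),
        ("early_evening", "Medium", "NS"),
        ("late_evening", "High", "NB"),
        ("late_evening", "Low", "NS"),
        ("late_evening", "Medium", "NM"),
    ]
    return RuleBase(rules=tuple(Rule(*row) for row in rows))


def _trapezoid(label: str, a: float, b: float, c: float, d: float) -> MembershipFunction:
    return MembershipFunction(label, ((a, 0.0), (b, 1.0), (c, 1.0), (d, 0.0)))


def default_time_mfs() -> tuple[MembershipFunction, ...]:
    """Six trapezoidal time-of-day sets (minutes) with 1-h linear shoulders.

    Each set's support is exactly its nominal interval — night 0-5 h, early
    morning 5-9, late morning 9-13, afternoon 13-17, early evening 17-20,
    late evening 20-24 — with the shoulders inside the interval, so a set
    only becomes active once its period has actually begun.  Night and
    Afternoon carry no rules; the remaining four labels match the rule
    base.
    """
    h = 60.0
    return (
        MembershipFunction("night", ((0.0, 1.0), (4 * h, 1.0), (5 * h, 0.0))),
        _trapezoid("early_morning", 5 * h, 6 * h, 8 * h, 9 * h),
        _trapezoid("late_morning", 9 * h, 10 * h, 12 * h, 13 * h),
        _trapezoid("afternoon", 13 * h, 14 * h, 16 * h, 17 * h),
        _trapezoid("early_evening", 17 * h, 18 * h, 19 * h, 20 * h),
        MembershipFunction(
            "late_evening", ((20 * h, 0.0), (21 * h, 1.0), (1439.0, 1.0))
        ),
    )


def default_action_mfs(q_max: float) -> tuple[MembershipFunction, ...]:
    """Seven triangular output sets NB..PB, symmetric about zero dose."""
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    c = q_max / 3.0
    labels = ["NB", "NM", "NS", "Z", "PS", "PM", "PB"]
    centers = [-3 * c, -2 * c, -c, 0.0, c, 2 * c, 3 * c]
    mfs = []
    for lab, ctr in zip(labels, centers):
        if lab == "NB":
            pts = ((-3 * c, 1.0), (-2 * c, 0.0))
        elif lab == "PB":
            pts = ((2 * c, 0.0), (3 * c, 1.0))
        else:
            pts = ((ctr - c, 0.0), (ctr, 1.0), (ctr + c, 0.0))
        mfs.append(MembershipFunction(lab, pts))
    return tuple(mfs)


def state_mfs_from_percentiles(
    p25: float, p50: float, p75: float
) -> tuple[MembershipFunction, ...]:
    """Low/Medium/High state sets personalised to reference percentiles.

    Low saturates below the 25th percentile of a healthy-reference filtered
    state, High above the 75th; Medium is the triangle between them.
    """
    if not p25 < p50 < p75:
        raise ValueError("percentiles must be strictly increasing")
    return (
        MembershipFunction("Low", ((p25, 1.0), (p50, 0.0))),
        MembershipFunction("Medium", ((p25, 0.0), (p50, 1.0), (p75, 0.0))),
        MembershipFunction("High", ((p50, 0.0), (p75, 1.0))),
    )


@dataclass(frozen=True)
class ControllerConfig:
    time_mfs: tuple[MembershipFunction, ...]
    state_mfs: tuple[MembershipFunction, ...]
    action_mfs: tuple[MembershipFunction, ...]
    q_max: float
    daily_dose_limit: int = 2
    dose_grid_points: int = 1001
    dead_band_frac: float = 0.01
    # time labels where each dose class may be honoured: the excitatory
    # agent is taken on waking, the inhibitory one at bedtime
    excitatory_labels: tuple[str, ...] = ("early_morning", "late_morning")
    inhibitory_labels: tuple[str, ...] = ("late_evening",)

    def __post_init__(self) -> None:
        if len(self.time_mfs) != 6:
            raise ValueError("expected six time-of-day membership functions")
        if len(self.state_mfs) != 3:
            raise ValueError("expected three state membership functions")
        if len(self.action_mfs) != 7:
            raise ValueError("expected seven action membership functions")
        if self.q_max <= 0:
            raise ValueError("q_max must be positive")

    @property
    def dose_grid(self) -> np.ndarray:
        return np.linspace(-self.q_max, self.q_max, self.dose_grid_points)

    @property
    def dead_band(self) -> float:
        return self.dead_band_frac * self.q_max

    def mf(self, kind: str, label: str) -> MembershipFunction:
        pool = {"time": self.time_mfs, "state": self.state_mfs, "action": self.action_mfs}[kind]
        for mf in pool:
            if mf.label == label:
                return mf
        raise KeyError(f"no {kind} membership function labelled {label!r}")


@dataclass
class DailyLedger:
    """Doses applied per calendar day, at most one of each class."""

    excitatory: dict[int, int] = field(default_factory=dict)
    inhibitory: dict[int, int] = field(default_factory=dict)

    def count(self, day: int) -> int:
        return self.excitatory.get(day, 0) + self.inhibitory.get(day, 0)

    def can_apply(self, day: int, excitatory: bool, limit: int = 2) -> bool:
        book = self.excitatory if excitatory else self.inhibitory
        return book.get(day, 0) < 1 and self.count(day) < limit

    def record(self, day: int, excitatory: bool) -> None:
        book = self.excitatory if excitatory else self.inhibitory
        book[day] = book.get(day, 0) + 1


def mamdani_infer(
    time_min: float,
    x_hat: float,
    config: ControllerConfig,
    rulebase: RuleBase | None = None,
) -> np.ndarray:
    """Aggregated output membership over the dose grid.

    Each rule fires at min(mu_time, mu_state); its consequent is clipped at
    the firing strength (min-implication) and the rule outputs are combined
    by pointwise maximum.
    """
    if not 0.0 <= time_min < 1440.0:
        raise ValueError(f"time_min must lie in [0, 1440), got {time_min}")
    if rulebase is None:
        rulebase = default_rulebase()
    grid = config.dose_grid
    agg = np.zeros_like(grid)
    for rule in rulebase.rules:
        strength = min(
            fuzzify(time_min, config.mf("time", rule.time_label)),
            fuzzify(x_hat, config.mf("state", rule.state_label)),
        )
        if strength <= 0.0:
            continue
        clipped = np.minimum(strength, fuzzify(grid, config.mf("action", rule.action_label)))
        np.maximum(agg, clipped, out=agg)
    return agg


def defuzzify_centroid(mu: np.ndarray, grid: np.ndarray) -> float:
    """Centre of mass of the aggregated set; 0 when the set is empty."""
    if mu.shape != grid.shape:
        raise ValueError("membership and grid shapes differ")
    mass = np.trapezoid(mu, grid)
    if mass <= 0.0:
        return 0.0
    return float(np.trapezoid(mu * grid, grid) / mass)


def schedule_actuation(
    q_star: float,
    time_min: float,
    day: int,
    ledger: DailyLedger,
    config: ControllerConfig,
) -> tuple[DoseEvent, int] | None:
    """Turn a crisp controller output into a dose event, or decline.

    Returns ``(dose, eta)`` with eta +1 (excitatory) / -1 (inhibitory), or
    None when the output is inside the dead band, the class is not allowed
    at this time of day, or the daily ledger is exhausted.
    """
    if abs(q_star) < config.dead_band:
        return None
    excitatory = q_star > 0
    labels = config.excitatory_labels if excitatory else config.inhibitory_labels
    in_region = any(fuzzify(time_min, config.mf("time", lab)) > 0 for lab in labels)
    if not in_region:
        return None
    if not ledger.can_apply(day, excitatory, config.daily_dose_limit):
        return None
    ledger.record(day, excitatory)
    tau = day * 1440 + int(time_min)
    return DoseEvent(tau=tau, q=abs(q_star)), (1 if excitatory else -1)
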