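"""Marginal-value-theorem cost-benefit model of post-ejaculatory mate guarding.

Male flies that stay mounted after insemination keep rival sperm away from
the female; how long that guarding phase should last is a classic
patch-residence problem.  Benefit (eggs secured) accrues with diminishing
returns while cost (predation exposure, forgone matings) accrues steadily,
so the marginal value theorem yields a finite optimal guarding duration.
Shorter-mating-duration (SMD) plasticity is adaptive whenever a change in a
male's state parameters moves that optimum down.

Model definition (the single seam other forms could be substituted behind):

    B(t) = (1/alpha) * (1 - exp(-beta * t))      benefit, eggs secured
    C(t) = (gamma / e) * t                       cost, egg-equivalents
    N(t) = B(t) - C(t)                           net payoff, maximised over t

``alpha`` is the inverse of the total clutch a male can secure (larger alpha,
fewer eggs in total), ``beta`` the benefit-accrual rate (per unit time), and
``gamma`` the cost parameter, measured in the composite units that make the
regime comparisons against beta/alpha dimensionally valid; the marginal cost
rate is gamma/e.  With this gauge the model's two qualitative transitions sit
exactly at the classifier boundaries:

* gamma <= beta/alpha      : t* >= 1/beta (at least one benefit time constant)
* beta/alpha < gamma < e*beta/alpha : interior optimum shrinking in gamma
* gamma >= e*beta/alpha    : guarding no longer pays, t* = 0

Interior closed form: t* = (1/beta) * ln(e*beta / (alpha*gamma)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GuardingParams",
    "PayoffCurve",
    "OptimalGuarding",
    "ScenarioPrediction",
    "benefit",
    "cost",
    "net_payoff",
    "optimal_guarding_time",
    "classify_regime",
    "predict_smd",
    "parameter_sweep",
]

Regime = Literal["below_window", "scenario_C_window", "scenario_D_window"]
SolutionKind = Literal["interior", "corner_zero", "corner_max"]

#: Relative tolerance for real-valued comparisons throughout the module.
REL_TOL = 1e-9


@dataclass(frozen=True)
class GuardingParams:
    """Parameters of the guarding payoff model.

    alpha : inverse total-benefit scale (> 0); total securable eggs = 1/alpha.
    beta  : benefit-accrual rate (> 0), per unit guarding time.
    gamma : cost parameter (>= 0); marginal cost rate is gamma/e, so the
            regime comparisons gamma vs beta/alpha and e*beta/alpha are
            dimensionally valid.
    t_max : admissible guarding horizon; defaults to 10/beta (several benefit
            time constants, enough to capture saturation).
    """

    alpha: float
    beta: float
    gamma: float
    t_max: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.t_max is None:
            object.__setattr__(self, "t_max", 10.0 / self.beta)
        if not math.isfinite(self.t_max) or self.t_max <= 0:
            raise ValueError(f"t_max must be finite and > 0, got {self.t_max}")

    @property
    def rate_ratio(self) -> float:
        """beta/alpha, the lower regime boundary for gamma."""
        return self.beta / self.alpha

    def replace(self, **changes) -> "GuardingParams":
        kwargs = {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "t_max": self.t_max,
        }
        kwargs.update(changes)
        return GuardingParams(**kwargs)


@dataclass(frozen=True)
class PayoffCurve:
    """Benefit, cost and net payoff evaluated on an ordered grid of durations."""

    times: np.ndarray
    benefit_values: np.ndarray
    cost_values: np.ndarray
    net_values: np.ndarray


@dataclass(frozen=True)
class OptimalGuarding:
    """Result of the guarding-time optimisation."""

    t_star: float
    payoff_at_optimum: float
    solution_kind: SolutionKind
    method: Literal["closed_form", "grid_search"]


@dataclass(frozen=True)
class ScenarioPrediction:
    """Comparative-statics prediction for a naive -> experienced parameter shift."""

    scenario: str
    naive_params: GuardingParams
    experienced_params: GuardingParams
    delta_t_star: float
    smd_predicted: bool
    changed_params: tuple[str, ...] = field(default=())


def _check_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("guarding duration t must be >= 0")
    return t


def benefit(t, params: GuardingParams):
    """Eggs secured after guarding for time ``t``: (1/alpha)(1 - exp(-beta t)).

    Concave and saturating at 1/alpha, so an interior MVT optimum can exist.
    Accepts scalars or arrays.
    """
    tt = _check_t(t)
    out = (1.0 / params.alpha) * -np.expm1(-params.beta * tt)
    return out.item() if np.isscalar(t) or np.ndim(t) == 0 else out


def benefit_derivative(t, params: GuardingParams):
    """Marginal benefit dB/dt = (beta/alpha) exp(-beta t)."""
    tt = _check_t(t)
    out = (params.beta / params.alpha) * np.exp(-params.beta * tt)
    return out.item() if np.isscalar(t) or np.ndim(t) == 0 else out


def cost(t, params: GuardingParams):
    """Cost of guarding for time ``t``: (gamma/e) * t.

    Linear in t and homogeneous of degree 1 in gamma; identically zero when
    gamma = 0.
    """
    tt = _check_t(t)
    out = (params.gamma / math.e) * tt
    return out.item() if np.isscalar(t) or np.ndim(t) == 0 else out


def net_payoff(t, params: GuardingParams):
    """Objective maximised over guarding time: benefit minus cost."""
    tt = _check_t(t)
    out = (1.0 / params.alpha) * -np.expm1(-params.beta * tt) - (
        params.gamma / math.e
    ) * tt
    return out.item() if np.isscalar(t) or np.ndim(t) == 0 else out


def payoff_curve(params: GuardingParams, n_points: int = 512) -> PayoffCurve:
    times = np.linspace(0.0, params.t_max, n_points)
    b = benefit(times, params)
    c = cost(times, params)
    return PayoffCurve(times=times, benefit_values=b, cost_values=c, net_values=b - c)


def _closed_form(params: GuardingParams) -> OptimalGuarding:
    # Stationarity (beta/alpha) e^{-beta t} = gamma/e  =>  t* = ln(e beta/(alpha gamma))/beta.
    if params.gamma == 0.0:
        t_star = params.t_max
        kind: SolutionKind = "corner_max"
    else:
        t_unc = math.log(math.e * params.beta / (params.alpha * params.gamma)) / params.beta
        if t_unc <= 0.0:
            t_star, kind = 0.0, "corner_zero"
        elif t_unc >= params.t_max:
            t_star, kind = params.t_max, "corner_max"
        else:
            t_star, kind = t_unc, "interior"
    return OptimalGuarding(
        t_star=t_star,
        payoff_at_optimum=net_payoff(t_star, params),
        solution_kind=kind,
        method="closed_form",
    )


def _golden_section(f, lo: float, hi: float, tol: float) -> float:
    """Maximise unimodal f on [lo, hi] to within tol in the argument."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    # each iteration shrinks the bracket by phi; cap defends against tol ~ 0
    for _ in range(200):
        if b - a <= tol:
            break
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    else:
        raise RuntimeError(
            f"golden-section refinement did not converge: bracket [{a}, {b}], tol {tol}"
        )
    return 0.5 * (a + b)


def _grid_search(params: GuardingParams, grid_size: int, tolerance: float) -> OptimalGuarding:
    grid = np.linspace(0.0, params.t_max, grid_size)
    vals = net_payoff(grid, params)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    if hi > lo:
        t_star = _golden_section(lambda t: net_payoff(t, params), lo, hi, tolerance)
    else:
        t_star = grid[i]
    # classify corners with the bracket resolution in mind
    step = params.t_max / (grid_size - 1)
    if t_star <= max(tolerance, step * 1e-6):
        t_star, kind = 0.0, "corner_zero"
    elif params.t_max - t_star <= max(tolerance, step * 1e-6):
        t_star, kind = params.t_max, "corner_max"
    else:
        kind = "interior"
    return OptimalGuarding(
        t_star=t_star,
        payoff_at_optimum=net_payoff(t_star, params),
        solution_kind=kind,
        method="grid_search",
    )


def optimal_guarding_time(
    params: GuardingParams,
    method: Literal["closed_form", "grid_search"] = "closed_form",
    grid_size: int = 10_000,
    tolerance: float = 1e-8,
) -> OptimalGuarding:
    """Optimal guarding duration on [0, t_max].

    ``closed_form`` uses the analytic stationary point with corner handling;
    ``grid_search`` takes the argmax over a uniform grid and refines the
    bracketing interval by golden-section search to ``tolerance`` in t.
    """
    if method == "closed_form":
        return _closed_form(params)
    if method == "grid_search":
        if grid_size < 1000:
            raise ValueError(f"grid_size must be >= 1000, got {grid_size}")
        if tolerance <= 0:
            raise ValueError("tolerance must be positive")
        return _grid_search(params, grid_size, tolerance)
    raise ValueError(f"unknown method {method!r}")


def classify_regime(params: GuardingParams) -> Regime:
    """Place gamma relative to the boundaries beta/alpha and e*beta/alpha.

    Exact equality at a boundary classifies into the lower-labelled regime
    (below_window at gamma = beta/alpha, scenario_C_window at e*beta/alpha),
    keeping the strict regime inequalities deterministic.
    """
    lower = params.rate_ratio
    upper = math.e * lower
    if params.gamma <= lower:
        return "below_window"
    if params.gamma <= upper:
        return "scenario_C_window"
    return "scenario_D_window"


_SCENARIO_LABELS = {
    ("alpha", 1): "A_alpha_larger",
    ("beta", -1): "B_beta_smaller",
    ("gamma", 1): "C_gamma_larger",
    ("gamma", -1): "D_gamma_smaller",
}


def _scenario_label(naive: GuardingParams, experienced: GuardingParams) -> tuple[str, tuple[str, ...]]:
    changed = tuple(
        name
        for name in ("alpha", "beta", "gamma")
        if getattr(naive, name) != getattr(experienced, name)
    )
    if len(changed) != 1:
        return "composite", changed
    name = changed[0]
    direction = 1 if getattr(experienced, name) > getattr(naive, name) else -1
    label = _SCENARIO_LABELS.get((name, direction))
    if label is None:
        return "composite", changed
    if name == "gamma":
        # C vs D is only meaningful relative to the naive male's regime
        regime = classify_regime(naive)
        if direction == 1 and regime != "scenario_C_window":
            return "composite", changed
        if direction == -1 and regime != "scenario_D_window":
            return "composite", changed
    return label, changed


def predict_smd(
    naive: GuardingParams,
    experienced: GuardingParams,
    method: Literal["closed_form", "grid_search"] = "closed_form",
    grid_size: int = 10_000,
    tolerance: float = 1e-8,
) -> ScenarioPrediction:
    """Compare optimal guarding for naive vs experienced parameters.

    SMD is predicted exactly when the experienced optimum is strictly shorter.
    """
    if (naive.alpha, naive.beta, naive.gamma, naive.t_max) == (
        experienced.alpha,
        experienced.beta,
        experienced.gamma,
        experienced.t_max,
    ):
        raise ValueError("naive and experienced parameters are identical")
    opt_n = optimal_guarding_time(naive, method, grid_size, tolerance)
    opt_e = optimal_guarding_time(experienced, method, grid_size, tolerance)
    delta = opt_e.t_star - opt_n.t_star
    label, changed = _scenario_label(naive, experienced)
    return ScenarioPrediction(
        scenario=label,
        naive_params=naive,
        experienced_params=experienced,
        delta_t_star=delta,
        smd_predicted=delta < 0,
        changed_params=changed,
    )


def parameter_sweep(
    base: GuardingParams,
    which: Literal["alpha", "beta", "gamma"],
    grid: Iterable[float] | Sequence[float],
    method: Literal["closed_form", "grid_search"] = "closed_form",
    grid_size: int = 10_000,
    tolerance: float = 1e-8,
) -> pd.DataFrame:
    """Optimum, payoff and regime along a one-parameter sweep.

    Returns a DataFrame with columns param_value, t_star, payoff,
    solution_kind, regime, in grid order.
    """
    values = list(grid)
    if not values:
        raise ValueError("sweep grid must be non-empty")
    rows = []
    for v in values:
        try:
            p = base.replace(**{which: float(v)})
            opt = optimal_guarding_time(p, method, grid_size, tolerance)
        except (ValueError, RuntimeError) as exc:
            raise ValueError(f"sweep failed at {which}={v!r}: {exc}") from exc
        rows.append(
            {
                "param_value": float(v),
                "t_star": opt.t_star,
                "payoff": opt.payoff_at_optimum,
                "solution_kind": opt.solution_kind,
                "regime": classify_regime(p),
            }
        )
    return pd.DataFrame(rows)
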