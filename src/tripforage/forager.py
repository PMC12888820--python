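"""Sequential foraging strategies and their Monte Carlo evaluation.

Three strategies are implemented over the same episode mechanics:

* ``plan_once`` — optimise a sequence of up to ``M`` trips at time zero and
  execute it verbatim until a find or exhaustion;
* ``replan`` — optimise up to ``M`` trips, execute only the first, and on
  an empty-handed return update the belief about the nearest patch (the
  memoryless exponential prior conditions to ``p e^{-p (d - r)}`` beyond
  the explored range ``r``) and re-optimise with the remaining time;
* ``local_rule`` — a two-step heuristic: find the best *single* trip
  ``d_m``; if it beats staying, check whether inserting a shorter first
  trip ``d_s < d_m`` has positive expected gain (three-scenario
  decomposition) and travel to whichever wins.

On any strategy, an episode ends when the forager finds a patch (it then
harvests it for the remainder of the horizon), or when exploring is no
longer favourable — the best single trip over the unexplored remainder
does no better than staying put — or when time runs out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .core import EnvironmentBelief, ForagerParams, TripPlan, patch_rate, prep_time
from .expected_utility import plan_expected_utility, two_trip_gain
from .planner import best_over_horizon, optimize_fixed_K

__all__ = [
    "BeliefState",
    "StrategyConfig",
    "EpisodeResult",
    "MonteCarloResult",
    "update_belief",
    "local_rule_step",
    "run_episode",
    "no_find_sequence",
    "policy_expected_utility",
    "monte_carlo_utility",
]

MODES = ("plan_once", "replan", "local_rule")


@dataclass(frozen=True)
class BeliefState:
    """Explored range and the (fixed-form) environment belief.

    The conditional nearest-patch density is ``p e^{-p (d - r)}`` on
    ``(r, D]`` and zero below ``r`` — the exponential prior is memoryless,
    so ``r`` is a sufficient statistic for everything learned from failed
    trips.
    """

    r: float
    belief: EnvironmentBelief

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= self.belief.D:
            raise ValueError(f"explored range r={self.r} outside [0, {self.belief.D}]")


def update_belief(state: BeliefState, executed_d: float) -> BeliefState:
    """Condition on a failed trip out to ``executed_d``: the range grows, nothing else."""
    if not executed_d > state.r:
        raise ValueError(
            f"executed trip distance {executed_d} must exceed the explored range {state.r}"
        )
    if executed_d > state.belief.D:
        raise ValueError(f"trip distance {executed_d} beyond the environment D={state.belief.D}")
    return BeliefState(r=float(executed_d), belief=state.belief)


@dataclass(frozen=True)
class StrategyConfig:
    """Which strategy to run and with what horizon / sampling setup."""

    mode: str
    M: int = 1
    seed: int = 0
    n_episodes: int = 0
    grid_n: int = 400

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode != "local_rule" and self.M < 1:
            raise ValueError("planning modes need a horizon M >= 1")
        if self.n_episodes < 0:
            raise ValueError("n_episodes must be >= 0")


def local_rule_step(
    state: BeliefState,
    params: ForagerParams,
    t_elapsed: float = 0.0,
    grid: Optional[np.ndarray] = None,
    grid_n: int = 400,
) -> Optional[float]:
    """One decision of the two-step local rule: ``None`` to stay, else a trip distance.

    Step 1: the best single trip ``d_m`` over the unexplored range; stay if
    it does not beat harvesting the known patch.  Step 2: maximise the
    three-scenario gain of a shorter first trip ``d_s < d_m``; take ``d_s``
    if that gain is positive, else ``d_m``.

    With ``grid`` given (ordered candidate endpoints), both steps are
    evaluated with per-bin sums in place of integrals — the discrete form
    the winner-take-all circuit implements — and decisions are restricted
    to grid points.
    """
    if grid is not None:
        return _local_rule_step_grid(state, params, np.asarray(grid, dtype=float), t_elapsed)

    belief, r = state.belief, state.r
    horizon = params.T - t_elapsed
    if horizon <= 0 or r >= belief.D:
        return None
    plan1, _ = optimize_fixed_K(1, belief, params, r=r, t_elapsed=t_elapsed, grid_n=grid_n)
    if plan1.is_empty:
        return None
    d_m = plan1.distances[0]

    # step 2: scan + polish the one-dimensional shorter-trip gain
    c = params.trip_time_factor
    hi = min(d_m, horizon / c - d_m)  # keep the two-trip plan feasible
    if hi <= r:
        return d_m
    lo = r
    ds_grid = np.linspace(lo, hi, 513)[1:-1]
    gains = two_trip_gain(ds_grid, d_m, belief, params, r=r, t_elapsed=t_elapsed)
    k = int(np.argmax(gains))
    lo_b = ds_grid[max(k - 1, 0)]
    hi_b = ds_grid[min(k + 1, len(ds_grid) - 1)]
    res = minimize_scalar(
        lambda ds: -float(two_trip_gain(ds, d_m, belief, params, r=r, t_elapsed=t_elapsed)),
        bounds=(lo_b, hi_b),
        method="bounded",
        options={"xatol": 1e-10 * belief.D},
    )
    best_ds, best_gain = float(ds_grid[k]), float(gains[k])
    if res.success and -res.fun > best_gain:
        best_ds, best_gain = float(res.x), float(-res.fun)
    if best_gain > 0.0:
        return best_ds
    return d_m


def _local_rule_step_grid(
    state: BeliefState,
    params: ForagerParams,
    grid: np.ndarray,
    t_elapsed: float,
) -> Optional[float]:
    """Discrete local rule with Riemann-sum integrals on a fixed grid.

    Works in relative-rate units (energies divided by ``R0``) with per-bin
    patch masses ``w_j = P1(x_j | r) * dx`` so that it is term-for-term the
    computation the feedforward circuit carries out; the circuit test
    demands bitwise-identical argmax decisions.
    """
    belief, r = state.belief, state.r
    horizon = params.T - t_elapsed
    if horizon <= 0 or r >= belief.D:
        return None
    x = grid
    dx = x[1] - x[0] if len(x) > 1 else belief.D
    g = params.rtilde_delta
    w = np.where(x > r, belief.p * np.exp(-belief.p * np.maximum(x - r, 0.0)) * dx, 0.0)
    rr = np.asarray(patch_rate(belief, x)) / params.R0

    u = w * (rr - 1.0)
    v = w * (rr + g)
    cum_u = np.cumsum(u)
    cum_xv = np.cumsum(x * v)
    cum_w = np.cumsum(w)
    gain1 = horizon * cum_u - cum_xv - 2.0 * g * x * cum_u - 2.0 * (1.0 + g) * x * (1.0 - cum_w)

    m = int(np.argmax(gain1))
    if not gain1[m] > 0.0:
        return None
    cum_wr = np.cumsum(w * rr)
    S_m = 1.0 - cum_w[m]
    gain2 = -2.0 * x * (1.0 + g) * (S_m + cum_wr[m] - cum_wr) + 2.0 * g * (x[m] - x) * cum_u
    gain2 = np.where(np.arange(len(x)) < m, gain2, -np.inf)
    if len(x) and np.any(gain2 > 0.0):
        s = int(np.argmax(gain2))
        return float(x[s])
    return float(x[m])


@dataclass(frozen=True)
class EpisodeResult:
    """Outcome of one realised episode."""

    trips: tuple[float, ...]  # empty-handed round trips actually completed
    found: bool
    d_found: Optional[float]
    finding_trip: Optional[float]  # planned endpoint of the trip that found the patch
    find_time: Optional[float]
    final_energy: float
    mean_rate: float


def _decide(
    strategy: StrategyConfig,
    belief: EnvironmentBelief,
    params: ForagerParams,
    r: float,
    t: float,
    cache: dict,
) -> Optional[float]:
    """Next trip distance (or None to stay) for the current state."""
    key = (strategy.mode, strategy.M, round(r, 9), round(t, 6))
    if key in cache:
        return cache[key]
    if params.T - t <= 0 or r >= belief.D:
        decision: Optional[float] = None
    elif strategy.mode == "replan":
        result = best_over_horizon(
            strategy.M, belief, params, r=r, t_elapsed=t, grid_n=strategy.grid_n
        )
        decision = None if result.best_plan.is_empty else result.best_plan.distances[0]
    else:  # local_rule
        decision = local_rule_step(
            BeliefState(r, belief), params, t_elapsed=t, grid_n=strategy.grid_n
        )
    cache[key] = decision
    return decision


def run_episode(
    strategy: StrategyConfig,
    belief: EnvironmentBelief,
    params: ForagerParams,
    true_d: Optional[float] = None,
    cache: Optional[dict] = None,
) -> EpisodeResult:
    """Execute one episode against a fixed nearest-patch location.

    ``true_d`` is the realised nearest-patch distance (``None`` for no
    patch within ``(0, D]``).  Finds happen on the outbound crossing; the
    reserve bookkeeping is exact because every empty-handed round trip nets
    zero energy by construction of the feeding time.
    """
    if cache is None:
        cache = {}
    T = params.T
    aRD = -params.RDelta
    c = params.trip_time_factor

    plan_queue: Optional[list[float]] = None
    if strategy.mode == "plan_once":
        key = ("plan_once_seq", strategy.M)
        if key not in cache:
            result = best_over_horizon(strategy.M, belief, params, grid_n=strategy.grid_n)
            cache[key] = list(result.best_plan.distances)
        plan_queue = list(cache[key])

    t, r = 0.0, 0.0
    trips: list[float] = []
    while True:
        if strategy.mode == "plan_once":
            d = plan_queue.pop(0) if plan_queue else None
        else:
            d = _decide(strategy, belief, params, r, t, cache)
        if d is None:
            final = params.R0 * (T - t)
            return EpisodeResult(tuple(trips), False, None, None, None, final, final / T)
        if not (r < d <= belief.D and t + c * d <= T * (1 + 1e-9)):
            raise RuntimeError(f"strategy proposed an infeasible trip d={d} at (r={r}, t={t})")
        if true_d is not None and r < true_d <= d:
            find_time = t + prep_time(params, d) + true_d / params.v
            final = 2.0 * d * aRD - true_d * aRD + (T - find_time) * patch_rate(belief, true_d)
            return EpisodeResult(tuple(trips), True, true_d, d, find_time, final, final / T)
        trips.append(d)
        t += c * d
        r = d


def no_find_sequence(
    strategy: StrategyConfig,
    belief: EnvironmentBelief,
    params: ForagerParams,
    cache: Optional[dict] = None,
) -> tuple[float, ...]:
    """Deterministic trip sequence a strategy executes when nothing is ever found."""
    return run_episode(strategy, belief, params, true_d=None, cache=cache).trips


def policy_expected_utility(
    strategy: StrategyConfig,
    belief: EnvironmentBelief,
    params: ForagerParams,
    cache: Optional[dict] = None,
) -> float:
    """Exact expected mean rate of a strategy.

    Before the first find every strategy follows its deterministic no-find
    trip sequence, and after a find all strategies behave identically, so
    the policy's expected utility equals the planned-sequence utility of
    that no-find sequence.
    """
    trips = no_find_sequence(strategy, belief, params, cache=cache)
    return plan_expected_utility(TripPlan(trips, origin_r=0.0), belief, params)


@dataclass(frozen=True)
class MonteCarloResult:
    mean: float
    se: float
    n: int
    rates: np.ndarray

    def __iter__(self):  # (mean, se) unpacking convenience
        return iter((self.mean, self.se))


def monte_carlo_utility(
    strategy: StrategyConfig,
    belief: EnvironmentBelief,
    params: ForagerParams,
    n: int,
    seed: int,
) -> MonteCarloResult:
    """Sample-mean utility over environments drawn from the prior.

    The nearest-patch distance is Exp(p); draws beyond ``D`` are the
    no-patch outcome (atom ``e^{-pD}``).  One generator is created per
    call and episode ``i`` consumes draw ``i``, so strategies compared at
    the same seed see common random numbers.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if belief.p > 0:
        draws = rng.exponential(1.0 / belief.p, size=n)
    else:
        draws = np.full(n, np.inf)
    cache: dict = {}
    rates = np.empty(n)
    for i, d in enumerate(draws):
        true_d = float(d) if d <= belief.D else None
        rates[i] = run_episode(strategy, belief, params, true_d=true_d, cache=cache).mean_rate
    mean = float(np.mean(rates))
    se = float(np.std(rates, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return MonteCarloResult(mean=mean, se=se, n=n, rates=rates)
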