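"""Optimal trip-sequence search.

The planner maximises the expected mean utility of ``K`` ordered round
trips ``r < d1 < ... < dK <= D``.  On a uniform grid ``x_j = j * D / n``
the problem has a convenient structure: a trip to ``x_j`` occupies exactly
``2 x_j (1 + |RDelta|/R0)`` time units, so elapsed time is proportional to
the *sum of grid indices* of the chosen endpoints.  The dynamic program
therefore runs over states (trip number, last endpoint index, cumulative
index sum); the cumulative index pins down the trip's start time exactly,
and each transition weight is affine in it.  The best grid plan is then
polished by a bounded continuous optimisation (SLSQP), accepted only when
it stays ordered and feasible and actually improves.

``value_iteration_oracle`` solves the same problem as a finite-horizon
Markov decision process by backward induction over (explored range,
elapsed-time bucket) states.  It exists to cross-check the sequence
optimiser (Bellman optimality), not for production use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .core import EnvironmentBelief, ForagerParams, TripPlan
from .expected_utility import (
    exp_moments,
    find_energy_integral,
    plan_expected_utility,
    plan_value,
    rate_mass,
)

__all__ = [
    "PlanEntry",
    "PlannerResult",
    "OracleResult",
    "optimize_fixed_K",
    "best_over_horizon",
    "value_iteration_oracle",
]

#: plans closer than this in utility are considered tied (fewer trips win)
TIE_TOL = 1e-10


@dataclass(frozen=True)
class PlanEntry:
    """Best plan using at most ``K`` trips, and its expected mean utility."""

    K: int
    plan: TripPlan
    utility: float


@dataclass(frozen=True)
class PlannerResult:
    """Planner output over a horizon of ``M`` trips.

    ``entries[k-1]`` holds the best plan with at most ``k`` trips, so the
    utilities are nondecreasing in ``k`` by construction.  ``kopt`` is the
    number of trips actually used by the overall best plan (ties broken
    toward fewer trips); ``saturated`` flags ``kopt < M``, in which case a
    longer horizon cannot change the solution.
    """

    entries: tuple[PlanEntry, ...]
    M: int
    kopt: int
    saturated: bool
    r: float
    t_elapsed: float

    @property
    def best_plan(self) -> TripPlan:
        return self.entries[-1].plan

    @property
    def best_utility(self) -> float:
        return self.entries[-1].utility

    def utilities(self) -> np.ndarray:
        return np.array([e.utility for e in self.entries])


def _grid_dp(
    belief: EnvironmentBelief,
    params: ForagerParams,
    r: float,
    horizon: float,
    grid_n: int,
    K: int,
):
    """Exact-k optima on the uniform grid, for every k = 1..K.

    Returns a list whose k-1'th element is ``(distances, value)`` for the
    best exact-k grid plan (``None`` if no feasible k-trip plan exists).
    Values are total expected final energies (not yet divided by horizon).
    """
    D = belief.D
    n = grid_n
    delta = D / n
    c = params.trip_time_factor
    x = D * np.arange(n + 1) / n  # x[0] = 0 is the virtual origin; x[n] = D exactly
    j_min = int(math.floor(r / delta)) + 1
    while j_min <= n and x[j_min] <= r:  # guard float edge
        j_min += 1
    B = int(math.floor(horizon / (c * delta) + 1e-12))
    results: list[Optional[tuple[list[float], float]]] = [None] * K
    if j_min > n or B < j_min:
        return results

    S_cap = min(B, K * n)
    p, R0 = belief.p, params.R0
    surv = np.exp(-p * np.maximum(x - r, 0.0))

    # first-trip weights: integrate from the explored range r itself
    phi_first = np.full(n + 1, -np.inf)
    js = np.arange(j_min, n + 1)
    phi_first[js] = find_energy_integral(r, x[js], x[js], 0.0, belief, params, rho=r, horizon=horizon)

    # transition weights phi[j, j'] (start-time-zero part) and the
    # belief-weighted rate mass psi[j, j'] carrying the affine time shift
    jj, jp = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    valid = (jj >= j_min) & (jp > jj)
    phi = np.full((n + 1, n + 1), -np.inf)
    a_v, b_v = x[jj[valid]], x[jp[valid]]
    phi[valid] = find_energy_integral(a_v, b_v, b_v, 0.0, belief, params, rho=r, horizon=horizon)
    psi_cum = np.concatenate(([0.0], np.asarray(rate_mass(r, x[1:], belief, rho=r), dtype=float).ravel()))
    psi = psi_cum[None, :] - psi_cum[:, None]  # psi[j, j'] for j < j'

    cdelta = c * delta
    j_arr = np.arange(n + 1)

    V = np.full((n + 1, S_cap + 1), -np.inf)
    sel1 = js[js <= S_cap]
    V[sel1, sel1] = phi_first[sel1]
    ptrs: list[np.ndarray] = []

    def read_best(k: int) -> Optional[tuple[list[float], float]]:
        term = surv[:, None] * R0 * (horizon - cdelta * np.arange(S_cap + 1)[None, :])
        tot = V + term
        if not np.any(np.isfinite(tot)):
            return None
        flat = np.swapaxes(tot, 0, 1)  # s-major: ties prefer smaller total distance
        s_star, j_star = np.unravel_index(int(np.argmax(flat)), flat.shape)
        value = float(tot[j_star, s_star])
        # backtrack through the pointer stack
        idxs = [int(j_star)]
        s_cur, j_cur = int(s_star), int(j_star)
        for i in range(k - 1, 0, -1):
            j_prev = int(ptrs[i - 1][j_cur, s_cur])
            s_cur -= j_cur
            j_cur = j_prev
            idxs.append(j_cur)
        idxs.reverse()
        return [float(x[j]) for j in idxs], value

    results[0] = read_best(1)
    for k in range(2, K + 1):
        V_new = np.full_like(V, -np.inf)
        ptr = np.zeros((n + 1, S_cap + 1), dtype=np.int32)
        finite_s = np.nonzero(np.isfinite(V).any(axis=0))[0]
        for s in finite_s:
            col = V[:, s]
            scores = col[:, None] + phi - (cdelta * s) * psi
            best = np.max(scores, axis=0)
            arg = np.argmax(scores, axis=0)
            ok = np.isfinite(best) & (j_arr >= 1) & (j_arr + s <= S_cap)
            tgt = j_arr[ok]
            V_new[tgt, s + tgt] = best[ok]
            ptr[tgt, s + tgt] = arg[ok]
        V = V_new
        ptrs.append(ptr)
        if not np.any(np.isfinite(V)):
            break
        results[k - 1] = read_best(k)
    return results


def _refine(
    distances: list[float],
    belief: EnvironmentBelief,
    params: ForagerParams,
    r: float,
    horizon: float,
) -> tuple[list[float], float]:
    """Polish a grid plan by bounded local continuous optimisation.

    Keeps the grid solution when SLSQP fails, leaves the ordered/feasible
    region, or does not improve.  Returns (distances, value/horizon).
    """
    D = belief.D
    c = params.trip_time_factor
    gap = 1e-5 * D
    x0 = np.asarray(distances, dtype=float)
    base = plan_value(x0, belief, params, r, horizon) / horizon

    def neg_obj(d):
        return -plan_value(d, belief, params, r, horizon) / horizon

    def cons_fun(d):
        d = np.asarray(d)
        lower = np.concatenate(([d[0] - (r + gap)], np.diff(d) - gap))
        return np.concatenate((lower, [D - d[-1], horizon - c * float(np.sum(d))]))

    try:
        res = minimize(
            neg_obj,
            x0,
            method="SLSQP",
            constraints=[{"type": "ineq", "fun": cons_fun}],
            options={"maxiter": 200, "ftol": 1e-14},
        )
    except Exception:  # pragma: no cover - scipy failure falls back to grid plan
        return list(x0), base
    d = np.asarray(res.x, dtype=float)
    tol = 1e-9 * D
    ordered = d[0] > r and np.all(np.diff(d) > 0) and d[-1] <= D + tol
    feasible = c * float(np.sum(d)) <= horizon * (1 + 1e-12)
    if not (ordered and feasible):
        return list(x0), base
    d[-1] = min(d[-1], D)
    val = plan_value(d, belief, params, r, horizon) / horizon
    if val > base:
        return list(d), val
    return list(x0), base


def _candidates(
    M: int,
    belief: EnvironmentBelief,
    params: ForagerParams,
    r: float,
    t_elapsed: float,
    grid_n: int,
    refine: bool,
) -> list[Optional[tuple[list[float], float]]]:
    horizon = params.T - t_elapsed
    if horizon <= 0:
        raise ValueError("no time left in the evaluation window")
    belief.require_profitable(params)
    raw = _grid_dp(belief, params, r, horizon, grid_n, M)
    out: list[Optional[tuple[list[float], float]]] = []
    for item in raw:
        if item is None:
            out.append(None)
            continue
        dists, value = item
        if refine:
            dists, util = _refine(dists, belief, params, r, horizon)
        else:
            util = value / horizon
        out.append((dists, util))
    return out


def _select(cands: list[tuple[tuple[float, ...], float]]) -> tuple[tuple[float, ...], float]:
    """Pick the best candidate; ties prefer fewer trips, then shorter total distance."""
    best_u = max(u for _, u in cands)
    tied = [cd for cd in cands if cd[1] >= best_u - TIE_TOL]
    tied.sort(key=lambda cd: (len(cd[0]), sum(cd[0])))
    return tied[0]


def optimize_fixed_K(
    K: int,
    belief: EnvironmentBelief,
    params: ForagerParams,
    r: float = 0.0,
    t_elapsed: float = 0.0,
    grid_n: int = 400,
    refine: bool = True,
) -> tuple[TripPlan, float]:
    """Best plan using at most ``K`` trips (including the empty stay plan).

    Exploring is never forced: whenever every trip sequence does worse than
    harvesting the known patch forever, the empty plan (utility exactly
    ``R0``) is returned.  A k-trip plan can always be emulated by a
    (k+1)-trip plan with a vanishing first trip, so the returned utility is
    nondecreasing in ``K``; ties go to fewer trips and shorter plans.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    cands: list[tuple[tuple[float, ...], float]] = [((), params.R0)]
    for item in _candidates(K, belief, params, r, t_elapsed, grid_n, refine):
        if item is not None:
            cands.append((tuple(item[0]), item[1]))
    dists, util = _select(cands)
    return TripPlan(dists, origin_r=r), float(util)


def best_over_horizon(
    M: int,
    belief: EnvironmentBelief,
    params: ForagerParams,
    r: float = 0.0,
    t_elapsed: float = 0.0,
    grid_n: int = 400,
    refine: bool = True,
) -> PlannerResult:
    """Optimal plans for every horizon ``k <= M`` from one dynamic-programming pass."""
    if M < 1:
        raise ValueError("M must be >= 1")
    exact = _candidates(M, belief, params, r, t_elapsed, grid_n, refine)
    entries = []
    pool: list[tuple[tuple[float, ...], float]] = [((), params.R0)]
    for k in range(1, M + 1):
        item = exact[k - 1]
        if item is not None:
            pool.append((tuple(item[0]), item[1]))
        dists, util = _select(pool)
        entries.append(PlanEntry(K=k, plan=TripPlan(dists, origin_r=r), utility=float(util)))
    kopt = len(entries[-1].plan)
    return PlannerResult(
        entries=tuple(entries),
        M=M,
        kopt=kopt,
        saturated=kopt < M,
        r=r,
        t_elapsed=t_elapsed,
    )


@dataclass(frozen=True)
class OracleResult:
    """Backward-induction solution of the trip MDP on a shared grid."""

    value: float  # expected final energy from the initial state
    mean_rate: float  # value / T
    grid: np.ndarray  # candidate endpoints x_1..x_n
    policy: np.ndarray  # policy[j, s]: 0 = stop, else next endpoint index
    rollout: tuple[float, ...]  # greedy no-find trip sequence from the start


def value_iteration_oracle(
    belief: EnvironmentBelief,
    params: ForagerParams,
    grid_n: int,
) -> OracleResult:
    """Solve the trip problem as an MDP by backward induction (test oracle).

    States are (largest explored grid index j, elapsed-time bucket s); a
    trip to ``x_j'`` advances time by exactly ``j'`` buckets of
    ``2 (1 + |RDelta|/R0) * D / n`` time units, so transitions land on
    buckets with no interpolation.  Values are conditional expected
    remaining energies; the optimal plan-once sequence satisfies these
    Bellman equations, which is what the cross-checks exploit.
    """
    if grid_n > 200:
        raise ValueError("the oracle is for testing: grid_n must be <= 200")
    belief.require_profitable(params)
    D, p = belief.D, belief.p
    T, R0 = params.T, params.R0
    n = grid_n
    delta = D / n
    c = params.trip_time_factor
    cdelta = c * delta
    x = D * np.arange(n + 1) / n
    B = int(math.floor(T / cdelta + 1e-12))

    jj, jp = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    valid = jp > jj
    F0 = np.full((n + 1, n + 1), -np.inf)
    a_v, b_v = x[jj[valid]], x[jp[valid]]
    # conditional find integral: density renormalised at the explored range x_j
    F0[valid] = find_energy_integral(a_v, b_v, b_v, 0.0, belief, params, rho=a_v, horizon=T)
    psi_c = np.zeros((n + 1, n + 1))
    psi_c[valid] = rate_mass(a_v, b_v, belief, rho=a_v)
    surv_c = np.where(valid, np.exp(-p * np.maximum(x[None, :] - x[:, None], 0.0)), 0.0)

    V = np.full((n + 1, B + 1), -np.inf)
    policy = np.zeros((n + 1, B + 1), dtype=np.int32)
    j_arr = np.arange(n + 1)
    for s in range(B, -1, -1):
        stay = R0 * (T - cdelta * s)
        v_next = np.full(n + 1, -np.inf)
        reach = j_arr[(j_arr >= 1) & (j_arr + s <= B)]
        if reach.size:
            v_next[reach] = V[reach, s + reach]
        with np.errstate(invalid="ignore"):
            cand = F0 - (cdelta * s) * psi_c + surv_c * v_next[None, :]
        cand[:, v_next == -np.inf] = -np.inf
        best = np.max(cand, axis=1)
        arg = np.argmax(cand, axis=1)
        take = best > stay  # ties prefer stopping (fewer trips)
        V[:, s] = np.where(take, best, stay)
        policy[:, s] = np.where(take, arg, 0)

    rollout = []
    j, s = 0, 0
    while policy[j, s] > 0:
        jn = int(policy[j, s])
        rollout.append(float(x[jn]))
        s += jn
        j = jn
    value = float(V[0, 0])
    return OracleResult(
        value=value,
        mean_rate=value / T,
        grid=x[1:].copy(),
        policy=policy,
        rollout=tuple(rollout),
    )
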