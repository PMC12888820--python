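"""Closed-form expected utility of planned trip sequences.

All expectations are taken over the location of the nearest undiscovered
patch, which is Exp(p)-distributed beyond the explored range, truncated at
the environment edge ``D`` (the remaining mass is the "no patch" outcome).
Because the patch-rate profile ``R(x) = mu (1 - gamma x)`` is linear, every
integrand is a quadratic times an exponential and integrates in closed
form; the symbolic forms implemented here are the reference, with adaptive
quadrature used as a cross-check in the test-suite.

Utilities are mean energy rates over the (remaining) evaluation window:
the energy expressions are divided by the horizon, so the stay-forever
baseline is exactly ``R0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import EnvironmentBelief, ForagerParams, TripPlan, prep_time, survival

__all__ = [
    "UtilityBreakdown",
    "plan_expected_utility",
    "scenario_decomposition",
    "relative_advantage",
]


def exp_moments(a, b, p: float, rho: float):
    """Moments ``J_k = int_a^b x^k p e^{-p (x - rho)} dx`` for k = 0, 1, 2.

    Vectorised over ``a`` and ``b``; the density origin ``rho`` shifts the
    exponential (conditioning on no patch up to ``rho``).  For ``p == 0``
    all moments vanish (no patches anywhere).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if p == 0.0:
        z = np.zeros(np.broadcast(a, b).shape)
        return z, z.copy(), z.copy()
    ea = np.exp(-p * (a - rho))
    eb = np.exp(-p * (b - rho))
    ip = 1.0 / p
    j0 = ea - eb
    j1 = (a + ip) * ea - (b + ip) * eb
    j2 = (a * a + 2.0 * a * ip + 2.0 * ip * ip) * ea - (b * b + 2.0 * b * ip + 2.0 * ip * ip) * eb
    return j0, j1, j2


def find_energy_integral(a, b, d_trip, t0, belief: EnvironmentBelief, params: ForagerParams, rho: float, horizon: float):
    """Expected final energy contributed by a find on one trip.

    Integrates ``P1(x | rho) * E(x)`` over the newly covered interval
    ``(a, b]`` of a trip to ``d_trip`` whose feeding starts at time ``t0``:
    ``E(x) = 2 d |RDelta| - x |RDelta| + (horizon - t0 - Omega(d) - x) R(x)``
    is the realised final energy when the patch sits at ``x`` (stocked
    reserve, minus outbound travel, plus harvest for the remaining time).
    Vectorised over ``a``, ``b``, ``d_trip`` and ``t0``.
    """
    aRD = -params.RDelta
    mu, gamma = belief.mu, belief.gamma
    tau = horizon - np.asarray(t0, dtype=float) - 2.0 * np.asarray(d_trip, dtype=float) * params.rtilde_delta
    q0 = 2.0 * np.asarray(d_trip, dtype=float) * aRD + tau * mu
    q1 = -aRD - mu * (tau * gamma + 1.0)
    q2 = mu * gamma
    j0, j1, j2 = exp_moments(a, b, belief.p, rho)
    return q0 * j0 + q1 * j1 + q2 * j2


def rate_mass(a, b, belief: EnvironmentBelief, rho: float):
    """``int_a^b P1(x | rho) R(x) dx`` — the belief-weighted patch rate."""
    j0, j1, _ = exp_moments(a, b, belief.p, rho)
    return belief.mu * j0 - belief.mu * belief.gamma * j1


def plan_value(distances, belief: EnvironmentBelief, params: ForagerParams, r: float, horizon: float) -> float:
    """Raw expected final energy of a trip sequence, without validation.

    Used by the planner's continuous refinement, which may probe slightly
    infeasible points; the closed forms remain smooth there.
    """
    R0 = params.R0
    c = params.trip_time_factor
    total = 0.0
    t0 = 0.0
    prev = r
    for d in distances:
        total += float(find_energy_integral(prev, d, d, t0, belief, params, rho=r, horizon=horizon))
        t0 += c * d
        prev = d
    tail = math.exp(-belief.p * max(prev - r, 0.0)) * R0 * (horizon - t0)
    return total + tail


def plan_expected_utility(
    plan: TripPlan,
    belief: EnvironmentBelief,
    params: ForagerParams,
    t_elapsed: float = 0.0,
) -> float:
    """Expected mean energy rate of executing ``plan`` over the remaining window.

    Averages the realised final energy over all nearest-patch locations
    (including the no-patch outcome) and divides by the remaining horizon
    ``T - t_elapsed``.  The empty plan returns exactly ``R0``.  Plans whose
    schedule cannot complete within the window are rejected.
    """
    belief.require_profitable(params)
    horizon = params.T - t_elapsed
    if horizon <= 0:
        raise ValueError(f"no time left: t_elapsed={t_elapsed} >= T={params.T}")
    if plan.is_empty:
        return params.R0
    if plan.distances[-1] > belief.D:
        raise ValueError(f"plan reaches {plan.distances[-1]} beyond D={belief.D}")
    if params.trip_time_factor * plan.total_distance() > horizon * (1.0 + 1e-9):
        raise ValueError(
            f"infeasible plan: schedule needs "
            f"{params.trip_time_factor * plan.total_distance():.6g} time units "
            f"but only {horizon:.6g} remain"
        )
    return plan_value(plan.distances, belief, params, plan.origin_r, horizon) / horizon


@dataclass(frozen=True)
class UtilityBreakdown:
    """Three-scenario decomposition of the gain from a preliminary short trip.

    ``total = s1 + s2 + s3`` is the change in expected mean utility from
    exploring ``(r, dL]`` in two trips ``{dS, dL}`` instead of one ``{dL}``:

    * ``s1`` (<= 0): extra travel wasted when no patch exists within ``dL``;
    * ``s2``: extra travel and feeding delay when the patch lies beyond the
      short trip (``dS < x <= dL``) — a loss whenever ``R(x) >= R0``;
    * ``s3`` (>= 0): earlier discovery when the patch lies within ``dS``.
    """

    s1: float
    s2: float
    s3: float

    @property
    def total(self) -> float:
        return self.s1 + self.s2 + self.s3


def scenario_decomposition(
    dS: float,
    dL: float,
    belief: EnvironmentBelief,
    params: ForagerParams,
    r: float = 0.0,
    t_elapsed: float = 0.0,
) -> UtilityBreakdown:
    """Expected gain of a short trip ``dS`` before a long trip ``dL``.

    Conditioned on the explored range ``r`` (the printed two-trip case is
    ``r = 0``); all terms are mean rates over the remaining window.
    """
    if not (r < dS < dL <= belief.D):
        raise ValueError(f"need r < dS < dL <= D, got r={r}, dS={dS}, dL={dL}, D={belief.D}")
    horizon = params.T - t_elapsed
    if horizon <= 0:
        raise ValueError("no time left in the evaluation window")
    R0, RD = params.R0, params.RDelta
    rt = params.rtilde_delta

    s1 = -survival(belief, r, dL) * 2.0 * dS * (R0 - RD) / horizon

    j0_far, _, _ = exp_moments(dS, dL, belief.p, r)
    rmass_far = float(rate_mass(dS, dL, belief, r))
    # integrand: 2 dS (R(x) - RDelta) + 2 (|RDelta|/R0) dS (R(x) - R0)
    s2 = -(2.0 * dS * (rmass_far - RD * float(j0_far)) + 2.0 * rt * dS * (rmass_far - R0 * float(j0_far))) / horizon

    j0_near, _, _ = exp_moments(r, dS, belief.p, r)
    rmass_near = float(rate_mass(r, dS, belief, r))
    s3 = 2.0 * rt * (dL - dS) * (rmass_near - R0 * float(j0_near)) / horizon

    return UtilityBreakdown(s1=float(s1), s2=float(s2), s3=float(s3))


def two_trip_gain(dS, dL: float, belief: EnvironmentBelief, params: ForagerParams, r: float = 0.0, t_elapsed: float = 0.0):
    """Vectorised ``scenario_decomposition(...).total`` over an array of ``dS``."""
    dS = np.asarray(dS, dtype=float)
    horizon = params.T - t_elapsed
    R0, RD = params.R0, params.RDelta
    rt = params.rtilde_delta
    p = belief.p

    s1 = -math.exp(-p * max(dL - r, 0.0)) * 2.0 * dS * (R0 - RD)
    j0_far, _, _ = exp_moments(dS, dL, p, r)
    rmass_far = rate_mass(dS, dL, belief, r)
    s2 = -(2.0 * dS * (rmass_far - RD * j0_far) + 2.0 * rt * dS * (rmass_far - R0 * j0_far))
    j0_near, _, _ = exp_moments(r, dS, p, r)
    rmass_near = rate_mass(r, dS, belief, r)
    s3 = 2.0 * rt * (dL - dS) * (rmass_near - R0 * j0_near)
    return (s1 + s2 + s3) / horizon


def relative_advantage(
    plan_K: TripPlan,
    plan_1: TripPlan,
    belief: EnvironmentBelief,
    params: ForagerParams,
) -> float:
    """Relative utility advantage of a multi-trip plan over a single-trip plan.

    ``(U_K - U_1) / U_1`` with both utilities the expected mean rates of the
    respective plans.  Raises on a zero denominator.
    """
    uK = plan_expected_utility(plan_K, belief, params)
    u1 = plan_expected_utility(plan_1, belief, params)
    if u1 == 0.0:
        raise ZeroDivisionError("single-trip reference utility is zero")
    return (uK - u1) / u1
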