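"""Elementary model objects for an energetically constrained central-place forager.

The model: a forager sits on a known food patch at the origin of a 1D
environment of size ``D``.  It harvests energy at rate ``R0 > 0`` on the
patch and burns energy at rate ``RDelta < 0`` while travelling at unit
speed.  It believes undiscovered patches are laid down uniformly with
density ``p`` per unit distance, so the nearest one is exponentially
distributed, and that a patch found at distance ``d`` would yield energy at
rate ``R(d) = mu * (1 - gamma * d)``.

Exploration is organised in round trips: before an outbound trip to ``d``
the forager feeds for exactly ``Omega(d) = 2 d |RDelta| / R0``, the time
needed to stock the energy for the full out-and-back journey, so that the
reserve never goes negative and returns to zero on every empty-handed
return.  These primitives (densities, rates, feeding times, trip schedules
and the piecewise-linear energy ledger) are what every higher-level module
builds on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ForagerParams",
    "EnvironmentBelief",
    "TripPlan",
    "Schedule",
    "EnergyLedger",
    "nearest_patch_pdf",
    "survival",
    "patch_rate",
    "prep_time",
    "build_schedule",
    "energy_trace",
]


@dataclass(frozen=True)
class ForagerParams:
    """Energetic rates and evaluation horizon of the forager.

    Parameters
    ----------
    R0
        Harvest rate on the known patch (energy/time, > 0).
    RDelta
        Energy rate while travelling (energy/time, < 0).
    T
        Evaluation horizon (time, > 0).  Utilities are mean energy rates
        over ``[0, T]``.
    v
        Travel speed; the model is formulated at ``v = 1`` which
        identifies time and distance units.
    """

    R0: float
    RDelta: float
    T: float
    v: float = 1.0

    def __post_init__(self) -> None:
        if not self.R0 > 0:
            raise ValueError(f"R0 must be > 0, got {self.R0}")
        if not self.RDelta < 0:
            raise ValueError(f"RDelta must be < 0, got {self.RDelta}")
        if not self.T > 0:
            raise ValueError(f"T must be > 0, got {self.T}")
        if self.v != 1.0:
            raise ValueError("the model is formulated at fixed travel speed v = 1")

    @property
    def rtilde_delta(self) -> float:
        """Relative travel cost |RDelta| / R0 (dimensionless, > 0)."""
        return -self.RDelta / self.R0

    @property
    def trip_time_factor(self) -> float:
        """Total time per unit trip distance: feeding + out + back.

        A trip to ``d`` occupies ``Omega(d) + 2 d = 2 d (1 + |RDelta|/R0)``.
        """
        return 2.0 * (1.0 + self.rtilde_delta)

    def with_horizon(self, T: float) -> "ForagerParams":
        return ForagerParams(self.R0, self.RDelta, T, self.v)


@dataclass(frozen=True)
class EnvironmentBelief:
    """Prior belief about patch density and quality.

    ``p`` is the patch density per unit distance (the nearest undiscovered
    patch is then Exp(p)-distributed), ``mu`` the harvest rate of a patch
    found at the origin and ``gamma`` the linear decay of patch quality
    with distance: ``R(d) = mu (1 - gamma d)``.  ``D`` is the environment
    size; no patch beyond ``D`` is considered.
    """

    p: float
    gamma: float
    mu: float
    D: float

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError(f"patch density p must be >= 0, got {self.p}")
        if self.gamma < 0:
            raise ValueError(f"quality decay gamma must be >= 0, got {self.gamma}")
        if not self.mu > 0:
            raise ValueError(f"patch rate mu must be > 0, got {self.mu}")
        if not self.D > 0:
            raise ValueError(f"environment size D must be > 0, got {self.D}")
        if self.gamma * self.D > 1.0:
            warnings.warn(
                f"gamma * D = {self.gamma * self.D:.4g} > 1: the patch rate "
                "R(d) is negative in part of the environment",
                UserWarning,
                stacklevel=2,
            )

    def require_profitable(self, params: ForagerParams) -> None:
        """Exploration only makes sense when mu exceeds the home rate R0."""
        if not self.mu > params.R0:
            raise ValueError(
                f"mu = {self.mu} must exceed R0 = {params.R0}: otherwise no "
                "patch can beat the known one and exploration is pointless"
            )


def nearest_patch_pdf(belief: EnvironmentBelief, r: float, d) -> np.ndarray | float:
    """Density of the nearest undiscovered patch given explored range ``r``.

    The uniform-density prior makes the nearest-patch distance exponential;
    after exploring out to ``r`` without a find, the memoryless conditional
    density is ``p * exp(-p (d - r))`` on ``(r, D]`` and zero elsewhere.
    Accepts scalar or array ``d``.
    """
    _check_range(belief, r)
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distance d must be >= 0")
    out = np.where(
        (d_arr >= r) & (d_arr <= belief.D),
        belief.p * np.exp(-belief.p * np.maximum(d_arr - r, 0.0)),
        0.0,
    )
    return out if out.ndim else float(out)


def survival(belief: EnvironmentBelief, r: float, d: float) -> float:
    """Probability of no patch in ``(r, d]`` given explored range ``r``."""
    _check_range(belief, r)
    if d < 0:
        raise ValueError("distance d must be >= 0")
    return math.exp(-belief.p * max(d - r, 0.0))


def patch_rate(belief: EnvironmentBelief, d) -> np.ndarray | float:
    """Harvest rate ``R(d) = mu (1 - gamma d)`` of a patch at distance ``d``.

    Deliberately not clipped at zero; configurations with ``gamma * D > 1``
    emit a warning at construction instead (see EnvironmentBelief).
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0) or np.any(d_arr > belief.D):
        raise ValueError(f"distance d must lie in [0, D={belief.D}]")
    out = belief.mu * (1.0 - belief.gamma * d_arr)
    return out if out.ndim else float(out)


def prep_time(params: ForagerParams, d) -> np.ndarray | float:
    """Feeding time ``Omega(d) = 2 d |RDelta| / R0`` that funds a round trip to ``d``.

    Harvesting for exactly this long yields ``Omega(d) R0 = 2 d |RDelta|``,
    the energy consumed by the out-and-back journey.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distance d must be >= 0")
    out = 2.0 * d_arr * params.rtilde_delta
    return out if out.ndim else float(out)


def _check_range(belief: EnvironmentBelief, r: float) -> None:
    if r < 0 or r > belief.D:
        raise ValueError(f"explored range r must lie in [0, D={belief.D}], got {r}")


@dataclass(frozen=True)
class TripPlan:
    """An ordered sequence of planned round-trip endpoints.

    ``distances`` must be strictly increasing and all strictly beyond the
    explored range ``origin_r`` at planning time.  The empty plan means
    "stay on the known patch forever".
    """

    distances: tuple[float, ...]
    origin_r: float = 0.0

    def __init__(self, distances: Sequence[float] = (), origin_r: float = 0.0):
        object.__setattr__(self, "distances", tuple(float(d) for d in distances))
        object.__setattr__(self, "origin_r", float(origin_r))
        prev = self.origin_r
        for d in self.distances:
            if not d > prev:
                raise ValueError(
                    f"trip distances must be strictly increasing and exceed "
                    f"origin_r={self.origin_r}: got {self.distances}"
                )
            prev = d

    def __len__(self) -> int:
        return len(self.distances)

    @property
    def is_empty(self) -> bool:
        return not self.distances

    def total_distance(self) -> float:
        return float(sum(self.distances))


@dataclass(frozen=True)
class Schedule:
    """Event times of a trip plan: feed start, departure and return per trip.

    ``leave_time[i] = feed_start[i] + Omega(d_i)``,
    ``return_time[i] = leave_time[i] + 2 d_i / v`` and trips chain
    back-to-back starting from ``feed_start[0] = 0``.
    """

    feed_start: np.ndarray
    leave_time: np.ndarray
    return_time: np.ndarray
    overflows: np.ndarray  # bool per trip: return_time > horizon

    def __len__(self) -> int:
        return len(self.feed_start)

    @property
    def fits(self) -> bool:
        return not bool(np.any(self.overflows))


def build_schedule(plan: TripPlan, params: ForagerParams, horizon: Optional[float] = None) -> Schedule:
    """Chain feeding and travel times of a plan into absolute event times.

    Trips whose return exceeds the horizon (``params.T`` by default) are
    flagged in ``Schedule.overflows``; downstream utility integration
    truncates at the horizon, and the planner never emits such plans.
    """
    if horizon is None:
        horizon = params.T
    d = np.asarray(plan.distances, dtype=float)
    omega = 2.0 * d * params.rtilde_delta
    travel = 2.0 * d / params.v
    durations = omega + travel
    feed_start = np.concatenate(([0.0], np.cumsum(durations)[:-1])) if len(d) else np.array([])
    leave = feed_start + omega
    ret = leave + travel
    return Schedule(feed_start, leave, ret, ret > horizon)


@dataclass(frozen=True)
class EnergyLedger:
    """Piecewise-linear energy-reserve trajectory over ``[0, T]``.

    ``times``/``reserves`` are the breakpoints (the reserve is linear in
    between), so minima and the values at event times are exact.
    """

    times: np.ndarray
    reserves: np.ndarray
    final_energy: float
    found: bool
    find_time: Optional[float]
    return_reserves: np.ndarray  # reserve at each completed empty-handed return

    def reserve_at(self, t) -> np.ndarray | float:
        out = np.interp(t, self.times, self.reserves)
        return out if np.ndim(t) else float(out)

    def min_reserve(self) -> float:
        return float(np.min(self.reserves))


def energy_trace(
    plan: TripPlan,
    params: ForagerParams,
    belief: EnvironmentBelief,
    found_at: Optional[float] = None,
) -> EnergyLedger:
    """Realised energy ledger of executing ``plan`` in one environment draw.

    ``found_at`` is the location of the nearest patch if the plan covers it
    (``found_at`` in ``(origin_r, d_K]``), else ``None``.  The forager feeds
    at ``R0``, travels at ``RDelta``, and on the outbound crossing of
    ``found_at`` switches permanently to harvesting at ``R(found_at)`` for
    the remainder of the horizon.  Events beyond ``T`` are truncated.
    """
    T = params.T
    R0, RD = params.R0, params.RDelta

    if found_at is not None:
        if not (plan.distances and plan.origin_r < found_at <= plan.distances[-1]):
            raise ValueError(
                f"found_at={found_at} is outside the plan's coverage "
                f"({plan.origin_r}, {plan.distances[-1] if plan.distances else plan.origin_r}]"
            )

    times = [0.0]
    reserves = [0.0]
    return_reserves = []
    t, e = 0.0, 0.0
    found = False
    find_time: Optional[float] = None

    def push(t_new: float, rate: float) -> bool:
        """Advance to t_new at the given rate; truncate at T.  Returns False if truncated."""
        nonlocal t, e
        if t >= T:
            return False
        t_clip = min(t_new, T)
        e = e + rate * (t_clip - t)
        t = t_clip
        times.append(t)
        reserves.append(e)
        return t_new <= T

    for i, d in enumerate(plan.distances):
        omega = prep_time(params, d)
        prev_cov = plan.distances[i - 1] if i else plan.origin_r
        if not push(t + omega, R0):
            break
        if found_at is not None and prev_cov < found_at <= d:
            # outbound leg only: detection at the first crossing of found_at
            if not push(t + found_at / params.v, RD):
                break
            found = True
            find_time = t
            push(T, patch_rate(belief, found_at))
            break
        if not push(t + 2.0 * d / params.v, RD):
            break
        return_reserves.append(e)
    else:
        push(T, R0)

    return EnergyLedger(
        times=np.asarray(times),
        reserves=np.asarray(reserves),
        final_energy=float(e),
        found=found,
        find_time=find_time,
        return_reserves=np.asarray(return_reserves, dtype=float),
    )
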