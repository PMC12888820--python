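"""A feedforward winner-take-all circuit implementing the local decision rule.

Five layers of distance-ordered nodes over a common grid ``x_1 < ... < x_n``:

1. **inputs** — two weight vectors: per-bin nearest-patch masses
   ``w_P[j] = P1(x_j | r) * dx`` (updated as the forager explores) and the
   relative patch-rate profile ``w_R[j] = R(x_j) / R0`` (slow environment
   statistics);
2. **local benefits** — the per-bin gain of a patch at ``x_j`` relative to
   staying, ``w_P (w_R - 1)``, and relative to travelling,
   ``w_P (w_R + Rtilde_Delta)``;
3. **single-trip value** — lower-triangular (cumulative) combinations of
   layers 1-2 give, at node ``m``, the expected gain of a single trip to
   ``x_m`` over staying put; rectification and winner-take-all extract the
   best single trip if any is profitable;
4. **shorter-trip value** — gated multiplicatively by layer 3's winner,
   node ``s`` carries the three-scenario gain of inserting a shorter first
   trip to ``x_s``; rectify + winner-take-all again;
5. **output** — the layer-4 winner if present, else the layer-3 winner,
   else nothing (stay); a binary on-patch signal gates the whole output.

All integrals become cumulative sums with fixed lower-triangular weights,
so beliefs enter only through layer-1 activity; the global neuromodulatory
gain ``Rtilde_Delta = |RDelta| / R0`` scales every travel-cost weight,
letting one architecture serve different energetic regimes.  Activities
are in units of ``R0 * time`` (energies divided by ``R0``): decisions
depend only on signs and argmaxes, so any common positive rescaling leaves
the output unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .core import ForagerParams, nearest_patch_pdf, patch_rate
from .forager import BeliefState

__all__ = ["CircuitSpec", "CircuitState", "make_grid", "build_circuit", "forward",
           "update_patch_weights", "dump_circuit", "load_circuit"]


def make_grid(D: float, n: int) -> np.ndarray:
    """Midpoints of ``n`` equal bins over ``(0, D]`` (per-bin width ``D/n``)."""
    if n < 2:
        raise ValueError("need at least 2 grid nodes")
    dx = D / n
    return (np.arange(n) + 0.5) * dx


@dataclass(frozen=True)
class CircuitSpec:
    """Distance grid, input weights and modulatory gain of the circuit.

    The inter-layer operators are structural (lower-triangular cumulative
    sums, local terms and gating) and are reconstructed from the grid, so
    only the grid, the two input-weight vectors, the gain and the horizon
    need to be stored.
    """

    grid: np.ndarray
    w_P: np.ndarray
    w_R: np.ndarray
    gain: float  # Rtilde_Delta = |RDelta| / R0, modulates travel-cost weights
    horizon: float  # evaluation window T, a fixed weight of layer 3

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.w_P) == len(self.w_R)):
            raise ValueError("grid, w_P and w_R must have equal lengths")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.w_P < 0):
            raise ValueError("patch-mass weights w_P must be nonnegative")
        if self.gain <= 0 or self.horizon <= 0:
            raise ValueError("gain and horizon must be positive")


@dataclass(frozen=True)
class CircuitState:
    """Layer activities of one forward pass and the resulting decision."""

    a1_patch: np.ndarray
    a1_rate: np.ndarray
    a2_stay: np.ndarray
    a2_travel: np.ndarray
    a3: np.ndarray
    a3_rect: np.ndarray
    winner3: np.ndarray  # one-hot (or all-zero) best single trip
    a4: np.ndarray
    a4_rect: np.ndarray
    winner4: np.ndarray  # one-hot (or all-zero) best shorter trip
    a5: np.ndarray  # one-hot selected trip; all-zero = stay
    decision_index: Optional[int]
    decision: Optional[float]


def build_circuit(state: BeliefState, params: ForagerParams, n: int) -> CircuitSpec:
    """Wire the circuit for the current belief state.

    ``w_P`` carries the conditional nearest-patch masses given the explored
    range (zero below ``r``), ``w_R`` the relative rate profile, and the
    gain the relative travel cost.
    """
    belief = state.belief
    grid = make_grid(belief.D, n)
    w_P = _patch_masses(belief, state.r, grid)
    w_R = np.asarray(patch_rate(belief, grid), dtype=float) / params.R0
    return CircuitSpec(grid=grid, w_P=w_P, w_R=w_R, gain=params.rtilde_delta, horizon=params.T)


def _patch_masses(belief, r: float, grid: np.ndarray) -> np.ndarray:
    """Per-bin nearest-patch masses; bins at or inside the explored range are zero."""
    dx = grid[1] - grid[0] if len(grid) > 1 else belief.D
    pdf = np.asarray(nearest_patch_pdf(belief, r, grid), dtype=float)
    return np.where(grid > r, pdf * dx, 0.0)


def update_patch_weights(spec: CircuitSpec, state: BeliefState) -> CircuitSpec:
    """Refresh ``w_P`` after exploration: zero the explored bins, renormalise the rest."""
    w_P = _patch_masses(state.belief, state.r, spec.grid)
    return CircuitSpec(grid=spec.grid, w_P=w_P, w_R=spec.w_R, gain=spec.gain, horizon=spec.horizon)


def _wta(a: np.ndarray) -> np.ndarray:
    """Winner-take-all: one-hot at the first maximum if positive, else all-zero."""
    out = np.zeros_like(a)
    if a.size and np.any(a > 0.0):
        out[int(np.argmax(a))] = 1.0
    return out


def forward(spec: CircuitSpec, on_patch: bool = True) -> CircuitState:
    """One forward pass: affine/cumulative combinations, products, rectify, WTA."""
    x = spec.grid
    n = len(x)
    w = spec.w_P
    rr = spec.w_R
    g = spec.gain
    T = spec.horizon

    L = np.tril(np.ones((n, n)))  # fixed cumulative (running-sum) operator
    Ls = np.tril(np.ones((n, n)), k=-1)  # strictly-below-the-winner gate

    # layer 2: per-bin benefit of a patch at x_j vs staying / vs travelling
    a2_stay = w * (rr - 1.0)
    a2_travel = w * (rr + g)

    # layer 3: expected gain of a single trip to x_m over staying
    cum_stay = L @ a2_stay
    cum_xtravel = L @ (x * a2_travel)
    cum_mass = L @ w
    a3 = T * cum_stay - cum_xtravel - 2.0 * g * x * cum_stay - 2.0 * (1.0 + g) * x * (1.0 - cum_mass)
    a3_rect = np.maximum(a3, 0.0)
    winner3 = _wta(a3_rect)
    active3 = float(winner3.sum())

    # layer 4: gain of a shorter first trip given the layer-3 winner.
    # Scalars about the winner are read out multiplicatively (one-hot dots).
    cum_wr = L @ (w * rr)
    x_m = float(winner3 @ x)
    tail_mass = float(winner3 @ (1.0 - cum_mass)) + float(winner3 @ cum_wr) - cum_wr
    a4 = active3 * (-2.0 * x * (1.0 + g) * tail_mass + 2.0 * g * (x_m - x) * cum_stay)
    below = Ls.T @ winner3  # 1 for nodes strictly below the winner
    a4 = a4 * below
    a4_rect = np.maximum(a4, 0.0)
    winner4 = _wta(a4_rect)

    # layer 5: shorter trip if one is profitable, else the single trip, else stay
    a5 = winner4 if winner4.any() else winner3
    if not on_patch:
        a5 = np.zeros_like(a5)
    idx = int(np.argmax(a5)) if a5.any() else None
    return CircuitState(
        a1_patch=w.copy(),
        a1_rate=rr.copy(),
        a2_stay=a2_stay,
        a2_travel=a2_travel,
        a3=a3,
        a3_rect=a3_rect,
        winner3=winner3,
        a4=a4,
        a4_rect=a4_rect,
        winner4=winner4,
        a5=a5,
        decision_index=idx,
        decision=float(x[idx]) if idx is not None else None,
    )


def dump_circuit(spec: CircuitSpec, path: Union[str, Path, None] = None) -> str:
    """Serialise a circuit to a plain JSON document (and optionally a file)."""
    doc = {
        "grid": spec.grid.tolist(),
        "w_P": spec.w_P.tolist(),
        "w_R": spec.w_R.tolist(),
        "gain": spec.gain,
        "horizon": spec.horizon,
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_circuit(source: Union[str, Path]) -> CircuitSpec:
    """Rebuild a circuit from :func:`dump_circuit` output (a path or a JSON string)."""
    text = source
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    doc = json.loads(text)
    return CircuitSpec(
        grid=np.asarray(doc["grid"], dtype=float),
        w_P=np.asarray(doc["w_P"], dtype=float),
        w_R=np.asarray(doc["w_R"], dtype=float),
        gain=float(doc["gain"]),
        horizon=float(doc["horizon"]),
    )
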