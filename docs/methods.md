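# Methods

## Model

A forager sits on a known food patch at the origin of a 1D environment of
size `D`, harvesting at rate `R0 > 0`. Travelling costs energy at rate
`RDelta < 0` at unit speed `v = 1` (which identifies time and distance
units; every "time" below is a distance unless a rate is involved). The
energy reserve is hard-constrained nonnegative. The prior over
undiscovered patches is a uniform density `p` per unit distance, so the
nearest patch distance is Exp(p) truncated at `D` with an atom
`e^{-pD}` for "no patch"; a patch at distance `d` yields
`R(d) = mu (1 - gamma d)` with `mu > R0` (exploration must have a
potential upside) and `gamma >= 0` (quality never improves with
distance). `R(d)` is deliberately *not* clipped at zero: configurations
with `gamma * D > 1` trigger a construction-time warning instead, because
clipping would silently change the closed forms and an optimal planner
never targets the negative-rate region anyway.

A planned trajectory is a strictly increasing sequence of round-trip
endpoints `r < d1 < ... < dK <= D` beyond the explored range `r`. The
forager arrives with zero reserve at `t = 0`, so each trip to `d` is
preceded by feeding for exactly `Omega(d) = 2 d |RDelta| / R0`; the
reserve then hits zero exactly on every empty-handed return, and there is
never leftover reserve to carry between trips. A find happens on the
outbound crossing of the patch location (in 1D the inbound leg covers no
new ground), after which the forager harvests `R(d_found)` for the
remainder of the window — literally, even if that rate were below `R0`
(the model has no within-trip abandonment).

Utility is the mean energy rate over the evaluation window `T`
(equivalently the final reserve at `T`), averaged over nearest-patch
locations. The empty plan therefore scores exactly `R0`. Plans whose
schedule cannot complete within the remaining window are rejected by the
evaluator and never produced by the planner; the realised-episode ledger
(`energy_trace`) instead truncates at `T`, so post-horizon events
contribute nothing.

## Closed forms

With `R(x)` linear, every expectation is a (quadratic polynomial) ×
(exponential) integral with antiderivatives in the moments
`J_k = ∫ x^k p e^{-p(x-rho)} dx`, `k = 0, 1, 2`. These symbolic forms are
the implementation; adaptive quadrature (and an independent
ledger-averaging oracle) appears only in the test-suite as a cross-check.
The three-scenario decomposition of the gain from a preliminary short trip
(no patch within `d_L` / patch beyond `d_S` / patch within `d_S`) is
implemented in its printed form; the identity
`U({dS,dL}) - U({dL}) = s1 + s2 + s3` then holds to rounding error and is
asserted at 1e-9 relative over random parameter draws. Conditioning on an
explored range `r` substitutes the renormalised density
`p e^{-p(d-r)}` and survival `e^{-p(d-r)}`; at `r = 0` the printed
expressions are recovered exactly.

## Planner numerics

On the uniform grid `x_j = j D / n` (default `n = 400`), a trip to `x_j`
occupies exactly `2 x_j (1 + |RDelta|/R0)` time units, so elapsed time is
proportional to the *sum of chosen grid indices*. The exact-K optimum is
found by dynamic programming over states (trip number, last endpoint
index, cumulative index sum); each transition weight is affine in the
start time, with the affine coefficient a prefix-sum difference, so one
DP pass of `K` layers yields the exact-k grid optimum for every `k <= K`.
The time-feasibility constraint (last return within the window) caps the
cumulative index at `floor(T_remaining / (c * D / n))`.

The best grid plan per `k` is then polished by SLSQP over the ordered
simplex (minimum inter-trip gap `1e-5 * D`, endpoints in `(r, D]`, total
trip time within the window); the refined plan is accepted only if it
stays ordered and feasible and strictly improves. Because a k-trip plan
can be emulated by a (k+1)-trip plan with a vanishing first trip, the
reported utility of "best plan with at most K trips" is nondecreasing in
K; `optimize_fixed_K` exposes exactly that at-most-K semantics, always
including the empty stay-forever plan. Ties within `1e-10` utility prefer
fewer trips, then shorter total distance — a minimal-effort canonical
solution that also pins down `K_opt` as the smallest maximising trip
count. `K_opt < M` implies the solution is saturated: growing the horizon
cannot change it.

`value_iteration_oracle` solves the identical problem as a finite-horizon
MDP by backward induction over (explored-range index, elapsed-time
bucket); the bucket width `2 (1 + |RDelta|/R0]) D / n` makes every
transition land on a bucket exactly, avoiding interpolation error. It is
capped at `grid_n <= 200` and exists to certify the sequence optimiser
(equality with forward enumeration, Bellman consistency), not for
production planning. On utility plateaus the greedy rollout and the
sequence optimiser may legitimately return different-length sequences of
equal value (ties broken toward stopping vs toward fewer trips); the
tests compare values there and sequences only where the optimum is
unique.

## Strategies

Re-planning re-runs the horizon-M planner from the current explored range
with the remaining time; because the exponential prior is memoryless the
explored range is a sufficient statistic. "No longer favourable to
explore" is operationalised as: the best single trip over the unexplored
remainder does not beat staying, or the whole space is explored — the
same test as step 1 of the local rule. The local rule re-derives the best
single trip from the current conditional belief on every round.

All three strategies share the episode mechanics, and before the first
find each follows a deterministic no-find trip sequence; a strategy's
exact expected utility is therefore the planned-sequence utility of that
no-find sequence (`policy_expected_utility`), which the Monte Carlo
sampler validates. Monte Carlo uses one generator per call, seeded
explicitly; episode `i` consumes draw `i`, so strategies compared at the
same seed see common random numbers. Near-optimality of the local rule is
asserted at 1% relative utility (the qualitative claim "near-optimal"
needs a number; 1% is the package's choice).

## Circuit

The local decision rule discretises onto bin midpoints
`x_j = (j - 1/2) D / n` with per-bin masses `w_P[j] = P1(x_j | r) dx`, so
all integrals become lower-triangular cumulative sums with *fixed*
weights: beliefs enter only through layer-1 activity, as a neural
implementation requires. Layer 2 carries the per-bin benefits
`w_P (w_R - 1)` (vs staying) and `w_P (w_R + RtildeDelta)` (vs
travelling); layer 3 assembles the single-trip gain over staying, in
units of `R0 x time`; layer 4, gated multiplicatively by layer 3's
one-hot winner, carries the discretised three-scenario gain of each
candidate shorter trip; layer 5 selects shorter-trip winner, else
single-trip winner, else stay, gated by a binary on-patch signal. Node
operations are restricted to affine combination, elementwise product of
two streams, rectification and winner-take-all (ties to the smallest
index, matching the planner's preference for shorter trips). The
survival factor is read from layer 1 as `1 - cumsum(w_P)`, exact as
`n -> inf` with discretisation bias at most `p dx`. Decisions depend only
on signs and argmaxes, so they are invariant under any positive rescaling
of layer-3/4 activities, and the correctness criterion is exact decision
equivalence with the grid-restricted local rule — no particular weight
normalisation is privileged. After an empty-handed trip the explored bins
of `w_P` are zeroed and the rest renormalised to the conditional density
(the explored range is excluded *strictly*, matching the rule's
candidate set). The travel-cost gain `RtildeDelta = |RDelta|/R0` is the
only modulated quantity; raising it monotonically shortens (and
eventually suppresses) the chosen trips on the demo profile.

## Presets

* `two_trip`: `D=1000, R0=0.1, RDelta=-0.1, mu=10, T=8000, gamma=0.001,
  p=0.24771` — short horizon, the two-vs-one-trip regime.
* `multi_trip`: `D=1000, R0=0.25, RDelta=-0.25, mu=10, T=24000,
  gamma=0.0006, p=0.24771` — long horizon, multi-trip planning and
  strategy comparison.
* `circuit_demo`: `D=1000, p=0.0061359, gamma=0.0004, mu=40, R0=1,
  RDelta=-1, T=8000`. Only the relative quantities
  (`R(d)/R0 = 40 (1 - 0.0004 d)`, `|RDelta|/R0 = 1`) matter for the
  circuit's decisions up to the horizon weight; the absolute scale is
  fixed by choosing `R0 = 1` and reusing the short horizon `T = 8000`.

## Problem sizes and randomness

The test-suite and the acceptance script run at desk scale: planner grids
of 150–400 points (sweeps at 150, headline runs at 400), brute-force
enumeration oracles at up to 20 grid points and 3 trips (and all
increasing sequences at 14 points for the Bellman check), Monte Carlo at
10^5 episodes for the closed-form comparison and 2x10^4 for strategy
ordering, 100 random draws for the circuit-equivalence sweep and 1000
episodes for the reserve invariants. Hypothesis-based property tests run
derandomised. All random draws flow from explicit integer seeds;
`scripts/acceptance.py` derives per-section generators from its `--seed`
via `SeedSequence`.

## What the random-draw distributions emulate — and what they do not

Random parameter draws span harvest rates 0.05–1, travel costs 0.05–1,
patch advantages `mu/R0` of 2–50, decay up to `gamma D = 1`, densities
`p D` from 10^-2 to ~300 and horizons 5000–30000 — wide enough to cover
sparse single-trip worlds through dense multi-trip worlds. They do not
emulate real foraging data: the environment is 1D and static, patches do
not deplete, travel is deterministic, the forager never gets lost, and
the prior's functional form is known exactly. Passing tests certify the
mathematics and the implementations against each other and against
independent oracles, not the model's fit to any animal.

## Known limitations

* The planner's grid DP is exact only on its grid; the continuous
  refinement is local, so an optimum far from every grid candidate could
  in principle be missed (mitigated by the default 400-point grid and the
  smoothness of the objective).
* Utility plateaus (dense environments, long horizons) make the optimal
  trip count ill-conditioned: many sequences agree in utility to 10^-13.
  `K_opt` is reported under the fewer-trips tie preference and is stable,
  but plateau sequences themselves are not unique.
* The MDP oracle's state space grows as `n x n^2/2`; it is capped at
  `n = 200` and intended for verification only.
* Re-planning caches decisions by (mode, horizon, range, time); episode
  simulation is exact but serial, so extremely long no-find sequences
  (tiny `p` with huge `T`) are the slow path.
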