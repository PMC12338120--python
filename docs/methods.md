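# Methods

This note documents the models, numerical procedures, and default parameters
of the package, and what its synthetic data can and cannot show.

## Graphs and structure matrices

An offset tube `GTube(n, k, p)` has nodes `(r, j)` for ring `r < n` and
protofilament `j < k`, longitudinal edges `(r,j)–(r+1,j)`, lateral edges
`(r,j)–(r,j+1)`, and seam edges `(r,k−1)–(r+p,0)` whenever `r+p ≤ n−1`. The
seam wiring direction is a convention; the opposite choice yields an
isomorphic graph. There is no periodic closure along the axis: boundary rings
simply omit out-of-range interactions. The microtubule graph is
`GTube(48,13,3)` — 624 monomers, matching 13 protofilaments of 48 monomers
with a 3-monomer seam pitch.

All spectral and convolutional code uses the Laplacian in the
`L = A − diag(A·1)` sign convention (non-positive spectrum). Every
downstream computation is consistent with this choice, and the diffusion
distance is invariant to a global sign flip applied to both operands. The
GCN structure matrix is this raw Laplacian — no symmetric normalization and
no self-loop augmentation.

## Linear graph diffusion distance and prolongations

The LGDD between a small graph G₁ and large graph G₂ minimizes
`‖(1/α) P L(G₁) − α L(G₂) P‖_F` over tall column-orthogonal P (Stiefel
constraint). The package fixes α = 1 throughout the main pipeline; an
optional golden-section outer search over α exists but is slow by design
(each probe re-optimizes P, and the α-profile has kinks and local minima).

The two-stage solver:

1. **Spectral assignment (RLAP).** Restricting P to `U₂ P̃ U₁ᵀ` with P̃ a
   subpermutation matrix turns the problem into a rectangular linear
   assignment between the eigenvalue lists with cost
   `((1/α)λⱼ − αλₗ)²`, solved exactly with
   `scipy.optimize.linear_sum_assignment`. This gives an upper bound on the
   distance and the initialization for stage 2.
2. **Stiefel refinement.** Riemannian gradient descent on the squared
   objective: projected Euclidean gradient, thin-QR retraction,
   Barzilai–Borwein step with Armijo backtracking; gradient-norm tolerance
   1e-6, default cap 1000 iterations, best iterate always returned (flagged
   when the tolerance was not met).

A structural fact worth knowing: the assignment initializer is *always* a
critical point of the constrained objective — its Riemannian gradient
vanishes identically, because the Euclidean gradient at `U₂ P̃ U₁ᵀ` lies in
the span removed by the tangent-space projection. First-order descent
started exactly there cannot move, so the optimizer first takes a small
seeded random tangent step (size 1e-2). The unperturbed initializer is kept
as a fallback, so the refined value never exceeds the assignment bound. In
practice, on tube-graph pairs the bound appears to be the local (and, under
perturbed multi-starts up to size 1.0, the global) optimum: refinement
confirms rather than improves it.

### Coarsening search

Candidates `GTube(24, k, p)` for `k ∈ {3..12}`, `p ∈ {0..3}` and seam
weights {1, 2} are scored by LGDD against `GTube(48,13,3)`; the search
reports both the assignment bound and the refined value and ranks by the
latter. Under this implementation the four k = 3 candidates separate cleanly
from every k ≥ 4 candidate (0.066–0.078 vs ≥ 0.080), confirming k = 3 as the
right coarsest scale; within k = 3 the ordering is p = 3 < 2 < 1 < 0 with a
~16% spread. These margins are small enough to be sensitive to construction
conventions, so the full ranking is always written out rather than only the
argmin. The hierarchy default follows the conventional choice
`GTube(24,3,0)` with unweighted seam, and the intermediate level
`GTube(24,13,1)` corresponds to merging each αβ-dimer pair.

## Models

A **member** is a GCN stack `X_m = ReLU(Z X_{m−1} W_m + b_m)` whose per-layer
outputs are concatenated node-wise and passed through a node-wise dense head
(sigmoid hidden layers, linear scalar output). The **GPCN** sums one member
per level: the fine member sees X directly; member i sees the restricted
input `P_{1,i}ᵀ X` and its output is prolonged back by `P_{1,i}`, the
composed product of pairwise prolongations. In the **A-GPCN** the `P_{1,i}`
are free parameters initialized from the diffusion-distance optimum and
updated by the same gradient steps as the weights; orthogonality is not
re-imposed during training (re-projection would discard part of the learning
signal, and nothing in the ensemble requires it).

Filter widths follow the inverted pattern of the reference configuration:
the coarsest member is widest (64/64/64 down to 16/16/16 at the fine level
for the 3-level model; dense head 256/32/8/1), since coarse capacity is
cheap. Baselines: plain ensembles of 1–3 members on the fine Laplacian;
N-GCN with one member per power `Z^r` (radii (1,2,4) and (1,2,4,8,16)); and
a DiffPool mirror of the 3-level topology where each projection is the
row-softmaxed output of an auxiliary GCN and coarse structure matrices
follow `Z' = Sᵀ Z S`. Whether ensemble members share the identical input X
is not otherwise constrained; here all members receive the same X.
Initialization is Glorot-uniform with a run-level seed; biases start at
zero.

All forward/backward passes run on a small reverse-mode tape over numpy
(`gpcn.autodiff`), written for exactly the operations these architectures
need; the closed-form input gradients in `energy_gradients` are validated
against it and against finite differences rather than re-derived per layer.

## Training

Adam with the usual defaults (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7), batches of
8, 20 batches per epoch. The split is 90/10 over frames with the run seed;
inputs and targets are standardized per (node, feature) using training-split
statistics only (std floored at 1e-8 for constant features such as clamped
node positions). The validation metric is NMSE — plain MSE in standardized
target space — and histories record the running minimum, which is monotone
by construction.

**Per-level training semantics.** A schedule event trains one subset of
levels for one epoch; the loss is always the fine-scale MSE of the full
ensemble forward, with only the event's member parameters (plus its P when
adaptive) receiving updates. This follows from evaluating error at the fine
scale: a coarse "smoothing step" still needs the whole ensemble's
prediction.

**Schedules.** `joint` trains everything every epoch. `mu_cycle` unrolls
`cycle(l) = [l] + γ·cycle(l+1) + [l]` from the finest level (γ = 1 is the
V-cycle fine→mid→coarse→mid→fine; γ = 0 degenerates to fine-only) and
repeats the cycle until the epoch budget is spent. `coarse_to_fine` trains
phases coarse → coarse+mid → all, advancing when validation has not improved
for 10 epochs.

**FLOP ledger.** Costs follow the printed estimates — GCN layer
`n·F·(|Z|+C)`, node-wise dense `n·F·C`, projection `n·m·k` — with no hidden
multiply–add factors. A training event is charged the full-ensemble forward
plus a backward over the event's trainable levels only, approximated at the
same formula cost as the corresponding forward pieces. This bookkeeping
choice is what makes coarse-level epochs cheaper than joint epochs; under
it, γ-cycles spend roughly 60% of joint training's FLOPs for the same epoch
count on the 3-level desk model.

## Simulator and synthetic data

Harmonic interactions only (no sterics, no dihedrals): bonds
`E = L(r − b₀)²` and angles `E = L(φ − φ₀)²` with φ in radians and φ₀
converted from tabulated degrees, matching the conventions of the harmonic
bond/angle styles in common MD engines. The five interaction families —
lateral association (5.15639 nm, including across the seam), longitudinal
association (5.0 nm), pitch angle (153.023°), longitudinal angle (180°), and
the four quadrilateral-cell angles (77.0694° acute / 102.931° obtuse, one
strength) — are enumerated by pattern-matching templates over the lattice.
Resting values are tabulated constants, *not* recomputed from coordinates:
the helix placement (radius 13 nm, 5 nm axial spacing, rise p·5/k per
lateral step) reproduces the advertised 26 nm diameter but its exact analytic
relation to the tabulated resting values is not published, so the as-built
geometry starts slightly strained and relaxes during the ramp.

Per-node energy attribution splits each bond's energy half/half and each
angle's energy in thirds among its participants, so per-node energies sum
exactly to the total. Forces are analytic gradients, validated against
central finite differences at 1e-5 relative.

Dynamics: BAOAB-split Langevin velocity Verlet (plain velocity Verlet when
damping and temperature are zero). The first two rings are clamped; a −y
load on the last two rings ramps linearly over the ramp phase and is held.
The full protocol's step counts (128000 ramp + 256000 hold, save every
32000 → 12 frames per run) are kept as the bookkeeping constants; the
printed physical units of the source model (monomer mass, 0.018 ns steps,
9e-14 N load) are mutually inconsistent, so the simulator uses reduced units
(nm lengths, unit mass, dimensionless energy/force) and makes no
physical-time claims. Defaults chosen once for the desk preset: timestep
0.01, load 5.0, damping 0.5, temperature 1e-4 — overdamped and stable across
the full strength grid {3..57}.

Saved features are the printed 10 per node: position (3), velocity (3), and
four interaction coefficients. The grid sweeps five strengths, so the
feature vector carries LatAssoc, LongAssoc, LatAngle, LongAngle and ties
QuadAngles to LatAngle's column (the list is configurable).

**Desk-scale preset** (the scale at which the training comparisons run):
12-ring tube `GTube(12,13,3)` with hierarchy `156 → 78 → 18` mirroring the
full-size coarsening, strength grid {3.0, 57.0} per parameter (2⁵ = 32 runs
× 12 frames = 384 frames), ramp 1500 + hold 1500 steps, save every 250.
Member widths are scaled to 0.25 of the reference configuration. These are
the package's study conditions: large enough for the qualitative effects
(adaptive > static > single; stiffness ordering under load), far too small
to reproduce absolute error levels of a 16807-run dataset at 624 nodes.

## What the tests do and do not show

The suite verifies exact structural properties, oracle agreement (brute-force
assignment, dense-arithmetic forwards, finite-difference gradients), protocol
bookkeeping, and — on the desk preset over three seeds — the qualitative
orderings: A-GPCN beats the matched GPCN and the single GCN on min validation
NMSE, and γ ∈ {2,3} schedules reach their attained error levels with fewer
ledger FLOPs than joint training needs for the same (accuracy-matched,
same-seed comparison, majority of seeds). Synthetic desk-scale data shares
the full protocol's structure but not its scale or diversity, so passing
tests support the mechanisms, not absolute performance numbers on real
microtubule simulations. The coarse-search ranking within k = 3 is
implementation-sensitive at the ~15% level (see the search section); the
k = 3 conclusion itself is robust.

## Known limitations

* Dense eigendecompositions and dense GCN arithmetic: appropriate at ≤ 624
  nodes, not beyond.
* The α-search over the diffusion distance is the slow outer-loop variant.
* DiffPool is implemented as an architectural baseline (forward + gradients);
  no auxiliary pooling losses are defined.
* The simulator is a mechanical model: no dynamic instability, hydrolysis
  chemistry, sterics, or solvent beyond Langevin friction; no exact
  reproduction of any particular MD engine's trajectories is claimed.
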