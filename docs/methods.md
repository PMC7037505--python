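# Methods

## Model

Residents threatened by a typhoon choose between Evacuate and Stay. The
government is not a strategic player; it acts only through parameters
that reshape the cost structure. All monetary quantities (P, C, C′, D,
E) live on one abstract value scale — no currency or discounting is
modelled — and payoffs are single-shot per round.

The bimatrix cells follow the accounting in the README. Two structural
facts matter for everything downstream:

* the **advantage of evacuating is affine** in the counterpart group's
  evacuating share: UE1 − US1 = A1·y + A2 with
  A1 = (δ−1)βD1 + E1[(1−θ)ε − η] and
  A2 = αP1 − α(C1−C1′) − (1−δ)(1−β)D1 + ηE1 (B1, B2 likewise with
  group-2 economics). The bracket in A1 groups the whole stay-cost term
  under E1; that grouping is the only one consistent with expanding
  UE1 − US1 from the cells, and a property test enforces the identity at
  1e−10.
* the pairing of V cells in the group-2 mixtures follows the subscript
  convention "first index = group 1's strategy": an evacuating group-2
  member meets V11 with probability x and V21 otherwise, which is the
  pairing under which B1·x + B2 ≡ UE2 − US2 holds for asymmetric
  economics.

## Mean-field analysis

Replicator dynamics ẋ = x(1−x)(A1y + A2), ẏ = y(1−y)(B1x + B2). The
Jacobian is

    J = [ (1−2x)(A1y+A2)   x(1−x)A1        ]
        [ y(1−y)B1         (1−2y)(B1x+B2)  ]

with the off-diagonal entries the exact partials ∂f/∂y and ∂g/∂x; a
central-finite-difference oracle (step 1e−6, tolerance 1e−5) pins them
in the test suite. Consequences worth stating explicitly:

* at the interior point (x\*, y\*) = (−B2/B1, −A2/A1) both diagonal
  entries vanish, so Tr J = 0 identically and
  Det J = −x\*y\*(1−x\*)(1−y\*)A1B1: the interior point is a saddle
  whenever A1B1 > 0 and can never be asymptotically stable;
* at (1,1), J = diag(−(A1+A2), −(B1+B2)), so full evacuation is stable
  exactly when A1+A2 > 0 and B1+B2 > 0 — i.e. when evacuating still
  pays once everyone evacuates. Under the reference profile
  A1+A2 = −0.53 < 0, so (1,1) is repelling and the symmetric diagonal
  flows to the interior share −A2/A1 ≈ 0.72 instead; the attracting
  corners are the miscoordination states (0,1) and (1,0).

Classification uses sign tests with a relative tolerance of 1e−9 on the
scale max(|A1|,|A2|,|B1|,|B2|)²: |Det| below it → degenerate, Det > 0
with |Tr| below it → center; the interior candidate must clear the
boundary by the same margin to count as interior. Trajectories are
integrated with fixed-step classical RK4 (default step 0.01); the flow
leaves the unit square invariant, so only round-off (≤1e−9) is clipped
back, and anything larger aborts as an integrator bug.

## Social network

The kin/friendship network is a Watts–Strogatz graph. The reference
scenario fixes only its size (200 nodes), so the lattice degree K = 4
and rewiring probability p = 0.1 are package defaults chosen as the
canonical small-world regime — high clustering (ring-lattice limit
3(K−2)/(4(K−1)) = 0.5 for K = 4) with short paths — and both are
config-exposed and echoed into every output. Rewiring preserves the
edge count N·K/2 and simplicity. Because diffusion on a disconnected
graph silently biases the response rate, generation retries with an
incremented seed (up to 100 attempts, logged) until connected. Graphs
are unweighted, so the neighbour-selection distribution
p_ij = A_ij / Σ_k A_ik reduces to the uniform choice; the weighted form
is kept for graphs that carry edge weights, but no weighting scheme is
shipped and the adjacency is treated as static.

## Imitation protocol

Per round, every node i: (1) accumulates payoff over all neighbours
from the bimatrix (aggregation `sum` by default; `mean` divides by
degree and is near-equivalent here because small-world degrees are
almost homogeneous); (2) samples one neighbour j from the
neighbour-choice distribution; (3) keeps its strategy if pr_i ≥ pr_j,
otherwise adopts j's strategy with probability
W = 1/(1 + exp[(pr_i − pr_j)/k]). The default variant makes adoption
*increase* with the neighbour's advantage, which is the standard
pairwise-comparison rule and the behaviour the protocol's verbal
description demands; an `as_printed` variant with the opposite exponent
sign is retained for fidelity experiments. Updates are synchronous by
default (all comparisons against the round-start state), with an
asynchronous scheme (random permutation, in-place) available. All nodes
are row players of the symmetric reference game; an optional group
attribute switches cell lookup to the (group_i, group_j)-appropriate
U/V entries for asymmetric economics.

Noise k = 1 is the neutral default. Payoffs are recomputed from the
current profile each round; nothing accumulates across rounds, and
consensus is absorbing (imitating an identical strategy changes
nothing).

## Ensembles, seeds, sweeps

An ensemble runs `n_reps` = 200 independent repetitions of
(draw graph → draw initial strategies at fraction 0.5 → play T = 20
rounds) and averages the per-round response rate; repetition r derives
its RNG stream from (master_seed, r) and its graph seed from a counter
formula below 2³¹, so repetitions are independent and individually
reproducible, and the whole ensemble is bit-reproducible from one
master seed. A `fixed_graph` flag (or an explicit graph argument)
freezes one network across repetitions for studies that want to isolate
strategy randomness.

Sweeps overwrite one policy coefficient along its grid — β, θ over
{0.05, 0.25, 0.45, 0.65, 0.85}; δ over {0.1, …, 0.5}; ε, η over
{0.9, …, 0.5} — while the non-swept coefficients hold at the grid
midpoints (β = θ = 0.45, δ = 0.3, ε = η = 0.7), the package's
documented base profile. Because grid values share the master seed
(common random numbers: identical graphs, initial conditions and update
draws), differences between grid points are purely payoff-driven, which
is what makes the endpoint contrast sharp at 200 repetitions. The trend
summary reports Spearman rank correlation between grid value and mean
final rate, the endpoint difference, and its pooled standard error from
the per-repetition finals.

## What the generator emulates — and what it does not

The synthetic setup reproduces the study conditions: a 200-node
small-world population, binary strategies initialised at 50 %, 20
rounds, 200 repetitions, noise k = 1, and the reference economics
(P=10, C=8, C′=1, D=4, E=2, α=0.5). It does *not* emulate heterogeneous
households (all nodes share one economics profile unless groups are
assigned), degree–attribute correlations, directed or weighted social
ties, information delays, or any coupling between the typhoon's
trajectory and α over time. Passing tests therefore show that the
*mechanism* — policy → payoffs → imitation → diffusion — behaves as the
theory predicts under the stated conditions, not that the model is
calibrated to any real evacuation.

Under the base profile the five policy trends are strong and monotone
(rank correlation ±1; endpoint gaps of tens of pooled standard errors).
At the grid extremes the simulated states follow the mean field: δ=0.5
removes the interior point and drives near-full evacuation (~0.96),
while β=0.05 settles near the interior share A2/|A1| ≈ 0.31 rather
than collapsing to zero — whether the extreme-β system empties out
entirely depends on the values chosen for the non-swept coefficients,
which is exactly the kind of base-profile sensitivity the sweep API is
meant to expose.

## Numerical and design choices

* Validation is eager and names the offending field; policy
  coefficients live in [0,1], economics are non-negative with C′ ≤ C.
  No ordering between ε and η is enforced: both sweep the same grid and
  the model is well-defined either way.
* The Fermi probability uses the overflow-safe logistic and saturates
  to the exact 0/1 limits for huge payoff gaps.
* Step 4 of the protocol ("performed 200 times, take the average") is
  read as 200 independent repetitions of the whole run; the alternative
  (averaging passes within a round) would contradict the per-repetition
  re-randomisation of initial strategies.
* Reported problem sizes: unit tests use 40–60-node graphs with a
  handful of repetitions; the trend suite runs the full 200-node,
  200-repetition ensembles, which completes in well under a minute; the
  one-step transition oracle checks the exact successor-vector
  distribution of the synchronous update on a 4-node path against
  50,000 Monte-Carlo replicates.
* All floating-point output files carry 6 significant digits, and every
  CSV/JSON artefact embeds the fully resolved configuration and master
  seed.

## Known limitations

The mean-field and network dynamics agree only qualitatively: the
two-population replicator system has miscoordination attractors that a
single well-mixed network population cannot reach (it lives on the
diagonal x = y), so mean-field labels should be read as organising the
simulation's tendencies, not predicting its exact final rates. Fermi
noise at k = 1 keeps corner states only metastable at finite T; runs
longer than T = 20 drift slowly toward absorption. The imitation rule's
payoff gate (never imitate a worse-or-equal neighbour) is part of the
protocol, not of the classical pairwise-comparison process, and it
breaks detailed-balance arguments that would otherwise apply.
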