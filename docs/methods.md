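# Methods

## The set-of-compounds model

A state is a pair (available compound set, ordered reaction list).  A
reaction `r` is applicable when `S(r) ⊆ available` and `r` is not already in
the list; applying it adds `P(r)` to the available set.  Nothing is ever
removed (no stoichiometry, no consumption), so availability is monotone and
any prefix of any constructed pathway is feasible.  Two consequences shape
the implementation:

* two states with equal available sets have identical futures, so the
  exhaustive searchers deduplicate on the available set alone;
* a reaction can usefully appear at most once per pathway, and this
  restriction is applied uniformly to BFS, DFS and the ant walks so all
  searchers explore the same space.

Stoichiometric coefficients are accepted in the input format and discarded:
every quantity the package computes (feasibility, novelty, connectivity,
branching) is defined on compound sets.  A reversible reaction is split at
load time into two independent directed reactions sharing a `parent_id`
(backward id suffixed `_rev`), which is also the identity used when counting
"unique" reactions and when scoring reaction-level precision/recall, so that
using both directions of one reaction is recognized as redundancy rather
than as two distinct steps.

## Cost

The four components are: length `|π̂|`, unique count `φ` (distinct
parent ids), productive count `ϕ` (steps whose products include a compound
neither freely available nor previously produced) and connectivity
`κ ∈ {1, α}`.  They are combined as

    f(π̂) = κ · (3|π̂| − φ − ϕ).

This particular combination is a design choice (only the components
themselves are canonical): it reduces to `κ·|π̂|` when every reaction is
unique and productive, so among complete solutions the pressure is purely
towards shortness; each fully redundant reaction adds +2 beyond its length
contribution; and since `3L − φ − ϕ ∈ [L, 3L]`, any complete solution beats
any partial one whenever `α > 3·L_max` — amply satisfied by the default
`α = 10·N_k = 100` for the problem sizes used here.  The formula is isolated
in `evaluate.cost`; any strictly monotone alternative preserves the
algorithm's ordering behaviour.

Connectivity seeds the propagation set as
`X₀ = (S(π̂₀) ∩ 𝒟) ∪ (P(π̂₀) − 𝒞)`.  Seeding with the first reaction's
products is deliberate: a seed containing only the initial substrate could
never propagate past the first reaction, making `κ = α` for every pathway
including manifestly complete ones.  The single forward pass over the
pathway (rather than iteration to fixpoint) is intentional as well — it
respects the reaction order, and on feasibility-replayable pathways it
agrees with order-respecting graph reachability over the consumed-by
relation, which the test suite checks against a networkx-based oracle.

Cleaning removes, to fixpoint and preserving order, every reaction whose
non-free products contain no target and feed no retained later reaction.
Removal cannot break replayability: a removed reaction's non-free products
were by definition consumed by nothing retained, and free products are
always available anyway.  Cleaning is idempotent and never lengthens a
pathway; both properties are tested.

## The colony loop

Defaults follow the recommended configuration: `N_k = 10` ants,
evaporation `ρ = 0.1`, `α = 10·N_k`, at most 100 iterations, walk length
bounded by the universe size.  The pheromone matrix is dense,
`(n+1) × n`, all ones at start; row 0 (the virtual start row) is supported
exactly on the reactions that consume a candidate initial substrate.
Selection is purely pheromone-proportional — no heuristic desirability
factor and no exponents, which keeps a single tunable mechanism.

Per iteration: every ant walks independently; each walk is cleaned and
costed; the whole matrix evaporates once; every *non-empty* cleaned pathway
deposits `1/f` on its start entry and consecutive pairs.  Partial solutions
therefore do deposit, but at `1/(α·…)` strength — the connectivity penalty
is the mechanism that down-weights them — while a walk that cleaning empties
(it synthesized nothing relevant) deposits nothing.  Depositing along the
*cleaned* order means pheromone edges can skip removed reactions; that is
the intended reading: the trail should encode the useful skeleton, not the
detours.

Stopping: the literature's "all ants follow different paths according to
their costs" clause is not operationalizable as written, so the loop stops
when the best cost has not strictly improved for `stall_iterations`
(default 20) or at `max_iterations` (default 100).  Best-so-far updates
require strict improvement, making runs fully reproducible for a given
seed; all randomness flows from one `numpy` generator.

When several compounds may serve as the starting substrate ("auto" mode in
the CLI), the candidate set is simply `ℐ = 𝒟`: row 0 then spans every
reaction consuming any target, and the colony itself learns which start is
useful.  This realizes automatic initial-substrate selection without a
separate mechanism.

## Exhaustive baselines

BFS returns a minimum-length solution and doubles as the optimality oracle
in tests (cross-checked against brute-force enumeration of all feasible
sequences on universes of ≤ 8 reactions).  DFS is depth-limited (default
bound 10) and prunes a state unless it is reached at a strictly smaller
depth than before; without that memoization a depth-10 exhaustive dive is
combinatorially infeasible on the benchmark networks, and the pruning is
correctness-preserving by the same monotone-futures argument as for BFS.
Both accept a seeded operator shuffle to reproduce randomized-run
protocols; states-expanded counts are reported for the scaling
experiments.

## Synthetic networks

`make_linear_network(L, …)` plants a chain `c₀ → … → c_L` (targets
`{c₀, c_L}`, initial `c₀`; chain steps may additionally consume a pool
compound).  `make_branched_network([L₁, …, L_k], …)` emits a root reaction
`root → hub` plus `k` chains from the hub ending in `k` target tips, so the
hub is consumed `k` times and the planted pathway's `β` exceeds 1; the
planted length is `1 + Σ Lᵢ`.  Distractors come in two kinds, and neither
can shorten the optimum because no distractor ever produces a planted-chain
compound:

* *noise* reactions consume a chain compound and produce only a pool
  compound — feasible wrong moves that stress the ants but add nothing new;
* *locked* reactions consume compounds unreachable from the chain and
  produce fresh dead-ends, sometimes cascading into further locked
  compounds.

Pool compounds are wired into several distractors as extra substrates,
mimicking the high connectivity degree of currency metabolites.

`grow_available_set` reproduces the growing-initial-conditions experiment:
it adds randomly drawn extra compounds to the minimal available set.  Draws
exclude (i) planted-pathway compounds — handing a target or intermediate
out for free would change the known solution the experiment is built
around — and (ii) compounds no reaction consumes, which cannot affect any
search (in split real datasets every compound is a substrate, so the second
exclusion is vacuous there).  Granting a locked compound unlocks its
reaction, whose fresh products inflate the deduplicated state space; this
is the mechanism behind the monotone growth of BFS/DFS states and time,
while colony success and time stay flat.

What the generator does *not* emulate: realistic degree distributions
beyond the pool-compound motif, reversible-pair structure, multi-substrate
coupling along the chain, or compartments.  Passing the synthetic suites
therefore demonstrates algorithmic correctness (feasibility, optimality
agreement, trend reproduction), not performance claims on curated
biochemical databases; the validation that requires the curated
KEGG-derived datasets fails with an explanatory message unless those files
are supplied under `data/kegg/`.

## Problem sizes and numerical choices

The shipped experiments run at desk scale, chosen so the full suite
finishes in seconds while every effect being tested is comfortably
resolved: oracle agreement on 50 random universes of 10 reactions;
planted recovery with `L = 6`, 20 distractors, 2 pool compounds over 20
seeded runs; scaling with `L = 5`, 40 distractors (so the drawable
locked-compound pool exceeds the largest grid point, 12) over the grid
{0, 4, 8, 12} with 5 draws per point.  Ties in probabilistic selection are
impossible (weights are strictly positive reals); ties in best-cost updates
resolve to first-found.  Degenerate inputs fail loudly: empty pathways have
no cost or connectivity, a branching factor over only-free substrates is
undefined, reactions with `S(r) = P(r)` are rejected at load time, and a
candidate initial substrate consumed by no reaction raises before any
search starts.

## Known limitations

* No stoichiometry, mass balance, thermodynamics or atom tracking: a
  "feasible" pathway here is set-feasible, which is necessary but not
  sufficient for biochemical realizability.
* The cost's algebraic form is one defensible choice among several; only
  its ordering properties (completeness dominance, shortness pressure,
  redundancy penalty) are load-bearing.
* The colony is a stochastic heuristic: optimality agreement is high on the
  tested families but not guaranteed; BFS remains the certificate when the
  universe is small enough.
* DFS state memoization makes absolute timing curves incomparable to naive
  implementations; only trends are meaningful.
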