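# pheropath

Ant-colony synthesis of feasible linear and branched metabolic pathways.

Given a list of biochemical reactions `ℛ` (each a directed transformation
between substrate and product compound *sets*, `S(r) → P(r)`), a set `𝒟` of
target compounds to relate, candidate initial substrates `ℐ ⊆ 𝒟`, and a set
`𝒞` of freely available currency metabolites (water, ATP, NAD, ...),
pheropath searches for an ordered reaction sequence `π = [π₀, …, π_N]` that
synthesizes every target.  It is aimed at people who need candidate routes
through a reaction database — for synthetic-biology route design, for
interpreting metabolomics hits, or for gap filling in metabolic
reconstructions — without atom-tracking or thermodynamic annotation.

## The model

The search runs in a **set-of-compounds (SoC) state space**: a state is the
set of currently available compounds together with the reactions applied so
far, and a transition applies a reaction whose *entire* substrate set is
available.  Compounds are never consumed away, so the model is monotone and
**every partial solution is substrate-feasible by construction** — including
branched topologies, where one compound feeds several downstream reactions.
The price is a state space far larger than the usual compound-and-reaction
graph; the colony searches it without ever materializing it.

Each iteration, `N_k` ants build pathways independently.  An ant picks a
first reaction consuming a compound of `ℐ` with probability proportional to
row 0 of a pheromone matrix `Ω` (initialized to 1 everywhere), seeds its
available set with that reaction's substrates and products plus `𝒞`, then
repeatedly samples one feasible unused reaction with probability
`p = Ω[π_i, r] / Σ Ω[π_i, r']`, until `𝒟` is available, no feasible reaction
remains, or a step bound is hit.  Walks are *cleaned* (reactions whose
non-free products are neither targets nor consumed downstream are removed to
fixpoint) and scored by

```
f(π̂) = κ(π̂) · (3|π̂| − φ(π̂) − ϕ(π̂))
```

where `|π̂|` is the length, `φ` counts unique reactions (a reversible
reaction used in both directions counts once — and is thereby penalized),
`ϕ` counts reactions producing at least one genuinely new non-free compound,
and the connectivity `κ ∈ {1, α}` is 1 exactly when every target lies in the
compound set grown from the initial substrate along the consumption chain

```
X₀ = (S(π̂₀) ∩ 𝒟) ∪ (P(π̂₀) − 𝒞)
X_{i+1} = X_i ∪ (P(π̂_{i+1}) − 𝒞)   if X_i ∩ S(π̂_{i+1}) ≠ ∅,  else X_i.
```

With the recommended `α = 10·N_k`, complete solutions always outrank partial
ones.  After each iteration the matrix evaporates (`Ω ← (1−ρ)·Ω`) and every
cleaned pathway deposits `1/f` on its start entry and on each consecutive
reaction pair.  Pathway topology is summarized by the branching factor
`β = (1/|S*_f|) Σ_s Σ_j 1[s ∈ S(r_j)]` (mean number of pathway reactions
consuming each non-free substrate; `β > 1` means branched), and agreement
with a reference pathway by `PR = TP/(TP+FP)`, `RC = TP/(TP+FN)`,
`Acc = (PR+RC)/2` at both the compound and the reaction level.

Exhaustive BFS (shortest solution, an optimality oracle) and depth-limited
DFS over the same space are included as baselines, as is a generator of
synthetic universes with planted linear/branched pathways, pool compounds
and distractor reactions.

## Worked example

A four-reaction toy universe (`r1: A→B`, `r2: B→C`, `r3: B→D`,
`r4: C+P→E`, with `P` freely available), relating `A`, `C` and `D` from `A`:

```
$ printf 'r1\tA\tB\tforward\nr2\tB\tC\tforward\nr3\tB\tD\tforward\nr4\tC+P\tE\tforward\n' > toy.tsv
$ printf 'P\n' > free.txt
$ pheropath search --reactions toy.tsv --free free.txt \
    --target A --target C --target D --initial A \
    --seed 1 --out-prefix toy_pathway
pathway: r1 -> r3 -> r2 (cost 3)
```

The colony finds the branched optimum: `r1` makes `B`, which feeds both
`r3` (→ `D`) and `r2` (→ `C`).  The cost block of `toy_pathway.json`
reads

```json
"cost": {"length": 3, "n_unique": 3, "n_productive": 3, "kappa": 1.0, "total": 3.0}
```

— three reactions, all unique and all productive, all targets connected
(`κ = 1`), so the total cost equals the pathway length; the branching factor
of this pathway is 1.5 (`A` consumed once, `B` twice).  `toy_pathway.dot`
holds the compound/reaction graph (free compounds dashed) and
`toy_pathway.history.csv` the per-iteration best/mean cost trace.  Exit
status is 0 for a complete solution, 3 for an incomplete best pathway, 2 for
usage errors.  `pheropath benchmark` sweeps searching time against a growing
initial available set on planted networks, and `pheropath evaluate` scores a
pathway JSON against a reference (PR/RC/Acc at both levels).

The same machinery is available as a library:

```python
from pheropath import AcoParams, make_linear_network, run

net = make_linear_network(L=6, n_distractors=20, n_pool=2, seed=42)
result = run(net.problem, AcoParams(seed=0))
print(result.pathway.ids, result.cost.total)   # 6 chain reactions, cost 6.0
```

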