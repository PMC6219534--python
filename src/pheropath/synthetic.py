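"""Synthetic reaction universes with planted feasible pathways.

These generators make every searcher testable without any database
download: a known linear or branched pathway is planted in a universe of
distractor reactions and high-connectivity pool compounds, so "planted =
optimal" is an oracle property.  Distractor reactions never create a
shorter route to a target: their products are always fresh compounds (or
pool compounds), never compounds of the planted chain.

Compound naming: planted-chain compounds ``X0000…``, branch compounds
``B<i>_<j>``, pool compounds ``P0000…``, distractor compounds
``D0000…`` — deliberately distinct from KEGG-style ``C…`` ids so mixed
tests cannot collide with real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reaction_net import Pathway, Reaction, ReactionUniverse, SearchProblem

__all__ = [
    "PlantedNetwork",
    "make_linear_network",
    "make_branched_network",
    "grow_available_set",
    "make_random_problem",
]


@dataclass(frozen=True)
class PlantedNetwork:
    """A universe with a known feasible pathway reaching all targets."""

    universe: ReactionUniverse
    planted_pathway: Pathway
    problem: SearchProblem
    minimal_available: frozenset[str]

    def __post_init__(self) -> None:
        # construction-time sanity: the planted pathway must replay and
        # reach every target
        final = self.planted_pathway.replay(
            self.minimal_available | self.problem.free_compounds
        )
        if not self.problem.targets <= final:
            raise AssertionError("planted pathway does not reach all targets")


def _make_distractors(
    rng: np.random.Generator,
    n_distractors: int,
    n_pool: int,
    pool_degree: int,
    visible: list[str],
) -> tuple[list[Reaction], list[str]]:
    """Distractor reactions of two kinds, never shortcutting the chain.

    *Noise* reactions (half) consume a planted-chain compound and
    produce only a pool compound (or a fresh dead-end when there is no
    pool): they are feasible wrong moves for the ants but synthesize
    nothing new.  *Locked* reactions (the other half) consume a fresh
    compound unreachable from the chain and produce a fresh dead-end,
    sometimes cascading into another locked compound — these are the
    reactions that extra initially-available compounds unlock, which is
    how a larger initial set inflates the exhaustive search space.

    Each pool compound is additionally wired into ~pool_degree
    distractors as an extra substrate, emulating the high connectivity
    degree of currency metabolites.
    """
    pool = [f"P{i:04d}" for i in range(n_pool)]
    reactions: list[Reaction] = []
    n_noise = n_distractors // 2
    n_locked = n_distractors - n_noise
    locked = [f"E{i:04d}" for i in range(n_locked)]
    for i in range(n_noise):
        sub = str(rng.choice(visible))
        prod = str(rng.choice(pool)) if pool else f"N{i:04d}"
        reactions.append(
            Reaction(
                id=f"RN{i:03d}",
                substrates=frozenset({sub}),
                products=frozenset({prod}),
            )
        )
    for i in range(n_locked):
        # always one fresh product, sometimes cascading into another
        # locked compound, so an unlocked reaction always yields a new
        # compound (granting extras can only enlarge the search space)
        prods = {f"F{i:04d}"}
        if n_locked > 1 and rng.random() < 0.5:
            j = int(rng.integers(n_locked - 1))
            prods.add(locked[j if j < i else j + 1])
        reactions.append(
            Reaction(
                id=f"RD{i:03d}",
                substrates=frozenset({locked[i]}),
                products=frozenset(prods),
            )
        )
    if reactions:
        for p in pool:
            k = min(pool_degree, len(reactions))
            for j in rng.choice(len(reactions), size=k, replace=False):
                r = reactions[j]
                new = Reaction(r.id, r.substrates | {p}, r.products, r.parent_id)
                if new.substrates != new.products:
                    reactions[j] = new
    return reactions, pool


def _assemble(
    rng: np.random.Generator,
    planted: list[Reaction],
    distractors: list[Reaction],
    pool: list[str],
    targets: frozenset[str],
    initial: frozenset[str],
    minimal: frozenset[str],
) -> PlantedNetwork:
    all_reactions = planted + distractors
    order = rng.permutation(len(all_reactions))
    universe = ReactionUniverse([all_reactions[i] for i in order])
    problem = SearchProblem(
        universe=universe,
        targets=targets,
        initial_candidates=initial,
        free_compounds=frozenset(pool),
    )
    return PlantedNetwork(
        universe=universe,
        planted_pathway=Pathway(tuple(planted)),
        problem=problem,
        minimal_available=minimal,
    )


def make_linear_network(
    L: int,
    n_distractors: int = 0,
    n_pool: int = 0,
    pool_degree: int = 3,
    seed: int = 0,
) -> PlantedNetwork:
    """A planted chain c0 → c1 → … → cL of L reactions (each may also
    consume a pool compound), plus distractors.  Targets are the chain
    ends; the initial substrate is c0.  Deterministic per seed."""
    if L < 1:
        raise ValueError("chain length L must be >= 1")
    rng = np.random.default_rng(seed)
    chain = [f"X{i:04d}" for i in range(L + 1)]
    pool_names = [f"P{i:04d}" for i in range(n_pool)]
    planted = []
    for i in range(L):
        subs = {chain[i]}
        if pool_names and rng.random() < 0.5:
            subs.add(str(rng.choice(pool_names)))
        planted.append(
            Reaction(
                id=f"RL{i:03d}",
                substrates=frozenset(subs),
                products=frozenset({chain[i + 1]}),
            )
        )
    distractors, pool = _make_distractors(
        rng, n_distractors, n_pool, pool_degree, visible=chain
    )
    return _assemble(
        rng,
        planted,
        distractors,
        pool,
        targets=frozenset({chain[0], chain[-1]}),
        initial=frozenset({chain[0]}),
        minimal=frozenset({chain[0]}),
    )


def make_branched_network(
    branch_lengths: list[int],
    n_distractors: int = 0,
    n_pool: int = 0,
    pool_degree: int = 3,
    seed: int = 0,
) -> PlantedNetwork:
    """A root reaction root → hub feeding k chains that end in k distinct
    target tips; the planted pathway (root reaction + all branch
    reactions) has branching factor > 1 because the hub compound is
    consumed by every branch."""
    if len(branch_lengths) < 2:
        raise ValueError("at least 2 branches are required")
    if any(L < 1 for L in branch_lengths):
        raise ValueError("every branch length must be >= 1")
    rng = np.random.default_rng(seed)
    root, hub = "X0000", "X0001"
    planted = [
        Reaction(
            id="RROOT", substrates=frozenset({root}), products=frozenset({hub})
        )
    ]
    tips = []
    branch_compounds = [root, hub]
    for b, L in enumerate(branch_lengths):
        prev = hub
        for j in range(L):
            nxt = f"B{b}_{j}"
            branch_compounds.append(nxt)
            planted.append(
                Reaction(
                    id=f"RB{b}_{j}",
                    substrates=frozenset({prev}),
                    products=frozenset({nxt}),
                )
            )
            prev = nxt
        tips.append(prev)
    distractors, pool = _make_distractors(
        rng, n_distractors, n_pool, pool_degree, visible=branch_compounds
    )
    return _assemble(
        rng,
        planted,
        distractors,
        pool,
        targets=frozenset({root, *tips}),
        initial=frozenset({root}),
        minimal=frozenset({root}),
    )


def grow_available_set(
    net: PlantedNetwork, n_extra: int, seed: int = 0
) -> frozenset[str]:
    """The minimal available set plus n_extra universe compounds drawn
    without replacement (mirrors the growing-initial-conditions
    experiment design).

    Compounds of the planted pathway are never drawn: handing a target
    or chain intermediate out for free would change the well-known
    solution the experiment is built around, rather than only inflating
    the search space.  Draws are restricted to compounds some reaction
    can consume — a compound nothing consumes cannot affect any search
    (in real datasets reversible splitting makes every compound a
    substrate, so this restriction is vacuous there).
    """
    if n_extra < 0:
        raise ValueError("n_extra must be >= 0")
    already = net.minimal_available | net.problem.free_compounds
    planted = net.planted_pathway.compounds()
    consumable = frozenset(
        s for r in net.universe for s in r.substrates
    )
    candidates = sorted(
        (net.universe.compounds & consumable) - already - planted
    )
    if n_extra > len(candidates):
        raise ValueError(
            f"requested {n_extra} extra compounds but only "
            f"{len(candidates)} are available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_extra, replace=False)
    return net.minimal_available | frozenset(candidates[i] for i in chosen)


def make_random_problem(
    seed: int,
    n_reactions: int = 10,
    n_compounds: int = 10,
    n_free: int = 1,
    n_extra_targets: int = 2,
) -> SearchProblem:
    """A random small universe with a guaranteed-reachable target set,
    for oracle-agreement tests: targets are sampled from the compound
    closure of the initial substrate, so BFS always finds a solution."""
    rng = np.random.default_rng(seed)
    names = [f"X{i:04d}" for i in range(n_compounds)]
    free = frozenset(f"P{i:04d}" for i in range(n_free))
    for _ in range(200):
        reactions = []
        for i in range(n_reactions):
            subs = frozenset(
                rng.choice(names + sorted(free), size=rng.integers(1, 3), replace=False)
            )
            prods = frozenset(
                rng.choice(names, size=rng.integers(1, 3), replace=False)
            )
            if subs == prods:
                continue
            reactions.append(
                Reaction(id=f"R{i:03d}", substrates=subs, products=prods)
            )
        if not reactions:
            continue
        universe = ReactionUniverse(reactions)
        substrate_compounds = sorted(
            {s for r in universe for s in r.substrates} - free
        )
        if not substrate_compounds:
            continue
        initial = str(rng.choice(substrate_compounds))
        # monotone closure from {initial} ∪ free
        available = set(free) | {initial}
        changed = True
        while changed:
            changed = False
            for r in universe:
                if r.substrates <= available and not r.products <= available:
                    available |= r.products
                    changed = True
        reachable = sorted((available - free) - {initial})
        if not reachable:
            continue
        k = min(n_extra_targets, len(reachable))
        extra = {str(c) for c in rng.choice(reachable, size=k, replace=False)}
        return SearchProblem(
            universe=universe,
            targets=frozenset({initial, *extra}),
            initial_candidates=frozenset({initial}),
            free_compounds=free,
        )
    raise RuntimeError("could not generate a solvable random problem")
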