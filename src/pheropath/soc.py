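"""The set-of-compounds (SoC) state model and exhaustive baselines.

A state is the set of currently available compounds plus the ordered
reactions applied so far.  A transition applies a reaction whose entire
substrate set is available; products are added and nothing is ever
removed, so the model is monotone and every path in the search tree is
feasible by construction.

BFS and depth-limited DFS over this space serve as correctness oracles
for the ant-colony searcher: BFS returns a minimum-length goal-reaching
pathway.  Both searchers deduplicate on the available-compound set —
under the monotone model two states with equal compound sets have
identical futures, so the pruning is correctness-preserving (DFS keeps
the smallest depth at which each set was reached, since a deeper revisit
can only reach a subset of the continuations).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .errors import DuplicateReactionError, FeasibilityError
from .reaction_net import Pathway, Reaction, ReactionUniverse, SearchProblem

__all__ = [
    "SocState",
    "SearchStats",
    "feasible_reactions",
    "apply_reaction",
    "is_goal",
    "bfs_search",
    "dfs_search",
]


@dataclass(frozen=True)
class SocState:
    """Available compounds + the reaction sequence that produced them."""

    available: frozenset[str]
    pathway: Pathway = field(default_factory=Pathway)

    def __post_init__(self) -> None:
        object.__setattr__(self, "available", frozenset(self.available))


def feasible_reactions(
    state: SocState, universe: ReactionUniverse
) -> list[Reaction]:
    """Reactions whose substrates are all available and that are not
    already in the pathway, in universe order."""
    used = set(state.pathway.ids)
    return [
        r
        for r in universe
        if r.id not in used and r.substrates <= state.available
    ]


def apply_reaction(state: SocState, r: Reaction) -> SocState:
    """Apply one feasible reaction, returning the successor state."""
    if r.id in set(state.pathway.ids):
        raise DuplicateReactionError(f"reaction {r.id} already in pathway")
    if not r.substrates <= state.available:
        raise FeasibilityError(
            f"reaction {r.id}: substrates "
            f"{sorted(r.substrates - state.available)} unavailable"
        )
    return SocState(
        available=state.available | r.products,
        pathway=Pathway(state.pathway.reactions + (r,)),
    )


def is_goal(state: SocState, targets: Iterable[str]) -> bool:
    return frozenset(targets) <= state.available


@dataclass
class SearchStats:
    """Bookkeeping for the exhaustive searchers; ``states_expanded``
    counts dequeued/visited states including the root."""

    pathway: Optional[Pathway]
    states_expanded: int


def bfs_search(
    problem: SearchProblem,
    initial_available: Iterable[str],
    *,
    rng: Optional[np.random.Generator] = None,
) -> Optional[Pathway]:
    """Breadth-first search; returns a goal-reaching pathway with the
    minimum number of reactions, or None if the goal is unreachable.
    Deterministic for a fixed reaction ordering; pass ``rng`` to shuffle
    the operator order once per run."""
    return bfs_search_detailed(problem, initial_available, rng=rng).pathway


def bfs_search_detailed(
    problem: SearchProblem,
    initial_available: Iterable[str],
    *,
    rng: Optional[np.random.Generator] = None,
) -> SearchStats:
    order = _operator_order(problem.universe, rng)
    root = SocState(frozenset(initial_available))
    if is_goal(root, problem.targets):
        return SearchStats(pathway=Pathway(), states_expanded=1)
    seen: set[frozenset[str]] = {root.available}
    queue: deque[SocState] = deque([root])
    expanded = 0
    while queue:
        state = queue.popleft()
        expanded += 1
        used = set(state.pathway.ids)
        for r in order:
            if r.id in used or not r.substrates <= state.available:
                continue
            nxt_avail = state.available | r.products
            if nxt_avail in seen:
                continue
            seen.add(nxt_avail)
            nxt = SocState(nxt_avail, Pathway(state.pathway.reactions + (r,)))
            if is_goal(nxt, problem.targets):
                return SearchStats(nxt.pathway, expanded)
            queue.append(nxt)
    return SearchStats(None, expanded)


def dfs_search(
    problem: SearchProblem,
    initial_available: Iterable[str],
    max_depth: int,
    *,
    rng: Optional[np.random.Generator] = None,
) -> Optional[Pathway]:
    """Depth-limited DFS; returns the first goal-reaching pathway found
    within ``max_depth`` reactions, or None.  Children are expanded in
    universe order unless ``rng`` shuffles the operators for the run."""
    return dfs_search_detailed(
        problem, initial_available, max_depth, rng=rng
    ).pathway


def dfs_search_detailed(
    problem: SearchProblem,
    initial_available: Iterable[str],
    max_depth: int,
    *,
    rng: Optional[np.random.Generator] = None,
) -> SearchStats:
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    order = _operator_order(problem.universe, rng)
    root = SocState(frozenset(initial_available))
    if is_goal(root, problem.targets):
        return SearchStats(Pathway(), 1)
    # best (smallest) depth at which each available-set was reached
    best_depth: dict[frozenset[str], int] = {root.available: 0}
    expanded = 0

    stack: list[SocState] = [root]
    while stack:
        state = stack.pop()
        expanded += 1
        depth = len(state.pathway)
        if depth >= max_depth:
            continue
        used = set(state.pathway.ids)
        # reversed so the first operator in `order` is explored first
        for r in reversed(order):
            if r.id in used or not r.substrates <= state.available:
                continue
            nxt_avail = state.available | r.products
            prev = best_depth.get(nxt_avail)
            if prev is not None and prev <= depth + 1:
                continue
            best_depth[nxt_avail] = depth + 1
            nxt = SocState(nxt_avail, Pathway(state.pathway.reactions + (r,)))
            if is_goal(nxt, problem.targets):
                return SearchStats(nxt.pathway, expanded)
            stack.append(nxt)
    return SearchStats(None, expanded)


def _operator_order(
    universe: ReactionUniverse, rng: Optional[np.random.Generator]
) -> list[Reaction]:
    order = list(universe.reactions)
    if rng is not None:
        perm = rng.permutation(len(order))
        order = [order[i] for i in perm]
    return order
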