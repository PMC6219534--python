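"""Shared fixtures: the four-reaction toy universe used throughout the
docs (r1: A→B, r2: B→C, r3: B→D, r4: C+P→E, with P freely available),
plus independent brute-force oracles."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import settings

from pheropath import Pathway, Reaction, ReactionUniverse, SearchProblem

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

U1_TSV = (
    "r1\tA\tB\tforward\n"
    "r2\tB\tC\tforward\n"
    "r3\tB\tD\tforward\n"
    "r4\tC+P\tE\tforward\n"
)


@pytest.fixture
def u1() -> ReactionUniverse:
    return ReactionUniverse(
        [
            Reaction("r1", frozenset("A"), frozenset("B")),
            Reaction("r2", frozenset("B"), frozenset("C")),
            Reaction("r3", frozenset("B"), frozenset("D")),
            Reaction("r4", frozenset({"C", "P"}), frozenset("E")),
        ]
    )


@pytest.fixture
def u1_problem(u1) -> SearchProblem:
    return SearchProblem(
        universe=u1,
        targets=frozenset({"A", "C", "D"}),
        initial_candidates=frozenset({"A"}),
        free_compounds=frozenset({"P"}),
    )


def brute_force_min_length(problem: SearchProblem, initial_available) -> int | None:
    """Exhaustive enumeration of all feasible no-repeat reaction
    sequences; returns the minimum goal-reaching length (0 if the goal
    holds at the root), or None.  Only viable for small universes."""
    targets = problem.targets
    best: list[int | None] = [None]

    def rec(available: frozenset, used: frozenset, depth: int) -> None:
        if targets <= available:
            if best[0] is None or depth < best[0]:
                best[0] = depth
            return
        if best[0] is not None and depth >= best[0]:
            return
        for r in problem.universe:
            if r.id in used or not r.substrates <= available:
                continue
            rec(available | r.products, used | {r.id}, depth + 1)

    rec(frozenset(initial_available), frozenset(), 0)
    return best[0]


def connectivity_oracle(pathway: Pathway, targets, free) -> bool:
    """Independent κ oracle: order-respecting reachability on the
    consumed-by DAG (edge i→j, i<j, when a non-free product of step i is
    a substrate of step j), traversed with networkx."""
    import networkx as nx

    targets = frozenset(targets)
    free = frozenset(free)
    first = pathway[0]
    seed = (first.substrates & targets) | (first.products - free)
    g = nx.DiGraph()
    g.add_node("seed")
    n = len(pathway)
    for j in range(1, n):
        if seed & pathway[j].substrates:
            g.add_edge("seed", j)
    for i in range(1, n):
        for j in range(i + 1, n):
            if (pathway[i].products - free) & pathway[j].substrates:
                g.add_edge(i, j)
    reachable = nx.descendants(g, "seed") if "seed" in g else set()
    synthesized = set(seed)
    for j in reachable:
        synthesized |= pathway[j].products - free
    return targets <= synthesized
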