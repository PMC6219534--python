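"""Pheromone-guided ant search over the set-of-compounds space.

Each iteration, every ant builds a feasibility-guaranteed reaction
sequence: it picks a first reaction consuming a candidate initial
substrate (weighted by the virtual start row of the pheromone matrix Ω),
seeds its available set with that reaction's substrates and products
plus the freely available compounds, then repeatedly chooses one
feasible not-yet-used reaction with probability proportional to the
pheromone on the (previous reaction → candidate) transition, until all
targets are available, no feasible reaction remains, or the walk-length
bound is hit.  Walks are then cleaned, costed, and the matrix is
evaporated by a proportion ρ and reinforced by 1/f along every cleaned
pathway.  The loop stops at ``max_iterations`` or when the best cost has
not improved for ``stall_iterations``.

Ω is dense, ``(n_reactions + 1) × n_reactions``: row 0 is the virtual
start row, supported exactly on the reactions that consume a candidate
initial substrate; row ``i + 1`` holds transitions out of reaction
``i``.  All supported entries start at 1 and remain strictly positive
(evaporation multiplies by ``1 − ρ`` and never reaches zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import NoStartReactionError
from .evaluate import CostBreakdown, clean_pathway, cost
from .reaction_net import Pathway, Reaction, SearchProblem
from .soc import is_goal

__all__ = [
    "AcoParams",
    "ColonyState",
    "AcoResult",
    "init_colony",
    "select_reaction",
    "ant_walk",
    "evaporate",
    "deposit",
    "run",
]

DEFAULT_N_ANTS = 10
DEFAULT_RHO = 0.1
DEFAULT_MAX_ITERATIONS = 100
DEFAULT_STALL_ITERATIONS = 20


@dataclass(frozen=True)
class AcoParams:
    """Colony parameters.

    alpha defaults to 10·n_ants, the recommended setting that makes any
    complete solution cheaper than any partial one; max_steps defaults
    to the number of reactions in the universe at run time.
    """

    n_ants: int = DEFAULT_N_ANTS
    rho: float = DEFAULT_RHO
    alpha: Optional[float] = None
    max_iterations: int = DEFAULT_MAX_ITERATIONS
    stall_iterations: int = DEFAULT_STALL_ITERATIONS
    max_steps: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ants < 1:
            raise ValueError("n_ants must be >= 1")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly between 0 and 1")
        if self.alpha is not None and self.alpha <= 1.0:
            raise ValueError("alpha must be > 1")
        if self.max_iterations < 1 or self.stall_iterations < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.max_steps is not None and self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")

    def effective_alpha(self) -> float:
        return self.alpha if self.alpha is not None else 10.0 * self.n_ants


class ColonyState:
    """Pheromone matrix plus best-so-far bookkeeping."""

    def __init__(self, problem: SearchProblem, params: AcoParams):
        n = len(problem.universe)
        self.problem = problem
        self.params = params
        self.initial_reactions: tuple[Reaction, ...] = tuple(
            r
            for r in problem.universe
            if r.substrates & problem.initial_candidates
        )
        if not self.initial_reactions:
            raise NoStartReactionError(
                "no reaction consumes any candidate initial substrate "
                f"{sorted(problem.initial_candidates)}"
            )
        self.pheromone = np.ones((n + 1, n), dtype=float)
        # start row supported exactly on the initial reactions
        self.pheromone[0, :] = 0.0
        for r in self.initial_reactions:
            self.pheromone[0, problem.universe.position(r.id)] = 1.0
        self.best_pathway: Optional[Pathway] = None
        self.best_cost: Optional[CostBreakdown] = None
        self.history: list[dict] = []

    def row_for(self, reaction: Optional[Reaction]) -> np.ndarray:
        """Pheromone row out of ``reaction`` (None = virtual start)."""
        if reaction is None:
            return self.pheromone[0]
        return self.pheromone[self.problem.universe.position(reaction.id) + 1]


def init_colony(problem: SearchProblem, params: AcoParams) -> ColonyState:
    """Build the start-reaction list and the all-ones pheromone matrix."""
    if not problem.initial_candidates:
        raise ValueError("initial_candidates must be non-empty")
    return ColonyState(problem, params)


def select_reaction(
    weights: Sequence[float],
    candidates: Sequence[Reaction],
    rng: np.random.Generator,
) -> Reaction:
    """Sample one candidate with probability proportional to its
    pheromone weight."""
    if not candidates:
        raise ValueError("cannot select from an empty candidate list")
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != len(candidates):
        raise ValueError("one weight per candidate required")
    if np.any(w <= 0.0):
        raise ValueError("pheromone weights must be strictly positive")
    idx = rng.choice(len(candidates), p=w / w.sum())
    return candidates[idx]


def ant_walk(
    problem: SearchProblem,
    colony: ColonyState,
    params: AcoParams,
    rng: np.random.Generator,
) -> Pathway:
    """One ant's raw walk (possibly failing to reach the goal)."""
    universe = problem.universe
    max_steps = params.max_steps if params.max_steps is not None else len(universe)

    start_weights = [
        colony.pheromone[0, universe.position(r.id)]
        for r in colony.initial_reactions
    ]
    first = select_reaction(start_weights, colony.initial_reactions, rng)
    available = set(first.substrates | first.products | problem.free_compounds)
    walk: list[Reaction] = [first]
    used = {first.id}

    while len(walk) < max_steps and not problem.targets <= available:
        feasible = [
            r
            for r in universe
            if r.id not in used and r.substrates <= available
        ]
        if not feasible:
            break
        row = colony.row_for(walk[-1])
        weights = [row[universe.position(r.id)] for r in feasible]
        chosen = select_reaction(weights, feasible, rng)
        walk.append(chosen)
        used.add(chosen.id)
        available |= chosen.products
    return Pathway(tuple(walk))


def evaporate(colony: ColonyState, rho: float) -> None:
    """Multiply every pheromone entry by (1 − ρ); entries stay > 0."""
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie strictly between 0 and 1")
    colony.pheromone *= 1.0 - rho


def deposit(
    colony: ColonyState, cleaned: Pathway, total_cost: float
) -> None:
    """Reinforce the start entry and every consecutive pair of the
    cleaned pathway by 1/f; an empty pathway deposits nothing."""
    if not cleaned:
        return
    if total_cost <= 0:
        raise ValueError("cost must be positive")
    universe = colony.problem.universe
    amount = 1.0 / total_cost
    cols = [universe.position(r.id) for r in cleaned]
    colony.pheromone[0, cols[0]] += amount
    for i in range(len(cols) - 1):
        colony.pheromone[cols[i] + 1, cols[i + 1]] += amount


@dataclass
class AcoResult:
    pathway: Pathway
    cost: Optional[CostBreakdown]
    complete: bool
    iterations: int
    history: list[dict] = field(default_factory=list)


def run(problem: SearchProblem, params: AcoParams) -> AcoResult:
    """Full colony loop: walk, clean, cost, evaporate, deposit, track
    the best, stop on stall or the iteration cap.  Reproducible for a
    given (problem, params, seed)."""
    rng = np.random.default_rng(params.seed)
    colony = init_colony(problem, params)
    alpha = params.effective_alpha()
    free = problem.free_compounds
    targets = problem.targets

    stall = 0
    iterations_done = 0
    for iteration in range(params.max_iterations):
        iterations_done = iteration + 1
        improved = False
        totals: list[float] = []
        cleaned_with_cost: list[tuple[Pathway, CostBreakdown]] = []
        for _ in range(params.n_ants):
            walk = ant_walk(problem, colony, params, rng)
            cleaned = clean_pathway(walk, targets, free)
            if not cleaned:
                continue
            breakdown = cost(cleaned, targets, free, alpha)
            cleaned_with_cost.append((cleaned, breakdown))
            totals.append(breakdown.total)
            if (
                colony.best_cost is None
                or breakdown.total < colony.best_cost.total
            ):
                colony.best_pathway = cleaned
                colony.best_cost = breakdown
                improved = True
        evaporate(colony, params.rho)
        for cleaned, breakdown in cleaned_with_cost:
            deposit(colony, cleaned, breakdown.total)
        colony.history.append(
            {
                "iteration": iteration,
                "best_cost": (
                    colony.best_cost.total if colony.best_cost else math.nan
                ),
                "mean_cost": float(np.mean(totals)) if totals else math.nan,
            }
        )
        stall = 0 if improved else stall + 1
        if colony.best_cost is not None and stall >= params.stall_iterations:
            break

    best = colony.best_pathway if colony.best_pathway is not None else Pathway()
    complete = colony.best_cost is not None and colony.best_cost.kappa == 1.0
    return AcoResult(
        pathway=best,
        cost=colony.best_cost,
        complete=complete,
        iterations=iterations_done,
        history=colony.history,
    )
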