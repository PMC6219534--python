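"""Pathway cleaning, cost components, connectivity, branching factor and
reference-pathway agreement measures.

The cost of a cleaned pathway π̂ combines four characteristics:

* its length ``|π̂|``,
* the number of *unique* reactions φ — distinct underlying reactions,
  counted by parent id so that using a reversible reaction in both
  directions is penalized,
* the number of *productive* reactions ϕ — positions whose products
  include at least one compound that is neither freely available nor
  produced by an earlier step,
* the connectivity κ ∈ {1, α} — whether every target is synthesized in
  a consumption chain reachable from the initial substrate.

These are combined as ``f(π̂) = κ · (3|π̂| − φ − ϕ)``, which reduces to
``κ·|π̂|`` when every reaction is unique and productive (pure
shortest-path pressure), adds +2 per fully redundant reaction, and with
``α ≫ 1`` makes any complete solution cheaper than any partial one of
length up to α/3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .reaction_net import Pathway

__all__ = [
    "CostBreakdown",
    "ComparisonReport",
    "clean_pathway",
    "count_unique",
    "count_productive",
    "connectivity",
    "cost",
    "branching_factor",
    "compare_to_reference",
]


@dataclass(frozen=True)
class CostBreakdown:
    length: int
    n_unique: int
    n_productive: int
    kappa: float
    total: float


@dataclass(frozen=True)
class ComparisonReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    accuracy: float
    level: str


def clean_pathway(
    pathway: Pathway,
    targets: Iterable[str],
    free_compounds: Iterable[str] = (),
) -> Pathway:
    """Remove, until fixpoint, every reaction whose non-free products
    contain no target and feed no retained later reaction.

    The result keeps the original order, is idempotent, and remains
    feasibility-replayable from the same initial available set: a
    removed reaction's non-free products were, by the rule, consumed by
    no retained reaction.
    """
    targets = frozenset(targets)
    free = frozenset(free_compounds)
    kept = list(pathway.reactions)
    changed = True
    while changed:
        changed = False
        # back-to-front so downstream removals are seen in the same sweep
        for i in range(len(kept) - 1, -1, -1):
            r = kept[i]
            useful = r.products - free
            if useful & targets:
                continue
            if any(useful & later.substrates for later in kept[i + 1 :]):
                continue
            del kept[i]
            changed = True
    return Pathway(tuple(kept))


def count_unique(pathway: Pathway) -> int:
    """Distinct underlying reactions (by parent id): the forward and
    backward halves of one reversible reaction count once."""
    return len(set(pathway.parent_ids))


def count_productive(
    pathway: Pathway, free_compounds: Iterable[str] = ()
) -> int:
    """Positions whose products include a compound neither free nor
    produced by any earlier step."""
    free = frozenset(free_compounds)
    produced: set[str] = set()
    n = 0
    for r in pathway:
        if (r.products - produced) - free:
            n += 1
        produced |= r.products
    return n


def connectivity(
    pathway: Pathway,
    targets: Iterable[str],
    free_compounds: Iterable[str],
    alpha: float,
) -> float:
    """κ: 1 if all targets lie in the compound set X grown from the
    first reaction along the consumption chain, else the penalty α.

    X starts from the initial substrate(s) of the first reaction that
    are targets, together with the first reaction's non-free products;
    each later reaction extends X with its non-free products only if it
    consumes something already in X.
    """
    targets = frozenset(targets)
    free = frozenset(free_compounds)
    if not pathway:
        raise ValueError("connectivity of an empty pathway is undefined")
    if not targets:
        raise ValueError("connectivity requires a non-empty target set")
    first = pathway[0]
    x = (first.substrates & targets) | (first.products - free)
    for r in pathway.reactions[1:]:
        if x & r.substrates:
            x = x | (r.products - free)
    return 1.0 if targets <= x else float(alpha)


def cost(
    pathway: Pathway,
    targets: Iterable[str],
    free_compounds: Iterable[str],
    alpha: float,
) -> CostBreakdown:
    """Total pathway cost f(π̂) = κ·(3|π̂| − φ − ϕ) with its components."""
    if not pathway:
        raise ValueError("cost of an empty pathway is undefined")
    length = len(pathway)
    n_unique = count_unique(pathway)
    n_productive = count_productive(pathway, free_compounds)
    kappa = connectivity(pathway, targets, free_compounds, alpha)
    total = kappa * (3 * length - n_unique - n_productive)
    return CostBreakdown(length, n_unique, n_productive, kappa, total)


def branching_factor(
    pathway: Pathway, free_compounds: Iterable[str] = ()
) -> float:
    """Average number of pathway reactions consuming each non-free
    substrate; > 1 signals a branched (non-linear) topology."""
    free = frozenset(free_compounds)
    if not pathway:
        raise ValueError("branching factor of an empty pathway is undefined")
    substrates = frozenset(
        s for r in pathway for s in r.substrates
    ) - free
    if not substrates:
        raise ValueError(
            "branching factor undefined: every substrate is freely available"
        )
    uses = sum(
        1 for s in substrates for r in pathway if s in r.substrates
    )
    return uses / len(substrates)


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def compare_to_reference(
    pathway: Pathway,
    reference: Pathway,
    level: str,
    free_compounds: Iterable[str] = (),
    include_free: bool = False,
) -> ComparisonReport:
    """TP/FP/FN and precision/recall/accuracy against a reference
    pathway, at the ``reactions`` level (parent ids) or the
    ``compounds`` level (all substrates and products; free compounds
    excluded from both sides unless ``include_free``)."""
    if not reference:
        raise ValueError("reference pathway must be non-empty")
    if level == "reactions":
        synth: frozenset[str] = frozenset(pathway.parent_ids)
        ref: frozenset[str] = frozenset(reference.parent_ids)
    elif level == "compounds":
        synth = pathway.compounds()
        ref = reference.compounds()
        if not include_free:
            free = frozenset(free_compounds)
            synth -= free
            ref -= free
    else:
        raise ValueError("level must be 'compounds' or 'reactions'")
    tp = len(synth & ref)
    fp = len(synth - ref)
    fn = len(ref - synth)
    pr = _ratio(tp, tp + fp)
    rc = _ratio(tp, tp + fn)
    return ComparisonReport(tp, fp, fn, pr, rc, (pr + rc) / 2, level)
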