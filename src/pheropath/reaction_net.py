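"""Domain types for compounds, reactions and reaction universes, plus
readers/writers for the reaction-table and pathway formats.

A reaction is a directed transformation between two compound *sets*:
stoichiometric coefficients are accepted on input but discarded, because
every downstream computation (feasibility, novelty, connectivity,
branching) is defined on sets.  A reversible biochemical reaction is
modelled as a pair of independent directed reactions with opposite
direction that share a ``parent_id``; the backward half carries a
``_rev`` suffix so both ids stay unique while the underlying database id
remains recoverable.

The on-disk reaction table is a TSV, one record per line::

    id <TAB> substrates <TAB> products <TAB> direction

where ``substrates``/``products`` are ``+``-separated compound ids with
an optional integer coefficient prefix (``2 C00002``), ``direction`` is
``forward`` or ``reversible``, and ``#`` starts a comment.  A JSON
equivalent with the same fields is accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import networkx as nx

from .errors import ReactionTableParseError, UniverseLoadError

__all__ = [
    "Reaction",
    "ReactionUniverse",
    "SearchProblem",
    "Pathway",
    "parse_reaction_table",
    "split_reversible",
    "write_reaction_table",
    "write_pathway",
    "read_pathway_json",
    "read_free_compounds",
]

REV_SUFFIX = "_rev"

_DIRECTIONS = frozenset({"forward", "reversible"})


@dataclass(frozen=True)
class Reaction:
    """One directed transformation S(r) -> P(r).

    ``parent_id`` links the forward and backward halves of a reversible
    reaction; for an irreversible reaction it equals ``id``.
    """

    id: str
    substrates: frozenset[str]
    products: frozenset[str]
    parent_id: str = ""

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise UniverseLoadError(
                f"reaction {self.id!r}: substrates and products must be non-empty"
            )
        if self.substrates == self.products:
            raise UniverseLoadError(
                f"reaction {self.id!r}: substrates == products; "
                "it can never produce a new compound"
            )
        if not self.parent_id:
            object.__setattr__(self, "parent_id", self.id)

    def reverse(self, id_suffix: str = REV_SUFFIX) -> "Reaction":
        """The opposite-direction reaction, sharing this one's parent_id."""
        return Reaction(
            id=self.id + id_suffix,
            substrates=self.products,
            products=self.substrates,
            parent_id=self.parent_id,
        )

    def __repr__(self) -> str:  # compact, for test diagnostics
        subs = "+".join(sorted(self.substrates))
        prods = "+".join(sorted(self.products))
        return f"<{self.id}: {subs} -> {prods}>"


class ReactionUniverse:
    """An ordered, duplicate-free collection of reactions.

    Order matters: the exhaustive searchers expand children in universe
    order, and the pheromone matrix indexes reactions by position.
    """

    def __init__(self, reactions: Iterable[Reaction]):
        self._reactions: tuple[Reaction, ...] = tuple(reactions)
        self._index: dict[str, int] = {}
        for pos, r in enumerate(self._reactions):
            if r.id in self._index:
                raise UniverseLoadError(f"duplicate reaction id {r.id!r}")
            self._index[r.id] = pos
        self.compounds: frozenset[str] = frozenset(
            c for r in self._reactions for c in r.substrates | r.products
        )

    @property
    def reactions(self) -> tuple[Reaction, ...]:
        return self._reactions

    def __len__(self) -> int:
        return len(self._reactions)

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self._reactions)

    def __getitem__(self, rid: str) -> Reaction:
        return self._reactions[self._index[rid]]

    def __contains__(self, rid: str) -> bool:
        return rid in self._index

    def position(self, rid: str) -> int:
        """Stable 0-based position of a reaction, used to index pheromone."""
        return self._index[rid]


@dataclass(frozen=True)
class SearchProblem:
    """The four inputs of a pathway-synthesis search.

    targets
        Compounds the synthesized pathway must relate (goal test is
        ``targets ⊆ available``).
    initial_candidates
        Subset of targets usable as the initial substrate.
    free_compounds
        Ubiquitous metabolites (water, ATP, ...) assumed present without
        synthesis; excluded from novelty/connectivity/branching.
    """

    universe: ReactionUniverse
    targets: frozenset[str]
    initial_candidates: frozenset[str]
    free_compounds: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", frozenset(self.targets))
        object.__setattr__(
            self, "initial_candidates", frozenset(self.initial_candidates)
        )
        object.__setattr__(self, "free_compounds", frozenset(self.free_compounds))
        if not self.targets:
            raise ValueError("targets must be non-empty")
        if not self.initial_candidates <= self.targets:
            raise ValueError("initial_candidates must be a subset of targets")
        if self.targets & self.free_compounds:
            raise ValueError(
                "a freely available compound cannot be a synthesis target: "
                f"{sorted(self.targets & self.free_compounds)}"
            )
        missing = {
            t
            for t in self.targets
            if not any(
                t in r.substrates or t in r.products for r in self.universe
            )
        }
        if missing:
            raise ValueError(
                f"targets absent from every reaction: {sorted(missing)}"
            )


@dataclass(frozen=True)
class Pathway:
    """An ordered reaction sequence; every prefix is substrate-feasible
    from the initial available set it was built from."""

    reactions: tuple[Reaction, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactions", tuple(self.reactions))

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self.reactions)

    def __getitem__(self, i):
        return self.reactions[i]

    def __bool__(self) -> bool:
        return bool(self.reactions)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def parent_ids(self) -> tuple[str, ...]:
        return tuple(r.parent_id for r in self.reactions)

    def compounds(self) -> frozenset[str]:
        return frozenset(
            c for r in self.reactions for c in r.substrates | r.products
        )

    def replay(self, initial_available: Iterable[str]) -> frozenset[str]:
        """Re-apply the sequence from ``initial_available``; raises
        FeasibilityError if any step's substrates are missing.  Returns
        the final available set."""
        from .errors import FeasibilityError

        available = set(initial_available)
        for i, r in enumerate(self.reactions):
            if not r.substrates <= available:
                raise FeasibilityError(
                    f"step {i} ({r.id}): substrates "
                    f"{sorted(r.substrates - available)} unavailable"
                )
            available |= r.products
        return frozenset(available)


# ---------------------------------------------------------------------------
# parsing


def _parse_compound_field(text: str, line_no: int) -> frozenset[str]:
    compounds = set()
    for token in text.split("+"):
        token = token.strip()
        if not token:
            raise ReactionTableParseError("empty compound token", line_no)
        parts = token.split()
        if len(parts) == 2 and parts[0].isdigit():
            token = parts[1]  # coefficient discarded
        elif len(parts) != 1:
            raise ReactionTableParseError(
                f"malformed compound token {token!r}", line_no
            )
        compounds.add(token)
    return frozenset(compounds)


def split_reversible(
    rid: str,
    substrates: frozenset[str],
    products: frozenset[str],
    direction: str,
) -> list[Reaction]:
    """Expand one tabular record into one (forward) or two (reversible)
    directed reactions; the reversible pair shares the record id as
    parent_id and the backward id gets the ``_rev`` suffix."""
    if direction not in _DIRECTIONS:
        raise ReactionTableParseError(
            f"direction must be one of {sorted(_DIRECTIONS)}, got {direction!r}"
        )
    forward = Reaction(id=rid, substrates=substrates, products=products)
    if direction == "forward":
        return [forward]
    return [forward, forward.reverse()]


def parse_reaction_table(
    source: IO[str] | str, dialect: str = "tsv"
) -> ReactionUniverse:
    """Read a reaction table (``tsv`` or ``json`` dialect) into a
    universe, splitting every reversible record into its two directed
    halves.  Line numbers are reported on parse errors."""
    if isinstance(source, str):
        from io import StringIO

        source = StringIO(source)
    if dialect == "json":
        records = json.load(source)
        reactions: list[Reaction] = []
        for rec in records:
            subs = frozenset(rec["substrates"])
            prods = frozenset(rec["products"])
            reactions.extend(
                split_reversible(rec["id"], subs, prods, rec["direction"])
            )
        return ReactionUniverse(reactions)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    reactions = []
    for line_no, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ReactionTableParseError(
                f"expected 4 tab-separated fields, got {len(fields)}", line_no
            )
        rid, subs_text, prods_text, direction = (f.strip() for f in fields)
        if not rid:
            raise ReactionTableParseError("empty reaction id", line_no)
        if direction not in _DIRECTIONS:
            raise ReactionTableParseError(
                f"direction must be one of {sorted(_DIRECTIONS)}, "
                f"got {direction!r}",
                line_no,
            )
        subs = _parse_compound_field(subs_text, line_no)
        prods = _parse_compound_field(prods_text, line_no)
        try:
            reactions.extend(split_reversible(rid, subs, prods, direction))
        except UniverseLoadError as exc:
            raise UniverseLoadError(f"line {line_no}: {exc}") from exc
    return ReactionUniverse(reactions)


def read_free_compounds(source: IO[str] | str) -> frozenset[str]:
    """One compound id per line; ``#`` comments and blanks ignored."""
    if isinstance(source, str):
        from io import StringIO

        source = StringIO(source)
    out = set()
    for raw in source:
        line = raw.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


# ---------------------------------------------------------------------------
# writing


def write_reaction_table(universe: ReactionUniverse, sink: IO[str]) -> None:
    """Emit the TSV reaction table.  Directed pairs sharing a parent_id
    are merged back into a single ``reversible`` record (forward
    orientation first), so ``parse(write(u))`` reproduces ids and
    compound sets exactly."""
    by_parent: dict[str, list[Reaction]] = {}
    order: list[str] = []
    for r in universe:
        if r.parent_id not in by_parent:
            order.append(r.parent_id)
        by_parent.setdefault(r.parent_id, []).append(r)
    for pid in order:
        group = by_parent[pid]
        if len(group) == 2:
            fwd = next(r for r in group if r.id == pid)
            sink.write(
                f"{fwd.id}\t{'+'.join(sorted(fwd.substrates))}\t"
                f"{'+'.join(sorted(fwd.products))}\treversible\n"
            )
        else:
            (r,) = group
            sink.write(
                f"{r.id}\t{'+'.join(sorted(r.substrates))}\t"
                f"{'+'.join(sorted(r.products))}\tforward\n"
            )


def _pathway_graph(pathway: Pathway, free: frozenset[str]) -> nx.DiGraph:
    g = nx.DiGraph()
    for r in pathway:
        g.add_node(r.id, kind="reaction")
        for s in r.substrates:
            g.add_node(s, kind="compound", free=s in free)
            g.add_edge(s, r.id)
        for p in r.products:
            g.add_node(p, kind="compound", free=p in free)
            g.add_edge(r.id, p)
    return g


def _to_dot(pathway: Pathway, free: frozenset[str]) -> str:
    lines = ["digraph pathway {", "  rankdir=LR;"]
    compounds = pathway.compounds()
    for c in sorted(compounds):
        style = (
            'shape=ellipse, style=dashed, color=gray, label="%s (free)"' % c
            if c in free
            else "shape=ellipse"
        )
        lines.append(f'  "{c}" [{style}];')
    for r in pathway:
        lines.append(f'  "{r.id}" [shape=box];')
    for r in pathway:
        for s in sorted(r.substrates):
            lines.append(f'  "{s}" -> "{r.id}";')
        for p in sorted(r.products):
            lines.append(f'  "{r.id}" -> "{p}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_pathway(
    pathway: Pathway,
    problem: SearchProblem,
    sink: IO[str],
    format: str = "json",
    cost_breakdown=None,
) -> None:
    """Serialize a non-empty pathway.

    ``json``: ordered reactions with per-step newly produced compounds
    and the cost breakdown if given.  ``dot``/``graphml``: bipartite
    compound/reaction graph with free compounds flagged.
    """
    if not pathway:
        raise ValueError("cannot write an empty pathway")
    free = problem.free_compounds
    if format == "json":
        produced: set[str] = set()
        steps = []
        for r in pathway:
            new = sorted((r.products - produced) - free)
            produced |= r.products
            steps.append(
                {
                    "id": r.id,
                    "parent_id": r.parent_id,
                    "substrates": sorted(r.substrates),
                    "products": sorted(r.products),
                    "new_compounds": new,
                }
            )
        doc = {
            "reactions": steps,
            "targets": sorted(problem.targets),
            "free_compounds": sorted(free),
        }
        if cost_breakdown is not None:
            doc["cost"] = {
                "length": cost_breakdown.length,
                "n_unique": cost_breakdown.n_unique,
                "n_productive": cost_breakdown.n_productive,
                "kappa": cost_breakdown.kappa,
                "total": cost_breakdown.total,
            }
        json.dump(doc, sink, indent=2)
        sink.write("\n")
    elif format == "dot":
        sink.write(_to_dot(pathway, free))
    elif format == "graphml":
        g = _pathway_graph(pathway, free)
        for line in nx.generate_graphml(g):
            sink.write(line + "\n")
    else:
        raise ValueError(f"unknown pathway format {format!r}")


def read_pathway_json(source: IO[str] | str) -> Pathway:
    """Reconstruct a Pathway from its JSON serialization."""
    if isinstance(source, str):
        from io import StringIO

        source = StringIO(source)
    doc = json.load(source)
    return Pathway(
        tuple(
            Reaction(
                id=step["id"],
                substrates=frozenset(step["substrates"]),
                products=frozenset(step["products"]),
                parent_id=step.get("parent_id", step["id"]),
            )
            for step in doc["reactions"]
        )
    )
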