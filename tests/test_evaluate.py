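"""Cleaning, cost components, connectivity, branching factor, and
reference-agreement measures, checked against hand traces and
independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from pheropath import (
    Pathway,
    Reaction,
    branching_factor,
    clean_pathway,
    compare_to_reference,
    connectivity,
    cost,
    make_random_problem,
)
from pheropath.evaluate import count_productive, count_unique
from pheropath.soc import SocState, apply_reaction, feasible_reactions

from conftest import connectivity_oracle

TARGETS = frozenset({"A", "C", "D"})
FREE = frozenset({"P"})


class TestClean:
    def test_removes_unconsumed_nontarget_tail(self, u1):
        pw = Pathway((u1["r1"], u1["r2"], u1["r3"], u1["r4"]))
        assert clean_pathway(pw, TARGETS, FREE).ids == ("r1", "r2", "r3")

    def test_idempotent_on_clean_input(self, u1):
        pw = Pathway((u1["r1"], u1["r2"], u1["r3"]))
        once = clean_pathway(pw, TARGETS, FREE)
        assert once.ids == pw.ids
        assert clean_pathway(once, TARGETS, FREE).ids == once.ids

    def test_removes_reaction_producing_only_free_compounds(self, u1):
        r5 = Reaction("r5", frozenset("C"), frozenset("P"))
        pw = Pathway((u1["r1"], u1["r2"], r5))
        assert clean_pathway(pw, {"A", "C"}, FREE).ids == ("r1", "r2")

    def test_cascading_removal_reaches_fixpoint(self, u1):
        # r4 feeds r6 whose product is neither target nor consumed:
        # removing r6 must then expose r4 for removal too
        r6 = Reaction("r6", frozenset("E"), frozenset("F"))
        pw = Pathway((u1["r1"], u1["r2"], u1["r3"], u1["r4"], r6))
        assert clean_pathway(pw, TARGETS, FREE).ids == ("r1", "r2", "r3")

    def test_cleaned_goal_pathway_still_reaches_goal(self, u1):
        pw = Pathway((u1["r1"], u1["r2"], u1["r3"], u1["r4"]))
        cleaned = clean_pathway(pw, TARGETS, FREE)
        assert TARGETS <= cleaned.replay({"A", "P"})


class TestCounts:
    def test_unique_all_distinct(self, u1):
        assert count_unique(Pathway((u1["r1"], u1["r2"], u1["r3"]))) == 3

    def test_unique_collapses_direction_pair(self):
        fwd = Reaction("rX", frozenset("A"), frozenset("B"))
        assert count_unique(Pathway((fwd, fwd.reverse()))) == 1

    def test_unique_empty(self):
        assert count_unique(Pathway()) == 0

    def test_productive_fresh_chain(self, u1):
        pw = Pathway((u1["r1"], u1["r2"], u1["r3"]))
        assert count_productive(pw, FREE) == 3

    def test_duplicate_producer_not_productive(self):
        a = Reaction("ra", frozenset("A"), frozenset("B"))
        b = Reaction("rb", frozenset("C"), frozenset("B"))
        assert count_productive(Pathway((a, b)), FREE) == 1

    def test_free_only_products_not_productive(self):
        r5 = Reaction("r5", frozenset("C"), frozenset("P"))
        assert count_productive(Pathway((r5,)), FREE) == 0


class TestConnectivity:
    def test_complete_chain(self, u1):
        pw = Pathway((u1["r1"], u1["r2"], u1["r3"]))
        assert connectivity(pw, TARGETS, FREE, alpha=100) == 1

    def test_partial_pathway_pays_alpha(self, u1):
        pw = Pathway((u1["r1"], u1["r2"]))
        assert connectivity(pw, TARGETS, FREE, alpha=100) == 100

    def test_sole_target_is_initial_substrate(self, u1):
        assert connectivity(Pathway((u1["r1"],)), {"A"}, FREE, alpha=100) == 1

    def test_disconnected_second_step_not_propagated(self):
        # second reaction consumes nothing produced so far: its products
        # must not count towards connectivity
        a = Reaction("ra", frozenset("A"), frozenset("B"))
        b = Reaction("rb", frozenset("Q"), frozenset("D"))
        pw = Pathway((a, b))
        assert connectivity(pw, {"A", "D"}, frozenset(), alpha=50) == 50

    @pytest.mark.parametrize("what", ["empty_pathway", "empty_targets"])
    def test_degenerate_inputs_rejected(self, u1, what):
        pw = Pathway() if what == "empty_pathway" else Pathway((u1["r1"],))
        targets = TARGETS if what == "empty_pathway" else frozenset()
        with pytest.raises(ValueError):
            connectivity(pw, targets, FREE, alpha=100)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_graph_reachability_oracle(self, seed):
        """κ == 1 exactly when all targets are reachable from the seed
        set over the order-respecting consumed-by relation."""
        problem = make_random_problem(seed=seed, n_reactions=9, n_compounds=8)
        rng = np.random.default_rng(seed)
        state = SocState(problem.initial_candidates | problem.free_compounds)
        for _ in range(int(rng.integers(1, 7))):
            feas = feasible_reactions(state, problem.universe)
            if not feas:
                break
            state = apply_reaction(state, feas[rng.integers(len(feas))])
        pw = state.pathway
        # a reachable extra target exists by construction, so at least
        # one reaction is feasible at the root
        assert pw
        kappa = connectivity(
            pw, problem.targets, problem.free_compounds, alpha=100
        )
        expected = connectivity_oracle(
            pw, problem.targets, problem.free_compounds
        )
        assert (kappa == 1) is expected


class TestCost:
    def test_ideal_pathway_costs_its_length(self, u1):
        bd = cost(Pathway((u1["r1"], u1["r2"], u1["r3"])), TARGETS, FREE, 100)
        assert (bd.length, bd.n_unique, bd.n_productive, bd.kappa) == (3, 3, 3, 1)
        assert bd.total == 3

    def test_partial_pathway_scaled_by_alpha(self, u1):
        bd = cost(Pathway((u1["r1"], u1["r2"])), TARGETS, FREE, 100)
        assert (bd.length, bd.n_unique, bd.n_productive, bd.kappa) == (2, 2, 2, 100)
        assert bd.total == 200

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            cost(Pathway(), TARGETS, FREE, 100)

    def test_redundant_reaction_strictly_increases_total(self, u1):
        fwd = Reaction("rX", frozenset("B"), frozenset({"A", "B"}))
        base = Pathway((u1["r1"], u1["r2"], u1["r3"]))
        padded = Pathway(base.reactions + (fwd, fwd.reverse()))
        assert (
            cost(padded, TARGETS, FREE, 100).total
            > cost(base, TARGETS, FREE, 100).total
        )

    def test_complete_beats_partial_for_large_alpha(self, u1):
        """With α ≫ 1 any complete solution costs less than any partial
        one of length up to α/3 — the pressure towards completeness."""
        complete = cost(Pathway((u1["r1"], u1["r2"], u1["r3"])), TARGETS, FREE, 100)
        partial = cost(Pathway((u1["r1"],)), TARGETS, FREE, 100)
        assert complete.total < partial.total


class TestBranching:
    def test_branched_chain(self, u1):
        pw = Pathway((u1["r1"], u1["r2"], u1["r3"]))
        assert branching_factor(pw, FREE) == 1.5  # A once, B twice

    def test_linear_chain(self, u1):
        assert branching_factor(Pathway((u1["r1"], u1["r2"])), FREE) == 1.0

    def test_free_substrate_filtered(self, u1):
        pw = Pathway((u1["r1"], u1["r2"], u1["r4"]))
        assert branching_factor(pw, FREE) == 1.0  # P filtered; A,B,C once

    def test_all_free_substrates_undefined(self):
        r = Reaction("r", frozenset("P"), frozenset("Q"))
        with pytest.raises(ValueError):
            branching_factor(Pathway((r,)), FREE)

    def test_at_least_one(self, u1):
        for ids in (("r1",), ("r1", "r2"), ("r1", "r2", "r3")):
            pw = Pathway(tuple(u1[i] for i in ids))
            assert branching_factor(pw, FREE) >= 1.0


class TestCompare:
    def _pw(self, *ids):
        return Pathway(
            tuple(
                Reaction(i, frozenset({f"s{i}"}), frozenset({f"p{i}"}))
                for i in ids
            )
        )

    def test_identical_pathways_score_one(self):
        pw = self._pw("r1", "r2")
        rep = compare_to_reference(pw, pw, "reactions")
        assert (rep.precision, rep.recall, rep.accuracy) == (1.0, 1.0, 1.0)

    def test_half_overlap(self):
        rep = compare_to_reference(
            self._pw("r1", "r2"), self._pw("r1", "r3"), "reactions"
        )
        assert (rep.tp, rep.fp, rep.fn) == (1, 1, 1)
        assert (rep.precision, rep.recall, rep.accuracy) == (0.5, 0.5, 0.5)

    def test_disjoint_pathways_score_zero(self):
        rep = compare_to_reference(
            self._pw("r1", "r2"), self._pw("r3", "r4"), "compounds"
        )
        assert (rep.precision, rep.recall, rep.accuracy) == (0.0, 0.0, 0.0)

    def test_reaction_level_uses_parent_ids(self):
        fwd = Reaction("rX", frozenset("A"), frozenset("B"))
        rep = compare_to_reference(
            Pathway((fwd.reverse(),)), Pathway((fwd,)), "reactions"
        )
        assert rep.precision == rep.recall == 1.0

    def test_free_compounds_excluded_by_default(self, u1):
        synth = Pathway((u1["r4"],))  # compounds C, P, E
        ref = Pathway((Reaction("q", frozenset("C"), frozenset("E")),))
        with_free = compare_to_reference(synth, ref, "compounds", FREE, include_free=True)
        without = compare_to_reference(synth, ref, "compounds", FREE)
        assert without.precision == 1.0 and with_free.precision < 1.0

    def test_empty_reference_rejected(self, u1):
        with pytest.raises(ValueError):
            compare_to_reference(Pathway((u1["r1"],)), Pathway(), "reactions")
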