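"""ILP model construction, optimality, directives, lineage extraction."""

import numpy as np
import pytest

from mmtrack.hypotheses import Assignment, HypothesisForest, SegmentHypothesis
from mmtrack.tracking import (Directive, DirectiveError, SizeError,
                              apply_directive, best_of_selections, brute_force_solve,
                              build_model, extract_lineage, feasible_selections,
                              filter_selections, random_instance, resolve_pixel,
                              solve, verify_solution)


def chain_instance(T=3, map_cost=0.1, seg_cost=-1.0, exit_cost=0.5):
    """One hypothesis per frame, mapping + exit per frame pair."""
    forests = [HypothesisForest(frame=t, hypotheses=[
        SegmentHypothesis(id=0, frame=t, top=10, bottom=40, cost=seg_cost)])
        for t in range(T)]
    assignments = []
    for t in range(T - 1):
        assignments.append([
            Assignment(0, "mapping", t, 0, (0,), map_cost),
            Assignment(1, "exit", t, 0, (), exit_cost),
        ])
    return forests, assignments


def test_single_chain_selected_with_expected_variable_count():
    """Three frames, one hypothesis each: 2 mapping + 2 exit variables; the
    chain is selected when mappings are cheaper than exits."""
    forests, assignments = chain_instance()
    model = build_model(forests, assignments)
    assert model.n_vars == 4
    sol = solve(model)
    assert sol.optimal
    kinds = sorted(a.kind for a in sol.selected)
    assert kinds == ["mapping", "mapping"]
    # objective: 2 mapping costs + 3 segment costs
    assert sol.objective == pytest.approx(2 * 0.1 + 3 * (-1.0))
    verify_solution(model, sol)


def test_empty_instance_brute_force():
    forests, assignments = chain_instance(T=2)
    model = build_model(forests, [[]])
    sol = brute_force_solve(model)
    assert sol.optimal
    assert sol.objective == 0.0
    assert sol.selected == []


def test_model_rejects_dangling_references():
    forests, assignments = chain_instance()
    assignments[0][0] = Assignment(0, "mapping", 0, 5, (0,), 0.1)
    from mmtrack.tracking import ModelConstructionError
    with pytest.raises(ModelConstructionError):
        build_model(forests, assignments)


def test_constraint_count_matches_structure():
    """Equalities: one per internal-frame hypothesis; inequalities: one per
    containment path per frame."""
    for seed in range(10):
        forests, assignments, _ = random_instance(seed)
        model = build_model(forests, assignments)
        T = len(forests)
        n_internal = sum(len(forests[t]) for t in range(1, T - 1))
        # paths contribute a constraint only when some hypothesis on them has
        # at least one activity variable
        n_paths = sum(
            sum(1 for path in forests[t].paths()
                if any(model.activity(t, hid) for hid in path))
            for t in range(T))
        assert len(model.rows_eq) == n_internal
        assert len(model.rows_ub) == n_paths


def test_objective_equals_independent_cost_sum():
    """The model objective on any feasible selection equals the sum of
    selected assignment costs plus active segment costs, recomputed
    independently."""
    for seed in range(8):
        forests, assignments, _ = random_instance(seed)
        model = build_model(forests, assignments)
        X = feasible_selections(model)
        for x in X[:: max(1, len(X) // 20)]:
            assert model.costs @ x == pytest.approx(
                model.segment_costs_of_selection(x), abs=1e-9)


def test_solve_matches_brute_force_on_random_instances():
    for seed in range(40):
        forests, assignments, _ = random_instance(seed)
        model = build_model(forests, assignments)
        a = solve(model)
        b = brute_force_solve(model)
        assert a.status == b.status == "optimal"
        assert a.objective == pytest.approx(b.objective, abs=1e-6)
        verify_solution(model, a)


def test_continuity_on_every_solution():
    """Every active segment at an internal frame has exactly one incoming and
    one outgoing assignment."""
    for seed in (3, 17, 29):
        forests, assignments, _ = random_instance(seed)
        model = build_model(forests, assignments)
        sol = solve(model)
        T = len(forests)
        for t in range(1, T - 1):
            for h in sol.active_segments.get(t, []):
                inc = sum(sol.x[v] for v in model.gamma_L(t, h))
                out = sum(sol.x[v] for v in model.gamma_R(t, h))
                assert inc == 1 and out == 1


def test_directives_agree_with_oracle_and_are_monotone():
    for seed in range(12):
        forests, assignments, _ = random_instance(seed)
        model = build_model(forests, assignments)
        n_base = len(model.rows_eq)
        X = feasible_selections(model)
        base = best_of_selections(model, X)
        h0 = base.active_segments[0][0] if base.active_segments.get(0) else 0
        k1 = len(base.active_segments.get(1, [])) if len(forests) > 2 else None
        directives = [
            Directive(kind="force_segment", frame=0, hypothesis=h0),
            Directive(kind="ban_segment", frame=0, hypothesis=h0),
            Directive(kind="set_count", frame=0,
                      count=len(base.active_segments.get(0, []))),
            Directive(kind="clamp", window=(0, 0), previous=base),
        ]
        if k1 is not None:
            directives.append(Directive(kind="set_count", frame=1, count=k1))
        for d in directives:
            m2 = build_model(forests, assignments)
            apply_directive(m2, d)
            a = solve(m2)
            b = best_of_selections(m2, filter_selections(m2, X, n_base))
            assert a.status == b.status
            if a.optimal:
                assert a.objective == pytest.approx(b.objective, abs=1e-6)
                # adding a constraint can never decrease the optimum
                assert a.objective >= base.objective - 1e-9


def test_redundant_force_keeps_solution():
    forests, assignments = chain_instance()
    model = build_model(forests, assignments)
    base = solve(model)
    m2 = build_model(forests, assignments)
    apply_directive(m2, Directive(kind="force_segment", frame=1, hypothesis=0))
    again = solve(m2)
    assert again.objective == pytest.approx(base.objective)
    assert np.array_equal(again.x, base.x)


def test_contradictory_directives_are_infeasible_not_an_error():
    forests, assignments = chain_instance()
    model = build_model(forests, assignments)
    apply_directive(model, Directive(kind="force_segment", frame=1, hypothesis=0))
    apply_directive(model, Directive(kind="ban_segment", frame=1, hypothesis=0))
    sol = solve(model)
    assert sol.status == "infeasible"


def test_force_and_ban_assignment():
    forests, assignments = chain_instance()
    model = build_model(forests, assignments)
    # ban the first mapping: chain must break via exit
    apply_directive(model, Directive(kind="ban_assignment", assignment=0))
    sol = solve(model)
    kinds = sorted(a.kind for a in sol.selected)
    assert "exit" in kinds
    with pytest.raises(DirectiveError):
        apply_directive(model, Directive(kind="ban_assignment", assignment=99))


def test_unknown_directive_ids_raise():
    forests, assignments = chain_instance()
    model = build_model(forests, assignments)
    with pytest.raises(DirectiveError):
        apply_directive(model, Directive(kind="force_segment", frame=0, hypothesis=7))
    with pytest.raises(DirectiveError):
        apply_directive(model, Directive(kind="nonsense"))


def test_warm_start_objective_identical_to_cold():
    for seed in range(10):
        forests, assignments, _ = random_instance(seed)
        model = build_model(forests, assignments)
        cold = solve(model)
        warm = solve(build_model(forests, assignments), warm_start=cold)
        assert warm.objective == pytest.approx(cold.objective, abs=1e-9)


def test_brute_force_size_guard():
    forests, assignments, _ = random_instance(0)
    model = build_model(forests, assignments)
    with pytest.raises(SizeError):
        brute_force_solve(model, max_vars=0)


def test_resolve_pixel_picks_smallest_containing():
    f = HypothesisForest(frame=0, hypotheses=[
        SegmentHypothesis(0, 0, 10, 50), SegmentHypothesis(1, 0, 10, 30)])
    assert resolve_pixel(f, 15) == 1
    assert resolve_pixel(f, 40) == 0
    with pytest.raises(DirectiveError):
        resolve_pixel(f, 99)


# ---------------------------------------------------------------------------
# lineage extraction

def test_chain_without_division_single_cell():
    forests, assignments = chain_instance(T=4)
    model = build_model(forests, assignments)
    sol = solve(model)
    cells = extract_lineage(sol, forests)
    assert len(cells) == 1
    assert cells[0].frames == [0, 1, 2, 3]
    assert not cells[0].divided


def test_single_division_three_cells_two_parent_links():
    forests = [
        HypothesisForest(frame=0, hypotheses=[
            SegmentHypothesis(0, 0, 10, 50, cost=-1.0)]),
        HypothesisForest(frame=1, hypotheses=[
            SegmentHypothesis(0, 1, 10, 30, cost=-1.0),
            SegmentHypothesis(1, 1, 30, 50, cost=-1.0)]),
    ]
    assignments = [[
        Assignment(0, "division", 0, 0, (0, 1), 0.1),
        Assignment(1, "exit", 0, 0, (), 0.5),
    ]]
    model = build_model(forests, assignments)
    sol = solve(model)
    cells = extract_lineage(sol, forests)
    assert len(cells) == 3
    parents = sorted(c.parent_id for c in cells if c.parent_id is not None)
    assert parents == [0, 0]
    assert cells[0].divided
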