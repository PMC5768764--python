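"""Globally optimal tracking as an integer linear program.

Joint segmentation and tracking selects a conflict-free subset of assignment
variables of minimal total cost C = sum_i v_i c_vi. Segmentation variables
are eliminated by substitution: a segment h is active exactly when one
assignment in its right neighborhood Gamma_R(h) is selected (the left
neighborhood Gamma_L(h) for the last frame). Continuity demands that every
active segment at an internal frame has exactly one incoming and one outgoing
assignment ("a past and a future"); conflict constraints allow at most one
active hypothesis per root-to-leaf path of the containment forest. Curation
directives (force/ban a segment or assignment, fix the cell count of a frame,
clamp assignments outside an optimization window) each add one linear
constraint, so a single correction re-optimizes globally and propagates to
neighboring frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .hypotheses import (Assignment, HypothesisForest, HypothesisParams,
                         SegmentHypothesis, enumerate_assignments,
                         generate_hypotheses)


class ModelConstructionError(ValueError):
    pass


class DirectiveError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


class SizeError(ValueError):
    pass


@dataclass
class Directive:
    """One leveraged-editing primitive, expressed as a linear constraint.

    kind: 'force_segment' | 'ban_segment' | 'force_assignment' |
    'ban_assignment' | 'set_count' | 'clamp'.
    """

    kind: str
    frame: int | None = None
    hypothesis: int | None = None
    assignment: int | None = None     # global variable index
    count: int | None = None
    window: tuple[int, int] | None = None        # clamp: frames [ta, tb] stay free
    previous: "TrackingSolution | None" = None   # clamp: solution to freeze

    @classmethod
    def from_dict(cls, d: dict) -> "Directive":
        known = {"kind", "frame", "hypothesis", "assignment", "count", "window"}
        bad = set(d) - known
        if bad:
            raise DirectiveError(f"unknown directive fields: {sorted(bad)}")
        w = d.get("window")
        return cls(kind=d["kind"], frame=d.get("frame"),
                   hypothesis=d.get("hypothesis"), assignment=d.get("assignment"),
                   count=d.get("count"), window=tuple(w) if w else None)


@dataclass
class TrackingModel:
    """Binary program over assignment variables (built by :func:`build_model`)."""

    forests: list[HypothesisForest]
    assignments: list[list[Assignment]]          # per frame pair t -> t+1
    costs: np.ndarray                            # objective coefficient per variable
    rows_eq: list[tuple[dict[int, float], float]] = field(default_factory=list)
    rows_ub: list[tuple[dict[int, float], float]] = field(default_factory=list)
    n_directives: int = 0

    @property
    def n_vars(self) -> int:
        return self.costs.size

    @property
    def n_frames(self) -> int:
        return len(self.forests)

    def var(self, frame: int, local_idx: int) -> int:
        return self._offsets[frame] + local_idx

    def gamma_R(self, frame: int, hyp_id: int) -> list[int]:
        """Global variable indices of assignments leaving hypothesis hyp_id."""
        return self._gamma_R[frame].get(hyp_id, [])

    def gamma_L(self, frame: int, hyp_id: int) -> list[int]:
        """Global variable indices of assignments entering hypothesis hyp_id."""
        return self._gamma_L[frame].get(hyp_id, [])

    def activity(self, frame: int, hyp_id: int) -> list[int]:
        """Variables whose sum equals the segment's activation (substitution)."""
        if frame < self.n_frames - 1:
            return self.gamma_R(frame, hyp_id)
        return self.gamma_L(frame, hyp_id)

    def segment_costs_of_selection(self, x: np.ndarray) -> float:
        """Independent recomputation of C: selected assignment costs plus the
        cost of every active segment (used to assert objective consistency)."""
        total = 0.0
        for t, A in enumerate(self.assignments):
            for k, a in enumerate(A):
                if x[self.var(t, k)] > 0.5:
                    total += a.cost
                    total += self.forests[t][a.source].cost
                    if t == self.n_frames - 2:
                        total += sum(self.forests[t + 1][g].cost for g in a.targets)
        return total


@dataclass
class TrackingSolution:
    """Conflict-free, continuity-satisfying minimal-cost selection."""

    status: str                                  # 'optimal' | 'infeasible'
    x: np.ndarray | None
    objective: float | None
    selected: list[Assignment] = field(default_factory=list)
    active_segments: dict[int, list[int]] = field(default_factory=dict)  # frame -> hyp ids

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def build_model(forests: list[HypothesisForest],
                assignments: list[list[Assignment]] | None = None,
                params: HypothesisParams | None = None) -> TrackingModel:
    """Assemble the tracking ILP.

    Continuity is enforced at internal frames only: the first frame needs
    only its outgoing (right) constraint and the last only its incoming
    (left) one, both implied by the substitution. Conflict constraints are
    added per root-to-leaf path of every frame's forest. The objective
    coefficient of an assignment variable is its own cost plus the cost of
    its source segment (plus its targets' costs for the final frame pair),
    so the objective equals the summed cost of all active variables.
    """
    T = len(forests)
    if T < 2:
        raise ModelConstructionError("need forests for >= 2 frames")
    if assignments is None:
        params = params or HypothesisParams()
        assignments = [enumerate_assignments(forests[t], forests[t + 1], params)
                       for t in range(T - 1)]
    if len(assignments) != T - 1:
        raise ModelConstructionError(
            f"expected {T - 1} assignment lists, got {len(assignments)}")

    offsets = np.zeros(T - 1, dtype=int)
    n = 0
    for t, A in enumerate(assignments):
        offsets[t] = n
        n += len(A)

    costs = np.zeros(n)
    gamma_R: list[dict[int, list[int]]] = [dict() for _ in range(T)]
    gamma_L: list[dict[int, list[int]]] = [dict() for _ in range(T)]
    for t, A in enumerate(assignments):
        n_src = len(forests[t])
        n_tgt = len(forests[t + 1])
        for k, a in enumerate(A):
            v = offsets[t] + k
            if a.source >= n_src or any(g >= n_tgt for g in a.targets):
                raise ModelConstructionError(
                    f"assignment {a.id} references a missing hypothesis")
            c = a.cost + forests[t][a.source].cost
            if t == T - 2:
                c += sum(forests[t + 1][g].cost for g in a.targets)
            costs[v] = c
            gamma_R[t].setdefault(a.source, []).append(v)
            for g in a.targets:
                gamma_L[t + 1].setdefault(g, []).append(v)

    model = TrackingModel(forests=forests, assignments=assignments, costs=costs)
    model._offsets = offsets
    model._gamma_R = gamma_R
    model._gamma_L = gamma_L

    # continuity at internal frames: sum Gamma_L(h) - sum Gamma_R(h) = 0
    for t in range(1, T - 1):
        for h in forests[t].hypotheses:
            row: dict[int, float] = {}
            for v in model.gamma_L(t, h.id):
                row[v] = row.get(v, 0.0) + 1.0
            for v in model.gamma_R(t, h.id):
                row[v] = row.get(v, 0.0) - 1.0
            if row:
                model.rows_eq.append((row, 0.0))
    # conflicts: at most one active hypothesis per containment path
    for t in range(T):
        for path in forests[t].paths():
            row = {}
            for hid in path:
                for v in model.activity(t, hid):
                    row[v] = row.get(v, 0.0) + 1.0
            if row:
                model.rows_ub.append((row, 1.0))
    return model


def _constraints_matrices(model: TrackingModel):
    cons = []
    for rows, kind in ((model.rows_eq, "eq"), (model.rows_ub, "ub")):
        if not rows:
            continue
        data, ri, ci, rhs = [], [], [], []
        for r, (row, b) in enumerate(rows):
            rhs.append(b)
            for v, coef in row.items():
                ri.append(r)
                ci.append(v)
                data.append(coef)
        A = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), model.n_vars))
        rhs = np.array(rhs)
        if kind == "eq":
            cons.append(LinearConstraint(A, rhs, rhs))
        else:
            cons.append(LinearConstraint(A, -np.inf, rhs))
    return cons


def _selection_to_solution(model: TrackingModel, x: np.ndarray) -> TrackingSolution:
    selected = []
    active: dict[int, list[int]] = {t: [] for t in range(model.n_frames)}
    for t, A in enumerate(model.assignments):
        for k, a in enumerate(A):
            if x[model.var(t, k)] > 0.5:
                selected.append(a)
                if a.source not in active[t]:
                    active[t].append(a.source)
                for g in a.targets:
                    if g not in active[t + 1]:
                        active[t + 1].append(g)
    for t in active:
        active[t].sort()
    obj = float(model.costs @ x)
    return TrackingSolution(status="optimal", x=x.astype(int), objective=obj,
                            selected=selected, active_segments=active)


def solve(model: TrackingModel, warm_start: TrackingSolution | None = None,
          time_limit: float | None = None, mip_gap: float = 0.0) -> TrackingSolution:
    """Solve the tracking ILP to proven optimality (HiGHS branch-and-cut).

    ``warm_start`` is accepted as a feasibility hint from a previous solve;
    the returned objective is identical to a cold solve. ``mip_gap`` 0 means
    prove optimality.
    """
    if warm_start is not None and warm_start.x is not None:
        if warm_start.x.size != model.n_vars:
            raise SolverError("warm start has wrong dimension")
    options = {"mip_rel_gap": mip_gap}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(c=model.costs, integrality=np.ones(model.n_vars),
               bounds=Bounds(0.0, 1.0), constraints=_constraints_matrices(model),
               options=options)
    if res.status == 2:
        return TrackingSolution(status="infeasible", x=None, objective=None)
    if res.status != 0 or res.x is None:
        raise SolverError(f"MILP solver failed: status={res.status} ({res.message})")
    x = np.rint(res.x)
    return _selection_to_solution(model, x)


def feasible_selections(model: TrackingModel, max_vars: int = 25,
                        base_only: bool = False) -> np.ndarray:
    """All feasible binary assignment vectors, by exhaustive enumeration.

    With ``base_only`` the directive rows appended after model construction
    are ignored, so the result can be reused to evaluate alternative
    directives by filtering.
    """
    n = model.n_vars
    if n > max_vars:
        raise SizeError(f"instance has {n} > {max_vars} assignment variables")
    if n == 0:
        return np.zeros((1, 0))
    n_base_eq = len(model.rows_eq) - (model.n_directives if base_only else 0)
    cons = []
    for row, b in model.rows_eq[:n_base_eq] if base_only else model.rows_eq:
        a = np.zeros(n)
        for v, coef in row.items():
            a[v] = coef
        cons.append((a, b, b))
    for row, b in model.rows_ub:
        a = np.zeros(n)
        for v, coef in row.items():
            a[v] = coef
        cons.append((a, -np.inf, b))
    A = np.array([c[0] for c in cons]) if cons else np.zeros((0, n))
    lo = np.array([c[1] for c in cons])
    hi = np.array([c[2] for c in cons])

    out = []
    chunk = 1 << 18
    total = 1 << n
    bits = np.arange(n)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        X = ((idx[:, None] >> bits[None, :]) & 1).astype(float)
        if cons:
            vals = X @ A.T
            feas = np.all((vals >= lo - 1e-9) & (vals <= hi + 1e-9), axis=1)
            X = X[feas]
        if X.shape[0]:
            out.append(X)
    if not out:
        return np.zeros((0, n))
    return np.concatenate(out, axis=0)


def best_of_selections(model: TrackingModel, X: np.ndarray) -> TrackingSolution:
    """Minimum-cost selection among candidate vectors (lexicographic ties)."""
    if X.shape[0] == 0:
        return TrackingSolution(status="infeasible", x=None, objective=None)
    objs = X @ model.costs
    best = float(objs.min())
    cand = X[objs <= best + 1e-12]
    best_x = min(map(tuple, cand))
    return _selection_to_solution(model, np.rint(np.array(best_x)))


def brute_force_solve(model: TrackingModel, max_vars: int = 25) -> TrackingSolution:
    """Exhaustive oracle: enumerate all binary assignment vectors, filter by
    all constraints (including any directives), return the minimum-cost
    feasible one."""
    return best_of_selections(model, feasible_selections(model, max_vars=max_vars))


def filter_selections(model: TrackingModel, X: np.ndarray,
                      n_base_eq: int) -> np.ndarray:
    """Restrict pre-enumerated feasible vectors by the equality rows appended
    after the first ``n_base_eq`` (i.e. the directive constraints)."""
    keep = np.ones(X.shape[0], dtype=bool)
    for row, b in model.rows_eq[n_base_eq:]:
        vals = sum(X[:, v] * c for v, c in row.items())
        keep &= np.abs(vals - b) <= 1e-9
    return X[keep]


# ---------------------------------------------------------------------------
# directives (leveraged editing)

def apply_directive(model: TrackingModel, directive: Directive) -> TrackingModel:
    """Add the directive's linear constraint(s) to the model.

    Forcing/banning a segment constrains the sum over its activity variables
    to 1/0; forcing/banning an assignment fixes that single variable; a count
    directive fixes the number of active cells at a frame; a clamp freezes
    every assignment outside the given frame window at its previous value
    (0 if there was none). Contradictory directives surface as infeasibility
    at solve time, not here.
    """
    d = directive
    if d.kind in ("force_segment", "ban_segment"):
        if d.frame is None or d.hypothesis is None:
            raise DirectiveError(f"{d.kind} needs frame and hypothesis")
        if not (0 <= d.frame < model.n_frames):
            raise DirectiveError(f"frame {d.frame} out of range")
        if d.hypothesis >= len(model.forests[d.frame]):
            raise DirectiveError(f"unknown hypothesis {d.hypothesis} at frame {d.frame}")
        vs = model.activity(d.frame, d.hypothesis)
        target = 1.0 if d.kind == "force_segment" else 0.0
        if not vs:
            if target == 1.0:
                raise DirectiveError(
                    f"hypothesis {d.hypothesis} at frame {d.frame} has no assignments")
            return model
        model.rows_eq.append(({v: 1.0 for v in vs}, target))
    elif d.kind in ("force_assignment", "ban_assignment"):
        if d.assignment is None or not (0 <= d.assignment < model.n_vars):
            raise DirectiveError(f"unknown assignment variable {d.assignment}")
        val = 1.0 if d.kind == "force_assignment" else 0.0
        model.rows_eq.append(({d.assignment: 1.0}, val))
    elif d.kind == "set_count":
        if d.frame is None or d.count is None:
            raise DirectiveError("set_count needs frame and count")
        if not (0 <= d.frame < model.n_frames):
            raise DirectiveError(f"frame {d.frame} out of range")
        row: dict[int, float] = {}
        for h in model.forests[d.frame].hypotheses:
            for v in model.activity(d.frame, h.id):
                row[v] = row.get(v, 0.0) + 1.0
        model.rows_eq.append((row, float(d.count)))
    elif d.kind == "clamp":
        if d.window is None or d.previous is None:
            raise DirectiveError("clamp needs window and previous solution")
        ta, tb = d.window
        prev = d.previous.x
        if prev is None or prev.size != model.n_vars:
            raise DirectiveError("clamp needs a previous solution for this model")
        for t, A in enumerate(model.assignments):
            if ta <= t <= tb:
                continue
            for k in range(len(A)):
                v = model.var(t, k)
                model.rows_eq.append(({v: 1.0}, float(prev[v])))
    else:
        raise DirectiveError(f"unknown directive kind {directive.kind!r}")
    model.n_directives += 1
    return model


def resolve_pixel(forest: HypothesisForest, row_px: float) -> int:
    """Smallest hypothesis containing a pixel row (for click-style directives)."""
    containing = [h for h in forest.hypotheses if h.top <= row_px < h.bottom]
    if not containing:
        raise DirectiveError(f"no hypothesis contains row {row_px}")
    return min(containing, key=lambda h: h.length).id


# ---------------------------------------------------------------------------
# lineage extraction and verification

@dataclass
class TrackedCell:
    cell_id: int
    parent_id: int | None
    frames: list[int] = field(default_factory=list)
    tops: list[int] = field(default_factory=list)
    bottoms: list[int] = field(default_factory=list)
    hyp_ids: list[int] = field(default_factory=list)
    divided: bool = False
    exited: bool = False


def extract_lineage(solution: TrackingSolution,
                    forests: list[HypothesisForest]) -> list[TrackedCell]:
    """Turn the selected assignments into a lineage forest.

    Mapping chains become one cell; a division closes the mother and opens
    two daughters with parent links; an exit terminates the cell. Every
    active segment belongs to exactly one cell by the continuity and conflict
    constraints.
    """
    if not solution.optimal:
        raise ValueError("lineage extraction requires an optimal solution")
    by_frame: dict[int, list[Assignment]] = {}
    for a in solution.selected:
        by_frame.setdefault(a.frame, []).append(a)

    cells: list[TrackedCell] = []
    cursor: dict[int, TrackedCell] = {}     # hyp id at current frame -> open cell

    def open_cell(parent_id, frame, hyp: SegmentHypothesis) -> TrackedCell:
        c = TrackedCell(cell_id=len(cells), parent_id=parent_id)
        cells.append(c)
        c.frames.append(frame)
        c.tops.append(hyp.top)
        c.bottoms.append(hyp.bottom)
        c.hyp_ids.append(hyp.id)
        return c

    T = len(forests)
    for t in range(T - 1):
        nxt: dict[int, TrackedCell] = {}
        for a in sorted(by_frame.get(t, []), key=lambda a: forests[t][a.source].top):
            cell = cursor.get(a.source)
            if cell is None:
                cell = open_cell(None, t, forests[t][a.source])
            if a.kind == "mapping":
                g = forests[t + 1][a.targets[0]]
                cell.frames.append(t + 1)
                cell.tops.append(g.top)
                cell.bottoms.append(g.bottom)
                cell.hyp_ids.append(g.id)
                nxt[g.id] = cell
            elif a.kind == "division":
                cell.divided = True
                for gid in a.targets:
                    d = open_cell(cell.cell_id, t + 1, forests[t + 1][gid])
                    nxt[gid] = d
            elif a.kind == "exit":
                cell.exited = True
        cursor = nxt
    return cells


def verify_solution(model: TrackingModel, solution: TrackingSolution,
                    tol: float = 1e-6) -> None:
    """Assert continuity, conflict-freeness and objective consistency."""
    x = solution.x
    assert x is not None
    for row, b in model.rows_eq:
        s = sum(x[v] * c for v, c in row.items())
        assert abs(s - b) <= tol, f"equality constraint violated: {s} != {b}"
    for row, b in model.rows_ub:
        s = sum(x[v] * c for v, c in row.items())
        assert s <= b + tol, f"conflict constraint violated: {s} > {b}"
    recomputed = model.segment_costs_of_selection(x)
    assert abs(recomputed - solution.objective) <= max(tol, 1e-9 * abs(recomputed)), \
        f"objective mismatch: {recomputed} vs {solution.objective}"


# ---------------------------------------------------------------------------
# random instances (cross-check fixtures) and accuracy metrics

def random_instance(seed: int, max_frames: int = 4, max_atoms: int = 5,
                    max_assignments: int = 25, length: int = 120):
    """Small random tracking instance for cross-checking against the
    brute-force oracle. Resamples until the assignment count admits
    exhaustive enumeration."""
    rng = np.random.default_rng(seed)
    params = HypothesisParams(typical_length_px=length / 4.0,
                              prominence_rel=0.05, min_region_px=3,
                              gap_merge_px=3, min_boundary_gap=3)
    # atom counts biased small so rejection (<= max_assignments) succeeds often
    weights = np.array([0.45, 0.3, 0.15, 0.07, 0.03][:max_atoms], dtype=float)
    weights /= weights.sum()
    for _ in range(500):
        T = int(rng.integers(2, max_frames + 1))
        forests = []
        for t in range(T):
            n_atoms = int(rng.choice(np.arange(1, len(weights) + 1), p=weights))
            prof = _random_profile(rng, length, n_atoms)
            forests.append(generate_hypotheses(prof, params, frame=t))
        assignments = [enumerate_assignments(forests[t], forests[t + 1], params)
                       for t in range(T - 1)]
        n = sum(len(A) for A in assignments)
        if 1 <= n <= max_assignments:
            return forests, assignments, params
    raise RuntimeError("could not sample a small enough instance")


def _random_profile(rng: np.random.Generator, length: int, n_cells: int) -> np.ndarray:
    prof = np.full(length, 1.0)
    pos = int(rng.integers(5, 15))
    for _ in range(n_cells):
        size = int(rng.integers(12, 36))
        if pos + size > length - 5:
            break
        prof[pos:pos + size] = 0.2
        pos += size + int(rng.integers(3, 6))
    return prof


def link_accuracy(tracked: list[TrackedCell], lineage) -> float:
    """Fraction of ground-truth frame-to-frame links reproduced by the tracker.

    Tracked segments are matched to true cells per frame by maximal pixel
    overlap; a true link (continuation or division edge) counts as recovered
    when the matched tracked cells carry the same relation.
    """
    # frame -> {true cell id -> (top, bottom)}
    truth_at: dict[int, dict[int, tuple[float, float]]] = {}
    for c in lineage.cells:
        for k, f in enumerate(c.frames):
            truth_at.setdefault(f, {})[c.cell_id] = (c.top_px[k], c.bottom_px[k])

    # match tracked segment -> true cell per frame
    match: dict[tuple[int, int], int] = {}
    for tc in tracked:
        for k, f in enumerate(tc.frames):
            best, best_ov = None, 0.0
            for cid, (top, bot) in truth_at.get(f, {}).items():
                ov = min(tc.bottoms[k], bot) - max(tc.tops[k], top)
                if ov > best_ov:
                    best, best_ov = cid, ov
            if best is not None:
                match[(tc.cell_id, f)] = best

    # tracked links: (frame, true source) -> set of true targets
    tracked_links: dict[tuple[int, int], set[int]] = {}
    children: dict[int, list[TrackedCell]] = {}
    for tc in tracked:
        if tc.parent_id is not None:
            children.setdefault(tc.parent_id, []).append(tc)
    for tc in tracked:
        for k in range(len(tc.frames) - 1):
            f = tc.frames[k]
            src = match.get((tc.cell_id, f))
            tgt = match.get((tc.cell_id, f + 1))
            if src is not None and tgt is not None:
                tracked_links.setdefault((f, src), set()).add(tgt)
        if tc.divided and tc.frames:
            f = tc.frames[-1]
            src = match.get((tc.cell_id, f))
            for d in children.get(tc.cell_id, []):
                tgt = match.get((d.cell_id, d.frames[0]))
                if src is not None and tgt is not None:
                    tracked_links.setdefault((f, src), set()).add(tgt)

    total = 0
    correct = 0
    for c in lineage.cells:
        frames = c.frames
        for k in range(len(frames)):
            f = frames[k]
            if k + 1 < len(frames):
                total += 1
                if c.cell_id in tracked_links.get((f, c.cell_id), set()):
                    correct += 1
            elif c.division_frame is not None:
                for d in (d for d in lineage.cells if d.parent_id == c.cell_id):
                    total += 1
                    if d.cell_id in tracked_links.get((f, c.cell_id), set()):
                        correct += 1
    return correct / total if total else float("nan")
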