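"""Candidate cell segments and inter-frame assignments.

The growth channel holds cells in single file, so segmentation reduces to
partitioning the channel's 1D vertical intensity profile. Cells appear as
dark intervals separated by bright seams. An excess of segment hypotheses is
generated per frame: atomic intervals delimited by prominent local maxima of
the profile, merged bottom-up (removing boundaries in order of increasing
prominence) into a hierarchy in which any two hypotheses on one root-to-leaf
path overlap and are therefore mutually exclusive. Candidate links between
consecutive frames are enumerated as mapping (one successor), division (two
adjacent successors) and exit assignments, each carrying a cost that scores
deviation from expected cell appearance and dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks


@dataclass
class HypothesisParams:
    """Knobs of hypothesis generation and cost assignment.

    Lengths are in pixels. ``typical_length_px`` anchors the length penalty
    and the assignment gates; ``expected_growth_dlog`` is the expected
    per-frame increment of log-size (rate * frame period).
    """

    smooth_window: int = 3
    prominence_rel: float = 0.08      # peak prominence, fraction of profile range
    min_boundary_gap: int = 4         # minimum distance between boundaries
    foreground_quantile: float = 0.5  # profile level separating cells from background
    gap_merge_px: int = 6             # bright runs shorter than this stay in one region
    min_region_px: int = 6
    typical_length_px: float = 45.0
    flank_px: int = 3
    w_int: float = 4.0                # weight of the interior-vs-flank contrast term
    w_len: float = 0.5                # weight of the length penalty
    w_growth: float = 8.0             # weight of the growth-deviation term
    w_shift: float = 2.0              # weight of the centre-displacement term
    w_div_asym: float = 1.0           # weight of the daughter-asymmetry term
    div_penalty: float = 0.2          # fixed cost of proposing a division
    expected_growth_dlog: float = 0.026
    max_shift_frac: float = 0.5       # gate: |centre shift| <= frac * typical length
    size_ratio_bounds: tuple[float, float] = (0.4, 2.5)
    adjacency_tol: int = 3            # daughters must abut within this many px
    gamma_exit: float = 1.0           # exit cost per hypothesis closer to the open end
    discard_top_px: int = 0           # optionally drop hypotheses near the open end


@dataclass
class SegmentHypothesis:
    """One candidate cell interval [top, bottom) at one frame."""

    id: int
    frame: int
    top: int
    bottom: int
    cost: float = 0.0
    tree_parent: int | None = None
    children: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return self.bottom - self.top

    @property
    def center(self) -> float:
        return 0.5 * (self.top + self.bottom)

    def overlaps(self, other: "SegmentHypothesis") -> bool:
        return self.top < other.bottom and other.top < self.bottom


@dataclass
class HypothesisForest:
    """All segment hypotheses of one frame, organized as a containment forest."""

    frame: int
    hypotheses: list[SegmentHypothesis] = field(default_factory=list)

    def __getitem__(self, hyp_id: int) -> SegmentHypothesis:
        return self.hypotheses[hyp_id]

    def __len__(self) -> int:
        return len(self.hypotheses)

    @property
    def roots(self) -> list[SegmentHypothesis]:
        return [h for h in self.hypotheses if h.tree_parent is None]

    @property
    def leaves(self) -> list[SegmentHypothesis]:
        return sorted((h for h in self.hypotheses if not h.children),
                      key=lambda h: h.top)

    def paths(self) -> list[list[int]]:
        """Root-to-leaf paths: the conflict sets (pairwise pixel-overlapping)."""
        out = []

        def walk(h: SegmentHypothesis, acc: list[int]):
            acc = acc + [h.id]
            if not h.children:
                out.append(acc)
            for cid in h.children:
                walk(self.hypotheses[cid], acc)

        for r in sorted(self.roots, key=lambda h: h.top):
            walk(r, [])
        return out

    def to_json(self) -> str:
        return json.dumps([{
            "id": h.id, "frame": h.frame, "top": h.top, "bottom": h.bottom,
            "cost": h.cost, "tree_parent": h.tree_parent,
            "children": list(h.children),
        } for h in self.hypotheses])


@dataclass
class Assignment:
    """Candidate link between consecutive frames.

    kind 'mapping': one target; 'division': two vertically adjacent targets
    ordered open end first; 'exit': no target.
    """

    id: int
    kind: str
    frame: int                    # source frame t (targets live at t + 1)
    source: int
    targets: tuple[int, ...]
    cost: float


# ---------------------------------------------------------------------------

def vertical_profile(channel_frame: np.ndarray, central_frac: float = 0.3,
                     smooth_window: int = 3) -> np.ndarray:
    """Per-row mean intensity over the central columns, lightly smoothed."""
    img = np.asarray(channel_frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single 2D channel frame")
    W = img.shape[1]
    half = max(int(round(W * central_frac / 2.0)), 1)
    lo, hi = W // 2 - half, W // 2 + half
    prof = img[:, lo:hi].mean(axis=1)
    if smooth_window > 1:
        prof = uniform_filter1d(prof, size=smooth_window, mode="nearest")
    return prof


def _foreground_regions(profile: np.ndarray, params: HypothesisParams) -> list[tuple[int, int]]:
    """Dark (cell-occupied) spans of the profile, bridged across short seams."""
    lo, hi = float(profile.min()), float(profile.max())
    if hi - lo <= 1e-12:
        return []
    thresh = lo + params.foreground_quantile * (hi - lo)
    mask = profile < thresh
    if not mask.any():
        return []
    # connected runs
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, mask.size))
    # bridge short bright gaps (inter-cell seams)
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= params.gap_merge_px:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= params.min_region_px]


def segment_cost(top: int, bottom: int, profile: np.ndarray,
                 params: HypothesisParams) -> float:
    """Appearance cost of one candidate interval.

    Dark interiors flanked by bright seams score low (negative); the length
    term penalizes the log-deviation from the typical cell length. Costs are
    translation-invariant: only the local profile enters.
    """
    scale = float(profile.max() - profile.min())
    if scale <= 1e-12:
        scale = 1.0
    interior = float(profile[top:bottom].mean())
    f = params.flank_px
    flank_vals = np.concatenate([
        profile[max(top - f, 0):top], profile[bottom:min(bottom + f, profile.size)]])
    flank = float(flank_vals.mean()) if flank_vals.size else interior
    contrast = (interior - flank) / scale          # negative for cell-like intervals
    len_pen = float(np.log((bottom - top) / params.typical_length_px) ** 2)
    return params.w_int * contrast + params.w_len * len_pen


def generate_hypotheses(profile: np.ndarray, params: HypothesisParams | None = None,
                        frame: int = 0) -> HypothesisForest:
    """Build the segment-hypothesis forest of one frame.

    Atomic intervals are delimited by local maxima of the profile whose
    prominence exceeds ``prominence_rel`` times the profile range; the
    hierarchy is built by iteratively removing boundaries in order of
    increasing prominence, each removal merging the two adjacent intervals
    into a parent hypothesis. A profile without boundaries yields a single
    full-interval hypothesis.
    """
    params = params or HypothesisParams()
    profile = np.asarray(profile, dtype=float)
    if profile.size < 3:
        raise ValueError("profile must have >= 3 rows")
    forest = HypothesisForest(frame=frame)
    regions = _foreground_regions(profile, params)
    if not regions:
        regions = [(0, profile.size)]

    next_id = 0
    for r0, r1 in regions:
        if params.discard_top_px and r1 <= params.discard_top_px:
            continue
        inner = profile[r0:r1]
        prom = params.prominence_rel * float(profile.max() - profile.min())
        peaks, props = find_peaks(inner, prominence=max(prom, 1e-12),
                                  distance=params.min_boundary_gap)
        boundaries = [int(p) + r0 for p in peaks]
        prominences = list(props["prominences"]) if len(peaks) else []
        cuts = [r0] + boundaries + [r1]
        # leaves: atomic intervals between boundaries
        nodes = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            h = SegmentHypothesis(id=next_id, frame=frame, top=a, bottom=b,
                                  cost=segment_cost(a, b, profile, params))
            next_id += 1
            forest.hypotheses.append(h)
            nodes.append(h)
        # merge hierarchy: remove boundaries by increasing prominence
        order = sorted(range(len(boundaries)), key=lambda k: (prominences[k], k))
        live = list(nodes)
        pos = {h.id: k for k, h in enumerate(live)}      # boundary k sits after live[k]
        bmap = list(range(len(boundaries)))              # boundary index -> gap index
        for bk in order:
            gap = bmap[bk]
            left, right = live[gap], live[gap + 1]
            parent = SegmentHypothesis(
                id=next_id, frame=frame, top=left.top, bottom=right.bottom,
                cost=segment_cost(left.top, right.bottom, profile, params),
                children=(left.id, right.id))
            next_id += 1
            left.tree_parent = parent.id
            right.tree_parent = parent.id
            forest.hypotheses.append(parent)
            live[gap:gap + 2] = [parent]
            bmap = [g if g < gap else g - 1 for g in bmap]
    return forest


def enumerate_assignments(forest_t: HypothesisForest, forest_t1: HypothesisForest,
                          params: HypothesisParams | None = None,
                          start_id: int = 0) -> list[Assignment]:
    """All admissible assignments from frame t to frame t+1.

    Mappings are gated by centre shift and size ratio; divisions link a
    mother to a vertically adjacent, disjoint daughter pair whose summed size
    is conserved up to growth; every source hypothesis additionally gets one
    exit assignment whose cost grows with the number of hypotheses between it
    and the open end (row 0), so that a deep cell can only leave by pushing
    out everything above it.
    """
    params = params or HypothesisParams()
    out: list[Assignment] = []
    max_shift = params.max_shift_frac * params.typical_length_px
    r_lo, r_hi = params.size_ratio_bounds
    aid = start_id

    tg = params.expected_growth_dlog
    for h in forest_t.hypotheses:
        for g in forest_t1.hypotheses:
            ratio = g.length / h.length
            if not (r_lo <= ratio <= r_hi):
                continue
            if abs(g.center - h.center) > max_shift:
                continue
            dlog = float(np.log(ratio))
            cost = (params.w_growth * (dlog - tg) ** 2
                    + params.w_shift * ((g.center - h.center)
                                        / params.typical_length_px) ** 2)
            out.append(Assignment(aid, "mapping", forest_t.frame, h.id, (g.id,), cost))
            aid += 1

    # divisions: adjacent disjoint pairs at t+1, ordered open end (smaller top) first
    hyps1 = sorted(forest_t1.hypotheses, key=lambda h: (h.top, h.bottom))
    for h in forest_t.hypotheses:
        for i, d1 in enumerate(hyps1):
            for d2 in hyps1[i + 1:]:
                if d1.overlaps(d2):
                    continue
                if not (0 <= d2.top - d1.bottom <= params.adjacency_tol):
                    continue
                s_sum = d1.length + d2.length
                ratio = s_sum / h.length
                if not (r_lo <= ratio <= r_hi):
                    continue
                center = 0.5 * (d1.top + d2.bottom)
                if abs(center - h.center) > max_shift:
                    continue
                dlog = float(np.log(ratio))
                asym = float(np.log(d1.length / d2.length))
                cost = (params.w_growth * (dlog - tg) ** 2
                        + params.w_shift * ((center - h.center)
                                            / params.typical_length_px) ** 2
                        + params.w_div_asym * asym ** 2
                        + params.div_penalty)
                out.append(Assignment(aid, "division", forest_t.frame, h.id,
                                      (d1.id, d2.id), cost))
                aid += 1

    for h in forest_t.hypotheses:
        n_above = sum(1 for g in forest_t.hypotheses if g.bottom <= h.top)
        out.append(Assignment(aid, "exit", forest_t.frame, h.id, (),
                              params.gamma_exit * n_above))
        aid += 1
    return out
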