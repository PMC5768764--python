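"""End-to-end channel analysis: images -> lineage -> quantified tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fluor as _fluor
from .growth import CellTrack, GrowthFit, fit_growth
from .hypotheses import HypothesisParams, enumerate_assignments, generate_hypotheses, vertical_profile
from .tracking import (Directive, TrackedCell, TrackingModel, TrackingSolution,
                       apply_directive, build_model, extract_lineage, solve)


@dataclass
class ChannelResult:
    """Everything produced by tracking one growth-channel stack."""

    forests: list
    model: TrackingModel
    solution: TrackingSolution
    cells: list[TrackedCell]
    params: HypothesisParams


def track_channel(phase_stack: np.ndarray, params: HypothesisParams | None = None,
                  directives: list[Directive] | None = None,
                  time_limit: float | None = None,
                  mip_gap: float = 0.0) -> ChannelResult:
    """Track one growth channel: hypotheses, global ILP, lineage extraction."""
    params = params or HypothesisParams()
    stack = np.asarray(phase_stack)
    forests = [generate_hypotheses(vertical_profile(stack[t], smooth_window=params.smooth_window),
                                   params, frame=t)
               for t in range(stack.shape[0])]
    assignments = [enumerate_assignments(forests[t], forests[t + 1], params)
                   for t in range(len(forests) - 1)]
    model = build_model(forests, assignments)
    for d in directives or []:
        apply_directive(model, d)
    solution = solve(model, time_limit=time_limit, mip_gap=mip_gap)
    if not solution.optimal:
        raise RuntimeError(f"tracking ILP ended with status {solution.status}")
    cells = extract_lineage(solution, forests)
    return ChannelResult(forests=forests, model=model, solution=solution,
                         cells=cells, params=params)


def cell_tracks(result: ChannelResult, frame_period: float,
                fluor_stack: np.ndarray | None = None,
                min_frames: int = 1) -> list[CellTrack]:
    """Convert tracked cells into quantification-ready tracks.

    Size proxy: vertical extent (bounding-box height) of the selected
    segment, in pixels. With a fluorescence stack, each cell-frame gets a
    total-fluorescence amplitude from the Cauchy + background fit of the
    column sums over the cell's rows.
    """
    tracks = []
    for c in result.cells:
        if len(c.frames) < min_frames:
            continue
        lengths = np.array(c.bottoms, dtype=float) - np.array(c.tops, dtype=float)
        fl: dict = {}
        if fluor_stack is not None:
            amps = []
            for k, f in enumerate(c.frames):
                seg = fluor_stack[f, c.tops[k]:c.bottoms[k], :]
                fit = _fluor.fit_cauchy_profile(_fluor.column_sums(seg))
                amps.append(fit.A)
            fl["fluor"] = np.array(amps)
        tracks.append(CellTrack(
            cell_id=c.cell_id, parent_id=c.parent_id,
            frames=np.array(c.frames),
            times=np.array(c.frames, dtype=float) * frame_period,
            lengths=lengths,
            positions=0.5 * (np.array(c.tops, float) + np.array(c.bottoms, float)),
            fluor_total=fl, divided=c.divided))
    return tracks


@dataclass
class GrowthSummary:
    """Population growth statistics over complete cell cycles."""

    fits: list[GrowthFit]
    cell_ids: list[int]
    mean_rate_dbl_h: float
    cv_rate: float
    median_r2_exp: float
    median_rel_error: float
    n_cells: int = field(default=0)


def summarize_growth(tracks: list[CellTrack], min_points: int = 3,
                     complete_cycles_only: bool = True) -> GrowthSummary:
    fits, ids = [], []
    for t in tracks:
        if complete_cycles_only and not t.complete_cycle:
            continue
        if t.times.size < min_points:
            continue
        fits.append(fit_growth(t))
        ids.append(t.cell_id)
    if not fits:
        raise ValueError("no tracks qualify for growth statistics")
    rates = np.array([f.doublings_per_hour for f in fits])
    return GrowthSummary(
        fits=fits, cell_ids=ids,
        mean_rate_dbl_h=float(rates.mean()),
        cv_rate=float(rates.std(ddof=1) / rates.mean()) if len(fits) > 1 else 0.0,
        median_r2_exp=float(np.median([f.r2_exp for f in fits])),
        median_rel_error=float(np.median([f.relative_error for f in fits])),
        n_cells=len(fits))
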