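"""Tracking-result export and import.

The export bundle is a JSON metadata file plus one CSV of per-cell,
per-time-point rows: cell id and ancestry, position in the channel (pixels
and cell rank counted from the closed end, mother = rank 0), bounding-box
area, and per imaging channel the total intensity, intensity percentiles
(5/25/50/75/95) and a fixed-width 16-bin intensity histogram. All files are
versioned via a ``schema_version`` key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import CellTrack
from .tracking import Directive, TrackedCell

SCHEMA_VERSION = 1
PERCENTILES = (5, 25, 50, 75, 95)
N_HIST_BINS = 16


class ExportError(ValueError):
    pass


@dataclass
class ExportBundle:
    metadata: dict
    rows: pd.DataFrame

    def cell_ids(self) -> list[int]:
        return sorted(self.rows["cell_id"].unique().tolist())


def _ancestors(cells_by_id: dict[int, TrackedCell], cid: int) -> list[int]:
    out = []
    cur = cells_by_id[cid]
    while cur.parent_id is not None:
        out.append(cur.parent_id)
        cur = cells_by_id[cur.parent_id]
    return out


def build_bundle(cells: list[TrackedCell], stacks: dict[str, np.ndarray],
                 data_source: str = "", channel_height_px: int | None = None,
                 vertical_position_px: int = 0) -> ExportBundle:
    """Assemble the export bundle from a tracked lineage and image stacks.

    ``stacks`` maps imaging-channel names (e.g. 'phase', 'fluor') to (T,H,W)
    arrays; intensity statistics are computed over each cell's bounding box.
    """
    by_id = {c.cell_id: c for c in cells}
    names = sorted(stacks)
    H = next(iter(stacks.values())).shape[1] if stacks else (channel_height_px or 0)
    ranges = {nm: (float(stacks[nm].min()), float(stacks[nm].max())) for nm in names}

    # rank from the closed end per frame: 0 = largest bottom
    per_frame: dict[int, list[tuple[int, int]]] = {}
    for c in cells:
        for k, f in enumerate(c.frames):
            per_frame.setdefault(f, []).append((c.bottoms[k], c.cell_id))
    rank: dict[tuple[int, int], int] = {}
    for f, lst in per_frame.items():
        for r, (_, cid) in enumerate(sorted(lst, reverse=True)):
            rank[(cid, f)] = r

    rows = []
    for c in sorted(cells, key=lambda c: c.cell_id):
        anc = _ancestors(by_id, c.cell_id)
        for k, f in enumerate(c.frames):
            top, bot = c.tops[k], c.bottoms[k]
            row = {
                "cell_id": c.cell_id,
                "parent_id": -1 if c.parent_id is None else c.parent_id,
                "ancestor_ids": ";".join(map(str, anc)),
                "frame": f,
                "top_px": top,
                "bottom_px": bot,
                "position_px": 0.5 * (top + bot),
                "cell_rank": rank[(c.cell_id, f)],
                "bbox_area_px": (bot - top) * (stacks[names[0]].shape[2] if names else 0),
                "divided": int(c.divided),
                "exited": int(c.exited),
            }
            for nm in names:
                seg = stacks[nm][f, top:bot, :]
                row[f"{nm}_total"] = float(seg.sum())
                for p, v in zip(PERCENTILES, np.percentile(seg, PERCENTILES)):
                    row[f"{nm}_p{p:02d}"] = float(v)
                hist, _ = np.histogram(seg, bins=N_HIST_BINS, range=ranges[nm])
                for b, hv in enumerate(hist):
                    row[f"{nm}_h{b:02d}"] = int(hv)
            rows.append(row)
    df = pd.DataFrame(rows)
    metadata = {
        "schema_version": SCHEMA_VERSION,
        "data_source": data_source,
        "total_cells": len(cells),
        "n_image_channels": len(names),
        "image_channels": names,
        "channel_height_px": channel_height_px if channel_height_px is not None else H,
        "image_height_px": H,
        "vertical_channel_position_px": vertical_position_px,
        "intensity_ranges": {nm: list(ranges[nm]) for nm in names},
        "n_rows": len(df),
    }
    return ExportBundle(metadata=metadata, rows=df)


def write_export(bundle: ExportBundle, directory: str | Path) -> dict[str, Path]:
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        paths = {"metadata": d / "metadata.json", "rows": d / "rows.csv"}
        paths["metadata"].write_text(json.dumps(bundle.metadata, indent=2))
        df = bundle.rows.sort_values(["cell_id", "frame"]) if len(bundle.rows) else bundle.rows
        df.to_csv(paths["rows"], index=False, float_format="%.17g")
    except OSError as e:
        raise ExportError(f"cannot write export to {d}: {e}") from e
    return paths


def read_export(directory: str | Path) -> ExportBundle:
    """Read and validate an export bundle; violations name the offending field."""
    d = Path(directory)
    try:
        metadata = json.loads((d / "metadata.json").read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise ExportError(f"cannot read metadata.json: {e}") from e
    if metadata.get("schema_version") != SCHEMA_VERSION:
        raise ExportError(
            f"schema_version mismatch: {metadata.get('schema_version')} != {SCHEMA_VERSION}")
    try:
        rows = pd.read_csv(d / "rows.csv", keep_default_na=False, na_values=[],
                           float_precision="round_trip")
        if "ancestor_ids" in rows.columns:
            rows["ancestor_ids"] = rows["ancestor_ids"].astype(str)
    except pd.errors.EmptyDataError:
        rows = pd.DataFrame(columns=["cell_id", "parent_id", "frame"])
    except OSError as e:
        raise ExportError(f"cannot read rows.csv: {e}") from e

    if len(rows):
        required = {"cell_id", "parent_id", "frame", "top_px", "bottom_px"}
        missing = required - set(rows.columns)
        if missing:
            raise ExportError(f"rows.csv missing columns: {sorted(missing)}")
        ids = set(rows["cell_id"].unique().tolist())
        for line, pid in enumerate(rows["parent_id"], start=2):
            if pid != -1 and pid not in ids:
                raise ExportError(f"rows.csv line {line}: parent_id {pid} refers to "
                                  "a cell that does not exist")
        for cid, grp in rows.groupby("cell_id"):
            fr = np.sort(grp["frame"].to_numpy())
            if np.any(np.diff(fr) != 1):
                raise ExportError(f"cell_id {cid}: frames not contiguous")
        n_cells = rows["cell_id"].nunique()
    else:
        n_cells = 0
    if metadata.get("total_cells") != n_cells:
        raise ExportError(
            f"metadata total_cells={metadata.get('total_cells')} but rows contain "
            f"{n_cells} cells")
    if "n_rows" in metadata and metadata["n_rows"] != len(rows):
        raise ExportError(
            f"metadata n_rows={metadata['n_rows']} but rows.csv has {len(rows)}")
    return ExportBundle(metadata=metadata, rows=rows)


def bundle_to_tracks(bundle: ExportBundle, frame_period: float,
                     fluor_column: str = "fluor_A") -> list[CellTrack]:
    """Cell tracks from an export bundle (lengths from the bounding box)."""
    tracks = []
    for cid, grp in bundle.rows.groupby("cell_id"):
        grp = grp.sort_values("frame")
        pid = int(grp["parent_id"].iloc[0])
        fl = {}
        if fluor_column in grp.columns:
            fl["fluor"] = grp[fluor_column].to_numpy(dtype=float)
        tracks.append(CellTrack(
            cell_id=int(cid), parent_id=None if pid == -1 else pid,
            frames=grp["frame"].to_numpy(),
            times=grp["frame"].to_numpy(dtype=float) * frame_period,
            lengths=(grp["bottom_px"] - grp["top_px"]).to_numpy(dtype=float),
            positions=grp["position_px"].to_numpy(dtype=float)
            if "position_px" in grp.columns else None,
            fluor_total=fl,
            divided=bool(grp["divided"].iloc[-1]) if "divided" in grp.columns else False))
    return tracks


def read_directives(path: str | Path) -> list[Directive]:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ExportError(f"directive file schema_version "
                          f"{doc.get('schema_version')} != {SCHEMA_VERSION}")
    return [Directive.from_dict(d) for d in doc.get("directives", [])]


def write_directives(directives: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {"schema_version": SCHEMA_VERSION, "directives": directives}, indent=2))
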