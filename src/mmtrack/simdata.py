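"""Synthetic mother-machine data generator.

Ground-truth lineages of exponentially growing, dividing bacteria confined to a
dead-end growth channel, rendered into phase-contrast + fluorescence image
stacks. The generator embodies the same assumptions the quantification stages
rely on: exponential single-cell growth with cell-to-cell rate variation,
binomial partitioning of fluorophores at division, Cauchy-shaped lateral spread
of fluorescence, additive background, first-order bleaching, and shot-noise
-like measurement error. Every downstream stage can therefore be tested against
exact ground truth without external data.

Coordinate convention: channel images are oriented with the open end at row 0;
the mother cell sits at the closed end (largest row index). Intervals are
half-open ``[top, bottom)`` in 0-based pixels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

LN2 = float(np.log(2.0))

#: conditions understood by the GFP production schedule
CONDITIONS = ("glucose", "lactose")


class ParameterError(ValueError):
    """Invalid simulation parameter; the message names the offending field."""


def _default_switch_schedule() -> list[tuple[float, str]]:
    # 4 h glucose / 4 h lactose alternation over a 24 h experiment
    return [(float(k) * 14400.0, "glucose" if k % 2 == 0 else "lactose") for k in range(6)]


@dataclass
class SimParams:
    """Parameters of the synthetic mother-machine experiment.

    Units are stated per field. Defaults describe an E. coli-like cell in
    M9 minimal medium imaged every 3 minutes at 100x magnification
    (0.065 um/px), growing at 0.75 doublings/hour with 17% cell-to-cell
    growth-rate variation, bleaching at 5.3e-5 per second.
    """

    growth_rate_mean: float = 0.75      # doublings/hour
    growth_rate_cv: float = 0.17        # dimensionless sd/mean of per-cell rates
    frame_period: float = 180.0         # seconds between frames
    n_frames: int = 480
    channel_length_px: int = 384        # vertical extent of the growth channel
    channel_width_px: int = 13          # visible channel width within the segment
    segment_width_px: int = 100         # width of the cropped per-channel image
    pixel_size_um: float = 0.065        # microns per pixel
    birth_length_um: float = 2.0        # mean cell length at birth
    division_asymmetry_sd: float = 0.035  # sd of daughter cytoplasm fraction around 0.5
    gfp_rate_on: float = 4000.0         # GFP production, molecules/hour (inducing condition)
    gfp_rate_off: float = 0.0           # molecules/hour (repressing condition)
    initial_gfp: int = 5000             # founder molecule count
    bleach_rate: float = 5.3e-5         # 1/second, bleaching + degradation
    autofluor_per_um: float = 421.8     # intensity per micron of cell length
    fluor_per_molecule: float = 27.7    # intensity amplitude per GFP molecule (1/lambda)
    cauchy_width: float = 5.5           # pixels, lateral spread of fluorescence
    background: float = 50.0            # per-pixel fluorescence background
    shot_noise_scale: float = 1.0       # pixel noise sd = scale * sqrt(pixel value)
    phase_contrast: float = 0.55        # brightness drop of cell interiors in phase images
    phase_noise_sd: float = 0.02        # additive noise in phase images
    switch_schedule: list[tuple[float, str]] = field(default_factory=_default_switch_schedule)
    seed: int = 0

    def validate(self) -> None:
        nonneg = (
            "growth_rate_mean", "growth_rate_cv", "gfp_rate_on", "gfp_rate_off",
            "bleach_rate", "autofluor_per_um", "fluor_per_molecule", "background",
            "shot_noise_scale", "phase_noise_sd", "initial_gfp",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("frame_period", "pixel_size_um", "birth_length_um", "cauchy_width"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0.0 < self.division_asymmetry_sd < 0.5):
            # the degenerate symmetric limit is requested with a tiny positive sd
            if self.division_asymmetry_sd != 0.0:
                raise ParameterError(
                    f"division_asymmetry_sd must be in [0, 0.5), got {self.division_asymmetry_sd}"
                )
        if self.n_frames < 2:
            raise ParameterError(f"n_frames must be >= 2, got {self.n_frames}")
        for name in ("channel_length_px", "channel_width_px", "segment_width_px"):
            if getattr(self, name) < 5:
                raise ParameterError(f"{name} must be >= 5, got {getattr(self, name)}")
        for t, cond in self.switch_schedule:
            if cond not in CONDITIONS:
                raise ParameterError(f"switch_schedule condition {cond!r} not in {CONDITIONS}")
        if not self.switch_schedule or self.switch_schedule[0][0] > 0:
            raise ParameterError("switch_schedule must start at time 0")

    def condition_at(self, time_s: float) -> str:
        cond = self.switch_schedule[0][1]
        for t, c in self.switch_schedule:
            if time_s >= t:
                cond = c
        return cond

    def gfp_rate_at(self, time_s: float) -> float:
        """GFP production rate (molecules/hour) in force at ``time_s``."""
        return self.gfp_rate_on if self.condition_at(time_s) == "lactose" else self.gfp_rate_off

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["switch_schedule"] = [[t, c] for t, c in self.switch_schedule]
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimParams":
        d = json.loads(Path(path).read_text())
        d["switch_schedule"] = [(float(t), str(c)) for t, c in d["switch_schedule"]]
        return cls(**d)


@dataclass
class SimCell:
    """Ground-truth record of one cell: per-frame true geometry and GFP count."""

    cell_id: int
    parent_id: int | None
    birth_frame: int
    growth_rate: float                  # doublings/hour, this cell's own rate
    division_frame: int | None = None
    exit_frame: int | None = None
    frames: list[int] = field(default_factory=list)
    length_um: list[float] = field(default_factory=list)
    top_px: list[float] = field(default_factory=list)
    bottom_px: list[float] = field(default_factory=list)
    gfp: list[int] = field(default_factory=list)

    @property
    def complete_cycle(self) -> bool:
        """Observed from birth to division (the filter used for growth statistics)."""
        return self.parent_id is not None and self.division_frame is not None


@dataclass
class GroundTruthLineage:
    params: SimParams
    cells: list[SimCell]

    def cell(self, cell_id: int) -> SimCell:
        return self._index[cell_id]

    def __post_init__(self) -> None:
        self._index = {c.cell_id: c for c in self.cells}

    def children(self, cell_id: int) -> list[SimCell]:
        return [c for c in self.cells if c.parent_id == cell_id]

    @property
    def n_divisions(self) -> int:
        return sum(1 for c in self.cells if c.division_frame is not None)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            for k, f in enumerate(c.frames):
                rows.append(
                    (c.cell_id, -1 if c.parent_id is None else c.parent_id, f,
                     c.top_px[k], c.bottom_px[k], c.length_um[k], c.gfp[k]))
        return pd.DataFrame(
            rows, columns=["cell_id", "parent_id", "frame", "top_px", "bottom_px",
                           "length_um", "gfp_count"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def segments_at(self, frame: int) -> list[tuple[int, float, float]]:
        """(cell_id, top_px, bottom_px) of cells present at ``frame``, closed end last."""
        out = []
        for c in self.cells:
            if c.frames and c.frames[0] <= frame <= c.frames[-1]:
                k = frame - c.frames[0]
                out.append((c.cell_id, c.top_px[k], c.bottom_px[k]))
        out.sort(key=lambda r: r[1])
        return out


class _LiveCell:
    __slots__ = ("cell_id", "parent_id", "birth_time", "birth_length", "rate_s",
                 "rate_dbl_h", "gfp", "record")

    def __init__(self, cell_id, parent_id, birth_time, birth_length, rate_dbl_h, gfp):
        self.cell_id = cell_id
        self.parent_id = parent_id
        self.birth_time = birth_time
        self.birth_length = birth_length
        self.rate_dbl_h = rate_dbl_h
        self.rate_s = rate_dbl_h * LN2 / 3600.0   # 1/s in natural-log units
        self.gfp = int(gfp)
        self.record = None  # SimCell, attached lazily

    def length_at(self, t: float) -> float:
        return self.birth_length * np.exp(self.rate_s * (t - self.birth_time))


def _draw_rate(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Per-cell growth rate, lognormal with the stated mean and CV (positivity)."""
    if cv == 0.0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def simulate_lineage(params: SimParams, seed: int | None = None) -> GroundTruthLineage:
    """Simulate a ground-truth lineage in one growth channel.

    Cells grow exponentially at per-cell rates drawn lognormally with the
    stated mean and CV, divide on doubling their birth length with a
    near-symmetric cytoplasm split, and partition their integer GFP content
    binomially. GFP bleaches by binomial thinning with per-frame survival
    exp(-bleach_rate * frame_period) and is produced at the schedule's
    condition-dependent rate. Cells pushed past the open end exit.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    dt = params.frame_period
    dt_h = dt / 3600.0
    chan_len = float(params.channel_length_px)
    px = params.pixel_size_um

    next_id = 0

    def new_cell(parent_id, birth_time, birth_length, gfp):
        nonlocal next_id
        c = _LiveCell(next_id, parent_id, birth_time, birth_length,
                      _draw_rate(rng, params.growth_rate_mean, params.growth_rate_cv), gfp)
        next_id += 1
        return c

    founder = new_cell(None, 0.0, params.birth_length_um, params.initial_gfp)
    # random phase within the cell cycle so the first division is not synchronous
    age_frac = rng.uniform(0.0, 1.0)
    founder.birth_time = -age_frac * LN2 / founder.rate_s

    live: list[_LiveCell] = [founder]   # ordered open end -> closed end
    done: list[SimCell] = []
    survival = float(np.exp(-params.bleach_rate * dt))

    for t_idx in range(params.n_frames):
        t = t_idx * dt
        rate = params.gfp_rate_at(t)
        if t_idx > 0:
            for c in live:
                n = rng.binomial(c.gfp, survival) if c.gfp > 0 else 0
                if rate > 0:
                    n += rng.poisson(rate * dt_h)
                c.gfp = int(n)

        # divisions: replace mother by two daughters (order: open-end daughter first)
        i = 0
        while i < len(live):
            c = live[i]
            length = c.length_at(t)
            if length >= 2.0 * c.birth_length and t > c.birth_time:
                if c.record is not None:
                    c.record.division_frame = t_idx
                    done.append(c.record)
                frac = 0.5
                if params.division_asymmetry_sd > 0:
                    frac = float(np.clip(
                        rng.normal(0.5, params.division_asymmetry_sd), 0.05, 0.95))
                # frac = cytoplasm fraction of the closed-end daughter
                n1 = rng.binomial(c.gfp, frac) if c.gfp > 0 else 0
                d_closed = new_cell(c.cell_id, t, frac * length, n1)
                d_open = new_cell(c.cell_id, t, (1.0 - frac) * length, c.gfp - n1)
                live[i:i + 1] = [d_open, d_closed]
                i += 2
            else:
                i += 1

        # positions: stack upward from the closed end
        bottom = chan_len
        keep: list[_LiveCell] = []
        exited: list[_LiveCell] = []
        for c in reversed(live):        # closed end first
            length_px = c.length_at(t) / px
            top = bottom - length_px
            # exit once the midpoint passes the open end: the majority of the
            # cell is then in the main flow channel and about to be swept away
            if bottom <= 0.0 or (top + bottom) / 2.0 < 0.0:
                exited.append(c)
                continue
            if c.record is None:
                c.record = SimCell(c.cell_id, c.parent_id, t_idx, c.rate_dbl_h)
            c.record.frames.append(t_idx)
            c.record.length_um.append(float(c.length_at(t)))
            c.record.top_px.append(float(top))
            c.record.bottom_px.append(float(bottom))
            c.record.gfp.append(c.gfp)
            keep.append(c)
            bottom = top
        for c in exited:
            if c.record is not None:
                c.record.exit_frame = t_idx
                done.append(c.record)
        live = list(reversed(keep))

    for c in live:
        if c.record is not None:
            done.append(c.record)
    done.sort(key=lambda r: r.cell_id)
    return GroundTruthLineage(params=params, cells=done)


# ---------------------------------------------------------------------------
# profiles and rendering

def cauchy_profile(A: float, B: float, i_mid: float, w: float, n_cols: int) -> np.ndarray:
    """Noise-free fluorescence column-sum profile: B + A / (1 + ((i - i_mid)/w)^2)."""
    if w <= 0:
        raise ParameterError(f"w must be > 0, got {w}")
    i = np.arange(n_cols, dtype=float)
    return B + A / (1.0 + ((i - i_mid) / w) ** 2)


def make_profile(A: float, B: float, i_mid: float = 50.0, w: float = 5.5,
                 n_cols: int = 100, noise_sd: float = 0.0,
                 seed: int | None = None) -> np.ndarray:
    """Synthetic column-sum profile with optional additive Gaussian noise."""
    if n_cols < 5:
        raise ParameterError(f"n_cols must be >= 5, got {n_cols}")
    c = cauchy_profile(A, B, i_mid, w, n_cols)
    if noise_sd > 0:
        c = c + np.random.default_rng(seed).normal(0.0, noise_sd, size=n_cols)
    return c


@dataclass
class SyntheticStack:
    """Rendered channel stack: phase + fluorescence frames and label masks."""

    phase: np.ndarray      # (T, H, W) float32
    fluor: np.ndarray      # (T, H, W) float32
    labels: np.ndarray     # (T, H, W) int32, 0 = background, else cell_id + 1
    params: SimParams

    def write_tiff(self, directory: str | Path, stem: str = "channel") -> dict[str, Path]:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "phase": d / f"{stem}_phase.tif",
            "fluor": d / f"{stem}_fluor.tif",
            "labels": d / f"{stem}_labels.tif",
        }
        tifffile.imwrite(paths["phase"], self.phase)
        tifffile.imwrite(paths["fluor"], self.fluor)
        tifffile.imwrite(paths["labels"], self.labels)
        return paths


def render_stack(lineage: GroundTruthLineage, params: SimParams | None = None,
                 seed: int | None = None) -> SyntheticStack:
    """Render a lineage into phase-contrast and fluorescence frames.

    Fluorescence: each cell contributes, over its rows, a column profile
    ``A_cell * rho_i / n_rows`` with ``rho_i`` the Cauchy shape centred on the
    channel, where ``A_cell = fluor_per_molecule * gfp + autofluor_per_um *
    length``. A flat per-pixel background is added, then zero-mean noise whose
    variance scales with the pixel value (shot-noise-like). Column sums over a
    cell's rows therefore follow B + A * rho_i with B proportional to the
    cell's height in rows.

    Phase contrast: cells are dark rectangles in the channel with bright
    inter-cell seams, Gaussian-blurred; only the 1D vertical profile matters
    downstream.
    """
    params = lineage.params if params is None else params
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    T, H, W = params.n_frames, params.channel_length_px, params.segment_width_px
    i_mid = W / 2.0
    rho = 1.0 / (1.0 + ((np.arange(W) - i_mid) / params.cauchy_width) ** 2)

    chan_lo = int(round(i_mid - params.channel_width_px / 2.0))
    chan_hi = chan_lo + params.channel_width_px

    phase = np.full((T, H, W), 0.80, dtype=np.float64)
    fluor = np.full((T, H, W), params.background, dtype=np.float64)
    labels = np.zeros((T, H, W), dtype=np.int32)

    for c in lineage.cells:
        for k, t_idx in enumerate(c.frames):
            top = max(c.top_px[k], 0.0)
            bottom = min(c.bottom_px[k], float(H))
            r0, r1 = int(np.ceil(top)), int(np.floor(bottom))
            if r1 <= r0:
                continue
            # fluorescence spread across all columns of the segment
            n_rows = r1 - r0
            A_cell = (params.fluor_per_molecule * c.gfp[k]
                      + params.autofluor_per_um * c.length_um[k])
            fluor[t_idx, r0:r1, :] += (A_cell / n_rows) * rho[None, :]
            # phase: dark interior, 1 px bright seam at each pole
            s0, s1 = min(r0 + 1, r1), max(r1 - 1, r0)
            phase[t_idx, s0:s1, chan_lo:chan_hi] -= params.phase_contrast
            labels[t_idx, r0:r1, chan_lo:chan_hi] = c.cell_id + 1

    for t_idx in range(T):
        phase[t_idx] = gaussian_filter(phase[t_idx], sigma=(1.0, 1.0))
    if params.phase_noise_sd > 0:
        phase += rng.normal(0.0, params.phase_noise_sd, size=phase.shape)
    if params.shot_noise_scale > 0:
        fluor += rng.normal(0.0, 1.0, size=fluor.shape) * (
            params.shot_noise_scale * np.sqrt(np.maximum(fluor, 0.0)))
    return SyntheticStack(phase=phase.astype(np.float32),
                          fluor=fluor.astype(np.float32),
                          labels=labels, params=params)


# ---------------------------------------------------------------------------
# sibling-pair generator for the fluorescence -> molecule calibration

def make_sibling_dataset(n_pairs: int, lambda_true: float, v_true: float,
                         total_fluor_range: tuple[float, float] = (2000.0, 50000.0),
                         size_noise_sd: float = 0.01,
                         seed: int | None = None,
                         division_asymmetry_sd: float = 0.035) -> pd.DataFrame:
    """Generate sibling-pair birth fluorescence data with known conversion factor.

    For each division: the mother carries ``n = round(lambda_true * F)``
    molecules at total fluorescence ``F``; the true cytoplasm fraction of
    daughter 1 is drawn around 0.5; molecules are partitioned binomially;
    the measured fluorescence fraction ``q`` receives Gaussian noise of
    variance ``v_true`` and the measured size fraction ``rho`` receives
    Gaussian noise of sd ``size_noise_sd``. Columns: x, y, rho, q plus the
    ground truth n_mother, frac_true.
    """
    if lambda_true <= 0:
        raise ParameterError(f"lambda_true must be > 0, got {lambda_true}")
    if v_true < 0:
        raise ParameterError(f"v_true must be >= 0, got {v_true}")
    rng = np.random.default_rng(seed)
    lo, hi = total_fluor_range
    F = rng.uniform(lo, hi, size=n_pairs)
    n = np.maximum(np.rint(lambda_true * F).astype(int), 1)
    if division_asymmetry_sd > 0:
        f = np.clip(rng.normal(0.5, division_asymmetry_sd, size=n_pairs), 0.05, 0.95)
    else:
        f = np.full(n_pairs, 0.5)
    n1 = rng.binomial(n, f)
    q = n1 / n
    if v_true > 0:
        q = q + rng.normal(0.0, np.sqrt(v_true), size=n_pairs)
    q = np.clip(q, 1e-6, 1.0 - 1e-6)
    rho = f.copy()
    if size_noise_sd > 0:
        rho = np.clip(rho + rng.normal(0.0, size_noise_sd, size=n_pairs),
                      1e-6, 1.0 - 1e-6)
    x = q * F
    y = (1.0 - q) * F
    return pd.DataFrame({"x": x, "y": y, "rho": rho, "q": q,
                         "n_mother": n, "frac_true": f})
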