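"""Single-cell growth-rate estimation and lineage statistics.

Cell elongation in the growth channel is exponential to excellent
approximation, so the growth rate of a cell cycle is the slope of a linear
regression of log-size on time. The posterior sd of that slope,

    sigma(a) = sqrt( var(x) (1 - r^2) / ((T - 1) var(t)) ),

with x = log s(t), follows from marginalizing the birth size out of the
Gaussian regression model. Exponential and linear models are compared through
squared Pearson correlations; their log-likelihoods differ by the exponent
-T log(1 - r^2). Lag times after a nutrient switch and genealogical
correlations of per-cell quantities are extracted from lineage forests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress, pearsonr

LN2 = float(np.log(2.0))


class InsufficientDataError(ValueError):
    pass


@dataclass
class CellTrack:
    """Per-cell time series: the unit of all quantification."""

    cell_id: int
    parent_id: int | None
    frames: np.ndarray          # contiguous frame indices
    times: np.ndarray           # seconds
    lengths: np.ndarray         # px or um (any consistent unit)
    positions: np.ndarray | None = None   # px, cell centre along the channel
    fluor_total: dict = field(default_factory=dict)  # channel -> amplitudes
    divided: bool = False       # division observed at the end of the track

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.lengths <= 0):
            raise ValueError("lengths must be positive")
        if self.frames.size and np.any(np.diff(self.frames) != 1):
            raise ValueError("frames must be contiguous")

    @property
    def complete_cycle(self) -> bool:
        """Birth and division both observed."""
        return self.parent_id is not None and self.divided


@dataclass
class GrowthFit:
    """Exponential growth fit of one cell cycle."""

    slope: float            # 1/hour, natural log units
    intercept: float        # log-size at t=0
    r2_exp: float           # squared Pearson r of log-size vs time
    r2_lin: float           # squared Pearson r of size vs time
    residuals: np.ndarray   # log-size residuals
    fitted_log: np.ndarray  # fitted log-sizes
    T: int
    sigma_a: float          # posterior sd of the slope, 1/hour

    @property
    def doublings_per_hour(self) -> float:
        return self.slope / LN2

    @property
    def sigma_doublings_per_hour(self) -> float:
        return self.sigma_a / LN2

    @property
    def relative_error(self) -> float:
        return self.sigma_a / abs(self.slope) if self.slope != 0 else float("inf")

    def fitted_sizes(self) -> np.ndarray:
        return np.exp(self.fitted_log)


def growth_rate_sd(x: np.ndarray, t_hours: np.ndarray, r2: float) -> float:
    """Posterior sd of the regression slope: sqrt(var(x)(1-r2)/((T-1)var(t)))."""
    T = x.size
    var_x = float(np.var(x, ddof=1))
    var_t = float(np.var(t_hours, ddof=1))
    if var_t <= 0:
        raise ValueError("times are degenerate")
    return float(np.sqrt(max(var_x * (1.0 - r2), 0.0) / ((T - 1) * var_t)))


def fit_growth(track: CellTrack) -> GrowthFit:
    """Least-squares exponential growth fit of a cell track.

    Regresses log-size on time (hours); also reports the squared Pearson
    correlation of the un-logged sizes with time for the linear-growth
    comparison.
    """
    T = track.times.size
    if T < 3:
        raise InsufficientDataError(f"need >= 3 points for a growth fit, got {T}")
    t_h = track.times / 3600.0
    x = np.log(track.lengths)
    res = linregress(t_h, x)
    fitted = res.intercept + res.slope * t_h
    r2_exp = float(res.rvalue ** 2)
    r2_lin = float(pearsonr(t_h, track.lengths).statistic ** 2)
    sigma_a = growth_rate_sd(x, t_h, r2_exp)
    return GrowthFit(slope=float(res.slope), intercept=float(res.intercept),
                     r2_exp=r2_exp, r2_lin=r2_lin, residuals=x - fitted,
                     fitted_log=fitted, T=T, sigma_a=sigma_a)


def loglik_exponent(T: int, r_squared: float) -> float:
    """Log-likelihood exponent -T log(1 - r^2) of a growth fit (natural log)."""
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError(f"r_squared must be in [0, 1], got {r_squared}")
    if r_squared == 1.0:
        return float("inf")
    return -T * float(np.log1p(-r_squared))


def loglik_ratio_exponent(T: int, r2_better: float, r2_worse: float) -> float:
    """Exponent of the likelihood ratio between two fits of the same track:
    T * (log(1 - r2_worse) - log(1 - r2_better))."""
    return loglik_exponent(T, r2_better) - loglik_exponent(T, r2_worse)


def size_error_profile(fits: list[GrowthFit], n_bins: int = 10) -> dict:
    """Relative size-measurement error stratified by fitted size.

    Each observation contributes its squared residual divided by the squared
    fitted size (for log fits the squared log-residual is the equivalent to
    second order); bins are by fitted size, and the square roots of the bin
    means are returned with standard errors.
    """
    sizes = np.concatenate([f.fitted_sizes() for f in fits])
    sq_rel = np.concatenate([f.residuals ** 2 for f in fits])
    edges = np.unique(np.quantile(sizes, np.linspace(0, 1, n_bins + 1)))
    idx = np.clip(np.searchsorted(edges, sizes, side="right") - 1, 0, len(edges) - 2)
    centers, rel_err, ses, counts = [], [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        m = float(np.mean(sq_rel[sel]))
        centers.append(float(np.mean(sizes[sel])))
        rel_err.append(float(np.sqrt(m)))
        se_sq = float(np.std(sq_rel[sel], ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        # delta method: se of sqrt(mean)
        ses.append(0.5 * se_sq / np.sqrt(m) if m > 0 else 0.0)
        counts.append(n)
    return {"bin_centers": np.array(centers), "rel_error": np.array(rel_err),
            "rel_error_se": np.array(ses), "counts": np.array(counts)}


# ---------------------------------------------------------------------------
# lag times and genealogical correlations

def lag_times(tracks: list[CellTrack], switch_time: float,
              threshold_molecules: float = 150.0, conversion: float = 1.0,
              horizon: float | None = None, channel: str = "fluor",
              lineage_parents: dict[int, int | None] | None = None) -> dict:
    """Per-lineage induction lag after a nutrient switch.

    The lag of a lineage is the delay from ``switch_time`` until the corrected
    molecule count (``conversion`` * fluorescence) first exceeds
    ``threshold_molecules``; lineages never exceeding it within ``horizon``
    seconds are reported as censored. The molecule count is followed through
    descendants, so a lineage's lag is the first crossing by the cell itself
    or any descendant. Returns {root_cell_id: (lag_minutes, censored)}.
    """
    if conversion <= 0:
        raise ValueError("conversion must be > 0")
    by_id = {t.cell_id: t for t in tracks}
    covering = [t for t in tracks if t.times[0] <= switch_time <= t.times[-1]]
    if not covering:
        raise ValueError("no tracks cover the switch time")
    horizon = horizon if horizon is not None else float("inf")

    children: dict[int, list[int]] = {}
    for t in tracks:
        pid = t.parent_id if lineage_parents is None else lineage_parents.get(t.cell_id)
        if pid is not None:
            children.setdefault(pid, []).append(t.cell_id)

    def first_crossing(cell_id: int) -> float | None:
        tr = by_id[cell_id]
        mol = conversion * np.asarray(tr.fluor_total.get(channel), dtype=float)
        sel = (tr.times >= switch_time) & (tr.times <= switch_time + horizon)
        above = sel & (mol > threshold_molecules)
        if np.any(above):
            return float(tr.times[np.argmax(above)])
        best = None
        for ch in children.get(cell_id, []):
            c = first_crossing(ch)
            if c is not None and (best is None or c < best):
                best = c
        return best

    out = {}
    for root in covering:
        cross = first_crossing(root.cell_id)
        if cross is None:
            out[root.cell_id] = (float("nan"), True)
        else:
            out[root.cell_id] = (max(cross - switch_time, 0.0) / 60.0, False)
    return out


def kin_correlation(values: dict[int, float], parents: dict[int, int | None],
                    generations_back: int = 1) -> tuple[float, int]:
    """Pearson correlation over pairs of cells whose most recent common
    ancestor is exactly ``generations_back`` generations in the past
    (k=1: sibling pairs). Returns (r, number of pairs)."""
    k = generations_back
    if k < 1:
        raise ValueError("generations_back must be >= 1")

    def ancestor(cid, steps):
        cur = cid
        for _ in range(steps):
            cur = parents.get(cur)
            if cur is None:
                return None
        return cur

    # MRCA exactly k back <=> same ancestor k generations up but different
    # ancestors k-1 generations up (k-1 = 0 means the cells themselves)
    groups: dict[int, list[int]] = {}
    for cid in sorted(values):
        a_k = ancestor(cid, k)
        if a_k is not None:
            groups.setdefault(a_k, []).append(cid)
    pairs = []
    for members in groups.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if ancestor(a, k - 1) != ancestor(b, k - 1):
                    pairs.append((values[a], values[b]))
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"only {len(pairs)} pairs with MRCA {generations_back} generations back")
    arr = np.array(pairs)
    # unordered pairs: symmetrize so the correlation does not depend on order
    v1 = np.concatenate([arr[:, 0], arr[:, 1]])
    v2 = np.concatenate([arr[:, 1], arr[:, 0]])
    r = float(pearsonr(v1, v2).statistic)
    return r, len(pairs)
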