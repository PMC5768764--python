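"""Registration and growth-channel extraction.

Raw field-of-view stacks drift and jitter over a multi-hour acquisition.
All frames are registered to the first frame by translation-only, sub-pixel
phase cross-correlation (other imaging channels reuse the phase-contrast
offsets). Growth channels appear as a periodic array of dark vertical
stripes in phase contrast; their x-centres are detected on the first frame
and each channel is cropped into its own fixed-width stack, oriented with
the open end at row 0, which is the tracker's expected input. Input images
are assumed already rotated so that channels are vertical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import shift as nd_shift
from scipy.signal import find_peaks
from skimage.registration import phase_cross_correlation


class InputError(ValueError):
    pass


class DetectionError(ValueError):
    pass


class GeometryError(ValueError):
    pass


@dataclass
class RegisteredStack:
    """Registered frames plus the recovered per-frame shifts."""

    frames: np.ndarray                 # (T, H, W) or (T, C, H, W)
    offsets: np.ndarray                # (T, 2): (dy, dx) applied to each frame
    channel_centers: list[float] | None = None


def register_stack(frames: np.ndarray, upsample_factor: int = 100,
                   reference_channel: int = 0) -> RegisteredStack:
    """Register all frames to the first frame (translation only, sub-pixel).

    For multi-channel stacks (T, C, H, W) the offsets are estimated on
    ``reference_channel`` (phase contrast) and applied to all channels.
    Frames are resampled by linear interpolation.
    """
    arr = np.asarray(frames, dtype=float)
    if arr.ndim == 3:
        arr = arr[:, None, :, :]
        squeeze = True
    elif arr.ndim == 4:
        squeeze = False
    else:
        raise InputError(f"expected (T,H,W) or (T,C,H,W) stack, got shape {arr.shape}")
    if arr.shape[0] == 0:
        raise InputError("empty stack")

    T = arr.shape[0]
    ref = arr[0, reference_channel]
    offsets = np.zeros((T, 2))
    out = arr.copy()
    for t in range(1, T):
        shift_est, _, _ = phase_cross_correlation(
            ref, arr[t, reference_channel], upsample_factor=upsample_factor)
        offsets[t] = shift_est
        for c in range(arr.shape[1]):
            out[t, c] = nd_shift(arr[t, c], shift_est, order=1, mode="nearest")
    if squeeze:
        out = out[:, 0]
    return RegisteredStack(frames=out, offsets=offsets)


def detect_channels(frame: np.ndarray, min_spacing: int = 10,
                    prominence_rel: float = 0.1) -> list[float]:
    """x-centres of the periodic growth-channel structures in one phase frame.

    Channels are dark vertical stripes; their centres are the prominent
    minima of the column-mean intensity profile.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise InputError("expected a single 2D phase-contrast frame")
    prof = img.mean(axis=0)
    rng = float(prof.max() - prof.min())
    if rng <= 1e-12:
        raise DetectionError("no intensity structure in frame (flat profile)")
    inv = prof.max() - prof
    peaks, props = find_peaks(inv, prominence=prominence_rel * rng,
                              distance=min_spacing)
    if len(peaks) == 0:
        raise DetectionError(
            f"no periodic channel structure found "
            f"(profile range {rng:.3g}, prominence floor {prominence_rel * rng:.3g})")
    # refine to sub-pixel by intensity-weighted centroid around each peak
    centers = []
    for p in peaks:
        lo, hi = max(p - 2, 0), min(p + 3, inv.size)
        wts = inv[lo:hi] - inv[lo:hi].min()
        xs = np.arange(lo, hi)
        centers.append(float(np.average(xs, weights=wts) if wts.sum() > 0 else p))
    return centers


def crop_channels(stack: RegisteredStack, segment_width: int = 100) -> list[np.ndarray]:
    """Cut one fixed-width stack per detected growth channel.

    Each output stack is ``segment_width`` px wide, centred on a channel,
    frames ordered by time, open end at row 0 (inherited from the input
    orientation).
    """
    if not stack.channel_centers:
        raise GeometryError("stack has no detected channel centers")
    frames = stack.frames
    W = frames.shape[-1]
    out = []
    for c in stack.channel_centers:
        lo = int(round(c - segment_width / 2.0))
        hi = lo + segment_width
        if lo < 0 or hi > W:
            raise GeometryError(
                f"crop [{lo}, {hi}) around channel at x={c:.1f} exceeds image "
                f"width {W}")
        out.append(frames[..., lo:hi].copy())
    return out


def preprocess_stack(frames: np.ndarray, segment_width: int = 100,
                     upsample_factor: int = 20) -> tuple[RegisteredStack, list[np.ndarray]]:
    """Register, detect channels on the first phase frame, and crop."""
    reg = register_stack(frames, upsample_factor=upsample_factor)
    first = reg.frames[0] if reg.frames.ndim == 3 else reg.frames[0, 0]
    reg.channel_centers = detect_channels(first)
    return reg, crop_channels(reg, segment_width=segment_width)


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_channel_stacks(stacks: list[np.ndarray], directory: str | Path,
                         stem: str = "growth_channel") -> list[Path]:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, s in enumerate(stacks):
        p = d / f"{stem}_{k:03d}.tif"
        tifffile.imwrite(p, s.astype(np.float32))
        paths.append(p)
    return paths
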