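"""Global drift correction by correlation maximization.

Stage drift in long time-lapse acquisitions is removed by finding, for each
consecutive frame pair, the rigid integer-voxel shift that maximizes the
normalized cross-correlation between the frames, and chaining these pairwise
shifts into a cumulative series relative to frame 0.  The search is
exhaustive over the shift window (stepwise in z, y, x), computed with the
FFT-accelerated normalized cross-correlation of
``skimage.feature.match_template``; correlation ties are broken toward the
smaller-magnitude shift.  Chaining consecutive pairs accumulates a
random-walk error over very long movies — the price of not assuming a
single static reference frame.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.feature import match_template

from .stack import TimeLapseStack

__all__ = ["DriftSeries", "estimate_drift", "apply_drift", "pairwise_shift"]


class UninformativeFrameError(ValueError):
    """A frame has zero intensity variance; correlation is undefined."""


@dataclass
class DriftSeries:
    """Cumulative per-frame shift (z, y, x) in voxels relative to frame 0."""

    shifts: np.ndarray  # (T, 3) float (integer-valued unless subvoxel)
    correlations: np.ndarray | None = None  # (T,) peak NCC per pair, corr[0]=1

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 3:
            raise ValueError("shifts must be (T, 3)")
        if np.any(self.shifts[0] != 0):
            raise ValueError("drift series must start at zero")

    def __len__(self) -> int:
        return len(self.shifts)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.shifts, columns=["dz", "dy", "dx"])
        df.insert(0, "frame", np.arange(len(df)))
        if self.correlations is not None:
            df["peak_ncc"] = self.correlations
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DriftSeries":
        df = pd.read_csv(path)
        corr = df["peak_ncc"].to_numpy() if "peak_ncc" in df else None
        return cls(df[["dz", "dy", "dx"]].to_numpy(), corr)


def _quadratic_peak_offset(vals: np.ndarray) -> float:
    """Subvoxel offset of a 1D quadratic through three points around a peak."""
    denom = vals[0] - 2 * vals[1] + vals[2]
    if denom == 0:
        return 0.0
    off = 0.5 * (vals[0] - vals[2]) / denom
    return float(np.clip(off, -0.5, 0.5))


def pairwise_shift(
    ref: np.ndarray,
    mov: np.ndarray,
    max_shift: int,
    subvoxel: bool = False,
) -> tuple[np.ndarray, float]:
    """Shift (z, y, x) that best aligns ``mov`` onto ``ref``.

    The interior of ``ref`` (cropped by ``max_shift`` on each axis that is
    wide enough) is used as a template and slid over ``mov``; the NCC peak
    position gives the shift.  A shift of ``s`` means ``mov`` is ``ref``
    translated by ``+s`` voxels.  Returns ``(shift, peak_correlation)``.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.std() == 0 or mov.std() == 0:
        raise UninformativeFrameError("uninformative frame: zero intensity variance")
    # crop as much as max_shift allows per axis; axes too small for the full
    # window get the largest feasible search range
    crops = [min(max_shift, (dim - 1) // 2) for dim in ref.shape]
    template = ref[tuple(slice(c, dim - c) for c, dim in zip(crops, ref.shape))]
    offsets = np.array(crops)
    cc = match_template(mov, template, pad_input=False)
    # candidate positions correspond to shifts = position - offsets
    flat = np.argwhere(cc == cc.max())
    shifts = flat - offsets
    best = flat[np.argmin(np.abs(shifts).sum(axis=1))]  # tie -> smallest |shift|
    shift = best - offsets
    peak = float(cc[tuple(best)])
    if np.any(np.abs(shift) >= max_shift):
        warnings.warn("correlation peak on the search boundary; max_shift may be too small")
    if subvoxel:
        sub = np.zeros(3, dtype=float)
        for ax in range(cc.ndim):
            idx = list(best)
            if 0 < best[ax] < cc.shape[ax] - 1:
                lo, hi = best.copy(), best.copy()
                lo[ax] -= 1
                hi[ax] += 1
                vals = np.array([cc[tuple(lo)], cc[tuple(best)], cc[tuple(hi)]])
                sub[ax] = _quadratic_peak_offset(vals)
        return shift.astype(float) + sub, peak
    return shift.astype(float), peak


def estimate_drift(
    stack: TimeLapseStack,
    max_shift: int = 10,
    subvoxel: bool = False,
) -> DriftSeries:
    """Estimate cumulative stage drift of a time-lapse stack.

    For each consecutive frame pair the integer shift in
    ``[-max_shift, max_shift]^3`` maximizing the normalized cross-correlation
    is found (optionally refined to subvoxel precision by quadratic
    interpolation around the peak); the cumulative sum gives the drift of
    every frame relative to frame 0.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    if stack.n_frames < 2:
        raise ValueError("need at least two frames to estimate drift")
    pair_shifts = [np.zeros(3)]
    corrs = [1.0]
    for t in range(1, stack.n_frames):
        shift, peak = pairwise_shift(stack.frame(t - 1), stack.frame(t), max_shift, subvoxel)
        pair_shifts.append(shift)
        corrs.append(peak)
    return DriftSeries(np.cumsum(pair_shifts, axis=0), np.asarray(corrs))


def apply_drift(
    stack: TimeLapseStack, drift: DriftSeries
) -> tuple[TimeLapseStack, np.ndarray]:
    """Translate each frame by minus its cumulative shift.

    Integer parts are applied by slicing (no interpolation); any fractional
    part by spline interpolation.  Voxels shifted in from outside the field
    of view are filled with 0 and marked invalid in the returned boolean
    mask (same shape as the stack).
    """
    if len(drift) != stack.n_frames:
        raise ValueError("drift length must equal the number of frames")
    from scipy.ndimage import shift as nd_shift

    out = np.zeros_like(stack.intensities, dtype=float)
    valid = np.zeros(stack.shape, dtype=bool)
    for t in range(stack.n_frames):
        s = -drift.shifts[t]
        frame = stack.frame(t).astype(float)
        if np.allclose(s, np.round(s)):
            si = np.round(s).astype(int)
            src = tuple(
                slice(max(0, -sh), min(dim, dim - sh))
                for sh, dim in zip(si, frame.shape)
            )
            dst = tuple(
                slice(max(0, sh), min(dim, dim + sh))
                for sh, dim in zip(si, frame.shape)
            )
            out[t][dst] = frame[src]
            valid[t][dst] = True
        else:
            out[t] = nd_shift(frame, s, order=1, cval=0.0)
            ones = nd_shift(np.ones_like(frame), s, order=1, cval=0.0)
            valid[t] = ones > 0.999
    corrected = TimeLapseStack(out, voxel_size=stack.voxel_size,
                               frame_interval=stack.frame_interval, channel=stack.channel)
    return corrected, valid
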