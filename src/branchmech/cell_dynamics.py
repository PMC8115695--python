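"""Collective cell motion from dense optical flow of the nuclei channel.

The internal flow field of a branch is estimated by dense optical flow on
consecutive 2D frames (single slice or maximum projection), converted to
µm/min, and decomposed into the component parallel to the branch axis
(positive = outward, toward the invading tip) and the orthogonal component.
A direction-consensus order parameter

    Phi(t) = | mean over branch pixels of sign(v_par) |

classifies each frame pair: Phi above a threshold means the cells move
collectively (outward or inward, by the sign of the mean parallel
velocity); below it the motion is uncoordinated.  Finally, the branch-mean
parallel velocity is correlated against the concurrent ECM signal: outward
collective motion pairs with matrix relaxation and inward motion with
contraction, so the correlation is computed between v_par(t) and -s̄(t)
over a window of time lags.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stack import TimeLapseStack
from .ecm_deformation import BranchGeometry

__all__ = [
    "VelocityField",
    "MotionPhase",
    "CouplingResult",
    "compute_flow",
    "decompose",
    "order_parameter",
    "segment_phases",
    "couple_cell_ecm",
]


@dataclass
class VelocityField:
    """Dense per-pixel velocities in µm/min for each consecutive frame pair.

    vy, vx : (T-1, Y, X) arrays; positive vy points down the rows (image
    convention), positive vx along the columns.
    """

    vy: np.ndarray
    vx: np.ndarray
    frame_interval: float

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vy, self.vx)


@dataclass
class MotionPhase:
    start: int  # first frame-pair index of the interval
    stop: int  # exclusive
    label: str  # collective_outward | collective_inward | uncoordinated
    phi: float  # mean order parameter over the interval


@dataclass
class CouplingResult:
    lags: np.ndarray
    correlations: np.ndarray
    peak_lag: int
    peak_correlation: float


def _pyramid_flow(a: np.ndarray, b: np.ndarray, radius: int, num_warp: int,
                  gaussian: bool, levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Coarse-to-fine dense flow: ILK at each pyramid level plus warping.

    Single-scale iterative Lucas-Kanade only captures displacements up to
    roughly its window radius; estimating on a downsampled pyramid first
    and refining the upsampled field on warped images extends the range to
    ``radius * 2**(levels-1)`` pixels.
    """
    from skimage.registration import optical_flow_ilk
    from skimage.transform import rescale, resize
    from scipy.ndimage import map_coordinates

    pyr_a, pyr_b = [a], [b]
    for _ in range(levels - 1):
        if min(pyr_a[-1].shape) < 4 * radius:
            break
        pyr_a.append(rescale(pyr_a[-1], 0.5, anti_aliasing=True))
        pyr_b.append(rescale(pyr_b[-1], 0.5, anti_aliasing=True))

    fy = fx = None
    for la, lb in zip(reversed(pyr_a), reversed(pyr_b)):
        if fy is None:
            fy = np.zeros(la.shape)
            fx = np.zeros(la.shape)
        else:
            fy = 2.0 * resize(fy, la.shape, order=1)
            fx = 2.0 * resize(fx, la.shape, order=1)
        yy, xx = np.mgrid[: la.shape[0], : la.shape[1]].astype(float)
        warped = map_coordinates(lb, [yy + fy, xx + fx], order=1, mode="nearest")
        ry, rx = optical_flow_ilk(la, warped, radius=radius, num_warp=num_warp,
                                  gaussian=gaussian)
        fy, fx = fy + ry, fx + rx
    return fy, fx


def compute_flow(
    stack: TimeLapseStack,
    *,
    radius: int = 7,
    num_warp: int = 10,
    gaussian: bool = True,
    pyramid_levels: int = 3,
) -> VelocityField:
    """Dense optical flow of the nuclei channel, scaled to µm/min.

    3D stacks are reduced to 2D by maximum projection along Z.  Flow is
    estimated per consecutive frame pair with a coarse-to-fine dense
    iterative Lucas-Kanade scheme (``skimage.registration.optical_flow_ilk``
    on an image pyramid), oriented so that the returned vectors give the
    motion of image features from frame t to frame t+1.  Blank frame pairs
    yield a zero field with a warning.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least two frames for optical flow")
    frames = stack.intensities.max(axis=1)  # T Y X
    vs_y, vs_x = stack.voxel_size[1], stack.voxel_size[2]
    dt = stack.frame_interval
    vy = np.zeros((stack.n_frames - 1,) + frames.shape[1:])
    vx = np.zeros_like(vy)
    for t in range(stack.n_frames - 1):
        a, b = frames[t], frames[t + 1]
        if a.std() == 0 or b.std() == 0:
            warnings.warn(f"blank frame at pair {t}: zero flow")
            continue
        fy, fx = _pyramid_flow(a, b, radius, num_warp, gaussian, pyramid_levels)
        vy[t] = fy * vs_y / dt
        vx[t] = fx * vs_x / dt
    return VelocityField(vy=vy, vx=vx, frame_interval=dt)


def decompose(
    field: VelocityField,
    geometry: BranchGeometry,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split velocities into branch-parallel and orthogonal components.

    Uses the in-plane (x, y) part of the branch axis.  ``v_par`` is signed
    positive outward along the axis; ``v_orth`` positive along the axis
    rotated +90° (counter-clockwise with y up).  Pixels outside ``mask``
    are NaN.  The decomposition is exactly invertible:
    ``v = v_par * axis + v_orth * axis_perp``.
    """
    ax = np.asarray(geometry.axis[:2], dtype=float)
    n = np.linalg.norm(ax)
    if n == 0:
        raise ValueError("branch axis has no in-plane component")
    ax = ax / n
    # image rows increase downward: vy is the -y (math) component
    v_par = field.vx * ax[0] + (-field.vy) * ax[1]
    v_orth = field.vx * (-ax[1]) + (-field.vy) * ax[0]
    if mask is not None:
        mask = np.asarray(mask, bool)
        v_par = np.where(mask, v_par, np.nan)
        v_orth = np.where(mask, v_orth, np.nan)
    return v_par, v_orth


def order_parameter(v_par: np.ndarray, min_speed: float = 0.0) -> tuple[float, float]:
    """(Phi, mean v_par) of one frame's parallel-velocity map.

    Phi is the absolute mean sign of v_par over valid pixels — 1 for
    perfectly unidirectional motion, near 0 for balanced directions.
    Pixels slower than ``min_speed`` (and NaNs) are excluded.
    """
    v = np.asarray(v_par, dtype=float).ravel()
    v = v[np.isfinite(v)]
    v = v[np.abs(v) > min_speed]
    if v.size == 0:
        return 0.0, 0.0
    return float(abs(np.mean(np.sign(v)))), float(np.mean(v))


def segment_phases(
    v_par_series: list[np.ndarray] | np.ndarray,
    phi_threshold: float = 0.5,
    min_speed: float = 0.0,
) -> tuple[list[MotionPhase], np.ndarray]:
    """Segment a movie into collective / uncoordinated migration phases.

    ``v_par_series`` is a sequence of per-frame-pair parallel-velocity maps
    (any shape; only valid pixels are used).  Each frame pair is labelled
    collective (outward or inward by the sign of the mean) when
    ``Phi >= phi_threshold``, else uncoordinated; consecutive equal labels
    merge into intervals.  Returns ``(phases, phi_per_frame)``.
    """
    labels: list[str] = []
    phis = np.empty(len(v_par_series))
    for i, v in enumerate(v_par_series):
        phi, mean_v = order_parameter(v, min_speed=min_speed)
        phis[i] = phi
        if phi >= phi_threshold and mean_v != 0:
            labels.append("collective_outward" if mean_v > 0 else "collective_inward")
        else:
            labels.append("uncoordinated")
    phases: list[MotionPhase] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            phases.append(MotionPhase(start=start, stop=i, label=labels[start],
                                      phi=float(np.mean(phis[start:i]))))
            start = i
    return phases, phis


def couple_cell_ecm(
    v_par_series: np.ndarray,
    s_series: np.ndarray,
    max_lag: int = 5,
    method: str = "pearson",
) -> CouplingResult:
    """Lagged correlation between collective cell motion and ECM motion.

    Correlates the branch-mean parallel velocity ``v_par(t)`` with the
    negated ECM toward-tip signal ``-s̄(t)`` (outward cell motion pairs with
    matrix relaxation) at every lag in ``[-max_lag, max_lag]``; positive lag
    means the cells lead the matrix.  Constant series make the correlation
    undefined and raise a ``ValueError``.
    """
    v = np.asarray(v_par_series, dtype=float)
    s = -np.asarray(s_series, dtype=float)
    if v.shape != s.shape or v.ndim != 1:
        raise ValueError("series must be equal-length 1D arrays")
    if np.std(v) == 0 or np.std(s) == 0:
        raise ValueError("constant series: correlation undefined")

    def _corr(a, b):
        if method == "spearman":
            from scipy.stats import spearmanr

            return float(spearmanr(a, b).statistic)
        return float(np.corrcoef(a, b)[0, 1])

    lags = np.arange(-max_lag, max_lag + 1)
    corrs = np.full(len(lags), np.nan)
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = v[: len(v) - lag], s[lag:]
        else:
            a, b = v[-lag:], s[: len(s) + lag]
        if len(a) >= 3 and np.std(a) > 0 and np.std(b) > 0:
            corrs[i] = _corr(a, b)
    best = int(np.nanargmax(corrs))
    return CouplingResult(lags=lags, correlations=corrs,
                          peak_lag=int(lags[best]),
                          peak_correlation=float(corrs[best]))
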