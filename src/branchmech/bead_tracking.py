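"""Tracer-bead detection and track linking.

Beads embedded in the collagen gel act as fiducial markers of matrix
deformation.  Detection follows intensity-threshold masking: connected
components of the supra-threshold mask become candidate beads, localized by
the intensity-weighted centroid on a linearly interpolated (upsampled)
intensity grid.  Two filters guard against wrong trajectories, applied in
this order: (1) components touching the image boundary margin are removed,
then (2) for every pair of beads closer than a minimum distance BOTH are
removed.  Linking is mutual-nearest-neighbour matching between consecutive
frames within a link radius; a track is kept only if it spans at least
three consecutive frames, and a missed detection terminates it (no gap
closing).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .stack import TimeLapseStack

__all__ = [
    "BeadDetection",
    "BeadTrack",
    "detect_beads",
    "detect_beads_stack",
    "link_tracks",
    "track_displacements",
    "tracks_to_dataframe",
]


@dataclass(frozen=True)
class BeadDetection:
    frame: int
    position: tuple[float, float, float]  # (x, y, z) µm
    intensity: float  # peak intensity, a.u.


@dataclass
class BeadTrack:
    """Ordered bead detections over strictly consecutive frames (length >= 3)."""

    track_id: int
    detections: list[BeadDetection]

    def __post_init__(self) -> None:
        frames = [d.frame for d in self.detections]
        if len(frames) < 3:
            raise ValueError("a track requires at least three consecutive frames")
        if np.any(np.diff(frames) != 1):
            raise ValueError("track frames must be strictly consecutive")

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.position for d in self.detections])

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])

    def __len__(self) -> int:
        return len(self.detections)


def _centroid_upsampled(patch: np.ndarray, origin: np.ndarray,
                        threshold: float, upsample: int) -> np.ndarray:
    """Intensity-weighted centroid (voxel coords, z-y-x) on an interpolated grid."""
    if upsample > 1:
        fine = ndimage.zoom(patch, upsample, order=1, grid_mode=True, mode="nearest")
    else:
        fine = patch
    # threshold-subtracted weights: boundary pixels of the mask get ~zero
    # weight, so the centroid is continuous under noise at the mask edge
    w = np.maximum(fine - threshold, 0.0)
    if w.sum() == 0:
        w = fine - fine.min()
    grids = np.meshgrid(*[(np.arange(n) + 0.5) / upsample - 0.5 for n in fine.shape],
                        indexing="ij")
    com = np.array([float((g * w).sum() / w.sum()) for g in grids])
    return com + origin


def detect_beads(
    frame_image: np.ndarray,
    *,
    frame: int = 0,
    threshold: float | None = None,
    min_distance: float = 5.0,
    boundary_margin: int = 2,
    upsample: int = 4,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    smooth_sigma: float = 1.0,
    min_size: int = 5,
) -> list[BeadDetection]:
    """Detect beads in one Z x Y x X volume.

    The frame is first smoothed with a Gaussian of width ``smooth_sigma``
    voxels (a matched filter for spot-like signals; it suppresses
    single-voxel noise excursions that would otherwise pass the mask at low
    SNR — set 0 to disable).  ``threshold`` defaults to Otsu's threshold on
    the smoothed frame (the mask rule is otherwise unparameterized).
    ``min_distance`` is in µm, ``boundary_margin`` in voxels, ``upsample``
    the linear interpolation factor of the centroid grid.  Returns
    detections with positions in µm.  An empty mask yields an empty list,
    not an error.
    """
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    img = np.asarray(frame_image, dtype=float)
    if img.ndim == 2:
        img = img[None]
    if smooth_sigma > 0:
        sig = [smooth_sigma if dim > 1 else 0.0 for dim in img.shape]
        img = ndimage.gaussian_filter(img, sig)
    if threshold is None:
        from skimage.filters import threshold_otsu

        if img.max() == img.min():
            return []
        threshold = float(threshold_otsu(img))
    mask = img > threshold
    if not mask.any():
        return []
    labels, n = ndimage.label(mask)
    if n == 0:
        return []

    if min_size > 1:
        # residual noise excursions above the threshold are tiny compared
        # with a real spot footprint; drop them before any geometry filter
        sizes = np.bincount(labels.ravel())
        small = np.where(sizes < min_size)[0]
        if small.size:
            mask &= ~np.isin(labels, small)
            labels, n = ndimage.label(mask)
            if n == 0:
                return []

    objects = ndimage.find_objects(labels)
    margin = boundary_margin
    detections: list[tuple[np.ndarray, float]] = []
    for lab, sl in enumerate(objects, start=1):
        # boundary filter first: touching the margin band disqualifies
        touches = any(
            s.start < margin or s.stop > dim - margin
            for s, dim, dim_len in zip(sl, img.shape, img.shape)
            if dim_len > 2 * margin  # skip degenerate axes (e.g. single Z slice)
        )
        if touches:
            continue
        pad = 2
        psl = tuple(slice(max(0, s.start - pad), min(dim, s.stop + pad))
                    for s, dim in zip(sl, img.shape))
        patch = img[psl]
        origin = np.array([s.start for s in psl], dtype=float)
        com_vox = _centroid_upsampled(patch, origin, threshold, upsample)
        peak = float(img[sl].max())
        detections.append((com_vox, peak))

    if not detections:
        return []
    vs = np.asarray(voxel_size, dtype=float)
    pos_um = np.array([(c + 0.5) * vs for c, _ in detections])[:, ::-1]  # -> x,y,z

    # pairwise min-distance filter: BOTH members of a close pair are removed
    keep = np.ones(len(pos_um), dtype=bool)
    if len(pos_um) >= 2 and min_distance > 0:
        pairs = cKDTree(pos_um).query_pairs(min_distance, output_type="ndarray")
        if len(pairs):
            keep[np.unique(pairs)] = False

    return [
        BeadDetection(frame=frame, position=tuple(p), intensity=inten)
        for p, (_, inten), k in zip(pos_um, detections, keep) if k
    ]


def detect_beads_stack(stack: TimeLapseStack, **kwargs) -> list[list[BeadDetection]]:
    """Run :func:`detect_beads` on every frame of a stack."""
    kwargs.setdefault("voxel_size", stack.voxel_size)
    return [
        detect_beads(stack.frame(t), frame=t, **kwargs)
        for t in range(stack.n_frames)
    ]


def link_tracks(
    detections_per_frame: list[list[BeadDetection]],
    link_radius: float = 10.0,
) -> list[BeadTrack]:
    """Link per-frame detections into tracks (mutual nearest neighbours).

    Between each consecutive frame pair, a detection in frame t is linked to
    one in frame t+1 only if each is the other's nearest neighbour and the
    distance is within ``link_radius`` (µm).  Chains of links spanning at
    least three consecutive frames become tracks; no detection belongs to
    two tracks; everything else is dropped.
    """
    n_frames = len(detections_per_frame)
    # successor[t][i] = index of matched detection in frame t+1, or -1
    successors: list[np.ndarray] = []
    for t in range(n_frames - 1):
        a = detections_per_frame[t]
        b = detections_per_frame[t + 1]
        succ = np.full(len(a), -1, dtype=int)
        if a and b:
            pa = np.array([d.position for d in a])
            pb = np.array([d.position for d in b])
            ta, tb = cKDTree(pa), cKDTree(pb)
            d_ab, j_ab = tb.query(pa)  # nearest in b for each a
            d_ba, i_ba = ta.query(pb)  # nearest in a for each b
            for i, (dist, j) in enumerate(zip(d_ab, j_ab)):
                if dist <= link_radius and i_ba[j] == i:
                    succ[i] = j
        successors.append(succ)

    has_pred = [np.zeros(len(f), dtype=bool) for f in detections_per_frame]
    for t, succ in enumerate(successors):
        for j in succ[succ >= 0]:
            has_pred[t + 1][j] = True

    tracks: list[BeadTrack] = []
    tid = 0
    for t0 in range(n_frames):
        for i0 in range(len(detections_per_frame[t0])):
            if has_pred[t0][i0]:
                continue  # not a chain start
            chain = [(t0, i0)]
            t, i = t0, i0
            while t < n_frames - 1 and successors[t][i] >= 0:
                i = successors[t][i]
                t += 1
                chain.append((t, i))
            if len(chain) >= 3:
                dets = [detections_per_frame[tt][ii] for tt, ii in chain]
                tracks.append(BeadTrack(track_id=tid, detections=dets))
                tid += 1
    return tracks


def track_displacements(tracks: list[BeadTrack]) -> pd.DataFrame:
    """Per-step displacement vectors for every track.

    Returns a DataFrame with columns ``track_id, frame, x_um, y_um, z_um,
    dx_um, dy_um, dz_um`` where ``frame`` stamps the start of the step and
    (x, y, z) is the bead position at that frame.
    """
    rows = []
    for tr in tracks:
        pos = tr.positions
        frames = tr.frames
        steps = np.diff(pos, axis=0)
        for f, p, d in zip(frames[:-1], pos[:-1], steps):
            rows.append((tr.track_id, int(f), *p, *d))
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "x_um", "y_um", "z_um",
                       "dx_um", "dy_um", "dz_um"],
    )


def tracks_to_dataframe(tracks: list[BeadTrack]) -> pd.DataFrame:
    """Long-format table (track_id, frame, x_um, y_um, z_um, intensity)."""
    rows = [
        (tr.track_id, d.frame, *d.position, d.intensity)
        for tr in tracks for d in tr.detections
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um",
                                       "z_um", "intensity"])
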