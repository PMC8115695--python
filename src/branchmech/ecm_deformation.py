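"""ECM deformation statistics from bead tracks and branch geometry.

All statistics are expressed in the branch reference frame: the tip position
and the outward branch axis.  Every per-step bead displacement is projected
into that frame, giving its distance ``r`` to the tip, its angle ``theta``
to the axis, and the signed scalar ``s`` — the component of the step toward
the tip.  Sign convention, fixed everywhere in the codebase: motion toward
the branch tip (matrix contraction) is positive ``s``; motion away
(relaxation) is negative.

The derived statistics mirror the observables of branch mechanics:
the near-field cumulative displacement curve (plastic gain over time), the
angular anisotropy profile s̄(theta), the 100-µm distance-stripe profile,
per-frame contraction/relaxation phase labels, and the post-perturbation
relaxation delta.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BranchGeometry",
    "project_samples",
    "cumulative_displacement",
    "stripe_profile",
    "angular_profile",
    "frame_mean_series",
    "label_phases_ecm",
    "relaxation_delta",
]


@dataclass
class BranchGeometry:
    """Branch tip position (µm), outward unit axis, near-field radius (µm).

    The near field is the ECM region between the tip and ``near_field_radius``
    (default 300 µm) ahead of it, where deformation statistics are computed.
    """

    tip: tuple[float, float, float]
    axis: tuple[float, float, float]
    near_field_radius: float = 300.0

    def __post_init__(self) -> None:
        if self.near_field_radius <= 0:
            raise ValueError("near_field_radius must be positive")
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("axis must be non-zero")
        self.axis = tuple(ax / n)
        self.tip = tuple(float(v) for v in self.tip)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "tip": list(self.tip), "axis": list(self.axis),
            "near_field_um": self.near_field_radius,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BranchGeometry":
        d = json.loads(Path(path).read_text())
        return cls(tip=tuple(d["tip"]), axis=tuple(d["axis"]),
                   near_field_radius=float(d.get("near_field_um", 300.0)))


def project_samples(displacements: pd.DataFrame, geometry: BranchGeometry) -> pd.DataFrame:
    """Project per-step displacements into the branch frame.

    ``displacements`` is the table from
    :func:`~branchmech.bead_tracking.track_displacements`.  Adds columns:

    - ``r_um`` — distance of the bead to the tip (µm),
    - ``theta_deg`` — angle between the tip→bead vector and the branch
      axis, in [0, 180],
    - ``s_um`` — signed displacement toward the tip:
      ``s = -Δu · (unit vector from tip to bead)``.
    """
    tip = np.asarray(geometry.tip)
    axis = np.asarray(geometry.axis)
    pos = displacements[["x_um", "y_um", "z_um"]].to_numpy()
    du = displacements[["dx_um", "dy_um", "dz_um"]].to_numpy()
    d = pos - tip
    r = np.linalg.norm(d, axis=1)
    safe_r = np.where(r < 1e-12, 1.0, r)
    d_hat = d / safe_r[:, None]
    cos_t = np.clip(d_hat @ axis, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_t))
    s = -(du * d_hat).sum(axis=1)
    out = displacements.copy()
    out["r_um"] = r
    out["theta_deg"] = np.where(r < 1e-12, 0.0, theta)
    out["s_um"] = s
    return out


def cumulative_displacement(
    samples: pd.DataFrame,
    geometry: BranchGeometry,
    *,
    frame_interval: float = 10.0,
) -> pd.DataFrame:
    """Near-field cumulative mean displacement series.

    Per bead, the signed toward-tip steps ``s`` are summed over time while
    the bead stays inside the near field; when a bead leaves the region its
    running sum is frozen at the exit value (it stops accumulating but keeps
    contributing its frozen value to the mean, so the series has no jumps
    from population changes).  The series value at each time is the mean of
    the per-bead running sums; it starts at 0 at t = 0.

    Returns columns ``time_min, cumulative_um, n_active`` where ``n_active``
    counts beads still inside the near field.
    """
    nf = samples[samples["r_um"] <= geometry.near_field_radius]
    track_ids = nf["track_id"].unique()
    if len(track_ids) == 0:
        raise ValueError("empty near field: no bead samples within the region")

    frames = np.arange(samples["frame"].min(), samples["frame"].max() + 2)
    cum = {tid: 0.0 for tid in track_ids}
    frozen: set = set()
    times, values, n_active = [0.0], [0.0], [len(track_ids)]
    by_frame = dict(tuple(samples[samples["track_id"].isin(track_ids)].groupby("frame")))
    t0 = frames[0]
    for f in frames[:-1]:
        grp = by_frame.get(f)
        if grp is not None:
            for _, row in grp.iterrows():
                tid = row["track_id"]
                if tid in frozen or tid not in cum:
                    continue
                if row["r_um"] > geometry.near_field_radius:
                    frozen.add(tid)
                    continue
                cum[tid] += row["s_um"]
        times.append((f - t0 + 1) * frame_interval)
        values.append(float(np.mean(list(cum.values()))))
        n_active.append(len(track_ids) - len(frozen))
    return pd.DataFrame({"time_min": times, "cumulative_um": values,
                         "n_active": n_active})


def angular_profile(
    samples: pd.DataFrame,
    *,
    bin_width_deg: float = 15.0,
    theta_max: float = 90.0,
) -> pd.DataFrame:
    """Mean signed displacement s̄ binned by angle theta to the branch axis.

    Default 15° bins over [0°, theta_max].  Returns ``theta_lo, theta_hi,
    theta_mid, s_mean, s_std, n``; empty bins carry NaN means.
    """
    edges = np.arange(0.0, theta_max + bin_width_deg / 2, bin_width_deg)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = samples[(samples["theta_deg"] >= lo) & (samples["theta_deg"] < hi)]
        rows.append((lo, hi, (lo + hi) / 2,
                     sel["s_um"].mean() if len(sel) else np.nan,
                     sel["s_um"].std() if len(sel) else np.nan,
                     len(sel)))
    return pd.DataFrame(rows, columns=["theta_lo", "theta_hi", "theta_mid",
                                       "s_mean", "s_std", "n"])


def stripe_profile(
    samples: pd.DataFrame,
    geometry: BranchGeometry,
    stripe_width: float = 100.0,
    *,
    r_max: float | None = None,
    per_frame: bool = False,
) -> pd.DataFrame:
    """Mean signed displacement in 100-µm distance stripes ahead of the tip.

    Samples are binned by their distance ``r`` to the tip into stripes
    [0, w), [w, 2w), …  Empty stripes are flagged (``n = 0``, NaN mean) —
    missing data is not zero displacement.  With ``per_frame`` the mean is
    reported per (stripe, frame) pair.
    """
    if stripe_width <= 0:
        raise ValueError("stripe_width must be positive")
    if r_max is None:
        r_max = float(samples["r_um"].max()) if len(samples) else stripe_width
    edges = np.arange(0.0, r_max + stripe_width, stripe_width)
    keys = ["stripe_lo", "stripe_hi"] + (["frame"] if per_frame else [])
    rows = []
    frames = sorted(samples["frame"].unique()) if per_frame else [None]
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_stripe = samples[(samples["r_um"] >= lo) & (samples["r_um"] < hi)]
        for f in frames:
            sel = in_stripe if f is None else in_stripe[in_stripe["frame"] == f]
            row = [lo, hi] + ([f] if per_frame else [])
            rows.append(row + [sel["s_um"].mean() if len(sel) else np.nan, len(sel)])
    return pd.DataFrame(rows, columns=keys + ["s_mean", "n"])


def frame_mean_series(samples: pd.DataFrame, geometry: BranchGeometry) -> pd.DataFrame:
    """Per-frame mean s̄ over all near-field samples (frame, s_mean, n)."""
    nf = samples[samples["r_um"] <= geometry.near_field_radius]
    g = nf.groupby("frame")["s_um"].agg(["mean", "count"]).reset_index()
    return g.rename(columns={"mean": "s_mean", "count": "n"})


def label_phases_ecm(s_mean_series: np.ndarray, noise_floor: float = 0.0) -> list[str]:
    """Label each frame contraction / relaxation / neutral from s̄(t).

    Positive mean toward-tip displacement is a contraction phase, negative a
    relaxation; magnitudes at or below ``noise_floor`` are neutral.  The
    recommended floor is twice the median per-frame |s̄| of a zero-field
    calibration scene.
    """
    s = np.asarray(s_mean_series, dtype=float)
    labels = np.where(s > noise_floor, "contraction",
                      np.where(s < -noise_floor, "relaxation", "neutral"))
    return list(labels)


def relaxation_delta(series: pd.DataFrame, event_frame: int) -> float:
    """Signed change of the cumulative series after a perturbation event.

    ``value(end) - value(event_frame)``; negative values mean the matrix
    relaxed (beads retracted opposite to the accumulated deformation), as
    seen after actin disruption.  An event at the last frame gives 0.
    """
    vals = series["cumulative_um"].to_numpy()
    if not 0 <= event_frame < len(vals):
        raise IndexError("event_frame outside the series")
    return float(vals[-1] - vals[event_frame])
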