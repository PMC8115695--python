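import numpy as np
import pandas as pd
import pytest

from branchmech.synthetic import FieldParams, make_displacement_field
from branchmech.ecm_deformation import BranchGeometry


@pytest.fixture
def default_field() -> FieldParams:
    return FieldParams(amplitude=2.0, decay_length=150.0, anisotropy_exponent=2.0,
                       period=60.0, plastic_fraction=0.5,
                       tip=(0.0, 0.0, 0.0), axis=(1.0, 0.0, 0.0))


@pytest.fixture
def origin_geometry() -> BranchGeometry:
    return BranchGeometry(tip=(0.0, 0.0, 0.0), axis=(1.0, 0.0, 0.0))


def advect_tracks(params: FieldParams, pos0: np.ndarray, n_frames: int,
                  frame_interval: float = 10.0) -> np.ndarray:
    """Ground-truth advection: frame-to-frame field increments (no imaging)."""
    u = make_displacement_field(params)
    times = np.arange(n_frames) * frame_interval
    tracks = np.empty((n_frames,) + pos0.shape)
    tracks[0] = pos0
    for t in range(1, n_frames):
        p = tracks[t - 1]
        tracks[t] = p + u(p, times[t]) - u(p, times[t - 1])
    return tracks


def tracks_to_displacement_table(tracks: np.ndarray) -> pd.DataFrame:
    """(T, N, 3) µm positions -> the per-step displacement table."""
    T, N, _ = tracks.shape
    rows = []
    for b in range(N):
        for t in range(T - 1):
            d = tracks[t + 1, b] - tracks[t, b]
            rows.append((b, t, *tracks[t, b], *d))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "z_um",
                                       "dx_um", "dy_um", "dz_um"])


def front_hemisphere_beads(rng: np.random.Generator, n: int,
                           r_lo: float = 20.0, r_hi: float = 290.0) -> np.ndarray:
    """Beads uniformly on the front hemisphere of the tip (axis = +x)."""
    r = rng.uniform(r_lo, r_hi, n)
    cos_t = rng.uniform(0.0, 1.0, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    sin_t = np.sqrt(1 - cos_t**2)
    return np.column_stack([r * cos_t, r * sin_t * np.cos(phi), r * sin_t * np.sin(phi)])
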