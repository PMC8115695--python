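"""Time-lapse image container and TIFF I/O.

The universal input of the pipeline is a calibrated T x Z x Y x X intensity
array.  Calibration (voxel size in micrometres, frame interval in minutes)
travels with the array; it is written to a JSON sidecar next to the TIFF so
that round-tripping through files is lossless.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class TimeLapseStack:
    """Multi-frame 3D image stack with spatial and temporal calibration.

    Parameters
    ----------
    intensities : ndarray, shape (T, Z, Y, X)
        Non-negative image intensities.  Single-slice (thin-Z) movies use
        Z = 1.
    voxel_size : tuple of float
        Voxel edge length ``(z, y, x)`` in micrometres.
    frame_interval : float
        Time between consecutive frames in minutes (acquisition default
        10 min).
    channel : str
        Free-form channel label (``"beads"``, ``"nuclei"``, ``"collagen"``).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_interval: float = 10.0
    channel: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim == 3:  # single frame convenience
            arr = arr[None]
        if arr.ndim != 4:
            raise ValueError(f"expected TZYX array, got shape {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive lengths (z, y, x)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.intensities = arr
        self.voxel_size = vs

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.intensities.shape

    def frame(self, t: int) -> np.ndarray:
        """Z x Y x X volume at frame ``t``."""
        return self.intensities[t]

    def voxels_to_um(self, zyx: np.ndarray) -> np.ndarray:
        """Convert (..., 3) voxel-index coordinates (z, y, x) to (x, y, z) µm.

        Coordinates are voxel-centre based: index ``i`` maps to
        ``(i + 0.5) * voxel_size``.
        """
        zyx = np.asarray(zyx, dtype=float)
        um = (zyx + 0.5) * np.asarray(self.voxel_size)
        return um[..., ::-1]

    def um_to_voxels(self, xyz: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`voxels_to_um` (µm (x, y, z) -> voxel (z, y, x))."""
        xyz = np.asarray(xyz, dtype=float)
        return xyz[..., ::-1] / np.asarray(self.voxel_size) - 0.5

    def save(self, path: str | Path) -> None:
        """Write the stack as a multi-page TIFF plus a calibration sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.intensities.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "voxel_size_um_zyx": list(self.voxel_size),
            "frame_interval_min": self.frame_interval,
            "channel": self.channel,
            "axes": "TZYX",
        }, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TimeLapseStack":
        path = Path(path)
        arr = tifffile.imread(path)
        if arr.ndim == 3:
            arr = arr[:, None]  # T Y X -> T 1 Y X
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            intensities=np.asarray(arr),
            voxel_size=tuple(meta.get("voxel_size_um_zyx", (1.0, 1.0, 1.0))),
            frame_interval=float(meta.get("frame_interval_min", 10.0)),
            channel=meta.get("channel", ""),
        )
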