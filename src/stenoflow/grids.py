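"""Regular voxel grids shared by the flow generator, acquisition and analysis.

All grids are axis-aligned and isotropic.  Axis 0 is the axial (principal
flow) direction; axes 1 and 2 span the transverse plane.  Physical
coordinates are in meters; voxel centers sit at ``origin + (i + 0.5) * dx``
with 0-based indices.  The axial coordinate is usually reported in units of
the unconstricted pipe diameter, with 0 at the stenosis center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """A regular, isotropic voxel grid.

    Parameters
    ----------
    shape:
        Number of voxels along (axial, transverse, transverse).
    voxel_size:
        Isotropic voxel edge length in meters.
    origin:
        Physical coordinate (m) of the low corner of voxel (0, 0, 0).
        Voxel centers are at ``origin + (index + 0.5) * voxel_size``.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**3

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical center coordinates (m) of the voxels along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable center-coordinate arrays (x, y, z)."""
        x = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        z = self.axis_centers(2)[None, None, :]
        return x, y, z

    def contains_x(self, x: float) -> bool:
        """Whether an axial coordinate lies within the voxel-center range."""
        c = self.axis_centers(0)
        return bool(c[0] <= x <= c[-1])

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "voxel_size": self.voxel_size,
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(tuple(d["shape"]), float(d["voxel_size"]), tuple(d["origin"]))
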