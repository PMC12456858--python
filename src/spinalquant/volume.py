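"""In-memory image volume container.

A volume is a Z x Y x X intensity grid (Z = rostral -> caudal section
order, Y = dorsoventral rows, X = mediolateral columns) together with
its voxel size in micrometres and an optional channel role tag
("autofluorescence", "signal", "annotation", ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """Z x Y x X voxel grid with physical voxel sizes.

    Parameters
    ----------
    data:
        Array of shape (Z, Y, X).  Any real dtype; registration and
        resampling promote to float32 internally.
    voxel_size_um:
        (z, y, x) voxel edge lengths in micrometres.
    channel:
        Free-text role of this channel, e.g. "autofluorescence".
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (60.0, 10.0, 10.0)
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D (Z,Y,X), got shape {self.data.shape}")
        vz, vy, vx = self.voxel_size_um
        if vz <= 0 or vy <= 0 or vx <= 0:
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_um}")
        self.voxel_size_um = (float(vz), float(vy), float(vx))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_sections(self) -> int:
        return self.data.shape[0]

    def astype(self, dtype) -> "ImageVolume":
        return replace(self, data=self.data.astype(dtype))

    def copy(self) -> "ImageVolume":
        return replace(self, data=self.data.copy())

    # -- SimpleITK bridge ------------------------------------------------
    # SimpleITK indexes (x, y, z); numpy arrays here are (z, y, x), which
    # is exactly the memory layout GetImageFromArray expects.

    def to_sitk(self, dtype=np.float32) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.astype(dtype)))
        vz, vy, vx = self.voxel_size_um
        img.SetSpacing((vx, vy, vz))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, channel: str = "") -> "ImageVolume":
        arr = sitk.GetArrayFromImage(img)
        sx, sy, sz = img.GetSpacing()
        return cls(arr, voxel_size_um=(sz, sy, sx), channel=channel)

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= atol for a, b in zip(self.voxel_size_um, other.voxel_size_um)
        )
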