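"""Multi-channel 3D image stacks and their on-disk form (multi-page TIFF + YAML sidecar).

An :class:`ImageStack` is the unit of microscopy input throughout the package:
a ``(C, Z, Y, X)`` voxel grid with named channels and physical calibration
(lateral pixel size and axial step, both in nanometres).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
import yaml

__all__ = ["ImageStack", "read_stack", "write_stack"]


@dataclass
class ImageStack:
    """A calibrated multi-channel voxel grid.

    Parameters
    ----------
    voxels : ndarray, shape (C, Z, Y, X)
        Intensities, finite and non-negative.
    channels : list of str
        One label per channel (e.g. ``"fluor"``, ``"exclusion"``, ``"nuclear"``).
    pixel_size_nm : float
        Lateral pixel size in nm (> 0).
    z_step_nm : float
        Axial plane spacing in nm (> 0).
    """

    voxels: np.ndarray
    channels: list = field(default_factory=list)
    pixel_size_nm: float = 160.0
    z_step_nm: float = 500.0

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim == 3:  # single channel convenience
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 4:
            raise ValueError("voxels must have shape (C, Z, Y, X)")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.voxels.shape[0])]
        if len(self.channels) != self.voxels.shape[0]:
            raise ValueError("channel labels must match the first voxel axis")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.z_step_nm <= 0:
            raise ValueError("z_step_nm must be > 0")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")

    @property
    def shape(self):
        """(Z, Y, X) shape of a single channel."""
        return self.voxels.shape[1:]

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return the (Z, Y, X) array for a named channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (have {self.channels})"
            ) from None
        return self.voxels[idx]


def _sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".yaml"


def write_stack(stack: ImageStack, path: str, meta_path: str | None = None) -> str:
    """Write a stack as a multi-page TIFF plus a YAML metadata sidecar.

    Pages are ordered channel-major ((C, Z, Y, X) flattened over the first two
    axes); the sidecar records the axis sizes, channel labels and calibration.
    Returns the sidecar path.
    """
    meta_path = meta_path or _sidecar_path(path)
    c, z, y, x = stack.voxels.shape
    tifffile.imwrite(path, stack.voxels.reshape(c * z, y, x).astype(np.float32),
                     photometric="minisblack")
    meta = {
        "pixel_size_nm": float(stack.pixel_size_nm),
        "z_step_nm": float(stack.z_step_nm),
        "channels": list(stack.channels),
        "n_planes": int(z),
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh)
    return meta_path


def read_stack(path: str, meta_path: str | None = None) -> ImageStack:
    """Read a TIFF + YAML sidecar pair written by :func:`write_stack`.

    Raises ``ValueError`` naming the missing field if the sidecar lacks
    ``pixel_size_nm`` or ``z_step_nm``.
    """
    meta_path = meta_path or _sidecar_path(path)
    if not os.path.exists(meta_path):
        raise FileNotFoundError(f"metadata sidecar not found: {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}
    for key in ("pixel_size_nm", "z_step_nm"):
        if key not in meta:
            raise ValueError(f"stack metadata missing required field {key!r}")
    pages = np.asarray(tifffile.imread(path), dtype=float)
    if pages.ndim == 2:  # single-page TIFF -> depth-1 stack
        pages = pages[None]
    channels = list(meta.get("channels") or [])
    n_chan = max(len(channels), 1)
    n_planes = int(meta.get("n_planes", pages.shape[0] // n_chan))
    if n_chan * n_planes != pages.shape[0]:
        raise ValueError(
            f"page count {pages.shape[0]} inconsistent with "
            f"{n_chan} channels x {n_planes} planes"
        )
    voxels = pages.reshape(n_chan, n_planes, *pages.shape[1:])
    return ImageStack(
        voxels=voxels,
        channels=channels or None,
        pixel_size_nm=float(meta["pixel_size_nm"]),
        z_step_nm=float(meta["z_step_nm"]),
    )
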