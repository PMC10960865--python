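"""Core image containers and file I/O.

A :class:`FluorescenceImage` is a 2-D array of non-negative intensities in
arbitrary units (a.u.) with optional pixel size metadata; a :class:`RoiMask`
is a boolean array congruent with the image it indexes, tagged with the
biological role of the region (cytosol, whole cell, membrane, or focal
adhesion). Images round-trip through TIFF via :mod:`tifffile`; masks are
stored as 8-bit TIFF (0/255); polygon ROIs load from JSON vertex lists
(pixel coordinates, origin top-left, y increasing downward, 0-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.draw import polygon as _sk_polygon

from .errors import FormatError, InvalidParamsError

ROI_ROLES = ("cytosol", "cell", "membrane", "focal_adhesion")


@dataclass
class FluorescenceImage:
    """2-D fluorescence intensity grid.

    Parameters
    ----------
    data:
        2-D float array of intensities, all finite and >= 0.
    pixel_size_um:
        Physical pixel size in micrometres per pixel, or None if unknown.
    channel:
        Free-text channel label (e.g. ``"YFP-iSH2"``).
    """

    data: np.ndarray
    pixel_size_um: float | None = None
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidParamsError(f"image must be 2-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise InvalidParamsError("image contains non-finite values")
        if np.any(self.data < 0):
            raise InvalidParamsError("image contains negative intensities")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise InvalidParamsError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def scaled(self, c: float) -> "FluorescenceImage":
        """Return a copy with intensities multiplied by ``c`` (c > 0)."""
        if c <= 0:
            raise InvalidParamsError("scale factor must be positive")
        return FluorescenceImage(self.data * c, self.pixel_size_um, self.channel)


@dataclass
class RoiMask:
    """Binary region of interest congruent with an image."""

    data: np.ndarray
    role: str = "cytosol"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise InvalidParamsError(f"mask must be 2-D, got shape {self.data.shape}")
        if self.role not in ROI_ROLES:
            raise InvalidParamsError(f"role must be one of {ROI_ROLES}, got {self.role!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_pixels(self) -> int:
        return int(self.data.sum())

    def check_congruent(self, image: FluorescenceImage) -> None:
        if self.shape != image.shape:
            raise InvalidParamsError(
                f"mask shape {self.shape} does not match image shape {image.shape}"
            )


def read_image(path: str | Path, channel: str = "", pixel_size_um: float | None = None) -> FluorescenceImage:
    """Read a single-page TIFF as a FluorescenceImage."""
    data = tifffile.imread(str(path))
    if data.ndim != 2:
        raise FormatError(f"{path}: expected a single 2-D page, got shape {data.shape}")
    return FluorescenceImage(np.asarray(data, dtype=float), pixel_size_um, channel)


def write_image(path: str | Path, image: FluorescenceImage) -> None:
    tifffile.imwrite(str(path), image.data.astype(np.float32))


def read_mask(path: str | Path, role: str = "cytosol") -> RoiMask:
    """Read an 8-bit TIFF mask; any non-zero pixel is inside the ROI."""
    data = tifffile.imread(str(path))
    if data.ndim != 2:
        raise FormatError(f"{path}: expected a single 2-D mask page, got shape {data.shape}")
    return RoiMask(data != 0, role)


def write_mask(path: str | Path, mask: RoiMask) -> None:
    tifffile.imwrite(str(path), (mask.data.astype(np.uint8) * 255))


def polygon_mask(vertices, shape: tuple[int, int], role: str = "cytosol") -> RoiMask:
    """Rasterize a polygon given as (x, y) vertex pairs into a mask.

    Coordinates are 0-based pixel coordinates with origin at the top-left
    corner and y increasing downward (image-row convention).
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise FormatError("polygon must be an (n>=3, 2) array of (x, y) pairs")
    rr, cc = _sk_polygon(verts[:, 1], verts[:, 0], shape=shape)
    grid = np.zeros(shape, dtype=bool)
    grid[rr, cc] = True
    return RoiMask(grid, role)


def read_polygon_roi(path: str | Path, shape: tuple[int, int], role: str = "cytosol") -> RoiMask:
    """Load a polygon ROI from a JSON file.

    Accepts either a bare list of ``[x, y]`` pairs or an object with a
    ``"vertices"`` key holding that list.
    """
    with open(path) as fh:
        obj = json.load(fh)
    if isinstance(obj, dict):
        obj = obj.get("vertices")
    if obj is None:
        raise FormatError(f"{path}: no polygon vertices found")
    return polygon_mask(obj, shape, role)
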