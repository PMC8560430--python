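"""Saline-permeation quantification from grayscale microscope images.

Liquid intrusion between the substrate and the encapsulation layer of a
thin-film electrode array shows up in microscope images as a region of
altered intensity spreading from the edge of an electrode opening.  The
pipeline is: threshold the grayscale image (Otsu's criterion or a fixed
manually-tuned level), restrict to a region of interest, then report

* the permeated percentage of the ROI, and
* the maximum permeation distance — the largest Euclidean distance from
  any permeated pixel to the electrode-opening boundary, in µm (exact
  distance transform).

The % area depends entirely on the ROI chosen as denominator; the ROI
is therefore always caller-supplied (a rectangle around one electrode
opening in typical use).  A permeation front is only an electrical
shorting risk once it could meet a front growing from the neighbouring
site, i.e. when the distance reaches half the inter-electrode spacing
(400 µm spacing → 200 µm midpoint rule).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import numpy.typing as npt
from scipy import ndimage
from skimage.draw import line
from skimage.filters import threshold_otsu

__all__ = [
    "DEFAULT_ELECTRODE_SPACING_UM",
    "MicroscopyImage",
    "PermeationResult",
    "binarize",
    "permeation_area_percent",
    "max_permeation_distance",
    "shorting_risk",
    "boundary_from_polygon",
    "load_image",
    "quantify",
]

DEFAULT_ELECTRODE_SPACING_UM = 400.0

# ITU-R 601 luminance weights for RGB -> grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class MicroscopyImage:
    """Grayscale image with a physical pixel size (µm per pixel)."""

    pixels: npt.NDArray[np.float64]
    pixel_size_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or min(px.shape) < 16:
            raise ValueError("image must be 2-D and at least 16x16 pixels")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class PermeationResult:
    """Mask plus derived permeation metrics for one image."""

    mask: npt.NDArray[np.bool_]
    area_percent: float
    max_distance_um: float
    risk: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_percent <= 100.0:
            raise ValueError("area_percent must be within [0, 100]")
        if self.max_distance_um < 0:
            raise ValueError("max_distance_um must be non-negative")


def binarize(image: MicroscopyImage, method: str = "otsu", threshold: float | None = None):
    """Flag permeated (bright) pixels.

    ``method='otsu'`` picks the threshold maximizing between-class
    variance; ``method='fixed'`` uses the caller's ``threshold`` and
    reproduces a manually adjusted level.  A constant image has no
    foreground: an empty mask is returned with a warning under Otsu.
    """
    px = image.pixels
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed thresholding needs a threshold value")
        return px > threshold
    if method != "otsu":
        raise ValueError(f"unknown method {method!r}")
    if np.ptp(px) == 0:
        warnings.warn("constant image: Otsu threshold undefined, returning empty mask")
        return np.zeros_like(px, dtype=bool)
    return px > threshold_otsu(px)


def permeation_area_percent(mask, roi) -> float:
    """Permeated percentage of the ROI: 100·|mask ∧ roi| / |roi|."""
    mask = np.asarray(mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if mask.shape != roi.shape:
        raise ValueError("mask and roi shapes differ")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI is empty")
    return 100.0 * int((mask & roi).sum()) / n_roi


def _boundary_image(shape, boundary: Sequence[tuple[int, int]]):
    b = np.zeros(shape, dtype=bool)
    coords = np.asarray(list(boundary), dtype=int)
    if coords.size == 0:
        raise ValueError("boundary is empty")
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("boundary must be (row, col) pairs")
    if np.any(coords < 0) or np.any(coords[:, 0] >= shape[0]) or np.any(coords[:, 1] >= shape[1]):
        raise ValueError("boundary coordinates outside the image")
    b[coords[:, 0], coords[:, 1]] = True
    return b


def max_permeation_distance(
    mask, boundary: Sequence[tuple[int, int]], pixel_size_um: float
) -> float:
    """Largest min-Euclidean distance (µm) from permeated pixels to the boundary.

    Coordinates are 0-based (row, col) pixel centers.  Computed with the
    exact Euclidean distance transform; 0 for an empty mask.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    mask = np.asarray(mask, dtype=bool)
    b = _boundary_image(mask.shape, boundary)
    if not mask.any():
        return 0.0
    dist = ndimage.distance_transform_edt(~b)
    return float(dist[mask].max() * pixel_size_um)


def shorting_risk(
    max_distance_um: float, electrode_spacing_um: float = DEFAULT_ELECTRODE_SPACING_UM
) -> bool:
    """Midpoint rule: risk once the front reaches half the site spacing.

    Fronts can grow from both neighbouring sites, so two fronts meet at
    spacing/2.
    """
    if max_distance_um < 0 or electrode_spacing_um <= 0:
        raise ValueError("distances must be non-negative, spacing positive")
    return max_distance_um >= electrode_spacing_um / 2.0


def boundary_from_polygon(vertices: Sequence[tuple[int, int]], shape) -> list[tuple[int, int]]:
    """Rasterize an electrode-opening polygon perimeter to boundary pixels.

    Degenerate (collinear) "polygons" such as a straight two-point
    boundary line are accepted; pixels falling outside the image are
    dropped.
    """
    v = np.asarray(list(vertices), dtype=int)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("polygon needs at least 2 (row, col) vertices")
    rr_all, cc_all = [], []
    for i in range(v.shape[0]):
        r0, c0 = v[i]
        r1, c1 = v[(i + 1) % v.shape[0]]
        rr, cc = line(r0, c0, r1, c1)
        rr_all.append(rr)
        cc_all.append(cc)
    rr = np.concatenate(rr_all)
    cc = np.concatenate(cc_all)
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    pts = sorted(set(zip(rr[keep].tolist(), cc[keep].tolist())))
    return pts


def load_image(image_path, meta_path=None, pixel_size_um: float | None = None) -> MicroscopyImage:
    """Load a PNG/TIFF image as grayscale (RGB via luminance weights).

    The pixel size comes from ``pixel_size_um`` or from a sidecar JSON
    with key ``pixel_size_um``.
    """
    import imageio.v3 as iio

    px = np.asarray(iio.imread(image_path), dtype=float)
    if px.ndim == 3:
        px = px[..., :3] @ _LUMA
    if meta_path is not None:
        with open(meta_path, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        pixel_size_um = meta.get("pixel_size_um", pixel_size_um)
    if pixel_size_um is None:
        raise ValueError("pixel size required (argument or sidecar JSON)")
    return MicroscopyImage(px, float(pixel_size_um))


def quantify(
    image: MicroscopyImage,
    roi,
    boundary: Sequence[tuple[int, int]],
    method: str = "otsu",
    threshold: float | None = None,
    electrode_spacing_um: float = DEFAULT_ELECTRODE_SPACING_UM,
) -> PermeationResult:
    """Full pipeline: threshold → ROI area % → max distance → risk flag.

    The mask is restricted to the ROI before the distance measurement so
    that unrelated bright structures elsewhere in the frame do not
    inflate the permeation extent.
    """
    mask = binarize(image, method=method, threshold=threshold)
    roi = np.asarray(roi, dtype=bool)
    area = permeation_area_percent(mask, roi)
    d = max_permeation_distance(mask & roi, boundary, image.pixel_size_um)
    return PermeationResult(
        mask=mask & roi,
        area_percent=area,
        max_distance_um=d,
        risk=shorting_risk(d, electrode_spacing_um),
    )
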