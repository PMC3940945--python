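"""Color deconvolution and per-slide threshold optimization.

Converts an 8-bit RGB slide into per-stain optical-density concentration maps
(Beer–Lambert unmixing against a counterstain/chromogen/residual basis) and
derives a binary immunoreactive mask with a per-slide optimized threshold —
the computer-assisted determination of immunoreactive area that whole-slide
quantification rests on.

The threshold rule is Otsu's between-class-variance maximization on the
deconvolved chromogen OD channel restricted to tissue, floored at a
configurable minimum OD so near-blank slides do not produce noise masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

from .synthetic import FAST_RED_OD, HEMATOXYLIN_OD, SlideImage

__all__ = [
    "StainVectors",
    "StainConcentrations",
    "ImmunoreactiveMask",
    "default_stain_vectors",
    "rgb_to_od",
    "deconvolve_stains",
    "recompose_od",
    "estimate_threshold",
    "immunoreactive_mask",
]

#: epsilon added to 8-bit intensities before the log transform (avoids log 0)
OD_EPSILON = 1.0 / 255.0

#: default minimum OD a chromogen threshold may take
DEFAULT_OD_FLOOR = 0.15

#: default connected-component size filter at 4 um/px (~128 um^2 debris)
DEFAULT_MIN_OBJECT_PX = 8

#: reject stain matrices whose condition number exceeds this
MAX_CONDITION_NUMBER = 50.0


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class StainVectors:
    """Unit stain basis in OD space; ``residual`` completes the 3x3 matrix."""

    counterstain: Tuple[float, float, float]
    chromogen: Tuple[float, float, float]
    residual: Tuple[float, float, float]

    @classmethod
    def from_pair(cls, counterstain, chromogen) -> "StainVectors":
        c = _unit(counterstain)
        h = _unit(chromogen)
        r = np.cross(c, h)
        nr = np.linalg.norm(r)
        if nr < 1e-8:
            raise ValueError("counterstain and chromogen vectors are collinear")
        return cls(tuple(c), tuple(h), tuple(r / nr))

    @property
    def matrix(self) -> np.ndarray:
        """Rows: counterstain, chromogen, residual."""
        return np.array([self.counterstain, self.chromogen, self.residual], dtype=float)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


def default_stain_vectors() -> StainVectors:
    """Hematoxylin counterstain with a fast-red-like chromogen (literature values)."""
    return StainVectors.from_pair(HEMATOXYLIN_OD, FAST_RED_OD)


@dataclass
class StainConcentrations:
    """Per-pixel stain concentrations (OD units), aligned to the input raster."""

    counterstain: np.ndarray
    chromogen: np.ndarray
    residual: np.ndarray
    vectors: StainVectors

    @property
    def shape(self):
        return self.chromogen.shape


@dataclass
class ImmunoreactiveMask:
    """Binary raster of chromogen-positive pixels after threshold + size filter."""

    mask: np.ndarray  # (H, W) bool
    threshold_used: float  # OD units
    min_object_px: int
    mpp: float  # microns per pixel


def rgb_to_od(pixels: np.ndarray, eps: float = OD_EPSILON) -> np.ndarray:
    """Per-channel optical density: ``-log10((I + eps) / 255)``."""
    return -np.log10((pixels.astype(np.float64) + eps) / 255.0)


def deconvolve_stains(slide: Union[SlideImage, np.ndarray],
                      vectors: StainVectors,
                      max_condition: float = MAX_CONDITION_NUMBER) -> StainConcentrations:
    """Unmix an RGB raster into per-stain concentration maps.

    Per-pixel OD is projected onto the stain basis by inverting the stain
    matrix; negative concentrations (numerical leakage) are clipped to 0.
    """
    pixels = getattr(slide, "pixels", slide)
    if pixels.ndim != 3 or pixels.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    cond = vectors.condition_number
    if cond > max_condition:
        raise ValueError(
            f"stain matrix is near-singular (condition number {cond:.2f} "
            f"exceeds {max_condition})")
    od = rgb_to_od(pixels)
    inv = np.linalg.inv(vectors.matrix)
    conc = od.reshape(-1, 3) @ inv
    np.clip(conc, 0.0, None, out=conc)
    conc = conc.reshape(od.shape)
    return StainConcentrations(
        counterstain=conc[..., 0], chromogen=conc[..., 1],
        residual=conc[..., 2], vectors=vectors)


def recompose_od(conc: StainConcentrations) -> np.ndarray:
    """Inverse of deconvolution: concentrations back to a per-channel OD image."""
    stacked = np.stack([conc.counterstain, conc.chromogen, conc.residual], axis=-1)
    flat = stacked.reshape(-1, 3) @ conc.vectors.matrix
    return flat.reshape(stacked.shape)


def estimate_threshold(chromogen_map: np.ndarray, tissue_mask: np.ndarray,
                       od_floor: float = DEFAULT_OD_FLOOR,
                       nbins: int = 256) -> float:
    """Per-slide chromogen threshold: Otsu on tissue pixels, floored.

    Returns the configured OD floor when the tissue histogram is degenerate
    (constant map) or when Otsu's optimum falls below the floor — i.e. the
    slide carries no chromogen mode above background.
    """
    if chromogen_map.shape != tissue_mask.shape:
        raise ValueError("chromogen map and tissue mask shapes differ")
    values = chromogen_map[tissue_mask]
    if values.size == 0:
        raise ValueError("tissue mask is empty; cannot estimate a threshold")
    if float(np.ptp(values)) < 1e-9:
        return float(od_floor)
    t = float(threshold_otsu(values, nbins=nbins))
    return max(t, float(od_floor))


def immunoreactive_mask(chromogen_map: np.ndarray, tissue_mask: np.ndarray,
                        threshold: float,
                        min_object_px: int = DEFAULT_MIN_OBJECT_PX,
                        mpp: float = 4.0) -> ImmunoreactiveMask:
    """Threshold the chromogen map within tissue and drop sub-capillary debris.

    ``mask = (chromogen >= threshold) & tissue`` followed by removal of
    8-connected components smaller than ``min_object_px``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if chromogen_map.shape != tissue_mask.shape:
        raise ValueError("chromogen map and tissue mask shapes differ")
    raw = (chromogen_map >= threshold) & tissue_mask
    if min_object_px > 1:
        labels = _cc_label(raw, connectivity=2)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        raw = sizes[labels] >= min_object_px
    return ImmunoreactiveMask(mask=raw, threshold_used=float(threshold),
                              min_object_px=int(min_object_px), mpp=float(mpp))
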