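"""Deterministic hot-spot selection and the hot-spot evidence index.

Conventional quantification picks the k densest small regions ("hot spots",
0.26 mm² circles here) of a marker and measures only there.  This module
replaces the pathologist's subjective choice by a reproducible rule: the
stained-pixel density field (mask convolved with the circular hot-spot
kernel) is evaluated on a stride grid, restricted to circles lying at least
90% inside evaluable tissue, and the k maxima are taken greedily with
non-overlap enforced by a 2-radius centre distance; ties break in row-major
scan order.

Whether "evident" hot spots exist at all — the minority situation for
vascular markers in heterogeneous tumours — is operationalized by the
evidence ratio: mean hot-spot area fraction over the whole-slide area
fraction, evident when it exceeds a configurable threshold (default 2.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy.signal import fftconvolve

from ._raster import disk_kernel, mm_per_px
from .stains import ImmunoreactiveMask
from .vessels import HOTSPOT_AREA_MM2, RegionOfInterest

__all__ = [
    "HotSpot",
    "HotSpotSet",
    "select_hotspots",
    "hotspot_evidence",
    "DEFAULT_EVIDENCE_THRESHOLD",
]

DEFAULT_EVIDENCE_THRESHOLD = 2.0
MIN_TISSUE_COVERAGE = 0.90


@dataclass
class HotSpot:
    """One selected circular hot spot with its density score."""

    roi: RegionOfInterest
    center_mm: Tuple[float, float]
    stained_px: int
    coverage_px: int
    rank: int

    @property
    def score_fraction_pct(self) -> float:
        """Stained-area fraction (%) within the circle's evaluable pixels."""
        return 100.0 * self.stained_px / self.coverage_px


@dataclass
class HotSpotSet:
    hotspots: List[HotSpot]
    k: int
    evidence_ratio: Optional[float] = None
    evident: Optional[bool] = None

    @property
    def mean_fraction_pct(self) -> float:
        return float(np.mean([h.score_fraction_pct for h in self.hotspots]))


def _int_convolve(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Exact integer counts of a 0/1 raster under a 0/1 kernel via FFT.

    The convolution of binary rasters is integral, so rounding removes the
    FFT float noise and makes downstream tie-breaking exact.
    """
    out = fftconvolve(arr.astype(np.float64), kernel.astype(np.float64), mode="same")
    return np.maximum(np.rint(out), 0.0).astype(np.int64)


def select_hotspots(mask: Union[ImmunoreactiveMask, np.ndarray],
                    evaluable: np.ndarray,
                    k: int = 3,
                    hotspot_area_mm2: float = HOTSPOT_AREA_MM2,
                    mpp: Optional[float] = None,
                    stride_px: Optional[int] = None,
                    min_coverage: float = MIN_TISSUE_COVERAGE) -> HotSpotSet:
    """Greedy top-k disjoint circular hot spots of the stained density field.

    Raises when the evaluable tissue cannot host ``k`` non-overlapping
    circles (the thin-sample situation real cohorts exclude).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if hotspot_area_mm2 <= 0:
        raise ValueError("hotspot_area_mm2 must be > 0")
    m = getattr(mask, "mask", mask)
    if mpp is None:
        mpp = getattr(mask, "mpp", None)
    if mpp is None:
        raise ValueError("mpp must be provided when mask is a bare array")
    s = mm_per_px(mpp)
    evaluable_area = float(np.count_nonzero(evaluable)) * s * s
    if evaluable_area < k * hotspot_area_mm2:
        raise ValueError(
            f"evaluable tissue ({evaluable_area:.2f} mm^2) is too small for "
            f"{k} non-overlapping hot spots of {hotspot_area_mm2} mm^2")

    radius_mm = math.sqrt(hotspot_area_mm2 / math.pi)
    r_px = radius_mm / s
    kernel = disk_kernel(r_px)
    kernel_px = int(kernel.sum())

    counts = _int_convolve(m, kernel)
    coverage = _int_convolve(evaluable, kernel)

    stride = stride_px if stride_px is not None else max(1, int(round(r_px / 4)))
    rows = np.arange(0, m.shape[0], stride)
    cols = np.arange(0, m.shape[1], stride)
    cand_counts = counts[np.ix_(rows, cols)]
    cand_cover = coverage[np.ix_(rows, cols)]
    valid = cand_cover >= min_coverage * kernel_px
    if int(valid.sum()) < k:
        raise ValueError(
            f"only {int(valid.sum())} candidate centres have >="
            f"{min_coverage:.0%} tissue coverage; cannot place {k} hot spots")

    vr, vc = np.nonzero(valid)
    flat_scan = vr * len(cols) + vc  # row-major scan order on the stride grid
    dens = cand_counts[vr, vc]
    order = np.lexsort((flat_scan, -dens))  # primary: density desc; ties: scan order

    min_d2 = (2.0 * r_px) ** 2
    sel: List[Tuple[int, int, int, int]] = []  # (row_px, col_px, count, cover)
    for idx in order:
        rp = int(rows[vr[idx]])
        cp = int(cols[vc[idx]])
        if all((rp - r0) ** 2 + (cp - c0) ** 2 >= min_d2 for r0, c0, *_ in sel):
            sel.append((rp, cp, int(dens[idx]), int(cand_cover[vr[idx], vc[idx]])))
            if len(sel) == k:
                break
    if len(sel) < k:
        raise ValueError(
            f"could only place {len(sel)} non-overlapping hot spots (requested {k})")

    hotspots = []
    for rank, (rp, cp, cnt, cov) in enumerate(sel, start=1):
        center = ((cp + 0.5) * s, (rp + 0.5) * s)
        roi = RegionOfInterest.circle(center, m.shape, mpp, hotspot_area_mm2)
        hotspots.append(HotSpot(roi=roi, center_mm=center, stained_px=cnt,
                                coverage_px=cov, rank=rank))
    return HotSpotSet(hotspots=hotspots, k=k)


def hotspot_evidence(hotspot_set: HotSpotSet,
                     whole_slide_fraction: float,
                     ratio_threshold: float = DEFAULT_EVIDENCE_THRESHOLD
                     ) -> Tuple[float, Optional[bool]]:
    """Evidence ratio = mean hot-spot area fraction / whole-slide area fraction.

    ``evident`` is True when the ratio reaches ``ratio_threshold``.  A zero
    (or negative) whole-slide fraction leaves the evidence undefined: the
    set is flagged with ``(nan, None)`` rather than a computed value.
    """
    if whole_slide_fraction <= 0:
        hotspot_set.evidence_ratio = float("nan")
        hotspot_set.evident = None
        return float("nan"), None
    ratio = hotspot_set.mean_fraction_pct / whole_slide_fraction
    evident = bool(ratio >= ratio_threshold)
    hotspot_set.evidence_ratio = float(ratio)
    hotspot_set.evident = evident
    return float(ratio), evident
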