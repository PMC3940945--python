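"""Reading and writing slides, masks, ground truth and reports.

Slides travel as RGB TIFF (or PNG), tissue and immunoreactive masks as
single-channel PNG, ground truth and hot spots as GeoJSON in mm coordinates,
tabular output as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import tifffile
from PIL import Image
from shapely.geometry import mapping

from .hotspots import HotSpotSet
from .stains import ImmunoreactiveMask
from .synthetic import GroundTruth, SlideImage

__all__ = [
    "write_slide_bundle",
    "read_slide",
    "write_mask_png",
    "read_mask_png",
    "ground_truth_geojson",
    "hotspots_geojson",
    "centroids_geojson",
    "markup_overlay",
]


def write_mask_png(mask: np.ndarray, path) -> Path:
    path = Path(path)
    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)
    return path


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def ground_truth_geojson(gt: GroundTruth) -> dict:
    """GeoJSON FeatureCollection of object polygons and cell centroids (mm)."""
    features = []
    for i, poly in enumerate(gt.object_polygons):
        features.append({
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"object_index": i, "kind": "object"},
        })
    for marker, pts in gt.cell_centroids.items():
        for x, y in np.asarray(pts).reshape(-1, 2):
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                "properties": {"kind": "cell_centroid", "marker": marker},
            })
    return {
        "type": "FeatureCollection",
        "features": features,
        "properties": {
            "pattern_kind": gt.pattern_kind,
            "seed": gt.seed,
            "true_area_fraction_pct": gt.true_area_fraction,
            "units": "mm",
        },
    }


def hotspots_geojson(hotspot_set: HotSpotSet) -> dict:
    feats = []
    for h in hotspot_set.hotspots:
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(h.center_mm[0]), float(h.center_mm[1])]},
            "properties": {
                "rank": h.rank,
                "radius_mm": h.roi.radius_mm,
                "area_mm2": h.roi.area_mm2,
                "stained_fraction_pct": h.score_fraction_pct,
            },
        })
    return {"type": "FeatureCollection", "features": feats,
            "properties": {"k": hotspot_set.k, "units": "mm",
                           "evidence_ratio": hotspot_set.evidence_ratio,
                           "evident": hotspot_set.evident}}


def centroids_geojson(centroids: np.ndarray, marker: str) -> dict:
    feats = [{"type": "Feature",
              "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
              "properties": {"marker": marker}}
             for x, y in np.asarray(centroids).reshape(-1, 2)]
    return {"type": "FeatureCollection", "features": feats,
            "properties": {"units": "mm"}}


def write_slide_bundle(out_dir, slide: SlideImage,
                       gt: Optional[GroundTruth] = None,
                       image_format: str = "tiff") -> Dict[str, Path]:
    """Write image + tissue mask (+ ground-truth GeoJSON) for one slide."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    if image_format == "tiff":
        img = out / f"{slide.slide_id}.tiff"
        tifffile.imwrite(img, slide.pixels,
                         resolution=(10_000.0 / slide.mpp, 10_000.0 / slide.mpp))
    else:
        img = out / f"{slide.slide_id}.png"
        Image.fromarray(slide.pixels).save(img)
    paths["image"] = img
    paths["tissue_mask"] = write_mask_png(
        slide.tissue_mask, out / f"{slide.slide_id}_tissue.png")
    if gt is not None:
        gj = out / f"{slide.slide_id}_truth.geojson"
        gj.write_text(json.dumps(ground_truth_geojson(gt)))
        paths["ground_truth"] = gj
    return paths


def read_slide(image_path, tissue_mask_path, mpp: float,
               slide_id: Optional[str] = None) -> SlideImage:
    image_path = Path(image_path)
    if image_path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(image_path)
    else:
        pixels = np.asarray(Image.open(image_path).convert("RGB"))
    tissue = read_mask_png(tissue_mask_path)
    return SlideImage(pixels=pixels.astype(np.uint8), mpp=mpp,
                      tissue_mask=tissue,
                      slide_id=slide_id or image_path.stem)


def markup_overlay(slide: SlideImage, mask: ImmunoreactiveMask,
                   color=(0, 200, 0), alpha: float = 0.5) -> np.ndarray:
    """Mark-up image: detected immunoreactive area tinted on the slide."""
    out = slide.pixels.astype(np.float64).copy()
    m = mask.mask
    tint = np.asarray(color, dtype=np.float64)
    out[m] = (1.0 - alpha) * out[m] + alpha * tint
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
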