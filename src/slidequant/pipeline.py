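"""End-to-end orchestration: slide -> quantification record -> cohort report.

`quantify_vessel_slide` / `quantify_cell_slide` run the full per-slide chain
(deconvolution, per-slide threshold, mask, whole-slide measures, hot-spot
selection, per-hot-spot estimators, evidence index) and
`run_synthetic_experiment` reproduces the study design on synthetic cohorts:
a homogeneous and a clustered vessel cohort, their 85%-clustered mixture, and
a 70%-homogeneous cell cohort, quantified identically and compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from . import cells as cells_mod
from . import cohort as cohort_mod
from . import hotspots as hotspots_mod
from . import stains as stains_mod
from . import synthetic as synth
from . import vessels as vessels_mod
from ._raster import mm_per_px
from .cells import CellDetectionParams
from .cohort import SlideQuantification
from .stains import StainVectors
from .synthetic import GroundTruth, MarkerCohortSpec, SlideImage
from .vessels import RegionOfInterest

__all__ = [
    "PipelineConfig",
    "ObserverJitter",
    "quantify_vessel_slide",
    "quantify_cell_slide",
    "run_synthetic_experiment",
    "match_centroids",
]


@dataclass(frozen=True)
class ObserverJitter:
    """Second-observer simulation: scaled threshold, jittered hot-spot circles."""

    threshold_scale: float = 1.10
    center_jitter_um: float = 50.0
    seed: int = 7


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the per-slide quantification chain."""

    vectors: StainVectors = field(default_factory=stains_mod.default_stain_vectors)
    od_floor: float = stains_mod.DEFAULT_OD_FLOOR
    min_object_px: int = stains_mod.DEFAULT_MIN_OBJECT_PX
    k_hotspots: int = 3
    hotspot_area_mm2: float = vessels_mod.HOTSPOT_AREA_MM2
    evidence_threshold: float = hotspots_mod.DEFAULT_EVIDENCE_THRESHOLD
    merge_gap_um: float = vessels_mod.DEFAULT_MERGE_GAP_UM
    chalkley_rotations: int = vessels_mod.DEFAULT_CHALKLEY_ROTATIONS
    chalkley_offsets: int = vessels_mod.DEFAULT_CHALKLEY_OFFSETS
    cell_params: CellDetectionParams = field(default_factory=CellDetectionParams)
    min_evaluable_area_mm2: float = cohort_mod.DEFAULT_MIN_EVALUABLE_AREA_MM2


def _measure_hotspots(mask, hotspot_set, evaluable):
    return [vessels_mod.area_fraction(mask, h.roi, evaluable)
            for h in hotspot_set.hotspots]


def quantify_vessel_slide(slide: SlideImage, marker: str = "cd31",
                          config: PipelineConfig = PipelineConfig(),
                          gt: Optional[GroundTruth] = None,
                          observer2: Optional[ObserverJitter] = None,
                          predefined_spots=None) -> SlideQuantification:
    """Full vessel quantification of one slide (area fraction, MVD, Chalkley).

    ``predefined_spots`` is an optional list of (x, y) mm centres; the three
    estimators are additionally measured in those fixed-position circles (the
    setting in which estimator agreement is assessed, free of the selection
    bias of density-maximal hot spots).
    """
    evaluable = slide.tissue_mask
    conc = stains_mod.deconvolve_stains(slide, config.vectors)
    threshold = stains_mod.estimate_threshold(conc.chromogen, evaluable,
                                              config.od_floor)
    mask = stains_mod.immunoreactive_mask(conc.chromogen, evaluable, threshold,
                                          config.min_object_px, slide.mpp)
    whole = RegionOfInterest.whole_slide(evaluable, slide.mpp)
    ws_fraction = vessels_mod.area_fraction(mask, whole, evaluable)

    hs = hotspots_mod.select_hotspots(mask, evaluable, config.k_hotspots,
                                      config.hotspot_area_mm2)
    hs_fractions = _measure_hotspots(mask, hs, evaluable)
    ratio, evident = hotspots_mod.hotspot_evidence(hs, ws_fraction,
                                                   config.evidence_threshold)
    mvd = [vessels_mod.microvessel_density(mask, h.roi, config.merge_gap_um)
           for h in hs.hotspots]
    chalk = [vessels_mod.chalkley_count(mask, h.roi,
                                        n_rotations=config.chalkley_rotations,
                                        n_offsets=config.chalkley_offsets)
             for h in hs.hotspots]

    rec = SlideQuantification(
        slide_id=slide.slide_id, marker=marker,
        evaluable_area_mm2=whole.area_mm2,
        whole_slide_area_fraction=ws_fraction,
        hotspot_area_fractions=hs_fractions,
        mvd_counts=mvd, chalkley_counts=chalk,
        evidence_ratio=ratio, evident=evident,
        pattern_kind=gt.pattern_kind if gt else None,
        true_area_fraction=gt.true_area_fraction if gt else None,
    )
    for center in (predefined_spots or []):
        roi = RegionOfInterest.circle(center, slide.shape, slide.mpp,
                                      config.hotspot_area_mm2)
        rec.predefined_spot_fractions.append(
            vessels_mod.area_fraction(mask, roi, evaluable))
        rec.predefined_spot_mvd.append(
            vessels_mod.microvessel_density(mask, roi, config.merge_gap_um))
        rec.predefined_spot_chalkley.append(
            vessels_mod.chalkley_count(mask, roi,
                                       n_rotations=config.chalkley_rotations,
                                       n_offsets=config.chalkley_offsets))
    if observer2 is not None:
        rec.obs2_whole_slide_area_fraction, rec.obs2_hotspot_area_fractions = (
            _second_observer(conc.chromogen, evaluable, threshold, hs, slide.mpp,
                             config, observer2))
    return rec


def _second_observer(chromogen, evaluable, threshold, hotspot_set, mpp,
                     config: PipelineConfig, jitter: ObserverJitter):
    """Jittered-selection sensitivity mode standing in for a second human.

    The second observer re-thresholds at a scaled threshold and re-measures
    hot-spot circles displaced by a seeded jitter; the hot-spot search itself
    is not repeated (it is deterministic and would be identical).
    """
    t2 = threshold * jitter.threshold_scale
    mask2 = stains_mod.immunoreactive_mask(chromogen, evaluable, t2,
                                           config.min_object_px, mpp)
    whole = RegionOfInterest.whole_slide(evaluable, mpp)
    ws2 = vessels_mod.area_fraction(mask2, whole, evaluable)
    rng = np.random.default_rng(jitter.seed)
    jmm = jitter.center_jitter_um / 1000.0
    fracs = []
    for h in hotspot_set.hotspots:
        dx, dy = rng.normal(0.0, jmm, 2)
        center = (h.center_mm[0] + dx, h.center_mm[1] + dy)
        roi = RegionOfInterest.circle(center, mask2.mask.shape, mpp,
                                      config.hotspot_area_mm2)
        fracs.append(vessels_mod.area_fraction(mask2, roi, evaluable))
    return ws2, fracs


def quantify_cell_slide(slide: SlideImage, marker: str = "foxp3",
                        config: PipelineConfig = PipelineConfig(),
                        gt: Optional[GroundTruth] = None,
                        conc=None, centroids=None) -> SlideQuantification:
    """Cell-marker quantification: detection, whole-slide and hot-spot density.

    Hot spots for a cell marker are that marker's own density hot spots
    (selected on its immunoreactive mask), not vessel hot spots.
    ``conc``/``centroids`` accept precomputed deconvolution/detection results
    so callers measuring detection performance do not repeat the work.
    """
    evaluable = slide.tissue_mask
    if conc is None:
        conc = stains_mod.deconvolve_stains(slide, config.vectors)
    if centroids is None:
        centroids = cells_mod.detect_cells(conc.chromogen, evaluable,
                                           config.cell_params, slide.mpp)
    whole = RegionOfInterest.whole_slide(evaluable, slide.mpp)
    ws_density = cells_mod.cell_density(centroids, whole, evaluable, slide.mpp)

    mask = stains_mod.immunoreactive_mask(
        conc.chromogen, evaluable, config.cell_params.detection_threshold,
        min_object_px=2, mpp=slide.mpp)
    hs = hotspots_mod.select_hotspots(mask, evaluable, config.k_hotspots,
                                      config.hotspot_area_mm2)
    pooled = np.zeros_like(evaluable)
    for h in hs.hotspots:
        pooled |= h.roi.pixel_set
    pooled_roi = RegionOfInterest("circle_union", None,
                                  config.k_hotspots * config.hotspot_area_mm2,
                                  pooled, slide.mpp)
    hs_density = cells_mod.cell_density(centroids, pooled_roi, evaluable, slide.mpp)

    true_density = None
    if gt is not None and marker in gt.cell_centroids:
        true_density = cells_mod.cell_density(gt.cell_centroids[marker], whole,
                                              evaluable, slide.mpp)
    return SlideQuantification(
        slide_id=slide.slide_id, marker=marker,
        evaluable_area_mm2=whole.area_mm2,
        whole_slide_cell_density=ws_density,
        hotspot_cell_density=hs_density,
        pattern_kind=gt.pattern_kind if gt else None,
        true_cell_density=true_density,
    )


def match_centroids(detected: np.ndarray, truth: np.ndarray,
                    max_dist_mm: float) -> Tuple[int, int, int]:
    """Greedy nearest matching of detected to true centroids.

    Returns ``(matched, n_detected, n_truth)``; each true centroid is matched
    at most once, within ``max_dist_mm``.
    """
    detected = np.asarray(detected).reshape(-1, 2)
    truth = np.asarray(truth).reshape(-1, 2)
    if len(detected) == 0 or len(truth) == 0:
        return 0, len(detected), len(truth)
    tree = cKDTree(truth)
    dists, idx = tree.query(detected, k=1)
    order = np.argsort(dists)
    used = np.zeros(len(truth), dtype=bool)
    matched = 0
    for i in order:
        if dists[i] > max_dist_mm:
            break
        j = idx[i]
        if not used[j]:
            used[j] = True
            matched += 1
        else:
            # nearest already taken; try any unused true centroid in range
            cand = tree.query_ball_point(detected[i], max_dist_mm)
            for j2 in cand:
                if not used[j2]:
                    used[j2] = True
                    matched += 1
                    break
    return matched, len(detected), len(truth)


@dataclass
class ExperimentResult:
    """Everything `run_synthetic_experiment` computes, for reporting/tests."""

    vessel_homogeneous: List[SlideQuantification]
    vessel_clustered: List[SlideQuantification]
    vessel_mixture: List[SlideQuantification]
    cell_records: List[SlideQuantification]
    reports: Dict[str, object]
    cell_match: Dict[str, int]  # pooled detection-vs-truth match counts
    seeds: Dict[str, int]

    @property
    def cell_recall(self) -> float:
        return self.cell_match["matched_recall"] / max(self.cell_match["n_true_separated"], 1)

    @property
    def cell_precision(self) -> float:
        return self.cell_match["matched_precision"] / max(self.cell_match["n_detected"], 1)


def _sub_seed(master_seed: int, tag: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(tag),))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2 ** 31))


def run_synthetic_experiment(master_seed: int = 0,
                             n_slides: int = 20,
                             canvas_mm: Tuple[float, float] = (8.0, 8.0),
                             mpp: float = 4.0,
                             config: PipelineConfig = PipelineConfig(),
                             heterogeneous_vessel_fraction: float = 0.85,
                             heterogeneous_cell_fraction: float = 0.30,
                             observer2: Optional[ObserverJitter] = ObserverJitter()
                             ) -> ExperimentResult:
    """Render and quantify the full synthetic study.

    Three cohorts of ``n_slides`` are rendered: homogeneous vessels,
    clustered vessels, and a cell cohort with the stated heterogeneous
    fraction.  The 85%-clustered vessel mixture is assembled from the two
    pure vessel cohorts at matched n.  Slides are processed streaming so only
    the per-slide records are retained.
    """
    seeds = {"vessel_homogeneous": _sub_seed(master_seed, 101),
             "vessel_clustered": _sub_seed(master_seed, 102),
             "cells": _sub_seed(master_seed, 103)}
    vspec = synth.vessel_marker_spec(mpp)
    cspec = synth.nuclear_cell_marker_spec(mpp)

    # three fixed spots along the slide midline: estimator agreement is
    # assessed in predefined circles, free of hot-spot selection bias
    cx, cy = canvas_mm[0] / 2.0, canvas_mm[1] / 2.0
    spots = [(cx - 1.2, cy), (cx, cy), (cx + 1.2, cy)]

    def run_vessels(het_fraction, seed):
        recs = []
        for slide, gt in synth.iter_cohort(n_slides, het_fraction, vspec, seed,
                                           canvas_mm):
            recs.append(quantify_vessel_slide(slide, vspec.name, config, gt,
                                              observer2=observer2,
                                              predefined_spots=spots))
        return recs

    vessel_h = run_vessels(0.0, seeds["vessel_homogeneous"])
    vessel_c = run_vessels(1.0, seeds["vessel_clustered"])

    n_clustered = int(round(n_slides * heterogeneous_vessel_fraction))
    vessel_mix = vessel_c[:n_clustered] + vessel_h[: n_slides - n_clustered]

    cell_recs = []
    matched_prec = matched_rec = n_det = n_true = 0
    for slide, gt in synth.iter_cohort(n_slides, heterogeneous_cell_fraction,
                                       cspec, seeds["cells"], canvas_mm):
        conc = stains_mod.deconvolve_stains(slide, config.vectors)
        det = cells_mod.detect_cells(conc.chromogen, slide.tissue_mask,
                                     config.cell_params, slide.mpp)
        rec = quantify_cell_slide(slide, cspec.name, config, gt,
                                  conc=conc, centroids=det)
        cell_recs.append(rec)
        truth = gt.cell_centroids.get(cspec.name, np.empty((0, 2)))
        # recall is assessed on well-separated true cells: the detector counts
        # merged pairs once by construction, so overlapping truth is excluded
        # from the recall denominator (precision uses all true cells)
        sep = _well_separated(truth,
                              config.cell_params.min_center_separation_um / 1000.0)
        mp, d, _ = match_centroids(det, truth, 2.0 * cspec.cell_radius)
        mr, _, _ = match_centroids(det, sep, 2.0 * cspec.cell_radius)
        matched_prec += mp
        matched_rec += mr
        n_det += d
        n_true += len(sep)

    for recs in (vessel_h, vessel_c, cell_recs):
        cohort_mod.apply_exclusion_filter(recs, config.min_evaluable_area_mm2)

    densities = [r.whole_slide_cell_density for r in cell_recs]
    cats, _ = cells_mod.categorize_frequency(densities)
    for rec, cat in zip(cell_recs, cats):
        rec.cell_category = cat

    reports = {
        "vessel_homogeneous": cohort_mod.compare_methods(vessel_h),
        "vessel_clustered": cohort_mod.compare_methods(vessel_c),
        "vessel_mixture": cohort_mod.compare_methods(vessel_mix),
        "cells": cohort_mod.compare_methods(cell_recs),
        "all_vessels": cohort_mod.compare_methods(vessel_h + vessel_c),
    }
    # estimator agreement over predefined spots pooled across both vessel
    # cohorts (2 x n_slides slides, 3 spots each)
    all_vessels = vessel_h + vessel_c
    pf = [f for r in all_vessels for f in r.predefined_spot_fractions]
    pm = [m for r in all_vessels for m in r.predefined_spot_mvd]
    pc = [c for r in all_vessels for c in r.predefined_spot_chalkley]
    reports["predefined_spots"] = {
        "area_fraction_vs_mvd": cohort_mod.pearson_correlation(
            pf, pm, ("spot_area_fraction", "spot_mvd")),
        "area_fraction_vs_chalkley": cohort_mod.pearson_correlation(
            pf, pc, ("spot_area_fraction", "spot_chalkley")),
    }
    if observer2 is not None:
        reports["interobserver_whole_slide"] = cohort_mod.interobserver_variability(
            [r.whole_slide_area_fraction for r in vessel_mix],
            [r.obs2_whole_slide_area_fraction for r in vessel_mix])
        reports["interobserver_hotspot"] = cohort_mod.interobserver_variability(
            [r.hotspot_mean_area_fraction for r in vessel_mix],
            [float(np.mean(r.obs2_hotspot_area_fractions)) for r in vessel_mix])
    else:
        reports["interobserver_whole_slide"] = None
        reports["interobserver_hotspot"] = None

    return ExperimentResult(
        vessel_homogeneous=vessel_h, vessel_clustered=vessel_c,
        vessel_mixture=vessel_mix, cell_records=cell_recs,
        reports=reports,
        cell_match={"matched_precision": matched_prec, "matched_recall": matched_rec,
                    "n_detected": n_det, "n_true_separated": n_true},
        seeds=seeds)


def _well_separated(points: np.ndarray, min_sep_mm: float) -> np.ndarray:
    points = np.asarray(points).reshape(-1, 2)
    if len(points) < 2:
        return points
    tree = cKDTree(points)
    close = np.zeros(len(points), dtype=bool)
    for i, j in tree.query_pairs(min_sep_mm):
        close[i] = close[j] = True
    return points[~close]
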