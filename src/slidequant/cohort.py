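"""Cohort-level statistics: exclusion, correlation, interobserver variability.

This is the statistical layer of the method comparison: slides with too
little evaluable tissue are excluded (marked, never deleted), the vessel
estimators are correlated against each other over hot spots, hot-spot and
whole-slide quantification are correlated per marker, and two observers'
measurements are compared with the cohort-mean-normalized variability
statistic (acceptable strictly below 10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SlideQuantification",
    "CorrelationResult",
    "InterobserverResult",
    "FlaggedAnalysis",
    "apply_exclusion_filter",
    "pearson_correlation",
    "interobserver_variability",
    "compare_methods",
    "DEFAULT_MIN_EVALUABLE_AREA_MM2",
]

#: slides with less evaluable tissue than this are excluded
DEFAULT_MIN_EVALUABLE_AREA_MM2 = 5.0

#: interobserver variability acceptable strictly below this percentage
INTEROBSERVER_ACCEPTABLE_PCT = 10.0

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class SlideQuantification:
    """Per-slide quantification record for one marker."""

    slide_id: str
    marker: str
    evaluable_area_mm2: float
    whole_slide_area_fraction: Optional[float] = None  # percent
    hotspot_area_fractions: List[float] = field(default_factory=list)
    mvd_counts: List[int] = field(default_factory=list)
    chalkley_counts: List[int] = field(default_factory=list)
    whole_slide_cell_density: Optional[float] = None  # cells / 0.1 mm^2
    hotspot_cell_density: Optional[float] = None
    cell_category: Optional[str] = None
    evidence_ratio: Optional[float] = None
    evident: Optional[bool] = None
    excluded: bool = False
    pattern_kind: Optional[str] = None  # from ground truth when available
    true_area_fraction: Optional[float] = None
    true_cell_density: Optional[float] = None
    obs2_whole_slide_area_fraction: Optional[float] = None
    obs2_hotspot_area_fractions: List[float] = field(default_factory=list)
    # measurements in predefined (fixed-position) spots, the estimator-
    # agreement setting where MVD/Chalkley are compared against area fraction
    predefined_spot_fractions: List[float] = field(default_factory=list)
    predefined_spot_mvd: List[int] = field(default_factory=list)
    predefined_spot_chalkley: List[int] = field(default_factory=list)

    @property
    def hotspot_mean_area_fraction(self) -> Optional[float]:
        if not self.hotspot_area_fractions:
            return None
        return float(np.mean(self.hotspot_area_fractions))

    def to_row(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "marker": self.marker,
            "pattern_kind": self.pattern_kind,
            "evaluable_area_mm2": self.evaluable_area_mm2,
            "excluded": self.excluded,
            "whole_slide_area_fraction_pct": self.whole_slide_area_fraction,
            "hotspot_mean_area_fraction_pct": self.hotspot_mean_area_fraction,
            "mvd_counts": ";".join(str(c) for c in self.mvd_counts),
            "chalkley_counts": ";".join(str(c) for c in self.chalkley_counts),
            "whole_slide_density_per_0.1mm2": self.whole_slide_cell_density,
            "hotspot_density_per_0.1mm2": self.hotspot_cell_density,
            "cell_category": self.cell_category,
            "evidence_ratio": self.evidence_ratio,
            "evident": self.evident,
            "true_area_fraction_pct": self.true_area_fraction,
            "true_density_per_0.1mm2": self.true_cell_density,
        }


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    pair: Tuple[str, str]

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_LEVEL


@dataclass
class FlaggedAnalysis:
    """Placeholder for an analysis that could not be run (e.g. n too small)."""

    pair: Tuple[str, str]
    reason: str


@dataclass
class InterobserverResult:
    per_slide_variability: List[float]  # percent
    acceptable: List[bool]
    cohort_mean: float

    @property
    def mean_variability(self) -> float:
        return float(np.mean(self.per_slide_variability))


def apply_exclusion_filter(records: Sequence[SlideQuantification],
                           min_area_mm2: float = DEFAULT_MIN_EVALUABLE_AREA_MM2
                           ) -> List[SlideQuantification]:
    """Mark slides with evaluable area strictly below the threshold as excluded.

    Records are marked in place (never deleted from the persisted table);
    the returned list contains only the kept records.  Idempotent.
    """
    if min_area_mm2 <= 0:
        raise ValueError("min_area_mm2 must be > 0")
    for rec in records:
        rec.excluded = rec.evaluable_area_mm2 < min_area_mm2
    return [rec for rec in records if not rec.excluded]


def pearson_correlation(x: Sequence[float], y: Sequence[float],
                        pair: Tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p-value (df = n-2)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    for arr, name in ((x, pair[0]), (y, pair[1])):
        if float(np.ptp(arr)) == 0.0:
            raise ValueError(f"variable {name!r} has zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=n, pair=tuple(pair))


def interobserver_variability(obs1: Sequence[float], obs2: Sequence[float]
                              ) -> InterobserverResult:
    """Per-slide |difference| normalized to the cohort mean, in percent.

    The cohort mean pools both observers' measurements; a slide is acceptable
    when its variability is strictly below 10%.
    """
    a = np.asarray(list(obs1), dtype=float)
    b = np.asarray(list(obs2), dtype=float)
    if a.shape != b.shape:
        raise ValueError("observer series must have equal length")
    cohort_mean = float(np.mean(np.concatenate([a, b])))
    if cohort_mean <= 0:
        raise ValueError("cohort mean must be positive to normalize differences")
    variability = (np.abs(a - b) / cohort_mean * 100.0).tolist()
    acceptable = [v < INTEROBSERVER_ACCEPTABLE_PCT for v in variability]
    return InterobserverResult(per_slide_variability=variability,
                               acceptable=acceptable, cohort_mean=cohort_mean)


def _maybe_pearson(x, y, pair):
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        return FlaggedAnalysis(pair=pair, reason=f"insufficient n ({x.size} < 3)")
    if float(np.ptp(x)) == 0.0 or float(np.ptp(y)) == 0.0:
        return FlaggedAnalysis(pair=pair, reason="zero variance in one variable")
    return pearson_correlation(x, y, pair)


def holm_adjust(pvalues: Sequence[float]) -> List[float]:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def compare_methods(records: Sequence[SlideQuantification],
                    min_cohort_n: int = 10,
                    holm: bool = False) -> Dict[str, object]:
    """Cohort-level method comparison report.

    Emits (a) pooled hot-spot-level correlations of area fraction against MVD
    and against Chalkley, (b) per-marker hot-spot vs whole-slide correlation,
    (c) per-slide hot-spot/whole-slide ratios, and (d) the per-marker
    correlations stratified by ground-truth pattern kind when available.
    Analyses that cannot run (insufficient n, zero variance) are flagged in
    place rather than raised.  Significance is unadjusted two-sided p < 0.05
    by default; ``holm=True`` additionally reports Holm-adjusted p-values for
    the emitted correlation family under ``"holm_adjusted_p"``.
    """
    active = [r for r in records if not r.excluded]
    report: Dict[str, object] = {
        "n_records": len(records),
        "n_active": len(active),
        "partial": len(active) < min_cohort_n,
    }

    # (a) Pooled hot spots: area fraction vs MVD, vs Chalkley
    af, mvd, chalk = [], [], []
    for rec in active:
        k = min(len(rec.hotspot_area_fractions), len(rec.mvd_counts),
                len(rec.chalkley_counts))
        af += rec.hotspot_area_fractions[:k]
        mvd += rec.mvd_counts[:k]
        chalk += rec.chalkley_counts[:k]
    report["area_fraction_vs_mvd"] = _maybe_pearson(
        af, mvd, ("hotspot_area_fraction", "mvd"))
    report["area_fraction_vs_chalkley"] = _maybe_pearson(
        af, chalk, ("hotspot_area_fraction", "chalkley"))

    # (b)+(d) per-marker hot-spot vs whole-slide, optionally stratified
    by_marker: Dict[str, List[SlideQuantification]] = {}
    for rec in active:
        by_marker.setdefault(rec.marker, []).append(rec)
    marker_corr: Dict[str, object] = {}
    stratified: Dict[str, Dict[str, object]] = {}
    ratios = []
    for marker, recs in by_marker.items():
        pairs = _hotspot_wholeslide_pairs(recs)
        marker_corr[marker] = _maybe_pearson(
            [p[0] for p in pairs], [p[1] for p in pairs],
            (f"{marker}_hotspot", f"{marker}_whole_slide"))
        strat: Dict[str, object] = {}
        kinds = {r.pattern_kind for r in recs if r.pattern_kind}
        for kind in sorted(kinds):
            sub = [r for r in recs if r.pattern_kind == kind]
            sp = _hotspot_wholeslide_pairs(sub)
            strat[kind] = _maybe_pearson(
                [p[0] for p in sp], [p[1] for p in sp],
                (f"{marker}_{kind}_hotspot", f"{marker}_{kind}_whole_slide"))
        stratified[marker] = strat
        for rec, (h, w) in zip(recs, pairs):
            ratios.append({
                "slide_id": rec.slide_id, "marker": marker,
                "pattern_kind": rec.pattern_kind,
                "hotspot_value": h, "whole_slide_value": w,
                "ratio": (h / w) if w else np.nan,
            })
    report["hotspot_vs_whole_slide"] = marker_corr
    report["stratified"] = stratified
    report["ratios"] = pd.DataFrame(ratios)
    report["scatter"] = pd.DataFrame([r.to_row() for r in records])
    if holm:
        family = {
            key: res for key, res in (
                [("area_fraction_vs_mvd", report["area_fraction_vs_mvd"]),
                 ("area_fraction_vs_chalkley", report["area_fraction_vs_chalkley"])]
                + [(f"hotspot_vs_whole_slide_{m}", res)
                   for m, res in marker_corr.items()])
            if isinstance(res, CorrelationResult)
        }
        adj = holm_adjust([res.p for res in family.values()])
        report["holm_adjusted_p"] = dict(zip(family.keys(), adj))
    return report


def _hotspot_wholeslide_pairs(recs: Sequence[SlideQuantification]):
    """(hot-spot, whole-slide) value pairs: area fraction for vessel records,
    cell density for cell records."""
    pairs = []
    for r in recs:
        if r.whole_slide_cell_density is not None:
            pairs.append((r.hotspot_cell_density, r.whole_slide_cell_density))
        else:
            pairs.append((r.hotspot_mean_area_fraction, r.whole_slide_area_fraction))
    return [(h, w) for h, w in pairs if h is not None and w is not None]
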