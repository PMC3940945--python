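# slidequant

Whole-slide versus hot-spot quantification of immunohistochemical (IHC)
markers on digitalized tissue sections, with a synthetic slide generator
that provides exact ground truth.

## The problem

The classical way to quantify tumour vascularization or immune infiltrate
is *hot-spot analysis*: a pathologist selects a few small regions of maximal
marker density (here circles of 0.26 mm²) and counts there — micro-vessel
density (MVD), a 25-dot Chalkley score, or cell counts. That convention
comes from carcinomas with reliably hot-spot-distributed vessels. In
heterogeneous tumours such as osteosarcoma, hot spots are often absent or
ambiguous, and a density-maximizing selection is *guaranteed* to
overestimate: for hot spots chosen as maxima of the stained-density field,

```
mean hot-spot area fraction  ≥  whole-slide area fraction
```

on every slide, with the gap growing with spatial heterogeneity.
`slidequant` implements both quantification strategies end to end, plus the
statistics to compare them, so the whole-slide-vs-hot-spot question can be
studied quantitatively — and, because real patient slides come without
pixel-level truth, a forward model that renders calibrated synthetic IHC
slides (red chromogen on hematoxylin, Beer–Lambert optics, Poisson or
Thomas-cluster spatial patterns) with exact ground truth.

## What it computes

* **Stain quantification** — colour deconvolution into counterstain /
  chromogen optical-density maps (`OD = −log10((I+ε)/255)`, projection onto
  a unit stain basis), per-slide Otsu threshold with an OD floor, and the
  binary immunoreactive mask with a debris size filter.
* **Vessel estimators** — immunoreactive area fraction (%), MVD
  (morphological closing bridges endothelial interruptions, 8-connected
  components counted by centroid-in-ROI), digital Chalkley count (25-dot
  graticule, best of 64 rotations × 9 translations, range 0–25).
* **Hot-spot selection** — deterministic greedy top-k disjoint circles of
  the stained-density field on a stride grid, plus the evidence ratio
  (mean hot-spot fraction / whole-slide fraction).
* **Cell metrics** — blob detection of discrete immunoreactive cells with
  physical size bounds and a minimum-separation merge rule; densities in
  cells per 0.1 mm²; tertile low/intermediate/high categorization.
* **Cohort statistics** — exclusion of slides with < 5 mm² evaluable
  tissue, Pearson correlations (two-sided, p < 0.05), and interobserver
  variability (|Δ| / cohort mean × 100, acceptable strictly below 10%).

## Worked example

```python
import slidequant as sq
from slidequant import synthetic, pipeline

# one clustered ("hot-spot distributed") vessel-marker slide, 8x8 mm @ 4 um/px
spec = synthetic.vessel_marker_spec(mpp=4.0)
slide, truth = next(iter(synthetic.iter_cohort(
    1, heterogeneous_fraction=1.0, marker_spec=spec, master_seed=7)))
rec = pipeline.quantify_vessel_slide(slide, gt=truth)
print(f"true area fraction      {truth.true_area_fraction:.2f}%")
print(f"whole-slide measurement {rec.whole_slide_area_fraction:.2f}%")
print(f"hot-spot mean fraction  {rec.hotspot_mean_area_fraction:.2f}%")
print(f"evidence ratio          {rec.evidence_ratio:.1f}  (evident={rec.evident})")
print(f"MVD per hot spot        {rec.mvd_counts}")
print(f"Chalkley per hot spot   {rec.chalkley_counts}")
```

prints

```
true area fraction      7.57%
whole-slide measurement 7.57%
hot-spot mean fraction  59.25%
evidence ratio          7.8  (evident=True)
MVD per hot spot        [2, 1, 2]
Chalkley per hot spot   [21, 21, 19]
```

The whole-slide measurement recovers the generator's ground truth to two
decimals, while the three density-selected hot spots read 59% stained area
on a 7.6% slide — the hot-spot overestimation mechanism, here on a slide
whose vessels sit in dense Thomas-process clusters. The hot spots land on
cluster cores where vessels fuse into a few connected components, so MVD
collapses to 1–2 while the Chalkley score saturates — exactly why
identification of "singular" vessels is unreliable in heavily stained
regions and area fraction is the robust estimator.

There is also a CLI for file-based workflows:

```
slidequant simulate --n-slides 20 --heterogeneous-fraction 0.85 --seed 0 --out-dir cohort/
slidequant quantify stain --image cohort/cd31-000.tiff --tissue-mask cohort/cd31-000_tissue.png --mpp 4 --out-dir out/
slidequant hotspots --image cohort/cd31-000.tiff --tissue-mask cohort/cd31-000_tissue.png --mpp 4 --out-dir out/
slidequant compare --cohort-dir cohort/ --report-dir report/
```

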