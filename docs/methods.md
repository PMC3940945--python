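# Methods

`slidequant` implements the quantification chain used to characterize the
immunovascular microenvironment of heterogeneous tumours (the motivating
tissue is decalcified osteosarcoma) on digitalized immunohistochemistry
sections, together with a synthetic slide generator that supplies the exact
ground truth patient slides cannot. This note records the models, the
defaults and why, and what the synthetic validation does and does not show.

## Forward model: synthetic slides

**Spatial processes.** Marker objects (vessels or cells) are placed by one of
two regimes, the standard dichotomy for "scattered" versus "hot-spot"
distributions:

* *homogeneous* — a homogeneous Poisson process with intensity λ (objects per
  mm²) restricted to the tissue polygon;
* *clustered* — a Thomas-type parent–offspring process: parents Poisson with
  intensity λ_p on the tissue region buffered by 4σ (so offspring intensity is
  stationary inside the window, without edge depletion), offspring counts
  Poisson with mean μ, displaced isotropically with standard deviation σ and
  restricted to the tissue window. The overall intensity is λ = λ_p·μ.

Defaults for the clustered vessel regime are λ_p = 0.3 parents/mm² and
σ = 0.25 mm, chosen so a 0.26 mm² hot-spot circle lands on a cluster core and
measures stained fractions in the tens of percent — the visual situation on
hot-spot-distributed vascular mark-ups — rather than saturating near 100%.

**Objects.** Vessels are elongated elliptical rings: outer radius uniform in
15–40 µm, elongation uniform in 1–2.5, the inner 55% of the radius left
unstained (lumen), and with probability 0.15 an unstained arc of 20–60° cut
from the wall, emulating interruptions of the endothelial lining by tissue
tears or weak staining. Cells are disks of radius 8 µm (nuclear-marker
scale). Objects are shapely polygons; the painted raster is their
pixel-centre rasterization, so the ground-truth stained-area fraction is
recomputable exactly from the stored polygons.

**Stain optics.** Per-pixel optical density is the Beer–Lambert composition
`OD = c_h·v_h + c_c·v_c` of a hematoxylin counterstain vector
(0.650, 0.704, 0.286) and a fast-red-like chromogen vector
(0.214, 0.851, 0.478) (unit-norm literature values); transmitted intensity is
`I = I0·10^−OD` plus additive Gaussian sensor noise (σ = 1.5 8-bit counts),
quantized to 8 bits. Counterstain OD inside tissue is N(0.25, 0.04²) white
noise, clipped at 0. Per-slide staining variability — a prominent feature of
decalcified material even under optimized retrieval — is modelled by a
per-slide base chromogen OD drawn uniformly from (0.6, 1.4), with ±15%
per-object jitter on top; this reconciles "per-slide intensity variability"
with "per-object optical density" in a single two-level draw.

**Cohorts.** A cohort draws a per-slide target (vessel area fraction uniform
on 1.17–12.77%, the reported range for the endothelial marker; cell density
log-uniform on 0.13–4.1 cells/0.1 mm², putting the median at the reported
0.73) and converts it to a placement intensity through the expected painted
area per object. Exactly `round(n·heterogeneous_fraction)` slides are
clustered, assigned by a seeded permutation; the defaults follow the reported
distribution-pattern frequencies (85% heterogeneous for the vessel marker,
30% for the FOXP3-like and 20% for the CD8-like cell markers). Per-slide
seeds derive from the master seed as
`SeedSequence(master_seed, spawn_key=(index,))`, so any slide is regenerable
in isolation. Identical seeds give bit-identical slides.

**What the generator does not emulate:** histological texture, nuclear
chromatin, necrosis, tissue folds, scanner artifacts beyond additive RGB
noise, and genuinely ambiguous staining. Ground-truth recovery results
therefore validate the *estimators and their contracts*, not robustness to
real-world image-quality failure modes; on real slides the per-slide
threshold and the tissue annotation remain the critical human-controlled
inputs.

## Quantification chain

**Deconvolution.** `OD = −log10((I + ε)/255)` with ε = 1/255 (avoids
log 0; a pure white pixel yields concentrations that clip to exactly 0), then
projection onto the stain basis by inverting the 3×3 matrix completed with
the normalized cross product as residual vector. Matrices with condition
number above 50 are rejected. Negative concentrations are clipped to 0.
Generator and quantifier share stain vectors only through configuration —
mismatched vectors degrade gracefully, as with real stains.

**Per-slide threshold.** Otsu's between-class-variance maximization on the
chromogen OD channel over tissue pixels (256-bin histogram), floored at
OD 0.15. The floor handles degenerate, effectively unimodal slides: a blank
slide returns the floor and an empty mask instead of a noise mask. The
threshold is re-optimized per slide, mirroring per-section colour-threshold
optimization. Masks are monotone in the threshold before size filtering.

**Mask.** `(chromogen ≥ t) ∧ tissue`, then removal of 8-connected components
smaller than 8 px (≈128 µm² at 4 µm/px — sub-capillary debris).

**Area fraction.** `100·|mask ∩ ROI ∩ evaluable| / |ROI ∩ evaluable|`.

**MVD.** Morphological closing with a disk of radius 8 µm (capillary-wall
scale) bridges staining interruptions, then 8-connected components are
counted by centroid-in-ROI membership, so vessels straddling adjacent hot
spots are counted once.

**Chalkley.** 25 dots sampled uniformly in the unit disk under a minimum
separation of 0.18 from a fixed layout seed shipped as a package constant
(physical eyepiece graticules vary between makes; a frozen layout makes
counts reproducible across installations). The graticule is scaled to the
hot-spot radius and the best placement over 64 rotations × 9 translations
(centre plus 8 points at 10% of the field radius) is taken — a finite,
deterministic stand-in for the pathologist's manual adjustment. A dot hits
when its nearest pixel centre is mask-positive; no sub-pixel interpolation.

**Hot-spot selection.** The stained-count field (mask ⊛ circular kernel of
radius r = √(0.26/π) mm) is evaluated on a stride grid (stride r/4),
restricted to centres whose circle lies ≥ 90% inside evaluable tissue
(avoids perimeter artifacts), and the k = 3 maxima are taken greedily with
centre distance ≥ 2r; ties break in row-major scan order. The convolution is
FFT-based but rounded to exact integer counts, so tie-breaking is exact.
Slides whose evaluable tissue cannot host k disjoint circles are rejected,
mirroring the exclusion of thin samples.

**Evidence index.** Whether "evident" hot spots exist is operationalized as
`evidence_ratio = mean hot-spot fraction / whole-slide fraction`, evident
when ≥ 2.0 (configurable, never hard-coded into results). Under the
ratio definition almost every clustered slide is evident, so an
85%-clustered cohort is majority-evident; the reported 15% "evident" figure
stems from a human judgement of discrete, unambiguous hot spots that a
density ratio does not capture. The index is reported descriptively.

**Cell detection.** Blob detection on the chromogen map at a fixed OD 0.30
threshold, components kept when their area lies in 50–800 µm², centroids
closer than 12 µm merged (counted once, union-find with mean position),
restricted to evaluable tissue. Densities are reported in cells per 0.1 mm²
everywhere, including CSV headers, to avoid unit drift. Cell-marker hot
spots are that marker's own density hot spots, not vessel hot spots — when
correlating hot-spot against whole-slide cell counts, the marker-specific
reading is the defensible one and is documented here as the package's
choice. Semiquantitative low/intermediate/high categories default to cohort
tertiles (the original cut points are not defined anywhere); ties go to the
lower category, and a fixed cut-point mode exists for sensitivity analysis.

## Cohort statistics

Slides with evaluable area strictly below 5 mm² are excluded — marked, never
deleted. Correlations are product-moment Pearson r with two-sided t-test
p-values (df = n−2); significance at p < 0.05, no multiple-testing
correction by default (`compare_methods(..., holm=True)` additionally
reports Holm-adjusted p-values for the emitted correlation family). Interobserver variability for slide i
is `|obs1_i − obs2_i| / cohort_mean × 100` with the cohort mean pooled over
both observers, acceptable strictly below 10%. The alternative reading
("compared to mean values" as the per-slide mean) changes the denominator
per slide; the cohort-mean form is the default because the per-slide
variabilities are then comparable across the cohort. The second observer is
simulated as a re-run with a scaled threshold (×1.10) and hot-spot circles
jittered by N(0, 50 µm) — a jittered-selection sensitivity mode, since the
original disagreement is human.

## The synthetic experiment

`run_synthetic_experiment` renders and quantifies three 20-slide cohorts at
8×8 mm and 4 µm/px (2000×2000 px; full-scale sections average ~70 mm², and
larger canvases are a configuration change): homogeneous vessels, clustered
vessels, and a 30%-clustered cell cohort. The 85%-clustered vessel mixture
is assembled from the two pure cohorts (17 clustered + 3 homogeneous) — at
matched n this is the same mixture distribution without a third render pass.
Expected behaviour, verified by the acceptance tests at fixed seeds:

* whole-slide area fraction recovers ground truth within 0.5 percentage
  points on every slide; cell detection recall/precision ≥ 0.9 against
  non-overlapping true cells;
* mean hot-spot fraction ≥ whole-slide fraction on every slide (selection
  bias of density maxima);
* the homogeneous cohort's hot-spot↔whole-slide correlation is strong
  (r ≥ 0.8, p < 0.05) while the clustered cohort's is strictly weaker, and
  the 85%-clustered vessel mixture correlates more weakly than the
  70%-homogeneous cell mixture — the direction of the reported vascular
  (r = 0.391, n.s.) versus lymphocyte (r = 0.835) contrast, without claiming
  those patient-derived values;
* identical master seeds reproduce slides, masks, hot spots and report
  tables bit-identically.

## Numerical choices and degenerate inputs

* ε = 1/255 in the OD transform; concentrations clipped at 0.
* Otsu on a 256-bin histogram; constant maps return the OD floor.
* 8-connectivity everywhere components are labelled.
* FFT convolutions rounded to integer counts before any comparison.
* Ties: hot-spot candidates by scan order; cell categories to the lower
  bin; Chalkley placements by grid order (first maximal placement wins).
* Empty tissue masks, zero-area ROIs, zero whole-slide fractions and
  near-singular stain matrices raise or flag (`evidence = (nan, None)`)
  rather than silently producing numbers.

## Problem sizes

Tests and the acceptance script run the study at 20 slides per cohort,
8×8 mm at 4 µm/px, with brute-force oracle comparisons on rasters ≤ 128×128
and reduced-scale (4×4 mm at 8 µm/px) cohorts for module-level simulation
checks. These sizes are the package's reference configuration; every knob
(canvas, resolution, cohort size, cluster geometry) is exposed for
larger runs.

## Known limitations

* The evidence index cannot reproduce a subjective "evident hot spot"
  judgement; it is a transparent, deterministic proxy.
* MVD saturates when clusters overlap heavily (merged components), exactly
  the failure mode that motivates area fraction as the robust estimator.
* Blob-based cell detection undercounts genuinely overlapping cells by
  design (merge rule); the validation therefore conditions on
  well-separated cells.
* Survival analysis of patient cohorts is out of scope.
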