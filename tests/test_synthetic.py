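"""Generator correctness: point-process moments, rendering, ground truth."""

import numpy as np
import pytest
import shapely
from shapely.geometry import box

from slidequant import synthetic as synth
from slidequant.synthetic import (
    RenderParams,
    SpatialPatternParams,
    StainModelParams,
    render_slide,
    sample_point_pattern,
)


REGION_10MM2 = box(0.0, 0.0, 5.0, 2.0)  # 10 mm^2


class TestPointPatterns:
    def test_zero_intensity_gives_empty_pattern(self):
        p = SpatialPatternParams.homogeneous(0.0)
        pts = sample_point_pattern(p, REGION_10MM2, seed=1)
        assert pts.shape == (0, 2)

    def test_poisson_counts_match_theoretical_moments(self):
        # lambda = 10 / mm^2 on 10 mm^2: E[N] = 100, Var[N] = 100
        p = SpatialPatternParams.homogeneous(10.0)
        reps = 1000
        counts = [len(sample_point_pattern(p, REGION_10MM2, seed=s))
                  for s in range(reps)]
        se_mean = np.sqrt(100.0 / reps)
        assert abs(np.mean(counts) - 100.0) < 4 * se_mean
        # index of dispersion of the counts themselves is ~1 for Poisson
        assert 0.8 < np.var(counts) / np.mean(counts) < 1.25

    def test_clustered_counts_match_compound_poisson_moments(self):
        # parents 0.5 / mm^2, offspring mean 20: E[N] = 0.5*10*20 = 100
        p = SpatialPatternParams.clustered(0.5, 20.0, cluster_sigma=0.1)
        reps = 1000
        counts = [len(sample_point_pattern(p, REGION_10MM2, seed=s))
                  for s in range(reps)]
        # compound-Poisson variance: lam*A*mu*(1+mu) = 5*20*21 = 2100
        se_mean = np.sqrt(2100.0 / reps)
        assert abs(np.mean(counts) - 100.0) < 4 * se_mean

    def test_all_points_inside_region(self):
        for p in (SpatialPatternParams.homogeneous(30.0),
                  SpatialPatternParams.clustered(1.0, 30.0, cluster_sigma=0.3)):
            pts = sample_point_pattern(p, REGION_10MM2, seed=3)
            assert len(pts) > 0
            assert shapely.contains_xy(REGION_10MM2, pts[:, 0], pts[:, 1]).all()

    def test_quadrat_dispersion_separates_homogeneous_from_clustered(self):
        """Var/mean over disjoint quadrats ~1 for Poisson, >1 for clusters."""
        region = box(0.0, 0.0, 8.0, 8.0)
        edges = np.linspace(0.0, 8.0, 5)  # 16 quadrats of 4 mm^2

        def dispersion(params, seed):
            pts = sample_point_pattern(params, region, seed)
            counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[edges, edges])
            return counts.var() / counts.mean()

        homog = np.mean([dispersion(SpatialPatternParams.homogeneous(30.0), s)
                         for s in range(20)])
        clust = np.mean([dispersion(
            SpatialPatternParams.clustered(0.3, 100.0, cluster_sigma=0.25), s)
            for s in range(20)])
        assert 0.75 < homog < 1.25
        assert clust > 1.5

    def test_non_positive_region_rejected(self):
        p = SpatialPatternParams.homogeneous(1.0)
        degenerate = box(0, 0, 1, 1).intersection(box(2, 2, 3, 3))
        with pytest.raises(ValueError, match="region"):
            sample_point_pattern(p, degenerate, seed=0)

    @pytest.mark.parametrize("bad", [
        dict(pattern_kind="weird", intensity=1.0),
        dict(pattern_kind="homogeneous", intensity=-1.0),
        dict(pattern_kind="clustered", intensity=1.0, parent_intensity=0.5,
             offspring_per_parent=2.0, cluster_sigma=0.0),
        dict(pattern_kind="homogeneous", intensity=1.0,
             vessel_radius_range=(0.04, 0.01)),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            SpatialPatternParams(**bad)


SMALL_STAIN = StainModelParams(mpp=8.0)


class TestRendering:
    def test_same_seed_is_bit_identical(self):
        p = SpatialPatternParams.homogeneous(8.0)
        cells = {"foxp3": SpatialPatternParams.homogeneous(5.0, "cell")}
        a_slide, a_gt = render_slide(p, cells, SMALL_STAIN, (2.0, 2.0), seed=9)
        b_slide, b_gt = render_slide(p, cells, SMALL_STAIN, (2.0, 2.0), seed=9)
        assert np.array_equal(a_slide.pixels, b_slide.pixels)
        assert np.array_equal(a_slide.tissue_mask, b_slide.tissue_mask)
        assert a_gt.true_area_fraction == b_gt.true_area_fraction
        assert np.array_equal(a_gt.cell_centroids["foxp3"],
                              b_gt.cell_centroids["foxp3"])

    def test_blank_slide_has_zero_fraction_and_counterstain_only(self):
        from slidequant.stains import deconvolve_stains, default_stain_vectors

        p = SpatialPatternParams.homogeneous(0.0)
        slide, gt = render_slide(p, {"m": SpatialPatternParams.homogeneous(0.0, "cell")},
                                 SMALL_STAIN, (2.0, 2.0), seed=4)
        assert gt.true_area_fraction == 0.0
        assert not gt.object_polygons
        conc = deconvolve_stains(slide, default_stain_vectors())
        tissue = slide.tissue_mask
        # chromogen channel is background noise only, counterstain is not
        assert np.quantile(conc.chromogen[tissue], 0.99) < 0.1
        assert conc.counterstain[tissue].mean() > 0.15

    def test_true_fraction_equals_polygon_rasterization_oracle(self):
        """Brute-force full-grid rasterization of the ground-truth polygons
        reproduces true_area_fraction exactly."""
        p = SpatialPatternParams.homogeneous(6.0)
        slide, gt = render_slide(p, None, SMALL_STAIN, (2.0, 2.0), seed=5)
        assert len(gt.object_polygons) > 0
        H, W = slide.shape
        s = slide.mpp / 1000.0
        xs = (np.arange(W) + 0.5) * s
        ys = (np.arange(H) + 0.5) * s
        X, Y = np.meshgrid(xs, ys)
        painted = np.zeros((H, W), dtype=bool)
        for poly in gt.object_polygons:
            shapely.prepare(poly)
            painted |= shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(H, W)
        oracle = 100.0 * np.count_nonzero(painted & slide.tissue_mask) \
            / np.count_nonzero(slide.tissue_mask)
        assert oracle == pytest.approx(gt.true_area_fraction, abs=1e-12)
        assert np.array_equal(painted, gt.painted_mask)

    def test_pixel_budget_rejected_with_mpp_hint(self):
        with pytest.raises(ValueError, match="mpp"):
            render_slide(SpatialPatternParams.homogeneous(1.0), None,
                         StainModelParams(mpp=0.5), (8.0, 8.0), seed=0)

    def test_tiny_canvas_rejected(self):
        with pytest.raises(ValueError, match="canvas"):
            render_slide(SpatialPatternParams.homogeneous(1.0), None,
                         SMALL_STAIN, (0.5, 0.5), seed=0)


class TestCohorts:
    def test_mixture_counts_match_rounding(self):
        spec = synth.MarkerCohortSpec(
            name="m", object_kind="vessel", target_range=(2.0, 6.0),
            stain=StainModelParams(mpp=16.0))
        cohort = synth.generate_cohort(20, 0.85, spec, 7, (2.0, 2.0))
        kinds = [gt.pattern_kind for _, gt in cohort]
        assert kinds.count("clustered") == 17
        assert kinds.count("homogeneous") == 3

    def test_zero_heterogeneous_fraction_is_all_homogeneous(self):
        spec = synth.MarkerCohortSpec(
            name="m", object_kind="cell", target_range=(3.0, 10.0),
            stain=StainModelParams(mpp=16.0))
        cohort = synth.generate_cohort(5, 0.0, spec, 7, (2.0, 2.0))
        assert all(gt.pattern_kind == "homogeneous" for _, gt in cohort)

    def test_master_seed_reproduces_cohort(self):
        spec = synth.MarkerCohortSpec(
            name="m", object_kind="vessel", target_range=(2.0, 6.0),
            stain=StainModelParams(mpp=16.0))
        a = synth.generate_cohort(3, 0.5, spec, 11, (2.0, 2.0))
        b = synth.generate_cohort(3, 0.5, spec, 11, (2.0, 2.0))
        c = synth.generate_cohort(3, 0.5, spec, 12, (2.0, 2.0))
        for (sa, ga), (sb, gb) in zip(a, b):
            assert np.array_equal(sa.pixels, sb.pixels)
            assert ga.seed == gb.seed
        assert [g.seed for _, g in a] != [g.seed for _, g in c]

    def test_slide_regenerable_in_isolation(self):
        spec = synth.vessel_marker_spec(mpp=16.0)
        cohort = synth.generate_cohort(3, 0.0, spec, 11, (2.0, 2.0))
        assert cohort[2][1].seed == synth.slide_seed(11, 2)

    def test_manifest_records_cohort_parameters(self):
        spec = synth.MarkerCohortSpec(
            name="m", object_kind="vessel", target_range=(2.0, 6.0),
            stain=StainModelParams(mpp=16.0))
        cohort = synth.generate_cohort(4, 0.5, spec, 3, (2.0, 2.0))
        df = synth.cohort_manifest(cohort, spec, 3)
        assert len(df) == 4
        assert set(df["pattern_kind"]) == {"homogeneous", "clustered"}
        assert (df["master_seed"] == 3).all()

    @pytest.mark.parametrize("n,frac", [(0, 0.5), (5, 1.5), (5, -0.1)])
    def test_invalid_cohort_parameters_rejected(self, n, frac):
        spec = synth.vessel_marker_spec(mpp=16.0)
        with pytest.raises(ValueError):
            synth.generate_cohort(n, frac, spec, 0, (2.0, 2.0))
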