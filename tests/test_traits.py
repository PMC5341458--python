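"""Likelihood-weighted proxy traits: centroid, mass, boxes, quadrants, orientation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from autoroot import (
    EmptyWellError,
    GrayWell,
    LikelihoodMap,
    TraitRecord,
    bbox_argmax,
    bbox_quantile,
    centroid,
    compute_traits,
    mass,
    orientation_field,
    orientation_histogram,
    quadrant_mass,
    quadrant_orientation,
)


def lmap_from(arr):
    return LikelihoodMap(L=np.asarray(arr, dtype=float), norm_max=1.0)


def random_lmap(rng, shape=(40, 24)):
    return lmap_from(rng.random(shape))


class TestCentroid:
    def test_uniform_map_centres_geometrically(self):
        lm = lmap_from(np.ones((11, 7)))
        assert centroid(lm) == pytest.approx((3.0, 5.0))

    def test_point_mass_sits_at_its_pixel(self):
        L = np.zeros((20, 20))
        L[13, 4] = 0.7
        assert centroid(lmap_from(L)) == (4.0, 13.0)

    def test_weighted_mean_of_two_points(self):
        L = np.zeros((5, 5))
        L[0, 0] = 1.0
        L[0, 2] = 3.0  # likelihoods need not be <=1 for the arithmetic check
        cx, cy = centroid(lmap_from(L))
        assert cx == pytest.approx(1.5)
        assert cy == 0.0

    def test_zero_map_raises_empty_well(self):
        with pytest.raises(EmptyWellError):
            centroid(lmap_from(np.zeros((4, 4))))


class TestMass:
    def test_zero_and_saturated_maps(self):
        assert mass(lmap_from(np.zeros((10, 10)))) == (0.0, 0.0)
        assert mass(lmap_from(np.ones((10, 10)))) == (100.0, 1.0)

    def test_checkerboard_counts_half(self):
        L = np.indices((10, 10)).sum(axis=0) % 2
        raw, norm = mass(lmap_from(L))
        assert raw == 50.0 and norm == 0.5


class TestBboxArgmax:
    def test_single_pixel_gives_unit_width_and_its_depth(self):
        L = np.zeros((100, 20))
        L[40, 5] = 0.8
        assert bbox_argmax(lmap_from(L)) == (1, 40)

    def test_uniform_map_scores_the_far_edges(self):
        lm = lmap_from(np.ones((30, 20)))
        width, depth = bbox_argmax(lm)
        assert width == 20  # right edge x=19, left edge x=0
        assert depth == 29

    def test_dim_far_pixel_outscores_bright_near_pixel(self):
        # the extremity rule scores L*x, so 0.3*8 = 2.4 beats 0.9*2 = 1.8
        L = np.zeros((5, 10))
        L[0, 2] = 0.9
        L[0, 8] = 0.3
        width, _ = bbox_argmax(lmap_from(L))
        assert width == 8 - 2 + 1


class TestBboxQuantile:
    def test_single_row_mass(self):
        L = np.zeros((200, 10))
        L[100, :] = 1.0
        _, depth = bbox_quantile(lmap_from(L), 0.95)
        assert depth == 100

    def test_uniform_rows_reach_fraction_at_row_94(self):
        lm = lmap_from(np.ones((100, 10)))
        _, depth = bbox_quantile(lm, 0.95)
        assert depth == 94

    def test_outlier_row_is_discounted_at_p95_but_not_at_full_mass(self):
        L = np.zeros((600, 5))
        L[10, 0] = 99.0
        L[500, 0] = 1.0
        assert bbox_quantile(lmap_from(L), 0.95)[1] == 10
        assert bbox_quantile(lmap_from(L), 1.0)[1] == 500

    def test_width_trims_symmetrically(self):
        L = np.zeros((5, 100))
        L[0, :] = 1.0  # uniform over 100 columns
        width, _ = bbox_quantile(lmap_from(L), 0.95)
        # trimming 2.5 mass from each side leaves columns 2..97
        assert width == 96

    def test_zero_map_raises_empty_well(self):
        with pytest.raises(EmptyWellError):
            bbox_quantile(lmap_from(np.zeros((4, 4))), 0.95)


class TestQuadrantMass:
    def test_uniform_divisible_height_splits_equally(self):
        q = quadrant_mass(lmap_from(np.ones((40, 10))))
        np.testing.assert_allclose(q, [100.0] * 4)

    def test_bottom_row_mass_lands_in_q3(self):
        L = np.zeros((40, 10))
        L[-1, :] = 1.0
        q = quadrant_mass(lmap_from(L))
        np.testing.assert_allclose(q, [0, 0, 0, 10.0])

    def test_remainder_rows_go_to_the_bottom_band(self):
        # height 10 -> bands of 2,2,2,4 rows
        q = quadrant_mass(lmap_from(np.ones((10, 3))))
        np.testing.assert_allclose(q, [6, 6, 6, 12])

    @given(
        L=hnp.arrays(np.float64, (23, 11), elements=st.floats(0, 1, width=32))
    )
    @settings(max_examples=25)
    def test_quadrants_conserve_total_mass(self, L):
        lm = lmap_from(L)
        assert quadrant_mass(lm).sum() == pytest.approx(mass(lm)[0], rel=1e-9, abs=1e-12)


class TestOrientationField:
    def test_vertical_stripe_scores_ninety_degrees_at_its_flanks(self):
        arr = np.full((20, 21), 0.05)
        arr[:, 10] = 0.9
        field = orientation_field(GrayWell(arr))
        flank = field.magnitude[5:15, 9] > 0
        assert flank.all()
        assert np.allclose(field.theta[5:15, 9], 90.0)

    def test_horizontal_stripe_scores_zero_degrees(self):
        arr = np.full((21, 20), 0.05)
        arr[10, :] = 0.9
        field = orientation_field(GrayWell(arr))
        assert np.allclose(field.theta[9, 5:15], 0.0)
        assert (field.magnitude[9, 5:15] > 0).all()

    def test_uniform_image_has_no_defined_orientation(self):
        field = orientation_field(GrayWell(np.full((10, 10), 0.4)))
        assert (field.magnitude == 0).all()

    def test_theta_lies_in_its_quadrant_wherever_defined(self):
        rng = np.random.default_rng(2)
        field = orientation_field(GrayWell(rng.random((15, 15))))
        defined = field.magnitude > 0
        assert (field.theta[defined] >= 0).all()
        assert (field.theta[defined] <= 90).all()


class TestOrientationHistogram:
    def test_single_pixel_bin_arithmetic(self):
        # a 45 degree structure angle falls in bin 5 = [45, 54)
        arr = np.full((9, 9), 0.1)
        # diagonal bright line from top-left to bottom-right: gradients are
        # perpendicular to it, |Gx| == |Gy|, so theta = 90 - 45 = 45
        np.fill_diagonal(arr, 0.9)
        well = GrayWell(arr)
        field = orientation_field(well)
        L = np.zeros((9, 9))
        L[4, 3] = 0.8  # a flank pixel of the diagonal
        assert field.magnitude[4, 3] > 0 and field.theta[4, 3] == pytest.approx(45.0)
        hist = orientation_histogram(lmap_from(L), field)
        np.testing.assert_allclose(hist, [0, 0, 0, 0, 0, 0.8, 0, 0, 0, 0])

    def test_zero_gradient_well_contributes_nothing(self):
        well = GrayWell(np.full((8, 8), 0.3))
        hist = orientation_histogram(lmap_from(np.ones((8, 8))), orientation_field(well))
        assert (hist == 0).all()

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25)
    def test_bins_conserve_the_masked_likelihood_total(self, seed):
        rng = np.random.default_rng(seed)
        well = GrayWell(rng.random((12, 9)))
        lm = lmap_from(rng.random((12, 9)))
        field = orientation_field(well)
        expected = lm.L[field.magnitude > 0].sum()
        assert orientation_histogram(lm, field).sum() == pytest.approx(
            expected, rel=1e-9
        )


class TestQuadrantOrientation:
    def test_vertical_mass_in_bottom_band_hits_the_last_cell(self):
        arr = np.full((40, 21), 0.05)
        arr[:, 10] = 0.9  # vertical line -> theta 90 -> bracket 3
        well = GrayWell(arr)
        field = orientation_field(well)
        L = np.zeros((40, 21))
        L[35, 9] = 1.0  # flank pixel in band Q3 (rows 30..39)
        qo = quadrant_orientation(lmap_from(L), field)
        expected = np.zeros(16)
        expected[3 * 4 + 3] = 1.0
        np.testing.assert_allclose(qo, expected)

    def test_diagonal_texture_falls_in_bracket_two(self):
        # 45 degrees lies in bracket 2 = [45, 67.5)
        arr = np.full((16, 16), 0.1)
        np.fill_diagonal(arr, 0.9)
        well = GrayWell(arr)
        field = orientation_field(well)
        lm = lmap_from(np.ones((16, 16)))
        qo = quadrant_orientation(lm, field).reshape(4, 4)
        on_diag = field.theta[field.magnitude > 0]
        frac_45 = np.isclose(on_diag, 45.0).mean()
        assert frac_45 > 0.5  # most defined pixels hug the diagonal
        assert qo[:, 2].sum() > qo[:, [0, 1, 3]].sum().sum()

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25)
    def test_sixteen_cells_conserve_the_ten_bin_total(self, seed):
        rng = np.random.default_rng(seed)
        well = GrayWell(rng.random((21, 13)))
        lm = lmap_from(rng.random((21, 13)))
        field = orientation_field(well)
        total10 = orientation_histogram(lm, field).sum()
        total16 = quadrant_orientation(lm, field).sum()
        assert total16 == pytest.approx(total10, rel=1e-9, abs=1e-12)


class TestTraitRecord:
    def test_empty_record_is_flagged_and_zeroed(self):
        rec = TraitRecord.empty("img.png", 3)
        d = rec.to_dict()
        assert d["empty_flag"] == 1
        assert d["well_index"] == 3
        traits = [
            v
            for k, v in d.items()
            if k not in ("image_id", "well_index", "empty_flag", "leaf_area", "leaf_hue")
        ]
        assert all(v == 0 for v in traits)
        assert d["leaf_area"] == "" and d["leaf_hue"] == ""

    def test_column_order_is_stable_and_complete(self):
        cols = TraitRecord.columns()
        assert cols[0] == "image_id"
        assert len(cols) == len(set(cols)) == 3 + 4 + 5 + 4 + 10 + 16 + 2
        d = TraitRecord.empty("x", 0).to_dict()
        assert list(d) == cols

    def test_compute_traits_satisfies_conservation(self):
        rng = np.random.default_rng(9)
        well = GrayWell(rng.random((40, 24)))
        lm = lmap_from(rng.random((40, 24)))
        rec = compute_traits(lm, well, image_id="synthetic", well_index=2)
        assert rec.quadrant_mass.sum() == pytest.approx(rec.mass, rel=1e-9)
        assert rec.quadrant_orientation.sum() == pytest.approx(
            rec.orientation.sum(), rel=1e-9
        )


class TestProxyValidity:
    def test_depth_proxy_rank_orders_wells_with_true_length(self, proxy_study):
        """Proxy-depth must rank wells consistently with true primary length."""
        from scipy import stats

        truths, records = proxy_study
        true_len = np.array([t.primary_length for t in truths])
        depth = np.array([r.depth_m for r in records])
        rho = stats.spearmanr(true_len, depth).statistic
        assert rho >= 0.9

    def test_elongation_increases_depth_traits_and_q3_mass(self):
        """A longer root must score deeper boxes and more bottom-band mass."""
        from autoroot import SyntheticRootSpec, analyse_well_images, generate_root_well
        from conftest import BATCH_STRETCH

        images = []
        for length in (150.0, 300.0, 450.0, 600.0):
            spec = SyntheticRootSpec(
                primary_length=length, n_laterals=0, curvature_amplitude=8.0, seed=21
            )
            images.append(generate_root_well(spec)[0])
        recs = analyse_well_images(images, stretch=BATCH_STRETCH)
        for trait in ("depth_m", "depth_p95", "depth_p99"):
            vals = [getattr(r, trait) for r in recs]
            assert vals == sorted(vals) and vals[0] < vals[-1], trait
        q3 = [r.quadrant_mass[3] for r in recs]
        assert q3 == sorted(q3) and q3[0] < q3[-1]
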