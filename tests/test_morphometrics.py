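"""Shape indices, distance statistics, FA segmentation and FRET indices."""

import math

import numpy as np
import pytest
from scipy import ndimage

from cellmech.morphometrics import (FretParams, HeightProfile,
                                    boundary_cytoplasm_ratio, circularity,
                                    count_ruffles, fret_index_ratiometric,
                                    fret_index_singlechain,
                                    nn_distance_density,
                                    nuclear_cytoplasmic_class,
                                    segment_focal_adhesions, solidity,
                                    threshold_mean, threshold_moments)
from cellmech.synthetic_data import (make_fa_scene, make_fret_stack,
                                     make_height_profile, make_point_pattern,
                                     make_shape_mask)


class TestCircularity:
    def test_digitized_disc_is_one(self):
        mask, _ = make_shape_mask("disc", {"radius": 120})
        assert circularity(mask) == pytest.approx(1.0, abs=0.02)

    def test_thin_line_approaches_zero(self):
        line = np.zeros((5, 400), bool)
        line[2, 2:398] = True
        assert circularity(line) < 0.02

    def test_elongated_ellipse_matches_elliptic_integral(self):
        mask, truth = make_shape_mask("ellipse", {"a": 200, "b": 10})
        assert circularity(mask) == pytest.approx(truth["circularity"],
                                                  rel=0.03)

    def test_invariant_under_90_degree_rotation_and_translation(self):
        mask, _ = make_shape_mask("ellipse", {"a": 60, "b": 25})
        assert circularity(np.rot90(mask)) == pytest.approx(
            circularity(mask), rel=1e-12)
        shifted = np.roll(mask, (3, 5), axis=(0, 1))
        assert circularity(shifted) == pytest.approx(circularity(mask),
                                                     rel=1e-12)

    def test_stable_under_arbitrary_rotation(self):
        mask, _ = make_shape_mask("ellipse", {"a": 150, "b": 75})
        rot = ndimage.rotate(mask.astype(float), 33.0, order=1) > 0.5
        assert circularity(rot) == pytest.approx(circularity(mask), rel=0.03)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            circularity(np.zeros((10, 10), bool))


class TestSolidity:
    def test_disc_is_convex(self):
        mask, _ = make_shape_mask("disc", {"radius": 100})
        assert solidity(mask) == pytest.approx(1.0, abs=0.01)

    def test_plus_sign_matches_polygon_geometry(self):
        verts = [(0, 40), (0, 80), (40, 80), (40, 120), (80, 120), (80, 80),
                 (120, 80), (120, 40), (80, 40), (80, 0), (40, 0), (40, 40)]
        mask, truth = make_shape_mask("polygon", {"vertices": verts})
        assert solidity(mask) == pytest.approx(truth["solidity"], rel=0.03)

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(0)
        blob = np.zeros((64, 64), bool)
        blob[rng.integers(10, 54, 100), rng.integers(10, 54, 100)] = True
        blob = ndimage.binary_dilation(blob, iterations=2)
        assert solidity(blob) <= 1.0 + 1e-12


class TestNeighbourDistances:
    def test_unit_lattice_enumeration(self):
        pts, _ = make_point_pattern("lattice", n=36)
        _, _, pooled = nn_distance_density(pts, k=5)
        values, counts = np.unique(np.round(pooled, 9), return_counts=True)
        assert set(values) <= {1.0, round(math.sqrt(2), 9), 2.0}
        # interior points see 4 at distance 1 and 1 at sqrt(2) among their 5 NN
        interior = pooled.reshape(36, 5)[[7, 8, 9, 10]]
        for row in interior:
            assert sorted(np.round(row, 6)) == [1.0, 1.0, 1.0, 1.0,
                                                round(math.sqrt(2), 6)]

    def test_histogram_integrates_to_one(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 10, (100, 2))
        density, edges, _ = nn_distance_density(pts)
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)

    def test_jittered_coincident_points_mass_near_zero(self):
        rng = np.random.default_rng(2)
        pts = np.full((20, 2), 5.0) + rng.normal(0, 1e-6, (20, 2))
        _, _, pooled = nn_distance_density(pts)
        assert pooled.max() < 1e-4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            nn_distance_density(np.zeros((4, 2)), k=5)


class TestRuffles:
    def test_single_planted_peak(self):
        profile, _ = make_height_profile((20.0,))
        assert count_ruffles(profile) == 1

    def test_threshold_is_strict(self):
        profile, truth = make_height_profile((10, 14.9, 15.1, 40))
        assert count_ruffles(profile) == truth["count_above_threshold"] == 2

    def test_flat_profile_has_none(self):
        assert count_ruffles(np.zeros(50)) == 0

    def test_mirror_symmetry(self):
        profile, _ = make_height_profile((18.0, 30.0, 12.0))
        assert count_ruffles(profile.samples[::-1]) == count_ruffles(profile)

    def test_profiles_summed_per_cell(self):
        p1, _ = make_height_profile((20.0,))
        p2, _ = make_height_profile((25.0, 30.0))
        assert count_ruffles([p1, p2]) == 3


class TestThresholds:
    def test_mean_threshold(self):
        img = np.array([[0.0, 2.0], [4.0, 6.0]])
        assert threshold_mean(img) == 3.0

    def test_moments_separates_bimodal(self):
        rng = np.random.default_rng(3)
        img = np.concatenate([rng.normal(10, 1, 4000),
                              rng.normal(100, 5, 1000)]).reshape(50, 100)
        thr = threshold_moments(img)
        assert 15 < thr < 90


class TestFASegmentation:
    def test_recovers_planted_fas_per_cell(self):
        pax, act, nuc, truth = make_fa_scene(n_nuclei=3, fas_per_cell=4)
        seg = segment_focal_adhesions(pax, act, nuc)
        assert seg.n_fas == truth["n_fas_inside"]
        assert seg.fas_per_cell == pytest.approx(4.0)
        assert len(seg.per_fa) == seg.n_fas
        assert (seg.per_fa["area"] > 0).all()

    def test_background_only_paxillin_gives_zero_fas(self):
        pax, act, nuc, _ = make_fa_scene(n_nuclei=2, fas_per_cell=0)
        seg = segment_focal_adhesions(pax, act, nuc)
        assert seg.n_fas == 0

    def test_fa_outside_actin_region_excluded(self):
        pax, act, nuc, truth = make_fa_scene(n_nuclei=3, fas_per_cell=2,
                                             n_outside_fas=2)
        seg = segment_focal_adhesions(pax, act, nuc)
        assert seg.n_fas == truth["n_fas_inside"]

    def test_adding_one_fa_adds_one_component(self):
        scenes = [make_fa_scene(n_nuclei=1, fas_per_cell=k)[0:3]
                  for k in (3, 4)]
        counts = [segment_focal_adhesions(*s).n_fas for s in scenes]
        assert counts[1] == counts[0] + 1

    def test_zero_nuclei_rejected(self):
        pax, act, nuc, _ = make_fa_scene(n_nuclei=1, fas_per_cell=1)
        with pytest.raises(ZeroDivisionError):
            segment_focal_adhesions(pax, act, np.zeros_like(nuc))

    def test_shape_mismatch_rejected(self):
        pax, act, nuc, _ = make_fa_scene()
        with pytest.raises(ValueError):
            segment_focal_adhesions(pax[:-1], act, nuc)


class TestFret:
    def test_direct_substitution_without_bleedthrough(self):
        shape = (16, 16)
        donor = np.full(shape, 50.0)
        idx = fret_index_ratiometric(donor, 2 * donor, donor,
                                     FretParams(0.0, 0.0),
                                     np.ones(shape, int))
        assert idx[1] == pytest.approx(2.0)

    def test_forward_model_inversion(self):
        donor = np.full((32, 32), 100.0)
        d, f, a, _ = make_fret_stack(np.full((32, 32), 0.8), 0.3, 0.1, donor)
        idx = fret_index_ratiometric(d, f, a, FretParams(0.3, 0.1),
                                     np.ones((32, 32), int))
        assert idx[1] == pytest.approx(0.8, abs=1e-12)

    def test_bleedthrough_does_not_shift_corrected_index(self):
        donor = np.full((16, 16), 80.0)
        mask = np.ones((16, 16), int)
        _, f0, a0, _ = make_fret_stack(np.full((16, 16), 0.5), 0.0, 0.0, donor)
        _, f1, a1, _ = make_fret_stack(np.full((16, 16), 0.5), 0.4, 0.0, donor)
        r0 = fret_index_ratiometric(donor, f0, a0, FretParams(0.0, 0.0), mask)
        r1 = fret_index_ratiometric(donor, f1, a1, FretParams(0.4, 0.0), mask)
        assert r1[1] == pytest.approx(r0[1], abs=1e-12)

    def test_nonpositive_donor_pixels_excluded_with_warning(self):
        donor = np.full((8, 8), 10.0)
        donor[0, 0] = 0.0
        with pytest.warns(UserWarning):
            idx = fret_index_ratiometric(donor, donor, donor,
                                         FretParams(0.0, 0.0),
                                         np.ones((8, 8), int))
        assert idx[1] == pytest.approx(1.0)

    def test_singlechain_planted_ratios(self):
        cfp = np.full((32, 32), 100.0)
        fret = np.zeros_like(cfp)
        mask = np.zeros((32, 32), int)
        mask[4:10, 4:10] = 1
        mask[20:26, 20:26] = 2
        fret[mask == 1] = 40.0   # ratio 0.4
        fret[mask == 2] = 90.0   # ratio 0.9
        idx = fret_index_singlechain(fret, cfp, mask)
        assert idx[1] == pytest.approx(0.4)
        assert idx[2] == pytest.approx(0.9)

    def test_singlechain_limits(self):
        cfp = np.full((8, 8), 10.0)
        mask = np.ones((8, 8), int)
        assert fret_index_singlechain(cfp, cfp, mask)[1] == pytest.approx(1.0)
        assert fret_index_singlechain(np.zeros_like(cfp), cfp,
                                      mask)[1] == pytest.approx(0.0)


class TestIntensityClassifiers:
    @pytest.mark.parametrize("nuc, cyt, tol, expected", [
        (10.0, 5.0, 0.1, "N>C"),
        (5.0, 5.0, 0.1, "N=C"),
        (5.0, 5.0, 0.0, "N=C"),
        (100.0, 95.0, 0.1, "N=C"),
        (100.0, 80.0, 0.1, "N>C"),
        (80.0, 100.0, 0.1, "N<C"),
    ])
    def test_classification_rule(self, nuc, cyt, tol, expected):
        assert nuclear_cytoplasmic_class(nuc, cyt, tol) == expected

    def test_uniform_image_ratio_one(self):
        img = np.full((20, 20), 7.0)
        b = np.zeros((20, 20), bool)
        b[0] = True
        c = np.zeros((20, 20), bool)
        c[10] = True
        assert boundary_cytoplasm_ratio(img, b, c) == pytest.approx(1.0)

    def test_planted_ratio_recovered(self):
        img = np.full((20, 20), 4.0)
        b = np.zeros((20, 20), bool)
        b[0] = True
        img[0] = 10.0  # boundary ratio 2.5
        c = np.zeros((20, 20), bool)
        c[10] = True
        assert boundary_cytoplasm_ratio(img, b, c) == pytest.approx(2.5)

    def test_overlapping_masks_rejected(self):
        img = np.ones((5, 5))
        m = np.ones((5, 5), bool)
        with pytest.raises(ValueError):
            boundary_cytoplasm_ratio(img, m, m)
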