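"""Geometric refinement: morphology, components, and the pupil shape index."""

import math

import numpy as np
import pytest

from pupilloc import AppConfig
from pupilloc.errors import NoCandidateRegions
from pupilloc.refine import (
    Region,
    connected_components,
    ellipse_fit_error,
    fill_holes,
    inertia_ratio,
    morphological_open,
    pupil_shape_index,
    select_pupil_region,
)

from conftest import (
    disc_mask,
    ellipse_mask,
    random_blob_region,
    single_region,
)


def bruteforce_components_8(mask):
    """Independent flood-fill labeling oracle (8-adjacency)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            comp = set()
            while stack:
                y, x = stack.pop()
                comp.add((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            comps.append(comp)
    return comps


def bruteforce_inertia_ratio(region):
    """Closed-form eigenvalues of the coordinate covariance matrix."""
    x, y = region.coords()
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.sum(dx * dx)) / x.size
    syy = float(np.sum(dy * dy)) / x.size
    sxy = float(np.sum(dx * dy)) / x.size
    root = math.sqrt((sxx - syy) ** 2 + 4 * sxy**2)
    lam_max = (sxx + syy + root) / 2
    lam_min = (sxx + syy - root) / 2
    return 0.0 if lam_max <= 0 else max(lam_min, 0.0) / lam_max


class TestOpening:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert not morphological_open(mask, 1).any()

    def test_large_square_nearly_preserved(self):
        mask = np.zeros((31, 31), dtype=bool)
        mask[5:26, 5:26] = True
        out = morphological_open(mask, 1)
        assert out.sum() >= 0.95 * mask.sum()
        assert not (out & ~mask).any()  # anti-extensive

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        mask = rng.random((40, 40)) < 0.45
        once = morphological_open(mask, 1)
        assert np.array_equal(once, morphological_open(once, 1))

    def test_radius_zero_is_identity(self):
        mask = np.eye(5, dtype=bool)
        assert np.array_equal(morphological_open(mask, 0), mask)


class TestConnectedComponents:
    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(connected_components(mask, 8)) == 1

    def test_separated_blobs_are_two(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[1:3, 1:3] = True
        mask[5:7, 5:7] = True
        assert len(connected_components(mask, 8)) == 2

    def test_matches_bruteforce_floodfill(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            mask = rng.random((15, 15)) < 0.4
            ours = connected_components(mask, 8)
            oracle = bruteforce_components_8(mask)
            assert len(ours) == len(oracle)
            our_sets = set()
            for r in ours:
                x, y = r.coords()
                our_sets.add(frozenset(zip(y, x)))
            assert our_sets == {frozenset(c) for c in oracle}

    def test_checkerboard_is_single_component(self):
        mask = np.indices((4, 4)).sum(axis=0) % 2 == 0
        assert len(connected_components(mask, 8)) == 1
        assert len(bruteforce_components_8(mask)) == 1


class TestFillHoles:
    def test_annulus_becomes_disc(self):
        outer = disc_mask((40, 40), (20, 20), 15)
        inner = disc_mask((40, 40), (20, 20), 6)
        region = single_region(outer & ~inner)
        filled = fill_holes(region)
        assert filled.area == region.area + inner.sum()

    def test_border_open_concavity_unchanged(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:9, 2:8] = True
        mask[6:10, 4:6] = False  # notch open to the bottom border
        region = connected_components(mask)[0]
        assert fill_holes(region).area == region.area

    def test_idempotent_and_extensive(self):
        outer = disc_mask((40, 40), (20, 20), 15)
        inner = disc_mask((40, 40), (20, 20), 6)
        region = single_region(outer & ~inner)
        once = fill_holes(region)
        assert fill_holes(once).area == once.area
        assert once.area >= region.area


class TestInertiaRatio:
    def test_disc_near_one(self):
        assert inertia_ratio(single_region(disc_mask((60, 60), (30, 30), 20))) >= 0.98

    def test_two_to_one_ellipse_near_quarter(self):
        region = single_region(ellipse_mask((100, 120), (60, 50), 40, 20))
        assert abs(inertia_ratio(region) - 0.25) <= 0.02

    def test_line_degenerates_to_zero(self):
        mask = np.zeros((3, 52), dtype=bool)
        mask[1, 1:51] = True
        assert inertia_ratio(single_region(mask)) == 0.0

    def test_matches_bruteforce_eigenvalues(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            region = random_blob_region(rng)
            assert inertia_ratio(region) == pytest.approx(
                bruteforce_inertia_ratio(region), abs=1e-9
            )


class TestEllipseFitError:
    def test_disc_residual_is_small(self):
        assert ellipse_fit_error(single_region(disc_mask((60, 60), (30, 30), 20))) <= 0.08

    def test_square_mismatch_is_large(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 5:35] = True
        assert ellipse_fit_error(single_region(mask)) > 0.1

    def test_refit_of_fitted_ellipse_is_fixed_point(self):
        region = single_region(ellipse_mask((100, 120), (60, 50), 40, 20, 0.4))
        from pupilloc.refine import _central_moments, _moment_ellipse_mask

        cx, cy, cov = _central_moments(region)
        refit = single_region(_moment_ellipse_mask(cx, cy, cov, 0, 0, (100, 120)))
        assert ellipse_fit_error(refit) <= 0.05


class TestPupilShapeIndex:
    def test_disc_scores_high(self, cfg):
        score = pupil_shape_index(single_region(disc_mask((60, 60), (30, 30), 20)), cfg)
        assert score.w >= 0.95

    def test_two_to_one_ellipse_score(self, cfg):
        score = pupil_shape_index(
            single_region(ellipse_mask((100, 120), (60, 50), 40, 20)), cfg
        )
        assert score.w == pytest.approx(0.55, abs=0.05)

    def test_line_bounded_by_second_term(self, cfg):
        mask = np.zeros((3, 52), dtype=bool)
        mask[1, 1:51] = True
        score = pupil_shape_index(single_region(mask), cfg)
        assert score.inertia_ratio == 0.0
        assert score.w <= 0.4

    def test_score_in_unit_interval(self, cfg):
        rng = np.random.default_rng(12)
        for _ in range(20):
            w = pupil_shape_index(random_blob_region(rng), cfg).w
            assert 0.0 <= w <= 1.0

    def test_translation_invariance_exact(self, cfg):
        rng = np.random.default_rng(5)
        region = random_blob_region(rng)
        moved = Region(
            label=region.label,
            bbox_x0=region.bbox_x0 + 37,
            bbox_y0=region.bbox_y0 + 11,
            mask=region.mask,
        )
        s0 = pupil_shape_index(region, cfg)
        s1 = pupil_shape_index(moved, cfg)
        assert s0.inertia_ratio == s1.inertia_ratio
        assert s0.fitting_error == s1.fitting_error
        assert s0.w == s1.w

    def test_rotation_robustness(self, cfg):
        base = pupil_shape_index(
            single_region(ellipse_mask((120, 120), (60, 60), 35, 20, 0.0)), cfg
        )
        rot = pupil_shape_index(
            single_region(ellipse_mask((120, 120), (60, 60), 35, 20, math.pi / 6)), cfg
        )
        assert abs(base.w - rot.w) <= 0.05

    def test_elongation_penalty_monotone(self, cfg):
        # fixed area, aspect ratios 1, 2, 4: inertia term strictly decreases
        area_r = 20.0
        terms = []
        for aspect in (1, 2, 4):
            a = area_r * math.sqrt(aspect)
            b = area_r / math.sqrt(aspect)
            region = single_region(ellipse_mask((140, 180), (90, 70), a, b))
            terms.append(pupil_shape_index(region, cfg).inertia_ratio)
        assert terms[0] > terms[1] > terms[2]

    def test_tiny_region_scores_zero(self, cfg):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2:4] = True
        assert pupil_shape_index(connected_components(mask)[0], cfg).w == 0.0


class TestSelectPupilRegion:
    def test_disc_beats_line(self, cfg):
        frame = np.zeros((80, 80), dtype=bool)
        frame |= disc_mask((80, 80), (30, 40), 20)
        frame[70, 10:60] = True
        regions = connected_components(frame)
        winner, score = select_pupil_region(regions, cfg)
        cx, cy = winner.centroid()
        assert math.hypot(cx - 30, cy - 40) < 1.0
        assert score.w >= 0.9

    def test_filled_disc_beats_eyebrow_bar(self, cfg):
        frame = np.zeros((120, 120), dtype=bool)
        frame |= disc_mask((120, 120), (60, 70), 20)
        frame &= ~disc_mask((120, 120), (55, 65), 4)  # glint hole
        frame[10:18, 20:80] = True  # eyebrow-like bar
        regions = [fill_holes(r) for r in connected_components(frame)]
        winner, _ = select_pupil_region(regions, cfg)
        cx, cy = winner.centroid()
        assert math.hypot(cx - 60, cy - 70) < 1.0

    def test_no_candidates_raises(self, cfg):
        with pytest.raises(NoCandidateRegions):
            select_pupil_region([], cfg)
        tiny = np.zeros((6, 6), dtype=bool)
        tiny[2:4, 2:4] = True
        with pytest.raises(NoCandidateRegions):
            select_pupil_region(connected_components(tiny), cfg)
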