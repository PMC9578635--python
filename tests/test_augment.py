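import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

from mofaug import (
    LesionPatch,
    Placement,
    PlacementConstraints,
    build_lesion_bank,
    check_placement,
    extract_lesions,
    mof_augment,
    oversample,
)
from mofaug.augment import enlarge, mirror, rotate

STRUCTURE_8 = np.ones((3, 3), bool)


def count_components(label):
    return ndimage.label(np.asarray(label) > 0, structure=STRUCTURE_8)[1]


def random_patch(rng, max_side=12):
    h = int(rng.integers(1, max_side))
    w = int(rng.integers(1, max_side))
    fp = rng.random((h, w)) < 0.6
    if not fp.any():
        fp[h // 2, w // 2] = True
    return LesionPatch(rng.uniform(0, 1, (h, w)), fp)


# ---------------------------------------------------------------------------
# extraction

class TestExtractLesions:
    def test_empty_label_gives_empty_list(self):
        assert extract_lesions(np.zeros((8, 8)), np.zeros((8, 8), np.uint8)) == []

    def test_single_pixel_lesion(self):
        label = np.zeros((5, 5), np.uint8)
        label[2, 3] = 1
        (patch,) = extract_lesions(np.arange(25.0).reshape(5, 5), label)
        assert patch.shape == (1, 1)
        assert patch.footprint.all()
        assert patch.pixels[0, 0] == 13.0
        assert patch.source_bbox == (2, 3, 1, 1)

    def test_component_count_matches_brute_force_flood_fill(self, rng):
        """Patch count equals an independent flood-fill component count."""
        for _ in range(20):
            label = (rng.random((24, 24)) < 0.12).astype(np.uint8)
            patches = extract_lesions(rng.random((24, 24)), label)
            assert len(patches) == _flood_fill_count(label)
            # total footprint area equals total lesion pixels
            assert sum(p.area for p in patches) == int(label.sum())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_lesions(np.zeros((4, 4)), np.zeros((5, 5), np.uint8))


def _flood_fill_count(label):
    """Brute-force 8-connected component count by iterative flood fill."""
    seen = np.zeros_like(label, bool)
    count = 0
    h, w = label.shape
    for r in range(h):
        for c in range(w):
            if label[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if (
                                0 <= nr < h and 0 <= nc < w
                                and label[nr, nc] and not seen[nr, nc]
                            ):
                                seen[nr, nc] = True
                                stack.append((nr, nc))
    return count


# ---------------------------------------------------------------------------
# transforms

class TestTransformAlgebra:
    def test_rotate_zero_is_identity(self, rng):
        for _ in range(10):
            p = random_patch(rng)
            r = rotate(p, 0.0)
            np.testing.assert_array_equal(r.pixels, p.pixels)
            np.testing.assert_array_equal(r.footprint, p.footprint)

    def test_quarter_turn_transposes_dimensions(self):
        # coordinate-map oracle: (i, j) -> (j, -i) swaps height and width
        p = LesionPatch(np.array([[1.0], [2.0]]), np.ones((2, 1), bool))
        r = rotate(p, math.pi / 2)
        assert r.footprint.shape == (1, 2)
        assert r.footprint.all()

    def test_four_quarter_turns_restore_footprint(self, rng):
        for _ in range(5):
            p = random_patch(rng)
            q = p
            for _ in range(4):
                q = rotate(q, math.pi / 2)
            assert q.footprint.shape == p.footprint.shape
            np.testing.assert_array_equal(q.footprint, p.footprint)

    def test_mirror_is_involution(self, rng):
        for tau in ("horizontal", "vertical"):
            p = random_patch(rng)
            q = mirror(mirror(p, tau), tau)
            np.testing.assert_array_equal(q.pixels, p.pixels)
            np.testing.assert_array_equal(q.footprint, p.footprint)

    def test_mirror_reflects_columns(self):
        p = LesionPatch(np.array([[1.0, 2.0]]), np.array([[True, False]]))
        q = mirror(p, "horizontal")
        np.testing.assert_array_equal(q.footprint, [[False, True]])
        np.testing.assert_array_equal(q.pixels, [[2.0, 1.0]])

    def test_mirror_invalid_axis_rejected(self, rng):
        with pytest.raises(ValueError):
            mirror(random_patch(rng), "diagonal")

    def test_enlarge_identity_and_doubling(self):
        p = LesionPatch(np.random.default_rng(0).random((3, 3)), np.ones((3, 3), bool))
        same = enlarge(p, 1.0)
        np.testing.assert_array_equal(same.pixels, p.pixels)
        assert enlarge(p, 2.0).shape == (6, 6)

    @given(omega=st.floats(0.5, 2.0), seed=st.integers(0, 100))
    def test_enlarge_dimension_arithmetic(self, omega, seed):
        p = random_patch(np.random.default_rng(seed))
        q = enlarge(p, omega)
        h, w = p.shape
        assert q.shape == (max(1, round(omega * h)), max(1, round(omega * w)))
        assert q.footprint.any()

    def test_enlarge_area_scales_roughly_quadratically(self):
        rng = np.random.default_rng(1)
        # disc footprint: area ratio ~ omega^2 within discretization error
        yy, xx = np.mgrid[0:21, 0:21]
        fp = (yy - 10) ** 2 + (xx - 10) ** 2 <= 64
        p = LesionPatch(rng.random((21, 21)), fp)
        for omega in (0.5, 1.5, 2.0):
            q = enlarge(p, omega)
            perimeter = 2 * math.pi * 8 * omega
            assert abs(q.area - omega**2 * p.area) <= 2 * perimeter + 4

    def test_enlarge_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            enlarge(random_patch(rng), 2.5)


# ---------------------------------------------------------------------------
# placement checking

def make_scene(size=64):
    organ = np.zeros((size, size), bool)
    organ[8:-8, 8:-8] = True
    existing = np.zeros((size, size), np.uint8)
    return organ, existing


class TestCheckPlacement:
    def test_margin_violation_rejected(self):
        organ, existing = make_scene()
        organ[:] = True
        patch = LesionPatch(np.ones((3, 3)), np.ones((3, 3), bool))
        decision = check_placement(
            Placement((2, 2), (3, 3)), patch, organ, existing,
            PlacementConstraints(border_margin=5),
        )
        assert not decision.accepted and decision.reason == "margin"

    def test_overlap_rejected(self):
        organ, existing = make_scene()
        existing[30:33, 30:33] = 1
        patch = LesionPatch(np.ones((3, 3)), np.ones((3, 3), bool))
        decision = check_placement(
            Placement((31, 31), (3, 3)), patch, organ, existing
        )
        assert not decision.accepted and decision.reason == "overlap"

    def test_clean_placement_accepted(self):
        organ, existing = make_scene()
        patch = LesionPatch(np.ones((3, 3)), np.ones((3, 3), bool))
        assert check_placement(Placement((30, 30), (3, 3)), patch, organ, existing)

    def test_full_footprint_containment_stricter_than_anchor(self):
        organ, existing = make_scene()
        patch = LesionPatch(np.ones((4, 4)), np.ones((4, 4), bool))
        edge = Placement((6, 30), (4, 4))  # anchor outside organ top edge...
        # anchor (6,30) lies outside organ rows (organ starts at 8)
        full = check_placement(
            edge, patch, organ, existing,
            PlacementConstraints(containment_mode="full_footprint"),
        )
        anchor = check_placement(
            edge, patch, organ, existing,
            PlacementConstraints(containment_mode="anchor_only"),
        )
        assert not full.accepted and full.reason == "containment"
        assert not anchor.accepted  # anchor itself is outside here too
        inside = Placement((8, 30), (4, 4))
        assert check_placement(
            inside, patch, organ, existing,
            PlacementConstraints(containment_mode="anchor_only"),
        ).accepted

    def test_min_separation_blocks_touching(self):
        organ, existing = make_scene()
        existing[30:33, 30:33] = 1
        patch = LesionPatch(np.ones((3, 3)), np.ones((3, 3), bool))
        touching = Placement((30, 33), (3, 3))  # adjacent, no overlap
        strict = check_placement(
            touching, patch, organ, existing,
            PlacementConstraints(min_separation=1),
        )
        loose = check_placement(
            touching, patch, organ, existing,
            PlacementConstraints(min_separation=0),
        )
        assert not strict.accepted and strict.reason == "overlap"
        assert loose.accepted


# ---------------------------------------------------------------------------
# oversampling drivers

class TestOversample:
    def test_m_zero_is_identity(self, small_phantom, rng):
        image, organ, label = small_phantom
        res = oversample(image, label, organ, 0, rng)
        np.testing.assert_array_equal(res.image.pixels, image.pixels)
        np.testing.assert_array_equal(res.label, label)
        assert res.accepted == 0

    def test_rate_four_gives_five_components_from_one(self, rng):
        """A single lesion oversampled at rate 4 yields 5 components."""
        size = 96
        organ = np.zeros((size, size), bool)
        organ[10:-10, 10:-10] = True
        image = np.zeros((size, size))
        label = np.zeros((size, size), np.uint8)
        yy, xx = np.mgrid[0:size, 0:size]
        disc = (yy - 48) ** 2 + (xx - 48) ** 2 <= 16
        image[disc] = 1.0
        label[disc] = 1
        res = oversample(image, label, organ, 4, rng)
        assert res.accepted == 4
        assert count_components(res.label) == 5

    def test_no_lesion_rejected(self, rng):
        with pytest.raises(ValueError, match="no lesion"):
            oversample(np.zeros((32, 32)), np.zeros((32, 32), np.uint8),
                       np.ones((32, 32), bool), 1, rng)

    def test_tiny_organ_reports_exhaustion(self, rng):
        size = 64
        organ = np.zeros((size, size), bool)
        organ[30:33, 30:33] = True  # smaller than any admissible placement
        image = np.zeros((size, size))
        label = np.zeros((size, size), np.uint8)
        label[30:40, 30:40] = 1
        image[30:40, 30:40] = 1.0
        res = oversample(image, label, organ, 3, rng)
        assert res.accepted == 0
        assert res.exhausted
        assert sum(res.rejections.values()) > 0


class TestMofAugment:
    def test_m_zero_is_identity(self, small_phantom, rng):
        image, organ, label = small_phantom
        bank = extract_lesions(image, label)
        res = mof_augment(image, label, organ, bank, 0, rng)
        np.testing.assert_array_equal(res.image.pixels, image.pixels)
        np.testing.assert_array_equal(res.label, label)

    def test_empty_bank_rejected(self, small_phantom, rng):
        image, organ, label = small_phantom
        with pytest.raises(ValueError, match="bank"):
            mof_augment(image, label, organ, [], 1, rng)

    def test_pastes_satisfy_all_constraints(self, small_phantom, rng):
        image, organ, label = small_phantom
        bank = extract_lesions(image, label)
        res = mof_augment(image, label, organ, bank, 4, rng)
        assert res.accepted == 4
        margin = 5
        h, w = res.label.shape
        new = (res.label > 0) & ~(label > 0)
        rows = np.flatnonzero(new.any(axis=1))
        cols = np.flatnonzero(new.any(axis=0))
        assert rows[0] >= margin and rows[-1] < h - margin
        assert cols[0] >= margin and cols[-1] < w - margin
        assert (new & ~organ).sum() == 0  # full organ containment

    def test_locality_outside_footprints_bitwise_unchanged(self, small_phantom, rng):
        image, organ, label = small_phantom
        bank = extract_lesions(image, label)
        res = mof_augment(image, label, organ, bank, 4, rng)
        new = (res.label > 0) & ~(label > 0)
        unchanged = ~new
        np.testing.assert_array_equal(
            res.image.pixels[unchanged], image.pixels[unchanged]
        )
        np.testing.assert_array_equal(res.label[unchanged], label[unchanged])

    def test_component_count_grows_by_accepted_pastes(self, phantom_spec, rng):
        from mofaug import generate_phantom

        image, organ, label = generate_phantom(phantom_spec(11))
        bank = extract_lesions(image, label)
        before = count_components(label)
        res = mof_augment(image, label, organ, bank, 4, rng)
        assert count_components(res.label) == before + res.accepted

    def test_determinism_same_seed_bitwise_identical(self, small_phantom):
        image, organ, label = small_phantom
        bank = extract_lesions(image, label)
        a = mof_augment(image, label, organ, bank, 4, np.random.default_rng(5))
        b = mof_augment(image, label, organ, bank, 4, np.random.default_rng(5))
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)
        np.testing.assert_array_equal(a.label, b.label)
        assert a.placements == b.placements
        assert a.rejections == b.rejections

    def test_lesion_fraction_strictly_increases(self, small_phantom, rng):
        image, organ, label = small_phantom
        bank = extract_lesions(image, label)
        res = mof_augment(image, label, organ, bank, 4, rng)
        assert res.accepted > 0
        assert res.label.mean() > (label > 0).mean()

    def test_bank_pools_patches_across_images(self, phantom_spec):
        from mofaug import generate_phantom

        pairs = []
        for seed in (1, 2):
            img, _, lab = generate_phantom(phantom_spec(seed))
            pairs.append((img, lab))
        bank = build_lesion_bank(pairs)
        assert len(bank) == sum(
            count_components(lab) for _, lab in pairs
        )
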