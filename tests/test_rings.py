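"""Ring geometry, overlap removal, profile recovery and aggregation."""

import numpy as np
import pytest

from plaquetime.rings import (
    aggregate_profiles,
    build_rings,
    homer_vs_maturity,
    profiles_to_frame,
    project_zstack,
    remove_overlaps,
    ring_means,
)
from plaquetime.simulate import DEFAULT_RING_PROFILES, simulate_ihc


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


class TestProjectZstack:
    def test_identical_planes_zero(self):
        stack = np.ones((3, 5, 5))
        assert np.allclose(project_zstack(stack), 0.0)

    def test_two_value_planes(self):
        stack = np.stack([np.zeros((4, 4)), np.full((4, 4), 2.0)])
        assert np.allclose(project_zstack(stack), 1.0)

    def test_matches_direct_formula(self, rng):
        stack = rng.normal(size=(6, 8, 8))
        direct = np.sqrt(((stack - stack.mean(0)) ** 2).mean(0))
        assert np.allclose(project_zstack(stack), direct)

    def test_single_plane_warns(self):
        with pytest.warns(UserWarning):
            out = project_zstack(np.ones((1, 4, 4)))
        assert out.shape == (4, 4)


class TestBuildRings:
    def test_shell_areas_match_geometry(self):
        mask = disc_mask((200, 200), (100, 100), 20)
        rs = build_rings(mask, pixel_size=1.0)
        for k in range(1, 4):
            expected = np.pi * ((20 + 10 * k) ** 2 - (20 + 10 * (k - 1)) ** 2)
            assert rs.rings[k].sum() == pytest.approx(expected, rel=0.05)

    def test_rings_match_edt_oracle_exactly(self):
        from scipy.ndimage import distance_transform_edt
        mask = disc_mask((120, 120), (60, 60), 15)
        rs = build_rings(mask, pixel_size=0.5, increment_um=5.0, max_um=15.0)
        d = distance_transform_edt(~mask, sampling=0.5)
        for k in range(1, 4):
            oracle = (d > 5.0 * (k - 1)) & (d <= 5.0 * k)
            assert np.array_equal(rs.rings[k], oracle)

    def test_rings_pairwise_disjoint(self):
        rs = build_rings(disc_mask((150, 150), (75, 75), 12), 1.0)
        total = np.zeros((150, 150), int)
        for ring in rs.rings:
            total += ring
        assert total.max() == 1

    def test_border_clipping_flagged(self):
        rs = build_rings(disc_mask((50, 50), (5, 5), 4), 1.0)
        assert rs.clipped

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            build_rings(np.zeros((10, 10), bool), 1.0)

    def test_bad_increment_rejected(self):
        mask = disc_mask((50, 50), (25, 25), 5)
        with pytest.raises(ValueError):
            build_rings(mask, 1.0, increment_um=7.0, max_um=30.0)


class TestRemoveOverlaps:
    def test_far_apart_unchanged(self):
        a = build_rings(disc_mask((300, 300), (70, 70), 10), 1.0, plaque_id="a")
        b = build_rings(disc_mask((300, 300), (230, 230), 10), 1.0, plaque_id="b")
        out = remove_overlaps([a, b])
        for before, after in zip((a, b), out):
            for r0, r1 in zip(before.rings, after.rings):
                assert np.array_equal(r0, r1)

    def test_close_plaques_contested_pixels_removed_symmetrically(self):
        # 15 um apart: facing shells overlap
        a = build_rings(disc_mask((200, 200), (100, 80), 10), 1.0, plaque_id="a")
        b = build_rings(disc_mask((200, 200), (100, 135), 10), 1.0, plaque_id="b")
        out = remove_overlaps([a, b])
        mult = np.zeros((200, 200), int)
        for rs in out:
            for ring in rs.rings:
                mult += ring
        assert mult.max() <= 1
        removed_a = a.rings[3].sum() - out[0].rings[3].sum()
        removed_b = b.rings[3].sum() - out[1].rings[3].sum()
        assert removed_a > 0 and removed_b > 0

    def test_duplicate_plaque_empties_all_rings(self):
        mask = disc_mask((100, 100), (50, 50), 8)
        a = build_rings(mask, 1.0, plaque_id="a")
        b = build_rings(mask.copy(), 1.0, plaque_id="b")
        out = remove_overlaps([a, b])
        assert all(ring.sum() == 0 for rs in out for ring in rs.rings)


class TestRingMeans:
    def test_constant_image(self):
        rs = build_rings(disc_mask((100, 100), (50, 50), 10), 1.0, plaque_id="p")
        prof = ring_means(np.full((100, 100), 7.0), [rs])[0]
        assert all(m == pytest.approx(7.0) for m in prof.means)

    def test_planted_profile_recovered_exactly_noiseless(self):
        chans, masks, truth = simulate_ihc(
            ["Abeta+h+q+", "Abeta+h-q-"], noise=0.0, image_size=300)
        sets = remove_overlaps([
            build_rings(m, 1.0, plaque_id=f"plaque_{i:03d}")
            for i, m in enumerate(masks)])
        for ch in ("lamp1", "homer1"):
            for prof in ring_means(chans[ch], sets, classes=truth.plaque_class):
                planted = truth.ring_means[prof.plaque_id][ch]
                for got, want in zip(prof.means, planted):
                    assert got == pytest.approx(want, abs=1e-9)

    def test_noisy_profile_within_sem(self):
        chans, masks, truth = simulate_ihc(["Abeta+h+q+"], noise=5.0,
                                           image_size=300, seed=5)
        rs = build_rings(masks[0], 1.0, plaque_id="plaque_000")
        prof = ring_means(chans["lamp1"], [rs])[0]
        for got, want, n in zip(prof.means,
                                truth.ring_means["plaque_000"]["lamp1"],
                                prof.pixel_counts):
            assert abs(got - want) < 3 * 5.0 / np.sqrt(n)

    def test_shape_mismatch_rejected(self):
        rs = build_rings(disc_mask((50, 50), (25, 25), 5), 1.0)
        with pytest.raises(ValueError):
            ring_means(np.zeros((10, 10)), [rs])


class TestAggregation:
    def _profiles(self):
        chans, masks, truth = simulate_ihc(
            ["Abeta+h+q+", "Abeta+h+q-", "Abeta+h-q-"] * 2,
            noise=0.5, image_size=400, seed=1)
        sets = remove_overlaps([
            build_rings(m, 1.0, plaque_id=f"plaque_{i:03d}")
            for i, m in enumerate(masks)])
        return ring_means(chans["lamp1"], sets, classes=truth.plaque_class,
                          image_id="img1", animal="m1")

    def test_single_plaque_is_its_own_profile(self):
        chans, masks, truth = simulate_ihc(["Abeta+h+q+"], noise=0.0)
        rs = build_rings(masks[0], 1.0, plaque_id="plaque_000")
        prof = ring_means(chans["lamp1"], [rs], classes=truth.plaque_class,
                          image_id="i", animal="a")
        agg = aggregate_profiles(prof)
        ring0 = agg[(agg["ring"] == 0)]
        assert ring0["mean"].iloc[0] == pytest.approx(
            truth.ring_means["plaque_000"]["lamp1"][0])

    def test_two_images_average(self):
        chans, masks, truth = simulate_ihc(["Abeta+h+q+"], noise=0.0)
        profs = []
        for img_id, offset in (("i1", 0.0), ("i2", 2.0)):
            rs = build_rings(masks[0], 1.0, plaque_id="plaque_000")
            p = ring_means(chans["lamp1"] + offset, [rs],
                           classes=truth.plaque_class, image_id=img_id,
                           animal="a")
            profs.extend(p)
        agg = aggregate_profiles(profs)
        ring0 = agg[agg["ring"] == 0]["mean"].iloc[0]
        assert ring0 == pytest.approx(
            truth.ring_means["plaque_000"]["lamp1"][0] + 1.0)

    def test_order_invariance(self):
        profs = self._profiles()
        a = aggregate_profiles(profs)
        b = aggregate_profiles(list(reversed(profs)))
        assert a.equals(b)

    def test_class_ordering_preserved(self):
        profs = self._profiles()
        agg = aggregate_profiles(profs).set_index(["class", "ring"])
        lamp0 = {c: agg.loc[(c, 0), "mean"] for c in
                 ("Abeta+h+q+", "Abeta+h+q-", "Abeta+h-q-")}
        assert lamp0["Abeta+h+q+"] > lamp0["Abeta+h+q-"] > lamp0["Abeta+h-q-"]

    def test_missing_labels_rejected(self):
        chans, masks, _ = simulate_ihc(["Abeta+h+q+"], noise=0.0)
        rs = build_rings(masks[0], 1.0, plaque_id="p")
        prof = ring_means(chans["lamp1"], [rs])
        with pytest.raises(ValueError):
            aggregate_profiles(prof)


class TestHomerVsMaturity:
    def test_perfect_line(self):
        x = np.arange(6.0)
        tab = homer_vs_maturity(2 - 3 * x, x)
        assert tab.iloc[0]["r"] == pytest.approx(-1.0)

    def test_planted_negative_relationship(self, rng):
        ratio = rng.uniform(0.5, 2.0, 30)
        homer = 50 - 10 * ratio + rng.normal(0, 2, 30)
        tab = homer_vs_maturity(homer, ratio)
        assert tab.iloc[0]["r"] < 0
        assert tab.iloc[0]["p"] < 0.01

    def test_per_animal_small_groups_flagged(self, rng):
        x = rng.uniform(0, 1, 8)
        tab = homer_vs_maturity(rng.normal(size=8), x,
                                animals=["m1"] * 6 + ["m2"] * 2)
        assert tab.set_index("scope").loc["m2", "flag"] == "undefined"
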