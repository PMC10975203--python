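import numpy as np
import pytest

from crowngrowth import (
    TreeCenter,
    ValidationError,
    branch_end_points,
    compute_growth,
    growth_density,
    make_grid,
    measure_tree_growth,
    summarize_orchard,
    to_spherical,
)
from crowngrowth.geometry import cell_indices
from crowngrowth.radial import RadialDistanceImage


def make_image(values, mask, res=5.0, tree_id="t", epoch="scan1", merged=False):
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    g = make_grid(res, 90.0 / values.shape[0])
    return RadialDistanceImage(
        grid=g,
        values=values,
        mask=mask,
        counts=mask.astype(int),
        outlier_percentile=99.0,
        tree_id=tree_id,
        epoch_label=epoch,
        merged=merged,
    )


@pytest.fixture
def random_image_pair(rng):
    shape = (18, 72)
    mask1 = rng.uniform(size=shape) < 0.4
    mask2 = rng.uniform(size=shape) < 0.4
    v1 = rng.uniform(0.2, 2.0, shape) * mask1
    v2 = rng.uniform(0.2, 2.0, shape) * mask2
    return (
        make_image(v1, mask1, epoch="scan1"),
        make_image(v2, mask2, epoch="scan3"),
    )


class TestComputeGrowth:
    def test_self_comparison_is_zero(self, random_image_pair):
        img, _ = random_image_pair
        g = compute_growth(img, img)
        assert g.mean_growth == 0.0
        assert g.sd_growth == 0.0
        assert np.all(g.valid_diffs == 0.0)

    def test_uniform_shift(self, random_image_pair):
        earlier, _ = random_image_pair
        later = make_image(
            earlier.values + 0.2 * earlier.mask, earlier.mask, epoch="scan3"
        )
        g = compute_growth(later, earlier)
        assert g.mean_growth == pytest.approx(0.2)
        assert g.sd_growth == pytest.approx(0.0, abs=1e-12)
        assert g.epoch_pair == ("scan1", "scan3")

    def test_intersection_mask(self):
        maskA = np.zeros((3, 4), bool)
        maskA[0, 0] = maskA[1, 1] = True  # cells {A, B}
        maskB = np.zeros((3, 4), bool)
        maskB[1, 1] = maskB[2, 2] = True  # cells {B, C}
        earlier = make_image(np.ones((3, 4)), maskA, res=90)
        later = make_image(np.full((3, 4), 1.5), maskB, res=90, epoch="scan3")
        g = compute_growth(later, earlier)
        assert g.n_valid_cells == 1
        assert g.valid_mask[1, 1] and not g.valid_mask[0, 0]

    def test_antisymmetry(self, random_image_pair):
        earlier, later = random_image_pair
        fwd = compute_growth(later, earlier)
        bwd = compute_growth(earlier, later)
        assert np.allclose(fwd.diff, -bwd.diff)
        assert np.array_equal(fwd.valid_mask, bwd.valid_mask)

    def test_translation_equivariance(self, random_image_pair):
        earlier, later = random_image_pair
        base = compute_growth(later, earlier)
        shifted = make_image(
            later.values + 0.07 * later.mask, later.mask, epoch="scan3"
        )
        assert compute_growth(shifted, earlier).mean_growth == pytest.approx(
            base.mean_growth + 0.07
        )

    def test_mismatches_rejected(self, random_image_pair):
        earlier, later = random_image_pair
        with pytest.raises(ValidationError, match="tree_id"):
            compute_growth(make_image(later.values, later.mask, tree_id="u"), earlier)
        coarse = make_image(np.ones((9, 36)), np.ones((9, 36), bool), res=10)
        with pytest.raises(ValidationError):
            compute_growth(coarse, earlier)
        with pytest.raises(ValidationError, match="merge"):
            compute_growth(
                make_image(later.values, later.mask, merged=True), earlier
            )

    def test_no_overlap_errors(self):
        maskA = np.zeros((2, 4), bool)
        maskA[0, 0] = True
        maskB = np.zeros((2, 4), bool)
        maskB[1, 1] = True
        with pytest.raises(ValidationError, match="both epochs"):
            compute_growth(
                make_image(np.ones((2, 4)), maskB, res=90),
                make_image(np.ones((2, 4)), maskA, res=90),
            )


def growth_with_mean(mean, tree_id):
    mask = np.ones((1, 4), bool)
    earlier = make_image(np.ones((1, 4)), mask, res=90, tree_id=tree_id)
    later = make_image(
        np.ones((1, 4)) + mean, mask, res=90, tree_id=tree_id, epoch="scan3"
    )
    return compute_growth(later, earlier)


class TestOrchardSummary:

    def test_hand_checked_two_tree_orchard(self):
        growths = [
            growth_with_mean(0.1, "a"),
            growth_with_mean(0.3, "b"),
        ]
        s = summarize_orchard(growths)
        assert s.mu == pytest.approx(0.2)
        assert s.me == pytest.approx(0.2)
        assert s.mae == pytest.approx(0.2)
        assert s.sigma == pytest.approx(0.1414, abs=2e-4)  # sample SD
        assert summarize_orchard(growths, sd_mode="population").sigma == (
            pytest.approx(0.1)
        )

    def test_self_comparison_orchard_is_all_zero(self, random_image_pair):
        img, _ = random_image_pair
        s = summarize_orchard([compute_growth(img, img)], sd_mode="population")
        assert s.mu == s.me == s.mae == 0.0
        assert s.sigma == 0.0

    def test_single_tree_sample_sd_flagged_undefined(self):
        s = summarize_orchard([growth_with_mean(0.2, "a")])
        assert np.isnan(s.sigma)

    def test_mae_dominates_me(self, rng):
        growths = [
            growth_with_mean(m, f"t{i}")
            for i, m in enumerate(rng.normal(0, 0.1, 9))
        ]
        s = summarize_orchard(growths)
        assert s.mae >= abs(s.me)

    def test_pooled_mode_uses_cells(self):
        growths = [
            growth_with_mean(0.1, "a"),
            growth_with_mean(0.3, "b"),
        ]
        s = summarize_orchard(growths, pooled=True)
        assert s.me == pytest.approx(0.2)  # equal cell counts -> same here
        assert s.mae == pytest.approx(0.2)

    def test_mixed_resolution_rejected(self):
        a = growth_with_mean(0.1, "a")
        mask = np.ones((2, 8), bool)
        earlier = make_image(np.ones((2, 8)), mask, res=45, tree_id="b")
        later = make_image(np.ones((2, 8)), mask, res=45, tree_id="b")
        with pytest.raises(ValidationError):
            summarize_orchard([a, compute_growth(later, earlier)])


class TestGrowthDensity:
    def _growths(self, means):
        return [growth_with_mean(m, f"t{i}") for i, m in enumerate(means)]

    def test_normalized(self, rng):
        curve = growth_density(self._growths(rng.uniform(0, 0.5, 20)))
        assert curve.integral() == pytest.approx(1.0, abs=1e-3)

    def test_centered_near_zero_for_null_growth(self, rng):
        curve = growth_density(self._growths(rng.normal(0, 0.01, 20)))
        mode = curve.x[np.argmax(curve.density)]
        assert abs(mode) < 0.02

    def test_degenerate_spike(self):
        curve = growth_density(self._growths([0.2, 0.2, 0.2]))
        assert curve.degenerate
        assert curve.x[0] == pytest.approx(0.2)
        assert curve.integral() == 1.0

    def test_synthetic_orchard_mode_in_growth_range(self, small_orchard):
        g5 = make_grid(5, 5)
        growths = [
            measure_tree_growth(f.cloud_earlier, f.cloud_later, f.center, g5)
            for f in small_orchard
        ]
        curve = growth_density(growths)
        mode = curve.x[np.argmax(curve.density)]
        assert 0.0 <= mode <= 0.5


class TestBranchEndPoints:
    def test_single_cell_closed_form(self):
        mask = np.zeros((18, 72), bool)
        mask[2, 1] = True  # centers: phi=12.5, theta=7.5
        values = np.where(mask, 2.0, 0.0)
        img = make_image(values, mask)
        center = TreeCenter("t", (1.0, 2.0, 3.0))
        cloud = branch_end_points(img, center)
        assert len(cloud) == 1
        p, t = np.radians(12.5), np.radians(7.5)
        expected = np.array(
            [
                1.0 + 2.0 * np.cos(p) * np.sin(t),
                2.0 + 2.0 * np.cos(p) * np.cos(t),
                3.0 + 2.0 * np.sin(p),
            ]
        )
        assert np.allclose(cloud.points[0], expected)

    @pytest.mark.parametrize("merge", [False, True])
    def test_round_trip_rebinning(self, small_orchard, merge):
        """Branch-end points re-bin into their source cells with their
        source values, for raw and equal-area-merged images."""
        from crowngrowth.radial import image_from_cloud

        fx = small_orchard[0]
        g = make_grid(5, 5)
        img = image_from_cloud(fx.cloud_earlier, fx.center, g, merge=merge)
        cloud = branch_end_points(img, fx.center)
        assert len(cloud) == img.n_populated
        sph = to_spherical(cloud, fx.center)
        assert np.allclose(np.sort(sph.r), np.sort(img.values[img.mask]))
        if not merge:
            rows, cols = cell_indices(sph.theta, sph.phi, g)
            rebinned = set(zip(rows.tolist(), cols.tolist()))
            assert rebinned == set(zip(*(a.tolist() for a in np.nonzero(img.mask))))
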