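"""TSD loss branches, closed-form gradients, smooth L1 and focal loss."""

import math

import numpy as np
import pytest

from tsdbox.boxes import Box, Relationship, circumradius
from tsdbox.losses import (
    batch_regression_loss,
    cos_theta,
    focal_loss,
    focal_loss_total,
    loss_names,
    smooth_l1,
    tsd_loss,
    tsd_loss_branch_value,
    tsd_loss_gradient,
)
from tsdbox.metrics import DatasetScale
from .conftest import random_pair

S100 = DatasetScale(100.0)


class TestSmoothL1:
    @pytest.mark.parametrize("x,expected", [(0, 0.0), (1, 0.5), (-1, 0.5), (3, 2.5), (0.5, 0.125)])
    def test_values(self, x, expected):
        assert smooth_l1(x) == pytest.approx(expected)

    def test_continuity_and_slope_at_knot(self):
        eps = 1e-7
        assert smooth_l1(1 - eps) == pytest.approx(smooth_l1(1 + eps), abs=1e-6)
        slope_in = (smooth_l1(1.0) - smooth_l1(1.0 - eps)) / eps
        slope_out = (smooth_l1(1.0 + eps) - smooth_l1(1.0)) / eps
        assert slope_in == pytest.approx(slope_out, abs=1e-5)
        assert slope_out == pytest.approx(1.0, abs=1e-5)

    def test_vectorized(self):
        out = smooth_l1(np.array([0.0, 1.0, 3.0]))
        assert np.allclose(out, [0.0, 0.5, 2.5])


class TestCosTheta:
    def test_equilateral_configuration_gives_half(self):
        # congruent squares with d == r1 == r2: law of cosines on an
        # equilateral triangle gives cos(theta) = 1/2 (theta = 60 deg)
        side = 4.0
        r = 0.5 * math.hypot(side, side)
        a = Box.from_center(0, 0, side, side)
        b = Box.from_center(r, 0, side, side)
        assert cos_theta(a, b) == pytest.approx(0.5)

    def test_near_coincident_centers_approach_one(self):
        a = Box.from_center(0, 0, 4, 4)
        b = Box.from_center(1e-9, 0, 4, 4.2)
        assert cos_theta(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_deep_overlap_clamps_to_one(self):
        # a thin tall box crossed by a wide short one: d < |r1 - r2| without
        # containment pushes the raw law-of-cosines value above 1
        a = Box(0, -50, 2, 50)
        b = Box(-1, -1, 3, 1)
        r1, r2 = circumradius(a), circumradius(b)
        d = 0.0  # both centers at (1, 0)
        raw = (r1**2 + r2**2 - d**2) / (2 * r1 * r2)
        assert raw > 1.0
        assert cos_theta(a, b) == 1.0

    def test_branch_misuse_raises(self):
        a = Box(0, 0, 2, 2)
        with pytest.raises(ValueError, match="intersect"):
            cos_theta(a, Box(5, 5, 7, 7))  # separated
        with pytest.raises(ValueError, match="intersect"):
            cos_theta(Box(0, 0, 10, 10), Box(2, 2, 4, 4))  # contained


class TestTsdLoss:
    def test_identical_boxes_zero_loss_via_contain(self):
        a = Box(3, 3, 9, 11)
        out = tsd_loss(a, a, S100)
        assert out.branch is Relationship.CONTAIN
        assert out.value == 0.0
        assert out.branch_variable_x == 0.0

    def test_separated_branch_frozen_value(self):
        # Chebyshev distance 10, S = 100 -> loss 1.0
        a = Box.from_center(0, 0, 2, 2)
        b = Box.from_center(10, 0, 2, 2)
        out = tsd_loss(a, b, S100)
        assert out.branch is Relationship.SEPARATED
        assert out.value == pytest.approx(1.0)
        assert out.gradient_dx == 1.0

    def test_contain_branch_frozen_value(self):
        # concentric boxes with circumradii 5 and 3 -> 1 - e^-2
        a = Box.from_center(0, 0, 6, 8)  # r = 5
        b = Box.from_center(0, 0, 3.6, 4.8)  # r = 3
        out = tsd_loss(a, b, S100)
        assert out.branch is Relationship.CONTAIN
        assert out.branch_variable_x == pytest.approx(2.0)
        assert out.value == pytest.approx(1.0 - math.exp(-2.0))

    def test_intersect_branch_value_is_one_minus_cos(self):
        a = Box.from_center(0, 0, 4, 4)
        b = Box.from_center(3, 0, 4, 4)
        out = tsd_loss(a, b, S100)
        assert out.branch is Relationship.INTERSECT
        assert out.value == pytest.approx(1.0 - cos_theta(a, b))

    def test_normalize_contain_radius_option(self):
        a = Box.from_center(0, 0, 6, 8)
        b = Box.from_center(0, 0, 3.6, 4.8)
        out = tsd_loss(a, b, S100, normalize_contain_radius=True)
        assert out.branch_variable_x == pytest.approx(2.0 / 10.0)

    def test_non_negative_on_random_sweep(self, rng):
        seen = set()
        for _ in range(10_000):
            a, b = random_pair(rng, center_range=(0, 64), side_range=(1, 32))
            out = tsd_loss(a, b, DatasetScale(float(rng.uniform(1, 500))))
            assert out.value >= 0.0
            seen.add(out.branch)
        assert seen == set(Relationship)  # sweep hit all three branches

    def test_separated_monotone_in_distance(self):
        a = Box.from_center(0, 0, 2, 2)
        vals = [
            tsd_loss(a, Box.from_center(d, 0, 2, 2), S100).value
            for d in (5, 10, 20, 40)
        ]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_contain_monotone_in_radius_gap(self):
        outer = Box.from_center(0, 0, 40, 40)
        vals = [
            tsd_loss(outer, Box.from_center(0, 0, s, s), S100).value
            for s in (40, 30, 20, 10)
        ]
        assert vals[0] == 0.0
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_intersect_monotone_in_center_distance(self):
        a = Box.from_center(0, 0, 8, 8)
        vals = [
            tsd_loss(a, Box.from_center(d, 0, 8, 8), S100).value
            for d in (1, 2, 4, 6)
        ]
        assert all(x < y for x, y in zip(vals, vals[1:]))


class TestGradients:
    @pytest.mark.parametrize(
        "branch,xs",
        [
            (Relationship.SEPARATED, np.linspace(0, 20, 100)),
            (Relationship.INTERSECT, np.linspace(0, math.pi, 100)),
            (Relationship.CONTAIN, np.linspace(0, 10, 100)),
        ],
    )
    def test_closed_form_matches_finite_difference(self, branch, xs):
        h = 1e-6
        for x in xs:
            lo, hi = max(x - h, 0.0), x + h
            if branch is Relationship.INTERSECT:
                hi = min(hi, math.pi)
            fd = (
                tsd_loss_branch_value(branch, hi) - tsd_loss_branch_value(branch, lo)
            ) / (hi - lo)
            grad = tsd_loss_gradient(branch, float(x))
            assert grad == pytest.approx(fd, rel=1e-6, abs=1e-6)

    def test_gradient_bounds(self):
        xs = np.linspace(0, math.pi, 1000)
        assert all(abs(tsd_loss_gradient(Relationship.INTERSECT, float(x))) <= 1.0 for x in xs)
        xs = np.linspace(1e-9, 10, 1000)
        grads = [tsd_loss_gradient(Relationship.CONTAIN, float(x)) for x in xs]
        assert all(0.0 < g <= 1.0 for g in grads)
        assert tsd_loss_gradient(Relationship.SEPARATED, 123.0) == 1.0

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            tsd_loss_gradient(Relationship.SEPARATED, -1.0)
        with pytest.raises(ValueError):
            tsd_loss_gradient(Relationship.INTERSECT, 4.0)  # > pi
        with pytest.raises(ValueError):
            tsd_loss_gradient(Relationship.CONTAIN, -0.1)


class TestFocalLoss:
    def test_reduces_to_scaled_cross_entropy(self):
        assert focal_loss(0.5, True, alpha=0.5, gamma=0.0) == pytest.approx(0.5 * math.log(2))

    def test_confident_correct_prediction_vanishes(self):
        assert focal_loss(1 - 1e-9, True) == pytest.approx(0.0, abs=1e-6)

    def test_gamma_two_downweights_easy_examples_hundredfold(self):
        ce = focal_loss(0.9, True, alpha=0.5, gamma=0.0)
        fl = focal_loss(0.9, True, alpha=0.5, gamma=2.0)
        assert fl == pytest.approx(0.01 * ce)

    def test_negative_anchor_uses_complement(self):
        assert focal_loss(0.1, False, alpha=0.5, gamma=0.0) == pytest.approx(
            -0.5 * math.log(0.9)
        )

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.5, 1.5])
    def test_probability_domain_enforced(self, p):
        with pytest.raises(ValueError):
            focal_loss(p, True)

    def test_total_normalized_by_assigned_anchors(self):
        probs = [0.9, 0.8, 0.1, 0.2, 0.3]
        pos = [True, True, False, False, False]
        per_anchor = sum(focal_loss(p, f) for p, f in zip(probs, pos))
        assert focal_loss_total(probs, pos) == pytest.approx(per_anchor / 2)
        assert focal_loss_total(probs, pos, n_assigned=5) == pytest.approx(per_anchor / 5)


class TestBatchRegressionLoss:
    def test_identical_pairs_give_zero_tsd(self):
        a = Box(0, 0, 4, 4)
        assert batch_regression_loss([(a, a)] * 5, S100, "tsd") == 0.0

    def test_single_pair_equals_pair_loss(self):
        a = Box.from_center(0, 0, 2, 2)
        b = Box.from_center(10, 0, 2, 2)
        assert batch_regression_loss([(a, b)], S100, "tsd") == pytest.approx(1.0)

    def test_mean_of_two_separated_pairs(self):
        a = Box.from_center(0, 0, 2, 2)
        pairs = [
            (a, Box.from_center(math.sqrt(50), 0, 2, 2)),  # loss 0.5
            (a, Box.from_center(math.sqrt(150), 0, 2, 2)),  # loss 1.5
        ]
        assert batch_regression_loss(pairs, S100, "tsd") == pytest.approx(1.0)

    def test_smooth_l1_on_encoded_deltas_zero_at_identity(self):
        a = Box(2, 3, 10, 12)
        assert batch_regression_loss([(a, a)], S100, "smooth_l1") == 0.0

    def test_iou_family_one_minus_metric(self):
        a = Box(0, 0, 2, 2)
        b = Box(1, 1, 3, 3)
        assert batch_regression_loss([(a, b)], S100, "iou") == pytest.approx(1 - 1 / 7)

    def test_registry_covers_all_names_and_rejects_unknown(self):
        assert set(loss_names()) == {"tsd", "smooth_l1", "iou", "giou", "diou", "ciou"}
        with pytest.raises(ValueError, match="unknown loss"):
            batch_regression_loss([(Box(0, 0, 1, 1), Box(0, 0, 1, 1))], S100, "l2")

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            batch_regression_loss([], S100, "tsd")
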