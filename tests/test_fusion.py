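import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duvmargin import fusion


class TestPatchImportance:
    def test_uniform_map(self):
        values = np.full((8, 8), 0.5)
        assert fusion.patch_importance(values, 0, 0, 4) == pytest.approx(0.5)

    def test_half_zeros_half_ones(self):
        values = np.zeros((4, 4))
        values[:2, :] = 1.0
        assert fusion.patch_importance(values, 0, 0, 4) == pytest.approx(0.5)

    def test_hand_computed_toy_map(self):
        values = np.arange(16).reshape(4, 4) / 15.0
        # footprint rows 0-1, cols 0-1 -> values {0, 1, 4, 5} / 15
        assert fusion.patch_importance(values, 0, 0, 2) == pytest.approx(10 / 60)
        # footprint rows 2-3, cols 2-3 -> values {10, 11, 14, 15} / 15
        assert fusion.patch_importance(values, 1, 1, 2) == pytest.approx(50 / 60)

    def test_out_of_bounds_footprint(self):
        with pytest.raises(ValueError):
            fusion.patch_importance(np.zeros((4, 4)), 1, 0, 4)
        with pytest.raises(ValueError):
            fusion.patch_importance(np.zeros((4, 4)), -1, 0, 2)


class TestPatchWeight:
    def test_below_threshold(self):
        assert fusion.patch_weight(0.24) == 0.0

    def test_boundary_kept(self):
        assert fusion.patch_weight(0.25) == 0.25

    def test_zero(self):
        assert fusion.patch_weight(0.0) == 0.0

    def test_above_threshold_passthrough(self):
        assert fusion.patch_weight(0.8) == 0.8

    @pytest.mark.parametrize("r", [-0.1, 1.1])
    def test_out_of_range(self, r):
        with pytest.raises(ValueError):
            fusion.patch_weight(r)

    @given(r=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=100, deadline=None)
    def test_codomain(self, r):
        w = fusion.patch_weight(r)
        assert w == 0.0 or 0.25 <= w <= 1.0


def oracle_decision(labels, weights, q):
    """Direct element-by-element re-evaluation of the fusion formulas."""
    h = 0
    for y, w in zip(labels, weights):
        if w * y > 0:
            h += 1
    return 1 if h > q * len(labels) else -1, h


class TestSlideDecision:
    def test_all_benign(self):
        for q in (0.0, 0.3, 1.0):
            result = fusion.slide_decision([-1, -1, -1], [0.9, 0.9, 0.9], q)
            assert result.h == 0
            assert result.slide_label == -1

    def test_hand_evaluation(self):
        result = fusion.slide_decision([1, -1, -1], [0.5, 0.9, 0.9], q=0.0)
        assert np.allclose(result.u, [0.5, -0.9, -0.9])
        assert result.h == 1
        assert result.m == 3
        assert result.slide_label == 1

    def test_low_importance_malignant_patch_ignored(self):
        result = fusion.slide_decision([1], [0.0], q=0.0)
        assert result.h == 0
        assert result.slide_label == -1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fusion.slide_decision([], [], 0.0)

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            fusion.slide_decision([1, -1], [0.5], 0.0)

    def test_invalid_q(self):
        with pytest.raises(ValueError):
            fusion.slide_decision([1], [0.5], q=1.5)

    def test_exhaustive_enumeration_small(self):
        weight_grid = np.round(np.arange(0.0, 1.0001, 0.25), 2)
        rng = np.random.default_rng(0)
        for m in range(1, 6):
            for labels in itertools.product((-1, 1), repeat=m):
                weights = rng.choice(weight_grid, size=m)
                for q in (0.0, 0.5, 1.0):
                    result = fusion.slide_decision(list(labels), weights, q)
                    expected_label, expected_h = oracle_decision(labels, weights, q)
                    assert result.slide_label == expected_label
                    assert result.h == expected_h

    @given(
        labels=st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=12),
        q=st.floats(min_value=0.0, max_value=1.0),
        data=st.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_flip_to_malignant_is_monotone(self, labels, q, data):
        weights = data.draw(
            st.lists(
                st.floats(min_value=0.0, max_value=1.0),
                min_size=len(labels),
                max_size=len(labels),
            )
        )
        base = fusion.slide_decision(labels, weights, q).slide_label
        idx = data.draw(st.integers(min_value=0, max_value=len(labels) - 1))
        flipped = list(labels)
        flipped[idx] = 1
        after = fusion.slide_decision(flipped, weights, q).slide_label
        assert not (base == 1 and after == -1)

    @given(
        labels=st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=12),
        data=st.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_q_monotone(self, labels, data):
        weights = data.draw(
            st.lists(
                st.floats(min_value=0.0, max_value=1.0),
                min_size=len(labels),
                max_size=len(labels),
            )
        )
        decisions = [
            fusion.slide_decision(labels, weights, q).slide_label
            for q in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        # once benign, stays benign as q grows
        assert decisions == sorted(decisions, reverse=True)

    def test_equals_majority_vote_at_half_q_odd_m(self, rng):
        # all weights above threshold, q = 0.5; odd M avoids the tie divergence
        for _ in range(50):
            m = int(rng.choice([1, 3, 5, 7, 9]))
            labels = rng.choice([-1, 1], size=m)
            if np.all(labels == labels[0]) and labels[0] == -1:
                pass  # still fine: both answer -1
            weights = rng.uniform(0.25, 1.0, size=m)
            fused = fusion.slide_decision(labels, weights, q=0.5).slide_label
            assert fused == fusion.majority_vote(labels)


class TestMajorityVote:
    def test_simple_majorities(self):
        assert fusion.majority_vote([1, 1, -1]) == 1
        assert fusion.majority_vote([-1, -1, -1, 1]) == -1

    def test_tie_goes_malignant(self):
        assert fusion.majority_vote([1, -1]) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fusion.majority_vote([])

    def test_exhaustive_counting_oracle(self):
        for m in range(1, 11):
            for labels in itertools.product((-1, 1), repeat=m):
                pos = sum(1 for y in labels if y == 1)
                neg = m - pos
                expected = 1 if pos > neg else (-1 if neg > pos else 1)
                assert fusion.majority_vote(list(labels)) == expected


class TestFusePatchSet:
    def test_end_to_end_on_toy_map(self):
        values = np.zeros((4, 4))
        values[:2, :2] = 1.0  # patch (0,0) hot
        result = fusion.fuse_patch_set(
            [0, 0, 1, 1], [0, 1, 0, 1], [1, 1, -1, -1], values, patch_size=2, q=0.0
        )
        assert result.m == 4
        assert result.r[0] == pytest.approx(1.0)
        assert result.w[1] == 0.0  # malignant but unimportant -> ignored
        assert result.h == 1
        assert result.slide_label == 1

    def test_report_written(self, tmp_path):
        values = np.full((4, 4), 0.6)
        result = fusion.fuse_patch_set([0], [0], [1], values, patch_size=4, q=0.0)
        report = fusion.write_fusion_report({"s1": result}, tmp_path / "fusion.csv")
        assert (tmp_path / "fusion.csv").exists()
        assert report.loc[0, "slide_label"] == 1
        assert report.loc[0, "u"] == pytest.approx(0.6)
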