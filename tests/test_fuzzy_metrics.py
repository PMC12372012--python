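import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fuzzedge import (
    EdgeMap,
    GrayImage,
    MembershipImage,
    evaluate_pair,
    fuzzy_confusion,
    fuzzy_distance_field,
    fuzzy_index,
    percent_summary,
    to_membership,
)


def brute_force_fd(support: np.ndarray) -> np.ndarray:
    """Nearest-support distance by exhaustive search, normalized by maxD."""
    m, n = support.shape
    pts = np.argwhere(support)
    out = np.empty((m, n))
    for r in range(m):
        for c in range(n):
            out[r, c] = min(math.hypot(r - p, c - q) for p, q in pts)
    return out / math.hypot(m - 1, n - 1)


def random_membership(seed, shape=(12, 12), sparsity=0.5):
    rng = np.random.default_rng(seed)
    vals = rng.random(shape)
    vals[rng.random(shape) < sparsity] = 0.0
    return MembershipImage(vals)


class TestToMembership:
    def test_edge_map_becomes_binary_membership(self):
        em = EdgeMap(np.eye(4, dtype=np.uint8))
        mi = to_membership(em)
        assert set(np.unique(mi.values)) == {0.0, 1.0}

    def test_8bit_endpoint(self):
        img = GrayImage(np.array([[0.0, 255.0]]), 255.0)
        np.testing.assert_array_equal(to_membership(img).values, [[0.0, 1.0]])

    def test_linearity_preserves_total_intensity(self, random_gray):
        img = random_gray(seed=2)
        mi = to_membership(img)
        assert mi.values.sum() * 255.0 == pytest.approx(img.pixels.sum())


class TestFuzzyConfusion:
    def test_identical_images_no_false_mass(self):
        a = random_membership(0)
        c = fuzzy_confusion(a, MembershipImage(a.values.copy()))
        assert c.card_ffp == 0 and c.card_ffn == 0
        assert c.card_ftp == pytest.approx(c.card_ni)

    def test_hand_worked_2x2(self):
        ni = MembershipImage(np.array([[1.0, 0.0], [0.0, 0.0]]), "reference")
        nd = MembershipImage(np.array([[0.5, 0.5], [0.0, 0.0]]), "detected")
        c = fuzzy_confusion(ni, nd)
        assert c.card_ftp == pytest.approx(0.5)
        assert c.card_ffp == pytest.approx(0.5)
        assert c.card_ffn == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(100))
    def test_cardinality_identities(self, seed):
        """|FTP| + |FFP| = |Ni| and |FTP| + |FFN| = |Nd| exactly."""
        ni, nd = random_membership(seed), random_membership(seed + 1000)
        c = fuzzy_confusion(ni, nd)
        assert c.card_ftp + c.card_ffp == pytest.approx(c.card_ni, abs=1e-9)
        assert c.card_ftp + c.card_ffn == pytest.approx(c.card_nd, abs=1e-9)

    def test_swap_symmetry(self):
        ni, nd = random_membership(5), random_membership(6)
        c1 = fuzzy_confusion(ni, nd)
        c2 = fuzzy_confusion(nd, ni)
        assert c1.card_ftp == pytest.approx(c2.card_ftp)
        assert c1.card_ffp == pytest.approx(c2.card_ffn)
        assert c1.card_ffn == pytest.approx(c2.card_ffp)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_confusion(random_membership(0, (4, 4)), random_membership(1, (5, 5)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_pointwise_bounded_difference_identity(self, seed):
        """min(a,b) + max(0, a-b) reconstructs a pointwise."""
        ni, nd = random_membership(seed), random_membership(seed + 1)
        c = fuzzy_confusion(ni, nd)
        np.testing.assert_allclose(c.ftp_map + c.ffp_map, ni.values, atol=1e-12)
        np.testing.assert_allclose(c.ftp_map + c.ffn_map, nd.values, atol=1e-12)


class TestDistanceField:
    def test_full_support_zero_everywhere(self):
        fd = fuzzy_distance_field(MembershipImage(np.ones((6, 6))))
        assert fd.fd.max() == 0

    def test_single_corner_pixel_unit_at_opposite_corner(self):
        vals = np.zeros((3, 3))
        vals[0, 0] = 1.0
        fd = fuzzy_distance_field(MembershipImage(vals))
        assert fd.fd[2, 2] == pytest.approx(1.0)
        assert fd.maxD == pytest.approx(math.sqrt(8))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        nd = random_membership(seed, (12, 12), sparsity=0.8)
        if not (nd.values > 0).any():
            nd.values[0, 0] = 0.5
        fd = fuzzy_distance_field(nd)
        np.testing.assert_allclose(fd.fd, brute_force_fd(nd.values > 0), atol=1e-9)

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError, match="no detected edges"):
            fuzzy_distance_field(MembershipImage(np.zeros((4, 4))))


class TestFuzzyIndex:
    def test_perfect_agreement_all_ones(self):
        ones = MembershipImage(np.ones((5, 5)))
        fd = fuzzy_distance_field(ones)
        assert fuzzy_index(ones, ones, fd) == pytest.approx(1.0)

    def test_hand_worked_2x2(self):
        ni = MembershipImage(np.array([[1.0, 0.0], [0.0, 0.0]]), "reference")
        nd = MembershipImage(np.array([[0.5, 0.5], [0.0, 0.0]]), "detected")
        fd = fuzzy_distance_field(nd)
        # brute force: support = {(0,0),(0,1)}, maxD = sqrt(2)
        w = 1 + 1 + 2 / (1 + 1 / math.sqrt(2))
        expected = (0.5 * w - 0.5 - 0.5) / (4 * 1.0)
        assert fuzzy_index(ni, nd, fd) == pytest.approx(expected)

    def test_upper_bound(self):
        ni, nd = random_membership(7), random_membership(8, sparsity=0.3)
        fd = fuzzy_distance_field(nd)
        fi = fuzzy_index(ni, nd, fd)
        m, n = ni.shape
        assert fi <= (1.0 / (1.0 + fd.fd)).sum() / (m * n) + 1e-12
        assert fi <= 1.0 + 1e-12

    def test_decreases_with_added_false_mass(self):
        base = np.zeros((8, 8))
        base[3, 2:6] = 1.0
        ni = MembershipImage(base, "reference")
        nd = MembershipImage(base.copy(), "detected")
        fd = fuzzy_distance_field(nd)
        fi0 = fuzzy_index(ni, nd, fd)
        # extra reference mass unmatched by detection raises |FFP| -> FI drops
        ni2 = base.copy()
        ni2[6, 6] = 0.8
        fi_ffp = fuzzy_index(MembershipImage(ni2), nd, fd)
        # extra detected mass unmatched by reference raises |FFN| -> FI drops
        nd2 = base.copy()
        nd2[6, 6] = 0.8
        fi_ffn = fuzzy_index(ni, MembershipImage(nd2), fuzzy_distance_field(MembershipImage(nd2)))
        assert fi_ffp < fi0 and fi_ffn < fi0

    def test_both_zero_rejected(self):
        z = MembershipImage(np.zeros((4, 4)))
        fake_fd = fuzzy_distance_field(MembershipImage(np.ones((4, 4))))
        with pytest.raises(ValueError, match="undefined"):
            fuzzy_index(z, MembershipImage(np.zeros((4, 4))), fake_fd)


class TestPercentSummary:
    def test_all_ones_is_100(self):
        ones = MembershipImage(np.ones((6, 6)))
        c = fuzzy_confusion(ones, MembershipImage(np.ones((6, 6))))
        pct_ftp, _, _ = percent_summary(c, 6, 6)
        assert pct_ftp == pytest.approx(100.0)

    def test_hand_worked_2x2(self):
        ni = MembershipImage(np.array([[1.0, 0.0], [0.0, 0.0]]))
        nd = MembershipImage(np.array([[0.5, 0.5], [0.0, 0.0]]))
        pct_ftp, _, _ = percent_summary(fuzzy_confusion(ni, nd), 2, 2)
        assert pct_ftp == pytest.approx(12.5)

    def test_ftp_plus_ffp_invariant_across_detections(self):
        """For a fixed reference, %FTP + %FFP is the same for every detection."""
        ni = random_membership(11)
        totals = []
        for seed in range(6):
            nd = random_membership(100 + seed, sparsity=0.4)
            conf = evaluate_pair(ni, nd)
            totals.append(conf.pct_ftp + conf.pct_ffp)
        np.testing.assert_allclose(totals, totals[0], atol=1e-9)
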