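"""Lovasz scoring and supervised-target switching."""

import numpy as np
import pytest

from atstseg.atst import (ATSTState, lovasz_extension_value, s_lovasz,
                          select_target, sym_divergence, update_tau)
from atstseg.io import LabelMask


def jaccard_loss_of_error_set(g: np.ndarray, err: np.ndarray) -> float:
    """Set-function oracle: Jaccard loss of the prediction g XOR err."""
    pred = np.logical_xor(g > 0.5, err > 0.5)
    fg = g > 0.5
    union = (pred | fg).sum()
    if union == 0:
        return 0.0
    return 1.0 - (pred & fg).sum() / union


def lovasz_oracle(g: np.ndarray, p: np.ndarray) -> float:
    """Choquet-integral oracle for the Lovasz extension.

    f(m) = integral over t in [0, max m] of Delta({i : m_i >= t}) dt with
    Delta the Jaccard-loss set function — evaluated exactly by summing over
    the superlevel sets between consecutive sorted error values.  Fully
    independent of the sorted-gradient accumulation in the implementation.
    """
    g = np.asarray(g, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    m = np.where(g > 0.5, 1.0 - p, p)
    levels = np.unique(m)[::-1]
    acc = 0.0
    prev_t = None
    for t in levels:
        if prev_t is not None:
            acc += (prev_t - t) * jaccard_loss_of_error_set(g, (m >= prev_t))
        prev_t = t
    if prev_t is not None and prev_t > 0:
        acc += (prev_t - 0.0) * jaccard_loss_of_error_set(g, (m >= prev_t))
    return acc


class TestLovaszExtension:
    def test_zero_at_perfect_binary_agreement(self):
        g = np.array([1.0, 0, 1, 0])
        assert lovasz_extension_value(g, g) == 0.0

    def test_vertex_equals_jaccard_loss(self):
        g = np.array([1.0, 0, 0, 1])
        p = np.array([1.0, 0, 1, 1])
        # IoU = |{0,3}| / |{0,2,3}| = 2/3
        assert lovasz_extension_value(g, p) == pytest.approx(1 / 3)

    def test_vertices_exhaustive_length6(self):
        """On every binary (g, p) pair of length 6 the extension equals 1 - IoU."""
        n = 6
        for gb in range(2 ** n):
            g = np.array([(gb >> k) & 1 for k in range(n)], dtype=float)
            if g.sum() == 0:
                continue
            for pb in range(2 ** n):
                p = np.array([(pb >> k) & 1 for k in range(n)], dtype=float)
                inter = np.minimum(g, p).sum()
                union = np.maximum(g, p).sum()
                expected = 1.0 - (inter / union if union else 1.0)
                assert lovasz_extension_value(g, p) == pytest.approx(expected)

    def test_fractional_against_independent_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 12))
            g = (rng.random(n) < 0.5).astype(float)
            if g.sum() == 0:
                g[0] = 1.0
            p = rng.random(n)
            assert lovasz_extension_value(g, p) == pytest.approx(
                lovasz_oracle(g, p), abs=1e-12)

    def test_range_and_degenerate_background(self, rng):
        for _ in range(20):
            g = (rng.random(10) < 0.5).astype(float)
            p = rng.random(10)
            v = lovasz_extension_value(g, p)
            assert 0.0 <= v <= 1.0
        # all-background target: defined as mean error
        p = np.array([0.2, 0.7, 0.1])
        assert lovasz_extension_value(np.zeros(3), p) == pytest.approx(p.mean())


class TestSymDivergence:
    def test_identity_and_symmetry(self, rng):
        p = rng.random((4, 4))
        q = rng.random((4, 4))
        assert sym_divergence(p, p) == 0.0
        assert sym_divergence(p, q) == pytest.approx(sym_divergence(q, p))
        assert sym_divergence(p, q) >= 0

    def test_closed_form_bernoulli(self):
        # 0.5*KL(0.9||0.1) + 0.5*KL(0.1||0.9) = 0.8*ln 9
        got = sym_divergence(np.array([0.9]), np.array([0.1]))
        assert got == pytest.approx(0.8 * np.log(9.0), rel=1e-9)

    def test_js_variant_bounded(self, rng):
        p = rng.random((6,))
        q = rng.random((6,))
        js = sym_divergence(p, q, kind="js")
        assert 0 <= js <= np.log(2) + 1e-12


class TestSLovasz:
    def test_perfect_clean_prediction_scores_zero(self):
        g = np.array([[1.0, 0], [0, 1]])
        assert s_lovasz(g, g, np.full((2, 2), 0.5)) == 0.0

    def test_zero_divergence_reduces_to_lev(self, rng):
        g = (rng.random((3, 3)) < 0.5).astype(float)
        g[0, 0] = 1
        p = rng.random((3, 3))
        lev = lovasz_extension_value(g, p)
        # noisy prediction equal to the (clamped) pseudo-label -> div = 0
        assert s_lovasz(g, p, g) == pytest.approx(lev, rel=1e-6)

    def test_arithmetic_composition(self, rng):
        g = (rng.random((4, 4)) < 0.5).astype(float)
        g[0, 0] = 1
        p_c = rng.random((4, 4))
        p_n = rng.random((4, 4))
        lev = lovasz_extension_value(g, p_c)
        div = sym_divergence(np.clip(g, 1e-6, 1 - 1e-6), p_n)
        assert s_lovasz(g, p_c, p_n) == pytest.approx(lev / np.exp(div))

    def test_monotone_decreasing_in_divergence(self, rng):
        g = (rng.random((4, 4)) < 0.5).astype(float)
        g[0, 0] = 1
        p_c = rng.random((4, 4))
        close = np.clip(g, 0.2, 0.8)       # mildly divergent from g
        far = np.clip(1 - g, 0.01, 0.99)   # strongly divergent
        assert s_lovasz(g, p_c, close) >= s_lovasz(g, p_c, far)


class TestUpdateTau:
    def test_warm_up_rule(self):
        st = ATSTState(window_len=100)
        for i in range(99):
            update_tau(st, 0.5)
            assert st.tau is None
        update_tau(st, 0.5)
        assert st.tau == pytest.approx(0.5)

    def test_constant_window(self):
        st = ATSTState(window_len=10)
        for _ in range(10):
            update_tau(st, 0.7)
        assert st.tau == pytest.approx(0.7)

    def test_percentile_of_explicit_list(self):
        st = ATSTState(window_len=100, h_percentile=50.0)
        for v in range(1, 101):
            update_tau(st, float(v))
        assert st.tau == pytest.approx(50.5)

    def test_eviction_keeps_window_length(self):
        st = ATSTState(window_len=5)
        for v in [1, 2, 3, 4, 5, 100]:
            update_tau(st, float(v))
        assert len(st.s_history) == 5
        assert list(st.s_history) == [2.0, 3.0, 4.0, 5.0, 100.0]

    def test_rejects_bad_scores(self):
        st = ATSTState(window_len=3)
        with pytest.raises(ValueError):
            update_tau(st, float("nan"))
        with pytest.raises(ValueError):
            update_tau(st, -0.1)


class TestSelectTarget:
    def _state(self, tau):
        st = ATSTState(window_len=3)
        st.tau = tau
        return st

    def test_unset_tau_keeps_pseudo_label(self, rng):
        gp = LabelMask((rng.random((4, 4)) < 0.5).astype(np.uint8))
        t = select_target(10.0, self._state(None), rng.random((4, 4)), gp)
        assert t.source == "pseudo_label"
        assert np.array_equal(t.mask.voxels, gp.voxels)

    def test_switch_above_threshold(self, rng):
        p = rng.random((4, 4))
        gp = LabelMask(np.zeros((4, 4), dtype=np.uint8))
        t = select_target(0.6, self._state(0.5), p, gp)
        assert t.source == "clean_prediction"
        assert np.array_equal(t.mask.voxels, (p >= 0.5).astype(np.uint8))

    def test_below_threshold_keeps_pseudo(self, rng):
        gp = LabelMask(np.ones((2, 2), dtype=np.uint8))
        t = select_target(0.4, self._state(0.5), rng.random((2, 2)), gp)
        assert t.source == "pseudo_label"

    def test_tie_switches(self, rng):
        t = select_target(0.5, self._state(0.5), rng.random((2, 2)),
                          LabelMask(np.ones((2, 2), dtype=np.uint8)))
        assert t.source == "clean_prediction"

    def test_decision_flips_exactly_at_tau(self, rng):
        st = self._state(0.5)
        p = rng.random((2, 2))
        gp = LabelMask(np.zeros((2, 2), dtype=np.uint8))
        eps = 1e-12
        assert select_target(0.5 - eps, st, p, gp).source == "pseudo_label"
        assert select_target(0.5 + eps, st, p, gp).source == "clean_prediction"
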