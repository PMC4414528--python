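"""Pattern quantification: extrema detection, incipient filter, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from auxring.model import RingState, TransportParams, homogeneous_steady_state
from auxring.quantify import (
    filter_incipient,
    find_extrema,
    summarize,
    summarize_profile,
)


def brute_force_extrema(values):
    """Walk left/right to the nearest unequal value; plateau keeps its
    lowest member index.  Independent of the run-length implementation."""
    v = list(values)
    n = len(v)
    if all(x == v[0] for x in v):
        return [], []
    maxima, minima = set(), set()
    for i in range(n):
        left = next(v[(i - d) % n] for d in range(1, n + 1) if v[(i - d) % n] != v[i])
        right = next(v[(i + d) % n] for d in range(1, n + 1) if v[(i + d) % n] != v[i])
        if v[i] > left and v[i] > right:
            kind = maxima
        elif v[i] < left and v[i] < right:
            kind = minima
        else:
            continue
        # collapse the plateau containing i to its lowest member index
        members = {i}
        for d in range(1, n):
            if v[(i + d) % n] == v[i]:
                members.add((i + d) % n)
            else:
                break
        for d in range(1, n):
            if v[(i - d) % n] == v[i]:
                members.add((i - d) % n)
            else:
                break
        kind.add(min(members))
    return sorted(maxima), sorted(minima)


class TestFindExtrema:
    def test_two_peak_ring(self):
        maxima, minima = find_extrema([5, 1, 1, 5, 1, 1])
        assert list(maxima) == [0, 3]
        assert len(minima) == 2

    def test_constant_ring_has_no_extrema(self):
        maxima, minima = find_extrema([2.0] * 8)
        assert len(maxima) == 0 and len(minima) == 0

    def test_wrapped_plateau_counts_once_at_lowest_index(self):
        maxima, minima = find_extrema([3, 1, 3, 3])
        assert list(maxima) == [0]
        assert list(minima) == [1]

    def test_too_short_ring_rejected(self):
        with pytest.raises(ValueError):
            find_extrema([1, 2])

    def test_matches_brute_force_on_random_rings(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = rng.integers(3, 13)
            v = rng.integers(0, 5, n).astype(float)
            maxima, minima = find_extrema(v)
            bf_max, bf_min = brute_force_extrema(v)
            assert list(maxima) == bf_max and list(minima) == bf_min

    def test_alternation_and_equal_counts(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            v = rng.uniform(0, 1, rng.integers(4, 40))
            maxima, minima = find_extrema(v)
            assert len(maxima) == len(minima)
            merged = sorted([(i, "M") for i in maxima] + [(i, "m") for i in minima])
            kinds = [k for _, k in merged]
            assert all(k1 != k2 for k1, k2 in zip(kinds, kinds[1:] + kinds[:1]))


class TestFilterIncipient:
    def build_ring(self, peak3):
        # peaks 10, 10, peak3 over minima all at 1.0
        return np.array([10.0, 1.0, 10.0, 1.0, peak3, 1.0])

    def test_borderline_peak_retained(self):
        # provisional amplitude (10+10+2)/3 - 1 = 6.33; cutoff 0.95 <= excess 1.0
        v = self.build_ring(2.0)
        maxima, minima = find_extrema(v)
        retained, removed = filter_incipient(v, maxima, minima)
        assert list(retained) == [0, 2, 4] and len(removed) == 0

    def test_shallow_peak_dropped(self):
        # excess 0.9 < 0.15 * ((10+10+1.9)/3 - 1) = 0.945
        v = self.build_ring(1.9)
        maxima, minima = find_extrema(v)
        retained, removed = filter_incipient(v, maxima, minima)
        assert list(retained) == [0, 2] and list(removed) == [4]

    def test_equal_peaks_all_survive(self):
        v = np.array([7.0, 1.0] * 5)
        maxima, minima = find_extrema(v)
        retained, removed = filter_incipient(v, maxima, minima)
        assert len(retained) == 5 and len(removed) == 0

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(31)
        v = rng.uniform(0, 10, 30)
        maxima, minima = find_extrema(v)
        retained, removed = filter_incipient(v, maxima, minima, threshold=0.0)
        assert np.array_equal(retained, maxima) and len(removed) == 0

    def test_flat_profile_flagged_degenerate(self):
        s = summarize_profile(np.full(10, 3.0), "cyto")
        assert s.degenerate and s.kappa_sim == 0.0 and s.amplitude == 0.0


class TestSummarize:
    def test_cosine_wavenumber_recovered(self):
        n, k = 60, 5
        rng = np.random.default_rng(41)
        v = 10 + 3 * np.cos(2 * np.pi * k * np.arange(n) / n)
        v += rng.normal(0, 0.01, n)
        s = summarize_profile(v, "cyto")
        assert s.kappa_sim == pytest.approx(k / n)

    def test_homogeneous_state_summary(self, default_params):
        A_star, a_star = homogeneous_steady_state(default_params)
        state = RingState(np.full(60, A_star), np.full(60, a_star))
        cyto, apo = summarize(state)
        assert cyto.kappa_sim == 0.0 and cyto.amplitude == 0.0
        assert cyto.mean_level == pytest.approx(A_star)
        assert apo.mean_level == pytest.approx(a_star)

    @given(shift=st.integers(0, 59))
    @settings(max_examples=20, deadline=None)
    def test_rotation_invariance(self, shift):
        rng = np.random.default_rng(47)
        v = rng.uniform(0, 10, 60)
        s0 = summarize_profile(v, "cyto")
        s1 = summarize_profile(np.roll(v, shift), "cyto")
        assert s1.kappa_sim == s0.kappa_sim
        assert s1.amplitude == pytest.approx(s0.amplitude)
        assert s1.mean_level == pytest.approx(s0.mean_level)
        assert s1.n_incipient_removed == s0.n_incipient_removed

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_covariance(self, scale):
        rng = np.random.default_rng(53)
        v = rng.uniform(0.5, 10, 40)
        s0 = summarize_profile(v, "cyto")
        s1 = summarize_profile(scale * v, "cyto")
        assert s1.kappa_sim == s0.kappa_sim
        assert np.array_equal(s1.maxima_idx, s0.maxima_idx)
        assert s1.amplitude == pytest.approx(scale * s0.amplitude)
        assert s1.avg_max == pytest.approx(scale * s0.avg_max)
        assert s1.mean_level == pytest.approx(scale * s0.mean_level)
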