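import collections
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stresscast.errors import InsufficientDataError, SearchError
from stresscast.phase_space import (
    DimensionScan,
    all_nearest_neighbors,
    delay_scan,
    dimension_scan,
    first_local_minimum,
    mutual_information,
    nearest_neighbor,
    reconstruct,
    select_embedding_dimension,
)


def entropy_oracle(symbols) -> float:
    """Independent plug-in Shannon entropy (bits) via Counter/math."""
    counts = collections.Counter(symbols)
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def mi_oracle(x: np.ndarray, tau: int) -> float:
    a, b = x[: len(x) - tau], x[tau:]
    return (
        entropy_oracle(a)
        + entropy_oracle(b)
        - entropy_oracle(list(zip(a, b)))
    )


class TestMutualInformation:
    def test_constant_sequence_zero_bits(self):
        assert mutual_information(np.full(50, 3.0), 3) == 0.0

    def test_period_two_alternation_is_one_bit(self):
        x = np.array([1.0, 2.0] * 20)
        assert mutual_information(x, 2) == pytest.approx(1.0, abs=1e-12)

    def test_iid_uniform_mi_vanishes(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 6, size=10000).astype(float)
        assert mutual_information(x, 1) <= 0.02

    def test_tau_out_of_range_raises(self):
        with pytest.raises(InsufficientDataError):
            mutual_information(np.arange(5.0), 5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_entropy_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=rng.integers(20, 200)).astype(float)
        tau = int(rng.integers(1, 5))
        assert mutual_information(x, tau) == pytest.approx(
            mi_oracle(x, tau), abs=1e-9
        )

    @given(st.lists(st.integers(0, 5), min_size=6, max_size=60), st.integers(1, 4))
    @settings(max_examples=50, deadline=None)
    def test_oracle_equivalence_property(self, levels, tau):
        x = np.asarray(levels, dtype=float)
        assert mutual_information(x, tau) == pytest.approx(mi_oracle(x, tau), abs=1e-9)


class TestDelaySelection:
    def test_first_local_minimum_of_curve(self):
        assert first_local_minimum([2.0, 1.1, 0.7, 0.9, 0.8]) == 3

    def test_no_interior_minimum_returns_none(self):
        assert first_local_minimum([2.0, 1.5, 1.0, 0.5, 0.1]) is None

    def test_monotone_curve_falls_back_to_argmin_with_warning(self, monkeypatch):
        import stresscast.phase_space as psmod

        fake = {1: 2.0, 2: 1.5, 3: 1.0, 4: 0.5}
        monkeypatch.setattr(
            psmod, "mutual_information", lambda x, tau, bins=None: fake[tau]
        )
        with pytest.warns(UserWarning, match="no interior local minimum"):
            scan = delay_scan(np.arange(50.0), 4)
        assert scan.selected_tau == 4 and scan.is_fallback

    def test_logistic_map_matches_direct_scan_oracle(self, logistic_5000):
        scan = delay_scan(logistic_5000, 8)
        # independent oracle: recompute the curve and apply the rule directly
        M = [mutual_information(logistic_5000, t) for t in range(1, 9)]
        pos = next(
            (t for t in range(2, 8) if M[t - 2] > M[t - 1] < M[t]),
            None,
        )
        expected = pos if pos is not None else int(np.argmin(M)) + 1
        assert scan.selected_tau == expected

    def test_too_short_series_raises(self):
        with pytest.raises(InsufficientDataError):
            delay_scan(np.arange(3.0), 5)


class TestReconstruct:
    def test_vectors_follow_delay_rule(self):
        x = np.arange(1.0, 11.0)  # s_1..s_10
        ps = reconstruct(x, tau=2, d=3)
        assert ps.N == 6
        np.testing.assert_array_equal(ps.vectors[0], [1, 3, 5])
        np.testing.assert_array_equal(ps.vectors[5], [6, 8, 10])

    def test_dimension_one_is_identity_embedding(self):
        x = np.arange(7.0)
        ps = reconstruct(x, tau=3, d=1)
        assert ps.N == 7
        np.testing.assert_array_equal(ps.vectors.ravel(), x)

    def test_padded_length_arithmetic(self):
        assert reconstruct(np.arange(44.0), 1, 4).N == 41

    def test_column_zero_recovers_series_prefix(self):
        rng = np.random.default_rng(0)
        x = rng.random(30)
        ps = reconstruct(x, tau=2, d=4)
        np.testing.assert_array_equal(ps.vectors[:, 0], x[: ps.N])

    def test_insufficient_length_raises(self):
        with pytest.raises(InsufficientDataError):
            reconstruct(np.arange(5.0), tau=3, d=3)


class TestNearestNeighbor:
    def test_geometry(self):
        ps = reconstruct(np.array([0.0, 0.0, 0.0, 1.0, 5.0, 5.0]), 1, 2)
        # vectors: (0,0),(0,0),(0,1),(1,5),(5,5)
        assert nearest_neighbor(ps, 4, exclusion=0) == 3

    def test_duplicate_points_tie_to_smallest_index(self):
        x = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        ps = reconstruct(x, 1, 2)
        assert nearest_neighbor(ps, 4, exclusion=0) == 0

    def test_full_exclusion_raises(self):
        ps = reconstruct(np.arange(6.0), 1, 2)
        with pytest.raises(SearchError):
            nearest_neighbor(ps, 0, exclusion=ps.N)

    @pytest.mark.parametrize("seed", range(5))
    def test_kdtree_search_agrees_with_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 200))
        V = rng.random((N, 3))
        excl = int(rng.integers(0, 3))
        fast = all_nearest_neighbors(V, exclusion=excl, dist_floor=-1.0)
        for i in range(N):
            dist = np.linalg.norm(V - V[i], axis=1)
            dist[np.abs(np.arange(N) - i) <= excl] = np.inf
            assert fast[i] == int(np.argmin(dist))


class TestDimensionScan:
    def test_henon_saturates_by_dimension_four(self, henon_5000):
        scan = dimension_scan(henon_5000[:2000], tau=1, d_max=10)
        d0 = select_embedding_dimension(scan, eps=0.05)
        assert d0 <= 4
        assert abs(scan.EV_values[d0 - 1] - 1.0) <= 0.05

    def test_iid_noise_fails_to_saturate(self):
        rng = np.random.default_rng(1)
        scan = dimension_scan(rng.random(1000), tau=1, d_max=10)
        with pytest.warns(UserWarning, match="does not saturate"):
            assert select_embedding_dimension(scan, eps=0.05) == 10

    def test_periodic_series_yields_finite_statistics(self):
        x = np.tile([0.1, 0.9, 0.4, 0.6, 0.2], 40)
        scan = dimension_scan(x, tau=1, d_max=8)
        assert np.all(np.isfinite(scan.E_values))
        assert np.all(scan.E_values > 0)
        assert np.all(np.isfinite(scan.EV_values[:-1]))

    def test_bit_reproducible_across_runs(self, henon_5000):
        a = dimension_scan(henon_5000[:1500], tau=1, d_max=6)
        b = dimension_scan(henon_5000[:1500], tau=1, d_max=6)
        np.testing.assert_array_equal(a.E_values, b.E_values)
        np.testing.assert_array_equal(a.EV_values, b.EV_values)


class TestSelectEmbeddingDimension:
    def _scan(self, ev):
        ev = np.asarray(ev, dtype=float)
        ds = np.arange(1, len(ev) + 2)
        return DimensionScan(
            ds=ds, E_values=np.ones(len(ds)), EV_values=np.append(ev, np.nan)
        )

    def test_two_consecutive_saturations_rule(self):
        assert select_embedding_dimension(self._scan([1.9, 1.3, 1.02, 1.01, 1.0])) == 3

    def test_immediate_saturation_returns_one(self):
        assert select_embedding_dimension(self._scan([1.0, 1.01, 1.0])) == 1

    def test_no_saturation_falls_back_to_d_max(self):
        with pytest.warns(UserWarning):
            assert select_embedding_dimension(self._scan([1.9, 1.5, 1.3, 1.2])) == 5
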