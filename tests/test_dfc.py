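"""Tapered windows, windowed correlations, state clustering and SDFC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsdbn.dfc import (ConfigurationError, DFCConfig, cluster_states,
                       count_windows, sdfc, taper_weights, windowed_fc)
from vsdbn.synthetic import default_states, planted_dfc_series


class TestTaper:
    def test_default_length_is_rect_plus_full_kernel(self):
        w = taper_weights(DFCConfig())
        assert len(w) == 22 + 2 * 11
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)

    def test_degenerate_kernel_gives_flat_rectangle(self):
        w = taper_weights(DFCConfig(gauss_halfwidth=0))
        np.testing.assert_allclose(w, np.full(22, 1 / 22), atol=1e-15)

    def test_symmetric_about_center(self):
        w = taper_weights(DFCConfig())
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)


class TestCountWindows:
    def test_full_study_length(self):
        assert count_windows(206, DFCConfig()) == 82

    def test_exact_fit_gives_one_window(self):
        cfg = DFCConfig()
        assert count_windows(cfg.window_length, cfg) == 1

    def test_short_tail_dropped(self):
        assert count_windows(50, DFCConfig()) == 4

    def test_too_short_series_rejected(self):
        with pytest.raises(ConfigurationError):
            count_windows(40, DFCConfig())

    @given(st.integers(44, 400), st.integers(1, 7))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_closed_form_matches_placement_enumeration(self, t_len, step):
        cfg = DFCConfig(step=step)
        L = cfg.window_length
        brute = sum(1 for start in range(0, t_len, step)
                    if start + L <= t_len)
        assert count_windows(t_len, cfg) == brute


class TestWindowedFC:
    def test_identical_columns_correlate_at_one(self, rng):
        x = rng.standard_normal(100)
        tensor = windowed_fc(np.column_stack([x, x]), DFCConfig())
        np.testing.assert_allclose(tensor[:, 0, 1], 1.0, atol=1e-12)

    def test_opposite_columns_correlate_at_minus_one(self, rng):
        x = rng.standard_normal(100)
        tensor = windowed_fc(np.column_stack([x, -x]), DFCConfig())
        np.testing.assert_allclose(tensor[:, 0, 1], -1.0, atol=1e-12)

    def test_uniform_weights_reproduce_plain_pearson(self, rng):
        cfg = DFCConfig(gauss_halfwidth=0)
        feats = rng.standard_normal((60, 4))
        tensor = windowed_fc(feats, cfg)
        L = cfg.window_length
        for w in range(tensor.shape[0]):
            seg = feats[w * cfg.step:w * cfg.step + L]
            oracle = np.corrcoef(seg.T)
            np.testing.assert_allclose(tensor[w], oracle, atol=1e-12)

    def test_matrices_symmetric_with_unit_diagonal(self, rng):
        tensor = windowed_fc(rng.standard_normal((90, 5)), DFCConfig())
        for mat in tensor:
            np.testing.assert_allclose(mat, mat.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(mat), 1.0, atol=1e-12)

    def test_zero_variance_component_zeroed_with_warning(self, rng):
        feats = rng.standard_normal((50, 3))
        feats[:, 1] = 2.0
        with pytest.warns(UserWarning, match="zero weighted"):
            tensor = windowed_fc(feats, DFCConfig())
        assert np.all(tensor[:, 0, 1] == 0)
        assert np.all(np.diag(tensor[0]) == 1.0)


class TestClusterStates:
    def test_first_window_is_state_one(self, rng):
        states = default_states(k_net=6, seed=1)
        pl = planted_dfc_series(states, dwell=100, v=500, seed=2,
                                noise_sd=0.1)
        res = cluster_states(windowed_fc(pl.features, DFCConfig()),
                             DFCConfig())
        assert res.assignments[0] == 1
        assert set(res.assignments) <= {1, 2, 3, 4}

    def test_all_identical_windows_flagged_degenerate(self, rng):
        x = rng.standard_normal((44, 4))
        feats = np.tile(x, (4, 1))
        tensor = windowed_fc(feats, DFCConfig(step=44))
        with pytest.warns(UserWarning, match="distinct"):
            res = cluster_states(tensor, DFCConfig())
        assert res.degenerate
        assert res.n_effective_states == 1

    def test_fewer_windows_than_k_rejected(self, rng):
        tensor = windowed_fc(rng.standard_normal((46, 4)), DFCConfig())
        with pytest.raises(ConfigurationError):
            cluster_states(tensor, DFCConfig())

    def test_multiple_tensors_share_centroids(self, rng):
        states = default_states(k_net=5, seed=3)
        tensors = []
        for seed in (4, 5):
            pl = planted_dfc_series(states, dwell=100, v=500, seed=seed,
                                    noise_sd=0.1)
            tensors.append(windowed_fc(pl.features, DFCConfig()))
        results = cluster_states(tensors, DFCConfig())
        assert len(results) == 2
        np.testing.assert_array_equal(results[0].centroids,
                                      results[1].centroids)
        assert results[0].assignments.shape[0] == tensors[0].shape[0]


class TestSDFC:
    def _result_pair(self, rng, transform):
        states = default_states(k_net=6, seed=6)
        pl = planted_dfc_series(states, dwell=100, v=500, seed=7,
                                noise_sd=0.1)
        res = cluster_states(windowed_fc(pl.features, DFCConfig()),
                             DFCConfig())
        import copy
        other = copy.deepcopy(res)
        other.centroids = transform(other.centroids)
        return res, other

    def test_identical_results_give_one(self, rng):
        a, b = self._result_pair(rng, lambda c: c)
        assert sdfc(a, b) == pytest.approx(1.0)

    def test_monotone_centroid_transform_is_invisible_to_spearman(self, rng):
        a, b = self._result_pair(rng, lambda c: c ** 3 + 0.5 * c)
        assert sdfc(a, b) == pytest.approx(1.0)

    def test_negated_centroids_give_minus_one(self, rng):
        a, b = self._result_pair(rng, lambda c: -c)
        assert sdfc(a, b) == pytest.approx(-1.0)

    def test_window_count_mismatch_rejected(self, rng):
        a, b = self._result_pair(rng, lambda c: c)
        import copy
        short = copy.deepcopy(b)
        short.assignments = short.assignments[:-3]
        short.tensor = short.tensor[:-3]
        with pytest.raises(ValueError, match="window counts"):
            sdfc(a, short)

    def test_self_similarity_is_one_for_any_fixture(self, rng):
        feats = rng.standard_normal((120, 5))
        res = cluster_states(windowed_fc(feats, DFCConfig()), DFCConfig())
        assert sdfc(res, res) == pytest.approx(1.0)

    def test_raw_mode_compares_windowed_matrices(self, rng):
        a, b = self._result_pair(rng, lambda c: c)
        cfg = DFCConfig(state_comparison="raw")
        assert sdfc(a, b, cfg) == pytest.approx(1.0)
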