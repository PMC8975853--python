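"""HALS NMF: correctness against a multiplicative-update oracle, objective
monotonicity, multistart selection, weight normalization and labeling."""

import numpy as np
import pytest

from screenrhythms import (
    frobenius_error,
    label_components,
    nmf_hals,
    nmf_multistart,
    normalize_weights,
)
from screenrhythms.nmf import Decomposition, restart_seeds


def mu_nmf_error(X, k, seed, n_iter=5000):
    """Independent oracle: Lee-Seung multiplicative updates to convergence."""
    rng = np.random.default_rng(seed)
    n, m = X.shape
    W = rng.uniform(0.1, 1.0, (n, k))
    H = rng.uniform(0.1, 1.0, (m, k))
    for _ in range(n_iter):
        W *= (X @ H) / np.maximum(W @ (H.T @ H), 1e-12)
        H *= (X.T @ W) / np.maximum(H @ (W.T @ W), 1e-12)
    return frobenius_error(X, W, H)


def planted_matrix(n, m, k, seed, noise=0.0):
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.2, 1.0, (n, k))
    H = rng.uniform(0.2, 1.0, (m, k))
    X = W @ H.T
    if noise:
        X = np.maximum(X + rng.normal(0, noise, X.shape), 0.0)
    return X


class TestHals:
    def test_exact_rank1_factorization(self, rng):
        X = planted_matrix(12, 9, 1, seed=5)
        dec = nmf_hals(X, 1, seed=3, tol=1e-12, max_iter=2000)
        assert dec.error < 1e-10

    def test_all_zero_matrix(self):
        dec = nmf_hals(np.zeros((5, 7)), 2, seed=0)
        assert dec.error == 0.0
        np.testing.assert_array_equal(dec.reconstruction(), 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_multiplicative_update_oracle(self, seed):
        """HALS and Lee-Seung converge to the same objective on planted 6x8."""
        X = planted_matrix(6, 8, 2, seed=seed)
        hals = nmf_hals(X, 2, seed=seed, tol=1e-12, max_iter=5000)
        mu = mu_nmf_error(X, 2, seed=seed + 100)
        assert hals.error <= mu + 1e-6
        assert abs(hals.error - mu) < 1e-6

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_objective_monotone_across_sweeps(self, k, default_profiles):
        dec = nmf_hals(default_profiles.X[:40], k, seed=7, max_iter=80)
        hist = np.asarray(dec.objective_history)
        assert (np.diff(hist) <= 1e-12).all()

    def test_factors_non_negative(self, default_profiles):
        dec = nmf_hals(default_profiles.X[:30], 3, seed=1)
        assert (dec.W >= 0).all() and (dec.H >= 0).all()

    def test_error_consistent_with_factors(self, default_profiles):
        X = default_profiles.X[:30]
        dec = nmf_hals(X, 3, seed=1)
        assert abs(dec.error - frobenius_error(X, dec.W, dec.H)) <= 1e-8 * max(dec.error, 1)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            nmf_hals(np.ones((4, 6)), 5, seed=0)

    def test_negative_input_rejected(self):
        X = np.ones((4, 6)); X[0, 0] = -1
        with pytest.raises(ValueError):
            nmf_hals(X, 2, seed=0)


class TestMultistart:
    def test_single_seed_equals_plain_run(self, default_profiles):
        X = default_profiles.X[:30]
        multi = nmf_multistart(X, 3, n_seeds=1, seed=9)
        single = nmf_hals(X, 3, seed=int(restart_seeds(9, 1)[0]))
        assert multi.error == single.error
        np.testing.assert_array_equal(multi.W, single.W)

    def test_returns_minimum_over_runs(self, default_profiles):
        X = default_profiles.X[:30]
        errors = [nmf_hals(X, 3, seed=int(s)).error for s in restart_seeds(4, 10)]
        assert nmf_multistart(X, 3, n_seeds=10, seed=4).error == min(errors)

    def test_best_beats_median_on_planted_data(self, default_profiles):
        X = default_profiles.X
        errors = [nmf_hals(X, 4, seed=int(s)).error for s in restart_seeds(2, 50)]
        assert nmf_multistart(X, 4, n_seeds=50, seed=2).error <= np.median(errors)


class TestNormalizeWeights:
    def test_rows_sum_to_unity(self, fitted4):
        nw = fitted4.normalized_weights()
        np.testing.assert_allclose(nw.weights.sum(axis=1), 1.0, atol=1e-9)
        assert ((nw.weights >= 0) & (nw.weights <= 1)).all()

    def test_unit_mass_columns_halve_equal_weights(self):
        W = np.array([[2.0, 2.0, 0.0, 0.0]])
        H = np.full((168, 4), 1 / 168)  # unit-mass columns
        dec = Decomposition(W, H, 4, 0.0, 0, 0)
        nw = normalize_weights(dec)
        np.testing.assert_allclose(nw.weights[0], [0.5, 0.5, 0.0, 0.0])

    def test_rescaling_preserves_reconstruction(self, fitted4):
        dec = fitted4.decomposition
        nw = fitted4.normalized_weights()
        mass = dec.H.sum(axis=0)
        before = dec.W @ dec.H.T
        after = (dec.W * mass) @ nw.H_unit.T
        np.testing.assert_allclose(before, after, atol=1e-9)

    def test_zero_row_names_participant(self):
        W = np.array([[1.0, 1.0], [0.0, 0.0]])
        H = np.full((168, 2), 1 / 168)
        dec = Decomposition(W, H, 2, 0.0, 0, 0, row_ids=["good", "dead"])
        with pytest.raises(ValueError, match="dead"):
            normalize_weights(dec)


class TestLabelComponents:
    @staticmethod
    def one_hot_component(hour_of_day):
        h = np.zeros(168)
        h[np.arange(7) * 24 + hour_of_day] = 1.0
        return h

    @pytest.mark.parametrize(
        "hour,label",
        [(8, "morning"), (12, "noon"), (17, "evening"), (23, "night"), (2, "night")],
    )
    def test_band_membership(self, hour, label):
        H = np.column_stack([self.one_hot_component(hour)])
        assert label_components(H) == [label]

    def test_same_band_gets_ordinal_suffix(self):
        H = np.column_stack(
            [self.one_hot_component(9), self.one_hot_component(6)]
        )
        assert label_components(H) == ["morning_2", "morning_1"]

    def test_default_population_yields_all_four_bands(self, fitted4):
        assert sorted(fitted4.component_labels()) == [
            "evening", "morning", "night", "noon",
        ]


class TestModelInterface:
    def test_results_expose_factors_and_summary(self, fitted4):
        assert fitted4.W.shape == (200, 4)
        assert fitted4.H.shape == (168, 4)
        text = fitted4.summary()
        assert "components (K)" in text and "4" in text

    def test_save_round_trip(self, tmp_path, fitted4):
        fitted4.save(tmp_path)
        import json
        import pandas as pd

        meta = json.loads((tmp_path / "decomposition.json").read_text())
        assert meta["k"] == 4
        W = pd.read_csv(tmp_path / "W.csv")
        assert len(W) == 200
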