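"""Sig transform, PCA score integration and ranking evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bindshift import (
    DeltaTable,
    alternative_integrations,
    build_integration_matrix,
    cumulative_accuracy,
    mutation_score,
    pca_integrate,
    sig_transform,
)


def make_table(deltas: np.ndarray, direct=None, mu_grid=None, motif_ids=None, tf_names=None):
    """Assemble a DeltaTable from a motif x mu delta matrix."""
    deltas = np.asarray(deltas, dtype=float)
    n, k = deltas.shape
    mu_grid = tuple(mu_grid) if mu_grid is not None else tuple(np.linspace(0, -20, k))
    motif_ids = motif_ids or [f"m{i:02d}" for i in range(n)]
    tf_names = tf_names or {mid: mid.upper() for mid in motif_ids}
    direct = np.ones_like(deltas, dtype=bool) if direct is None else np.asarray(direct, bool)
    rows = []
    for i, mid in enumerate(motif_ids):
        for j, mu in enumerate(mu_grid):
            rows.append(
                {"motif_id": mid, "tf_name": tf_names[mid], "mu": mu,
                 "delta": deltas[i, j], "p_ref": 0.01 if direct[i, j] else 0.5,
                 "p_mut": 0.5, "direct": bool(direct[i, j])}
            )
    return DeltaTable(frame=pd.DataFrame(rows), mu_grid=mu_grid)


class TestSigTransform:
    def test_zero(self):
        assert sig_transform(0.0) == 0.0

    def test_e_minus_one_maps_to_one(self):
        assert sig_transform(np.e - 1) == pytest.approx(1.0, abs=1e-15)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-1e6, 1e6, allow_nan=False))
    def test_odd_function(self, x):
        assert sig_transform(-x) == pytest.approx(-sig_transform(x), abs=1e-12)

    def test_strictly_increasing(self):
        x = np.linspace(-5, 5, 101)
        assert (np.diff(sig_transform(x)) > 0).all()


class TestBuildIntegrationMatrix:
    def test_never_direct_motifs_are_dropped(self):
        direct = np.ones((3, 4), bool)
        direct[1] = False
        table = make_table(np.ones((3, 4)), direct=direct)
        M = build_integration_matrix(table)
        assert M.n_motifs == 2
        assert "m01" not in M.motif_ids

    def test_zero_deltas_give_zero_matrix(self):
        M = build_integration_matrix(make_table(np.zeros((3, 4))))
        assert not np.any(M.D)

    def test_entries_are_sig_of_delta(self):
        deltas = np.array([[0.5, -2.0], [3.0, 0.0]])
        M = build_integration_matrix(make_table(deltas, mu_grid=(0.0, -10.0)))
        np.testing.assert_allclose(M.D, sig_transform(deltas))

    def test_no_direct_tf_yields_empty_result_not_error(self):
        table = make_table(np.ones((2, 3)), direct=np.zeros((2, 3), bool))
        M = build_integration_matrix(table)
        assert M.n_motifs == 0
        pred = pca_integrate(M)
        assert pred.positive == () and pred.negative == ()

    def test_min_direct_threshold(self):
        direct = np.zeros((2, 4), bool)
        direct[0, :2] = True
        direct[1, 0] = True
        table = make_table(np.ones((2, 4)), direct=direct)
        assert build_integration_matrix(table, min_direct=2).motif_ids == ("m00",)


class TestPcaIntegrate:
    def test_single_column_reduces_to_sorting_by_delta(self):
        deltas = np.array([[0.3], [-1.5], [0.9], [-0.1]])
        table = make_table(deltas, mu_grid=(-13.0,))
        pred = pca_integrate(build_integration_matrix(table))
        assert pred.positive == ("m02", "m00")
        assert pred.negative == ("m01", "m03")

    def test_rank_one_matrix_scores_proportional_to_row_factor(self, rng):
        u = rng.uniform(0.5, 2.0, size=8)
        v = rng.uniform(0.5, 1.5, size=5)
        D = np.outer(u, v)
        # choose deltas so that Sig(delta) = D exactly
        deltas = np.sign(D) * (np.exp(np.abs(D)) - 1)
        pred = pca_integrate(build_integration_matrix(make_table(deltas)))
        scores = np.abs(pred.scores.to_numpy())
        np.testing.assert_allclose(scores / scores[0], u * np.linalg.norm(v) / (u[0] * np.linalg.norm(v)), rtol=1e-9)

    def test_duplicating_a_column_of_collinear_profiles_preserves_order(self, rng):
        # delta profiles across mu are proportional motif to motif (the
        # near-rank-1 regime real scans live in); duplicating a grid column
        # then leaves the projection order exactly unchanged
        u = np.sort(rng.uniform(0.2, 3.0, size=10))
        v = np.array([1.0, 0.5, 0.1])
        D = np.outer(u, v)
        deltas = np.sign(D) * (np.exp(np.abs(D)) - 1)
        t1 = make_table(deltas, mu_grid=(0.0, -10.0, -20.0))
        dup = np.hstack([deltas, deltas[:, [1]]])
        t2 = make_table(dup, mu_grid=(0.0, -10.0, -20.0, -13.0))
        p1 = pca_integrate(build_integration_matrix(t1))
        p2 = pca_integrate(build_integration_matrix(t2))
        assert p1.positive == p2.positive and p1.negative == p2.negative

    def test_duplicating_a_column_barely_perturbs_generic_rankings(self, rng):
        from scipy.stats import spearmanr

        deltas = rng.normal(0, 1, size=(10, 3))
        t1 = make_table(deltas, mu_grid=(0.0, -10.0, -20.0))
        t2 = make_table(np.hstack([deltas, deltas[:, [1]]]), mu_grid=(0.0, -10.0, -20.0, -13.0))
        s1 = pca_integrate(build_integration_matrix(t1)).scores
        s2 = pca_integrate(build_integration_matrix(t2)).scores
        rho = spearmanr(s1.to_numpy(), s2.reindex(s1.index).to_numpy()).statistic
        assert rho >= 0.9

    def test_projection_matches_svd_oracle(self, rng):
        # |D @ eps| must equal sigma_1 * |u_1| from the SVD
        for _ in range(20):
            D = rng.normal(0, 1, size=(10, 6))
            deltas = np.sign(D) * (np.exp(np.abs(D)) - 1)
            M = build_integration_matrix(make_table(deltas))
            pred = pca_integrate(M)
            u, s, _ = np.linalg.svd(M.D)
            np.testing.assert_allclose(
                np.abs(pred.scores.to_numpy()), s[0] * np.abs(u[:, 0]), atol=1e-9
            )

    def test_sign_recovery_follows_mean_delta(self):
        deltas = np.array([[0.4, 0.6, 0.2], [-0.5, -0.1, -0.9], [0.0, 0.0, 0.0]])
        pred = pca_integrate(build_integration_matrix(make_table(deltas)))
        assert pred.scores["m00"] > 0
        assert pred.scores["m01"] < 0
        assert pred.scores["m02"] == 0
        assert "m02" not in pred.positive + pred.negative

    def test_scale_equivariance_for_collinear_profiles(self, rng):
        # Sig is nonlinear, so global delta rescaling is only exactly
        # order-preserving in the rank-1 regime the method assumes
        u = np.sort(rng.uniform(0.2, 3.0, size=12)) * np.resize([1, -1], 12)
        v = np.array([1.0, 0.6, 0.2, 0.05, 0.01, 0.002])
        deltas = np.outer(u, v)
        p1 = pca_integrate(build_integration_matrix(make_table(deltas)))
        p2 = pca_integrate(build_integration_matrix(make_table(5.0 * deltas)))
        assert p1.positive == p2.positive and p1.negative == p2.negative

    def test_scale_change_barely_perturbs_generic_rankings(self, rng):
        from scipy.stats import spearmanr

        deltas = rng.normal(0, 2, size=(12, 6))
        s1 = pca_integrate(build_integration_matrix(make_table(deltas))).scores
        s2 = pca_integrate(build_integration_matrix(make_table(5.0 * deltas))).scores
        rho = spearmanr(s1.to_numpy(), s2.reindex(s1.index).to_numpy()).statistic
        assert rho >= 0.9

    def test_tf_collapse_takes_best_rank(self):
        deltas = np.array([[2.0], [1.0], [0.5]])
        tf_names = {"m00": "FOXA1", "m01": "foxa1", "m02": "GATA3"}
        table = make_table(deltas, mu_grid=(-13.0,), tf_names=tf_names)
        pred = pca_integrate(build_integration_matrix(table))
        assert pred.tf_positive == ("FOXA1", "GATA3")  # case-insensitive collapse
        assert pred.tf_rank("gata3") == 2


class TestAlternativeIntegrations:
    def test_single_column_all_methods_agree(self, rng):
        deltas = rng.normal(0, 1, size=(8, 1))
        table = make_table(deltas, mu_grid=(-13.0,))
        ref = pca_integrate(build_integration_matrix(table))
        for method in ("median_rank", "median_delta", "single_mu"):
            alt = alternative_integrations(table, method, mu=-13.0)
            assert alt.positive == ref.positive and alt.negative == ref.negative

    def test_median_delta_on_constant_rows(self):
        deltas = np.tile(np.array([[0.2], [-3.0], [1.0]]), (1, 5))
        pred = alternative_integrations(make_table(deltas), "median_delta")
        assert pred.positive == ("m02", "m00")
        assert pred.negative == ("m01",)

    def test_median_rank_magnitudes_invariant_to_column_rescaling(self, rng):
        # the rank-based magnitude ordering ignores per-column scale; only
        # the sign split (mean delta) can react to rescaling
        deltas = rng.normal(0, 1, size=(9, 4))
        scaled = deltas * np.array([1.0, 10.0, 0.3, 7.0])
        p1 = alternative_integrations(make_table(deltas), "median_rank")
        p2 = alternative_integrations(make_table(scaled), "median_rank")

        def magnitude_order(pred):
            s = pred.scores
            return tuple(sorted(s.index, key=lambda mid: (-abs(s[mid]), mid)))

        assert magnitude_order(p1) == magnitude_order(p2)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown integration method"):
            alternative_integrations(make_table(np.ones((2, 2))), "rra")


class TestMutationScore:
    def test_empty_prediction_scores_zero(self):
        table = make_table(np.ones((2, 3)), direct=np.zeros((2, 3), bool))
        pred = pca_integrate(build_integration_matrix(table))
        assert mutation_score(pred, table) == 0.0

    def test_k_larger_than_motif_count_uses_all(self, rng):
        deltas = rng.normal(0, 1, size=(4, 3))
        table = make_table(deltas)
        pred = pca_integrate(build_integration_matrix(table))
        expected = table.mean_abs_delta().loc[list(pred.positive) + list(pred.negative)].mean()
        assert mutation_score(pred, table, k=100) == pytest.approx(expected)

    def test_k_must_be_positive(self):
        table = make_table(np.ones((2, 2)))
        pred = pca_integrate(build_integration_matrix(table))
        with pytest.raises(ValueError):
            mutation_score(pred, table, k=0)


class TestCumulativeAccuracy:
    def _pred(self, deltas, tf_names=None):
        table = make_table(deltas, mu_grid=(-13.0,), tf_names=tf_names)
        return pca_integrate(build_integration_matrix(table))

    def test_perfect_predictions(self):
        pred = self._pred(np.array([[3.0], [1.0]]))
        curve = cumulative_accuracy([(pred, "M00"), (pred, "M00")])
        assert (curve == 1.0).all()

    def test_absent_tf_never_recovered(self):
        pred = self._pred(np.array([[3.0], [1.0]]))
        curve = cumulative_accuracy([(pred, "NOPE")], max_rank=3)
        assert (curve == 0.0).all()

    def test_hand_counted_curve(self):
        p1 = self._pred(np.array([[3.0], [2.0], [1.0]]))  # M00 rank 1
        p2 = self._pred(np.array([[1.0], [2.0], [3.0]]))  # M00 rank 3
        curve = cumulative_accuracy([(p1, "M00"), (p2, "M00")], max_rank=3)
        np.testing.assert_allclose(curve, [0.5, 0.5, 1.0])

    def test_direction_restricts_the_list(self):
        pred = self._pred(np.array([[3.0], [-2.0]]))
        assert cumulative_accuracy([(pred, "M01", "negative")], max_rank=1)[0] == 1.0
        assert cumulative_accuracy([(pred, "M01", "positive")], max_rank=1)[0] == 0.0

    def test_curve_monotone_non_decreasing(self, rng):
        preds = [self._pred(rng.normal(0, 1, size=(6, 1))) for _ in range(5)]
        cases = [(p, "M03") for p in preds]
        curve = cumulative_accuracy(cases, max_rank=6)
        assert (np.diff(curve) >= 0).all() and curve.max() <= 1.0
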