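"""SOM clustering, class contrast, relative expression, ranking."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from topconnmf import (
    SomLayer,
    associate_groups_with_classes,
    bmu,
    class_contrast,
    build_group_matrices,
    hierarchical_cluster,
    rank_biomarkers,
    relative_expression,
    som_step,
)
from topconnmf.errors import (
    DegenerateClassError,
    TooFewFeaturesError,
    ValidationError,
)


def _blobs(rng, n_per=12, k=3, sep=20.0):
    """Four well-separated column blobs in k dims; returns H (k x s), labels."""
    centers = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)[:, :k]
    cols, labels = [], []
    for c, center in enumerate(centers):
        cols.append(sep * center[None, :] + rng.random((n_per, k)))
        labels.extend([c] * n_per)
    H = np.vstack(cols).T
    return H, np.asarray(labels)


class TestBmuAndStep:
    def _layer(self, weights):
        return SomLayer(weights=np.asarray(weights, float), grid_shape=(1, len(weights)))

    def test_bmu_nearest_and_tie_rule(self):
        layer = self._layer([[0.0, 0.0], [1.0, 1.0]])
        assert bmu(np.array([0.1, 0.0]), layer) == 0
        assert bmu(np.array([1.0, 1.0]), layer) == 1
        assert bmu(np.array([0.5, 0.5]), layer) == 0  # equidistant -> lowest index

    def test_full_pull_moves_bmu_to_input(self):
        layer = self._layer([[0.0, 0.0], [5.0, 5.0]])
        h = np.array([0.4, 0.2])
        som_step(h, layer, t=0, eta=1.0, sigma=1e-9)
        np.testing.assert_allclose(layer.weights[0], h)

    def test_zero_rate_is_identity(self):
        layer = self._layer([[0.0, 1.0], [2.0, 3.0]])
        before = layer.weights.copy()
        som_step(np.array([9.0, 9.0]), layer, t=0, eta=0.0)
        np.testing.assert_allclose(layer.weights, before)

    def test_half_pull_hand_arithmetic(self):
        layer = self._layer([[0.0, 0.0], [100.0, 100.0]])
        som_step(np.array([2.0, 2.0]), layer, t=0, eta=0.5, sigma=1e9)
        # sigma huge -> N=1 everywhere: every prototype moves halfway
        np.testing.assert_allclose(layer.weights[0], [1.0, 1.0])

    def test_finite_weights_for_finite_input(self, rng):
        layer = self._layer(rng.standard_normal((4, 3)))
        for t in range(20):
            som_step(rng.standard_normal(3), layer, t)
        assert np.all(np.isfinite(layer.weights))


class TestHierarchicalCluster:
    def test_recovers_separated_blobs(self, rng):
        H, labels = _blobs(rng)
        hier = hierarchical_cluster(H, seed=0)
        assert adjusted_rand_score(labels, hier.assignments) == 1.0
        assert set(hier.assignments) <= {1, 2, 3, 4}

    def test_duplicate_columns_same_group(self, rng):
        H, _ = _blobs(rng)
        H[:, 5] = H[:, 3]
        hier = hierarchical_cluster(H, seed=1)
        assert hier.assignments[5] == hier.assignments[3]

    def test_deterministic_given_seeds(self, rng):
        H, _ = _blobs(rng)
        a = hierarchical_cluster(H, seed=3)
        b = hierarchical_cluster(H, seed=3)
        assert np.array_equal(a.assignments, b.assignments)

    def test_permutation_equivariant(self, rng):
        H, _ = _blobs(rng)
        perm = rng.permutation(H.shape[1])
        a = hierarchical_cluster(H, seed=4).assignments
        b = hierarchical_cluster(H[:, perm], seed=4).assignments
        assert np.array_equal(a[perm], b)

    def test_too_few_features_rejected(self, rng):
        with pytest.raises(TooFewFeaturesError):
            hierarchical_cluster(rng.random((3, 3)), seed=0)


class TestClassContrast:
    def test_symmetric_masses_give_zero(self):
        H = np.ones((3, 4))  # all columns carry identical mass
        c = class_contrast(H, np.array(["control", "diseased", "control", "diseased"]))
        assert c.C_mu == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # mu_B=6, mu_D=2, n_B=n_D=2 -> C_mu = 1
        H = np.array([[3.0, 3.0, 1.0, 1.0]])
        H = np.vstack([H, np.zeros_like(H)])  # k=2, masses 3,3,1,1
        c = class_contrast(H, np.array(["control", "control", "diseased", "diseased"]))
        assert (c.mu_B, c.mu_D, c.n_B, c.n_D) == (6.0, 2.0, 2, 2)
        assert c.C_mu == pytest.approx(1.0)

    def test_c_sigma_matches_formula_loop(self, rng):
        H = rng.random((3, 4))
        labels = np.array(["control", "control", "diseased", "diseased"])
        c = class_contrast(H, labels)
        masses = np.abs(H).sum(axis=0)
        muB, muD = masses[:2].sum(), masses[2:].sum()
        oracle = (
            sum((masses[j] - muB) ** 2 for j in (0, 1))
            - sum((masses[j] - muD) ** 2 for j in (2, 3))
        ) / 4
        assert c.C_sigma == pytest.approx(oracle, rel=1e-12)

    def test_explicit_index_sets(self, rng):
        H = rng.random((2, 6))
        c = class_contrast(H, control_cols=[0, 1, 2], diseased_cols=[3, 4, 5])
        assert c.n_B == 3 and c.n_D == 3

    def test_empty_class_rejected(self, rng):
        with pytest.raises(DegenerateClassError):
            class_contrast(rng.random((2, 3)), np.array(["control"] * 3))

    def test_sign_recovers_planted_direction(self):
        """Columns with planted heavier control mass give C_mu > 0."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            H = rng.random((4, 20))
            H[:, :10] *= 1.5  # control-associated columns carry more mass
            c = class_contrast(H, np.array(["control"] * 10 + ["diseased"] * 10))
            hits += c.C_mu > 0
        assert hits >= 95


class TestRelativeExpression:
    def test_identical_matrices_give_ones(self, rng):
        M = rng.random((3, 4)) + 0.5
        rel = relative_expression(M, M, M, M)
        np.testing.assert_allclose(rel.Xr, 1.0)

    def test_zero_gamma_zeroes_everything(self, rng):
        M = rng.random((3, 4)) + 0.5
        rel = relative_expression(M, M, M, M, gammas=(0.0, 1.0, 1.0))
        np.testing.assert_allclose(rel.Xr, 0.0)

    def test_hand_arithmetic(self):
        B = np.full((2, 2), 3.0)
        rel = relative_expression(2 * B, B, B, B)
        np.testing.assert_allclose(rel.Xr, 2.0)

    def test_negative_entries_rejected(self):
        M = np.ones((2, 2))
        with pytest.raises(ValidationError):
            relative_expression(-M, M, M, M)


class TestRanking:
    def test_full_fraction_returns_all_ordered(self, rng):
        Xr = rng.random((4, 7)) + 0.5
        table = rank_biomarkers(Xr, [f"f{j}" for j in range(7)], top_fraction=1.0)
        assert len(table) == 7
        assert np.all(np.diff(table["score"].to_numpy()) <= 0)

    def test_single_deviating_feature_ranks_first(self):
        Xr = np.ones((5, 6))
        Xr[:, 2] = 10.0
        table = rank_biomarkers(Xr, [f"f{j}" for j in range(6)], top_fraction=0.5)
        assert table["feature_id"].iloc[0] == "f2"

    def test_ceiling_arithmetic(self, rng):
        Xr = rng.random((2, 200)) + 0.5
        table = rank_biomarkers(Xr, [f"f{j}" for j in range(200)], top_fraction=0.03)
        assert len(table) == 6

    def test_group_association_uses_expression_contrast(self, small_expression):
        X = small_expression
        X.values[X.class_mask("diseased"), :6] *= 3.0  # first half up in disease
        assignments = np.array([1] * 6 + [2] * 6)
        classes = associate_groups_with_classes(X, assignments)
        assert set(classes[:6]) == {"diseased"} and set(classes[6:]) == {"control"}

    def test_group_matrices_shapes_and_baseline(self, small_expression):
        Dm, Bm, Pm, Pcm = build_group_matrices(small_expression)
        for M in (Dm, Bm, Pm, Pcm):
            assert M.shape == small_expression.values.shape
            assert np.all(M >= 0)
        # baseline is constant across samples
        assert np.allclose(Bm, Bm[0][None, :])
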