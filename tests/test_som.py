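"""Kohonen map training, BMU lookup, hit maps and neuron probabilities."""

import numpy as np
import pytest

from dcepnms import KohonenSOM, hit_maps, neuron_probabilities, normalize_profiles
from dcepnms.som import HitMaps, hex_positions


@pytest.fixture(scope="module")
def three_cluster_data():
    """Three well-separated clusters with small within-cluster spread (exact
    duplicates would make prototype weights collide and BMU ties degenerate)."""

    rng = np.random.default_rng(42)
    protos = rng.standard_normal((3, 40)) * 2.0
    X = np.repeat(protos, 60, axis=0) + rng.normal(0, 0.05, (180, 40))
    labels = np.repeat([1, 2, 3], 60)
    return X, labels, protos


@pytest.fixture(scope="module")
def trained(three_cluster_data):
    X, _, _ = three_cluster_data
    return KohonenSOM(rows=4, cols=4, max_epochs=120, cover_steps=40, random_state=0).fit(X)


class TestNormalization:
    def test_scale_invariance(self, rng):
        C = rng.random((5, 60))
        a = normalize_profiles(C, 10)
        b = normalize_profiles(2.0 * C, 10)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_zero_profile_maps_to_zero(self):
        out = normalize_profiles(np.zeros((1, 60)), 10)
        assert np.all(out == 0)

    def test_peak_is_one(self, rng):
        C = rng.random((20, 60)) + 0.1
        feats = normalize_profiles(C, 10)
        np.testing.assert_allclose(np.max(np.abs(feats), axis=1), 1.0)


class TestLattice:
    def test_hexagonal_nearest_neighbor_distance_is_one(self):
        pos = hex_positions(8, 8)
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(1.0)

    def test_positions_count(self):
        assert hex_positions(8, 8).shape == (64, 2)


class TestTraining:
    def test_determinism_same_seed(self, three_cluster_data):
        X, _, _ = three_cluster_data
        a = KohonenSOM(rows=4, cols=4, max_epochs=60, cover_steps=20, random_state=5).fit(X)
        b = KohonenSOM(rows=4, cols=4, max_epochs=60, cover_steps=20, random_state=5).fit(X)
        np.testing.assert_array_equal(a.weights_, b.weights_)

    def test_cluster_prototypes_captured(self, three_cluster_data):
        """Noiseless repeated prototypes are reproduced exactly by some neuron."""

        _, _, protos = three_cluster_data
        X = np.repeat(protos, 40, axis=0)
        som = KohonenSOM(rows=4, cols=4, max_epochs=120, cover_steps=40, random_state=1).fit(X)
        d = np.linalg.norm(som.weights_[:, None, :] - protos[None, :, :], axis=-1)
        assert np.all(d.min(axis=0) < 1e-6)

    def test_quantization_error_does_not_worsen_in_tuning(self, rng):
        """The tuning phase never drives the mean BMU distance above its
        starting value, and any oscillation stays small.  (With a smoothing
        neighborhood the batch update minimizes the smoothed distortion, so
        the raw quantization error may cycle within a narrow band rather
        than decrease strictly.)"""

        X = np.repeat(rng.standard_normal((3, 40)) * 2.0, 60, axis=0)
        X = X + rng.normal(0, 0.3, X.shape)
        som = KohonenSOM(rows=4, cols=4, max_epochs=100, cover_steps=30, tol=0.0, random_state=1).fit(X)
        tuning = som.quantization_errors_[30:]
        assert tuning[-1] <= tuning[0] + 1e-12
        assert np.max(tuning) <= 1.01 * tuning[0]
        assert np.max(np.diff(tuning)) <= 0.02 * tuning[0]

    def test_warns_with_fewer_inputs_than_neurons(self, rng):
        with pytest.warns(UserWarning, match="fewer training vectors"):
            KohonenSOM(rows=4, cols=4, max_epochs=5, random_state=0).fit(rng.random((6, 10)))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            KohonenSOM().fit(np.empty((0, 10)))

    def test_topology_preservation(self, trained, three_cluster_data):
        """Input-space neighbors map closer on the lattice than random pairs."""

        X, _, _ = three_cluster_data
        rng = np.random.default_rng(0)
        X = X + rng.normal(0, 0.05, X.shape)  # break exact duplicates
        bmu = trained.predict(X)
        pos = trained.positions_
        d_in = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        np.fill_diagonal(d_in, np.inf)
        nn = np.argmin(d_in, axis=1)
        d_nn = np.linalg.norm(pos[bmu] - pos[bmu[nn]], axis=-1).mean()
        rand = rng.integers(0, X.shape[0], X.shape[0])
        d_rand = np.linalg.norm(pos[bmu] - pos[bmu[rand]], axis=-1).mean()
        assert d_nn < 0.5 * d_rand


class TestBMU:
    def test_weight_vector_maps_to_its_neuron(self, trained):
        j = 7
        row, col = trained.bmu(trained.weights_[j])
        assert row * trained.cols + col == j

    def test_stable_under_tiny_perturbation(self, trained):
        j = 10
        w = trained.weights_[j] + 1e-9
        assert trained.predict(w[None, :])[0] == j

    def test_brute_force_oracle(self, trained, rng):
        X = rng.standard_normal((100, trained.weights_.shape[1]))
        brute = np.array(
            [int(np.argmin([np.linalg.norm(x - w) for w in trained.weights_])) for x in X]
        )
        np.testing.assert_array_equal(trained.predict(X), brute)

    def test_length_mismatch_rejected(self, trained):
        with pytest.raises(ValueError):
            trained.predict(np.zeros((1, 3)))


class TestHitMapsAndProbabilities:
    def test_single_feature_hit(self, trained):
        f = trained.weights_[5][None, :]
        hm = hit_maps(trained, f, np.array([2]))
        assert hm.total == 1
        assert hm.counts[1].ravel()[5] == 1
        assert hm.counts.sum() - hm.counts[1].ravel()[5] == 0

    def test_counts_conserved_and_order_invariant(self, trained, three_cluster_data, rng):
        X, labels, _ = three_cluster_data
        hm = hit_maps(trained, X, labels)
        assert hm.total == X.shape[0]
        perm = rng.permutation(X.shape[0])
        hm2 = hit_maps(trained, X[perm], labels[perm])
        np.testing.assert_array_equal(hm.counts, hm2.counts)

    def test_invalid_label_rejected(self, trained):
        with pytest.raises(ValueError):
            hit_maps(trained, trained.weights_[:2], np.array([0, 4]))

    def test_probability_ratios(self):
        counts = np.zeros((3, 2, 2), dtype=int)
        counts[:, 0, 0] = [2, 1, 1]
        counts[:, 0, 1] = [5, 0, 0]
        counts[:, 1, 0] = [0, 3, 1]
        counts[:, 1, 1] = [1, 1, 1]
        probs = neuron_probabilities(HitMaps(counts))
        np.testing.assert_allclose(probs.P[:, 0, 0], [0.5, 0.25, 0.25])
        np.testing.assert_allclose(probs.P[:, 0, 1], [1, 0, 0])
        np.testing.assert_allclose(probs.P.sum(axis=0), 1.0)
        assert not probs.empty_mask.any()

    def test_empty_neuron_filled_from_nearest(self):
        counts = np.zeros((3, 2, 2), dtype=int)
        counts[:, 0, 0] = [4, 0, 0]  # the only non-empty neuron
        counts[:, 1, 1] = [0, 0, 0]
        counts[:, 0, 1] = [0, 2, 2]
        counts[:, 1, 0] = [0, 0, 4]
        probs = neuron_probabilities(HitMaps(counts))
        assert probs.empty_mask[1, 1]
        np.testing.assert_allclose(probs.P.sum(axis=0), 1.0)

    def test_uniform_fill_option(self):
        counts = np.zeros((3, 2, 2), dtype=int)
        counts[:, 0, 0] = [1, 1, 2]
        probs = neuron_probabilities(HitMaps(counts), empty_fill="uniform")
        np.testing.assert_allclose(probs.P[:, 1, 1], 1 / 3)

    def test_literal_scaling_prefactor(self):
        counts = np.ones((3, 8, 8), dtype=int)
        probs = neuron_probabilities(HitMaps(counts), scaling="literal")
        np.testing.assert_allclose(probs.P.sum(axis=0), 1.0 / 1296.0)

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            neuron_probabilities(HitMaps(np.zeros((3, 2, 2), dtype=int)))
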