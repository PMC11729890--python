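"""Probability-weighted model averaging and the PNMS volume pipeline."""

import numpy as np
import pytest

from dcepnms import (
    ConcentrationProfile,
    PNMSModel,
    averaged_ktrans,
    averaged_ve,
    averaged_vp,
    run_pnms_volume,
    voxel_probabilities,
)
from dcepnms.benchmarks import averaging_identities
from dcepnms.phantom import PhantomSpec, generate_phantom, generate_profile_set, paper_like_counts
from dcepnms.som import normalize_profiles
from dcepnms.validation import label_profiles


@pytest.fixture(scope="module")
def fitted_model():
    n1, n2, n3 = paper_like_counts(1200)
    ps = generate_profile_set(n1, n2, n3, noise_sigma=0.02, seed=11)
    labels, _ = label_profiles(ps.profiles, ps.aif)
    feats = normalize_profiles(ps.profiles, ps.grid.n_baseline)
    model = PNMSModel(max_epochs=120, random_state=11).fit(feats, labels)
    return ps, feats, model


class TestVoxelProbabilities:
    def test_matches_bmu_indexed_entry(self, fitted_model):
        """Cross-module oracle: the voxel triple equals the BMU's table row."""

        ps, feats, model = fitted_model
        P = model.neuron_probabilities_.P.reshape(3, -1)
        rng = np.random.default_rng(0)
        idx = rng.choice(ps.profiles.shape[0], 100, replace=False)
        for i in idx:
            profile = ConcentrationProfile(ps.grid, ps.profiles[i])
            triple = voxel_probabilities(model.som_, model.neuron_probabilities_, profile)
            j = model.som_.predict(feats[i][None, :])[0]
            np.testing.assert_array_equal(triple, P[:, j])

    def test_probabilities_sum_to_one(self, fitted_model):
        _, feats, model = fitted_model
        P = model.predict_proba(feats[:500])
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestAveraging:
    def test_vp_degenerate_and_uniform_weights(self):
        assert averaged_vp(np.array([1.0, 0, 0]), 0.01, 0.05, 0.09) == pytest.approx(0.01)
        assert averaged_vp(np.array([1 / 3, 1 / 3, 1 / 3]), 0.01, 0.02, 0.03) == pytest.approx(0.02)

    def test_vp_zero_weights_undefined(self):
        assert np.isnan(averaged_vp(np.zeros(3), 0.01, 0.02, 0.03))

    def test_ktrans_renormalization(self):
        assert averaged_ktrans(np.array([0.0, 1.0, 0.0]), 0.1, 0.3) == pytest.approx(0.1)
        assert averaged_ktrans(np.array([0.5, 0.25, 0.25]), 0.2, 0.2) == pytest.approx(0.2)
        # weights (0, 0.6, 0.2) renormalize to (0.75, 0.25)
        expected = 0.75 * 0.11 + 0.25 * 0.29
        assert averaged_ktrans(np.array([0.0, 0.6, 0.2]), 0.11, 0.29) == pytest.approx(expected)

    def test_ktrans_nonleaky_is_zero(self):
        assert averaged_ktrans(np.array([1.0, 0.0, 0.0]), 0.1, 0.3) == 0.0

    def test_ve_ratio_and_sentinels(self):
        assert averaged_ve(0.2, 2.0) == pytest.approx(0.1)
        assert averaged_ve(0.0, 2.0) == 0.0
        assert np.isnan(averaged_ve(0.2, 0.0))

    def test_convexity(self, rng):
        """Averaged values never leave the hull of their components."""

        P = rng.dirichlet(np.ones(3), size=200)
        vals = rng.random((200, 3)) * 0.1
        out = averaged_vp(P, vals[:, 0], vals[:, 1], vals[:, 2])
        assert np.all(out >= vals.min(axis=1) - 1e-12)
        assert np.all(out <= vals.max(axis=1) + 1e-12)

    def test_onehot_reduction_and_rescale_invariance(self):
        r = averaging_identities(seed=3, n=600)
        assert r["onehot_max_abs_diff"] == 0.0
        assert r["rescale_max_rel_diff"] < 1e-12


@pytest.fixture(scope="module")
def volume_run():
    ph = generate_phantom(PhantomSpec(shape=(20, 20, 1), noise_sigma=0.02, seed=21))
    X = ph.volume.reshape(-1, ph.grid.n_t)[ph.mask.ravel()]
    labels, _ = label_profiles(X, ph.aif)
    feats = normalize_profiles(X, ph.grid.n_baseline)
    model = PNMSModel(max_epochs=120, random_state=21).fit(feats, labels)
    res = run_pnms_volume(ph.volume, ph.mask, ph.aif, model)
    return ph, res


class TestVolumePipeline:
    def test_probability_maps_partition_inside_mask(self, volume_run):
        ph, res = volume_run
        total = res.P1 + res.P2 + res.P3
        np.testing.assert_allclose(total[ph.mask], 1.0, atol=1e-12)
        assert np.all(total[~ph.mask] == 0)

    def test_masks_respect_model1_maskout(self, volume_run):
        _, res = volume_run
        assert not np.any(res.masks[2] & res.masks[1])
        assert not np.any(res.masks[3] & res.masks[1])

    def test_rgb_channel_coding(self, volume_run):
        """Fused map codes (R, G, B) = (P3, P2, P1)."""

        ph, res = volume_run
        pure1 = res.P1 > 0.99
        assert pure1.any()
        assert np.all(res.rgb[..., 2][pure1] == 255)
        assert np.all(res.rgb[..., 0][pure1] == 0)

    def test_averaged_maps_within_component_hull(self, volume_run):
        ph, res = volume_run
        from dcepnms.kinetics import fit_models_matrix

        X = ph.volume.reshape(-1, ph.grid.n_t)[ph.mask.ravel()]
        fits = fit_models_matrix(X, ph.aif)
        lo = np.minimum.reduce([fits["vp1"], fits["vp2"], fits["vp3"]])
        hi = np.maximum.reduce([fits["vp1"], fits["vp2"], fits["vp3"]])
        vp = res.vp[ph.mask]
        assert np.all(vp >= lo - 1e-12) and np.all(vp <= hi + 1e-12)

    def test_flags_present_and_boolean(self, volume_run):
        _, res = volume_run
        for key in ("empty_bmu", "nonleaky", "kep_nonpositive", "low_p3_ve"):
            assert res.flags[key].dtype == bool

    def test_mask_mismatch_rejected(self, volume_run, aif):
        ph, _ = volume_run
        model = PNMSModel()
        with pytest.raises(ValueError):
            run_pnms_volume(ph.volume, np.ones((3, 3, 1), bool), ph.aif, model)
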