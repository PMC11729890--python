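"""Forward-model correctness and least-squares fitting of the nested models."""

import numpy as np
import pytest

from dcepnms import (
    AIF,
    ConcentrationProfile,
    SingularFitError,
    TimeGrid,
    fit_model,
    model1_forward,
    model2_forward,
    model3_forward,
)
from dcepnms.kinetics import _exp_conv_many, exp_conv, fit_models_matrix


class TestForwardModels:
    def test_model1_zero_and_identity(self, aif):
        assert np.all(model1_forward(0.0, aif).c == 0)
        np.testing.assert_array_equal(model1_forward(1.0, aif).c, aif.c)

    def test_nested_reductions(self, aif):
        """Each model reduces to its parent when the extra parameter is 0."""

        np.testing.assert_allclose(
            model2_forward(0.02, 0.0, aif).c, model1_forward(0.02, aif).c, atol=1e-15
        )
        np.testing.assert_allclose(
            model3_forward(0.02, 0.1, 0.0, aif).c, model2_forward(0.02, 0.1, aif).c, atol=1e-15
        )

    def test_patlak_constant_aif_closed_form(self):
        """For a constant AIF c0 the leakage integral is exactly kt*c0*T."""

        grid = TimeGrid(np.linspace(0, 5, 101), n_baseline=0)
        aif = AIF(grid, np.full(101, 0.7))
        out = model2_forward(0.0, 0.12, aif).c
        np.testing.assert_allclose(out, 0.12 * 0.7 * grid.t, rtol=1e-12)

    def test_patlak_monotone_for_nonnegative_aif(self, aif):
        out = model2_forward(0.0, 0.2, aif).c
        assert np.all(np.diff(out) >= -1e-15)

    def test_model3_impulse_tail_decays_at_kep(self, grid):
        """After an impulse-like AIF the leakage term decays as exp(-kep t)."""

        c = np.zeros(grid.n_t)
        c[30] = 1.0
        conv = exp_conv(c, grid.t, 2.0)
        seg = slice(35, 120)
        slope = np.polyfit(grid.t[seg], np.log(conv[seg]), 1)[0]
        assert slope == pytest.approx(-2.0, rel=1e-6)

    def test_linearity_by_superposition(self, aif, rng):
        """Models 1 and 2 are linear in (vp, ktrans)."""

        v1, k1, v2, k2 = rng.uniform(0.01, 0.3, 4)
        lhs = model2_forward(v1 + v2, k1 + k2, aif).c
        rhs = model2_forward(v1, k1, aif).c + model2_forward(v2, k2, aif).c
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    @pytest.mark.parametrize("kep", [0.05, 0.7, 6.0])
    def test_exp_conv_many_matches_scalar(self, grid, kep, rng):
        c = rng.random(grid.n_t)
        many = _exp_conv_many(c, grid.t, np.array([kep]))[0]
        np.testing.assert_allclose(many, exp_conv(c, grid.t, kep), rtol=1e-10, atol=1e-14)

    def test_exp_conv_nonuniform_grid(self):
        """The non-uniform-grid path agrees with the uniform fast path."""

        t = np.linspace(0, 4, 81)
        c = np.exp(-((t - 1.0) ** 2) / 0.1)
        ref = exp_conv(c, t, 1.5)
        t2 = t.copy()
        t2[40] += 1e-13  # break exact uniformity, same geometry
        out = exp_conv(c, t2, 1.5)
        np.testing.assert_allclose(out, ref, rtol=1e-6)


class TestFitting:
    def test_noiseless_model2_recovery(self, aif):
        profile = model2_forward(0.02, 0.1, aif)
        fit = fit_model(profile, aif, 2)
        assert fit.params.vp == pytest.approx(0.02, rel=1e-6)
        assert fit.params.ktrans == pytest.approx(0.1, rel=1e-6)
        assert fit.ssr <= 1e-12
        assert fit.n_fit == aif.grid.n_fit

    def test_noiseless_model3_recovery(self, aif):
        profile = model3_forward(0.02, 0.1, 0.5, aif)
        fit = fit_model(profile, aif, 3)
        assert fit.params.kep == pytest.approx(0.5, rel=1e-3)
        assert fit.params.vp == pytest.approx(0.02, rel=1e-3)
        assert fit.params.ve == pytest.approx(0.2, rel=1e-3)

    def test_ssr_nesting_monotone(self, aif, rng):
        """SSR1 >= SSR2 >= SSR3 for arbitrary noisy profiles."""

        base = model3_forward(0.02, 0.15, 1.0, aif).c
        C = base + rng.normal(0, 0.02, size=(50, base.size))
        f = fit_models_matrix(C, aif)
        assert np.all(f["ssr2"] <= f["ssr1"] * (1 + 1e-9) + 1e-300)
        assert np.all(f["ssr3"] <= f["ssr2"] * (1 + 1e-9) + 1e-300)

    def test_zero_aif_is_singular(self, grid):
        dead = AIF(grid, np.zeros(grid.n_t))
        profile = ConcentrationProfile(grid, np.ones(grid.n_t))
        with pytest.raises(SingularFitError):
            fit_model(profile, dead, 1)

    def test_grid_mismatch_rejected(self, aif):
        other = TimeGrid(np.arange(50) * 0.03, n_baseline=5)
        profile = ConcentrationProfile(other, np.zeros(50))
        with pytest.raises(ValueError):
            fit_model(profile, aif, 1)


class TestTypes:
    def test_timegrid_validation(self):
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            TimeGrid(np.arange(10.0), n_baseline=10)

    def test_pkparams_ve_and_flags(self):
        from dcepnms import PKParams

        p = PKParams(vp=0.02, ktrans=0.2, kep=2.0)
        assert p.ve == pytest.approx(0.1)
        assert p.flags == []
        bad = PKParams(vp=1.4, ktrans=-0.1)
        assert "vp_out_of_range" in bad.flags
        assert "ktrans_negative" in bad.flags
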