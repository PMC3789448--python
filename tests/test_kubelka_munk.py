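"""Two-flux layer solution, two-layer stacking and the skin forward model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from skinmaps import (
    LayerRT,
    SkinParams,
    flux_variables,
    forward_spectrum,
    layer_rt,
    stack_two,
)
from skinmaps.chromophores import (
    ScatteringModel,
    dermis_absorption,
    epidermis_absorption,
)


class TestFluxVariables:
    def test_pure_absorber(self):
        fv = flux_variables(3.0, 0.0)
        assert fv.beta == pytest.approx(1.0)
        assert fv.K == pytest.approx(fv.k) == pytest.approx(6.0)

    def test_pure_scatterer(self):
        fv = flux_variables(0.0, 5.0)
        assert fv.beta == 0.0
        assert fv.K == 0.0

    def test_hand_evaluated_example(self):
        fv = flux_variables(1.0, 1.0)
        assert fv.K == pytest.approx(math.sqrt(12.0), rel=1e-12)
        assert fv.beta == pytest.approx(math.sqrt(1.0 / 3.0), rel=1e-12)

    def test_rejects_vacuum(self):
        with pytest.raises(ValueError):
            flux_variables(0.0, 0.0)

    @given(
        mu_a=st.floats(1e-6, 1e3),
        mu_s=st.floats(0.0, 1e3),
    )
    def test_beta_bounded(self, mu_a, mu_s):
        fv = flux_variables(mu_a, mu_s)
        assert 0.0 <= fv.beta <= 1.0


class TestLayerRT:
    def test_zero_thickness_is_no_medium(self):
        rt = layer_rt(2.0, 30.0, 0.0)
        assert rt.R == 0.0 and rt.T == 1.0

    def test_pure_absorber_is_beer_lambert(self):
        mu_a, d = 4.0, 0.05
        rt = layer_rt(mu_a, 0.0, d)
        assert rt.R == pytest.approx(0.0, abs=1e-15)
        assert rt.T == pytest.approx(math.exp(-2.0 * mu_a * d), rel=1e-12)

    def test_semi_infinite_limit(self):
        mu_a, mu_s = 1.0, 20.0
        fv = flux_variables(mu_a, mu_s)
        rt = layer_rt(mu_a, mu_s, 1e4)
        assert rt.T == pytest.approx(0.0, abs=1e-300)
        assert rt.R == pytest.approx((1 - fv.beta) / (1 + fv.beta), rel=1e-12)

    def test_overflow_guarded_for_huge_optical_depth(self):
        rt = layer_rt(1e4, 1e4, 1e4)
        assert np.isfinite(rt.R) and np.isfinite(rt.T)

    def test_rejects_negative_thickness(self):
        with pytest.raises(ValueError):
            layer_rt(1.0, 1.0, -0.1)

    @given(
        mu_a=st.floats(1e-4, 500.0),
        mu_s=st.floats(0.0, 500.0),
        d=st.floats(1e-4, 2.0),
    )
    def test_energy_conservation(self, mu_a, mu_s, d):
        rt = layer_rt(mu_a, mu_s, d)
        assert rt.R >= 0.0 and rt.T >= 0.0
        assert rt.R + rt.T <= 1.0 + 1e-12


class TestStackTwo:
    def test_transparent_second_layer(self):
        l1 = LayerRT(R=np.float64(0.3), T=np.float64(0.5))
        vac = LayerRT(R=np.float64(0.0), T=np.float64(1.0))
        st_ = stack_two(l1, vac)
        assert st_.R_total == pytest.approx(0.3)
        assert st_.T_total == pytest.approx(0.5)

    def test_transparent_first_layer(self):
        l2 = LayerRT(R=np.float64(0.4), T=np.float64(0.2))
        vac = LayerRT(R=np.float64(0.0), T=np.float64(1.0))
        st_ = stack_two(vac, l2)
        assert st_.R_total == pytest.approx(0.4)
        assert st_.T_total == pytest.approx(0.2)

    def test_rejects_total_internal_reflection(self):
        with pytest.raises(ValueError):
            stack_two(LayerRT(R=np.float64(1.0), T=np.float64(0.0)), LayerRT(R=np.float64(1.0), T=np.float64(0.0)))

    @given(
        r1=st.floats(0.0, 0.95),
        t1=st.floats(0.0, 0.95),
        r2=st.floats(0.0, 0.95),
        t2=st.floats(0.0, 0.95),
    )
    def test_matches_interreflection_series(self, r1, t1, r2, t2):
        # brute-force geometric series R1 + T1^2 R2 sum (R1 R2)^n
        st_ = stack_two(LayerRT(R=np.float64(r1), T=np.float64(t1)), LayerRT(R=np.float64(r2), T=np.float64(t2)))
        acc_r, acc_t, prod = 0.0, 0.0, 1.0
        for _ in range(2000):
            acc_r += prod
            prod *= r1 * r2
            if prod < 1e-18:
                break
        series_r = r1 + t1**2 * r2 * acc_r
        series_t = t1 * t2 * acc_r
        assert st_.R_total == pytest.approx(series_r, abs=1e-12)
        assert st_.T_total == pytest.approx(series_t, abs=1e-12)


def _oracle_forward(p: SkinParams, grid, table, scattering: ScatteringModel):
    """Straight-line scalar reimplementation of the layer/stack equations."""
    out = []
    for lam in grid.wavelengths:
        mua1 = float(epidermis_absorption(lam, p.f_mel))
        mua2 = float(dermis_absorption(lam, p.f_blood, p.c_oxy, table))
        values = []
        for mua, mus, d_mm in (
            (mua1, float(scattering.epidermis(lam)), p.d_epi),
            (mua2, float(scattering.dermis(lam)), p.d_dermis),
        ):
            k, s = 2.0 * mua, 2.0 * mus
            K = math.sqrt(k * (k + 2.0 * s))
            beta = math.sqrt(k / (k + 2.0 * s))
            d = d_mm / 10.0
            ekd, emkd = math.exp(K * d), math.exp(-K * d)
            denom = (1 + beta) ** 2 * ekd - (1 - beta) ** 2 * emkd
            values.append(((1 - beta**2) * (ekd - emkd) / denom, 4 * beta / denom))
        (R1, T1), (R2, T2) = values
        out.append(R1 + T1**2 * R2 / (1 - R1 * R2))
    return np.array(out)


class TestForwardSpectrum:
    def test_matches_independent_oracle(self, grid, table):
        scattering = ScatteringModel()
        for p in (
            SkinParams(0.10, 0.05, 0.02, 0.70, 1.0),
            SkinParams(0.30, 0.08, 0.015, 0.60, 2.0),
            SkinParams(0.013, 0.01, 0.07, 0.90, 0.6),
        ):
            spec = forward_spectrum(p, grid=grid, table=table, scattering=scattering)
            np.testing.assert_allclose(
                spec.values, _oracle_forward(p, grid, table, scattering), atol=1e-12
            )

    def test_melanin_darkens_skin(self, ctx):
        i550 = int(np.where(ctx.grid.wavelengths == 550.0)[0][0])
        base = SkinParams(0.05, 0.05, 0.02, 0.7, 1.0)
        values = []
        for f_mel in (0.05, 0.15, 0.30, 0.44):
            p = SkinParams(f_mel, base.d_epi, base.f_blood, base.c_oxy, base.d_dermis)
            values.append(forward_spectrum(p, grid=ctx.grid).values[i550])
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_w_shape_at_high_blood_oxygenation(self, ctx):
        # thin, lightly pigmented epidermis over an oxygenated, blood-rich dermis
        p = SkinParams(0.013, 0.01, 0.07, 0.90, 1.5)
        spec = forward_spectrum(p, grid=ctx.grid)
        v = dict(zip(ctx.grid.wavelengths, spec.values))
        assert v[540] < v[520] and v[540] < v[560]  # first oxyhaemoglobin band
        assert v[580] < v[560] and v[580] < v[600]  # second oxyhaemoglobin band

    def test_continuity_in_each_parameter(self, ctx):
        p0 = np.array([0.15, 0.06, 0.02, 0.6, 1.2])
        base = ctx.reflectance_batch(p0[None, :])[0]
        for j in range(5):
            dp = p0.copy()
            dp[j] *= 1.0 + 1e-7
            shifted = ctx.reflectance_batch(dp[None, :])[0]
            assert np.max(np.abs(shifted - base)) < 1e-4

    def test_beer_lambert_limit_of_the_stack(self, grid, table):
        # with scattering switched off in both layers the stack transmits
        # exp(-2 (mua1 d1 + mua2 d2)) and reflects nothing
        no_scatter = ScatteringModel(
            epidermis=_ZeroScattering(), dermis=_ZeroScattering()
        )
        p = SkinParams(0.10, 0.05, 0.02, 0.70, 1.0)
        lam = grid.wavelengths
        mua1 = epidermis_absorption(lam, p.f_mel)
        mua2 = dermis_absorption(lam, p.f_blood, p.c_oxy, table)
        l1 = layer_rt(mua1, 0.0, p.d_epi / 10.0)
        l2 = layer_rt(mua2, 0.0, p.d_dermis / 10.0)
        st_ = stack_two(l1, l2)
        expected = np.exp(-2.0 * (mua1 * p.d_epi / 10.0 + mua2 * p.d_dermis / 10.0))
        np.testing.assert_allclose(st_.T_total, expected, rtol=1e-10)
        np.testing.assert_allclose(st_.R_total, 0.0, atol=1e-15)

    def test_rejects_out_of_bounds_parameters(self, grid):
        with pytest.raises(ValueError):
            forward_spectrum(SkinParams(0.6, 0.05, 0.02, 0.7, 1.0), grid=grid)

    def test_reflectance_within_unit_interval(self, ctx, rng):
        lo, hi = ctx.bounds.lower(), ctx.bounds.upper()
        P = lo + (hi - lo) * rng.random((64, 5))
        R = ctx.reflectance_batch(P)
        assert np.all(R >= 0.0) and np.all(R <= 1.0)


class _ZeroScattering:
    def __call__(self, lam):
        return np.zeros_like(np.asarray(lam, dtype=float))
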