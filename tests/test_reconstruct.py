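"""FISTA deconvolution: operator norms, convergence, DC/AC splitting."""

import numpy as np
import pytest

from polsdom import (
    DeconvOptions,
    ModulationScheme,
    PolarizationStack,
    PSFModel,
    fista_deconvolve,
    fixture_two_points,
    olid_filter,
    render_stack,
    sdom_baseline,
    split_dc_ac,
)
from polsdom.reconstruct import _ForwardOperator, estimate_lipschitz

from .conftest import cosine_fit_oracle


class TestEstimateLipschitz:
    def test_delta_psf_is_isometry(self):
        L = estimate_lipschitz(PSFModel.delta(), (16, 16))
        assert L == pytest.approx(1.0, rel=1e-3)

    def test_unit_sum_kernel_bounded_by_one(self):
        psf = PSFModel(fwhm_nm=200.0, pixel_size_nm=20.0)
        L = estimate_lipschitz(psf, (24, 24))
        assert L <= 1.0 + 1e-9

    @pytest.mark.parametrize("fwhm", [60.0, 200.0])
    def test_against_dense_svd_oracle(self, fwhm):
        """Brute-force matrix of the forward operator on a small grid."""
        psf = PSFModel(fwhm_nm=fwhm, pixel_size_nm=20.0)
        shape = (8, 8)
        opts = DeconvOptions()
        op = _ForwardOperator(psf, shape, M=1, opts=opts)
        dim = op.padded_shape[0] * op.padded_shape[1]
        cols = []
        for j in range(dim):
            e = np.zeros((1,) + op.padded_shape)
            e.flat[j] = 1.0
            cols.append(op.forward(e).ravel())
        A = np.column_stack(cols)
        L_dense = np.linalg.svd(A, compute_uv=False)[0] ** 2
        L_power = estimate_lipschitz(psf, shape, opts, n_iters=60)
        assert L_power == pytest.approx(L_dense, rel=0.01)


class TestFistaDeconvolve:
    def test_delta_psf_fixed_point(self, scheme4x30, delta_psf):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0.1, 1.0, (30, 12, 12))
        stack = PolarizationStack(frames, ModulationScheme(1, 30), 20.0)
        res = fista_deconvolve(stack, delta_psf, DeconvOptions(max_iters=100, tol=1e-12))
        np.testing.assert_allclose(res.g_stack, frames, rtol=1e-6)

    def test_objective_monotone_on_random_problems(self):
        """Monotone-FISTA property over a batch of random small problems."""
        psf = PSFModel(fwhm_nm=120.0, pixel_size_nm=20.0)
        scheme = ModulationScheme(1, 4)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            frames = rng.uniform(0.0, 1.0, (4, 12, 12))
            stack = PolarizationStack(frames, scheme, 20.0)
            res = fista_deconvolve(stack, psf, DeconvOptions(max_iters=15))
            assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_noiseless_forward_model_objective_vanishes(self, gaussian_psf):
        """Data generated by the same forward model: the objective at the
        true object is zero, so FISTA's objective must head there."""
        scheme = ModulationScheme(1, 8)
        field = fixture_two_points(100.0, 20.0, 40.0, 0.8, shape=(32, 32))
        stack = render_stack(field, gaussian_psf, scheme)
        res = fista_deconvolve(
            stack, gaussian_psf, DeconvOptions(max_iters=700, tol=1e-14, init="zero")
        )
        assert res.objective_trace[-1] < 1e-4 * res.objective_trace[0]

    def test_flux_conserved_after_convergence(self, gaussian_psf):
        scheme = ModulationScheme(1, 8)
        field = fixture_two_points(100.0, 20.0, 40.0, 0.8, shape=(32, 32))
        stack = render_stack(field, gaussian_psf, scheme)
        res = fista_deconvolve(stack, gaussian_psf, DeconvOptions(max_iters=300, tol=1e-12))
        data_flux = stack.frames.sum(axis=(1, 2))
        recon_flux = res.g_stack.sum(axis=(1, 2))
        np.testing.assert_allclose(recon_flux, data_flux, rtol=0.02)

    def test_nonnegative_projection(self, gaussian_psf):
        rng = np.random.default_rng(4)
        frames = rng.normal(0.2, 0.5, (4, 16, 16))  # includes negatives
        stack = PolarizationStack(frames, ModulationScheme(1, 4), 20.0)
        res = fista_deconvolve(stack, gaussian_psf, DeconvOptions(max_iters=20))
        assert np.min(res.g_stack) >= 0.0

    def test_multi_period_stack_rejected(self, scheme4x30, gaussian_psf):
        stack = PolarizationStack(np.zeros((120, 8, 8)), scheme4x30, 20.0)
        with pytest.raises(ValueError, match="single-period"):
            fista_deconvolve(stack, gaussian_psf)

    def test_upsample_halves_grid_pitch(self, gaussian_psf):
        field = fixture_two_points(120.0, 45.0, 90.0, 1.0, shape=(32, 32))
        stack = render_stack(field, gaussian_psf, ModulationScheme(1, 8))
        res = fista_deconvolve(stack, gaussian_psf, DeconvOptions(max_iters=30, upsample=2))
        assert res.g_stack.shape == (8, 64, 64)
        assert res.pixel_size_nm == pytest.approx(10.0)
        assert np.all(np.diff(res.objective_trace) <= 1e-9)


class TestSplitDcAc:
    def test_single_pixel_example_vs_oracle(self, single_emitter_stack):
        stack, _ = single_emitter_stack
        first = PolarizationStack(
            stack.frames[:30], ModulationScheme(1, 30), stack.pixel_size_nm
        )
        Gdc, Gac_stack, B = split_dc_ac(first.frames, first.scheme)
        assert Gdc[8, 8] == pytest.approx(1.5, abs=1e-12)
        assert B[8, 8] == pytest.approx(0.5, abs=1e-12)
        a0, b_fit, _ = cosine_fit_oracle(first.frames[:, 8, 8], first.frame_angles)
        assert Gdc[8, 8] == pytest.approx(a0, abs=1e-9)
        assert B[8, 8] == pytest.approx(b_fit, abs=1e-9)

    def test_constant_stack_has_zero_ac(self):
        Gdc, Gac_stack, B = split_dc_ac(np.full((8, 4, 4), 2.0), ModulationScheme(1, 8))
        assert np.max(B) < 1e-14
        np.testing.assert_allclose(Gdc, 2.0)

    def test_pure_cosine_trace(self):
        scheme = ModulationScheme(1, 30)
        theta = scheme.angles
        trace = np.cos(theta - np.deg2rad(30.0)) ** 2
        Gdc, Gac_stack, B = split_dc_ac(trace[:, None, None], scheme)
        assert Gdc[0, 0] == pytest.approx(0.5, abs=1e-12)
        assert B[0, 0] == pytest.approx(0.5, abs=1e-12)
        np.testing.assert_allclose(
            Gac_stack[:, 0, 0], trace - 0.5, atol=1e-12
        )

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            split_dc_ac(np.zeros((3, 2, 2)), ModulationScheme(1, 4))

    def test_dc_is_mean_of_g_stack(self, gaussian_psf):
        field = fixture_two_points(80.0, 10.0, 30.0, 0.6, shape=(32, 32))
        stack = render_stack(field, gaussian_psf, ModulationScheme(1, 8))
        res = fista_deconvolve(stack, gaussian_psf, DeconvOptions(max_iters=40))
        np.testing.assert_allclose(res.Gdc, res.g_stack.mean(axis=0), atol=1e-12)


class TestSdomBaseline:
    def test_zero_weight_reduces_to_plain_fista(self, gaussian_psf):
        field = fixture_two_points(100.0, 0.0, 90.0, 1.0, shape=(32, 32))
        stack = render_stack(field, gaussian_psf, ModulationScheme(1, 4))
        a = fista_deconvolve(stack, gaussian_psf, DeconvOptions(max_iters=25))
        b = sdom_baseline(stack, gaussian_psf, 0.0, DeconvOptions(max_iters=25))
        np.testing.assert_allclose(a.g_stack, b.g_stack, atol=1e-9)

    def test_huge_weight_zeroes_everything(self, gaussian_psf):
        field = fixture_two_points(100.0, 0.0, 90.0, 1.0, shape=(32, 32))
        stack = render_stack(field, gaussian_psf, ModulationScheme(1, 4))
        res = sdom_baseline(stack, gaussian_psf, 1e6, DeconvOptions(max_iters=25))
        assert np.max(np.abs(res.g_stack)) == 0.0

    def test_monotone_composite_objective(self, gaussian_psf):
        rng = np.random.default_rng(7)
        frames = rng.uniform(0, 1, (4, 16, 16))
        stack = PolarizationStack(frames, ModulationScheme(1, 4), 20.0)
        res = sdom_baseline(stack, gaussian_psf, 0.01, DeconvOptions(max_iters=30))
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_negative_weight_rejected(self, gaussian_psf):
        stack = PolarizationStack(np.zeros((4, 8, 8)), ModulationScheme(1, 4), 20.0)
        with pytest.raises(ValueError):
            sdom_baseline(stack, gaussian_psf, -1.0)
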