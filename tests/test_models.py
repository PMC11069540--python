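import numpy as np
import pytest

from glefric import (
    MemoryKernel,
    fit_kernel_model,
    fit_viscosity_scaling,
    internal_friction_ratio,
)
from glefric.extraction import KernelEstimate
from glefric.models import FitError, select_n_exp


def estimate_from_kernel(kernel, dt=0.005, t_max=8.0, noise=0.0, seed=0):
    """Analytic G(t) sampled on a lag grid, optionally with relative noise."""
    t = np.arange(int(t_max / dt) + 1) * dt
    G = kernel.G_of_t(t)
    if noise > 0:
        rng = np.random.default_rng(seed)
        G = G * (1.0 + noise * rng.standard_normal(t.size))
        G[0] = 0.0
    est = KernelEstimate(t=t, G=G, Gamma=np.gradient(G, dt), mass=1.0)
    est.gamma = kernel.total_friction
    return est


class TestKernelModelFit:
    def test_noiseless_two_exponential_recovery(self):
        truth = MemoryKernel.from_components(exp=[(6.0, 0.8), (4.0, 0.05)])
        est = estimate_from_kernel(truth)
        fit = fit_kernel_model(est, n_exp=2, n_osc=0, seed=0)
        comps = sorted(fit.exponentials, key=lambda c: -c.tau)
        assert comps[0].gamma == pytest.approx(6.0, rel=0.01)
        assert comps[0].tau == pytest.approx(0.8, rel=0.01)
        assert comps[1].gamma == pytest.approx(4.0, rel=0.01)
        assert comps[1].tau == pytest.approx(0.05, rel=0.01)

    def test_amplitudes_sum_to_plateau_exactly(self):
        truth = MemoryKernel.from_components(exp=[(7.0, 0.5), (3.0, 0.03)])
        est = estimate_from_kernel(truth, noise=0.02)
        fit = fit_kernel_model(est, n_exp=3, n_osc=1, seed=1)
        assert fit.total_friction == pytest.approx(est.gamma, rel=1e-10)

    def test_overparametrized_fit_preserves_total(self):
        truth = MemoryKernel.single_exponential(10.0, 0.3)
        est = estimate_from_kernel(truth)
        fit = fit_kernel_model(est, n_exp=3, n_osc=0, seed=0)
        assert fit.total_friction == pytest.approx(10.0, rel=1e-10)
        # the recovered kernel reproduces G even if components degenerate
        assert np.allclose(fit.G_of_t(est.t[1:]), est.G[1:], rtol=0.02, atol=0.05)

    def test_oscillation_frequency_recovered_with_noise(self):
        # omega tau ~ 5 with 2% multiplicative noise on G
        truth = MemoryKernel.from_components(exp=[(6.0, 0.4)], osc=[(2.0, 0.25, 20.0)])
        est = estimate_from_kernel(truth, dt=0.002, t_max=4.0, noise=0.02, seed=2)
        fit = fit_kernel_model(est, n_exp=1, n_osc=1, seed=0)
        (osc,) = fit.oscillations
        assert osc.omega == pytest.approx(20.0, rel=0.05)

    def test_model_selection_finds_true_order(self):
        truth = MemoryKernel.from_components(exp=[(6.0, 0.8), (4.0, 0.05)])
        est = estimate_from_kernel(truth, noise=0.005, seed=3)
        assert select_n_exp(est, max_exp=3) == 2

    def test_missing_plateau_rejected(self):
        truth = MemoryKernel.single_exponential(5.0, 0.2)
        est = estimate_from_kernel(truth)
        est.gamma = None
        with pytest.raises(ValueError):
            fit_kernel_model(est, n_exp=1, n_osc=0)


class TestViscosityScalingFit:
    def test_pure_linear_scaling(self):
        eta = np.array([1.0, 2.0, 4.0, 6.0, 10.0])
        fit = fit_viscosity_scaling(np.column_stack([eta, 5.0 * eta]), seed=0)
        assert fit.alpha == pytest.approx(5.0, abs=0.01)
        assert fit.beta == pytest.approx(1.0, abs=0.01)
        assert fit.epsilon == pytest.approx(0.0, abs=0.01)
        assert fit.internal_friction_ratio == pytest.approx(0.0, abs=0.01)

    def test_constant_times_fit_flat(self):
        # viscosity-insensitive solute: the fitted curve is flat
        eta = np.array([1.0, 2.0, 4.0, 8.0])
        fit = fit_viscosity_scaling(np.column_stack([eta, np.full(4, 7.0)]), seed=0)
        pred = fit.predict(np.linspace(1, 8, 20))
        assert np.max(np.abs(pred - 7.0)) / 7.0 < 0.01

    def test_sublinear_exponent_recovery(self):
        rng = np.random.default_rng(1)
        eta = np.array([1.0, 2.0, 3.0, 5.0, 7.0, 10.0])
        tau = 2.0 * eta**0.45
        noisy = tau * (1.0 + 0.03 * rng.standard_normal(6))
        fit = fit_viscosity_scaling(
            np.column_stack([eta, noisy, 0.03 * tau]), seed=0
        )
        assert fit.beta == pytest.approx(0.45, abs=0.1)

    def test_prediction_at_reference_is_alpha_plus_eps(self):
        eta = np.array([1.0, 3.0, 6.0, 10.0])
        fit = fit_viscosity_scaling(np.column_stack([eta, 2 * eta**0.5 + 1]), seed=0)
        assert fit.predict(1.0) == pytest.approx(fit.alpha + fit.epsilon, rel=1e-9)
        assert 0.0 <= fit.internal_friction_ratio <= 1.0

    def test_identifiability_bootstrap_coverage(self):
        # 4 conditions on eta in [1, 10] with 5% noise: the 90% bootstrap CI
        # for beta covers the truth in >= 85% of replicates
        eta = np.array([1.0, 2.5, 5.0, 10.0])
        beta_true = 0.6
        tau = 3.0 * eta**beta_true + 1.0
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            noisy = tau * (1.0 + 0.05 * rng.standard_normal(4))
            fit = fit_viscosity_scaling(
                np.column_stack([eta, noisy, 0.05 * tau]),
                n_bootstrap=100, seed=rep,
            )
            lo, hi = fit.beta_ci(0.90)
            hits += lo <= beta_true <= hi
        assert hits >= int(0.85 * n_rep)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_viscosity_scaling([(1.0, 2.0), (2.0, 3.0)])
        with pytest.raises(ValueError):
            fit_viscosity_scaling([(1.0, 2.0), (1.0, 2.1), (1.0, 1.9)])
        with pytest.raises(ValueError):
            fit_viscosity_scaling([(-1.0, 2.0), (2.0, 3.0), (3.0, 4.0)])


class TestInternalFrictionRatio:
    @pytest.mark.parametrize(
        "alpha,eps,expected", [(1.0, 0.0, 0.0), (0.0, 1.0, 1.0), (1.0, 4.0, 0.8)]
    )
    def test_ratio_arithmetic(self, alpha, eps, expected):
        from glefric.models import ScalingFit

        fit = ScalingFit(alpha=alpha, beta=1.0, epsilon=eps)
        r, ci = internal_friction_ratio(fit)
        assert r == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        from glefric.models import ScalingFit

        fit = ScalingFit(alpha=0.0, beta=1.0, epsilon=0.0)
        with pytest.raises(ValueError):
            fit.internal_friction_ratio
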