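import math

import numpy as np
import pytest

from glefric import (
    MemoryKernel,
    diffusion_time,
    grote_hynes,
    kramers_overdamped,
    make_potential,
    markovian_mfpt,
    memory_regime,
)
from glefric.rate_theory import memoryless_reactive_frequency


class TestKramersOverdamped:
    def test_unit_prefactor_case(self):
        # gamma=1, U0=0, |U''min U''max| = 4 pi^2 -> tau = 1
        r = kramers_overdamped(1.0, 0.0, 2.0 * math.pi, -2.0 * math.pi)
        assert r.time == pytest.approx(1.0, rel=1e-12)

    def test_direct_evaluation(self):
        r = kramers_overdamped(1.0, 4.0, 1.0, -1.0)
        assert r.time == pytest.approx(2.0 * math.pi * math.e**4, rel=1e-12)

    def test_linear_in_friction(self):
        t1 = kramers_overdamped(1.5, 3.0, 8.0, -4.0).time
        t2 = kramers_overdamped(3.0, 3.0, 8.0, -4.0).time
        assert t2 == pytest.approx(2.0 * t1, rel=1e-12)

    def test_wrong_curvature_signs_rejected(self):
        with pytest.raises(ValueError):
            kramers_overdamped(1.0, 1.0, -1.0, -1.0)
        with pytest.raises(ValueError):
            kramers_overdamped(1.0, 1.0, 1.0, 1.0)


class TestMarkovianMFPT:
    def test_free_diffusion_exact(self):
        # flat U, reflect 0, absorb L: tau = gamma L^2 / (2 k_BT)
        p = make_potential("flat", extent=2.0)
        r = markovian_mfpt(p, 3.0, q_start=0.0, q_absorb=1.0, q_reflect=0.0)
        assert r.time == pytest.approx(1.5, rel=1e-8)

    def test_linear_in_friction(self, quartic_profile):
        t1 = markovian_mfpt(quartic_profile, 1.0, -1.0, 1.0, -2.5).time
        t2 = markovian_mfpt(quartic_profile, 0.5, -1.0, 1.0, -2.5).time
        assert t2 == pytest.approx(t1 / 2.0, rel=1e-10)

    def test_kramers_deviation_about_20pc_at_4kbt(self, quartic_profile):
        # high-friction Kramers vs the exact double-integral solution on a
        # smooth 4 k_BT double well: deviation in the 12-28% range
        exact = markovian_mfpt(quartic_profile, 1.0, -1.0, 1.0, -2.5).time
        kr = kramers_overdamped(1.0, 4.0, 32.0, -16.0).time
        dev = abs(kr - exact) / exact * 100.0
        assert 12.0 < dev < 28.0

    def test_deviation_decreases_with_barrier_height(self):
        devs = []
        for u0 in (2.0, 4.0, 8.0):
            p = make_potential("double_well_quartic", barrier=u0)
            exact = markovian_mfpt(p, 1.0, -1.0, 1.0, -2.5).time
            kr = kramers_overdamped(1.0, u0, 8 * u0, -4 * u0).time
            devs.append(abs(kr - exact) / exact)
        assert devs[0] > devs[1] > devs[2]

    def test_start_outside_interval_rejected(self, quartic_profile):
        with pytest.raises(ValueError):
            markovian_mfpt(quartic_profile, 1.0, q_start=-2.0, q_absorb=1.0,
                           q_reflect=-1.0)


class TestGroteHynes:
    mass, cmin, cmax, u0 = 1.0, 32.0, -16.0, 4.0

    def test_memoryless_limit_matches_closed_form(self):
        # single-exponential kernel with tau -> 0 approaches the classical
        # Kramers intermediate-friction root
        gamma = 8.0
        wb = math.sqrt(abs(self.cmax) / self.mass)
        k = MemoryKernel.single_exponential(gamma, 1e-3 / wb)
        gh = grote_hynes(k, self.mass, self.cmin, self.cmax, self.u0)
        lam_ml = memoryless_reactive_frequency(gamma, self.mass, wb)
        assert gh.reactive_frequency == pytest.approx(lam_ml, rel=0.01)

    def test_strong_friction_limit_is_overdamped_kramers(self):
        wb = math.sqrt(abs(self.cmax) / self.mass)
        gamma = 100.0 * self.mass * wb
        k = MemoryKernel.single_exponential(gamma, 1e-4 / wb)
        gh = grote_hynes(k, self.mass, self.cmin, self.cmax, self.u0)
        kr = kramers_overdamped(gamma, self.u0, self.cmin, self.cmax)
        assert gh.time == pytest.approx(kr.time, rel=0.01)

    def test_reactive_frequency_bounded_by_barrier_frequency(self):
        wb = math.sqrt(abs(self.cmax) / self.mass)
        k = MemoryKernel.from_components(exp=[(5, 0.3)], osc=[(2, 0.1, 20.0)])
        gh = grote_hynes(k, self.mass, self.cmin, self.cmax, self.u0)
        assert 0.0 < gh.reactive_frequency <= wb
        assert gh.time > 0

    def test_friction_monotonically_slows_reactive_mode(self):
        lams = []
        for g in (1.0, 3.0, 10.0, 30.0):
            k = MemoryKernel.from_components(exp=[(g, 0.2), (2.0, 0.02)])
            gh = grote_hynes(k, self.mass, self.cmin, self.cmax, self.u0)
            lams.append(gh.reactive_frequency)
        assert np.all(np.diff(lams) < 0)

    def test_oscillating_component_quadrature_route_agrees(self):
        k = MemoryKernel.from_components(exp=[(5, 0.3)], osc=[(2, 0.1, 20.0)])
        a = grote_hynes(k, self.mass, self.cmin, self.cmax, self.u0)
        b = grote_hynes(k, self.mass, self.cmin, self.cmax, self.u0,
                        laplace_method="quadrature")
        assert a.reactive_frequency == pytest.approx(b.reactive_frequency, rel=1e-6)


class TestDiffusionTime:
    def test_unit_case(self):
        assert diffusion_time(1.0, 1.0) == 1.0

    def test_quadratic_in_length(self):
        assert diffusion_time(2.0, 2.0) == 4.0 * diffusion_time(2.0, 1.0)

    def test_deg_rad_unit_invariance(self):
        # gamma in rad units with L in rad == gamma in deg units with L in deg
        gamma_rad, L_rad = 5.0, math.radians(60.0)
        s = 180.0 / math.pi
        gamma_deg, L_deg = gamma_rad / s**2, 60.0
        assert diffusion_time(gamma_rad, L_rad) == pytest.approx(
            diffusion_time(gamma_deg, L_deg), rel=1e-12
        )


class TestMemoryRegime:
    def test_fast_component_flagged_near_markovian(self):
        gamma, L = 10.0, 1.0
        tau_d = diffusion_time(gamma, L)
        k = MemoryKernel.single_exponential(gamma, tau_d / 100.0)
        rep = memory_regime(k, gamma, L)
        assert rep["components"][0]["regime"] == "near-markovian"

    def test_long_small_mode_flagged_inert(self):
        gamma, L = 10.0, 1.0
        k = MemoryKernel.from_components(exp=[(9.0, 0.5), (1.0, 100.0)])
        rep = memory_regime(k, gamma, L)
        long_mode = rep["components"][1]
        assert long_mode["regime"] == "slow-down-proximal"
        assert "inert" in long_mode.get("note", "")

    def test_speedup_classification(self):
        gamma, L = 10.0, 1.0
        k = MemoryKernel.single_exponential(gamma, 1.0)  # tau = tau_D / 10
        rep = memory_regime(k, gamma, L)
        assert rep["components"][0]["regime"] == "speed-up"
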