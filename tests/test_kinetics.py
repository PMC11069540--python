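import numpy as np
import pytest

from glefric import (
    MemoryKernel,
    Trajectory,
    first_passage_times,
    make_potential,
    markovian_mfpt,
    mfpt_vs_condition,
    simulate_gle,
    translational_diffusion,
)
from glefric.kinetics import NoEventsError


def triangle_trajectory(dt=0.01, period=4.0, n=40_000):
    t = np.arange(n) * dt
    return Trajectory(values=2 * np.abs((t / period) % 1 - 0.5) - 0.5, dt=dt)


class TestFirstPassage:
    def test_triangle_wave_event_times_exact(self):
        # linear ramp from -0.5 to +0.5 in 2 time units: -0.4 -> +0.4
        # takes 0.8/0.5 = 1.6; alternation adds the return leg symmetrically
        tr = triangle_trajectory()
        res = first_passage_times(tr, -0.4, 0.4, seed=0)
        assert res.times.std() < 1e-9  # all events identical
        assert res.mean == pytest.approx(2.0, abs=1e-9)
        assert res.n_events == 100

    def test_rapid_recrossings_do_not_spawn_events(self):
        # source recrossed twice inside one event; renewal rule counts one
        q = np.array([-1.0, 0.1, -1.0, 0.1, -1.0, 0.1, 1.1, -1.0, 1.1])
        tr = Trajectory(values=q, dt=1.0)
        res = first_passage_times(tr, 0.0, 1.0, seed=0)
        assert res.n_events == 2

    def test_overdamped_quartic_matches_exact_oracle(self, quartic_profile):
        gamma = 2.0
        kern = MemoryKernel.single_exponential(gamma, 0.002)
        tr = simulate_gle(quartic_profile, kern, mass=0.005, dt=2e-4,
                          n_steps=60_000_000, seed=6, q0=-1.0)
        tr = tr.decimate(5)
        res = first_passage_times(tr, -1.0, 1.0, seed=0)
        oracle = markovian_mfpt(quartic_profile, gamma, -1.0, 1.0, -2.5).time
        assert abs(res.mean - oracle) < 3 * res.stderr

    def test_direction_asymmetry_on_tilted_double_well(self):
        # deep -> shallow is slower than shallow -> deep for every seed
        q = np.linspace(-2.5, 2.5, 501)
        u = 3.0 * (q**2 - 1) ** 2 + 0.8 * q  # left well deeper
        prof = make_potential("tabulated", q=q, u=u)
        kern = MemoryKernel.single_exponential(1.0, 0.02)
        for seed in (0, 1, 2):
            tr = simulate_gle(prof, kern, mass=0.05, dt=0.002,
                              n_steps=5_000_000, seed=seed, q0=-1.0)
            fwd = first_passage_times(tr, -1.0, 1.0, seed=0)   # deep -> shallow
            bwd = first_passage_times(tr, 1.0, -1.0, seed=0)   # shallow -> deep
            assert bwd.mean < fwd.mean

    def test_decimation_robustness(self, quartic_profile):
        kern = MemoryKernel.single_exponential(1.0, 0.01)
        tr = simulate_gle(quartic_profile, kern, mass=0.02, dt=0.001,
                          n_steps=20_000_000, seed=7, q0=-1.0)
        full = first_passage_times(tr, -1.0, 1.0, seed=0)
        half = first_passage_times(tr.decimate(2), -1.0, 1.0, seed=0)
        assert abs(half.mean - full.mean) / full.mean < 0.02

    def test_pooled_gauche_matches_single_gauche(self, triple_well):
        # symmetric triple well has no gauche offset here
        prof = make_potential("cosine_dihedral", barrier=2.5)
        kern = MemoryKernel.single_exponential(1.0, 0.05)
        g = np.radians(120.0)
        tr = simulate_gle(prof, kern, mass=0.5, dt=0.005, n_steps=10_000_000, seed=8)
        pooled = first_passage_times(tr, g, 0.0, pool_symmetric=True, seed=0)
        single = first_passage_times(tr, g, 0.0, seed=0)
        err = np.hypot(pooled.stderr, single.stderr)
        assert abs(pooled.mean - single.mean) < 3 * err
        assert pooled.n_events > single.n_events

    def test_zero_events_raises_with_diagnostics(self):
        # target is crossed only before the first source crossing, so no
        # source->target event ever completes
        q = np.array([0.3, 0.2, 0.05, 0.15, 0.05, 0.15, 0.05])
        tr = Trajectory(values=q, dt=0.01)
        with pytest.raises(NoEventsError, match="diagnostics"):
            first_passage_times(tr, 0.1, 0.25, seed=0)

    def test_position_outside_support_rejected(self):
        tr = Trajectory(values=np.linspace(-1, 1, 100), dt=0.01)
        with pytest.raises(ValueError):
            first_passage_times(tr, -2.0, 0.5, seed=0)


class TestTranslationalDiffusion:
    def test_exact_linear_msd(self):
        t = np.linspace(0, 10, 100)
        D = translational_diffusion((t, 6 * 0.3 * t), dimensionality=3)
        assert D == pytest.approx(0.3, rel=1e-12)

    def test_brownian_walk_recovery(self):
        rng = np.random.default_rng(2)
        D, dt, n = 0.1, 0.01, 500_000
        pos = np.cumsum(np.sqrt(2 * D * dt) * rng.standard_normal((n, 3)), axis=0)
        est = translational_diffusion(pos, dt=dt, fit_window=(dt, 200 * dt))
        assert est == pytest.approx(D, rel=0.05)

    def test_two_walks_ratio_of_two(self):
        rng = np.random.default_rng(3)
        dt, n = 0.01, 500_000
        w = rng.standard_normal((n, 3))
        p1 = np.cumsum(np.sqrt(2 * 0.1 * dt) * w, axis=0)
        p2 = np.cumsum(np.sqrt(2 * 0.2 * dt) * w, axis=0)
        d1 = translational_diffusion(p1, dt=dt, fit_window=(dt, 200 * dt))
        d2 = translational_diffusion(p2, dt=dt, fit_window=(dt, 200 * dt))
        assert d2 / d1 == pytest.approx(2.0, rel=1e-9)

    def test_non_monotonic_msd_rejected(self):
        t = np.linspace(0, 10, 50)
        msd = np.sin(t)
        with pytest.raises(ValueError):
            translational_diffusion((t, msd), dimensionality=3)


class TestConditionTable:
    def test_reference_ratio_is_one(self):
        df = mfpt_vs_condition([("neat", 1.0, (5.0, 0.1))], reference="neat")
        assert df["tau_ratio"].iloc[0] == 1.0

    def test_linear_tau_gives_eta_ratios(self):
        entries = [(f"c{e}", e, (5.0 * e, 0.0)) for e in (1.0, 2.0, 4.0, 8.0)]
        df = mfpt_vs_condition(entries, reference="c1.0")
        assert np.allclose(df["tau_ratio"], df["eta_rel"])

    def test_ratio_error_propagation_matches_bootstrap(self):
        rng = np.random.default_rng(0)
        tau, err, tau0, err0 = 10.0, 0.5, 5.0, 0.2
        df = mfpt_vs_condition(
            [("ref", 1.0, (tau0, err0)), ("x", 3.0, (tau, err))], reference="ref"
        )
        boot = rng.normal(tau, err, 200_000) / rng.normal(tau0, err0, 200_000)
        assert df.loc[df.condition == "x", "tau_ratio_stderr"].iloc[0] == pytest.approx(
            boot.std(), rel=0.05
        )

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            mfpt_vs_condition([("a", 1.0, (1.0, 0.1))], reference="b")
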