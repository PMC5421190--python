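import copy

import numpy as np
import pytest

from spherenf.bifurcation import AnalysisTemplate, balanced_hopf_point
from spherenf.mesh import build_icosphere
from spherenf.model_core import (
    ConnectivityParams,
    DelayParams,
    FiringParams,
    ModelParams,
    firing_rate,
    kernel_mass,
)
from spherenf.planforms import branches_for_degree, synthesize
from spherenf.simulator import (
    SimConfig,
    Trajectory,
    build_coupling,
    center_of_mass,
    simulate,
    simulate_homogeneous,
    standing_wave_ratio,
)
from spherenf.spectral import LinearizationContext, rightmost_eigenvalue


def balanced_params(scale: float, delta: float = 0.1) -> ModelParams:
    """Raw parameters on the balanced-kernel line, scaled relative to the
    n=0 Hopf point (scale < 1 stable, > 1 oscillatory)."""
    template = AnalysisTemplate(1.0, 0.5, DelayParams(3.0, 1.0))
    hp = balanced_hopf_point(0, template)
    firing = FiringParams(1.0, 4.0, delta)
    from spherenf.model_core import firing_rate_derivative

    kappa = float(firing_rate_derivative(0.0, firing, 1))
    conn = ConnectivityParams(
        scale * hp.kJ1 / kappa, scale * hp.kJ2 / kappa, 1.0, 0.5
    )
    return ModelParams(firing, conn, DelayParams(3.0, 1.0))


class TestCoupling:
    def test_constant_preserving_row_sums(self, mesh_level2):
        params = balanced_params(0.9)
        coupling = build_coupling(mesh_level2, params)
        w0 = kernel_mass(params.connectivity)
        assert np.allclose(
            coupling.kernel_matrix.sum(axis=1), w0, atol=1e-12
        )
        assert coupling.max_delay == params.delay.max_delay

    def test_uncorrected_rows_deviate(self, mesh_level2):
        params = balanced_params(0.9)
        coupling = build_coupling(mesh_level2, params, constant_preserving=False)
        w0 = kernel_mass(params.connectivity)
        assert np.max(np.abs(coupling.kernel_matrix.sum(axis=1) - w0)) > 1e-6


class TestSimulate:
    def test_equilibrium_preserved(self, mesh_level2):
        params = balanced_params(0.9)
        cfg = SimConfig(dt=0.05, t_final=5.0, mesh_level=2)
        traj = simulate(cfg, params, mesh=mesh_level2)
        drift = np.max(np.abs(traj.fields[-1] - traj.equilibrium.u_hat))
        assert drift < 1e-10

    def test_stable_regime_decays(self, mesh_level2):
        params = balanced_params(0.8)
        cfg = SimConfig(
            dt=0.05, t_final=60.0, mesh_level=2,
            initial=("random", 1e-3), seed=5, save_every=20,
        )
        traj = simulate(cfg, params, mesh=mesh_level2)
        dev0 = np.max(np.abs(traj.fields[0] - traj.equilibrium.u_hat))
        dev1 = np.max(np.abs(traj.fields[-1] - traj.equilibrium.u_hat))
        assert dev1 < 0.2 * dev0

    def test_mesh_growth_rate_near_spectral_eigenvalue(self, mesh_level2):
        """Perturb the homogeneous mode in an unstable regime: the degree-0
        power grows at roughly twice the leading eigenvalue's real part.  The
        level-2 mesh quadrature shifts the effective gain, so only order-of-
        magnitude agreement is expected here; the sharp quantitative check
        lives in TestHomogeneousReduction."""
        params = balanced_params(1.1)
        from spherenf.model_core import find_equilibria

        eq = find_equilibria(params)[0]
        ctx = LinearizationContext(params, eq, n_max=3)
        lead = rightmost_eigenvalue(ctx)
        assert lead.n == 0 and lead.lam.real > 0

        cfg = SimConfig(
            dt=0.02, t_final=80.0, mesh_level=2,
            initial=("harmonic", 1e-6, 0, 0), save_every=5,
        )
        traj = simulate(cfg, params, mesh=mesh_level2)
        df = traj.diagnostics
        sel = (df.time >= 20.0) & (df.time <= 70.0)
        t = df.time[sel].to_numpy()
        logp = np.log(df.power_0[sel].to_numpy())
        slope = np.polyfit(t, logp, 1)[0]
        assert slope > 0
        assert slope / 2.0 == pytest.approx(lead.lam.real, rel=0.6)

    def test_harmonic_perturbation_targets_degree(self, mesh_level2):
        params = balanced_params(0.9)
        cfg = SimConfig(
            dt=0.05, t_final=1.0, mesh_level=2, initial=("harmonic", 1e-2, 2, 1)
        )
        traj = simulate(cfg, params, mesh=mesh_level2)
        p = traj.diagnostics.iloc[0]
        powers = np.array([p[f"power_{n}"] for n in range(1, 6)])
        assert np.argmax(powers) + 1 == 2

    def test_explicit_field_initial_condition(self, mesh_level2):
        params = balanced_params(0.9)
        u0 = np.full(len(mesh_level2), 0.123)
        cfg = SimConfig(dt=0.05, t_final=0.5, mesh_level=2,
                        initial=("field", u0))
        traj = simulate(cfg, params, mesh=mesh_level2)
        assert traj.fields[0] == pytest.approx(u0)

    def test_wrong_field_length_rejected(self, mesh_level2):
        params = balanced_params(0.9)
        cfg = SimConfig(initial=("field", np.zeros(7)))
        with pytest.raises(ValueError):
            simulate(cfg, params, mesh=mesh_level2)

    def test_unknown_initial_kind_rejected(self, mesh_level2):
        params = balanced_params(0.9)
        with pytest.raises(ValueError):
            simulate(SimConfig(initial=("bogus",)), params, mesh=mesh_level2)

    def test_matches_homogeneous_reduction(self, mesh_level2):
        """A homogeneous start evolves like the scalar distributed-delay
        reduction, up to the mesh quadrature error of the delayed integral
        (about 7e-4 at level 2, an order of magnitude less at level 3)."""
        params = balanced_params(0.9)
        u_init = 0.05
        cfg = SimConfig(
            dt=0.01, t_final=10.0, mesh_level=2,
            initial=("field", np.full(len(mesh_level2), u_init)),
            save_every=100,
        )
        traj = simulate(cfg, params, mesh=mesh_level2)
        times, u = simulate_homogeneous(params, u_init, 10.0, dt=0.01)
        for t_saved, field in zip(traj.times, traj.fields):
            k = int(round(t_saved / 0.01))
            assert np.max(np.abs(field - u[k])) < 2e-3


class TestHomogeneousReduction:
    def test_equilibrium_is_fixed_point(self):
        params = balanced_params(0.9)
        # balanced kernel: u = 0 is the steady state
        _, u = simulate_homogeneous(params, 0.0, 10.0)
        assert np.max(np.abs(u)) < 1e-12

    def test_limit_cycle_period_matches_hopf_frequency(self):
        """Slightly beyond the balanced n=0 Hopf point at the supercritical
        threshold side, the oscillation period approaches 2 pi / omega0."""
        params = balanced_params(1.05, delta=0.1)
        _, u = simulate_homogeneous(params, 0.05, 400.0, dt=0.01)
        tail = u[-20000:]
        # count mean crossings to estimate the period
        m = tail.mean()
        up = (tail[:-1] < m) & (tail[1:] >= m)
        idx = np.where(up)[0]
        period = np.mean(np.diff(idx)) * 0.01
        template = AnalysisTemplate(1.0, 0.5, DelayParams(3.0, 1.0))
        omega0 = balanced_hopf_point(0, template).omega
        assert period == pytest.approx(2 * np.pi / omega0, rel=0.05)

    def test_growth_rate_matches_spectral_eigenvalue(self):
        """The linear growth rate of a small homogeneous perturbation matches
        the real part of the leading characteristic root to 1%."""
        from scipy.signal import hilbert

        from spherenf.model_core import find_equilibria

        params = balanced_params(1.1)
        eq = find_equilibria(params)[0]
        lead = rightmost_eigenvalue(LinearizationContext(params, eq, n_max=3))
        assert lead.n == 0 and lead.lam.real > 0
        t, u = simulate_homogeneous(params, 1e-6, 200.0, dt=0.01)
        env = np.abs(hilbert(u))
        sel = (t >= 50.0) & (t <= 180.0)
        slope = np.polyfit(t[sel], np.log(env[sel]), 1)[0]
        assert slope == pytest.approx(lead.lam.real, rel=0.01)

    def test_callable_history(self):
        params = balanced_params(0.9)
        times, u = simulate_homogeneous(
            params, lambda t: 0.01 * np.cos(t), 5.0
        )
        assert u[0] == pytest.approx(0.01)
        assert np.all(np.isfinite(u))


class TestDiagnostics:
    @staticmethod
    def synthetic_trajectory(mesh, branch_name, omega=0.8, n_frames=40):
        branch = next(
            b for b in branches_for_degree(4) if b.name == branch_name
        )
        period = 2 * np.pi / omega
        times = np.linspace(0.0, 2 * period, n_frames)
        fields = np.array(
            [synthesize(branch, 1.0, omega, t, mesh.vertices) for t in times]
        )
        params = balanced_params(0.9)
        from spherenf.model_core import find_equilibria

        return Trajectory(
            times=times,
            fields=fields,
            diagnostics=None,
            mesh=mesh,
            params=params,
            equilibrium=find_equilibria(params)[0],
            dt=times[1] - times[0],
        )

    def test_standing_wave_ratio_low_for_standing(self, mesh_level3):
        traj = self.synthetic_trajectory(mesh_level3, "O(2)~")
        assert standing_wave_ratio(traj, 4) < 0.05

    def test_standing_wave_ratio_high_for_rotating(self, mesh_level3):
        traj = self.synthetic_trajectory(mesh_level3, "SO(2)4~")
        assert standing_wave_ratio(traj, 4) > 0.8

    def test_center_of_mass_tracks_hotspot(self, mesh_level2):
        u = np.exp(5.0 * mesh_level2.vertices[:, 2])  # peak at north pole
        com = center_of_mass(u, mesh_level2)
        com /= np.linalg.norm(com)
        assert com[2] == pytest.approx(1.0, abs=1e-6)

    def test_validated_dt_caps(self):
        cfg = SimConfig(dt=0.5)
        assert cfg.validated_dt(max_delay=4.0, tau0=0.06) == pytest.approx(0.03)
        assert cfg.validated_dt(max_delay=4.0, tau0=3.0) == pytest.approx(0.05)
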