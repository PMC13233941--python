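"""Phonon normal-mode algebra: dynamical matrix, masses, projections,
occupations and the three-term energy accounting."""

import math

import numpy as np
import pytest

import neurophonon as nv
from neurophonon.phonon import mode_masses_from
from neurophonon.sl_model import OscillatorParams

from conftest import hetero_model


def two_osc_model(s=0.5, hbar=1.0):
    """Two identical activated oscillators with real coupling K = -s
    (so the amplitude coupling matrix is S = s)."""
    p = nv.preset("activated")
    K = np.array([[0, -s], [-s, 0]], dtype=complex)
    return nv.NetworkModel((p, p), K, hbar)


def make_recording(model, envelope, phases=None, fs=256.0):
    """Synthetic recording with a prescribed envelope (N, T) and phases."""
    n, T = envelope.shape
    t = np.arange(T) / fs
    if phases is None:
        phases = np.array([p.omega for p in model.oscillators])[:, None] * t
    z = envelope * np.exp(1j * phases)
    return nv.MultichannelRecording(
        fs=fs, channels=[f"ch{j}" for j in range(n)], data=z.real, analytic=z
    )


class TestBuildBasis:
    def test_requires_limit_cycle_and_noise_naming_channels(self):
        p_ok = nv.preset("activated")
        p_bad = nv.preset("suppressed")
        model = nv.NetworkModel((p_ok, p_bad), np.zeros((2, 2), complex))
        with pytest.raises(ValueError, match=r"\[1\]"):
            nv.build_basis(model)
        p0 = p_ok.with_(D=0.0)
        model = nv.NetworkModel((p0, p_ok), np.zeros((2, 2), complex))
        with pytest.raises(ValueError, match="mass"):
            nv.build_basis(model)

    def test_single_oscillator_printed_frequency(self, activated):
        # V'' = 797, m = hbar/2D = 50 -> Omega^2 = 15.94
        basis = nv.build_basis(nv.NetworkModel.single(activated, hbar=1.0))
        assert basis.omega_sq[0] == pytest.approx(15.94, rel=1e-12)
        assert basis.Omega[0] == pytest.approx(math.sqrt(15.94), rel=1e-12)
        assert basis.M[0] == pytest.approx(50.0, rel=1e-12)

    def test_uncoupled_network_is_diagonal(self):
        rng = np.random.default_rng(3)
        osc = tuple(
            OscillatorParams(2.0, 1.0, 0.5, 2 * np.pi * 10, float(D))
            for D in rng.uniform(0.005, 0.02, 3)
        )
        model = nv.NetworkModel(osc, np.zeros((3, 3), complex))
        basis = nv.build_basis(model)
        assert np.allclose(basis.Phi, np.diag(np.diag(basis.Phi)))
        expected = np.sort(basis.curvatures / basis.masses)
        assert np.allclose(basis.omega_sq, expected, rtol=1e-12)
        # modes are coordinate axes (up to ordering): one unit entry per column
        assert np.allclose(np.max(np.abs(basis.modes), axis=0), 1.0, atol=1e-12)
        assert np.allclose(np.sum(np.abs(basis.modes) > 1e-12, axis=0), 1)

    def test_two_oscillator_analytic_eigenfrequencies(self):
        """2x2 toy: Omega^2 in {V''/m, (V''+2s)/m} to 1e-10."""
        s = 0.5
        model = two_osc_model(s)
        basis = nv.build_basis(model)
        p = model.oscillators[0]
        vpp = nv.potential_curvature(p, model.hbar)
        m = model.hbar / (2 * p.D)
        expected = np.sort([vpp / m, (vpp + 2 * s) / m])
        assert np.max(np.abs(basis.omega_sq - expected)) < 1e-10

    def test_orthonormality_and_eigen_residual(self):
        model = hetero_model(4, seed=1)
        basis = nv.build_basis(model)
        assert basis.n_modes == 4
        assert np.max(np.abs(basis.modes.T @ basis.modes - np.eye(4))) < 1e-10
        for ell in range(4):
            res = basis.Phi @ basis.modes[:, ell] - basis.omega_sq[ell] * basis.modes[:, ell]
            assert np.max(np.abs(res)) < 1e-8

    def test_unstable_mode_flagged_not_dropped(self, activated):
        # strong negative S (positive Re K) makes one Phi eigenvalue negative
        K = np.array([[0, 500.0], [500.0, 0]], dtype=complex)
        model = nv.NetworkModel((activated, activated), K)
        with pytest.warns(RuntimeWarning, match="unstable"):
            basis = nv.build_basis(model)
        assert basis.n_modes == 2
        assert basis.unstable.sum() == 1
        assert np.all(basis.Omega >= 0)


class TestModeMasses:
    def test_uniform_noise_gives_site_mass(self):
        model = two_osc_model()
        basis = nv.build_basis(model)
        m = model.hbar / (2 * model.oscillators[0].D)
        assert np.allclose(nv.mode_masses(basis, model), m, rtol=1e-12)

    def test_weighted_sum_example(self):
        # m = (50, 100), v = (1/sqrt2, 1/sqrt2) -> M = 75
        v = np.array([[1 / math.sqrt(2)], [1 / math.sqrt(2)]])
        assert mode_masses_from(np.array([50.0, 100.0]), v)[0] == pytest.approx(75.0)

    def test_trace_identity(self):
        model = hetero_model(5, seed=7)
        basis = nv.build_basis(model)
        assert basis.M.sum() == pytest.approx(basis.masses.sum(), rel=1e-12)


class TestIsolatedModeFrequency:
    def test_uncoupled_equals_eigenfrequency(self, activated):
        model = nv.NetworkModel(
            (activated, activated.with_(D=0.02)), np.zeros((2, 2), complex)
        )
        basis = nv.build_basis(model)
        for ell in range(2):
            assert nv.isolated_mode_frequency(basis, model, ell) == pytest.approx(
                basis.Omega[ell], rel=1e-12
            )

    def test_heterogeneous_brute_force(self):
        model = hetero_model(3, seed=2)
        basis = nv.build_basis(model)
        for ell in range(3):
            v = basis.modes[:, ell]
            brute = math.sqrt(sum(basis.curvatures[j] * v[j] ** 2 for j in range(3))
                              / basis.M[ell])
            assert nv.isolated_mode_frequency(basis, model, ell) == pytest.approx(brute)


class TestProjection:
    def test_zero_fluctuation_zero_modes(self):
        model = two_osc_model()
        basis = nv.build_basis(model)
        r_e = nv.equilibrium_amplitude(model.oscillators[0])
        env = np.full((2, 512), r_e)
        rec = make_recording(model, env)
        traj = nv.project_recording(basis, model, rec)
        assert np.max(np.abs(traj.q)) < 1e-10

    def test_single_mode_excitation(self):
        model = hetero_model(3, seed=4, coupling=0.2)
        basis = nv.build_basis(model)
        # delta r along v^(1)/sqrt(m) excites only mode 1
        dr = (basis.modes[:, 1] / np.sqrt(basis.masses))[:, None] * np.ones((1, 256))
        q = basis.modes.T @ (np.sqrt(basis.masses)[:, None] * dr)
        assert np.allclose(q[1], 1.0, atol=1e-12)
        assert np.max(np.abs(q[[0, 2]])) < 1e-12

    def test_round_trip_identity(self):
        model = hetero_model(4, seed=5)
        basis = nv.build_basis(model)
        rng = np.random.default_rng(0)
        dr = rng.normal(0, 0.1, (4, 1000))
        q = basis.modes.T @ (np.sqrt(basis.masses)[:, None] * dr)
        back = nv.reconstruct_amplitudes(basis, model, q)
        assert np.max(np.abs(back - dr)) < 1e-10

    def test_channel_mismatch_error(self):
        model = two_osc_model()
        basis = nv.build_basis(model)
        rec = make_recording(hetero_model(3), np.ones((3, 128)))
        with pytest.raises(ValueError, match="channels"):
            nv.project_recording(basis, model, rec)


class TestOccupation:
    def test_analytic_harmonic_trajectory(self):
        model = nv.NetworkModel.single(nv.preset("activated"))
        basis = nv.build_basis(model)
        Omega, M, hbar = basis.Omega[0], basis.M[0], model.hbar
        A = 0.2
        fs = 512.0
        n_per = round(fs * 2 * np.pi / Omega)
        t = np.arange(20 * n_per) / fs
        q = A * np.cos(Omega * t)[None, :]
        p = (-M * Omega * A * np.sin(Omega * t))[None, :]
        traj = nv.ModeTrajectory(q=q, p=p, dt=1 / fs)
        raw, clipped = nv.mode_occupation(traj, basis, hbar)
        expected = 0.5 * M * Omega**2 * A**2 / (hbar * Omega) - 0.5
        assert raw[0] == pytest.approx(expected, rel=1e-3)
        # doubling A quadruples the energy
        traj4 = nv.ModeTrajectory(q=2 * q, p=2 * p, dt=1 / fs)
        raw4, _ = nv.mode_occupation(traj4, basis, hbar)
        assert raw4[0] + 0.5 == pytest.approx(4 * (raw[0] + 0.5), rel=1e-9)

    def test_empty_mode_floors_at_ground_state(self):
        model = nv.NetworkModel.single(nv.preset("activated"))
        basis = nv.build_basis(model)
        traj = nv.ModeTrajectory(q=np.zeros((1, 64)), p=np.zeros((1, 64)), dt=1 / 256)
        raw, clipped = nv.mode_occupation(traj, basis, 1.0)
        assert raw[0] == pytest.approx(-0.5)
        assert clipped[0] == 0.0


class TestEnergyReport:
    def test_real_coupling_gives_zero_coupling_term(self):
        model = two_osc_model()  # Im K = 0
        basis = nv.build_basis(model)
        rec = make_recording(model, np.full((2, 512), 1.5))
        rep = nv.energy_report(model, basis, rec)
        assert rep.coupling_term == 0.0
        assert rep.total == rep.amplitude_term + rep.phase_term + rep.coupling_term

    def test_aligned_phases_minimise_coupling_energy(self, activated):
        # J = -1/2 r_e^2 Im K > 0 requires Im K < 0
        K = np.array([[0, -2j], [-2j, 0]])
        model = nv.NetworkModel((activated, activated), K)
        basis = nv.build_basis(model)
        r_e = nv.equilibrium_amplitude(activated)
        env = np.full((2, 512), r_e)
        t = np.arange(512) / 256.0
        phases = np.tile(activated.omega * t, (2, 1))  # identical phases
        rec = make_recording(model, env, phases)
        rep = nv.energy_report(model, basis, rec)
        J = 0.5 * r_e * r_e * 2.0
        assert rep.coupling_term == pytest.approx(-J, rel=1e-9)

    def test_ground_state_amplitude_term(self):
        model = two_osc_model()
        basis = nv.build_basis(model)
        r_e = nv.equilibrium_amplitude(model.oscillators[0])
        rec = make_recording(model, np.full((2, 512), r_e))
        rep = nv.energy_report(model, basis, rec)
        assert rep.amplitude_term == pytest.approx(
            model.hbar * basis.Omega.sum() / 2, rel=1e-9
        )

    def test_total_invariant_under_channel_permutation(self):
        model = hetero_model(3, seed=9, coupling=0.4)
        basis = nv.build_basis(model)
        _, rec = nv.make_fixture("activated", 3, 0.3, seed=6, duration=4.0)
        # use the hetero model on the simulated envelopes for a generic input
        rec = nv.MultichannelRecording(fs=rec.fs, channels=rec.channels,
                                       data=rec.data, analytic=rec.analytic)
        rep = nv.energy_report(model, basis, rec)

        perm = [2, 0, 1]
        osc_p = tuple(model.oscillators[j] for j in perm)
        K_p = model.K[np.ix_(perm, perm)]
        model_p = nv.NetworkModel(osc_p, K_p, model.hbar)
        basis_p = nv.build_basis(model_p)
        rec_p = nv.MultichannelRecording(
            fs=rec.fs, channels=[rec.channels[j] for j in perm],
            data=rec.data[perm], analytic=rec.analytic[perm],
        )
        rep_p = nv.energy_report(model_p, basis_p, rec_p)
        assert rep_p.total == pytest.approx(rep.total, rel=1e-9)


class TestSimulatedModeDynamics:
    def test_mode_fluctuation_rate_matches_omega(self):
        """The projected mode autocorrelation decays at a rate matching the
        eigenfrequency Omega (which equals the amplitude relaxation rate
        2*lambda up to the noise correction); pilot-calibrated 25% band."""
        model, rec = nv.make_fixture("activated", 3, 0.0, seed=13, duration=60.0)
        basis = nv.build_basis(model)
        traj = nv.project_recording(basis, model, rec)
        q = traj.q[:, int(5 * 2048):]
        lag = int(0.1 * 2048)
        for ell in range(3):
            x = q[ell] - q[ell].mean()
            rho = (x[:-lag] * x[lag:]).mean() / x.var()
            rate = -math.log(rho) / 0.1
            assert abs(rate - basis.Omega[ell]) / basis.Omega[ell] < 0.25
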