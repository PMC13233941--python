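"""Neural-phonon normal modes of a Stuart-Landau network.

Expanding the network's effective amplitude Hamiltonian to second order
around the limit-cycle amplitudes r_e,j gives a mass-weighted dynamical
matrix

    Phi_jj = (V''(r_e,j) + sum_k S_jk) / m_j,      Phi_jk = -S_jk / sqrt(m_j m_k)

with site masses m_j = hbar / 2 D_j (s), amplitude-coupling matrix
S_jk = -Re K_jk (s^-1) and local curvature V''(r_e,j) = 2 hbar lambda^2/D
- 3 hbar zeta.  Its orthonormal eigenvectors v^(l) are the spatial patterns
of collective amplitude fluctuation ("neural phonons"), with eigenfrequency
Omega_l = sqrt(eigenvalue) and mode mass M_l = sum_j m_j (v_j^(l))^2.  The
mode count equals the channel count, so the amplitude field is exactly the
superposition r_j(t) = r_e,j + sum_l v_j^(l)/sqrt(m_j) q_l(t).

Energy accounting treats each mode as a quantised harmonic oscillator with
quanta hbar*Omega_l, estimating occupations classically from the projected
trajectory, and adds the phase (rotor) and Josephson-like cosine coupling
terms of the total neural Hamiltonian.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .simulator import MultichannelRecording, NetworkModel
from .sl_model import equilibrium_amplitude, potential_curvature

__all__ = [
    "PhononBasis",
    "ModeTrajectory",
    "EnergyReport",
    "build_basis",
    "mode_masses",
    "isolated_mode_frequency",
    "project_recording",
    "reconstruct_amplitudes",
    "mode_occupation",
    "energy_report",
]

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class PhononBasis:
    """Normal-mode decomposition of the quadratic amplitude Hamiltonian.

    ``modes`` holds orthonormal eigenvectors as columns; ``Omega`` is sorted
    ascending in Omega^2.  Negative Phi eigenvalues (harmonically unstable
    modes) are kept, flagged in ``unstable``, with Omega = sqrt(|Omega^2|)
    to be read as an imaginary frequency.
    """

    curvatures: np.ndarray  # V''(r_e,j), per channel
    masses: np.ndarray      # m_j = hbar/2D_j, s
    S: np.ndarray           # symmetric amplitude coupling, s^-1
    Phi: np.ndarray         # dynamical matrix, s^-2
    modes: np.ndarray       # columns v^(l), dimensionless
    omega_sq: np.ndarray    # Phi eigenvalues, s^-2 (signed)
    Omega: np.ndarray       # sqrt(|omega_sq|), rad/s
    M: np.ndarray           # mode masses, s
    unstable: np.ndarray    # bool flags, True where omega_sq < 0

    @property
    def n_modes(self) -> int:
        return self.Omega.size

    def to_dict(self) -> dict:
        return {
            "Omega_rad_s": self.Omega.tolist(),
            "omega_sq": self.omega_sq.tolist(),
            "mode_masses_s": self.M.tolist(),
            "site_masses_s": self.masses.tolist(),
            "curvatures": self.curvatures.tolist(),
            "unstable": self.unstable.astype(bool).tolist(),
        }


@dataclass
class ModeTrajectory:
    """Projected mode displacements q_l(t), momenta p_l(t) and occupations.

    ``occupation`` is clipped at the ground-state floor 0; the raw estimator
    value (which can dip to -1/2 for an empty mode) is kept in
    ``occupation_raw``.  Modes with Omega = 0 carry NaN occupation.
    """

    q: np.ndarray           # (N_modes, T)
    p: np.ndarray           # (N_modes, T), M_l dq/dt
    dt: float
    occupation: np.ndarray = field(default=None)  # type: ignore[assignment]
    occupation_raw: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class EnergyReport:
    """Three-term energy accounting of the total neural Hamiltonian.

    amplitude_term = sum_l hbar Omega_l (<n_l> + 1/2);
    phase_term     = sum_j (<p_phi,j>^2 / 2 I_j - f_phi(r_e,j) <p_phi,j>)
                     with rotor inertia I_j = m_j r_e,j^2;
    coupling_term  = -sum_{j<k} J_jk <cos(phi_j - phi_k)> with
                     J_jk = -1/2 r_e,j r_e,k Im K_jk.
    ``total`` is their exact sum.
    """

    amplitude_term: float
    phase_term: float
    coupling_term: float
    total: float
    occupations: np.ndarray

    def to_dict(self) -> dict:
        return {
            "amplitude_term": self.amplitude_term,
            "phase_term": self.phase_term,
            "coupling_term": self.coupling_term,
            "total": self.total,
            "occupations": [float(x) for x in self.occupations],
        }


def _fix_sign(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first component over 1e-12 made positive."""
    out = vecs.copy()
    for col in range(out.shape[1]):
        v = out[:, col]
        idx = np.argmax(np.abs(v) > 1e-12)
        if v[idx] < 0:
            out[:, col] = -v
    return out


def build_basis(model: NetworkModel) -> PhononBasis:
    """Assemble and diagonalise the dynamical matrix of the network.

    Every site must carry a limit cycle (lambda_j > 0) and noise (D_j > 0);
    otherwise the harmonic expansion point r_e,j or the mass m_j does not
    exist, and the offending channels are named in the error.
    """
    bad_lam = [j for j, p in enumerate(model.oscillators) if p.lambda_ <= 0]
    if bad_lam:
        raise ValueError(
            f"no limit cycle at channels {bad_lam} (lambda <= 0); "
            "phonon expansion requires lambda > 0 at every site"
        )
    bad_d = [j for j, p in enumerate(model.oscillators) if p.D <= 0]
    if bad_d:
        raise ValueError(
            f"infinite effective mass at channels {bad_d} (D = 0); "
            "phonon masses m = hbar/2D require D > 0"
        )
    hbar = model.hbar
    curv = np.array([potential_curvature(p, hbar) for p in model.oscillators])
    m = np.array([hbar / (2.0 * p.D) for p in model.oscillators])
    S = -model.K.real.copy()
    np.fill_diagonal(S, 0.0)

    n = model.n_channels
    Phi = -S / np.sqrt(np.outer(m, m))
    np.fill_diagonal(Phi, (curv + S.sum(axis=1)) / m)

    evals, evecs = np.linalg.eigh(Phi)
    order = np.argsort(evals, kind="stable")
    evals, evecs = evals[order], _fix_sign(evecs[:, order])
    unstable = evals < -_EIG_TOL
    Omega = np.sqrt(np.abs(evals))
    M = mode_masses_from(m, evecs)
    if np.any(unstable):
        warnings.warn(
            f"{int(unstable.sum())} harmonically unstable mode(s) "
            "(negative Phi eigenvalue); Omega entries flagged are imaginary",
            RuntimeWarning,
            stacklevel=2,
        )
    return PhononBasis(
        curvatures=curv, masses=m, S=S, Phi=Phi, modes=evecs,
        omega_sq=evals, Omega=Omega, M=M, unstable=unstable,
    )


def mode_masses_from(site_masses: np.ndarray, modes: np.ndarray) -> np.ndarray:
    """M_l = sum_j m_j (v_j^(l))^2 — collective inertia of each mode."""
    return (site_masses[:, None] * modes**2).sum(axis=0)


def mode_masses(basis: PhononBasis, model: NetworkModel) -> np.ndarray:
    return mode_masses_from(
        np.array([model.hbar / (2.0 * p.D) for p in model.oscillators]), basis.modes
    )


def isolated_mode_frequency(basis: PhononBasis, model: NetworkModel, ell: int) -> float:
    """Curvature-weighted average Omega_l^2 = (1/M_l) sum_j V''(r_e,j) (v_j^(l))^2.

    Equals the eigen-frequency exactly when the coupling S vanishes.
    """
    v = basis.modes[:, ell]
    return math.sqrt((basis.curvatures * v**2).sum() / basis.M[ell])


def _amplitude_envelope(recording: MultichannelRecording) -> np.ndarray:
    """Per-channel amplitude r_j(t): exact from the complex state if retained,
    else the Hilbert analytic envelope of the real data."""
    if recording.analytic is not None:
        return np.abs(recording.analytic)
    return np.abs(hilbert(recording.data, axis=1))


def project_recording(
    basis: PhononBasis,
    model: NetworkModel,
    recording: MultichannelRecording,
    hbar: float | None = None,
) -> ModeTrajectory:
    """Project amplitude fluctuations onto the phonon basis.

    q_l(t) = sum_j v_j^(l) sqrt(m_j) delta r_j(t) with
    delta r_j = r_j(t) - r_e,j; momenta p_l = M_l dq_l/dt by central
    differences.  The projection is exactly invertible
    (:func:`reconstruct_amplitudes`).
    """
    if recording.n_channels != model.n_channels:
        raise ValueError(
            f"recording has {recording.n_channels} channels but the model has "
            f"{model.n_channels}"
        )
    hbar = model.hbar if hbar is None else hbar
    r_e = np.array([equilibrium_amplitude(p) for p in model.oscillators])
    dr = _amplitude_envelope(recording) - r_e[:, None]
    sqm = np.sqrt(basis.masses)
    q = basis.modes.T @ (sqm[:, None] * dr)
    dt = 1.0 / recording.fs
    p = basis.M[:, None] * np.gradient(q, dt, axis=1)
    traj = ModeTrajectory(q=q, p=p, dt=dt)
    raw, clipped = mode_occupation(traj, basis, hbar)
    traj.occupation_raw, traj.occupation = raw, clipped
    return traj


def reconstruct_amplitudes(
    basis: PhononBasis, model: NetworkModel, q: np.ndarray
) -> np.ndarray:
    """Invert the projection: delta r_j(t) = sum_l v_j^(l)/sqrt(m_j) q_l(t)."""
    return (basis.modes / np.sqrt(basis.masses)[:, None]) @ q


def mode_occupation(
    mode_traj: ModeTrajectory, basis: PhononBasis, hbar: float
) -> tuple[np.ndarray, np.ndarray]:
    """Classical occupation estimate per mode: n = E_l / (hbar Omega_l) - 1/2.

    E_l = <p^2>/2M_l + M_l Omega_l^2 <q^2>/2 from time averages.  Returns
    ``(raw, clipped)``; zero-frequency modes are excluded (NaN) with a
    warning, and the clipped report floors the estimate at 0.
    """
    q2 = (mode_traj.q**2).mean(axis=1)
    p2 = (mode_traj.p**2).mean(axis=1)
    energy = p2 / (2.0 * basis.M) + 0.5 * basis.M * basis.Omega**2 * q2
    raw = np.full(basis.n_modes, np.nan)
    ok = basis.Omega > 0
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} zero-frequency mode(s) excluded from occupation",
            RuntimeWarning,
            stacklevel=2,
        )
    raw[ok] = energy[ok] / (hbar * basis.Omega[ok]) - 0.5
    return raw, np.where(np.isnan(raw), np.nan, np.clip(raw, 0.0, None))


def _phases(recording: MultichannelRecording) -> np.ndarray:
    if recording.analytic is not None:
        z = recording.analytic
    else:
        z = hilbert(recording.data, axis=1)
    return np.unwrap(np.angle(z), axis=1)


def energy_report(
    model: NetworkModel,
    basis: PhononBasis,
    recording: MultichannelRecording,
    mode_traj: ModeTrajectory | None = None,
) -> EnergyReport:
    """Evaluate the three terms of the total neural Hamiltonian on a recording.

    The phase-coupling strengths J_jk = -1/2 r_e,j r_e,k Im K_jk are
    evaluated at the equilibrium amplitudes; <cos(Delta phi)> is the time
    average over the recording (the real part of the complex phase-locking
    statistic).  Rotor momenta use p_phi,j = I_j <dphi_j/dt> from unwrapped
    phase differences.
    """
    hbar = model.hbar
    if mode_traj is None:
        mode_traj = project_recording(basis, model, recording)
    occ = mode_traj.occupation
    stable = ~basis.unstable & (basis.Omega > 0)
    amplitude_term = float(
        np.sum(hbar * basis.Omega[stable] * (occ[stable] + 0.5))
    )

    phi = _phases(recording)
    dphi = np.gradient(phi, 1.0 / recording.fs, axis=1).mean(axis=1)
    r_e = np.array([equilibrium_amplitude(p) for p in model.oscillators])
    inertia = basis.masses * r_e**2
    f_phi = np.array(
        [p.omega - p.chi * re**2 for p, re in zip(model.oscillators, r_e)]
    )
    p_phi = inertia * dphi
    phase_term = float(np.sum(p_phi**2 / (2.0 * inertia) - f_phi * p_phi))

    J = -0.5 * np.outer(r_e, r_e) * model.K.imag
    coupling_term = 0.0
    n = model.n_channels
    for j in range(n):
        for k in range(j + 1, n):
            if J[j, k] != 0.0:
                coupling_term -= J[j, k] * float(np.cos(phi[j] - phi[k]).mean())

    total = amplitude_term + phase_term + coupling_term
    return EnergyReport(
        amplitude_term=amplitude_term,
        phase_term=phase_term,
        coupling_term=float(coupling_term),
        total=total,
        occupations=occ,
    )
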