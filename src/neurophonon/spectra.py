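"""Closed-form spectral observables from the phonon basis.

Each phonon mode responds to its projected noise drive as a driven harmonic
oscillator, q''_l + Omega_l^2 q_l = eta_l(t), giving the Green's function
G_l(w) = (Omega_l^2 - w^2)^{-1} and (with flat drive spectrum 2*hbar) the
mode power spectral density

    S_ql(w) = 2 hbar / (Omega_l^2 - w^2)^2.

As printed this form has non-integrable poles at w = Omega_l; a per-mode
damping gamma regularises it to 2 hbar / ((Omega_l^2-w^2)^2 + gamma^2 w^2),
recovering the printed expression pointwise away from resonance as
gamma -> 0.  Channel cross-spectra, magnitude-squared coherence, envelope
(amplitude-amplitude) correlations, the linear phase-amplitude-coupling
slope 2*chi*r_e, and an optional 1/w background are derived from the same
mode sum.
"""

from __future__ import annotations

import math

import numpy as np

from .phonon import PhononBasis
from .simulator import NetworkModel
from .sl_model import OscillatorParams, equilibrium_amplitude

__all__ = [
    "SpectralResult",
    "default_gamma",
    "mode_psd",
    "cross_spectrum",
    "analytic_coherence",
    "analytic_aac",
    "pac_strength",
    "one_over_f_background",
    "spectral_result",
]

TWO_PI = 2.0 * math.pi


def default_gamma(model: NetworkModel) -> float:
    """Default damping: the linearised amplitude relaxation rate 2*lambda,
    averaged over sites (s^-1)."""
    return 2.0 * float(np.mean([p.lambda_ for p in model.oscillators]))


def mode_psd(
    basis: PhononBasis,
    hbar: float,
    freq_hz: np.ndarray,
    gamma: float | np.ndarray,
) -> np.ndarray:
    """Per-mode displacement PSD on a frequency grid (Hz); shape (N_modes, F).

    S_ql(w) = 2 hbar / ((Omega_l^2 - w^2)^2 + gamma_l^2 w^2), w = 2 pi f.
    ``gamma`` must be positive: the undamped form diverges at resonance.
    """
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if np.any(gamma <= 0):
        raise ValueError(
            "gamma must be > 0: the undamped mode PSD 2*hbar/(Omega^2-w^2)^2 "
            "diverges at resonance"
        )
    if gamma.size == 1:
        gamma = np.full(basis.n_modes, gamma[0])
    elif gamma.size != basis.n_modes:
        raise ValueError(f"gamma must be scalar or per-mode ({basis.n_modes})")
    f = np.asarray(freq_hz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency grid must be nonnegative")
    w = TWO_PI * f
    om2 = (basis.Omega**2)[:, None]
    g = gamma[:, None]
    return 2.0 * hbar / ((om2 - w[None, :] ** 2) ** 2 + g**2 * w[None, :] ** 2)


def cross_spectrum(
    basis: PhononBasis,
    model: NetworkModel,
    freq_hz: np.ndarray,
    gamma: float | np.ndarray | None = None,
    use_mode_masses: bool = False,
) -> np.ndarray:
    """Channel cross-spectral matrix S_jk(w) = sum_l v_j^(l) v_k^(l)/sqrt(m_j m_k) S_ql(w).

    Returns shape (N, N, F); real, symmetric and positive semidefinite at
    every frequency (it is a sum of rank-1 outer products with nonnegative
    weights).  Site masses m_j are used in the 1/sqrt(m_j m_k) weight by
    default; ``use_mode_masses`` switches to the mode masses M_l reading.
    """
    if gamma is None:
        gamma = default_gamma(model)
    sq = mode_psd(basis, model.hbar, freq_hz, gamma)  # (L, F)
    if use_mode_masses:
        w = basis.modes / np.sqrt(basis.M)[None, :]  # v_j^(l)/sqrt(M_l)
        return np.einsum("jl,kl,lf->jkf", w, basis.modes, sq)
    w = basis.modes / np.sqrt(basis.masses)[:, None]  # v_j^(l)/sqrt(m_j)
    return np.einsum("jl,kl,lf->jkf", w, w, sq)


def analytic_coherence(S: np.ndarray) -> np.ndarray:
    """Magnitude-squared coherence rho_jk(w) = |S_jk|^2 / (S_jj S_kk), in [0, 1].

    Entries whose autospectra vanish are masked as NaN rather than
    propagated; the diagonal is 1 wherever S_jj > 0.
    """
    S = np.asarray(S)
    diag = np.einsum("jjf->jf", S).real  # (N, F)
    denom = diag[:, None, :] * diag[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.abs(S) ** 2 / denom
    rho = np.where(denom > 0, rho, np.nan)
    return np.clip(rho, 0.0, 1.0, out=rho, where=~np.isnan(rho))


def analytic_aac(
    basis: PhononBasis,
    model: NetworkModel,
    q2: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Envelope-correlation matrix predicted by shared phonon loadings.

    Raw quantity: sum_l v_j^(l) v_k^(l) / (m_j m_k) <q_l^2>, with the
    zero-point default <q_l^2> = hbar / (2 M_l Omega_l) unless ``q2`` (e.g.
    estimated from a projected trajectory) is supplied.  Returns
    ``(raw, normalised)`` where the normalised matrix has unit diagonal
    (a correlation must live in [-1, 1]).
    """
    if q2 is None:
        ok = basis.Omega > 0
        q2 = np.zeros(basis.n_modes)
        q2[ok] = model.hbar / (2.0 * basis.M[ok] * basis.Omega[ok])
    q2 = np.asarray(q2, dtype=float)
    raw = np.einsum("jl,kl,l->jk", basis.modes, basis.modes, q2) / np.outer(
        basis.masses, basis.masses
    )
    d = np.sqrt(np.diag(raw))
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = raw / np.outer(d, d)
    norm = np.where(np.outer(d, d) > 0, norm, 0.0)
    np.fill_diagonal(norm, np.where(d > 0, 1.0, 0.0))
    return raw, norm


def pac_strength(params: OscillatorParams, r_e: float | None = None) -> float:
    """Linear phase-amplitude-coupling slope 2 chi r_e.

    First-order expansion of the phase velocity around the limit cycle,
    dphi/dt ~ omega - chi r_e^2 - 2 chi r_e q(t): the coefficient coupling
    the amplitude fluctuation q to the phase velocity.  Zero iff chi = 0
    (amplitude and phase decoupled).
    """
    if r_e is None:
        if params.lambda_ <= 0:
            raise ValueError("pac_strength requires lambda > 0 (limit cycle)")
        r_e = equilibrium_amplitude(params)
    return 2.0 * params.chi * r_e


def one_over_f_background(amplitude: float, freq_hz: np.ndarray) -> np.ndarray:
    """Additive 1/w broadband background, amplitude / (2 pi f).

    Models the high-temperature Bose-Einstein occupation n ~ kT/(hbar w) of
    many incoherent background modes.  amplitude = 0 disables (returns
    zeros); bins at f = 0 are masked as NaN.
    """
    if amplitude < 0:
        raise ValueError(f"background amplitude must be >= 0, got {amplitude}")
    f = np.asarray(freq_hz, dtype=float)
    if amplitude == 0.0:
        return np.zeros_like(f)
    with np.errstate(divide="ignore"):
        out = amplitude / (TWO_PI * f)
    return np.where(f > 0, out, np.nan)


class SpectralResult:
    """Bundle of analytic spectra on a common frequency grid."""

    def __init__(
        self,
        freq_hz: np.ndarray,
        mode_psd: np.ndarray,
        cross: np.ndarray,
        coherence: np.ndarray,
        gamma: np.ndarray,
        background_amp: float = 0.0,
    ) -> None:
        self.freq = np.asarray(freq_hz, dtype=float)
        self.mode_psd = mode_psd
        self.cross = cross
        self.coherence = coherence
        self.gamma = gamma
        self.background_amp = background_amp


def spectral_result(
    basis: PhononBasis,
    model: NetworkModel,
    freq_hz: np.ndarray,
    gamma: float | np.ndarray | None = None,
    background_amp: float = 0.0,
) -> SpectralResult:
    """Compute mode PSDs, cross-spectra and coherence in one pass."""
    if gamma is None:
        gamma = default_gamma(model)
    g = np.atleast_1d(np.asarray(gamma, dtype=float))
    sq = mode_psd(basis, model.hbar, freq_hz, gamma)
    if background_amp:
        sq = sq + one_over_f_background(background_amp, freq_hz)[None, :]
    cross = cross_spectrum(basis, model, freq_hz, gamma)
    coh = analytic_coherence(cross)
    return SpectralResult(freq_hz, sq, cross, coh,
                          g if g.size == basis.n_modes else np.full(basis.n_modes, g[0]),
                          background_amp)
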