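"""Closed-form single Stuart-Landau oscillator quantities.

The Stuart-Landau (SL) oscillator is the normal form of a Hopf bifurcation,

    dz/dt = (lambda + i omega) z - (zeta + i chi) |z|^2 z + eta(t),

with complex state z = r e^{i phi} (microvolts), linear growth rate ``lambda``
(s^-1), nonlinear saturation ``zeta`` (uV^-2 s^-1), amplitude-phase coupling
``chi`` (uV^-2 s^-1), intrinsic angular frequency ``omega`` (rad/s) and
complex white noise of intensity ``D`` (uV^2/s) with autocorrelation
<eta(t) eta*(t')> = 2 D delta(t - t').

This module provides the noiseless closed-form trajectory, the drift
potential U(r) of the radial Fokker-Planck equation, the effective
("quantum") potential V(r) obtained from the similarity transform
P = psi exp(-U/2D) that maps the radial FPE onto an imaginary-time
Schroedinger operator, the stationary Boltzmann density exp(-U/D) and its
Shannon entropy, and the curvature V''(r_e) that seeds the phonon normal-mode
analysis of a coupled network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "OscillatorParams",
    "PolarState",
    "PRESETS",
    "preset",
    "preset_names",
    "equilibrium_amplitude",
    "deterministic_trajectory",
    "drift_potential",
    "quantum_potential",
    "potential_curvature",
    "stationary_density",
    "stationary_entropy",
    "default_r_grid",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class OscillatorParams:
    """Per-channel SL parameters (lambda, zeta, chi, omega, D).

    ``omega`` is angular (rad/s) internally; use :meth:`from_dict` /
    :meth:`to_dict` for the Hz interface convention.
    """

    lambda_: float
    zeta: float
    chi: float
    omega: float
    D: float

    def __post_init__(self) -> None:
        vals = (self.lambda_, self.zeta, self.chi, self.omega, self.D)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"all SL parameters must be finite, got {vals}")
        if self.zeta <= 0:
            raise ValueError(f"zeta must be > 0 (nonlinear saturation), got {self.zeta}")
        if self.D < 0:
            raise ValueError(f"noise intensity D must be >= 0, got {self.D}")

    @property
    def omega_hz(self) -> float:
        return self.omega / TWO_PI

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "OscillatorParams":
        """Build from a config mapping; accepts ``omega_hz`` or ``omega`` (rad/s)."""
        if "omega_hz" in d:
            omega = TWO_PI * float(d["omega_hz"])
        else:
            omega = float(d["omega"])
        return cls(
            lambda_=float(d["lambda"]),
            zeta=float(d["zeta"]),
            chi=float(d["chi"]),
            omega=omega,
            D=float(d["D"]),
        )

    def to_dict(self) -> dict:
        return {
            "lambda": self.lambda_,
            "zeta": self.zeta,
            "chi": self.chi,
            "omega_hz": self.omega_hz,
            "D": self.D,
        }

    def with_(self, **kw) -> "OscillatorParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PolarState:
    """Amplitude (uV, >= 0) and phase (rad) of the complex oscillator state."""

    r: float
    phi: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"amplitude r must be >= 0, got {self.r}")

    @property
    def z(self) -> complex:
        return self.r * complex(math.cos(self.phi), math.sin(self.phi))


# Archetypal cognitive regimes (lambda, zeta, chi, D); the intrinsic frequency
# is the alpha-band value 10 Hz used throughout the simulated examples.
_ALPHA_OMEGA = TWO_PI * 10.0

PRESETS: dict[str, OscillatorParams] = {
    "activated": OscillatorParams(2.0, 1.0, 0.8, _ALPHA_OMEGA, 0.010),
    "suppressed": OscillatorParams(-0.5, 1.0, 0.2, _ALPHA_OMEGA, 0.005),
    "exploratory": OscillatorParams(0.5, 5.0, 1.2, _ALPHA_OMEGA, 0.050),
}


def preset_names() -> tuple[str, ...]:
    return tuple(PRESETS)


def preset(name: str, omega_hz: float | None = None) -> OscillatorParams:
    """Return the named regime preset, optionally overriding the frequency."""
    try:
        p = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown regime {name!r}; valid regimes: {sorted(PRESETS)}"
        ) from None
    if omega_hz is not None:
        p = p.with_(omega=TWO_PI * omega_hz)
    return p


def equilibrium_amplitude(params: OscillatorParams) -> float:
    """Equilibrium (limit-cycle) amplitude r_e = sqrt(lambda/zeta), 0 if lambda <= 0.

    A non-positive growth rate is a valid quiescent regime without a limit
    cycle, not an error.
    """
    if params.lambda_ <= 0:
        return 0.0
    return math.sqrt(params.lambda_ / params.zeta)


def deterministic_trajectory(
    params: OscillatorParams,
    r0: float,
    phi0: float,
    t_grid: Iterable[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Exact noiseless amplitude and phase trajectory on ``t_grid``.

    For lambda != 0,

        r(t)   = r0 e^{lambda t} / sqrt(g(t)),   g(t) = 1 + (zeta r0^2/lambda)(e^{2 lambda t} - 1)
        phi(t) = phi0 + omega t - (chi / 2 zeta) ln g(t)

    which for lambda > 0 is the textbook relaxation onto r_e = sqrt(lambda/zeta).
    The lambda = 0 bifurcation point is the removable limit
    g(t) -> 1 + 2 zeta r0^2 t.  The instantaneous frequency relaxes to
    omega - chi*lambda/zeta when lambda > 0.

    Returns ``(r, phi)`` arrays; phi is unwrapped (cumulative).
    """
    if r0 <= 0:
        raise ValueError(f"initial amplitude r0 must be > 0, got {r0}")
    t = np.asarray(list(t_grid) if not isinstance(t_grid, np.ndarray) else t_grid,
                   dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) < 0)):
        raise ValueError("t_grid must be a 1-D nondecreasing array")
    lam, zeta, chi, omega = params.lambda_, params.zeta, params.chi, params.omega
    if lam == 0.0:
        g = 1.0 + 2.0 * zeta * r0**2 * t
        r = r0 / np.sqrt(g)
    else:
        g = 1.0 + (zeta * r0**2 / lam) * np.expm1(2.0 * lam * t)
        r = r0 * np.exp(lam * t) / np.sqrt(g)
    phi = phi0 + omega * t - (chi / (2.0 * zeta)) * np.log(g)
    return r, phi


def drift_potential(params: OscillatorParams, r) -> np.ndarray | float:
    """Radial drift potential U(r) = -1/2 lambda r^2 + 1/4 zeta r^4.

    U is the integral of minus the radial drift f_r = lambda r - zeta r^3;
    its minimum sits at r_e when lambda > 0 with depth -lambda^2/(4 zeta).
    """
    r = np.asarray(r, dtype=float)
    out = -0.5 * params.lambda_ * r**2 + 0.25 * params.zeta * r**4
    return out if out.ndim else float(out)


def quantum_potential(params: OscillatorParams, hbar: float, r) -> np.ndarray | float:
    """Effective potential of the imaginary-time Schroedinger operator.

        V(r) = (hbar/2) [ lambda - 3 zeta r^2 + (1/2D)(lambda - zeta r^2)^2 r^2 ]

    a sixth-order even polynomial in r.  The deterministic limit D = 0 has no
    V (the similarity transform divides by D), so D must be positive.
    """
    if params.D <= 0:
        raise ValueError("quantum potential requires D > 0 (deterministic limit has no V)")
    if hbar <= 0:
        raise ValueError(f"hbar must be > 0, got {hbar}")
    r = np.asarray(r, dtype=float)
    lam, zeta, D = params.lambda_, params.zeta, params.D
    out = 0.5 * hbar * (
        lam - 3.0 * zeta * r**2 + (lam - zeta * r**2) ** 2 * r**2 / (2.0 * D)
    )
    return out if out.ndim else float(out)


def potential_curvature(params: OscillatorParams, hbar: float) -> float:
    """Curvature of V at the limit-cycle amplitude, V''(r_e) = 2 hbar lambda^2/D - 3 hbar zeta.

    Requires lambda > 0 (the formula is evaluated at r_e = sqrt(lambda/zeta),
    which does not exist otherwise) and D > 0.
    """
    if params.lambda_ <= 0:
        raise ValueError(
            f"no limit cycle for lambda={params.lambda_} <= 0; curvature at r_e undefined"
        )
    if params.D <= 0:
        raise ValueError("potential curvature requires D > 0")
    if hbar <= 0:
        raise ValueError(f"hbar must be > 0, got {hbar}")
    return 2.0 * hbar * params.lambda_**2 / params.D - 3.0 * hbar * params.zeta


def default_r_grid(params: OscillatorParams, n: int = 4096) -> np.ndarray:
    """Amplitude grid [0, r_max] covering the support of exp(-U/D).

    r_max = max(3 r_e, 6 sqrt(D/|lambda|), 1) for lambda != 0; fallback 10 uV
    at the bifurcation point where neither scale exists.
    """
    if params.lambda_ != 0.0:
        r_e = equilibrium_amplitude(params)
        spread = math.sqrt(params.D / abs(params.lambda_)) if params.D > 0 else 0.0
        r_max = max(3.0 * r_e, 6.0 * spread, 1.0)
    else:
        r_max = 10.0
    return np.linspace(0.0, r_max, n)


def stationary_density(
    params: OscillatorParams, r_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary Boltzmann density P_s(r) = N^-1 exp(-U(r)/D) on the grid.

    Returns ``(r_grid, density)``; the density is trapezoid-normalised to
    integrate to 1 on the grid.
    """
    if params.D <= 0:
        raise ValueError("stationary density requires D > 0")
    if r_grid is None:
        r_grid = default_r_grid(params)
    r = np.asarray(r_grid, dtype=float)
    if r.ndim != 1 or r.size < 8:
        raise ValueError("r_grid must be a 1-D array with at least 8 points")
    u = drift_potential(params, r)
    logp = -(u - u.min()) / params.D  # shift for overflow safety
    p = np.exp(logp)
    norm = np.trapezoid(p, r)
    return r, p / norm


def stationary_entropy(
    params: OscillatorParams, r_grid: np.ndarray | None = None
) -> float:
    """Differential Shannon entropy -int P_s ln P_s dr of the stationary density, nats.

    Cross-checked internally against the algebraically equivalent form
    <U>/D + ln N (Boltzmann identity); the two quadratures must agree to 1e-6.
    """
    r, p = stationary_density(params, r_grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = np.where(p > 0, p * np.log(p), 0.0)
    h_direct = -np.trapezoid(integrand, r)

    # identity route: P_s = exp(-U/D)/N  =>  H = <U>/D + ln N
    u = drift_potential(params, r)
    n_const = np.trapezoid(np.exp(-(u - u.min()) / params.D), r)
    log_norm = math.log(n_const) - u.min() / params.D
    mean_u = np.trapezoid(u * p, r)
    h_identity = mean_u / params.D + log_norm
    if not math.isclose(h_direct, h_identity, rel_tol=1e-6, abs_tol=1e-6):
        raise ArithmeticError(
            f"entropy identity violated: direct={h_direct}, <U>/D+lnN={h_identity}; "
            "grid likely under-resolves the density"
        )
    return h_direct
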