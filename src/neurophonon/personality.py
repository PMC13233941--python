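"""The neural personality map: regime classification from model coordinates.

Five quantities span the map: the growth-to-damping ratio lambda/zeta (which
sets the equilibrium amplitude), the phonon eigenfrequencies Omega, the
noise intensity D (which sets the phonon mass hbar/2D), the amplitude-phase
coupling chi (which sets PAC strength), and the coupling matrix K summarised
by mean |Re K|, mean |Im K| and its spectral radius.  Archetypal regions of
this space are labelled by deterministic threshold rules; coordinates that
fall outside every rule region are reported as "unclassified" rather than
snapped to a nearest label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import NetworkModel

__all__ = [
    "PersonalityCoordinates",
    "ClassificationThresholds",
    "DEFAULT_THRESHOLDS",
    "coordinates_from_model",
    "classify_personality",
    "LABELS",
]

LABELS = (
    "suppressed",
    "activated",
    "exploratory",
    "drowsy/transitional",
    "hypercoherent/overload",
    "fragmented",
    "unclassified",
)


@dataclass(frozen=True)
class PersonalityCoordinates:
    """Network-averaged coordinates in the five-parameter personality space."""

    ratio: float            # lambda/zeta, uV^2
    omega_mean: float       # mean phonon eigenfrequency, rad/s (0 if unknown)
    omega_spread: float     # std of eigenfrequencies, rad/s
    D: float                # uV^2/s
    chi: float              # uV^-2 s^-1
    k_mean_re: float        # mean |Re K| off-diagonal, s^-1
    k_mean_im: float        # mean |Im K| off-diagonal, s^-1
    k_spectral_radius: float


@dataclass(frozen=True)
class ClassificationThresholds:
    """Documented decision thresholds; defaults separate the three presets."""

    high_ratio: float = 1.0       # "high lambda/zeta" at >= 1 uV^2
    low_d: float = 0.02           # "low D" below 0.02 uV^2/s
    very_low_d: float = 0.002
    high_chi: float = 0.5
    very_high_chi: float = 1.5
    low_chi: float = 0.3
    strong_k: float = 0.5         # mean |K| >= 0.5 s^-1
    weak_k: float = 0.1

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


DEFAULT_THRESHOLDS = ClassificationThresholds()


def coordinates_from_model(
    model: NetworkModel, Omega: np.ndarray | None = None
) -> PersonalityCoordinates:
    """Summarise a network model (and optionally its phonon frequencies)."""
    lam = np.array([p.lambda_ for p in model.oscillators])
    zet = np.array([p.zeta for p in model.oscillators])
    chi = np.array([p.chi for p in model.oscillators])
    D = np.array([p.D for p in model.oscillators])
    n = model.n_channels
    off = ~np.eye(n, dtype=bool)
    if n > 1:
        k_re = float(np.abs(model.K.real[off]).mean())
        k_im = float(np.abs(model.K.imag[off]).mean())
        k_rad = float(np.max(np.abs(np.linalg.eigvals(model.K))))
    else:
        k_re = k_im = k_rad = 0.0
    if Omega is None:
        om_mean = om_spread = 0.0
    else:
        om_mean = float(np.mean(Omega))
        om_spread = float(np.std(Omega))
    return PersonalityCoordinates(
        ratio=float(np.mean(lam / zet)),
        omega_mean=om_mean,
        omega_spread=om_spread,
        D=float(np.mean(D)),
        chi=float(np.mean(chi)),
        k_mean_re=k_re,
        k_mean_im=k_im,
        k_spectral_radius=k_rad,
    )


def classify_personality(
    coords: PersonalityCoordinates,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Deterministic rule-based label for a point in the personality map.

    Rules, evaluated in order:

    1. suppressed            — ratio < 0 (no limit cycle anywhere on average)
    2. hypercoherent/overload— very low D and very high chi
    3. activated             — high ratio, low D, high chi, strong coupling
    4. exploratory           — moderate ratio (0 < ratio < high) and high D
    5. fragmented            — high D, low chi, weak coupling
    6. drowsy/transitional   — moderate ratio, intermediate D, low chi
    7. unclassified          — anything else
    """
    t = thresholds
    k_mean = max(coords.k_mean_re, coords.k_mean_im)
    if coords.ratio < 0:
        return "suppressed"
    if coords.D < t.very_low_d and coords.chi >= t.very_high_chi:
        return "hypercoherent/overload"
    if (
        coords.ratio >= t.high_ratio
        and coords.D < t.low_d
        and coords.chi >= t.high_chi
        and k_mean >= t.strong_k
    ):
        return "activated"
    if 0 < coords.ratio < t.high_ratio and coords.D >= t.low_d:
        return "exploratory"
    if coords.D >= t.low_d and coords.chi < t.low_chi and k_mean < t.weak_k:
        return "fragmented"
    if (
        0 < coords.ratio < t.high_ratio
        and t.very_low_d <= coords.D < t.low_d
        and coords.chi < t.high_chi
    ):
        return "drowsy/transitional"
    return "unclassified"
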