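"""Empirical EEG observables from multichannel recordings.

Band-limited complex analytic signals z_j^(b)(t) are obtained by a 4th-order
zero-phase Butterworth band-pass followed by the Hilbert transform; |z| is
the envelope, arg z the instantaneous phase.  From these the standard
connectivity measures are computed:

* AAC  — envelope-envelope product series and Pearson correlation,
* PAC  — |z^(b')| cos(arg z^(b)) series, its mean, and the correlation of
         the fast envelope with the slow rhythm's phase velocity,
* PLV  — |<exp(i Delta phi)>_t| in [0, 1],
* coherence — |<z_i z_j*>| / sqrt(<|z_i|^2><|z_j|^2>) in [0, 1],
* coherence entropy — Shannon entropy of the normalised pairwise coherence
  distribution (nats),

plus Welch PSDs (2 s Hann windows, 50% overlap, one-sided density) and
band-integrated power.  Circular time-shift surrogates provide null bands
for the "indistinguishable from chance" claims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .simulator import MultichannelRecording

__all__ = [
    "BandDefinition",
    "BANDS",
    "analytic_band_signal",
    "edge_trim_samples",
    "welch_psd",
    "band_power",
    "aac",
    "pac",
    "plv",
    "plv_matrix",
    "coherence_matrix",
    "coherence_entropy",
    "surrogate_null",
]


@dataclass(frozen=True)
class BandDefinition:
    """Named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"band requires 0 < f_lo < f_hi, got {self}")

    def validate_fs(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.f_hi} Hz is at or above "
                f"Nyquist {fs / 2} Hz"
            )


# Conventional EEG activity bands; alpha is the 8-13 Hz convention used for
# alpha-power integration.
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 45.0),
}


def _as_band(band: BandDefinition | str | tuple) -> BandDefinition:
    if isinstance(band, BandDefinition):
        return band
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise KeyError(f"unknown band {band!r}; valid: {sorted(BANDS)}") from None
    lo, hi = band
    return BandDefinition(f"{lo}-{hi}Hz", float(lo), float(hi))


def edge_trim_samples(band: BandDefinition | str | tuple, fs: float) -> int:
    """Samples to drop at each end of a filtered signal: six time-constants
    of the band's lower corner, 6 fs / f_lo (covers the zero-phase filter
    transient and Hilbert-transform edge leakage)."""
    b = _as_band(band)
    return int(round(6.0 * fs / b.f_lo))


def analytic_band_signal(
    recording: MultichannelRecording,
    band: BandDefinition | str | tuple,
    trim: bool = False,
) -> np.ndarray:
    """Complex band-limited analytic signals, shape (N, T).

    Zero-phase (forward-backward) 4th-order Butterworth band-pass, then the
    Hilbert transform per channel.  ``trim=True`` removes
    :func:`edge_trim_samples` from each end to discard filter transients.
    """
    b = _as_band(band)
    b.validate_fs(recording.fs)
    sos = sps.butter(4, [b.f_lo, b.f_hi], btype="bandpass", fs=recording.fs,
                     output="sos")
    x = sps.sosfiltfilt(sos, recording.data, axis=1)
    z = sps.hilbert(x, axis=1)
    if trim:
        k = edge_trim_samples(b, recording.fs)
        if 2 * k >= z.shape[1]:
            raise ValueError(
                f"recording too short to trim {k} samples per edge in band {b.name}"
            )
        z = z[:, k:-k]
    return z


def welch_psd(
    recording: MultichannelRecording,
    window_seconds: float = 2.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD per channel (Hann windows).

    Returns ``(freq_hz, psd)`` with psd shape (N, F) in uV^2/Hz.  The
    recording must hold at least two overlapping windows.
    """
    nperseg = int(round(window_seconds * recording.fs))
    noverlap = int(round(overlap * nperseg))
    min_len = nperseg + (nperseg - noverlap)
    if recording.n_samples < min_len:
        raise ValueError(
            f"recording too short for Welch ({recording.n_samples} samples; "
            f"need at least {min_len} = two {window_seconds} s windows at "
            f"{int(100 * overlap)}% overlap)"
        )
    freq, psd = sps.welch(
        recording.data, fs=recording.fs, window="hann", nperseg=nperseg,
        noverlap=noverlap, detrend="constant", scaling="density", axis=1,
    )
    return freq, psd


def band_power(
    freq_hz: np.ndarray, psd: np.ndarray, band: BandDefinition | str | tuple
) -> np.ndarray:
    """Trapezoidal integral of the PSD over the band, per channel (uV^2).

    Band edges falling between grid points are handled by linear
    interpolation so a constant PSD c integrates exactly to c*(f_hi-f_lo).
    """
    b = _as_band(band)
    f = np.asarray(freq_hz, dtype=float)
    p = np.atleast_2d(np.asarray(psd, dtype=float))
    lo = max(b.f_lo, f[0])
    hi = min(b.f_hi, f[-1])
    if hi <= lo:
        return np.zeros(p.shape[0])
    inside = (f > lo) & (f < hi)
    grid = np.concatenate(([lo], f[inside], [hi]))
    out = np.empty(p.shape[0])
    for j in range(p.shape[0]):
        vals = np.concatenate(
            ([np.interp(lo, f, p[j])], p[j, inside], [np.interp(hi, f, p[j])])
        )
        out[j] = np.trapezoid(vals, grid)
    return out


def aac(z1: np.ndarray, z2: np.ndarray) -> dict:
    """Amplitude-amplitude coupling between two band signals.

    Returns the pointwise envelope product series |z1||z2| and the Pearson
    correlation of the two envelopes as the association summary.
    """
    z1 = np.asarray(z1).ravel()
    z2 = np.asarray(z2).ravel()
    if z1.shape != z2.shape:
        raise ValueError("signals must have equal length")
    a1, a2 = np.abs(z1), np.abs(z2)
    if a1.std() == 0 or a2.std() == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(a1, a2)[0, 1])
    return {"series": a1 * a2, "corr": corr}


def pac(
    z_phase: np.ndarray,
    z_amp: np.ndarray,
    fs: float,
    phase_band: BandDefinition | str | tuple | None = None,
    amp_band: BandDefinition | str | tuple | None = None,
    phase_velocity_smooth_s: float = 0.0,
) -> dict:
    """Phase-amplitude coupling of a fast envelope by a slow rhythm's phase.

    Series: PAC(t) = |z_amp(t)| cos(arg z_phase(t)).  Summaries: the mean
    of the series, and the Pearson correlation between the fast envelope
    and the slow rhythm's phase velocity (the estimator the model's chi
    mechanism predicts to be nonzero).  The sample-wise phase velocity of a
    noisy rhythm is white-noise dominated; ``phase_velocity_smooth_s``
    applies a moving average of that length (s) before correlating, which
    concentrates the estimator on the slow amplitude-fluctuation band.  If
    both bands are given, the phase band must not lie above the amplitude
    band (b == b' self-coupling of a single rhythm is allowed).
    """
    if phase_band is not None and amp_band is not None:
        bp, ba = _as_band(phase_band), _as_band(amp_band)
        if bp.f_lo > ba.f_lo:
            raise ValueError(
                f"phase band {bp.name} lies above amplitude band {ba.name}; "
                "the phase source must be the slower rhythm"
            )
    z_phase = np.asarray(z_phase).ravel()
    z_amp = np.asarray(z_amp).ravel()
    if z_phase.shape != z_amp.shape:
        raise ValueError("signals must have equal length")
    env = np.abs(z_amp)
    phase = np.unwrap(np.angle(z_phase))
    series = env * np.cos(np.angle(z_phase))
    phase_vel = np.gradient(phase) * fs
    if phase_velocity_smooth_s > 0:
        k = max(int(round(phase_velocity_smooth_s * fs)), 1)
        phase_vel = uniform_filter1d(phase_vel, k)
    if env.std() == 0 or phase_vel.std() == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(env, phase_vel)[0, 1])
    return {
        "series": series,
        "mean": float(series.mean()),
        "phase_velocity_corr": corr,
        "strength": abs(corr),
    }


def plv(
    z1: np.ndarray, z2: np.ndarray, return_excluded: bool = False
) -> float | tuple[float, int]:
    """Phase-locking value |<exp(i(phi1 - phi2))>_t| in [0, 1].

    Samples where either signal has zero amplitude carry no phase and are
    excluded; ``return_excluded=True`` also reports their count.
    """
    z1 = np.asarray(z1).ravel()
    z2 = np.asarray(z2).ravel()
    if z1.shape != z2.shape:
        raise ValueError("signals must have equal length")
    ok = (np.abs(z1) > 0) & (np.abs(z2) > 0)
    n_excluded = int((~ok).sum())
    if not np.any(ok):
        raise ValueError("no samples with defined phase in both signals")
    dphi = np.angle(z1[ok]) - np.angle(z2[ok])
    value = float(np.abs(np.exp(1j * dphi).mean()))
    return (value, n_excluded) if return_excluded else value


def plv_matrix(zb: np.ndarray) -> np.ndarray:
    """Pairwise PLV matrix of band signals (N, T): symmetric, unit diagonal."""
    zb = np.asarray(zb)
    n = zb.shape[0]
    out = np.eye(n)
    for j in range(n):
        for k in range(j + 1, n):
            out[j, k] = out[k, j] = plv(zb[j], zb[k])
    return out


def coherence_matrix(zb: np.ndarray) -> np.ndarray:
    """Pairwise coherence |<z_i z_j*>| / sqrt(<|z_i|^2><|z_j|^2>) in [0, 1].

    The expectation is the whole-epoch time average.  Zero-power channels
    are masked (NaN row/column); valid diagonal entries are exactly 1.
    """
    zb = np.asarray(zb)
    if zb.ndim != 2 or zb.shape[0] < 2:
        raise ValueError("need a (N>=2, T) array of band signals")
    T = zb.shape[1]
    cross = (zb @ zb.conj().T) / T
    power = np.real(np.diag(cross))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.abs(cross) / np.sqrt(np.outer(power, power))
    rho[power == 0, :] = np.nan
    rho[:, power == 0] = np.nan
    np.clip(rho, 0.0, 1.0, out=rho, where=~np.isnan(rho))
    return rho


def coherence_entropy(
    rho: np.ndarray, include_diagonal: bool = False
) -> float:
    """Shannon entropy (nats) of the normalised pairwise coherence distribution.

    By default the sum runs over off-diagonal unordered pairs (the unit
    self-coherence diagonal would otherwise dominate the distribution);
    ``include_diagonal=True`` gives the literal all-(i, j) reading.  NaN
    (masked) entries are excluded.  Maximum is ln(#terms) for a uniform
    distribution; an all-zero matrix has no distribution and errors.
    """
    rho = np.asarray(rho, dtype=float)
    if include_diagonal:
        iu = np.triu_indices(rho.shape[0], k=0)
    else:
        iu = np.triu_indices(rho.shape[0], k=1)
    vals = rho[iu]
    vals = vals[~np.isnan(vals)]
    total = vals.sum()
    if vals.size == 0 or total <= 0:
        raise ValueError("coherence entropy undefined: no positive entries")
    p = vals / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return float(-terms.sum())


def surrogate_null(
    statistic,
    z1: np.ndarray,
    z2: np.ndarray,
    n_surrogates: int = 200,
    seed: int = 0,
    quantile: float = 0.95,
) -> tuple[float, np.ndarray]:
    """Circular time-shift surrogate null for a pairwise statistic.

    ``statistic(z1, z2) -> float`` is evaluated with z2 circularly shifted
    by random offsets in [0.05 T, 0.95 T]; returns the ``quantile`` of the
    null distribution together with the draws.
    """
    rng = np.random.default_rng(seed)
    z2 = np.asarray(z2).ravel()
    T = z2.size
    lo, hi = int(0.05 * T), int(0.95 * T)
    draws = np.empty(n_surrogates)
    for i in range(n_surrogates):
        shift = int(rng.integers(lo, max(hi, lo + 1)))
        draws[i] = statistic(z1, np.roll(z2, shift))
    return float(np.quantile(draws, quantile)), draws
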