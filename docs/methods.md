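# Methods

## Model

The package models each EEG channel as a stochastic Stuart–Landau (SL)
oscillator — the normal form of a supercritical Hopf bifurcation with a
general complex cubic coefficient — coupled diffusively through a complex
symmetric matrix `K` with zero diagonal:

    dz_j = [(λ_j + iω_j) z_j − (ζ_j + iχ_j)|z_j|² z_j + Σ_k K_jk (z_k − z_j)] dt + dW_j.

Units: `z` in μV, `λ` s⁻¹, `ζ, χ` μV⁻²s⁻¹, `ω` rad/s, `K` s⁻¹, noise
intensity `D` μV²/s. For `λ > 0` the noiseless oscillator has a limit
cycle at `r_e = √(λ/ζ)` rotating at `ω − χλ/ζ`; the closed-form noiseless
trajectory is implemented with the algebraically robust parameterisation
`r(t) = r0 e^{λt}/√g(t)`, `g = 1 + (ζr0²/λ)(e^{2λt} − 1)`, which is valid
for either sign of `λ` and has the removable limit
`g → 1 + 2ζr0²t` at the bifurcation point `λ = 0`.

### Noise convention (a factor-of-two worth stating)

The complex noise is specified by `⟨η(t)η*(t')⟩ = 2D δ(t−t')`, which we
take to mean each real component of `dW` has variance `D·dt` per step.
Conventions in the literature differ by factors of two; ours is stated
here because two consequences depend on it:

* the per-component stationary variance of the quiescent (λ<0) linear
  oscillator is `D/2|λ|`, so `⟨|z|²⟩ = D/|λ|`;
* the drift-potential Boltzmann density `P_s ∝ exp(−U(r)/D)` returned by
  `stationary_density` is the standard single-`D` radial-FPE form; under
  the component convention above, the simulated Cartesian process
  concentrates somewhat more tightly (as if `exp(−2U/D)`). The package
  exposes the single-`D` form as the model's reference density and treats
  the simulator comparison statistically (a Kolmogorov–Smirnov check with
  a pilot-calibrated bound of 0.15 that absorbs both the convention gap
  and the autocorrelation of SDE samples). Users who need the tighter
  density can evaluate `stationary_density` on a parameter set with `D`
  halved.

### Integration

Cartesian complex coordinates avoid the `1/r` singularity of the polar
noise term; since the noise is additive, the Itô and Stratonovich readings
coincide. The default scheme is Euler–Heun (predictor–corrector on the
drift, deterministic order 2); Euler–Maruyama is available via
`scheme="euler"`. Default `dt = 1/2048 s`; an explicit stability bound
`dt ≤ 0.1/max_j(|λ_j| + 3ζ_j r_e,j²)` is enforced with a refusal that
names a usable step. Output may be decimated (e.g. to 256 Hz) with
scipy's order-8 zero-phase Chebyshev-I low-pass (`signal.decimate`
defaults). All randomness flows from a single named integer seed through
one `numpy` Generator; identical (model, config, seed) reproduces
recordings bit-exactly. Note that an explicit scheme's discrete limit
cycle sits `O(ω⁴dt³)` off `r_e`; at the default step and 10 Hz this is a
~2×10⁻⁴ μV bias, negligible against the noise-driven fluctuation but
visible in noise-free checks.

### Regime presets

Three archetypal operating points parameterise the simulator and all test
fixtures (λ, ζ, χ, D) = activated (2.0, 1.0, 0.8, 0.010), suppressed
(−0.5, 1.0, 0.2, 0.005), exploratory (0.5, 5.0, 1.2, 0.050). The intrinsic
frequency is not part of the regime definition; all presets default to the
alpha-band value `ω = 2π·10 rad/s`, overridable per oscillator.
`make_fixture` places identical preset oscillators on a ring lattice with
complex nearest-neighbour coupling `strength·(1 + 0.5i)` — the real part
exchanges amplitude, the imaginary part couples phases.

## Effective potentials and the phonon basis

The similarity transform `P = ψ e^{−U/2D}` of the radial Fokker–Planck
equation yields an imaginary-time Schrödinger operator with

    V(r) = (ħ/2)[λ − 3ζr² + (λ − ζr²)² r²/2D],

a sixth-order even polynomial; its curvature at the limit cycle is
`V''(r_e) = 2ħλ²/D − 3ħζ`. `ħ` is a free fluctuation-localisation scale
with units μV·s (default 1, always explicit in model files); it cancels
out of every classical observable and enters only the quantised
bookkeeping (masses `m = ħ/2D`, quanta `ħΩ`).

Second-order expansion of the network amplitude energy around the limit
cycles gives the dynamical matrix

    Φ_jj = (V''(r_e,j) + Σ_k S_jk)/m_j,   Φ_jk = −S_jk/√(m_j m_k),

with `S = −Re K`. Its eigendecomposition (ascending eigenvalues,
deterministic sign fix: first component above 1e−12 made positive) defines
mode patterns `v^(ℓ)`, frequencies `Ω_ℓ = √eigenvalue` and mode masses
`M_ℓ = Σ_j m_j (v_j^(ℓ))²`. Negative eigenvalues (harmonically unstable
expansions, reachable in parameter scans with strong positive `Re K`) are
kept and flagged rather than dropped; their `Omega` entry stores the
magnitude of the imaginary frequency. Mode count always equals channel
count, and the projection
`q_ℓ(t) = Σ_j v_j^(ℓ) √m_j (r_j(t) − r_e,j)` is exactly invertible.

A useful identity: for a single site, `Ω² = V''/m = 4λ² − 6ζD`, so
`Ω ≈ 2λ` — the quantised-mode frequency numerically coincides with the
amplitude relaxation rate. Because the SL amplitude dynamics is
first-order (overdamped), the simulated `q_ℓ` spectra are zero-peaked
Lorentzians of half-width `Ω`, not displaced resonance peaks; the
empirical signature of `Ω_ℓ` is therefore the autocorrelation decay rate
(equivalently the half-power frequency) of the projected mode, which is
what the test suite checks (25% band calibrated from pilot runs).

### Energy accounting

Occupations are estimated classically per mode:
`E_ℓ = ⟨p²⟩/2M_ℓ + ½M_ℓΩ_ℓ²⟨q²⟩`, `n_ℓ = E_ℓ/ħΩ_ℓ − ½`, with momenta
`p = M dq/dt` by central differences; the clipped report floors `n` at 0
and the raw value is retained. The total energy adds a phase (rotor) term
`Σ_j (⟨p_φ⟩²/2I_j − f_φ(r_e,j)⟨p_φ⟩)` with inertia `I_j = m_j r_e,j²` and
`p_φ = I_j⟨dφ/dt⟩` from unwrapped phases, and a coupling term
`−Σ_{j<k} J_jk ⟨cos(φ_j − φ_k)⟩` with `J_jk = −½ r_e,j r_e,k Im K_jk`
evaluated at equilibrium amplitudes (a time-resolved `J(t)` would make the
coupling energy depend on the amplitude estimator; the equilibrium choice
makes it well-defined per recording). `⟨cos Δφ⟩` is the real part of the
complex phase-locking statistic.

## Analytic spectra

Treating each mode as a noise-driven harmonic oscillator gives the
Green's-function PSD `S_q(ω) = 2ħ/(Ω² − ω²)²` with a flat drive spectrum
`2ħ`. As printed this has non-integrable poles; the package regularises
with a per-mode damping γ, `S_q = 2ħ/((Ω²−ω²)² + γ²ω²)`, recovering the
undamped form pointwise as γ→0 away from resonance. The default
`γ = 2·mean(λ)` is the linearised amplitude relaxation rate — the damping
the SL dynamics itself supplies. Channel cross-spectra use site masses in
the weight `v_j v_k/√(m_j m_k)` (a mode-mass variant is exposed via
`use_mode_masses`); coherence is the magnitude-squared form
`|S_jk|²/(S_jj S_kk)`, which lies in [0,1] by Cauchy–Schwarz. The analytic
envelope-correlation (AAC) matrix is the eigenvector-overlap sum with
zero-point default `⟨q²⟩ = ħ/2MΩ`, exposed both raw and symmetrically
normalised to unit diagonal (a correlation must lie in [−1,1]). The PAC
slope is `2χr_e` (zero iff amplitude and phase decouple), and an optional
`amplitude/ω` term models the broadband 1/f background of many incoherent
modes in their high-temperature occupation limit.

## Empirical metrics

Band signals: 4th-order zero-phase Butterworth band-pass then Hilbert
transform; band defaults delta 1–4, theta 4–8, alpha 8–13, beta 13–30,
gamma 30–45 Hz. Edge trim is six time-constants of the band's lower corner
(`6fs/f_lo` samples per side), sized so a pure in-band tone's envelope is
recovered to ≤1% — three time-constants cover the filter transient but not
the Hilbert edge leakage. Welch PSDs use 2 s Hann windows at 50% overlap,
one-sided density normalisation; band power integrates the PSD
trapezoidally with interpolated band edges. PLV, coherence and coherence
entropy follow their standard estimator definitions with whole-epoch time
averages; coherence entropy sums over off-diagonal unordered pairs by
default (the unit diagonal would otherwise dominate the distribution; the
literal all-pairs reading is available via `include_diagonal=True`).
Null bands for "indistinguishable from chance" statements use circular
time-shift surrogates (200 draws, shifts in [0.05T, 0.95T], fixed seed).

The PAC summary correlates the fast envelope with the slow rhythm's phase
velocity. Two estimator pitfalls are handled explicitly: (i) sample-wise
phase velocity of a noisy rhythm is white-noise dominated, so an optional
moving average (`phase_velocity_smooth_s`, typically 0.1–0.25 s) focuses
the estimator on the amplitude-fluctuation band; (ii) band-pass filtering
pulls instantaneous frequency toward the band centre when the envelope
dips, which injects a spurious envelope–frequency correlation for
narrowband signals whose carrier is off-centre — for simulated oscillators
the raw analytic state should be used instead of a re-filtered copy. In
this model χ > 0 lowers the phase velocity when the amplitude rises, so
the predicted correlation is negative with magnitude growing in χ.

## Personality map

Model coordinates `(λ/ζ, Ω statistics, D, χ, K summaries)` are classified
by ordered threshold rules (all configurable, defaults chosen to separate
the three presets): suppressed ⇔ λ/ζ < 0; hypercoherent/overload ⇔
D < 0.002 and χ ≥ 1.5; activated ⇔ λ/ζ ≥ 1, D < 0.02, χ ≥ 0.5 and mean
|K| ≥ 0.5; exploratory ⇔ 0 < λ/ζ < 1 and D ≥ 0.02; fragmented ⇔ D ≥ 0.02,
χ < 0.3, mean |K| < 0.1; drowsy/transitional ⇔ moderate ratio,
intermediate D, low χ. Coordinates outside every region return
"unclassified" rather than a forced nearest label. `K` is summarised by
mean |Re K|, mean |Im K| and spectral radius; richer descriptors (e.g.
eigenvalue entropy of K) are a documented extension point.

## What the synthetic data does and does not emulate

The simulator generates exactly the model's own dynamics: narrowband
limit-cycle rhythms with additive Gaussian white noise, stationary
parameters, and instantaneous symmetric coupling. Real EEG additionally
contains 1/f background, nonstationarity, artefacts, volume conduction and
reference effects, none of which are produced here — so green tests show
that the estimators and the closed-form theory agree on data obeying the
model's assumptions, not that the model describes any particular
recording. Import of real data is supported through the CSV + JSON
sidecar format only; preprocessing (artefact rejection, surface
Laplacian/CSD) is out of scope.

## Problem sizes and numerical choices

Test and acceptance runs use 1–4 channels and 10–60 s at `dt = 1/2048 s`
— long enough that stationary averages stabilise (amplitude relaxation
time 1/2λ = 0.25 s in the activated regime gives hundreds of effective
samples per minute) while keeping any single check to seconds of compute.
Stochastic assertions are pinned to named seeds; statistical tolerances
(KS 0.15, mode-rate 25%, PAC averaged over three seeds) were calibrated
from pilot runs at these sizes and are documented where used. Degenerate
eigenvalues get a deterministic orthonormal basis from `eigh` plus the
sign convention; zero-frequency modes are excluded from occupation
estimates with a warning; masked (zero-power) channels propagate as NaN
rather than poisoning whole matrices.

## Known limitations

* The harmonic (phonon) layer assumes every site has a limit cycle
  (λ > 0) and noise (D > 0); suppressed-regime channels cannot enter a
  basis.
* The quadratic expansion ignores rare large excursions and any
  multiplicative or coloured noise; the Green's-function spectra describe
  envelope fluctuations, not the voltage carrier.
* The two-dimensional Schrödinger eigenproblem of the joint
  amplitude–phase operator is out of scope; only its radial potential is
  evaluated.
* The γ regularisation of the mode PSD is an interpretation: the printed
  undamped form is its γ→0 limit and is non-integrable at resonance.
* Personality thresholds are heuristics over a qualitative taxonomy, not
  fitted decision boundaries.
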