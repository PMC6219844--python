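# Methods

This note documents the models, estimators and defaults behind
`gammaclamp`: what each component assumes, which parameters matter and
why they have the values they do, and what the synthetic data do and
do not share with recordings from real tissue.

## Conventions

* Signals are uniformly sampled at 10 kHz (`dt = 1e-4 s`), the rate of
  the acquisition/control loop; controller and plant share this grid
  so closed-loop coupling needs no interpolation.
* Oscillation phase is in degrees with the **LFP trough at 0°**,
  increasing through the cycle, range [0°, 360°). A *phase advance* is
  a shift toward smaller phase. Pyramidal cells fire near 0°.
* Inward membrane currents are negative, outward positive. Phasic
  (minimum-subtracted) currents are reported as positive magnitudes
  with the holding potential recorded (−70 mV isolates excitation,
  0 mV inhibition).
* Every stochastic component draws from its own stream derived from a
  single master seed (fixed stream offsets), so whole experiments
  replay bit-exactly.

## Plants

### Stuart–Landau (Hopf normal form)

State `z ∈ ℂ` with

    dz/dt = (μ + iω₀) z − (1 + i·c) |z|² z + g·u(t)·e^{iβ} + ση(t),

where μ (1/s) is the bifurcation parameter (limit cycle radius √μ for
μ > 0), ω₀ the angular frequency (default 2π·40 Hz), c the shear
(amplitude–frequency coupling, default 0), u(t) the opsin drive along
the state-plane direction β, and η complex white noise. The LFP is
`obs_gain · Re z` (default 0.03 mV per state unit, i.e. ~0.3 mV
oscillation at μ = 100).

**Drive direction.** β defaults to +90°: the drive acts along the
hidden variable in quadrature with the observed LFP. With this choice
an in-phase clamp raises the frequency, and the power extremes sit at
±90° feedback phase — the configuration that reproduces the
experimental phenomenology.

**Drive high-pass.** The plant represents the network *at* its
oscillating working point — the slow ramp that created the oscillation
is absorbed into μ. Only the fast component of the drive couples; a
1 Hz one-pole high-pass (`drive_hp_hz`) removes the DC, without which
the ramp (times `drive_gain`) would push the state far off the limit
cycle and no weak-perturbation regime would exist.

**Integration.** The drift is advanced with a Heun (RK2) step; noise
enters as the standard additive Euler–Maruyama increment (for additive
noise the Itô and Stratonovich readings coincide, so stochastic Heun
is consistent). A first-order step at the fixed 10 kHz grid biases the
cycle radius by ≈ (ω₀·dt)²/2 relative terms — about 1.6 % at 40 Hz —
which would swamp the 0.1 % closed-form checks; the Heun step reduces
the bias below 0.02 %. A state-magnitude guard aborts with a
diagnostic naming the step size and parameters if the integration
diverges.

### E–I mass model

A Wilson–Cowan pair (rates E, I ∈ [0, 1], sigmoid activation) with
time constants τ_E = 3.3 ms, τ_I = 6.6 ms and the classic weight set
(w_EE = 16, w_EI = 12, w_IE = 15, w_II = 3), but with softened sigmoid
slopes (a_E = 0.7, a_I = 1.0) so the oscillation is born in a
supercritical Hopf bifurcation as the drive crosses threshold: below
threshold a fixed point, above it a graded limit cycle in the low
gamma band (~30–45 Hz across the ramp). The external drive enters the
E population only (`drive_gain = 2.7`), mirroring an opsin expressed
in pyramidal cells.

Observables:

* **Synaptic conductances** g_e = `ge_gain`·s_E and g_i =
  `gi_gain`·s_I, with s_E, s_I one-pole filtered rates (1 and 2 ms).
  A held cell at −70 mV additionally receives the direct photocurrent
  `g_opsin`·u(t). Holding currents are ±(g·70 mV); `gi_gain` (4.0) is
  deliberately larger than `ge_gain` (1.2) so baseline phasic
  inhibition dominates phasic excitation, as in tissue.
* **LFP**: a mix of the synaptic signals (70 % s_E / 30 % s_I by
  default), sign-inverted so its trough falls near the E-rate peak,
  with a quadratic distortion term (`harmonic_amp`) adding the second
  harmonic that makes the waveform non-sinusoidal. The mix keeps the
  spike-preferred phase within ~30–40° of the trough (the residual
  offset is the synaptic/measurement filter lag at gamma frequency).
  No quantitative waveform was available to calibrate against; the
  harmonic amplitude is a configuration knob.
* **Spiking**: each of `n_cells` (12) pyramidal cells is an
  inhomogeneous Poisson process with intensity

      λ(t) = r₀ · max(0, 1 + (E − Ē)/s + γ·(u − ū)),

  where Ē and ū are slow (0.3 s) running baselines, s =
  `e_mod_scale` (0.55) scales the E fluctuation to a ~75 % baseline
  modulation depth, and γ = `opsin_spike_gain` (1.5) is the direct
  photocurrent's contribution to excitability. Because both modulating
  terms are zero-mean, oscillation and clamp redistribute spikes
  within the cycle while the time-averaged rate stays at r₀
  (`spike_rate_hz` = 3 Hz): sparse, trough-locked firing whose
  *synchrony* — not rate — tracks oscillation power. This homeostatic
  normalization is a deliberate modelling choice: a literally
  E-proportional intensity inherits the mass model's coupling between
  oscillation amplitude and cycle-averaged E, which would move the
  mean rate by tens of percent under a strong clamp — precisely the
  behaviour the biological finding rules out. Rate invariance remains
  a falsifiable property (intensity clipping breaks it when the
  modulation saturates), which is what the tests check.
* An OU noise process (σ = 0.15, τ = 5 ms) on the E input produces
  cycle-to-cycle period jitter (CV ≈ 4 %) and amplitude fluctuations.

A run whose plateau LFP shows no spectral peak at least 10× the
low-frequency floor is flagged `oscillating: False` in its metadata
rather than raising.

### Measurement stage

Both plants observe their raw LFP through a causal first-order
band-pass (1–200 Hz default, matching a typical acquisition chain)
plus optional white measurement noise, *before* the signal is recorded
or fed back. Analyses that need the plant-side signal (PRC phase
referencing) can use the raw trace stored in the run's extras.

## Controller

The command at step n is
`max(threshold, ramp[n] · (1 + k1·LFP[n−1] + k2·d̄LFP[n−1]))` inside
the clamp window and `ramp[n]` outside; d̄LFP is the per-sample first
difference (mV/ms) averaged over a trailing 2 ms boxcar, so k2 carries
ms/mV and both feedback terms are dimensionless. The loop is strictly
causal with a one-sample (0.1 ms) feedback latency emulating the
hardware pipeline. The threshold-linear driver (default threshold 0)
means no negative light — saturation is part of the contract, not an
error. The opsin stage is a first-order low-pass with asymmetric
activation/deactivation time constants; 6/12 ms defaults put the
simulated LED-to-peak-current lag in the tens-of-degrees range at
gamma frequency, the order observed experimentally (the constants are
not published quantities and are exposed as configuration).

A requested feedback phase ψ converts to gains via the pure-tone
relation k1 = K·cos ψ, k2 = K·sin ψ/ω_ms at a stated reference
frequency; `phase_to_gains` implements it and the sweep machinery
accepts either explicit (k1, k2) grids or phase grids.

## Averaged theory (weak feedback)

For weak periodic forcing `A·cos(φ + ψ)·e^{iβ}` of the Stuart–Landau
limit cycle (φ the oscillator phase), cycle-averaging gives

    δR  = A·cos(ψ + β) / (4μ)        (amplitude; relaxation rate 2μ)
    δω  = A·sin(ψ + β) / (2R₀)       (frequency)

`feedback_chain` assembles the full discrete loop transfer function —
measurement band-pass, loop latency, k1 and k2 paths (difference +
boxcar), opsin pole, drive high-pass — evaluated at the limit-cycle
frequency, so ψ and A follow from the configuration instead of being
fitted.

The *observed* tone power needs one more term: the counter-rotating
half of the forcing drives a 2ω perturbation of the rotating-frame
state whose mixing back into the carrier adds a forced component

    δA_obs = δR + Re[(A/4)·e^{−i(β−ψ)}·(1/(2μ + 2iω) + 1/(2iω))]

to the measured tone amplitude. The correction rotates the power
curve by ≈ atan(μ/ω) relative to the radius response; including it
brings the predicted power curve within ~7 % (relative L2) of
simulation, against ~50 % without. Consequently the reference sweep
configuration runs at μ = 50 (μ/ω ≈ 0.2), where amplitude and
frequency responses are in near-quadrature and the ΔF/ΔP zero
crossings sit ~87° apart; at μ = 100 the same physics puts them at
~73°. The closed-form amplitude/frequency checks use μ = 100
separately.

The analytic PRC of the zero-shear oscillator is
`δθ = (area/R₀)·sin(θ − β)` (θ in the trough convention, advance
positive, area = impulse strength). `measure_prc` reproduces it within
~5 % when kicks are centered on their target phase and phases are
referenced to the plant-side LFP; referencing against the measured
(band-passed) LFP rotates the curve by the acquisition lag (~10° at
40 Hz), which is a property of the recording chain, not the
oscillator.

## Estimators

* **Instantaneous frequency/power**: 200 ms Hann segments, 75 %
  overlap; in-band FFT peak (8× zero-padding) refined by quadratic
  interpolation of the log magnitude; power read at the tone
  (A²/2 calibration). Bias < 0.01 Hz on in-band tones; power scales as
  amplitude². Segments without in-band energy give NaN samples.
* **Clamp ratios**: track means inside the window versus 1 s flanks
  before/after; flanks shrink with a recorded warning when the window
  sits near the trace edge. Ratios are amplitude-scale invariant.
* **LED–LFP phase**: Welch cross-spectrum (500 ms Hann, 50 % overlap),
  phase at the bin of maximal cross-magnitude, positive = LED
  advanced.
* **Morlet spectrogram**: complex Morlet (7-cycle default) on a
  log-spaced 20–120 Hz grid via the wavelet transform, magnitudes
  normalized by √scale so a pure tone's ridge is centered on its own
  frequency (the raw scale-domain magnitude is tilted low by the
  amplitude normalization). The input is decimated to 1 kHz first,
  which is transparent below the analysis band.
* **Spike phase**: 200 ms Hann window centered on the spike, dominant
  in-band tone, phase of the cosine at the spike time mapped to the
  trough convention. Validated to ±1.5° by exhaustive placement.
* **Cycle averaging**: zero-phase 20–120 Hz band-pass + local minima
  for troughs; modal period from a 1 ms histogram of inter-trough
  intervals; cycles deviating more than 20 % from the mode rejected
  (boundary inclusive — "more than 20 %" is rejected); accepted cycles
  linearly resampled onto 64 uniform phase bins.
* **Current vectors**: amplitude-weighted circular mean of the phasic
  cycle average (unweighted means are available); magnitude = mean
  phasic amplitude in pA. ΔE/ΔI are Cartesian vector differences.
* **Tests on phase vectors**: exact two-sided binomial sign test (ties
  dropped); paired Hotelling T² on (R cos θ, R sin θ) differences
  (unit-vector variant available), F-referenced with p = 2,
  cross-checked against a sign-flip permutation oracle.

## Reference studies and problem sizes

`studies.py` freezes the configurations behind the tests and the
acceptance script:

* **Rotation sweep**: 12 feedback phases × 8 s closed-loop runs on the
  deterministic μ = 50 plant, gain 0.6/mV (~20 % modulation depth),
  clamp 4–6 s.
* **PRC study**: 16 phases × 3 s twin runs, 1 ms kicks, shifts read 5
  cycles after the kick.
* **E–I battery**: 4 trials per condition (unclamped twins,
  power-raising clamp at feedback phase 270°, frequency-raising at
  45°; gain 0.3/mV at the 31 Hz plateau frequency), 8 s runs with the
  ramp saturating at 4 s so the 5–7 s clamp window and its flanks sit
  on a stationary plateau. Spike statistics pool ~300 spikes per
  condition — deliberately the scale of the original recordings, and
  enough to resolve the R and phase effects while the ±2 SE rate band
  is ~12 %.

These sizes keep the whole suite within a few minutes on one core;
they are the package's reference conditions, not limits of the
implementation.

## What the synthetic slices do not capture

* The E–I mass model is a two-population rate model: no conductance
  synapses, no spatial structure, no interneuron diversity, no
  spike-timing feedback from the Poisson cells onto the field. The
  LFP is a constructed mix, not a biophysical forward model.
* The homeostatic spiking intensity builds rate invariance in (except
  under saturation); the corresponding tests therefore demonstrate
  that the *pipeline detects* synchrony/phase changes at constant
  rate, not that rate invariance is an emergent prediction.
* The frequency-raising regime of the E–I plant places the imposed
  excitation ΔE at ~200° (early down-stroke). Trough-adjacent
  excitation (ΔE ≈ 270–330°) raises power but slightly *lowers*
  frequency in this model, so the correspondence between excitation
  phase and frequency change holds in the down-stroke/trough
  configurations exercised, not over the whole circle.
* Opsin kinetics are a single asymmetric pole with guessed constants;
  irradiance, expression gradients and photocurrent saturation are out
  of scope.
* Passing tests on these plants validate the method and its
  implementation; they do not certify behaviour on tissue data beyond
  the qualitative structure built into the generators.
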