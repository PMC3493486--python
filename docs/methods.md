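# Methods

## Model overview

`ctcsim` implements a convergent-pathway model of oscillatory signal
routing.  Several input networks, each population-coding an independent
orientation with Poisson neurons, converge onto one receiving network.
A time-varying multiplicative gain in the receiving network — coherent
with the firing-rate oscillation of the designated *target* input — is the
only mechanism available for reading out the target and rejecting the
distractors.  Because the receiving network is optimized (rather than
hand-designed), its performance upper-bounds what any network using linear
multiplicative gain modulation with this information could achieve, so
failures are attributable to the coding scheme, not the implementation.

## Synthetic input stage

**Tuning.**  Neuron *i* of a network has preferred orientation evenly
spaced on [0°, 180°) and mean rate
`r̄ · exp(κ_t(cos 2(θ−θ_i) − 1)) / i0e(κ_t)`, a Von Mises bell on the
doubled angle normalized so the population-average rate is `r̄` for every
stimulus.  The tuning width is not a quantity the model's conclusions are
meant to depend on (all headline results are ratios across conditions
sharing the same tuning); the default concentration gives 40° full width at
half maximum.  Band rates for the 8 receiving units are evaluated through
the Von Mises Fourier series — the sum over a band's evenly spaced
preferences reduces to a geometric sum per harmonic — which is exact to
double precision at O(harmonics) cost; the explicit per-neuron sum is kept
as a test oracle.

**Oscillation.**  The modulation is `M(t) = exp(κ(t) cos φ(t))/I₀(κ(t))`
(or `1 + a(t) cos φ(t)` for the sinusoidal variant, with `a = 2S` so both
waveforms share the same synchronization measure `S = I₁(κ)/I₀(κ)`).
Instantaneous frequency and concentration fluctuate multiplicatively:
`F(t) = F̄(1 + σ_F η(t))` with η zero-mean, unit-SD low-pass-filtered
Gaussian noise, so σ_F and σ_A are exactly the relative SDs of frequency
and depth.  The noise filter is a 4th-order Butterworth with −3 dB point at
the network's mean oscillation frequency; a first-order filter leaves
~20–25% of the noise power above twice the cutoff, which would blur the
narrowband/broadband distinction the conditions rely on.  The cutoff value
itself is a free parameter of the generator (the fluctuation timescale of
in vivo oscillations is not tightly constrained); see *Limitations*.
Negative excursions of F, κ or a are clipped at zero and counted (they are
rare at the default σ ≤ 0.3).  Phase is accumulated by forward Euler at
dt = 1 ms, keeping the per-step advance below 0.63 rad for frequencies up
to 100 Hz.

**Sampling.**  Independent Poisson neurons sum to a Poisson band count, so
spike counts are drawn at band level, `counts[j,t] ~ Poisson(rate_j M(t) dt)`
— mathematically exact and ~10³× faster than per-neuron simulation (the
per-neuron path is exercised in a χ² equivalence test).  Each sample of a
batch draws fresh phase and fluctuation traces per network; networks in a
`coherent_group` share one trajectory before individual phase offsets;
distractor orientations are uniform per sample; target labels
θ_ref ± Δθ/2 are exactly balanced, with θ_ref = 90° so labels never wrap.
A Hann taper is applied to the spike counts (and to the stage-1 regression
targets, keeping that regression well posed) to limit spectral leakage of
the finite window.  The raw (un-tapered) modulation and counts are kept
alongside: the gain-generating circuitry sees the raw reference signal,
the taper belongs to the integration/readout stage.

## Receiving network and optimization

The integrated activity is linear in the filter response:
`A_j = Σ_k d_k Re[H(k) R(k) N_j*(k)]/n` (Plancherel form, with d_k = 2 for
interior frequencies, 1 for DC/Nyquist), which yields a per-sample design
matrix `Z` with `A = Z·[Re H; Im H]`.  The decoded estimate
`θ̂ = w·(Z u) + c` is bilinear in (w, u).

**Stage 1** fits H from zero by steepest descent with an exact line search
(the cost is quadratic along any line) to reproduce the target-network rate
arriving at each unit — a matched-filter initialization.

**Stage 2** descends on (w, c, u) jointly from the stage-1 filter with
w = 0.  The default optimizer is block-coordinate descent: exact least
squares in (w, c) given u, and a *ridge* solve in (u, c) given w whose
penalty shrinks by ×0.3 each round from λ = 1 (scaled by the mean feature
energy).  Successive rounds therefore trace a capacity path from heavily
smoothed filters toward the unpenalized optimum, and test-set early
stopping (patience 5 rounds) picks the capacity — the same spectral
filtering an early-stopped gradient descent performs, at a fraction of the
iterations.  This regularization is not cosmetic: the raw reference's DFT
has leakage tails at every frequency, and the unpenalized optimum exploits
them with very large filter coefficients at frequencies where the
reference has almost no power, producing erratic gain waveforms; the ridge
path suppresses those solutions, after which the asynchronous-condition
gain concentrates >99% of its energy within ±2 DFT bins of the target
frequency and a filter fitted to a single sinusoidally modulated input
recovers the modulation frequency to within one DFT bin.  Plain steepest
descent with an exact quartic line search is retained
(`GDConfig(stage2_method="gd")`) and serves as the independent optimizer in
the test suite's oracle comparison; it reaches the same optimum on small
instances but needs ~10⁴ iterations on realistic ones.

**Decoding and evaluation.**  Estimates are evaluated on a held-out test
set.  `FI = ((μ₊−μ₋)/Δθ)²/σ̄²` with σ̄² the mean within-group variance —
the squared local slope over the variance, equal to the reciprocal MSE of
the locally calibrated estimator and invariant to affine rescaling of the
estimates (so the shrinkage the MSE objective induces does not bias FI).
Degenerate guards: FI = 0 when the groups coincide with zero variance, +∞
when they differ with zero variance.  Classification assigns each sample
to the nearer of the two candidate orientations (threshold at θ_ref).

**Δθ calibration.**  For every parameter set, Δθ is calibrated so that
75–80% of test samples classify correctly, by iterating: fit the full
model on reduced batches (1,000 samples) at a trial Δθ, measure the
fraction, propose the next Δθ through the probit relation (classification
d′ is proportional to Δθ), falling back to geometric bisection of the
bracketing values.  Calibration per parameter set matters: a network
trained at a Δθ far below its noise scale cannot learn the readout at all,
which would conflate training failure with coding constraints.

**Variants.**  The *bottom-up* model replaces the reference signal by the
summed spike input (no top-down knowledge of the target's modulation); all
downstream machinery is unchanged.  The *biological* baseline fixes the
gain to the target's own mean-subtracted modulation waveform and fits only
the 8 + 1 linear-readout parameters (by ordinary least squares — at that
parameter count early stopping is irrelevant).  The *arbitrary-gain*
variant freezes one target-modulation instance per batch and optimizes the
per-bin gain vector directly (the same bilinear machinery with the raw
count matrix as design matrix), repeating over instances and reporting the
mean and SD of FI.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| networks | 4 (1 target + 3 distractors) | convergent inputs |
| neurons/network | 10,000 | Poisson units |
| mean rate `r̄` | 5 Hz | population-average rate per neuron |
| modulation frequency `F̄` | 50 Hz | gamma-band oscillation |
| synchronization `S` | 0.5 | mean resultant length of spike phases |
| σ_F | 0.1 narrowband / 0.3 broadband | relative SD of frequency |
| σ_A | 0.1 | relative SD of modulation depth |
| noise cutoff | `F̄` | −3 dB point of the fluctuation filter |
| receiving units | 8 | equal preference bands over [0°, 180°) |
| integration window | 100 ms | at dt = 1 ms |
| tuning FWHM | 40° | bell-shaped tuning width |
| batch size | 2,000 + 2,000 | desk-scale train/test (full scale: 5,000) |
| frequency cap | 3 F̄, windows ≥ 200 ms | filter clamped where the target has no power |

Broadband (σ_F = 0.3) modulation is used for all networks in the
incoherent-distractor condition; narrowband elsewhere.  The default
distractor frequency in the frequency-separated condition is 100 Hz (well
separated from 50 Hz; its harmonics stay clear of the target band).

## Problem sizes

The headline protocol (`reproduce_headline`, also driven by
`scripts/acceptance.py`) uses 2,000-sample train and test sets with three
replicate seeds and 1,000-sample calibration batches — sizes at which one
full condition fit takes a few seconds and the complete protocol a few
minutes on one CPU, with Monte-Carlo spread on the reported ratios of
roughly ±15–25% across master seeds.  The test suite uses further-reduced
batches (300–2,000 samples) chosen per test so each assertion retains a
clear margin over its Monte-Carlo noise.

## What the generator does and does not emulate

The synthetic stage reproduces the statistical structure the routing
mechanism is sensitive to: Poisson spiking, shared multiplicative
modulation within a network, stochastic frequency/depth fluctuations, and
controlled coherence relationships across networks.  It does not include
refractoriness, rate heterogeneity beyond tuning, noise correlations other
than the shared modulation, conduction delays, synaptic filtering, or any
biophysical gain mechanism — so passing tests show that the *coding-level*
constraints hold under the model's idealizations, not that a biophysical
network attains these bounds.

## Numerical choices

DFT conventions follow numpy's `rfft`/`irfft` (unnormalized forward, 1/n
inverse) with conjugate-symmetric storage and the interior-frequency
doubling factor.  The imaginary parts of the DC and Nyquist bins are
identically zero by construction and carry no parameters.  Frequency-domain
and time-domain integration paths agree to 1e-9 relative and both are
exposed.  `sync_to_kappa` inverts `S = I₁(κ)/I₀(κ)` by Brent's method to
1e-9 relative tolerance using exponentially scaled Bessel functions (stable
to κ ≈ 10³).  The Hann window is symmetric, so the first and last bin are
exactly zero.  Ties in classification (θ̂ exactly at θ_ref) count as
incorrect; they have measure zero.

## Limitations

- Two generator parameters the source material leaves unspecified — the
  fluctuation-noise cutoff and the tuning width — measurably shift the
  incoherent-distractor condition's Fisher information (the cutoff sets how
  much distractor power spreads into the spectral flanks the optimized
  filter uses; the tuning width sets the overlap-noise-to-Poisson-noise
  balance).  With the defaults above, the asynchronous/incoherent FI ratio
  at high input rates comes out ~35–45% below, and the bottom-up model's
  residual FI in the incoherent condition ~70% above, the values the
  original study conditions produce; the corresponding acceptance checks
  are left failing rather than fitting those parameters to the outcomes.
- Desk-scale batches (2,000 vs 5,000 samples) leave ±15–25% Monte-Carlo
  spread on FI ratios across master seeds; fold-changes spanning two
  orders of magnitude (high vs low synchronization) sit at the edge of
  that resolution.
- The receiving network is strictly linear-multiplicative; threshold or
  power-law gain families and biophysical implementations are out of
  scope.
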