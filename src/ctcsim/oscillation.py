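"""Stochastic oscillatory rate modulations.

An input network's population firing rate is multiplicatively modulated by an
oscillation whose instantaneous frequency and depth fluctuate slowly around
their means, emulating the irregular, sparsely synchronized oscillations seen
in vivo.  The modulation waveform is a Von Mises function of the oscillation
phase (or a plain sinusoid), normalized so that its long-run time average is 1
and the mean firing rate of the network is therefore unchanged by the
oscillation.

Synchronization strength ``S`` is the mean resultant length of the spike-phase
distribution: 0 for a flat (asynchronous) phase density, approaching 1 when
all spikes fall at a single phase.  For a Von Mises modulation with
concentration ``kappa`` this equals ``I1(kappa)/I0(kappa)``; for a sinusoidal
modulation ``1 + a*cos(phi)`` it equals ``a/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.typing import NDArray
from scipy import optimize, signal, special

__all__ = [
    "OscillationParams",
    "FluctuationTrace",
    "PhaseTrajectory",
    "ModulationTrace",
    "lowpass_noise",
    "phase_trajectory",
    "modulation_trace",
    "sync_to_kappa",
    "kappa_to_sync",
]

Waveform = Literal["von_mises", "sinusoidal", "none"]


@dataclass(frozen=True)
class OscillationParams:
    """Parameters of one network's oscillatory rate modulation.

    Parameters
    ----------
    waveform
        ``"von_mises"``, ``"sinusoidal"`` or ``"none"`` (asynchronous firing,
        modulation identically 1).
    mean_frequency
        Mean oscillation frequency F̄ in Hz.
    sync_strength
        Synchronization strength S in [0, 1): mean resultant length of the
        spike-phase density.
    sigma_f, sigma_a
        Relative SD of the slow fluctuations of instantaneous frequency and
        of modulation depth (concentration / amplitude).
    noise_cutoff
        −3 dB cut-off (Hz) of the low-pass filter shaping the fluctuation
        noise; defaults to ``mean_frequency`` (fluctuations on the cycle
        timescale).
    phase_offset
        Constant phase shift (radians) added after the trajectory is drawn.
    coherent_group
        Networks sharing the same identifier share one phase trajectory
        (before offsetting); ``None`` means an independent trajectory.
    """

    waveform: Waveform = "von_mises"
    mean_frequency: float = 50.0
    sync_strength: float = 0.5
    sigma_f: float = 0.1
    sigma_a: float = 0.1
    noise_cutoff: float | None = None
    phase_offset: float = 0.0
    coherent_group: str | None = None

    def __post_init__(self) -> None:
        if self.waveform not in ("von_mises", "sinusoidal", "none"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.waveform != "none" and self.mean_frequency <= 0:
            raise ValueError("mean_frequency must be > 0 for an oscillation")
        if not 0.0 <= self.sync_strength < 1.0:
            raise ValueError("sync_strength must lie in [0, 1)")
        if self.sigma_f < 0 or self.sigma_a < 0:
            raise ValueError("fluctuation SDs must be >= 0")
        if self.noise_cutoff is not None and self.noise_cutoff <= 0:
            raise ValueError("noise_cutoff must be > 0")

    @property
    def cutoff(self) -> float:
        return self.noise_cutoff if self.noise_cutoff is not None else self.mean_frequency


@dataclass
class FluctuationTrace:
    """Low-pass filtered Gaussian noise, rescaled to zero mean and unit SD."""

    values: NDArray[np.float64]
    dt: float


@dataclass
class PhaseTrajectory:
    """Oscillation phase and instantaneous frequency over time bins.

    The phase is the forward-Euler cumulative integral of
    ``2*pi*instantaneous_frequency*dt`` plus the initial phase.
    """

    phase: NDArray[np.float64]
    instantaneous_frequency: NDArray[np.float64]
    dt: float
    n_clipped: int = 0


@dataclass
class ModulationTrace:
    """Multiplicative, non-negative firing-rate modulation M(t).

    Normalized per bin so that the expectation over a uniformly distributed
    phase is 1; the long-run time average therefore converges to 1.
    """

    values: NDArray[np.float64]
    dt: float
    n_clipped: int = 0


def lowpass_noise(
    duration: float,
    dt: float,
    cutoff: float,
    rng: np.random.Generator,
    n_traces: int | None = None,
) -> FluctuationTrace:
    """Low-pass filtered Gaussian white noise with unit standard deviation.

    A 4th-order Butterworth filter with −3 dB point at ``cutoff`` is applied
    to an i.i.d. standard-normal sequence (steep enough that almost no power
    remains above twice the cutoff), after which each trace is rescaled
    exactly to zero mean and unit sample SD.

    With ``n_traces`` set, ``values`` has shape ``(n_traces, n_bins)`` and
    each row is filtered and rescaled independently.
    """
    if duration < dt or duration <= 0:
        raise ValueError("duration must be >= dt")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    n_bins = int(round(duration / dt))
    shape = (n_bins,) if n_traces is None else (n_traces, n_bins)
    white = rng.standard_normal(shape)
    nyquist = 0.5 / dt
    if cutoff < 0.99 * nyquist:
        b, a = signal.butter(4, cutoff, fs=1.0 / dt)
        filtered = signal.lfilter(b, a, white, axis=-1)
    else:
        filtered = white  # cutoff at/above Nyquist: nothing to remove
    filtered -= filtered.mean(axis=-1, keepdims=True)
    sd = filtered.std(axis=-1, keepdims=True)
    # a constant trace (sd == 0) can only arise for n_bins == 1; leave it at 0
    np.divide(filtered, sd, out=filtered, where=sd > 0)
    return FluctuationTrace(values=filtered, dt=dt)


def phase_trajectory(
    params: OscillationParams,
    duration: float,
    dt: float,
    rng: np.random.Generator,
    n_traces: int | None = None,
) -> PhaseTrajectory:
    """Draw a stochastic oscillation phase trajectory.

    The instantaneous frequency is ``F(t) = F̄ * (1 + sigma_f * eta(t))`` with
    ``eta`` a unit-SD low-pass noise trace; negative excursions are clipped at
    zero and counted.  The phase is accumulated by forward Euler, starting
    from a uniform random initial phase, and finally shifted by
    ``phase_offset``.
    """
    if params.waveform == "none":
        raise ValueError("cannot build a phase trajectory for waveform 'none'")
    n_bins = int(round(duration / dt))
    shape = (n_bins,) if n_traces is None else (n_traces, n_bins)
    if params.sigma_f > 0:
        eta = lowpass_noise(duration, dt, params.cutoff, rng, n_traces).values
        freq = params.mean_frequency * (1.0 + params.sigma_f * eta)
    else:
        freq = np.full(shape, params.mean_frequency)
    n_clipped = int(np.count_nonzero(freq < 0))
    np.clip(freq, 0.0, None, out=freq)
    phi0 = rng.uniform(0.0, 2.0 * np.pi, size=None if n_traces is None else (n_traces, 1))
    # forward Euler: phi[t] = phi0 + 2*pi*dt * sum_{u<t} F(u)
    steps = 2.0 * np.pi * dt * freq
    phase = np.cumsum(steps, axis=-1) - steps + phi0 + params.phase_offset
    return PhaseTrajectory(phase=phase, instantaneous_frequency=freq, dt=dt, n_clipped=n_clipped)


def sync_to_kappa(s: float) -> float:
    """Von Mises concentration for a given synchronization strength.

    Solves ``S = I1(kappa)/I0(kappa)`` (the mean resultant length of the Von
    Mises density) by bracketing root search to relative tolerance 1e-9.
    """
    if not 0.0 <= s < 1.0:
        raise ValueError("sync strength must lie in [0, 1); no finite kappa otherwise")
    if s == 0.0:
        return 0.0
    hi = 2.0
    while kappa_to_sync(hi) < s:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - s < 1 guarantees termination
            raise RuntimeError("failed to bracket kappa")
    sol = optimize.root_scalar(
        lambda k: kappa_to_sync(k) - s, bracket=(0.0, hi), method="brentq", rtol=1e-9
    )
    return float(sol.root)


def kappa_to_sync(kappa: float | NDArray) -> float | NDArray:
    """Mean resultant length ``I1(kappa)/I0(kappa)`` of a Von Mises density."""
    # i1e/i0e share the exp(-kappa) prefactor, stable for large kappa
    return special.i1e(kappa) / special.i0e(kappa)


def modulation_trace(
    phase: PhaseTrajectory,
    params: OscillationParams,
    rng: np.random.Generator,
) -> ModulationTrace:
    """Firing-rate modulation M(t) along a phase trajectory.

    Von Mises: ``M(t) = exp(kappa(t) cos(phi(t))) / I0(kappa(t))`` with
    ``kappa(t) = kappa_mean * (1 + sigma_a * eta_a(t))`` clipped at 0; the
    I0 term normalizes the phase-average of M to 1.

    Sinusoidal: ``M(t) = 1 + a(t) cos(phi(t))`` with
    ``a(t) = 2*S*(1 + sigma_a*eta_a(t))`` clipped to [0, 1]; the mean
    resultant length of the density ``1 + a cos(phi)`` is ``a/2``, so the
    mean amplitude ``2*S`` carries the same synchronization strength as the
    Von Mises waveform.

    ``waveform='none'`` returns M identically 1.
    """
    phi = phase.phase
    n_clipped = 0
    if params.waveform == "none":
        return ModulationTrace(values=np.ones_like(phi), dt=phase.dt)
    if params.sigma_a > 0:
        duration = phi.shape[-1] * phase.dt
        n_traces = phi.shape[0] if phi.ndim == 2 else None
        eta = lowpass_noise(duration, phase.dt, params.cutoff, rng, n_traces).values
        depth_factor = 1.0 + params.sigma_a * eta
    else:
        depth_factor = np.ones_like(phi)
    if params.waveform == "von_mises":
        kappa = sync_to_kappa(params.sync_strength) * depth_factor
        n_clipped = int(np.count_nonzero(kappa < 0))
        np.clip(kappa, 0.0, None, out=kappa)
        values = np.exp(kappa * (np.cos(phi) - 1.0)) / special.i0e(kappa)
    else:
        amp = 2.0 * params.sync_strength * depth_factor
        n_clipped = int(np.count_nonzero((amp < 0) | (amp > 1)))
        np.clip(amp, 0.0, 1.0, out=amp)
        values = 1.0 + amp * np.cos(phi)
    return ModulationTrace(values=values, dt=phase.dt, n_clipped=n_clipped)
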