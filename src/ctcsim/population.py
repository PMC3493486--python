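"""Synthetic input networks and sample-batch generation.

Each input network is a population of Poisson neurons coding an orientation
on the 0-180 degree circle with bell-shaped tuning curves, its instantaneous
rate multiplied by the network's oscillatory modulation.  Neurons project to
8 receiving units by preferred-orientation band, so for simulation we
aggregate each network to 8 band rates and draw band-level Poisson counts
(the sum of independent Poisson neurons is Poisson, so this is exact; the
per-neuron path is retained in the test suite as an oracle).

A :class:`SampleBatch` holds everything one decoding experiment needs: the
summed spike counts per receiving unit and time bin, the target network's
modulation trace (the receiving network's top-down reference signal), the
target band-rate traces (the stage-1 regression targets) and the stimulus
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from numpy.typing import NDArray
from scipy import special

from .oscillation import (
    ModulationTrace,
    OscillationParams,
    PhaseTrajectory,
    modulation_trace,
    phase_trajectory,
)

__all__ = [
    "InputNetworkSpec",
    "ConditionSpec",
    "SampleBatch",
    "CONDITION_NAMES",
    "tuning_concentration",
    "band_rates",
    "per_neuron_rates",
    "sample_counts",
    "build_condition",
    "generate_batch",
    "hann_window",
]

THETA_REF = 90.0  # reference orientation (deg); centred so labels never wrap

CONDITION_NAMES = (
    "asynchronous",
    "incoherent_same_band",
    "frequency_separated",
    "phase_separated",
    "broadband_target_asynch",
    "broadband_target_incoherent",
)


@dataclass(frozen=True)
class InputNetworkSpec:
    """One input network: a Poisson population with orientation tuning."""

    n_neurons: int = 10_000
    mean_rate: float = 5.0  # Hz per neuron, population average
    tuning_fwhm: float = 40.0  # full width at half maximum of tuning (deg)
    oscillation: OscillationParams = field(default_factory=OscillationParams)
    role: Literal["target", "distractor"] = "distractor"

    def __post_init__(self) -> None:
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be > 0")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")


@dataclass(frozen=True)
class ConditionSpec:
    """A full input condition: one target plus distractor networks."""

    condition: str
    networks: tuple[InputNetworkSpec, ...]
    n_bands: int = 8
    dt: float = 1e-3
    integration_time: float = 0.1
    freeze_target_modulation: bool = False

    def __post_init__(self) -> None:
        roles = [net.role for net in self.networks]
        if roles.count("target") != 1:
            raise ValueError("exactly one network must have role 'target'")
        if self.networks[0].n_neurons < self.n_bands:
            raise ValueError("need at least one neuron per band")

    @property
    def target_index(self) -> int:
        return next(i for i, net in enumerate(self.networks) if net.role == "target")

    @property
    def n_bins(self) -> int:
        return int(round(self.integration_time / self.dt))


@dataclass
class SampleBatch:
    """Binned spike counts plus per-sample reference signals and labels.

    ``counts[sample, unit, bin]`` is summed over all input networks.
    ``target_modulation[sample, bin]`` is the target network's modulation
    trace M(t); ``target_band_rates[sample, unit, bin]`` the target-network
    rate (spikes/s) arriving at each unit.  Labels are ``theta_ref ±
    delta_theta/2`` in degrees, balanced between the two values.
    """

    counts: NDArray[np.float64]
    target_modulation: NDArray[np.float64]
    target_band_rates: NDArray[np.float64]
    labels: NDArray[np.float64]
    delta_theta: float
    dt: float
    windowed: bool = False
    # un-tapered copies, preserved across windowing: the gain-generating
    # circuitry sees the raw reference signal (target modulation top-down,
    # summed spikes bottom-up); the taper applies to the integrated spike
    # activity only
    target_modulation_raw: NDArray[np.float64] | None = None
    counts_raw: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        if self.target_modulation_raw is None:
            self.target_modulation_raw = self.target_modulation
        if self.counts_raw is None:
            self.counts_raw = self.counts

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]


def tuning_concentration(fwhm_deg: float) -> float:
    """Concentration of the doubled-angle Von Mises tuning curve.

    The tuning curve ``exp(kappa*(cos(2*(theta - pref)) - 1))`` (angles in
    degrees on the 180-degree circle) falls to half its peak at
    ``theta - pref = fwhm/2``.
    """
    if fwhm_deg <= 0:
        raise ValueError("tuning FWHM must be > 0")
    if not np.isfinite(fwhm_deg):
        return 0.0  # flat (untuned) population
    return float(np.log(2.0) / (1.0 - np.cos(np.deg2rad(fwhm_deg))))


def per_neuron_rates(spec: InputNetworkSpec, stimulus: float) -> NDArray[np.float64]:
    """Mean firing rate of each neuron for a given stimulus orientation.

    Preferred orientations are evenly spaced on [0, 180); the bell-shaped
    tuning curve is a Von Mises on the doubled angle, globally scaled so the
    population-average rate equals ``spec.mean_rate``.
    """
    if not 0.0 <= stimulus < 180.0:
        raise ValueError("stimulus must lie in [0, 180) degrees")
    prefs = np.arange(spec.n_neurons) * (180.0 / spec.n_neurons)
    kappa = tuning_concentration(spec.tuning_fwhm)
    shape = np.exp(kappa * (np.cos(2.0 * np.deg2rad(stimulus - prefs)) - 1.0))
    # population average of exp(kappa*(cos psi - 1)) over uniform psi = i0e(kappa)
    return spec.mean_rate * shape / special.i0e(kappa)


def band_rates(
    spec: InputNetworkSpec, stimulus: float | NDArray, n_bands: int = 8
) -> NDArray[np.float64]:
    """Summed firing rate (spikes/s) per preferred-orientation band.

    Bands partition [0, 180) into ``n_bands`` equal widths; all neurons whose
    preference falls in a band project to the same receiving unit.  Accepts a
    vector of stimuli, returning shape ``(n_stimuli, n_bands)``.

    Evaluated through the Von Mises Fourier series
    ``exp(kappa cos psi) = I0 + 2 sum_m I_m cos(m psi)``: the sum over a
    band's evenly spaced preferences becomes a geometric sum per harmonic,
    so the result is exact (series truncated below double precision) at
    O(n_harmonics) cost per stimulus instead of O(n_neurons).
    """
    stim = np.atleast_1d(np.asarray(stimulus, dtype=float))
    if np.any((stim < 0) | (stim >= 180.0)):
        raise ValueError("stimulus must lie in [0, 180) degrees")
    n, r_mean = spec.n_neurons, spec.mean_rate
    kappa = tuning_concentration(spec.tuning_fwhm)
    # harmonic amplitudes I_m(kappa)/I_0(kappa), truncated at double precision
    m = np.arange(1, 200)
    ratio = special.ive(m, kappa) / special.i0e(kappa)
    m = m[ratio > 1e-17]
    ratio = ratio[ratio > 1e-17]
    # geometric sum of e^{-i 2 m p} over each band's evenly spaced preferences
    delta = np.pi / n  # doubled-angle spacing of preferences (rad)
    band_starts = np.arange(n_bands) * (np.pi / n_bands)  # doubled-angle band origins
    n_b = n // n_bands
    z = np.exp(-2j * m * delta)  # per-harmonic ratio of the geometric series
    with np.errstate(invalid="ignore", divide="ignore"):
        geo = (1.0 - z**n_b) / (1.0 - z)
    geo = np.where(np.isclose(z, 1.0), float(n_b), geo)
    s_m_j = np.exp(-2j * np.outer(m, band_starts)) * geo[:, None]  # (M, n_bands)
    phase = np.exp(2j * np.outer(np.deg2rad(stim), m))  # (S, M)
    out = r_mean * (n_b + 2.0 * np.real(phase @ (ratio[:, None] * s_m_j)))
    return out if np.ndim(stimulus) >= 1 else out[0]


def sample_counts(
    rates: NDArray[np.float64],
    modulation: ModulationTrace | NDArray[np.float64],
    dt: float,
    rng: np.random.Generator,
) -> NDArray[np.int64]:
    """Poisson spike counts per unit and time bin.

    ``counts[j, t] ~ Poisson(rates[j] * M(t) * dt)``; exact aggregation of
    the band's independent Poisson neurons.
    """
    m = modulation.values if isinstance(modulation, ModulationTrace) else np.asarray(modulation)
    lam = np.asarray(rates, dtype=float)[:, None] * m[None, :] * dt
    return rng.poisson(lam)


def _osc(
    waveform: str = "von_mises",
    frequency: float = 50.0,
    sync: float = 0.5,
    sigma_f: float = 0.1,
    phase_offset: float = 0.0,
    coherent_group: str | None = None,
) -> OscillationParams:
    return OscillationParams(
        waveform=waveform,  # type: ignore[arg-type]
        mean_frequency=frequency,
        sync_strength=sync,
        sigma_f=sigma_f,
        sigma_a=0.1,
        phase_offset=phase_offset,
        coherent_group=coherent_group,
    )


def build_condition(
    name: str,
    n_networks: int = 4,
    mean_rate: float = 5.0,
    sync_strength: float = 0.5,
    target_frequency: float = 50.0,
    distractor_frequency: float = 100.0,
    distractor_waveform: str = "von_mises",
    distractor_sigma_f: float | None = None,
    integration_time: float = 0.1,
    dt: float = 1e-3,
    n_neurons: int = 10_000,
    n_bands: int = 8,
    tuning_fwhm: float = 40.0,
    freeze_target_modulation: bool = False,
) -> ConditionSpec:
    """Build the oscillation structure for one named distractor condition.

    ``asynchronous``: narrowband Von Mises target, unmodulated distractors.
    ``incoherent_same_band``: all networks broadband (sigma_F = 0.3) at the
    target frequency with independent phase trajectories.
    ``frequency_separated``: narrowband target; distractors at
    ``distractor_frequency`` with independent phases (Von Mises or
    sinusoidal; narrow or broad via ``distractor_sigma_f``).
    ``phase_separated``: all networks share one coherent phase trajectory,
    offset by ``2*pi*k/n_networks``.
    ``broadband_target_*``: broadband target modulation with asynchronous or
    broadband-incoherent distractors.
    """
    if name not in CONDITION_NAMES:
        raise ValueError(f"unknown condition {name!r}; valid: {CONDITION_NAMES}")

    def net(role: str, osc: OscillationParams) -> InputNetworkSpec:
        return InputNetworkSpec(
            n_neurons=n_neurons,
            mean_rate=mean_rate,
            tuning_fwhm=tuning_fwhm,
            oscillation=osc,
            role=role,  # type: ignore[arg-type]
        )

    n_dist = n_networks - 1
    if name in ("asynchronous", "broadband_target_asynch"):
        sf = 0.1 if name == "asynchronous" else 0.3
        nets = [net("target", _osc(frequency=target_frequency, sync=sync_strength, sigma_f=sf))]
        nets += [net("distractor", _osc(waveform="none", sync=0.0)) for _ in range(n_dist)]
    elif name in ("incoherent_same_band", "broadband_target_incoherent"):
        nets = [net("target", _osc(frequency=target_frequency, sync=sync_strength, sigma_f=0.3))]
        nets += [
            net("distractor", _osc(frequency=target_frequency, sync=sync_strength, sigma_f=0.3))
            for _ in range(n_dist)
        ]
    elif name == "frequency_separated":
        d_sf = 0.1 if distractor_sigma_f is None else distractor_sigma_f
        nets = [net("target", _osc(frequency=target_frequency, sync=sync_strength, sigma_f=0.1))]
        nets += [
            net(
                "distractor",
                _osc(
                    waveform=distractor_waveform,
                    frequency=distractor_frequency,
                    sync=sync_strength,
                    sigma_f=d_sf,
                ),
            )
            for _ in range(n_dist)
        ]
    else:  # phase_separated
        nets = [
            net(
                "target" if k == 0 else "distractor",
                _osc(
                    frequency=target_frequency,
                    sync=sync_strength,
                    sigma_f=0.1,
                    phase_offset=2.0 * np.pi * k / n_networks,
                    coherent_group="shared",
                ),
            )
            for k in range(n_networks)
        ]
    return ConditionSpec(
        condition=name,
        networks=tuple(nets),
        n_bands=n_bands,
        dt=dt,
        integration_time=integration_time,
        freeze_target_modulation=freeze_target_modulation,
    )


def _network_modulations(
    cond: ConditionSpec, n_samples: int, rng: np.random.Generator
) -> list[NDArray[np.float64]]:
    """Per-network modulation traces of shape (n_samples, n_bins).

    Networks sharing a ``coherent_group`` share the per-sample phase
    trajectory (before their individual phase offsets); the target network's
    trace can be frozen across samples (arbitrary-gain experiments).
    """
    T, dt = cond.integration_time, cond.dt
    group_phase: dict[str, PhaseTrajectory] = {}
    out: list[NDArray[np.float64]] = []
    for i, netspec in enumerate(cond.networks):
        osc = netspec.oscillation
        if osc.waveform == "none":
            out.append(np.ones((n_samples, cond.n_bins)))
            continue
        freeze = cond.freeze_target_modulation and i == cond.target_index
        n_draw = 1 if freeze else n_samples
        if osc.coherent_group is not None:
            key = osc.coherent_group
            if key not in group_phase:
                base = replace(osc, phase_offset=0.0)
                group_phase[key] = phase_trajectory(base, T, dt, rng, n_traces=n_draw)
            traj = group_phase[key]
            traj = PhaseTrajectory(
                phase=traj.phase + osc.phase_offset,
                instantaneous_frequency=traj.instantaneous_frequency,
                dt=traj.dt,
                n_clipped=traj.n_clipped,
            )
        else:
            traj = phase_trajectory(osc, T, dt, rng, n_traces=n_draw)
        m = modulation_trace(traj, osc, rng).values
        if freeze:
            m = np.broadcast_to(m, (n_samples, cond.n_bins)).copy()
        out.append(m)
    return out


def generate_batch(
    cond: ConditionSpec,
    delta_theta: float,
    n_samples: int,
    seed: int | np.random.SeedSequence,
) -> SampleBatch:
    """Generate one train or test set of spike-count samples.

    Half the samples carry target orientation ``theta_ref - delta/2``, half
    ``theta_ref + delta/2`` (shuffled); distractor orientations are uniform
    on [0, 180) per sample; every network gets fresh phase and fluctuation
    traces per sample (unless the target modulation is frozen).
    """
    if n_samples % 2:
        raise ValueError("n_samples must be even (balanced labels)")
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    labels = np.concatenate(
        [np.full(half, THETA_REF - delta_theta / 2.0), np.full(half, THETA_REF + delta_theta / 2.0)]
    )
    rng.shuffle(labels)

    modulations = _network_modulations(cond, n_samples, rng)
    counts = np.zeros((n_samples, cond.n_bands, cond.n_bins), dtype=np.int64)
    tgt = cond.target_index
    for i, netspec in enumerate(cond.networks):
        if netspec.role == "target":
            stims = labels
        else:
            stims = rng.uniform(0.0, 180.0, size=n_samples)
        rates = band_rates(netspec, stims, cond.n_bands)  # (n_samples, n_bands)
        lam = rates[:, :, None] * modulations[i][:, None, :] * cond.dt
        counts += rng.poisson(lam)
    target_rates = band_rates(cond.networks[tgt], labels, cond.n_bands)
    target_band_rate_traces = target_rates[:, :, None] * modulations[tgt][:, None, :]
    return SampleBatch(
        counts=counts.astype(float),
        target_modulation=modulations[tgt],
        target_band_rates=target_band_rate_traces,
        labels=labels,
        delta_theta=delta_theta,
        dt=cond.dt,
    )


def hann_window(batch: SampleBatch) -> SampleBatch:
    """Apply a Hann taper along time to counts and reference signals.

    Reduces spectral leakage of the finite integration window.  The window
    multiplies the spike counts, the stage-1 target rate traces and the
    target modulation alike, keeping the stage-1 regression well posed.
    """
    if batch.windowed:
        raise ValueError("batch is already windowed")
    w = np.hanning(batch.n_bins)
    return SampleBatch(
        counts=batch.counts * w,
        target_modulation=batch.target_modulation * w,
        target_band_rates=batch.target_band_rates * w,
        labels=batch.labels,
        delta_theta=batch.delta_theta,
        dt=batch.dt,
        windowed=True,
        target_modulation_raw=batch.target_modulation_raw,
        counts_raw=batch.counts_raw,
    )
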