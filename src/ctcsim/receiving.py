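"""The receiving network: filtered gain modulation and temporal integration.

Each of the 8 projection units multiplies its incoming spike train by a
common time-varying gain g(t) and integrates over the window:
``A_j = sum_t g(t) * n_j(t)``.  The gain may be negative (net inhibition),
so distractor spikes arriving in negative-gain periods cancel those arriving
in positive-gain periods.

In the top-down model g(t) is a linearly filtered version of the target
network's firing-rate modulation: ``G(k) = H(k) * R(k)`` in the discrete
Fourier domain, where R is the DFT of the reference signal and H the filter
frequency response being optimized.  Plancherel's theorem lets the
integrated activity be written as a real linear function of the stacked
real/imaginary parts of H — the per-sample design matrix used by all
gradient-descent stages.

DFT conventions: unnormalized forward transform, 1/n inverse (numpy
``rfft``/``irfft``); H is stored at the n//2+1 non-negative frequencies with
conjugate symmetry implied, and sums over frequency double the interior
bins (the negative-frequency half of the spectrum is redundant for real
signals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "FilterFrequencyResponse",
    "n_freqs",
    "freq_weights",
    "gain_from_filter",
    "integrate",
    "plancherel_integrate",
    "design_matrix",
    "design_matrices",
    "bottom_up_reference",
]


@dataclass
class FilterFrequencyResponse:
    """Complex filter response H(k) at non-negative DFT frequencies.

    ``coefficients[k]`` applies at frequency ``k / T`` Hz for a window of
    duration T; ``n_bins`` is the length of the underlying time window.
    The k = 0 (DC) coefficient must be real, as must the Nyquist bin when
    ``n_bins`` is even.
    """

    coefficients: NDArray[np.complex128]
    n_bins: int

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        if self.coefficients.shape != (n_freqs(self.n_bins),):
            raise ValueError(
                f"expected {n_freqs(self.n_bins)} coefficients for {self.n_bins} bins"
            )

    @classmethod
    def zeros(cls, n_bins: int) -> "FilterFrequencyResponse":
        return cls(np.zeros(n_freqs(n_bins), dtype=complex), n_bins)

    def as_real_vector(self) -> NDArray[np.float64]:
        """Stack [Re H; Im H] into one real parameter vector."""
        return np.concatenate([self.coefficients.real, self.coefficients.imag])

    @classmethod
    def from_real_vector(cls, u: NDArray[np.float64], n_bins: int) -> "FilterFrequencyResponse":
        k = n_freqs(n_bins)
        return cls(u[:k] + 1j * u[k:], n_bins)


def n_freqs(n_bins: int) -> int:
    """Number of non-negative DFT frequencies for an n_bins window."""
    return n_bins // 2 + 1


def freq_weights(n_bins: int) -> NDArray[np.float64]:
    """Multiplicity of each non-negative frequency in the full DFT sum.

    1 for DC (and Nyquist when n_bins is even), 2 for interior bins whose
    negative-frequency twins are folded in by conjugate symmetry.
    """
    d = np.full(n_freqs(n_bins), 2.0)
    d[0] = 1.0
    if n_bins % 2 == 0:
        d[-1] = 1.0
    return d


def gain_from_filter(
    h: FilterFrequencyResponse, reference: NDArray[np.float64]
) -> NDArray[np.float64]:
    """Gain trace g(t): the reference signal passed through the filter.

    ``g = irfft(H * rfft(reference))``; with H identically 1 this returns
    the reference unchanged.  Accepts a batch of references (..., n_bins).
    """
    ref = np.asarray(reference, dtype=float)
    if ref.shape[-1] != h.n_bins:
        raise ValueError("reference length does not match filter bin count")
    return np.fft.irfft(h.coefficients * np.fft.rfft(ref, axis=-1), n=h.n_bins, axis=-1)


def integrate(gain: NDArray[np.float64], counts: NDArray[np.float64]) -> NDArray[np.float64]:
    """Integrated activity ``A_j = sum_t g(t) * counts[j, t]`` per unit.

    Broadcasts over leading sample axes: gain (..., n_bins) against counts
    (..., n_units, n_bins) gives (..., n_units).
    """
    gain = np.asarray(gain, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if gain.shape[-1] != counts.shape[-1]:
        raise ValueError("gain and counts disagree on the number of time bins")
    return np.einsum("...t,...jt->...j", gain, counts)


def plancherel_integrate(
    h: FilterFrequencyResponse,
    reference_spectrum: NDArray[np.complex128],
    count_spectra: NDArray[np.complex128],
) -> NDArray[np.float64]:
    """Integrated activity computed entirely in the frequency domain.

    ``A_j = (1/n) sum_k d_k Re[ H(k) R(k) conj(N_j(k)) ]`` with d_k the
    frequency multiplicities; equals ``integrate(gain_from_filter(...))``
    to numerical precision on the same windowed sample.
    """
    d = freq_weights(h.n_bins) / h.n_bins
    g_spec = h.coefficients * np.asarray(reference_spectrum)
    prod = g_spec * np.conj(np.asarray(count_spectra))
    return np.einsum("k,...jk->...j", d, prod.real)


def design_matrix(
    reference_spectrum: NDArray[np.complex128],
    count_spectra: NDArray[np.complex128],
    n_bins: int,
) -> NDArray[np.float64]:
    """Per-sample matrix Z mapping stacked [Re H; Im H] to activity A.

    With ``B_j(k) = (d_k/n) R(k) conj(N_j(k))`` the activity is
    ``A_j = sum_k Re H_k Re B_jk - Im H_k Im B_jk``, i.e. ``A = Z u`` with
    ``Z = [Re B, -Im B]`` of shape (n_units, 2 * n_freqs).
    """
    d = freq_weights(n_bins) / n_bins
    b = d * np.asarray(reference_spectrum) * np.conj(np.asarray(count_spectra))
    return np.concatenate([b.real, -b.imag], axis=-1)


def design_matrices(
    references: NDArray[np.float64], counts: NDArray[np.float64]
) -> NDArray[np.float64]:
    """Stack of per-sample design matrices for a whole batch.

    references: (n_samples, n_bins); counts: (n_samples, n_units, n_bins).
    Returns (n_samples, n_units, 2 * n_freqs).
    """
    n_bins = references.shape[-1]
    r = np.fft.rfft(references, axis=-1)
    c = np.fft.rfft(counts, axis=-1)
    return design_matrix(r[:, None, :], c, n_bins)


def bottom_up_reference(counts: NDArray[np.float64]) -> NDArray[np.float64]:
    """Summed spike activity across units: the bottom-up reference signal.

    In the bottom-up model the circuitry generating the gain modulation sees
    no top-down control signal, only the combined input spike train; the
    same filter machinery then acts on this sum instead of the target
    modulation.
    """
    return np.asarray(counts, dtype=float).sum(axis=-2)
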