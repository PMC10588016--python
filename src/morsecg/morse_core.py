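"""Closed-form generalized Morse wavelet math and analytic filterbank design.

The generalized Morse wavelet is a two-parameter family of exactly analytic
wavelets defined directly in the frequency domain:

    Psi(omega) = U(omega) * a_{beta,gamma} * omega**beta * exp(-omega**gamma)

where ``U`` is the unit step (no support at non-positive frequencies),
``gamma`` controls the symmetry of the envelope (gamma = 3 gives zero
skewness), and ``beta = P^2 / gamma`` is the decay parameter derived from the
time-bandwidth product ``P^2``.  The normalizing constant is chosen as

    a_{beta,gamma} = 2 * (e * gamma / beta) ** (beta / gamma)

so that the spectral peak amplitude equals exactly 2 - the usual convention
for analytic wavelets, and a cleanly testable invariant.  The peak sits at
the angular frequency (beta/gamma)**(1/gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MorseParams",
    "FilterBank",
    "morse_wavelet_ft",
    "peak_frequency",
    "design_filterbank",
]


@dataclass(frozen=True)
class MorseParams:
    """Generalized Morse wavelet parameters.

    Parameters
    ----------
    gamma : float
        Symmetry parameter, > 0.  Default 3 (zero-skewness family).
    p2 : float
        Time-bandwidth product ``P^2``, > 0.  Controls how many oscillations
        fit under the envelope.  Default 60.
    """

    gamma: float = 3.0
    p2: float = 60.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError(f"gamma must be a positive finite number, got {self.gamma}")
        if not (np.isfinite(self.p2) and self.p2 > 0):
            raise ValueError(f"p2 must be a positive finite number, got {self.p2}")

    @property
    def beta(self) -> float:
        """Decay parameter ``beta = P^2 / gamma``."""
        return self.p2 / self.gamma


def morse_wavelet_ft(omega, params: MorseParams | None = None) -> np.ndarray:
    """Frequency-domain amplitude of the generalized Morse wavelet.

    Evaluates ``a * omega**beta * exp(-omega**gamma)`` for positive
    frequencies and exactly 0 for ``omega <= 0``, with the peak-amplitude-2
    normalization.

    Parameters
    ----------
    omega : array_like
        Angular frequency grid in radians/sample.  Must be finite.
    params : MorseParams, optional
        Wavelet parameters; defaults to gamma=3, P^2=60.

    Returns
    -------
    numpy.ndarray
        Nonnegative amplitude, same shape as ``omega``.
    """
    if params is None:
        params = MorseParams()
    omega = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ValueError("omega grid contains non-finite entries (NaN or inf)")
    beta, gamma = params.beta, params.gamma
    amp = np.zeros(omega.shape if omega.shape else (1,), dtype=float)
    om = np.atleast_1d(omega)
    pos = om > 0
    # log-space evaluation: 2*exp(r*(1+log(1/r_inv)) ...) avoids overflow of
    # omega**beta for large beta; r = beta/gamma
    r = beta / gamma
    with np.errstate(divide="ignore"):
        log_amp = np.log(2.0) + r * (1.0 + np.log(gamma / beta)) + beta * np.log(
            om[pos]
        ) - om[pos] ** gamma
    amp = np.zeros_like(om)
    amp[pos] = np.exp(log_amp)
    return amp.reshape(omega.shape) if omega.shape else amp[0]


def peak_frequency(params: MorseParams) -> float:
    """Angular frequency of the Morse wavelet's spectral maximum.

    Returns ``(beta/gamma)**(1/gamma)`` in radians/sample.
    """
    beta = params.beta
    if beta <= 0:
        raise ValueError(
            f"peak frequency undefined for beta={beta}: the wavelet has no interior maximum"
        )
    return float((beta / params.gamma) ** (1.0 / params.gamma))


@dataclass
class FilterBank:
    """A bank of analytic Morse filters on a geometric center-frequency grid.

    Attributes
    ----------
    center_frequencies : numpy.ndarray
        Descending center frequencies in radians/sample; consecutive entries
        differ by the exact factor ``2**(-1/voices_per_octave)``.
    filters : numpy.ndarray
        (n_filters, padded_length) nonnegative frequency-domain amplitudes on
        the full DFT grid of the padded transform length.  Bins representing
        non-positive frequencies are exactly zero (analyticity).
    """

    center_frequencies: np.ndarray
    filters: np.ndarray
    voices_per_octave: int
    signal_length: int
    sampling_rate: float
    params: MorseParams
    padded_length: int = field(default=0)

    @property
    def n_filters(self) -> int:
        return len(self.center_frequencies)

    @property
    def center_frequencies_hz(self) -> np.ndarray:
        """Center frequencies converted to Hz via f = omega * fs / (2*pi)."""
        return self.center_frequencies * self.sampling_rate / (2.0 * np.pi)

    def filters_for_length(self, n_fft: int) -> np.ndarray:
        """Evaluate the bank's filters on the DFT grid of an arbitrary length.

        The filter centered at ``omega_c`` is the base wavelet evaluated at the
        rescaled argument ``omega * (omega_p / omega_c)`` so its peak lands on
        ``omega_c`` (self-similarity).
        """
        omega_p = peak_frequency(self.params)
        k = np.arange(n_fft)
        omega = 2.0 * np.pi * k / n_fft
        # bins above Nyquist alias to negative frequencies: zero support there
        omega = np.where(k > n_fft // 2, -1.0, omega)
        scale = omega_p / self.center_frequencies[:, None]
        return morse_wavelet_ft(omega[None, :] * scale, self.params)

    def to_table(self) -> pd.DataFrame:
        """Center frequencies as a table in both radians/sample and Hz."""
        return pd.DataFrame(
            {
                "center_rad_per_sample": self.center_frequencies,
                "center_hz": self.center_frequencies_hz,
            }
        )


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def padded_length_for(signal_length: int) -> int:
    """FFT length after reflection extension: next power of two of N + 2*ceil(N/2)."""
    ext = signal_length + 2 * ((signal_length + 1) // 2)
    return _next_pow2(ext)


def _omega_max_default(params: MorseParams) -> float:
    """Largest center frequency whose filter amplitude at Nyquist (pi) is
    at most half its peak, found by bisection.

    The amplitude at pi of the filter centered at omega_c increases
    monotonically with omega_c on (0, pi], reaching the full peak value 2 at
    omega_c = pi, so the half-peak crossing is unique.
    """
    omega_p = peak_frequency(params)

    def amp_at_nyquist(omega_c: float) -> float:
        return float(morse_wavelet_ft(np.array([np.pi * omega_p / omega_c]), params)[0])

    lo, hi = 1e-8, np.pi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if amp_at_nyquist(mid) > 1.0:
            hi = mid
        else:
            lo = mid
    return lo


def _omega_min_default(params: MorseParams, signal_length: int) -> float:
    """Smallest admissible center: two approximate time-domain standard
    deviations (each ~ sqrt(P^2)/omega) must fit in the N-sample window."""
    return 2.0 * np.sqrt(2.0) * np.sqrt(params.p2) / signal_length


def design_filterbank(
    signal_length: int,
    sampling_rate: float,
    params: MorseParams | None = None,
    voices_per_octave: int = 12,
    freq_limits: tuple[float, float] | None = None,
) -> FilterBank:
    """Design an analytic Morse filterbank for fixed-length signals.

    Center frequencies form the geometric grid
    ``omega_k = omega_max * 2**(-k / voices_per_octave)`` descending to the
    smallest center >= ``omega_min``, so the bank gains exactly
    ``voices_per_octave`` filters per octave of span.

    Parameters
    ----------
    signal_length : int
        Length of the signals the bank will transform, in samples (>= 4).
    sampling_rate : float
        Sampling rate in Hz; used only to report frequencies in Hz and to
        validate explicit ``freq_limits``.
    params : MorseParams, optional
        Wavelet family parameters (default gamma=3, P^2=60).
    voices_per_octave : int
        Number of filters per frequency doubling (>= 1); default 12.
    freq_limits : (low, high) in Hz, optional
        Explicit frequency span; must satisfy 0 < low < high <= Nyquist.
        When omitted, the high limit keeps spectral leakage past Nyquist
        below half the peak and the low limit keeps the wavelet's time
        support inside the analysis window.
    """
    if params is None:
        params = MorseParams()
    if signal_length < 4:
        raise ValueError(f"signal_length must be >= 4, got {signal_length}")
    if voices_per_octave < 1:
        raise ValueError(f"voices_per_octave must be >= 1, got {voices_per_octave}")
    if sampling_rate <= 0:
        raise ValueError(f"sampling_rate must be positive, got {sampling_rate}")

    if freq_limits is not None:
        low, high = freq_limits
        nyq = sampling_rate / 2.0
        if not (0 < low < high <= nyq):
            raise ValueError(
                f"freq_limits must satisfy 0 < low < high <= Nyquist ({nyq} Hz); "
                f"got low={low}, high={high}"
            )
        omega_min = 2.0 * np.pi * low / sampling_rate
        omega_max = 2.0 * np.pi * high / sampling_rate
    else:
        omega_max = _omega_max_default(params)
        omega_min = _omega_min_default(params, signal_length)

    n_octaves = np.log2(omega_max / omega_min)
    if n_octaves < 0:
        raise ValueError(
            f"frequency grid is empty: omega_max={omega_max:.4g} < omega_min={omega_min:.4g} "
            f"rad/sample (signal too short for this P^2?)"
        )
    n_filters = int(np.floor(n_octaves * voices_per_octave)) + 1
    k = np.arange(n_filters)
    centers = omega_max * 2.0 ** (-k / voices_per_octave)

    bank = FilterBank(
        center_frequencies=centers,
        filters=np.empty((0, 0)),
        voices_per_octave=voices_per_octave,
        signal_length=signal_length,
        sampling_rate=sampling_rate,
        params=params,
        padded_length=padded_length_for(signal_length),
    )
    bank.filters = bank.filters_for_length(bank.padded_length)
    return bank
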