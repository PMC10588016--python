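"""FFT-based continuous wavelet transform against a Morse filterbank.

Each filter row of the scalogram is the inverse DFT of (forward DFT of the
boundary-extended signal x filter), trimmed back to the original support.
Because the Morse filters are real and nonnegative in the frequency domain
with no support at negative frequencies, the coefficients are the analytic
signal seen through each band - no conjugation ambiguity arises.

Boundary handling defaults to symmetric reflection extension by ceil(N/2)
samples on each side (curbing edge artifacts on short ECG segments); a
``periodic`` mode performs a plain circular transform, under which the
magnitude is exactly shift-covariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .morse_core import FilterBank, MorseParams, design_filterbank, _next_pow2

__all__ = ["Scalogram", "cwt", "magnitude", "MorseScalogram"]


@dataclass
class Scalogram:
    """Complex CWT coefficients with frequency and time axes.

    Attributes
    ----------
    coefficients : numpy.ndarray
        Complex matrix (n_filters, n_samples); row order matches the
        filterbank's descending center frequencies.
    frequencies : numpy.ndarray
        Center frequency of each row in Hz, descending.
    times : numpy.ndarray
        Time of each column in seconds.
    """

    coefficients: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    params: MorseParams
    sampling_rate: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.coefficients.shape


def cwt(signal, bank: FilterBank, boundary: str = "reflect") -> Scalogram:
    """Continuous wavelet transform of a real signal against a filterbank.

    Parameters
    ----------
    signal : array_like
        Real-valued samples; length must equal ``bank.signal_length``.
    bank : FilterBank
        Analytic Morse filterbank from :func:`morsecg.design_filterbank`.
    boundary : {"reflect", "periodic"}
        ``reflect`` (default) extends the signal by symmetric reflection by
        ceil(N/2) samples each side before the transform and trims after;
        ``periodic`` transforms circularly with no extension.

    Returns
    -------
    Scalogram
        Complex coefficients (n_filters, len(signal)).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"signal must be one-dimensional, got shape {x.shape}")
    if len(x) != bank.signal_length:
        raise ValueError(
            f"signal length {len(x)} does not match filterbank signal_length "
            f"{bank.signal_length}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values (NaN or inf)")

    n = len(x)
    if boundary == "reflect":
        pad = (n + 1) // 2
        ext = np.concatenate([x[pad - 1 :: -1] if pad <= n else x[::-1], x, x[: -pad - 1 : -1]])
        n_fft = _next_pow2(len(ext))
        work = np.zeros(n_fft)
        work[: len(ext)] = ext
        start = pad
    elif boundary == "periodic":
        n_fft = n
        work = x
        start = 0
    else:
        raise ValueError(f"boundary must be 'reflect' or 'periodic', got {boundary!r}")

    filters = (
        bank.filters
        if bank.filters.size and bank.filters.shape[1] == n_fft
        else bank.filters_for_length(n_fft)
    )
    xf = np.fft.fft(work)
    coeffs = np.fft.ifft(xf[None, :] * filters, axis=1)[:, start : start + n]

    return Scalogram(
        coefficients=coeffs,
        frequencies=bank.center_frequencies_hz.copy(),
        times=np.arange(n) / bank.sampling_rate,
        params=bank.params,
        sampling_rate=bank.sampling_rate,
    )


def magnitude(scalogram: Scalogram) -> np.ndarray:
    """Elementwise modulus of the scalogram coefficients (nonnegative)."""
    return np.abs(scalogram.coefficients)


class MorseScalogram(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: ECG segments -> scalogram magnitude stacks.

    ``fit`` designs the Morse filterbank for the segment length seen in the
    data; ``transform`` maps an (n_segments, n_samples) array to an
    (n_segments, n_filters, n_samples) array of CWT coefficient magnitudes.

    Parameters
    ----------
    sampling_rate : float
        Sampling rate in Hz (default 128).
    gamma, p2 : float
        Morse wavelet parameters (defaults 3 and 60).
    voices_per_octave : int
        Filters per octave (default 12).
    freq_limits : (low, high) in Hz, optional
        Explicit filterbank span.
    boundary : {"reflect", "periodic"}
        Boundary rule passed to :func:`cwt`.

    Attributes
    ----------
    bank_ : FilterBank
        The designed filterbank.
    frequencies_ : numpy.ndarray
        Row center frequencies in Hz, descending.
    """

    def __init__(
        self,
        sampling_rate: float = 128.0,
        gamma: float = 3.0,
        p2: float = 60.0,
        voices_per_octave: int = 12,
        freq_limits: tuple[float, float] | None = None,
        boundary: str = "reflect",
    ):
        self.sampling_rate = sampling_rate
        self.gamma = gamma
        self.p2 = p2
        self.voices_per_octave = voices_per_octave
        self.freq_limits = freq_limits
        self.boundary = boundary

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"X must be (n_segments, n_samples), got shape {X.shape}")
        self.bank_ = design_filterbank(
            signal_length=X.shape[1],
            sampling_rate=self.sampling_rate,
            params=MorseParams(gamma=self.gamma, p2=self.p2),
            voices_per_octave=self.voices_per_octave,
            freq_limits=self.freq_limits,
        )
        self.frequencies_ = self.bank_.center_frequencies_hz
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "bank_"):
            raise RuntimeError("MorseScalogram must be fitted before transform")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"X must be (n_segments, n_samples), got shape {X.shape}")
        out = np.empty((X.shape[0], self.bank_.n_filters, X.shape[1]))
        for i, row in enumerate(X):
            out[i] = magnitude(cwt(row, self.bank_, boundary=self.boundary))
        return out
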