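"""Morlet time-frequency decomposition and ERD/S quantification.

Wavelets are parameterized by the FWHM of their temporal amplitude envelope
(140 ms by default), so the number of cycles grows automatically with
frequency.  With that convention the FWHM of the kernel's power spectrum is
(2 ln 2) / (pi * fwhm_t) ~ 4.46 Hz, i.e. the spectral resolution quoted for
the analysis.  Power is expressed in dB relative to the median resting-state
power (median over rest epochs and time points, per frequency); negative
values are event-related desynchronization (ERD), positive values
synchronization (ERS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import Epochs
from .csp import BandSpec

#: default analysis grid
DEFAULT_FREQS = np.arange(3.0, 30.0 + 1e-9, 0.3)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def morlet_kernel(freq_hz: float, sfreq: float, fwhm_t_s: float = 0.14,
                  n_sigma: float = 5.0) -> np.ndarray:
    """Complex Morlet kernel, L2-normalized, truncated at +-n_sigma.

    The Gaussian amplitude envelope has temporal FWHM ``fwhm_t_s``.
    """
    if freq_hz >= sfreq / 2:
        raise ValueError(f"wavelet frequency {freq_hz} >= Nyquist")
    sigma = fwhm_t_s * _FWHM_TO_SIGMA
    if sigma * sfreq < 2:
        raise ValueError("temporal FWHM too short for the sampling rate")
    half = int(np.ceil(n_sigma * sigma * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    gauss = np.exp(-(t ** 2) / (2 * sigma ** 2))
    # admissibility correction: remove the DC leakage of low-cycle kernels
    dc = np.exp(-0.5 * (2 * np.pi * freq_hz * sigma) ** 2)
    kernel = (np.exp(2j * np.pi * freq_hz * t) - dc) * gauss
    return kernel / np.linalg.norm(kernel)


def spectral_fwhm(kernel: np.ndarray, sfreq: float, n_fft: int = 2 ** 16) -> float:
    """FWHM of the kernel's FFT power spectrum, by linear interpolation."""
    spec = np.abs(np.fft.fft(kernel, n_fft)) ** 2
    freqs = np.fft.fftfreq(n_fft, 1.0 / sfreq)
    pos = freqs >= 0
    spec, freqs = spec[pos], freqs[pos]
    peak = np.argmax(spec)
    half = spec[peak] / 2.0

    def cross(idx_range) -> float:
        for i in idx_range:
            lo, hi = sorted((spec[i], spec[i + 1]))
            if lo <= half <= hi:
                f0, f1, s0, s1 = freqs[i], freqs[i + 1], spec[i], spec[i + 1]
                return f0 + (half - s0) * (f1 - f0) / (s1 - s0)
        raise ValueError("half-maximum crossing not found")

    f_left = cross(range(peak, 0, -1))
    f_right = cross(range(peak, len(spec) - 1))
    return float(abs(f_right - f_left))


@dataclass
class TFRArray:
    """Wavelet power: (epochs, components, frequencies, times), uV^2."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fwhm_t: float
    valid: np.ndarray  # (frequencies, times) True where no edge contamination

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


def tfr_transform(epochs: Epochs | np.ndarray, sfreq: float | None = None,
                  times: np.ndarray | None = None,
                  freqs: np.ndarray = DEFAULT_FREQS,
                  fwhm_t: float = 0.14,
                  dtype: np.dtype | type = np.complex128) -> TFRArray:
    """Morlet power of every epoch/component at each grid frequency.

    Convolution is 'same'-mode per epoch; samples closer to an epoch edge
    than half the kernel support are flagged invalid at that frequency.
    """
    if isinstance(epochs, Epochs):
        data, sfreq, times = epochs.data, epochs.sfreq, epochs.times
    else:
        data = np.asarray(epochs)
        if sfreq is None or times is None:
            raise ValueError("sfreq and times required for array input")
    freqs = np.asarray(freqs, dtype=float)
    n_t = data.shape[-1]
    real_dtype = np.float32 if np.dtype(dtype) == np.complex64 else np.float64
    data = np.asarray(data, dtype=real_dtype)
    power = np.empty(data.shape[:-1] + (len(freqs), n_t), dtype=real_dtype)
    valid = np.zeros((len(freqs), n_t), dtype=bool)
    for i, f in enumerate(freqs):
        kernel = morlet_kernel(f, sfreq, fwhm_t).astype(dtype)
        conv = sps.oaconvolve(data, kernel[(None,) * (data.ndim - 1)],
                              mode="same", axes=-1)
        power[..., i, :] = np.abs(conv) ** 2
        half = len(kernel) // 2
        margin = half // 2  # half the one-sided support
        if 2 * margin < n_t:
            valid[i, margin : n_t - margin] = True
    return TFRArray(power, freqs, np.asarray(times), fwhm_t, valid)


@dataclass
class ERDSTimecourse:
    """Band ERD/S dynamics in dB; negative = ERD, positive = ERS."""

    values: np.ndarray  # (epochs-or-subjects, times) or (times,)
    times: np.ndarray
    band: BandSpec
    condition: str = ""
    reference: str = "median rest power per frequency"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ERD/S values must be finite")


def rest_reference(tfr_rest: TFRArray) -> np.ndarray:
    """Median rest power over epochs and valid times, per component and
    frequency: shape (components, frequencies)."""
    if tfr_rest.power.shape[0] == 0:
        raise ValueError("rest TFR is empty")
    n_comp, n_freq = tfr_rest.power.shape[1:3]
    ref = np.empty((n_comp, n_freq))
    for i in range(n_freq):
        tsel = tfr_rest.valid[i]
        if not tsel.any():
            tsel = slice(None)
        ref[:, i] = np.median(tfr_rest.power[:, :, i, tsel], axis=(0, 2))
    if np.any(ref <= 0):
        raise ValueError("degenerate rest reference: zero median power")
    return ref


def erds_db(tfr_active: TFRArray, tfr_rest: TFRArray, band: BandSpec,
            collapse: str = "median") -> ERDSTimecourse:
    """Band ERD/S time-course of the active epochs vs the rest reference.

    Returns the median (over epochs, band frequencies and components) dB
    time-course; with ``collapse='none'`` the per-epoch course is kept.
    """
    band.validate()
    fsel = (tfr_active.freqs >= band.range_hz[0] - 1e-9) & \
           (tfr_active.freqs <= band.range_hz[1] + 1e-9)
    if not fsel.any():
        raise ValueError(f"band {band.range_hz} not covered by the TFR grid")
    ref = rest_reference(tfr_rest)  # (comp, freq)
    ratio = tfr_active.power[:, :, fsel, :] / ref[None, :, fsel, None]
    db = 10.0 * np.log10(ratio)
    if collapse == "median":
        values = np.median(db, axis=(0, 1, 2))
    elif collapse == "epochs":
        values = np.median(db, axis=(1, 2))
    elif collapse == "none":
        values = db
    else:
        raise ValueError(f"unknown collapse mode {collapse!r}")
    return ERDSTimecourse(values, tfr_active.times, band)
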