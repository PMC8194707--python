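"""Complex-Morlet time-frequency analysis of accelerometer traces.

A complex Morlet wavelet at central frequency ``fc`` is

    w(t, fc) = A * exp(-t^2 / (2 sigma_t^2)) * exp(i 2 pi fc t),

with a constant quality ratio fc / sigma_f = 7, sigma_t = 1 / (2 pi sigma_f)
and normalisation A = (sigma_t sqrt(pi))^(-1/2) so that the wavelet has unit
energy. The time-varying energy of a signal s(t) is the squared modulus of
its convolution with the wavelet,

    E(t, fc) = |(w(., fc) * s)(t)|^2,

evaluated over a frequency sweep (0.05-5 Hz by default, 100 linear bins).
Phase is discarded. The energy matrix is rendered as a fixed-size
(28 x 28 x 3) colormapped image in [0, 1] — the input consumed by the
stacked-autoencoder classifier; time maps to image width (so traces of
unequal duration land on a common raster) and frequency to height with low
frequencies at the bottom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

__all__ = [
    "MORLET_QUALITY_RATIO",
    "TF_COLORMAP",
    "MorletWavelet",
    "FrequencyGrid",
    "TFRepresentation",
    "TFImage",
    "build_morlet",
    "make_frequency_grid",
    "transform",
    "render_image",
]

#: Constant ratio fc / sigma_f of the Morlet family.
MORLET_QUALITY_RATIO = 7.0

#: Name of the fixed rainbow-style colormap used for TF images.
TF_COLORMAP = "jet"

#: Wavelet support truncation, in units of sigma_t (Gaussian tail < 1e-8).
_SUPPORT_SIGMAS = 6.0


@dataclass(frozen=True)
class MorletWavelet:
    fc: float
    sigma_f: float
    sigma_t: float
    A: float
    sampling_rate: float
    times: np.ndarray  # symmetric support, seconds
    samples: np.ndarray  # complex, evaluated on `times`


@dataclass(frozen=True)
class FrequencyGrid:
    frequencies: np.ndarray
    fmin: float
    fmax: float
    n_bins: int


@dataclass(frozen=True)
class TFRepresentation:
    """Energy matrix E(t, fc): rows are grid frequencies, columns time samples."""

    energy: np.ndarray  # (n_bins, T), non-negative
    time_axis: np.ndarray  # seconds, length T
    frequency_grid: FrequencyGrid


@dataclass(frozen=True)
class TFImage:
    """H x W x 3 colormapped image in [0, 1]; low frequency at the bottom row."""

    pixels: np.ndarray
    source_axis: str = ""

    def flatten(self) -> np.ndarray:
        return self.pixels.reshape(-1)


def build_morlet(fc: float, sampling_rate: float) -> MorletWavelet:
    """Construct the complex Morlet wavelet at central frequency ``fc`` (Hz).

    The support is truncated at +-6 sigma_t and sampled at the trace rate.
    A warning is emitted when the sampling rate is below the Nyquist
    requirement 2 fc.
    """
    if not np.isfinite(fc) or fc <= 0:
        raise ValueError(f"fc must be positive and finite, got {fc!r}")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if sampling_rate <= 2 * fc:
        warnings.warn(
            f"sampling rate {sampling_rate} Hz is not above 2*fc = {2 * fc} Hz; "
            "the wavelet is undersampled",
            stacklevel=2,
        )
    sigma_f = fc / MORLET_QUALITY_RATIO
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    A = (sigma_t * np.sqrt(np.pi)) ** -0.5
    half = int(np.ceil(_SUPPORT_SIGMAS * sigma_t * sampling_rate))
    times = np.arange(-half, half + 1) / sampling_rate
    samples = A * np.exp(-(times**2) / (2 * sigma_t**2)) * np.exp(2j * np.pi * fc * times)
    return MorletWavelet(
        fc=fc, sigma_f=sigma_f, sigma_t=sigma_t, A=A,
        sampling_rate=sampling_rate, times=times, samples=samples,
    )


def make_frequency_grid(fmin: float = 0.05, fmax: float = 5.0, n_bins: int = 100) -> FrequencyGrid:
    """Linearly spaced frequency sweep with both endpoints included."""
    if not (0 < fmin < fmax):
        raise ValueError(f"need 0 < fmin < fmax, got fmin={fmin}, fmax={fmax}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    return FrequencyGrid(
        frequencies=np.linspace(fmin, fmax, n_bins), fmin=fmin, fmax=fmax, n_bins=n_bins
    )


# One-slot cache of the wavelet filter bank in the frequency domain: the bank
# depends only on (grid, sampling rate, fft size), all constant within a cohort.
_BANK_CACHE: dict = {}


def _filter_bank(grid: FrequencyGrid, sampling_rate: float, nfft: int):
    key = (grid.fmin, grid.fmax, grid.n_bins, sampling_rate, nfft)
    cached = _BANK_CACHE.get(key)
    if cached is not None:
        return cached
    wavelets = [build_morlet(fc, sampling_rate) for fc in grid.frequencies]
    bank = np.empty((grid.n_bins, nfft), dtype=complex)
    lengths = np.empty(grid.n_bins, dtype=int)
    for i, w in enumerate(wavelets):
        lengths[i] = len(w.samples)
        bank[i] = np.fft.fft(w.samples, nfft)
    _BANK_CACHE.clear()
    _BANK_CACHE[key] = (bank, lengths)
    return bank, lengths


def _max_support(grid: FrequencyGrid, sampling_rate: float) -> int:
    sigma_t_max = MORLET_QUALITY_RATIO / (2 * np.pi * grid.fmin)
    return 2 * int(np.ceil(_SUPPORT_SIGMAS * sigma_t_max * sampling_rate)) + 1


def transform(signal: np.ndarray, sampling_rate: float, grid: FrequencyGrid) -> TFRepresentation:
    """Morlet energy map of a 1-D signal: |w(., fc) * s|^2 per grid frequency.

    Convolution uses mode "same" with zero padding, so the output has one
    column per input sample. The discrete convolution sum is scaled by the
    sample interval to approximate the continuous convolution integral.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size < 2:
        raise ValueError("signal must be 1-D with at least 2 samples")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains NaN or infinite values")
    T = signal.size
    # Pad to a power of two covering linear (non-circular) convolution with
    # the longest wavelet in the bank; a fixed size keeps the bank cacheable.
    nfft = 1 << int(T + _max_support(grid, sampling_rate) - 1).bit_length()
    bank, lengths = _filter_bank(grid, sampling_rate, nfft)
    S = np.fft.fft(signal, nfft)
    conv = np.fft.ifft(bank * S, axis=1)
    dt = 1.0 / sampling_rate
    energy = np.empty((grid.n_bins, T))
    for i in range(grid.n_bins):
        start = (lengths[i] - 1) // 2  # centre of the "same" window
        energy[i] = np.abs(conv[i, start : start + T] * dt) ** 2
    return TFRepresentation(
        energy=energy,
        time_axis=np.arange(T) / sampling_rate,
        frequency_grid=grid,
    )


def render_image(
    tfr: TFRepresentation,
    height: int = 28,
    width: int = 28,
    colormap: str = TF_COLORMAP,
    normalization: str = "per-image",
    global_range: tuple[float, float] | None = None,
) -> TFImage:
    """Render an energy matrix as an H x W x 3 image in [0, 1].

    Energy is min-max normalised (per image by default, or to a caller-
    supplied global range), mapped through the fixed colormap, then
    bilinearly resampled: time to width, frequency to height with the
    lowest frequency on the bottom row. All-constant energy maps to the
    colormap's lowest colour.
    """
    E = np.asarray(tfr.energy, dtype=float)
    if E.size == 0:
        raise ValueError("empty time-frequency representation")
    if normalization == "global" and global_range is not None:
        lo, hi = global_range
    elif normalization == "per-image":
        lo, hi = E.min(), E.max()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    norm = np.zeros_like(E) if hi <= lo else np.clip((E - lo) / (hi - lo), 0.0, 1.0)
    rgb = colormaps[colormap](norm)[..., :3]
    rgb = rgb[::-1]  # row 0 = highest frequency (image top)
    if rgb.shape[:2] != (height, width):
        rgb = resize(rgb, (height, width), order=1, mode="edge", anti_aliasing=False)
    return TFImage(pixels=np.clip(rgb, 0.0, 1.0))
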