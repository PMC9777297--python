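"""Complex Morlet wavelet band power and frontal alpha asymmetry features.

The time-frequency feature set assigns to each 1-s window one log band-power
value per (channel, band) — obtained by convolving with complex Morlet
wavelets at 1-Hz steps across the band and averaging squared magnitude over
time and frequency — plus one frontal-alpha-asymmetry (FAA) score per
frontal homologous electrode pair.

A complex Morlet wavelet is a complex exponential tapered by a Gaussian,

    w(t) = exp(-t^2 / 2 s^2) * exp(i 2 pi f t),

where the Gaussian width s = C / (2 pi f) is set by the number of cycles C
at centre frequency f.  Kernels are L2-normalised to unit energy so that
white noise yields the same expected power at every centre frequency.

FAA follows the convention  FAA = ln P_right - ln P_left  in the alpha band:
positive values indicate relatively *greater left* cortical activation
(alpha power varies inversely with activation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .bands import ALPHA, TABLE_BANDS, BandSpec
from .features import FeatureArray, FeatureDescriptor, flag_zero_variance
from .montage import Montage, homologous_pairs
from .preprocessing import WindowSet

DEFAULT_CYCLES = 7.0
POWER_FLOOR = 1e-12  # uV^2; log power of silence is ln of this floor
_PAD_SECONDS = 2.0   # wavelet time axis spans +/- 2 s


@dataclass(frozen=True)
class WaveletParams:
    """Centre frequency f (Hz), cycle count C, and sampling rate."""

    f: float
    cycles: float = DEFAULT_CYCLES
    sampling_rate: float = 250.0

    def __post_init__(self) -> None:
        if self.f <= 0 or self.cycles <= 0 or self.sampling_rate <= 0:
            raise ValueError("f, cycles and sampling_rate must be positive")

    @property
    def s(self) -> float:
        """Gaussian width in seconds: s = C / (2 pi f)."""
        return self.cycles / (2.0 * np.pi * self.f)

    @property
    def t(self) -> np.ndarray:
        """Time axis centred at zero spanning +/- 2 s."""
        half = round(_PAD_SECONDS * self.sampling_rate)
        return np.arange(-half, half + 1) / self.sampling_rate


def complex_morlet(params: WaveletParams, normalize: bool = True) -> np.ndarray:
    """The complex Morlet kernel on the +/- 2 s grid, unit energy by default."""
    s = params.s
    if s <= 0:
        raise ValueError("Gaussian width must be positive")
    t = params.t
    # analytic convention: positive-frequency carrier, so the magnitude
    # spectrum peaks at +f; band powers are identical under conjugation
    kernel = np.exp(-t**2 / (2.0 * s**2)) * np.exp(2j * np.pi * params.f * t)
    if normalize:
        kernel = kernel / np.linalg.norm(kernel)
    return kernel


def band_frequencies(band: BandSpec) -> np.ndarray:
    """Integer-Hz wavelet centre frequencies spanning the band."""
    freqs = np.arange(np.ceil(band.f_lo), np.floor(band.f_hi) + 1.0)
    if freqs.size == 0:  # sub-1-Hz-wide band: use the midpoint
        freqs = np.array([(band.f_lo + band.f_hi) / 2.0])
    return freqs


def _batch_band_log_power(windows: np.ndarray, sampling_rate: float,
                          bands: tuple[BandSpec, ...],
                          cycles: float = DEFAULT_CYCLES) -> np.ndarray:
    """Log band power for every (window, channel, band).

    ``windows`` is (n_windows, n_channels, n_samples).  Each channel trace is
    reflection-padded by 2 s per side so the kernel support fits, convolved
    (FFT) with unit-energy Morlet kernels at 1-Hz steps, and the squared
    magnitude is averaged over the original samples and over the band's
    frequencies before taking ln (floored at ``POWER_FLOOR``).
    """
    nyq = sampling_rate / 2.0
    for band in bands:
        if band.f_hi >= nyq:
            raise ValueError(f"band {band.name} reaches Nyquist ({nyq} Hz)")
    n_w, n_ch, n_s = windows.shape
    max_pad = round(_PAD_SECONDS * sampling_rate)
    flat = np.asarray(windows, dtype=np.float32).reshape(n_w * n_ch, n_s)
    out = np.empty((n_w, n_ch, len(bands)))
    for b, band in enumerate(bands):
        freqs = band_frequencies(band)
        # Kernel support: the widest Gaussian in the band, truncated at four
        # widths (tail energy < 1e-6 of total) but never beyond the +/- 2 s
        # wavelet span.  Shorter supports keep the FFTs small.
        s_max = cycles / (2.0 * np.pi * freqs.min())
        pad = min(max_pad, int(np.ceil(4.0 * s_max * sampling_rate)))
        k_len = 2 * pad + 1
        padded = np.pad(flat, ((0, 0), (pad, pad)), mode="reflect")
        nfft = sfft.next_fast_len(padded.shape[1] + k_len - 1)
        spec = sfft.fft(padded, n=nfft, axis=1)
        # centre of the 'same' convolution for the original (unpadded) samples
        start = (k_len - 1) // 2 + pad
        t = np.arange(-pad, pad + 1) / sampling_rate
        acc = np.zeros(n_w * n_ch)
        for f in freqs:
            s = cycles / (2.0 * np.pi * f)
            kernel = np.exp(-t**2 / (2.0 * s**2)) * np.exp(2j * np.pi * f * t)
            kernel = (kernel / np.linalg.norm(kernel)).astype(np.complex64)
            kspec = sfft.fft(kernel, n=nfft)
            conv = sfft.ifft(spec * kspec[None, :], axis=1)[:, start:start + n_s]
            acc += np.mean(np.abs(conv)**2, axis=1)
        power = acc / len(freqs)
        out[:, :, b] = np.log(np.maximum(power, POWER_FLOOR)).reshape(n_w, n_ch)
    return out


def wavelet_power(window: np.ndarray, band: BandSpec, cycles: float = DEFAULT_CYCLES,
                  sampling_rate: float = 250.0) -> np.ndarray:
    """Log band power per channel for one window (n_channels, n_samples)."""
    if window.ndim != 2:
        raise ValueError("window must be (n_channels, n_samples)")
    return _batch_band_log_power(window[None], sampling_rate, (band,), cycles)[0, :, 0]


def faa(power_left: np.ndarray | float, power_right: np.ndarray | float) -> np.ndarray | float:
    """Frontal alpha asymmetry from log powers: ln P_right - ln P_left."""
    return np.asarray(power_right) - np.asarray(power_left)


def extract_timefreq_features(window_set: WindowSet,
                              bands: tuple[BandSpec, ...] = TABLE_BANDS,
                              montage: Montage | None = None,
                              cycles: float = DEFAULT_CYCLES,
                              alpha_band: BandSpec = ALPHA) -> FeatureArray:
    """Per-window log band powers for all (channel, band) plus frontal FAA.

    With the default 63-channel montage and five bands this yields
    63 x 5 + 7 = 322 columns.  FAA columns reuse the alpha-band log powers
    of the frontal homologous pairs; constant columns are flagged in their
    descriptors.
    """
    if montage is None:
        raise ValueError("montage is required to name channels and pairs")
    if window_set.n_windows == 0:
        return FeatureArray(np.empty((0, 0)), (), window_set.labels,
                            window_set.groups, window_set.participant_id)
    if window_set.windows.shape[1] != montage.n_channels:
        raise ValueError("window channel count does not match montage")

    band_list = tuple(bands)
    if alpha_band not in band_list:
        all_bands = band_list + (alpha_band,)
    else:
        all_bands = band_list
    logp = _batch_band_log_power(window_set.windows, window_set.sampling_rate,
                                 all_bands, cycles)
    alpha_idx = all_bands.index(alpha_band)

    cols: list[np.ndarray] = []
    descriptors: list[FeatureDescriptor] = []
    for b, band in enumerate(band_list):
        for c, ch in enumerate(montage.channel_names):
            cols.append(logp[:, c, b])
            descriptors.append(FeatureDescriptor("band_power", band.name, channel=ch))
    for left, right in homologous_pairs(montage, "frontal"):
        li, ri = montage.index(left), montage.index(right)
        cols.append(faa(logp[:, li, alpha_idx], logp[:, ri, alpha_idx]))
        descriptors.append(FeatureDescriptor("faa", alpha_band.name, pair=(left, right)))

    X = np.column_stack(cols)
    desc = flag_zero_variance(tuple(descriptors), X)
    return FeatureArray(X, desc, window_set.labels, window_set.groups,
                        window_set.participant_id)
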