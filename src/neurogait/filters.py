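"""Preprocessing filter bank for ΔHbO channel series.

Six methods are provided, all linear and channel-independent:

``butterworth``
    4th-order IIR band-pass (default 0.01-0.5 Hz), applied zero-phase
    (forward-backward) so features are not lag-shifted.
``fir``
    Window-method FIR band-pass, also zero-phase. A literal 4th-order
    (5-tap) FIR cannot realize a 0.01 Hz edge, so the design uses an
    odd-length window whose support covers at least two periods of the
    low cut-off; the tap count is configurable.
``kalman``
    Causal scalar random-walk Kalman filter per channel
    (state x_k = x_{k-1} + w, observation y_k = x_k + v).
``wiener``
    Time-varying Wiener filter on a short-time Fourier transform: per-bin
    gain S/(S+N) with the noise power spectrum estimated from a designated
    rest-baseline segment.
``gaussian`` / ``hrf``
    Unit-sum kernel smoothing (Gaussian of configured FWHM, or the canonical
    double-gamma hemodynamic response kernel) with reflected-edge padding, so
    the DC level is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .blocks import TimeSeriesBlock
from .synthgen import canonical_hrf

__all__ = ["FilterSpec", "apply_filter", "apply_bandpass", "kalman_smooth",
           "wiener_smooth", "smooth_kernel", "FILTER_METHODS"]

FILTER_METHODS = ("butterworth", "fir", "kalman", "wiener", "gaussian", "hrf")

_GAUSS_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class FilterSpec:
    """Configuration for one preprocessing method."""

    method: str = "hrf"
    band: tuple[float, float] = (0.01, 0.5)
    order: int = 4
    fir_taps: int | None = None          # odd; default from low band edge
    kalman_q: float = 1e-4
    kalman_r: float = 1e-2
    wiener_window_s: float = 16.0   # must fit inside the 30 s rest baseline
    baseline_s: tuple[float, float] | None = None   # rest segment for N est.
    gaussian_fwhm_s: float = 4.0
    hrf_duration_s: float = 30.0

    def __post_init__(self) -> None:
        if self.method not in FILTER_METHODS:
            raise ValueError(f"unknown filter method {self.method!r}")
        if self.method in ("butterworth", "fir"):
            lo, hi = self.band
            if not 0 < lo < hi:
                raise ValueError("band must satisfy 0 < low < high")
        if self.kalman_q <= 0 or self.kalman_r <= 0:
            raise ValueError("Kalman variances must be positive")
        if self.wiener_window_s <= 0 or self.gaussian_fwhm_s <= 0:
            raise ValueError("window/FWHM must be positive")


def apply_filter(block: TimeSeriesBlock, spec: FilterSpec) -> TimeSeriesBlock:
    """Dispatch to the configured method; returns a new block."""
    if spec.method in ("butterworth", "fir"):
        return apply_bandpass(block, spec)
    if spec.method == "kalman":
        return kalman_smooth(block, spec)
    if spec.method == "wiener":
        return wiener_smooth(block, spec)
    return smooth_kernel(block, spec)


# ---------------------------------------------------------------- band-pass

def butterworth_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    lo, hi = spec.band
    return signal.butter(spec.order, [lo, hi], btype="bandpass", fs=fs,
                         output="sos")


def fir_taps(spec: FilterSpec, fs: float) -> np.ndarray:
    lo, hi = spec.band
    n = spec.fir_taps
    if n is None:
        # support >= two periods of the low edge
        n = int(round(2.0 / lo * fs))
    if n % 2 == 0:
        n += 1
    return signal.firwin(n, [lo, hi], pass_zero=False, fs=fs)


def apply_bandpass(block: TimeSeriesBlock, spec: FilterSpec) -> TimeSeriesBlock:
    """Zero-phase band-pass (Butterworth IIR or window-method FIR)."""
    lo, hi = spec.band
    nyq = block.fs / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz >= Nyquist {nyq} Hz")
    x = block.data
    if spec.method == "butterworth":
        sos = butterworth_sos(spec, block.fs)
        y = signal.sosfiltfilt(sos, x, axis=-1)
    else:
        taps = fir_taps(spec, block.fs)
        if taps.size >= block.n_samples:
            raise ValueError("FIR kernel longer than the signal")
        padlen = min(3 * taps.size, block.n_samples - 1)
        y = signal.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)
    return block.with_data(y)


# ------------------------------------------------------------------ Kalman

def kalman_smooth(block: TimeSeriesBlock, spec: FilterSpec) -> TimeSeriesBlock:
    """Causal random-walk Kalman filter, per channel.

    Initialization: x0 = first sample, P0 = r. The steady-state gain of the
    scalar recursion is reached within a few samples for the default q/r.
    """
    q, r = spec.kalman_q, spec.kalman_r
    x = block.data
    y = np.empty_like(x)
    for ch in range(x.shape[0]):
        est = x[ch, 0]
        p = r
        y[ch, 0] = est
        for k in range(1, x.shape[1]):
            p = p + q                      # predict
            gain = p / (p + r)             # update
            est = est + gain * (x[ch, k] - est)
            p = (1.0 - gain) * p
            y[ch, k] = est
    return block.with_data(y)


# ------------------------------------------------------------------ Wiener

def _stft_pair(n_window: int, fs: float) -> signal.ShortTimeFFT:
    win = signal.windows.hann(n_window, sym=False)
    hop = max(1, n_window // 2)
    return signal.ShortTimeFFT(win, hop=hop, fs=fs, fft_mode="onesided")

def wiener_smooth(block: TimeSeriesBlock, spec: FilterSpec,
                  noise_psd: np.ndarray | None = None,
                  signal_psd: np.ndarray | None = None) -> TimeSeriesBlock:
    """STFT-domain Wiener filter with per-bin gain S/(S+N).

    ``N`` is the noise power spectrum, estimated from the rest-baseline
    segment named by ``spec.baseline_s`` (or passed explicitly via
    ``noise_psd``). ``S`` is the per-frame clean-signal power estimate
    ``max(|X|² - N, 0)`` unless ``signal_psd`` pins it explicitly, in which
    case the gains are the stationary ``S/(S+N)`` values.
    """
    n_window = int(round(spec.wiener_window_s * block.fs))
    if n_window < 4:
        raise ValueError("wiener window must span at least 4 samples")
    n_window = min(n_window, block.n_samples)
    stft = _stft_pair(n_window, block.fs)

    if noise_psd is None:
        if spec.baseline_s is None:
            raise ValueError("wiener filter needs a baseline segment or an "
                             "explicit noise PSD")
        b0, b1 = spec.baseline_s
        i0, i1 = int(round(b0 * block.fs)), int(round(b1 * block.fs))
        if i1 - i0 < n_window:
            raise ValueError("baseline segment shorter than the STFT window")
        base = block.data[:, i0:i1]
        bs = stft.stft(base, axis=-1)
        noise_psd = np.mean(np.abs(bs) ** 2, axis=-1)    # (ch, bins)
    noise_psd = np.atleast_2d(noise_psd)

    X = stft.stft(block.data, axis=-1)                   # (ch, bins, frames)
    N = noise_psd[..., None]
    if signal_psd is not None:
        S = np.atleast_2d(signal_psd)[..., None] * np.ones_like(np.abs(X))
    else:
        S = np.maximum(np.abs(X) ** 2 - N, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(S + N > 0, S / (S + N), 1.0)
    y = stft.istft(gain * X, k1=block.n_samples)[..., : block.n_samples]
    return block.with_data(np.real(y))


def wiener_gains(signal_psd: np.ndarray, noise_psd: np.ndarray) -> np.ndarray:
    """Stationary per-bin Wiener gains S/(S+N) (exposed for verification)."""
    S = np.asarray(signal_psd, dtype=float)
    N = np.asarray(noise_psd, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(S + N > 0, S / (S + N), 1.0)


# --------------------------------------------------------------- smoothing

def smooth_kernel(block: TimeSeriesBlock, spec: FilterSpec) -> TimeSeriesBlock:
    """Convolve with a unit-sum Gaussian or canonical-HRF kernel
    (reflected-edge padding, same-length output)."""
    if spec.method == "gaussian":
        sigma_samples = spec.gaussian_fwhm_s / _GAUSS_FWHM_TO_SIGMA * block.fs
        radius = int(np.ceil(4 * sigma_samples))
        if 2 * radius + 1 > block.n_samples:
            raise ValueError("Gaussian kernel longer than the signal")
        y = ndimage.gaussian_filter1d(block.data, sigma_samples, axis=-1,
                                      mode="reflect")
        return block.with_data(y)

    kernel = canonical_hrf(block.fs, spec.hrf_duration_s)
    if kernel.size > block.n_samples:
        raise ValueError("HRF kernel longer than the signal")
    y = ndimage.convolve1d(block.data, kernel, axis=-1, mode="reflect")
    return block.with_data(y)


def gaussian_sigma_samples(fwhm_s: float, fs: float) -> float:
    """σ in samples for a Gaussian smoothing kernel of the given FWHM."""
    return fwhm_s / _GAUSS_FWHM_TO_SIGMA * fs
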