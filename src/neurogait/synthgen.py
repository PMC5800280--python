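"""Synthetic two-wavelength fNIRS recordings for a walk/rest block paradigm.

The generator reproduces the statistical structure the downstream decoding
pipeline assumes: a task-locked hemodynamic response (boxcar convolved with a
canonical double-gamma HRF) superposed with cardiac, respiratory and
Mayer-wave sinusoids, a slow linear drift and white noise. Oxygenated
hemoglobin (HbO) carries the task response; deoxygenated hemoglobin (HbR) is
an inverted, attenuated copy, matching the usual antiphase behaviour of the
two chromophores.

Sampling is deliberately slow (default 1.81 Hz, the rate of the DYNOT-class
tomography instrument the protocol assumes), which puts the 1-1.5 Hz cardiac
band above Nyquist. Cardiac contamination is therefore injected at its
*aliased* frequency ``|f - fs*round(f/fs)|`` so that the contaminant the
filters see is actually representable at this rate.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .blocks import (
    HBO_KIND,
    HBR_KIND,
    OD_KIND,
    Montage,
    NoiseSpec,
    Paradigm,
    TimeSeriesBlock,
)

__all__ = [
    "make_paradigm",
    "default_paradigm",
    "default_montage",
    "canonical_hrf",
    "simulate_hbo",
    "hemo_to_od",
    "aliased_frequency",
    "HBR_INVERSION_RATIO",
]

#: HbR task component = -ratio x HbO task component (typical inversion ratio;
#: only HbO is analysed downstream).
HBR_INVERSION_RATIO = 1.0 / 3.0


def make_paradigm(trial_count: int, task_s: float, rest_s: float,
                  lead_in_s: float, lead_out_s: float, fs: float) -> Paradigm:
    """Build the block design and its per-sample boxcar regressor."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    if trial_count < 0:
        raise ValueError("trial_count must be non-negative")
    for name, v in (("task_s", task_s), ("rest_s", rest_s),
                    ("lead_in_s", lead_in_s), ("lead_out_s", lead_out_s)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")

    total = lead_in_s + trial_count * (task_s + rest_s) + lead_out_s
    n = int(round(total * fs))
    t = np.arange(n) / fs
    boxcar = np.zeros(n)
    onset = lead_in_s
    for _ in range(trial_count):
        boxcar[(t >= onset) & (t < onset + task_s)] = 1.0
        onset += task_s + rest_s
    return Paradigm(trial_count=trial_count, task_s=task_s, rest_s=rest_s,
                    lead_in_s=lead_in_s, lead_out_s=lead_out_s, fs=fs,
                    boxcar=boxcar)


def default_paradigm(fs: float = 1.81) -> Paradigm:
    """The walking protocol: 10 trials of 10 s treadmill walk + 20 s standing
    rest, with 30 s lead-in/lead-out rest (300 s active duration)."""
    return make_paradigm(10, 10.0, 20.0, 30.0, 30.0, fs)


def default_montage() -> Montage:
    """12-channel grid over left M1: 5 sources and 4 detectors on a 3 cm
    lattice around C3. Positions are metadata only; all channels are 3 cm
    source-detector pairs."""
    s = 3.0
    # sources on lattice corners/centre, detectors interleaved
    sources = {
        "S1": (0.0, 0.0), "S2": (2 * s, 0.0), "S3": (s, s),
        "S4": (0.0, 2 * s), "S5": (2 * s, 2 * s),
    }
    detectors = {
        "D1": (s, 0.0), "D2": (0.0, s), "D3": (2 * s, s), "D4": (s, 2 * s),
    }
    channels = (
        ("S1", "D1"), ("S1", "D2"), ("S2", "D1"), ("S2", "D3"),
        ("S3", "D1"), ("S3", "D2"), ("S3", "D3"), ("S3", "D4"),
        ("S4", "D2"), ("S4", "D4"), ("S5", "D3"), ("S5", "D4"),
    )
    return Montage(sources=sources, detectors=detectors, channels=channels,
                   separation_cm=s)


def canonical_hrf(fs: float, duration_s: float = 30.0, peak_delay_s: float = 6.0,
                  undershoot_delay_s: float = 16.0, peak_disp: float = 1.0,
                  undershoot_disp: float = 1.0,
                  undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response kernel, unit-sum normalized.

    ``h(t) = g(t; peak_delay, disp) - ratio * g(t; undershoot_delay, disp)``
    with ``g`` the gamma density (shape = delay/dispersion, scale =
    dispersion). Defaults give the familiar ~5 s peak with a late undershoot.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if duration_s < peak_delay_s:
        raise ValueError("duration_s must cover the response peak")
    t = np.arange(int(round(duration_s * fs))) / fs
    peak = stats.gamma.pdf(t, a=peak_delay_s / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, a=undershoot_delay_s / undershoot_disp,
                            scale=undershoot_disp)
    h = peak - undershoot_ratio * under
    total = h.sum()
    if total == 0:
        raise ValueError("degenerate HRF kernel (zero sum)")
    return h / total


def aliased_frequency(f: float, fs: float) -> float:
    """Frequency at which a sinusoid of true frequency ``f`` appears when
    sampled at ``fs`` (folding about Nyquist)."""
    return abs(f - fs * round(f / fs))


def _task_component(paradigm: Paradigm, amplitude: float) -> np.ndarray:
    kernel = canonical_hrf(paradigm.fs)
    conv = np.convolve(paradigm.boxcar, kernel)[: paradigm.n_samples]
    return amplitude * conv


def _noise_channels(n_channels: int, n_samples: int, fs: float,
                    noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_samples) / fs
    out = np.zeros((n_channels, n_samples))
    comps = (
        (aliased_frequency(noise.cardiac_hz, fs), noise.cardiac_amp),
        (aliased_frequency(noise.respiration_hz, fs), noise.respiration_amp),
        (aliased_frequency(noise.mayer_hz, fs), noise.mayer_amp),
    )
    for ch in range(n_channels):
        for f, a in comps:
            phase = rng.uniform(0.0, 2 * np.pi)
            out[ch] += a * np.sin(2 * np.pi * f * t + phase)
        out[ch] += noise.drift_per_sample * np.arange(n_samples)
        if noise.white_sd > 0:
            out[ch] += rng.normal(0.0, noise.white_sd, n_samples)
    return out


def simulate_hbo(paradigm: Paradigm, montage: Montage,
                 response_amplitude_uM: float = 1.0,
                 noise: NoiseSpec | None = None,
                 ) -> tuple[TimeSeriesBlock, TimeSeriesBlock]:
    """Simulate ΔHbO and ΔHbR blocks (μM) for one subject.

    Every channel receives the same task component (boxcar ⊛ HRF scaled by
    ``response_amplitude_uM``) plus channel-specific noise realizations with
    independent phases. HbR is the task component scaled by
    ``-HBR_INVERSION_RATIO`` plus its own independent noise at one third of
    the configured amplitudes. Reproducible for a fixed ``noise.seed``.
    """
    if noise is None:
        noise = NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    n_ch = montage.n_channels
    n = paradigm.n_samples
    task = _task_component(paradigm, response_amplitude_uM)

    hbo = task[None, :] + _noise_channels(n_ch, n, paradigm.fs, noise, rng)
    hbr_noise_spec = NoiseSpec(
        cardiac_hz=noise.cardiac_hz, cardiac_amp=noise.cardiac_amp / 3.0,
        respiration_hz=noise.respiration_hz,
        respiration_amp=noise.respiration_amp / 3.0,
        mayer_hz=noise.mayer_hz, mayer_amp=noise.mayer_amp / 3.0,
        drift_per_sample=noise.drift_per_sample / 3.0,
        white_sd=noise.white_sd / 3.0, seed=noise.seed)
    hbr = (-HBR_INVERSION_RATIO * task)[None, :] + _noise_channels(
        n_ch, n, paradigm.fs, hbr_noise_spec, rng)

    names = [f"{s}-{d}" for s, d in montage.channels]
    hbo_block = TimeSeriesBlock(hbo, paradigm.fs, HBO_KIND, montage=montage,
                                channel_names=names)
    hbr_block = TimeSeriesBlock(hbr, paradigm.fs, HBR_KIND, montage=montage,
                                channel_names=names)
    return hbo_block, hbr_block


def hemo_to_od(hbo: TimeSeriesBlock, hbr: TimeSeriesBlock, ext: np.ndarray,
               l_cm: float, dpf: float
               ) -> tuple[TimeSeriesBlock, TimeSeriesBlock]:
    """Forward Beer-Lambert: hemoglobin concentration changes -> OD changes.

    ``ΔA(t, λi) = d * l * (α_HbO(λi) ΔcHbO(t) + α_HbR(λi) ΔcHbR(t))`` with
    ``ext`` the 2x2 extinction matrix (rows = wavelengths, columns =
    [HbO, HbR], μM⁻¹·cm⁻¹). Inverse of :func:`neurogait.mbll.mbll_convert`.
    """
    ext = np.asarray(ext, dtype=float)
    if ext.shape != (2, 2):
        raise ValueError("extinction table must be 2x2")
    if abs(np.linalg.det(ext)) < 1e-12:
        raise np.linalg.LinAlgError("extinction table is singular")
    if l_cm <= 0 or dpf <= 0:
        raise ValueError("path length and DPF must be positive")
    if hbo.data.shape != hbr.data.shape or hbo.fs != hbr.fs:
        raise ValueError("HbO and HbR blocks must be aligned")

    conc = np.stack([hbo.data, hbr.data])          # (2, ch, n)
    od = dpf * l_cm * np.einsum("wk,kcn->wcn", ext, conc)
    mk = dict(fs=hbo.fs, kind=OD_KIND, montage=hbo.montage,
              channel_names=hbo.channel_names, units="dOD")
    from .mbll import WAVELENGTHS_NM
    od1 = TimeSeriesBlock(od[0], wavelength_nm=WAVELENGTHS_NM[0], **mk)
    od2 = TimeSeriesBlock(od[1], wavelength_nm=WAVELENGTHS_NM[1], **mk)
    return od1, od2
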