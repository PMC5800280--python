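"""Shared containers for multichannel fNIRS time series and experiment metadata.

A recording is represented as a :class:`TimeSeriesBlock`: a channels x samples
matrix at a single uniform sampling rate, tagged with what the rows mean
(optical-density changes at one wavelength, or a hemoglobin chromophore) and
the optode montage that produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Paradigm",
    "Montage",
    "TimeSeriesBlock",
    "NoiseSpec",
    "OD_KIND",
    "HBO_KIND",
    "HBR_KIND",
]

OD_KIND = "optical_density"
HBO_KIND = "HbO"
HBR_KIND = "HbR"


@dataclass(frozen=True)
class Paradigm:
    """Block design: ``lead_in`` rest, then ``trial_count`` cycles of task+rest,
    then ``lead_out`` rest. The boxcar regressor is 1 during task samples."""

    trial_count: int
    task_s: float
    rest_s: float
    lead_in_s: float
    lead_out_s: float
    fs: float
    boxcar: np.ndarray = field(repr=False)

    @property
    def active_duration_s(self) -> float:
        """Duration of the trial section, excluding lead-in/lead-out."""
        return self.trial_count * (self.task_s + self.rest_s)

    @property
    def total_duration_s(self) -> float:
        return self.lead_in_s + self.active_duration_s + self.lead_out_s

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_s * self.fs))

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def task_intervals(self) -> list[tuple[float, float]]:
        """(onset, offset) seconds for each task block."""
        out = []
        t = self.lead_in_s
        for _ in range(self.trial_count):
            out.append((t, t + self.task_s))
            t += self.task_s + self.rest_s
        return out

    def rest_intervals(self) -> list[tuple[float, float]]:
        """(onset, offset) seconds for each within-trial rest block."""
        out = []
        t = self.lead_in_s
        for _ in range(self.trial_count):
            out.append((t + self.task_s, t + self.task_s + self.rest_s))
            t += self.task_s + self.rest_s
        return out


@dataclass(frozen=True)
class Montage:
    """Planar optode layout: labeled source/detector scalp positions plus the
    source-detector pairings that define measurement channels."""

    sources: dict[str, tuple[float, float]]
    detectors: dict[str, tuple[float, float]]
    channels: tuple[tuple[str, str], ...]
    separation_cm: float = 3.0

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_distance(self, idx: int) -> float:
        s, d = self.channels[idx]
        ps = np.asarray(self.sources[s], dtype=float)
        pd = np.asarray(self.detectors[d], dtype=float)
        return float(np.linalg.norm(ps - pd))


@dataclass
class TimeSeriesBlock:
    """channels x samples signal matrix with uniform sampling.

    ``kind`` is one of ``optical_density`` (with ``wavelength_nm`` set),
    ``HbO`` or ``HbR`` (units μM).
    """

    data: np.ndarray
    fs: float
    kind: str
    montage: Montage | None = None
    wavelength_nm: float | None = None
    units: str = "uM"
    channel_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.isfinite(self.data).all():
            raise ValueError("TimeSeriesBlock contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.kind == OD_KIND and self.wavelength_nm is None:
            raise ValueError("optical-density block requires wavelength_nm")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def with_data(self, data: np.ndarray) -> "TimeSeriesBlock":
        """Copy of this block with ``data`` replaced (metadata preserved)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass(frozen=True)
class NoiseSpec:
    """Physiological + instrumental contaminants injected by the generator.

    Frequencies in Hz, amplitudes in the units of the target block (μM for
    hemoglobin). ``drift`` is a slope per sample; ``white_sd`` the standard
    deviation of additive white noise.
    """

    cardiac_hz: float = 1.2
    cardiac_amp: float = 0.20
    respiration_hz: float = 0.5
    respiration_amp: float = 0.10
    mayer_hz: float = 0.10
    mayer_amp: float = 0.15
    drift_per_sample: float = 1e-4
    white_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.cardiac_hz, self.respiration_hz, self.mayer_hz):
            if f <= 0:
                raise ValueError("noise frequencies must be positive")
        for a in (self.cardiac_amp, self.respiration_amp, self.mayer_amp, self.white_sd):
            if a < 0:
                raise ValueError("noise amplitudes must be non-negative")

    @staticmethod
    def silent(seed: int = 0) -> "NoiseSpec":
        return NoiseSpec(cardiac_amp=0.0, respiration_amp=0.0, mayer_amp=0.0,
                         drift_per_sample=0.0, white_sd=0.0, seed=seed)
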