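"""Modified Beer-Lambert Law conversion of optical-density changes to ΔHbO/ΔHbR.

For each channel and sample,

    [ΔcHbO; ΔcHbR] = E⁻¹ [ΔA(λ1); ΔA(λ2)] / (d * l)

where ``E`` is the 2x2 extinction-coefficient matrix (μM⁻¹·cm⁻¹), ``l`` the
source-detector distance (cm) and ``d`` the differential path-length factor.
The default extinction table holds commonly used literature coefficients for
760/830 nm; any quantitative study should supply its own table because the
MBLL defines the algebra, not the constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .blocks import HBO_KIND, HBR_KIND, OD_KIND, TimeSeriesBlock

__all__ = [
    "ExtinctionTable",
    "MbllParams",
    "DEFAULT_EXTINCTION",
    "WAVELENGTHS_NM",
    "mbll_convert",
    "load_extinction_csv",
]

WAVELENGTHS_NM = (760.0, 830.0)

#: rows = wavelengths (760, 830 nm), cols = (HbO, HbR) — Cope-derived
#: literature coefficients commonly shipped with fNIRS toolchains. Absolute
#: concentration scale depends on the coefficient unit convention adopted;
#: the decode/classify pipeline is invariant to that global scale.
DEFAULT_EXTINCTION = np.array([[1.4866, 3.8437],
                               [2.2314, 1.7917]])

_SINGULARITY_TOL = 1e-12


@dataclass(frozen=True)
class ExtinctionTable:
    """2x2 extinction matrix: rows wavelengths, columns (HbO, HbR)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("extinction table must be 2x2")
        if (m <= 0).any():
            raise ValueError("extinction coefficients must be positive")
        if abs(np.linalg.det(m)) < _SINGULARITY_TOL:
            raise np.linalg.LinAlgError("extinction table is singular")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class MbllParams:
    """Geometry: l = source-detector distance (cm), d = path-length factor."""

    l_cm: float = 3.0
    dpf: float = 6.0

    def __post_init__(self) -> None:
        if self.l_cm <= 0 or self.dpf <= 0:
            raise ValueError("l_cm and dpf must be positive")


def load_extinction_csv(path: str | Path) -> ExtinctionTable:
    """Read a 2x2 extinction matrix from CSV (two rows of two values)."""
    m = np.loadtxt(path, delimiter=",")
    return ExtinctionTable(m)


def mbll_convert(od_pair: tuple[TimeSeriesBlock, TimeSeriesBlock],
                 ext: ExtinctionTable | np.ndarray | None = None,
                 params: MbllParams | None = None,
                 ) -> tuple[TimeSeriesBlock, TimeSeriesBlock]:
    """Invert the MBLL per sample and channel; returns (ΔHbO, ΔHbR) in μM."""
    if ext is None:
        ext = ExtinctionTable(DEFAULT_EXTINCTION)
    if isinstance(ext, np.ndarray):
        ext = ExtinctionTable(ext)
    if params is None:
        params = MbllParams()

    od1, od2 = od_pair
    for od in (od1, od2):
        if od.kind != OD_KIND:
            raise ValueError("mbll_convert expects optical-density blocks")
    if od1.data.shape != od2.data.shape or od1.fs != od2.fs:
        raise ValueError("both wavelengths must cover the same channels/samples")

    dA = np.stack([od1.data, od2.data])            # (2, ch, n)
    einv = np.linalg.inv(ext.matrix)
    conc = np.einsum("kw,wcn->kcn", einv, dA) / (params.dpf * params.l_cm)
    mk = dict(fs=od1.fs, montage=od1.montage, channel_names=od1.channel_names,
              units="uM")
    return (TimeSeriesBlock(conc[0], kind=HBO_KIND, **mk),
            TimeSeriesBlock(conc[1], kind=HBR_KIND, **mk))
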