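"""File I/O: long-format CSV/TSV channel tables, SNIRF (HDF5) and YAML config.

The long CSV format has columns ``time_s, channel, label, value`` where
``label`` is a wavelength (nm, for optical density) or a chromophore name.
SNIRF output writes the ``/nirs/data1`` layout (dataTimeSeries, time,
measurementList entries) with source/detector positions from the montage.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .blocks import HBO_KIND, HBR_KIND, OD_KIND, Montage, TimeSeriesBlock
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["write_block_csv", "read_block_csv", "write_snirf", "read_snirf",
           "write_features_csv", "read_features_csv", "load_yaml",
           "dump_yaml"]


def _labels(block: TimeSeriesBlock) -> list[str]:
    if block.channel_names is not None:
        return list(block.channel_names)
    return [f"ch{i + 1}" for i in range(block.n_channels)]


def write_block_csv(block: TimeSeriesBlock, path: str | Path,
                    sep: str = ",") -> None:
    """Write a block as a long-format channel table."""
    path = Path(path)
    label = (f"{block.wavelength_nm:g}nm" if block.kind == OD_KIND
             else block.kind)
    names = _labels(block)
    t = block.time_s
    frames = [pd.DataFrame({"time_s": t, "channel": names[c], "label": label,
                            "value": block.data[c]})
              for c in range(block.n_channels)]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, sep=sep, index=False)
    logger.info("wrote %d samples x %d channels to %s",
                block.n_samples, block.n_channels, path)


def read_block_csv(path: str | Path, fs: float, kind: str = HBO_KIND,
                   sep: str = ",") -> TimeSeriesBlock:
    """Read a long-format channel table back into a block."""
    df = pd.read_csv(path, sep=sep)
    required = {"time_s", "channel", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    channels = list(dict.fromkeys(df["channel"]))
    data = np.stack([df.loc[df["channel"] == ch, "value"].to_numpy()
                     for ch in channels])
    wavelength = None
    if kind == OD_KIND and "label" in df.columns:
        lab = str(df["label"].iloc[0])
        if lab.endswith("nm"):
            wavelength = float(lab[:-2])
    logger.info("read %s (%d channels) from %s", kind, len(channels), path)
    return TimeSeriesBlock(data, fs=fs, kind=kind, channel_names=channels,
                           wavelength_nm=wavelength)


def write_snirf(path: str | Path, od_pair: tuple[TimeSeriesBlock, TimeSeriesBlock],
                montage: Montage) -> None:
    """Write a two-wavelength optical-density pair as a SNIRF HDF5 file."""
    od1, od2 = od_pair
    path = Path(path)
    src_names = list(montage.sources)
    det_names = list(montage.detectors)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        data1 = nirs.create_group("data1")
        series = np.vstack([od1.data, od2.data]).T       # samples x measurements
        data1.create_dataset("dataTimeSeries", data=series)
        data1.create_dataset("time", data=od1.time_s)
        idx = 1
        for block, wl_index in ((od1, 1), (od2, 2)):
            for (s, d) in montage.channels:
                ml = data1.create_group(f"measurementList{idx}")
                ml.create_dataset("sourceIndex", data=src_names.index(s) + 1)
                ml.create_dataset("detectorIndex", data=det_names.index(d) + 1)
                ml.create_dataset("wavelengthIndex", data=wl_index)
                ml.create_dataset("dataType", data=1)    # CW amplitude family
                ml.create_dataset("dataTypeIndex", data=1)
                idx += 1
        probe = nirs.create_group("probe")
        probe.create_dataset(
            "wavelengths", data=[od1.wavelength_nm, od2.wavelength_nm])
        probe.create_dataset(
            "sourcePos2D", data=[montage.sources[s] for s in src_names])
        probe.create_dataset(
            "detectorPos2D", data=[montage.detectors[d] for d in det_names])
    logger.info("wrote SNIRF file %s", path)


def read_snirf(path: str | Path, montage: Montage | None = None,
               ) -> tuple[TimeSeriesBlock, TimeSeriesBlock]:
    """Read back a SNIRF file written by :func:`write_snirf`."""
    with h5py.File(path, "r") as f:
        data1 = f["nirs/data1"]
        series = np.asarray(data1["dataTimeSeries"])
        t = np.asarray(data1["time"])
        wavelengths = np.asarray(f["nirs/probe/wavelengths"])
        n_meas = series.shape[1]
        wl_index = np.empty(n_meas, dtype=int)
        for i in range(n_meas):
            wl_index[i] = int(np.asarray(
                data1[f"measurementList{i + 1}/wavelengthIndex"]))
    if t.size < 2:
        raise ValueError("SNIRF time vector too short to infer fs")
    fs = 1.0 / float(np.mean(np.diff(t)))
    blocks = []
    for k, wl in enumerate(wavelengths, start=1):
        cols = np.where(wl_index == k)[0]
        blocks.append(TimeSeriesBlock(series[:, cols].T, fs=fs, kind=OD_KIND,
                                      wavelength_nm=float(wl),
                                      montage=montage))
    logger.info("read SNIRF file %s", path)
    return blocks[0], blocks[1]


def write_features_csv(fm: FeatureMatrix, path: str | Path) -> None:
    """Feature matrix as CSV: feature columns, then trial and label."""
    df = pd.DataFrame(fm.X, columns=list(fm.feature_names))
    df["trial"] = fm.trial_index
    df["label"] = fm.y
    df.to_csv(path, index=False)
    logger.info("wrote %d observations to %s", fm.n_observations, path)


def read_features_csv(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    names = tuple(c for c in df.columns if c not in ("label", "trial"))
    trial = (df["trial"].to_numpy() if "trial" in df.columns
             else np.zeros(len(df), dtype=int))
    return FeatureMatrix(df[list(names)].to_numpy(), df["label"].to_numpy(),
                         names, trial)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh) or {}
    logger.info("loaded config %s", path)
    return out


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    logger.info("wrote config %s", path)
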