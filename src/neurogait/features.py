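"""Feature extraction from the spatially averaged ΔHbO series.

The 12 channels are averaged sample-wise into a single series, which is then
windowed by the paradigm's task/rest sessions and summarized by up to six
statistics per window:

====  ==========================================================
SM    signal mean, (1/N) Σ z_i
SS    signal slope — least-squares line fit over (time, value)
SP    signal peak, max z_i
SK    skewness  E[((z-μ)/σ)³]          (population moments)
KR    kurtosis  E[((z-μ)/σ)⁴]          (non-excess; Gaussian ≈ 3)
SV    signal variance, population (1/N)
====  ==========================================================

Each 10 s task and 20 s rest session may be sub-windowed (default 6
sub-windows per session) so that ten trials yield ~120 labeled observations,
which matches the granularity at which per-subject decoding accuracies are
usually reported; whole-session windows are also available. Features are
min-max rescaled to [0, 1]; held-out observations are rescaled with training
bounds and clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import Paradigm, TimeSeriesBlock

__all__ = ["FeatureMatrix", "FEATURE_NAMES", "spatial_average",
           "session_windows", "extract_features", "rescale_features",
           "apply_rescale"]

FEATURE_NAMES = ("SM", "SS", "SP", "KR", "SK", "SV")

WALK, REST = "walk", "rest"


@dataclass
class FeatureMatrix:
    """Observations x features with class labels and rescaling metadata."""

    X: np.ndarray
    y: np.ndarray                       # labels: "walk" / "rest"
    feature_names: tuple[str, ...]
    trial_index: np.ndarray             # trial each observation came from
    rescale_bounds: tuple[np.ndarray, np.ndarray] | None = None
    scaled: bool = field(default=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y lengths disagree")

    @property
    def n_observations(self) -> int:
        return self.X.shape[0]


def spatial_average(block: TimeSeriesBlock) -> np.ndarray:
    """Per-sample arithmetic mean across channels."""
    if block.n_channels < 1 or block.n_samples < 1:
        raise ValueError("cannot average an empty block")
    return block.data.mean(axis=0)


def _subdivide(i0: int, i1: int, k: int) -> list[tuple[int, int]]:
    """Split [i0, i1) into k contiguous near-equal index windows."""
    edges = np.linspace(i0, i1, k + 1).round().astype(int)
    return [(int(edges[j]), int(edges[j + 1])) for j in range(k)]


def session_windows(paradigm: Paradigm, subwindows_per_task: int = 6,
                    window_mode: str = "subwindow",
                    ) -> list[tuple[int, int, str, int]]:
    """Index windows (start, stop, label, trial) over the averaged series.

    ``window_mode='session'`` yields one window per whole task/rest session;
    ``'subwindow'`` splits each task session into ``subwindows_per_task``
    equal windows and draws the *same number* of equally long windows,
    evenly spaced, from each rest session. Matching the rest windows in both
    count and duration keeps the labels balanced and prevents decoders from
    keying on window length instead of signal content.
    """
    if window_mode not in ("session", "subwindow"):
        raise ValueError("window_mode must be 'session' or 'subwindow'")
    k = 1 if window_mode == "session" else int(subwindows_per_task)
    if k < 1:
        raise ValueError("subwindows_per_task must be >= 1")
    fs = paradigm.fs
    out: list[tuple[int, int, str, int]] = []
    for trial, ((t0, t1), (r0, r1)) in enumerate(
            zip(paradigm.task_intervals(), paradigm.rest_intervals())):
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        j0, j1 = int(round(r0 * fs)), int(round(r1 * fs))
        if window_mode == "session":
            out.append((i0, i1, WALK, trial))
            out.append((j0, j1, REST, trial))
            continue
        task_windows = _subdivide(i0, i1, k)
        for (a, b) in task_windows:
            out.append((a, b, WALK, trial))
        wl = int(round((i1 - i0) / k))
        if j1 - j0 < wl:
            raise ValueError("rest session shorter than one task sub-window")
        starts = np.linspace(j0, j1 - wl, k).round().astype(int)
        for s in starts:
            out.append((int(s), int(s) + wl, REST, trial))
    return out


def _window_features(z: np.ndarray, t: np.ndarray,
                     names: tuple[str, ...]) -> list[float]:
    n = z.size
    mu = z.sum() / n
    var = ((z - mu) ** 2).sum() / n
    sd = np.sqrt(var)
    vals = []
    for name in names:
        if name == "SM":
            vals.append(mu)
        elif name == "SP":
            vals.append(z.max())
        elif name == "SV":
            vals.append(var)
        elif name == "SS":
            # least-squares slope over (time, value)
            tm = t - t.mean()
            denom = (tm ** 2).sum()
            if denom == 0:
                raise ValueError("degenerate window: zero time spread for SS")
            vals.append(float((tm * (z - mu)).sum() / denom))
        elif name in ("SK", "KR"):
            if sd == 0:
                raise ValueError(
                    f"degenerate window for {name}: zero standard deviation")
            zn = (z - mu) / sd
            vals.append(float((zn ** (3 if name == "SK" else 4)).mean()))
        else:
            raise ValueError(f"unknown feature {name!r}")
    return vals


def extract_features(avg: np.ndarray, paradigm: Paradigm,
                     feature_names: tuple[str, ...] = FEATURE_NAMES,
                     subwindows_per_task: int = 6,
                     window_mode: str = "subwindow",
                     slope_time_axis: str = "seconds") -> FeatureMatrix:
    """Window the averaged series and compute the requested statistics.

    ``slope_time_axis='seconds'`` makes SS a slope in signal-units per second;
    ``'samples'`` uses the sample index instead.
    """
    avg = np.asarray(avg, dtype=float)
    windows = session_windows(paradigm, subwindows_per_task, window_mode)
    min_n = 3 if ("SK" in feature_names or "KR" in feature_names) else 2
    rows, labels, trials = [], [], []
    for (a, b, label, trial) in windows:
        z = avg[a:b]
        if z.size < min_n:
            raise ValueError(
                f"window [{a}:{b}) has {z.size} samples; need >= {min_n}")
        if slope_time_axis == "seconds":
            t = np.arange(a, b) / paradigm.fs
        else:
            t = np.arange(a, b, dtype=float)
        rows.append(_window_features(z, t, tuple(feature_names)))
        labels.append(label)
        trials.append(trial)
    return FeatureMatrix(np.array(rows), np.array(labels),
                         tuple(feature_names), np.array(trials))


def sliding_window_features(avg: np.ndarray, paradigm: Paradigm,
                            trial: int, phase: str,
                            feature_names: tuple[str, ...] = FEATURE_NAMES,
                            window_samples: int = 3,
                            stride: int = 1) -> FeatureMatrix:
    """Overlapping-window features over one trial's task or rest phase.

    Used by the online trigger stage, where a single 10 s epoch must supply
    enough observations for a ten-subset vote: a length-``window_samples``
    window sliding by ``stride`` yields one observation per step.
    """
    avg = np.asarray(avg, dtype=float)
    if phase == WALK:
        t0, t1 = paradigm.task_intervals()[trial]
    elif phase == REST:
        t0, t1 = paradigm.rest_intervals()[trial]
    else:
        raise ValueError("phase must be 'walk' or 'rest'")
    i0, i1 = int(round(t0 * paradigm.fs)), int(round(t1 * paradigm.fs))
    if i1 - i0 < window_samples:
        raise ValueError("phase shorter than the sliding window")
    rows = []
    for a in range(i0, i1 - window_samples + 1, stride):
        z = avg[a:a + window_samples]
        t = np.arange(a, a + window_samples) / paradigm.fs
        rows.append(_window_features(z, t, tuple(feature_names)))
    n = len(rows)
    return FeatureMatrix(np.array(rows), np.array([phase] * n),
                         tuple(feature_names), np.full(n, trial))


def rescale_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Column-wise min-max rescaling to [0, 1]; bounds stored for reuse."""
    lo = fm.X.min(axis=0)
    hi = fm.X.max(axis=0)
    if np.any(hi <= lo):
        bad = [fm.feature_names[i] for i in np.where(hi <= lo)[0]]
        raise ValueError(f"constant feature column(s): {bad}")
    X = (fm.X - lo) / (hi - lo)
    return FeatureMatrix(X, fm.y, fm.feature_names, fm.trial_index,
                         rescale_bounds=(lo, hi), scaled=True)


def apply_rescale(fm: FeatureMatrix,
                  bounds: tuple[np.ndarray, np.ndarray]) -> FeatureMatrix:
    """Rescale held-out observations with training bounds, clipping to [0,1]."""
    lo, hi = bounds
    X = np.clip((fm.X - lo) / (hi - lo), 0.0, 1.0)
    return FeatureMatrix(X, fm.y, fm.feature_names, fm.trial_index,
                         rescale_bounds=(lo, hi), scaled=True)
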