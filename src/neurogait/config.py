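"""Run configuration: one YAML-serializable object covering every stage.

The configuration round-trips exactly through ``to_dict``/``from_dict``
(hence through YAML), and a single global seed fans out deterministically to
per-stage, per-subject seeds via ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .blocks import NoiseSpec
from .filters import FILTER_METHODS, FilterSpec
from .classifiers import CLASSIFIER_FAMILIES

__all__ = ["RunConfig", "stage_seed"]

_STAGES = ("synthgen", "classify", "trigger", "gait")


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the end-to-end pipeline, with protocol defaults."""

    seed: int = 0
    out_dir: str = "runs"
    n_subjects: int = 9
    # paradigm
    trial_count: int = 10
    task_s: float = 10.0
    rest_s: float = 20.0
    lead_in_s: float = 30.0
    lead_out_s: float = 30.0
    fs: float = 1.81
    # generator
    response_amplitude_uM: float = 1.0
    noise: dict = field(default_factory=lambda: asdict(NoiseSpec()))
    # mbll
    dpf: float = 6.0
    separation_cm: float = 3.0
    # preprocessing / features
    filters: tuple[str, ...] = FILTER_METHODS
    filter_params: dict = field(default_factory=dict)
    feature_names: tuple[str, ...] = ("SM", "SS", "SP", "KR", "SK", "SV")
    subwindows_per_task: int = 6
    window_mode: str = "subwindow"
    # classification
    classifiers: tuple[str, ...] = CLASSIFIER_FAMILIES
    cv_folds: int = 10
    # online trigger
    online_classifier: str = "lda"
    online_filter: str = "hrf"
    trigger_threshold: float = 0.9
    trigger_subsets: int = 10
    # leg + controller
    stride_period_s: float = 1.2
    kp: float = 100.0
    kv: float = 20.0
    sim_duration_s: float = 5.0
    sim_dt: float = 1e-3
    initial_error_rad: float = 0.3

    def __post_init__(self) -> None:
        for m in self.filters:
            if m not in FILTER_METHODS:
                raise ValueError(f"unknown filter {m!r}")
        for c in self.classifiers:
            if c not in CLASSIFIER_FAMILIES:
                raise ValueError(f"unknown classifier {c!r}")
        if self.online_classifier not in CLASSIFIER_FAMILIES:
            raise ValueError(f"unknown classifier {self.online_classifier!r}")

    # ------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("filters", "feature_names", "classifiers"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for k in ("filters", "feature_names", "classifiers"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .io import load_yaml
        return cls.from_dict(load_yaml(path))

    def to_yaml(self, path: str | Path) -> None:
        from .io import dump_yaml
        dump_yaml(self.to_dict(), path)

    # --------------------------------------------------------------- seeds
    def noise_spec(self, subject: int = 0) -> NoiseSpec:
        return NoiseSpec(**{**self.noise,
                            "seed": stage_seed(self.seed, "synthgen", subject)})

    def filter_spec(self, method: str) -> FilterSpec:
        params = dict(self.filter_params.get(method, {}))
        if method == "wiener" and "baseline_s" not in params:
            params["baseline_s"] = (0.0, self.lead_in_s)
        return FilterSpec(method=method, **params)

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage/per-subject seed below 2**31."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage), index])
    return int(ss.generate_state(1)[0] % (2 ** 31))
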