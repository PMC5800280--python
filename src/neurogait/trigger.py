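"""Online decision layer gating gait commands against false triggers.

A decoder trained offline on nine trials classifies the held-out trial's
observations. The unseen trial is randomly partitioned into ten disjoint
subsets; each subset casts one binary vote (majority of its observations'
predicted labels, ties conservatively toward rest), and the gait cycle is
started only when at least 90% of the subsets vote "walk". With per-subset
correctness p the trigger probability is the binomial tail
Σ_{j>=ceil(0.9 n)} C(n,j) p^j (1-p)^(n-j), which makes false triggers at
rest vanishingly rare for any reasonable per-subset error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .features import REST, WALK, FeatureMatrix, apply_rescale, rescale_features

__all__ = ["TriggerDecision", "partition_trial", "online_decision",
           "leave_one_trial_out", "START_GAIT", "HOLD"]

START_GAIT = "start_gait"
HOLD = "hold"


@dataclass(frozen=True)
class TriggerDecision:
    """Outcome of voting over one unseen trial."""

    subset_labels: tuple[str, ...]
    walk_fraction: float
    command: str
    threshold: float = 0.9


def partition_trial(n_observations: int, n_subsets: int = 10,
                    seed: int = 0) -> list[np.ndarray]:
    """Random partition into ``n_subsets`` disjoint index subsets whose sizes
    differ by at most one; reproducible per seed."""
    if n_observations < n_subsets:
        raise ValueError("fewer observations than subsets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_observations)
    return [np.sort(s) for s in np.array_split(perm, n_subsets)]


def online_decision(model: BaseEstimator, X: np.ndarray,
                    n_subsets: int = 10, threshold: float = 0.9,
                    seed: int = 0, subset_mode: str = "majority",
                    ) -> TriggerDecision:
    """Partition the trial's observations, vote per subset, gate the command.

    ``subset_mode='majority'`` takes the majority of each subset's predicted
    labels (ties -> rest); ``'mean'`` classifies each subset's mean feature
    vector instead. ``command`` is ``start_gait`` iff
    ``walk_fraction >= threshold`` (inclusive, so 9/10 passes a 0.9 bar).
    """
    if not hasattr(model, "classes_"):
        raise RuntimeError("model must be fitted before online use")
    if subset_mode not in ("majority", "mean"):
        raise ValueError("subset_mode must be 'majority' or 'mean'")
    X = np.asarray(X, dtype=float)
    subsets = partition_trial(X.shape[0], n_subsets, seed)
    labels = []
    for idx in subsets:
        if subset_mode == "mean":
            pred = model.predict(X[idx].mean(axis=0, keepdims=True))[0]
            labels.append(str(pred))
        else:
            pred = model.predict(X[idx])
            walk_votes = int(np.sum(pred == WALK))
            # strict majority required: ties fall to rest (no false trigger)
            labels.append(WALK if 2 * walk_votes > len(idx) else REST)
    walk_fraction = labels.count(WALK) / n_subsets
    command = START_GAIT if walk_fraction >= threshold else HOLD
    return TriggerDecision(tuple(labels), walk_fraction, command, threshold)


def leave_one_trial_out(model: BaseEstimator, fm: FeatureMatrix,
                        test_trial: int, n_subsets: int = 10,
                        threshold: float = 0.9, seed: int = 0,
                        subset_mode: str = "majority",
                        phase: str | None = WALK,
                        test_features: FeatureMatrix | None = None,
                        ) -> TriggerDecision:
    """Train on all trials but one (unscaled features; bounds fit on the
    training trials), then run the voting rule on the held-out trial.

    ``phase`` restricts the held-out observations to one intention period
    (default: the walk phase, i.e. "should the gait cycle start now?");
    ``None`` uses the whole trial. ``test_features`` overrides the held-out
    observations, e.g. with finer-grained sliding-window features of the
    same epoch.
    """
    train_mask = fm.trial_index != test_trial
    if train_mask.all() or not train_mask.any():
        raise ValueError(f"trial {test_trial} not present, or is all trials")
    train = FeatureMatrix(fm.X[train_mask], fm.y[train_mask],
                          fm.feature_names, fm.trial_index[train_mask])
    if test_features is not None:
        test = test_features
    else:
        test_mask = ~train_mask
        if phase is not None:
            test_mask &= fm.y == phase
        test = FeatureMatrix(fm.X[test_mask], fm.y[test_mask],
                             fm.feature_names, fm.trial_index[test_mask])
    train_scaled = rescale_features(train)
    test_scaled = apply_rescale(test, train_scaled.rescale_bounds)
    from sklearn.base import clone
    fitted = clone(model).fit(train_scaled.X, train_scaled.y)
    return online_decision(fitted, test_scaled.X, n_subsets=n_subsets,
                           threshold=threshold, seed=seed,
                           subset_mode=subset_mode)
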