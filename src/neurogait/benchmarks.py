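"""Reference benchmark accuracies for walk/rest fNIRS decoding.

Published per-subject offline accuracies (percent) for the best-performing
configuration of this kind of interface — a cubic-kernel SVM on
HRF-smoothed ΔHbO features, nine healthy subjects, 10-fold CV. They serve
as the comparison point for synthetic-recovery experiments and for sanity
checks of summary arithmetic; they are inputs, not outputs, of this package.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SVM_HRF_SUBJECT_ACCURACIES", "mean_benchmark_accuracy"]

#: best-case per-subject accuracies (%), subjects S1..S9
SVM_HRF_SUBJECT_ACCURACIES = (77.5, 72.5, 68.3, 74.2, 73.3, 80.8, 65.0,
                              76.7, 86.7)


def mean_benchmark_accuracy() -> float:
    """Arithmetic mean of the nine benchmark accuracies (percent)."""
    return float(np.mean(SVM_HRF_SUBJECT_ACCURACIES))
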