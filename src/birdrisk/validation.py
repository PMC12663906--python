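"""Validation of BSRI statuses against observer-assigned statuses.

Bird-control personnel assign a qualitative local bird status (normal /
alert / critical) at each runway inspection.  Comparing those labels with
the quantified status derived from BSRI thresholds gives a 3x3 confusion
matrix and the usual summary metrics.  Inspections whose observer status is
unknown (nocturnal / low-visibility) are excluded from validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bsri import BSRIResult
from .io_model import STATUSES

__all__ = ["ConfusionMatrix", "build_confusion", "accuracy_metrics"]


@dataclass
class ConfusionMatrix:
    """Counts indexed (observed status, predicted status) over normal/alert/critical."""

    matrix: np.ndarray  # 3x3 int, rows = observed, cols = predicted
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(STATUSES, name="observed"),
            columns=pd.Index(STATUSES, name="predicted"),
        )


def build_confusion(results: Sequence[BSRIResult]) -> ConfusionMatrix:
    """Tally observer vs. BSRI-predicted statuses.

    Every result must carry a predicted ``status``; results with observer
    status ``unknown`` are counted in ``n_excluded`` only.
    """
    idx = {s: i for i, s in enumerate(STATUSES)}
    m = np.zeros((3, 3), dtype=int)
    excluded = 0
    for r in results:
        if r.status is None:
            raise ValueError("BSRIResult without an assigned status; assign statuses first")
        if r.observer_status == "unknown":
            excluded += 1
            continue
        m[idx[r.observer_status], idx[r.status]] += 1
    return ConfusionMatrix(matrix=m, n_excluded=excluded)


def accuracy_metrics(cm: ConfusionMatrix) -> dict:
    """Overall accuracy (%) plus per-class recall and precision.

    Recall is the diagonal over the observed-row sum, precision the diagonal
    over the predicted-column sum.  Classes that never occur (zero row or
    column) get ``None`` rather than a fabricated zero.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix (all inspections excluded?)")
    m = cm.matrix
    diag = np.diag(m)
    rows = m.sum(axis=1)
    cols = m.sum(axis=0)
    recall = {
        s: (float(diag[i] / rows[i]) if rows[i] > 0 else None)
        for i, s in enumerate(STATUSES)
    }
    precision = {
        s: (float(diag[i] / cols[i]) if cols[i] > 0 else None)
        for i, s in enumerate(STATUSES)
    }
    return {
        "overall_accuracy_pct": float(diag.sum() / total * 100.0),
        "recall": recall,
        "precision": precision,
        "n_validated": total,
        "n_excluded": cm.n_excluded,
    }
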