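"""Continual-learning evaluation metrics.

The accuracy matrix ``acc[N, n]`` stores the percent accuracy on task n
after the model has learned task N (lower-triangular, 1-based task
indices mapped to 0-based rows/columns).  From it derive:

* average accuracy after phase N — the mean of row N over the N seen tasks;
* forward transfer rate (FTR) — mean relative shortfall of each task's
  first-learned accuracy against its jointly trained reference,
  ``FTR = 1/(N-1) * sum_{n=2..N} (acc**_n - acc_{n,n}) / acc**_n`` (%);
  lower means more plastic;
* backward forgetting rate (BFR) — mean relative decay of each old task
  between first learning and the final phase,
  ``BFR = 1/(N-1) * sum_{n=1..N-1} (acc*_n - acc_{N,n}) / acc*_n`` (%);
  lower means more stable.

Cohen's kappa is computed from the confusion matrix:
``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement p_o (trace
fraction) and chance agreement p_e from the row/column marginals.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "AccuracyMatrix",
    "cohen_kappa",
    "confusion_matrix",
    "average_accuracy",
    "forward_transfer_rate",
    "backward_forgetting_rate",
    "aggregate_subject_table",
    "subject_table",
]


class AccuracyMatrix:
    """Lower-triangular record of per-task accuracies across phases (%, 0-100)."""

    def __init__(self, n_phases: int):
        self.acc = np.full((n_phases, n_phases), np.nan)

    def set(self, phase: int, task: int, value: float) -> None:
        if task > phase:
            raise ValueError("acc[N, n] is defined only for n <= N")
        if not (0.0 <= value <= 100.0):
            raise ValueError("accuracies are percentages in [0, 100]")
        self.acc[phase, task] = value

    def row(self, phase: int) -> np.ndarray:
        r = self.acc[phase, : phase + 1]
        if np.isnan(r).any():
            raise ValueError(f"row {phase} is incomplete")
        return r

    def first_learned(self) -> np.ndarray:
        """Diagonal acc*_n: accuracy of each task when first learned."""
        return np.diag(self.acc)

    @property
    def n_phases(self) -> int:
        return self.acc.shape[0]


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def cohen_kappa(confusion: np.ndarray) -> float:
    cm = np.asarray(confusion, dtype=np.float64)
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) / total) @ (cm.sum(axis=0) / total))
    if p_e >= 1.0 - 1e-12:
        if p_o >= 1.0 - 1e-12:
            return 1.0
        raise ValueError("chance agreement is 1; kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def average_accuracy(m: AccuracyMatrix, phase: int | None = None) -> float:
    """Mean accuracy over all seen tasks after the given phase (default last)."""
    if phase is None:
        phase = m.n_phases - 1
    return float(m.row(phase).mean())


def forward_transfer_rate(m: AccuracyMatrix, joint_reference: np.ndarray) -> float:
    """Plasticity: relative loss of incremental vs. joint first-learning (%).

    ``joint_reference[n]`` holds acc**_{n+2}, the jointly trained accuracy
    for each incremental task (tasks 2..N).
    """
    n_phases = m.n_phases
    ref = np.asarray(joint_reference, dtype=np.float64)
    if len(ref) != n_phases - 1:
        raise ValueError("need one joint reference per incremental task")
    if (ref <= 0).any():
        raise ValueError("joint reference accuracies must be positive")
    first = m.first_learned()[1:]
    return float(100.0 * np.mean((ref - first) / ref))


def backward_forgetting_rate(m: AccuracyMatrix) -> float:
    """Stability: relative decay of old tasks at the final phase (%)."""
    n = m.n_phases
    if n < 2:
        raise ValueError("BFR needs at least two phases")
    final = m.row(n - 1)[: n - 1]
    first = m.first_learned()[: n - 1]
    if (first <= 0).any():
        raise ValueError("first-learned accuracies must be positive")
    return float(100.0 * np.mean((first - final) / first))


def aggregate_subject_table(values) -> tuple[float, float]:
    """Mean and sample (N-1) standard deviation of a per-subject column."""
    v = np.asarray(values, dtype=np.float64)
    if len(v) < 2:
        raise ValueError("need at least 2 values for a sample std")
    return float(v.mean()), float(v.std(ddof=1))


def subject_table(columns: dict[str, "np.ndarray"], subjects=None):
    """Per-subject results table with Avg./Std. footer rows.

    ``columns`` maps column names to equal-length per-subject vectors;
    returns a pandas DataFrame indexed by subject with the mean and the
    sample standard deviation appended as footer rows.
    """
    import pandas as pd

    df = pd.DataFrame(columns)
    if subjects is not None:
        df.index = list(subjects)
    footer = pd.DataFrame(
        {name: dict(zip(("Avg.", "Std."), aggregate_subject_table(vals)))
         for name, vals in columns.items()}).T
    out = pd.concat([df, footer.T])
    return out
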