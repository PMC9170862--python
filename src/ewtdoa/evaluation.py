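"""Agreement metrics: index vs reference, and predicted vs true states.

Continuous agreement between an index trace and the reference series is
summarised by Pearson's r, the mean squared error (MSE), its square root
(RMSE), and the coefficient of determination R^2.  Categorical agreement
between state sequences uses the 4x4 confusion matrix (rows = true,
columns = predicted, ordered DA, MA, LA, AW) and Cohen's kappa,

    K = (n * sum_i n_ii - sum_i n_.i n_i.) / (n^2 - sum_i n_.i n_i.),

which discounts the agreement expected by chance from the marginals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import STATES
from .model import IndexTrace

__all__ = [
    "AgreementReport",
    "StateAgreement",
    "agreement",
    "state_agreement",
    "pearson_r",
    "cohen_kappa",
]


@dataclass(frozen=True)
class AgreementReport:
    """Continuous agreement between a predicted index and the reference."""

    pearson_r: float  # NaN when undefined (zero variance)
    mse: float
    rmse: float
    r2: float
    n: int
    n_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "mse": self.mse,
            "rmse": self.rmse,
            "r2": self.r2,
            "n": self.n,
            "n_dropped": self.n_dropped,
        }

    def __str__(self) -> str:
        r = "undefined" if np.isnan(self.pearson_r) else f"{self.pearson_r:.4f}"
        return (
            f"n={self.n} (dropped {self.n_dropped})  r={r}  "
            f"MSE={self.mse:.2f}  RMSE={self.rmse:.2f}  R2={self.r2:.4f}"
        )


@dataclass(frozen=True)
class StateAgreement:
    """Categorical agreement between true and predicted state sequences."""

    confusion: pd.DataFrame  # rows true, cols predicted, order DA,MA,LA,AW
    kappa: float
    accuracy: float
    n: int

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "accuracy": self.accuracy,
            "n": self.n,
            "confusion": self.confusion.to_dict(),
        }

    def __str__(self) -> str:
        return (
            f"n={self.n}  kappa={self.kappa:.4f}  accuracy={self.accuracy:.4f}\n"
            f"{self.confusion}"
        )


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN when either series has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx**2).sum() * (dy**2).sum())
    if denom == 0:
        return float("nan")
    return float((dx * dy).sum() / denom)


def agreement(pred: IndexTrace | np.ndarray, ref: np.ndarray) -> AgreementReport:
    """Pearson r, MSE, RMSE and R^2 between an index trace and a reference.

    When ``pred`` is a trace, its 1 Hz timestamps select the matching
    reference elements (track element k is the value at second k + 1).
    Pairs with a missing value on either side are dropped and counted.
    """
    ref = np.asarray(ref, dtype=float)
    if isinstance(pred, IndexTrace):
        idx = np.clip(np.round(pred.t).astype(int) - 1, 0, len(ref) - 1)
        x = pred.value
        y = ref[idx]
    else:
        x = np.asarray(pred, dtype=float)
        y = ref
        if x.shape != y.shape:
            raise ValueError("pred and ref must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    resid = y - x
    mse = float(np.mean(resid**2))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = float("nan") if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return AgreementReport(
        pearson_r=pearson_r(x, y),
        mse=mse,
        rmse=float(np.sqrt(mse)),
        r2=r2,
        n=int(x.size),
        n_dropped=n_dropped,
    )


def confusion_matrix(
    true_states: np.ndarray, pred_states: np.ndarray, labels=STATES
) -> pd.DataFrame:
    """Count matrix, rows = true, columns = predicted."""
    true_states = np.asarray(true_states)
    pred_states = np.asarray(pred_states)
    mat = pd.DataFrame(
        0, index=list(labels), columns=list(labels), dtype=int
    )
    for t, p in zip(true_states, pred_states):
        if t in mat.index and p in mat.columns:
            mat.loc[t, p] += 1
    return mat


def cohen_kappa(confusion: np.ndarray | pd.DataFrame) -> float:
    """Cohen's kappa from a square confusion matrix."""
    m = np.asarray(confusion, dtype=float)
    n = m.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    diag = np.trace(m)
    marg = (m.sum(axis=0) * m.sum(axis=1)).sum()
    denom = n**2 - marg
    if denom == 0:
        return 1.0  # all mass in one cell: complete (if trivial) agreement
    return float((n * diag - marg) / denom)


def state_agreement(
    true_states: np.ndarray, pred_states: np.ndarray
) -> StateAgreement:
    """Confusion matrix, Cohen's kappa and accuracy over the 4-state alphabet.

    States absent from the inputs keep their (zero) rows and columns so
    that reports stay comparable across recordings.  Pairs where either
    side is outside the alphabet (e.g. UNCLASSIFIED) are excluded.
    """
    true_states = np.asarray(true_states)
    pred_states = np.asarray(pred_states)
    if true_states.shape != pred_states.shape:
        raise ValueError("state sequences must have equal length")
    if true_states.size == 0:
        raise ValueError("empty state sequences")
    mat = confusion_matrix(true_states, pred_states)
    n = int(mat.to_numpy().sum())
    if n == 0:
        raise ValueError("no pairs within the 4-state alphabet")
    return StateAgreement(
        confusion=mat,
        kappa=cohen_kappa(mat),
        accuracy=float(np.trace(mat.to_numpy()) / n),
        n=n,
    )


def per_state_recall(sa: StateAgreement) -> dict[str, float]:
    """Recall (row-normalised diagonal) per state; NaN for absent states."""
    m = sa.confusion.to_numpy(dtype=float)
    row = m.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rec = np.diag(m) / row
    return dict(zip(sa.confusion.index, rec))


def write_report(path, **sections) -> None:
    """Dump metric dataclasses / dicts as one JSON report."""
    payload = {}
    for k, v in sections.items():
        payload[k] = v.to_dict() if hasattr(v, "to_dict") else v
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
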