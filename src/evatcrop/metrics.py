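"""Evaluation metrics for ET0 estimates against the Penman–Monteith
reference: R², Willmott's degree of agreement d, RMSE, RMSRE, and their
pairwise averages Ag (goodness) and Ae (error).

Conventions. R² is the standard coefficient of determination
1 − SSres/SStot with SStot about the reference mean (1 for a perfect
fit, 0 for the reference-mean predictor). A ``verbatim`` mode computes
the raw ratio Σ(ref−pred)² / Σ(ref−mean(pred))² instead — a form that is
0 for a perfect fit and is provided for auditing only. Undefined cases
(constant reference for R²/d, any zero reference for RMSRE) return NaN
rather than raising or substituting an epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MetricReport:
    """All six metrics for one model/combination/phase.

    ``rmse`` is in mm d⁻¹; ``rmsre`` is dimensionless; ``ae`` averages the
    two and therefore carries mixed units.
    """

    r2: float
    d: float
    rmse: float
    rmsre: float
    ag: float
    ae: float


def _pair(reference, predicted) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValueError("reference and predicted must be 1-d of equal length")
    if ref.size < 2:
        raise ValueError("need at least two paired values")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(pred))):
        raise ValueError("non-finite values in metric inputs")
    return ref, pred


def coefficient_of_determination(reference, predicted, verbatim: bool = False) -> float:
    ref, pred = _pair(reference, predicted)
    if verbatim:
        den = float(np.sum((ref - pred.mean()) ** 2))
        if den == 0.0:
            return float("nan")
        return float(np.sum((ref - pred) ** 2)) / den
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(np.sum((ref - pred) ** 2)) / ss_tot


def degree_of_agreement(reference, predicted) -> float:
    """Willmott's index: 1 − Σ(pred−ref)² / Σ(|pred−ref̄| + |ref−ref̄|)²,
    bounded in [0, 1] and 1 only for a perfect fit."""
    ref, pred = _pair(reference, predicted)
    rbar = ref.mean()
    den = float(np.sum((np.abs(pred - rbar) + np.abs(ref - rbar)) ** 2))
    if den == 0.0:
        return float("nan")
    return 1.0 - float(np.sum((pred - ref) ** 2)) / den


def rmse(reference, predicted) -> float:
    ref, pred = _pair(reference, predicted)
    return float(np.sqrt(np.mean((ref - pred) ** 2)))


def rmsre(reference, predicted) -> float:
    """Root mean square relative error; NaN if any reference value is zero
    (daily ET0 over a vegetated surface is strictly positive, so this only
    arises on degenerate synthetic inputs)."""
    ref, pred = _pair(reference, predicted)
    if np.any(ref == 0.0):
        return float("nan")
    return float(np.sqrt(np.mean(((ref - pred) / ref) ** 2)))


def combine(r2: float, d: float, rmse_: float, rmsre_: float) -> MetricReport:
    """Assemble a report with Ag = (R²+d)/2 and Ae = (RMSE+RMSRE)/2;
    NaN components propagate into the averages."""
    return MetricReport(r2=r2, d=d, rmse=rmse_, rmsre=rmsre_,
                        ag=(r2 + d) / 2.0, ae=(rmse_ + rmsre_) / 2.0)


def evaluate(reference, predicted) -> MetricReport:
    """All six metrics for one paired series."""
    return combine(
        coefficient_of_determination(reference, predicted),
        degree_of_agreement(reference, predicted),
        rmse(reference, predicted),
        rmsre(reference, predicted),
    )
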