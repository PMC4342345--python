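"""Predictive validation of the segment regressions.

Within each bootstrap iteration, 20% of that iteration's segments are
resampled (without replacement) ``reps`` times and scored against the
iteration's own fitted model: logistic predictions are correct when the
predicted B/W category matches the observed one (W iff fitted
probability strictly exceeds 0.5), linear predictions when the observed
transformed membership probability falls inside the 95% prediction
interval. Proportions are aggregated over all validated segments with a
binomial (normal-approximation) 95% confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import BootstrapSummary, FittedModel, ModelDesign, fit_model

__all__ = ["ValidationReport", "predict_category", "prediction_interval", "validate"]


@dataclass
class ValidationReport:
    kind: str
    proportion_correct: float
    ci_lower: float
    ci_upper: float
    n_validated: int
    fraction: float
    reps: int


def predict_category(fit: FittedModel, x: np.ndarray, cutoff: float = 0.5) -> str:
    """Predicted segment category: "W" iff fitted probability > cutoff."""
    prob = float(fit.predict_probability(np.atleast_2d(x))[0])
    return "W" if prob > cutoff else "B"


def prediction_interval(
    fit: FittedModel,
    x: np.ndarray,
    level: float = 0.95,
) -> tuple[float, float]:
    """t-based prediction interval for a new observation at x.

    Computed on the transformed (arcsine-square-root) response scale:
    y-hat +/- t_{df} * s * sqrt(1 + x'(X'X)^{-1}x). A fit with zero
    residual variance yields a degenerate zero-width interval (flagged).
    """
    if fit.kind != "linear":
        raise ValueError("prediction intervals apply to linear fits")
    if fit.xtx_inv is None:
        raise ValueError("fit lacks a full-rank (X'X)^{-1}; cannot form interval")
    if fit.df_resid < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    x = np.asarray(x, dtype=float)
    xd = np.concatenate([[1.0], x])
    yhat = float(xd @ fit.coef)
    if not fit.sigma2 > 1e-12:  # exact fits leave only float residue
        warnings.warn("zero residual variance: degenerate prediction interval",
                      stacklevel=2)
        return (yhat, yhat)
    lev = float(xd @ fit.xtx_inv @ xd)
    half = stats.t.ppf(0.5 + level / 2, fit.df_resid) * math.sqrt(fit.sigma2 * (1.0 + lev))
    return (yhat - half, yhat + half)


def _iteration_correct(fit: FittedModel, design: ModelDesign, rows: np.ndarray,
                       cutoff: float, level: float) -> np.ndarray:
    """Per-row correctness indicators under one iteration's model."""
    cols = [design.names.index(nm) for nm in fit.names]
    X = design.X[np.ix_(rows, cols)]
    y = design.y[rows]
    if fit.kind == "logistic":
        probs = fit.predict_probability(X)
        pred_w = probs > cutoff
        return pred_w == (y > 0.5)
    lo_hi = np.array([prediction_interval(fit, x, level=level) for x in X])
    return (y >= lo_hi[:, 0]) & (y <= lo_hi[:, 1])


def validate(
    boot: BootstrapSummary,
    design: ModelDesign,
    fraction: float = 0.2,
    reps: int = 1000,
    seed: int = 0,
    cutoff: float = 0.5,
    level: float = 0.95,
    out_of_bag: bool = False,
) -> ValidationReport:
    """Repeated-subsample validation against per-iteration models.

    For each bootstrap iteration the iteration's stepwise-selected model
    is refit on its resampled rows, then ``reps`` subsets of
    ``fraction`` of those rows (drawn without replacement) are scored.
    With ``out_of_bag=True`` the subsets are instead drawn from segments
    absent from the iteration's resample — a stricter check than the
    in-bag default.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    total_correct = 0
    total_n = 0
    for b in range(boot.B):
        rows = boot.iteration_rows[b]
        included = [j for j in range(len(boot.names)) if boot.inclusion[b, j]]
        sub = design.subset(rows=rows, cols=included)
        fit = fit_model(sub)
        if out_of_bag:
            pool = np.setdiff1d(np.arange(design.n), np.unique(rows))
            if pool.size == 0:
                continue
        else:
            pool = rows
        m = max(1, int(round(fraction * pool.size)))
        correct = _iteration_correct(fit, design, pool, cutoff, level).astype(np.int64)
        keys = rng.random((reps, pool.size))
        subset_idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        total_correct += int(correct[subset_idx].sum())
        total_n += reps * m
    if total_n == 0:
        raise RuntimeError("no iteration could be validated")
    p = total_correct / total_n
    half = 1.959963984540054 * math.sqrt(max(p * (1 - p), 0.0) / total_n)
    return ValidationReport(kind=boot.kind, proportion_correct=p,
                            ci_lower=max(0.0, p - half), ci_upper=min(1.0, p + half),
                            n_validated=total_n, fraction=fraction, reps=reps)
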