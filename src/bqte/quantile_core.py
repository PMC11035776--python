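"""Empirical quantile functions, the QTE curve, and the average effect.

The quantile treatment effect (QTE) at level ``p`` compares the same
quantile of the two marginal outcome distributions.  In a randomized trial
each arm's observed distribution identifies the corresponding potential
outcome marginal, so the QTE is identified without any assumption on the
joint distribution of the two potential outcomes.

Sign convention: durations are "bad", so effects are reported as the
*reduction* ``Q_control(p) - Q_treatment(p)``; a beneficial treatment gives
positive reductions.  Both arms' quantiles are stored so the econometric
convention (treated minus untreated) is always recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trial import ArmSample, DomainError, QuantileGrid, TrialData

#: quantile estimators offered; ``inverse_ecdf`` is the default because the
#: estimation procedure is stated in terms of ordered observations and it
#: makes mean(QTE) == ATE exact on the midpoint grid with equal arms.
QUANTILE_METHODS = ("inverse_ecdf", "linear")


@dataclass(frozen=True)
class QTECurve:
    """Per-arm quantiles and their difference on a quantile grid.

    ``reduction[i] = q_control[i] - q_treatment[i]`` (days saved by
    treatment at level ``levels[i]``).
    """

    levels: QuantileGrid
    q_control: np.ndarray
    q_treatment: np.ndarray
    reduction: np.ndarray

    def __post_init__(self) -> None:
        m = self.levels.m
        for name in ("q_control", "q_treatment", "reduction"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (m,):
                raise ValueError(f"{name} must have length {m}")
            object.__setattr__(self, name, v)

    @property
    def mean_reduction(self) -> float:
        return float(np.mean(self.reduction))


def _check_method(method: str) -> None:
    if method not in QUANTILE_METHODS:
        raise DomainError(f"unknown quantile method {method!r}; choose from {QUANTILE_METHODS}")


def empirical_quantile(sample: ArmSample, p, method: str = "inverse_ecdf"):
    """Empirical quantile of one arm at level(s) ``p`` in (0, 1).

    ``inverse_ecdf`` returns the left-continuous inverse ECDF, i.e. the
    order statistic x_(k) with k = ceil(p*n).  ``linear`` is the
    conventional linearly interpolated quantile (numpy's default).
    """
    _check_method(method)
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise DomainError("quantile level must lie strictly inside (0, 1)")
    xs = sample.sorted()
    if method == "inverse_ecdf":
        k = np.ceil(p_arr * xs.size).astype(int)  # 1-based rank
        out = xs[np.clip(k - 1, 0, xs.size - 1)]
    else:
        out = np.quantile(xs, p_arr, method="linear")
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else np.asarray(out, dtype=float)


def default_grid(trial: TrialData) -> QuantileGrid:
    """Control-anchored midpoint grid: levels (i - 0.5)/n0 for i = 1..n0.

    Anchoring on the control arm keeps one grid level per control order
    statistic, which is what back-transformation to the control duration
    scale needs.
    """
    return QuantileGrid.midpoints(trial.n_control)


def qte_curve(trial: TrialData, grid: QuantileGrid | None = None,
              method: str = "inverse_ecdf") -> QTECurve:
    """QTE curve: both arms' empirical quantiles on ``grid`` and the reduction.

    With equal arm sizes, the midpoint grid and ``inverse_ecdf`` this is
    exactly "sort both arms and difference element-wise".
    """
    if grid is None:
        grid = default_grid(trial)
    q0 = empirical_quantile(trial.control, grid.levels, method)
    q1 = empirical_quantile(trial.treatment, grid.levels, method)
    return QTECurve(levels=grid, q_control=q0, q_treatment=q1, reduction=q0 - q1)


def ate(trial: TrialData) -> float:
    """Average treatment effect as a mean reduction in duration (days).

    ``mean(control) - mean(treatment)``; positive means treatment shortens
    the outcome.
    """
    return float(np.mean(trial.control.outcomes) - np.mean(trial.treatment.outcomes))
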