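"""Back-transformation of the QTE to the measurement-unit (day) scale.

The BQTE curve re-indexes the QTE from quantile level to untreated
duration: "how many days shorter is a d-day cold expected to be under
treatment, at the same quantile level".  With day- or half-day-resolution
outcomes many grid levels map to one observed control duration; the BQTE
value at that duration is the mean of the QTE over the whole block of
levels the ECDF sends there.

The upper-tail effect (UTBQTE) averages the effect over an upper-tail
region of the untreated distribution (e.g. colds lasting >= 15 days).  It
contrasts the top-``k0`` control outcomes with the proportionally matched
top-``k1`` treatment outcomes, and — like the QTE itself — makes no
assumption about whether treatment preserves individual ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantile_core import ate, default_grid, qte_curve
from .trial import QuantileGrid, RangeError, TrialData


@dataclass(frozen=True)
class BQTECurve:
    """Treatment effect (days) as a function of untreated duration (days).

    ``n_support[i]`` counts the quantile-grid levels whose control quantile
    equals ``duration[i]``; it is 0 for points obtained by interpolation
    between observed durations.
    """

    duration: np.ndarray
    reduction: np.ndarray
    n_support: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.duration, dtype=float)
        r = np.asarray(self.reduction, dtype=float)
        ns = np.asarray(self.n_support, dtype=int)
        if not (d.shape == r.shape == ns.shape) or d.ndim != 1:
            raise ValueError("duration, reduction and n_support must be 1-d and equal length")
        if np.any(np.diff(d) <= 0):
            raise ValueError("duration must be strictly increasing")
        object.__setattr__(self, "duration", d)
        object.__setattr__(self, "reduction", r)
        object.__setattr__(self, "n_support", ns)

    def at(self, d) -> np.ndarray:
        """Evaluate the curve at duration(s) ``d`` by linear interpolation.

        No extrapolation: ``d`` must lie inside the observed control range.
        """
        d_arr = np.atleast_1d(np.asarray(d, dtype=float))
        lo, hi = self.duration[0], self.duration[-1]
        if np.any(d_arr < lo) or np.any(d_arr > hi):
            raise RangeError(f"duration outside control range [{lo}, {hi}]")
        return np.interp(d_arr, self.duration, self.reduction)


@dataclass(frozen=True)
class TailEffect:
    """Matched-upper-tail average effect above a duration threshold."""

    threshold: float
    tail_fraction: float
    mean_reduction: float
    n_control_tail: int
    n_treatment_tail: int


def _block_average(q_control: np.ndarray, effects: np.ndarray) -> BQTECurve:
    """Average ``effects`` over blocks of grid levels sharing a control quantile."""
    durations, inverse, counts = np.unique(q_control, return_inverse=True, return_counts=True)
    sums = np.zeros_like(durations)
    np.add.at(sums, inverse, effects)
    return BQTECurve(duration=durations, reduction=sums / counts, n_support=counts)


def bqte_curve(trial: TrialData, at=None, grid: QuantileGrid | None = None,
               method: str = "inverse_ecdf") -> BQTECurve:
    """Back-transformed QTE curve on the control duration scale.

    For each distinct control quantile value ``d`` on the (by default
    control-anchored midpoint) grid, the reduction is the mean QTE over all
    grid levels mapping to ``d``.  If ``at`` is given, the curve is
    evaluated at those durations (linear interpolation between observed
    durations; requested points must lie inside the control range).
    """
    if grid is None:
        grid = default_grid(trial)
    curve = qte_curve(trial, grid, method)
    base = _block_average(curve.q_control, curve.reduction)
    if at is None:
        return base
    at_arr = np.unique(np.asarray(at, dtype=float))
    red = base.at(at_arr)
    support = np.zeros(at_arr.size, dtype=int)
    exact = np.isin(at_arr, base.duration)
    if exact.any():
        idx = np.searchsorted(base.duration, at_arr[exact])
        support[exact] = base.n_support[idx]
    return BQTECurve(duration=at_arr, reduction=red, n_support=support)


def utbqte(trial: TrialData, threshold: float, rounding: str = "half_up") -> TailEffect:
    """Upper-tail average effect: colds lasting ``threshold`` days or longer.

    Let ``k0`` be the number of control outcomes >= threshold (closed tail)
    and ``k1 = round(k0 * n1/n0)`` (clamped to >= 1) the proportionally
    matched treatment count.  The effect is mean(top-k0 control) minus
    mean(top-k1 treatment).  ``rounding`` for ``k1`` is ``half_up``
    (default), ``floor`` or ``ceil``.
    """
    x0 = trial.control.sorted()
    x1 = trial.treatment.sorted()
    k0 = int(np.sum(x0 >= threshold))
    if k0 == 0:
        raise RangeError(f"no control observation >= {threshold}")
    raw = k0 * trial.n_treatment / trial.n_control
    if rounding == "half_up":
        k1 = int(np.floor(raw + 0.5))
    elif rounding == "floor":
        k1 = int(np.floor(raw))
    elif rounding == "ceil":
        k1 = int(np.ceil(raw))
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    k1 = max(1, min(k1, trial.n_treatment))
    mean0 = float(np.mean(x0[-k0:]))
    mean1 = float(np.mean(x1[-k1:]))
    return TailEffect(threshold=float(threshold),
                      tail_fraction=k0 / trial.n_control,
                      mean_reduction=mean0 - mean1,
                      n_control_tail=k0,
                      n_treatment_tail=k1)


def whole_sample_tail(trial: TrialData) -> TailEffect:
    """UTBQTE at the minimum control duration; equals the ATE when the
    proportional rounding is exact (always, for equal arm sizes)."""
    eff = utbqte(trial, float(np.min(trial.control.outcomes)))
    assert eff.n_control_tail == trial.n_control
    if eff.n_treatment_tail == trial.n_treatment:
        # exact whole-sample limit; cross-check against the ATE
        assert abs(eff.mean_reduction - ate(trial)) < 1e-9
    return eff
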