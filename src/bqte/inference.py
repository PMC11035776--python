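"""Percentile-bootstrap confidence bands for the trial estimators.

Arms are independent samples in a randomized trial, so resampling is
stratified: each replicate redraws each arm with replacement, separately.
Curve estimators are re-evaluated on the *original* trial's grid levels or
durations, giving pointwise bands.  Replicate ``j`` uses an RNG substream
derived deterministically from ``(seed, j)``, so increasing ``n_boot``
extends the replicate sequence without reshuffling earlier replicates.

Back-transformed estimators can fail on a replicate whose control range no
longer covers an evaluation point; that replicate contributes a missing
value there, and points where more than half the replicates are missing
are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import backtransform, coupling_bounds, quantile_core
from .trial import DomainError, RangeError, TrialData

ESTIMATORS = ("ate", "qte", "bqte", "utbqte", "bounds")


@dataclass(frozen=True)
class BandedCurve:
    """Point estimate(s) with pointwise percentile bands.

    ``index`` holds the evaluation points: quantile levels (qte), durations
    (bqte, bounds) or a single threshold/placeholder (utbqte, ate).  For
    the ``bounds`` estimator the estimate rows are stacked
    (min_reduction then max_reduction over the same durations) and
    ``index`` is tiled accordingly.  ``flagged`` marks points where more
    than 50% of replicates were missing.
    """

    estimator: str
    index: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_boot: int
    seed: int
    flagged: np.ndarray

    @property
    def interval(self) -> tuple[float, float]:
        """The (lower, upper) pair for scalar estimators."""
        if self.estimate.size != 1:
            raise ValueError("interval is defined only for scalar estimators")
        return float(self.lower[0]), float(self.upper[0])


def _resample(trial: TrialData, rng: np.random.Generator) -> TrialData:
    c = rng.choice(trial.control.outcomes, size=trial.n_control, replace=True)
    t = rng.choice(trial.treatment.outcomes, size=trial.n_treatment, replace=True)
    return TrialData.from_arrays(c, t, trial.control.label, trial.treatment.label)


def _make_evaluator(trial: TrialData, estimator: str, method: str,
                    threshold: float | None, durations, grid):
    """Fix the evaluation points from the original trial and return
    (index, evaluate(trial) -> vector with NaN for failures)."""
    if estimator == "ate":
        index = np.array([np.nan])
        return index, lambda t: np.array([quantile_core.ate(t)])
    if estimator == "qte":
        if grid is None:
            grid = quantile_core.default_grid(trial)
        return grid.levels, lambda t: quantile_core.qte_curve(t, grid, method).reduction
    if estimator == "bqte":
        base = backtransform.bqte_curve(trial, method=method)
        index = base.duration if durations is None else np.unique(np.asarray(durations, float))

        def ev(t: TrialData) -> np.ndarray:
            curve = backtransform.bqte_curve(t, method=method)
            out = np.full(index.size, np.nan)
            inside = (index >= curve.duration[0]) & (index <= curve.duration[-1])
            if inside.any():
                out[inside] = curve.at(index[inside])
            return out

        return index, ev
    if estimator == "utbqte":
        if threshold is None:
            raise DomainError("utbqte bootstrap needs a threshold")
        index = np.array([float(threshold)])

        def ev(t: TrialData) -> np.ndarray:
            try:
                return np.array([backtransform.utbqte(t, threshold).mean_reduction])
            except RangeError:
                return np.array([np.nan])

        return index, ev
    if estimator == "bounds":
        base = coupling_bounds.bounds_table(trial, method=method)
        durs = base["duration"] if durations is None else np.unique(np.asarray(durations, float))
        index = np.concatenate([durs, durs])

        def ev(t: TrialData) -> np.ndarray:
            tab = coupling_bounds.bounds_table(t, method=method)
            lo = np.full(durs.size, np.nan)
            hi = np.full(durs.size, np.nan)
            inside = (durs >= tab["duration"][0]) & (durs <= tab["duration"][-1])
            if inside.any():
                pres = np.interp(durs[inside], tab["duration"], tab["preserved"])
                rev = np.interp(durs[inside], tab["duration"], tab["reversed"])
                lo[inside] = np.minimum(pres, rev)
                hi[inside] = np.maximum(pres, rev)
            return np.concatenate([lo, hi])

        return index, ev
    raise DomainError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")


def bootstrap_bands(trial: TrialData, estimator: str, *, n_boot: int = 1000,
                    level: float = 0.95, seed: int, method: str = "inverse_ecdf",
                    threshold: float | None = None, durations=None,
                    grid=None) -> BandedCurve:
    """Pointwise percentile bootstrap bands for a named estimator.

    Parameters
    ----------
    estimator
        One of ``ate``, ``qte``, ``bqte``, ``utbqte``, ``bounds``.
    n_boot
        Number of stratified resamples (>= 100).
    level
        Two-sided coverage level in (0.5, 1); bands are the (1 +/- level)/2
        empirical percentiles over replicates.
    seed
        Master seed; replicate j draws from ``default_rng([seed, j])``.
    threshold, durations, grid
        Estimator-specific evaluation points (utbqte / bqte, bounds / qte).
    """
    if n_boot < 100:
        raise DomainError("n_boot must be at least 100")
    if not 0.5 < level < 1.0:
        raise DomainError("level must lie in (0.5, 1)")
    index, evaluate = _make_evaluator(trial, estimator, method, threshold, durations, grid)
    estimate = evaluate(trial)
    reps = np.empty((n_boot, estimate.size))
    for j in range(n_boot):
        rng = np.random.default_rng([seed, j])
        reps[j] = evaluate(_resample(trial, rng))
    alpha = (1.0 - level) / 2.0
    n_missing = np.isnan(reps).sum(axis=0)
    flagged = n_missing > 0.5 * n_boot
    with np.errstate(all="ignore"):
        lower = np.nanpercentile(reps, 100 * alpha, axis=0)
        upper = np.nanpercentile(reps, 100 * (1 - alpha), axis=0)
    return BandedCurve(estimator=estimator, index=index, estimate=estimate,
                       lower=lower, upper=upper, level=level, n_boot=n_boot,
                       seed=seed, flagged=flagged)
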