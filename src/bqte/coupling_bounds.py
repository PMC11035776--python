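"""Extreme couplings of the two arms and bounds on individual-level effects.

A randomized trial identifies the two marginal potential-outcome
distributions but not their joint distribution, hence not the distribution
of individual-level effects X - X*.  The joint distribution is, however,
bounded by the two extreme couplings of the margins (the Fréchet–Hoeffding
bounds):

* order preserved (comonotonic): both margins paired rank-for-rank; this
  maximizes the correlation r = cor(X, X*) and minimizes the variance of
  the paired differences — the QTE curve is exactly this coupling's effect
  vector, so the QTE is the minimum-variance reading of the individual
  effects;
* order reversed (countermonotonic): ranks paired opposite ways; minimal r,
  maximal variance of the differences.

Both couplings preserve the margins, so the mean effect is the same (the
grid ATE) under either; only the spread differs, via

    var(X - X*) = v + v* - 2 r sqrt(v v*),

which equals (sqrt(v) - sqrt(v*))^2 at r = +1 and (sqrt(v) + sqrt(v*))^2
at r = -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .backtransform import BQTECurve, _block_average
from .quantile_core import empirical_quantile
from .trial import DomainError, QuantileGrid, TrialData

Ordering = Literal["preserved", "reversed"]

#: status value set when an arm has zero variance and r is undefined
DEGENERATE_VARIANCE = "degenerate_variance"


@dataclass(frozen=True)
class CoupledSample:
    """Paired pseudo-observations (x, x_star) under an assumed ordering.

    x are control-scale values, x_star treatment-scale values, both
    evaluated on a common midpoint quantile grid so unequal arm sizes are
    handled.  ``r`` is the Pearson correlation of the pairs, or ``None``
    with ``status == "degenerate_variance"`` when an arm has zero variance.
    """

    x: np.ndarray
    x_star: np.ndarray
    ordering: Ordering
    r: float | None
    v: float
    v_star: float
    status: str = "ok"

    @property
    def m(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class TEDistribution:
    """Individual-level effect distribution implied by one coupling.

    ``effects = x - x_star`` per pair (positive = duration reduced).  Both
    extreme couplings leave the margins untouched, so ``mean`` equals the
    grid ATE under either ordering; only ``variance`` distinguishes them.
    """

    effects: np.ndarray
    ordering: Ordering
    mean: float
    variance: float


class DurationBounds(NamedTuple):
    """Bounds on the expected individual-level reduction at one untreated
    duration, from the two extreme couplings."""

    duration: float
    preserved: float
    reversed_: float
    min_reduction: float
    max_reduction: float


def couple(trial: TrialData, ordering: Ordering = "preserved",
           m: int | None = None, method: str = "inverse_ecdf") -> CoupledSample:
    """Couple the two arms' quantile functions on a midpoint grid.

    Preserved pairs (Q0(p_i), Q1(p_i)); reversed pairs (Q0(p_i), Q1(1-p_i)).
    Default m is the control arm size; for equal arms with m = n this is
    pairing the sorted raw values (optionally one arm reversed).
    """
    if ordering not in ("preserved", "reversed"):
        raise DomainError(f"ordering must be 'preserved' or 'reversed', got {ordering!r}")
    if m is None:
        m = trial.n_control
    if m < 2:
        raise DomainError("need m >= 2 grid levels")
    levels = QuantileGrid.midpoints(m).levels
    x = empirical_quantile(trial.control, levels, method)
    p1 = levels if ordering == "preserved" else levels[::-1]
    x_star = empirical_quantile(trial.treatment, p1, method)
    v = float(np.var(x))
    v_star = float(np.var(x_star))
    if v == 0.0 or v_star == 0.0:
        return CoupledSample(x, x_star, ordering, None, v, v_star, DEGENERATE_VARIANCE)
    r = float(np.corrcoef(x, x_star)[0, 1])
    return CoupledSample(x, x_star, ordering, r, v, v_star)


def te_distribution(coupled: CoupledSample) -> TEDistribution:
    """Effect distribution x - x_star implied by a coupled sample.

    Under the preserved ordering the effects vector is exactly the QTE
    reduction vector on the same grid.
    """
    effects = coupled.x - coupled.x_star
    return TEDistribution(effects=effects, ordering=coupled.ordering,
                          mean=float(np.mean(effects)),
                          variance=float(np.var(effects)))


def te_variance(v: float, v_star: float, r: float) -> float:
    """Variance of the individual effect: v + v* - 2 r sqrt(v v*).

    r = +1 gives the mathematical minimum (sqrt(v) - sqrt(v*))^2, r = -1
    the maximum (sqrt(v) + sqrt(v*))^2.
    """
    if v < 0 or v_star < 0:
        raise DomainError("variances must be non-negative")
    if not -1.0 <= r <= 1.0:
        raise DomainError(f"correlation r={r} outside [-1, 1]")
    s = np.sqrt(v * v_star)
    if r == 1.0:
        return float((np.sqrt(v) - np.sqrt(v_star)) ** 2)
    if r == -1.0:
        return float((np.sqrt(v) + np.sqrt(v_star)) ** 2)
    return float(v + v_star - 2.0 * r * s)


def _coupled_bqte(trial: TrialData, ordering: Ordering, m: int | None,
                  method: str) -> BQTECurve:
    cs = couple(trial, ordering, m, method)
    return _block_average(cs.x, cs.x - cs.x_star)


def reversed_bqte_curve(trial: TrialData, m: int | None = None,
                        method: str = "inverse_ecdf") -> BQTECurve:
    """Back-transformed effect curve under the order-reversed coupling.

    Block-averaged over the same grid levels as the ordinary BQTE curve
    (which is the preserved-order analogue) and interpolated identically.
    """
    return _coupled_bqte(trial, "reversed", m, method)


def bounds_at_duration(trial: TrialData, d: float, m: int | None = None,
                       method: str = "inverse_ecdf") -> DurationBounds:
    """Range of expected individual-level reduction at untreated duration d.

    The two extreme couplings give the two attainable extremes of the
    coupling-conditional mean effect at d; they are returned by name
    (``preserved``, ``reversed_``) and as the ordered pair
    (``min_reduction``, ``max_reduction``).  In the upper tail of a
    beneficial treatment the reversed coupling gives the larger reduction
    (the preserved/QTE value stays closest to the ATE); below the median
    the roles swap, which is why the pair is sorted rather than labeled.
    """
    pres = float(_coupled_bqte(trial, "preserved", m, method).at(d)[0])
    rev = float(_coupled_bqte(trial, "reversed", m, method).at(d)[0])
    return DurationBounds(duration=float(d), preserved=pres, reversed_=rev,
                          min_reduction=min(pres, rev), max_reduction=max(pres, rev))


def bounds_table(trial: TrialData, m: int | None = None,
                 method: str = "inverse_ecdf") -> dict:
    """Per-duration bounds plus the coupling summary header.

    Returns a dict with the preserved and reversed BQTE curves evaluated on
    the preserved curve's duration support, the empirical r under each
    ordering, the grid variances, and the theoretical variance limits at
    r = +/-1.
    """
    pres_curve = _coupled_bqte(trial, "preserved", m, method)
    rev_curve = _coupled_bqte(trial, "reversed", m, method)
    rev_on_pres = rev_curve.at(pres_curve.duration)
    cs_p = couple(trial, "preserved", m, method)
    cs_r = couple(trial, "reversed", m, method)
    v, v_star = cs_p.v, cs_p.v_star
    return {
        "duration": pres_curve.duration,
        "preserved": pres_curve.reduction,
        "reversed": rev_on_pres,
        "min_reduction": np.minimum(pres_curve.reduction, rev_on_pres),
        "max_reduction": np.maximum(pres_curve.reduction, rev_on_pres),
        "n_support": pres_curve.n_support,
        "r_preserved": cs_p.r,
        "r_reversed": cs_r.r,
        "v": v,
        "v_star": v_star,
        "var_min_mathematical": te_variance(v, v_star, 1.0),
        "var_max_mathematical": te_variance(v, v_star, -1.0),
        "var_preserved": te_distribution(cs_p).variance,
        "var_reversed": te_distribution(cs_r).variance,
        "status": cs_p.status,
    }
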