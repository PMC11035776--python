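"""Synthetic two-arm duration-trial generator with explicit joint structure.

The generator draws *paired* potential outcomes, so the hidden truth the
trial never reveals — the joint distribution of (untreated, treated)
durations — is available for testing.  Construction:

1. latent standard-normal pairs with correlation ``rank_rho`` (a Gaussian
   copula: one parameter interpolates between fully reversed ranks at -1,
   independence at 0, and exact rank invariance at +1);
2. both margins mapped through the control marginal's inverse CDF;
3. the treatment copy pushed through a monotone effect map on the duration
   scale, so the population QTE has closed form (``true_qte``) and does not
   depend on ``rank_rho`` — the identification point the QTE rests on;
4. optional rounding to a whole- or half-day lattice;
5. complete randomization: a random permutation splits the units into the
   two fixed arm sizes, and each unit reveals one potential outcome.

Control marginals offered: gamma (right-skewed continuous durations) and
negative binomial (integer day counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .trial import DomainError, QuantileGrid, TrialData


class ConfigError(ValueError):
    """Invalid simulator configuration."""


# --- effect maps: monotone quantile maps on the duration scale ------------


@dataclass(frozen=True)
class Shift:
    """Constant reduction of c days (clamped so durations stay >= 0)."""

    c: float

    def reduction(self, d: np.ndarray) -> np.ndarray:
        return np.minimum(self.c, np.asarray(d, dtype=float))

    def apply(self, d: np.ndarray) -> np.ndarray:
        return np.maximum(np.asarray(d, dtype=float) - self.c, 0.0)


@dataclass(frozen=True)
class Scale:
    """Multiplicative map: a d-day untreated course lasts s*d days treated."""

    s: float

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ConfigError("scale factor must be non-negative")

    def reduction(self, d: np.ndarray) -> np.ndarray:
        return (1.0 - self.s) * np.asarray(d, dtype=float)

    def apply(self, d: np.ndarray) -> np.ndarray:
        return self.s * np.asarray(d, dtype=float)


@dataclass(frozen=True)
class Piecewise:
    """Duration-dependent reduction, linear between knots, flat outside.

    ``reductions[k]`` is the reduction (days) applied at untreated duration
    ``knots[k]``; the implied treated duration d - reduction(d) must be
    non-decreasing in d so the map stays a valid quantile map.
    """

    knots: tuple
    reductions: tuple

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        r = np.asarray(self.reductions, dtype=float)
        if k.size != r.size or k.size < 2:
            raise ConfigError("need matching knots/reductions vectors of length >= 2")
        if np.any(np.diff(k) <= 0):
            raise ConfigError("knots must be strictly increasing")
        if np.any(np.diff(k - r) < 0):
            raise ConfigError("effect map not monotone: d - reduction(d) must be non-decreasing")
        object.__setattr__(self, "knots", tuple(k))
        object.__setattr__(self, "reductions", tuple(r))

    def reduction(self, d: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(d, dtype=float), self.knots, self.reductions)

    def apply(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return np.maximum(d - self.reduction(d), 0.0)


EffectMap = Shift | Scale | Piecewise


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic trial.

    Defaults emulate a common-cold duration trial: ~8-day mean untreated
    duration with right skew (gamma, shape 4, rate 0.5), 100 participants
    per arm, a 2-day constant shortening, exact rank invariance, and
    half-day outcome resolution.
    """

    n_control: int = 100
    n_treatment: int = 100
    control_marginal: str = "gamma"
    marginal_params: Mapping[str, float] = field(
        default_factory=lambda: {"shape": 4.0, "rate": 0.5})
    effect_map: EffectMap = field(default_factory=lambda: Shift(2.0))
    rank_rho: float = 1.0
    rounding: str = "half_day"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_treatment < 2:
            raise ConfigError("each arm needs at least 2 units")
        if not -1.0 <= self.rank_rho <= 1.0:
            raise ConfigError("rank_rho must lie in [-1, 1]")
        if self.rounding not in ("none", "half_day", "whole_day"):
            raise ConfigError(f"unknown rounding {self.rounding!r}")
        self._marginal_dist()  # validate parameters eagerly

    def _marginal_dist(self):
        p = dict(self.marginal_params)
        if self.control_marginal == "gamma":
            shape, rate = p.get("shape"), p.get("rate")
            if not (shape and rate and shape > 0 and rate > 0):
                raise ConfigError("gamma marginal needs positive 'shape' and 'rate'")
            return stats.gamma(a=shape, scale=1.0 / rate)
        if self.control_marginal == "negbinom":
            size, prob = p.get("size"), p.get("prob")
            if not (size and prob and size > 0 and 0 < prob < 1):
                raise ConfigError("negbinom marginal needs 'size' > 0 and 'prob' in (0,1)")
            return stats.nbinom(n=size, p=prob)
        raise ConfigError(f"unknown control marginal {self.control_marginal!r}")

    def control_quantile(self, u) -> np.ndarray:
        return np.asarray(self._marginal_dist().ppf(np.asarray(u, dtype=float)), dtype=float)


def _round(x: np.ndarray, rounding: str) -> np.ndarray:
    if rounding == "none":
        return x
    step = 0.5 if rounding == "half_day" else 1.0
    return np.round(x / step) * step


def simulate_trial(config: SimConfig) -> tuple[TrialData, pd.DataFrame]:
    """Draw one trial; return the revealed data and the hidden truth.

    The truth frame has one row per unit with both potential outcomes
    (``x_control``, ``x_treatment``) and the revealed ``arm``; the
    ``TrialData`` contains only what a real trial would observe.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_control + config.n_treatment
    rho = config.rank_rho
    # explicit Cholesky of the 2x2 correlation so rho = +/-1 stays exact
    z0 = rng.standard_normal(n)
    z1 = rho * z0 + np.sqrt(max(1.0 - rho * rho, 0.0)) * rng.standard_normal(n)
    x0 = config.control_quantile(stats.norm.cdf(z0))
    x1 = config.effect_map.apply(config.control_quantile(stats.norm.cdf(z1)))
    x0 = _round(x0, config.rounding)
    x1 = np.maximum(_round(x1, config.rounding), 0.0)
    perm = rng.permutation(n)
    arm = np.empty(n, dtype=object)
    arm[perm[:config.n_control]] = "control"
    arm[perm[config.n_control:]] = "treatment"
    truth = pd.DataFrame({"x_control": x0, "x_treatment": x1, "arm": arm})
    trial = TrialData.from_arrays(x0[arm == "control"], x1[arm == "treatment"])
    return trial, truth


def true_qte(config: SimConfig, grid: QuantileGrid) -> np.ndarray:
    """Population QTE reduction implied by the marginal and effect map.

    Closed form: reduction(p) = Q0(p) - max(g(Q0(p)), 0) where g is the
    effect map; independent of ``rank_rho`` (quantiles only see margins).
    Computed before rounding — lattice effects are a finite-sample feature.
    """
    q0 = config.control_quantile(grid.levels)
    return q0 - np.maximum(config.effect_map.apply(q0), 0.0)
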