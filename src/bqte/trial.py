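"""Core containers for a two-arm duration trial.

A trial consists of two independent samples of non-negative outcome
durations (days), one per arm.  Under randomization each arm's empirical
distribution identifies the marginal distribution of the corresponding
potential outcome, which is all the quantile-based estimators in this
package require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TrialError(Exception):
    """Base class for errors raised by this package."""


class InputDataError(TrialError, ValueError):
    """Invalid outcome data (negative, non-finite, or too few observations)."""


class DomainError(TrialError, ValueError):
    """A parameter outside its mathematical domain (e.g. p not in (0,1))."""


class RangeError(TrialError, ValueError):
    """A requested duration outside the observed control range."""


@dataclass(frozen=True)
class ArmSample:
    """Outcomes observed in one arm.

    Parameters
    ----------
    outcomes
        Non-negative, finite durations in days.  Half-day resolution (or any
        positive real) is supported; ties are expected and meaningful.
    label
        Arm name, conventionally ``"control"`` or ``"treatment"``.
    """

    outcomes: np.ndarray
    label: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.outcomes, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise InputDataError(f"arm {self.label!r}: outcomes must be a non-empty 1-d array")
        if not np.all(np.isfinite(arr)):
            raise InputDataError(f"arm {self.label!r}: non-finite outcome values")
        if np.any(arr < 0):
            raise InputDataError(f"arm {self.label!r}: negative outcome values")
        object.__setattr__(self, "outcomes", arr)

    @property
    def n(self) -> int:
        return self.outcomes.size

    def sorted(self) -> np.ndarray:
        return np.sort(self.outcomes)


@dataclass(frozen=True)
class TrialData:
    """The two arms of a randomized two-arm trial.

    Arm sizes may differ; every estimator handles unequal ``n`` by working
    on a common quantile grid.
    """

    control: ArmSample
    treatment: ArmSample

    def __post_init__(self) -> None:
        if self.control.label == self.treatment.label:
            raise InputDataError("arm labels must be distinct")
        for arm in (self.control, self.treatment):
            if arm.n < 2:
                raise InputDataError(
                    f"arm {arm.label!r} has {arm.n} observation(s); need at least 2"
                )

    @property
    def n_control(self) -> int:
        return self.control.n

    @property
    def n_treatment(self) -> int:
        return self.treatment.n

    @classmethod
    def from_arrays(cls, control, treatment,
                    control_label: str = "control",
                    treatment_label: str = "treatment") -> "TrialData":
        return cls(ArmSample(np.asarray(control, dtype=float), control_label),
                   ArmSample(np.asarray(treatment, dtype=float), treatment_label))


@dataclass(frozen=True)
class QuantileGrid:
    """Strictly increasing quantile levels, each in the open interval (0, 1)."""

    levels: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if lv.ndim != 1 or lv.size == 0:
            raise DomainError("grid must contain at least one level")
        if np.any(lv <= 0) or np.any(lv >= 1):
            raise DomainError("grid levels must lie strictly inside (0, 1)")
        if np.any(np.diff(lv) <= 0):
            raise DomainError("grid levels must be strictly increasing")
        object.__setattr__(self, "levels", lv)

    @property
    def m(self) -> int:
        return self.levels.size

    @classmethod
    def midpoints(cls, m: int) -> "QuantileGrid":
        """Midpoint levels (i - 0.5)/m for i = 1..m."""
        if m < 1:
            raise DomainError("midpoint grid needs m >= 1")
        return cls((np.arange(1, m + 1) - 0.5) / m)
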