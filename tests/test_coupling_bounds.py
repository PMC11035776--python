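"""Extreme couplings, the variance identity, and day-scale bounds."""

import itertools

import numpy as np
import pytest

from bqte import (
    DomainError,
    QuantileGrid,
    TrialData,
    ate,
    bounds_at_duration,
    bounds_table,
    couple,
    qte_curve,
    te_distribution,
    te_variance,
)
from bqte.coupling_bounds import DEGENERATE_VARIANCE
from conftest import random_trial


def all_pairings(x, y):
    """Every possible joint arrangement of two equal-size margins."""
    x = np.sort(x)
    for perm in itertools.permutations(range(len(y))):
        yield x, np.asarray(y)[list(perm)]


class TestCouple:
    def test_identical_arms_preserved_r_is_one(self, rng):
        x = rng.gamma(4.0, 2.0, size=6)
        cs = couple(TrialData.from_arrays(x, x), "preserved")
        assert np.isclose(cs.r, 1.0)

    def test_symmetric_arm_reversed_r_is_minus_one(self):
        x = [1.0, 2, 3, 4, 5]
        cs = couple(TrialData.from_arrays(x, x), "reversed")
        assert np.isclose(cs.r, -1.0)

    def test_monotone_pair_structure(self, rng):
        t = random_trial(rng, 8, 5)
        pres = couple(t, "preserved")
        assert np.all(np.diff(pres.x) >= 0) and np.all(np.diff(pres.x_star) >= 0)
        rev = couple(t, "reversed")
        assert np.all(np.diff(rev.x) >= 0) and np.all(np.diff(rev.x_star) <= 0)

    def test_degenerate_variance_flagged_not_numeric(self):
        t = TrialData.from_arrays([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        cs = couple(t, "preserved")
        assert cs.r is None
        assert cs.status == DEGENERATE_VARIANCE

    def test_margins_preserved_so_mean_effect_is_coupling_free(self, rng):
        for _ in range(30):
            t = random_trial(rng)
            pres = te_distribution(couple(t, "preserved"))
            rev = te_distribution(couple(t, "reversed"))
            assert np.isclose(pres.mean, rev.mean, atol=1e-12)
            assert np.array_equal(np.sort(couple(t, "preserved").x_star),
                                  np.sort(couple(t, "reversed").x_star))

    def test_extremal_over_all_pairings(self, rng):
        """Rearrangement inequality, checked exhaustively: among all n!
        joints with the given margins, the preserved coupling attains the
        max correlation / min effect variance and the reversed the min / max."""
        for _ in range(100):
            n = int(rng.integers(3, 6))
            t = random_trial(rng, n, n, lattice=None)
            pres = couple(t, "preserved", m=n)
            rev = couple(t, "reversed", m=n)
            v_pres = te_distribution(pres).variance
            v_rev = te_distribution(rev).variance
            for x, y in all_pairings(t.control.outcomes, t.treatment.outcomes):
                r = np.corrcoef(x, y)[0, 1]
                v = np.var(x - y)
                assert pres.r >= r - 1e-12 >= rev.r - 2e-12
                assert v_pres - 1e-12 <= v <= v_rev + 1e-12


class TestTEDistribution:
    def test_preserved_effects_equal_qte_reduction(self, rng):
        t = random_trial(rng, 9, 6)
        cs = couple(t, "preserved")
        curve = qte_curve(t, QuantileGrid.midpoints(cs.m))
        assert np.array_equal(te_distribution(cs).effects, curve.reduction)

    def test_pure_shift_preserved_variance_zero(self, shift_trial):
        dist = te_distribution(couple(shift_trial, "preserved"))
        assert np.allclose(dist.effects, 3.0)
        assert dist.variance == 0.0

    def test_variance_identity_holds(self, rng):
        for _ in range(200):
            t = random_trial(rng, lattice=None)
            for ordering in ("preserved", "reversed"):
                cs = couple(t, ordering)
                dist = te_distribution(cs)
                expected = te_variance(cs.v, cs.v_star, cs.r)
                assert abs(dist.variance - expected) < 1e-9


class TestTEVariance:
    @pytest.mark.parametrize("v,v_star,r,expected", [
        (4.0, 4.0, 1.0, 0.0),
        (4.0, 9.0, -1.0, 25.0),
        (4.0, 9.0, 0.0, 13.0),
    ])
    def test_closed_forms(self, v, v_star, r, expected):
        assert te_variance(v, v_star, r) == expected

    def test_limits_exact(self, rng):
        for _ in range(50):
            v, v_star = rng.uniform(0.1, 50, size=2)
            assert te_variance(v, v_star, 1.0) == (np.sqrt(v) - np.sqrt(v_star)) ** 2
            assert te_variance(v, v_star, -1.0) == (np.sqrt(v) + np.sqrt(v_star)) ** 2

    @pytest.mark.parametrize("r", [-1.5, 1.01])
    def test_correlation_domain_enforced(self, r):
        with pytest.raises(DomainError):
            te_variance(1.0, 1.0, r)


class TestBounds:
    def test_bounds_ordered_for_pure_shift(self, shift_trial):
        for d in np.sort(shift_trial.control.outcomes):
            b = bounds_at_duration(shift_trial, float(d))
            assert b.min_reduction <= b.max_reduction
            assert np.isclose(b.preserved, 3.0)

    def test_identical_arms_hand_enumeration(self):
        # control = treatment = {1,2,3}: preserved effect 0 everywhere;
        # reversed pairs (1,3),(2,2),(3,1) give effects -2, 0, +2
        t = TrialData.from_arrays([1, 2, 3], [1, 2, 3])
        at_median = bounds_at_duration(t, 2.0)
        assert at_median.preserved == 0.0 and at_median.reversed_ == 0.0
        low = bounds_at_duration(t, 1.0)
        assert (low.min_reduction, low.max_reduction) == (-2.0, 0.0)
        high = bounds_at_duration(t, 3.0)
        assert (high.min_reduction, high.max_reduction) == (0.0, 2.0)

    def test_preserved_deviates_least_from_ate(self, rng):
        # the order-preserving coupling hugs the ATE; the reversal strays most
        for _ in range(100):
            t = random_trial(rng)
            a = te_distribution(couple(t, "preserved")).mean
            dev_p = np.mean(np.abs(te_distribution(couple(t, "preserved")).effects - a))
            dev_r = np.mean(np.abs(te_distribution(couple(t, "reversed")).effects - a))
            assert dev_p <= dev_r + 1e-12

    def test_bounds_table_summary_consistent(self, rng):
        t = random_trial(rng, 10, 10)
        tab = bounds_table(t)
        assert np.all(tab["min_reduction"] <= tab["max_reduction"])
        assert tab["var_preserved"] <= tab["var_reversed"]
        assert tab["var_min_mathematical"] <= tab["var_preserved"] + 1e-12
        assert tab["var_reversed"] <= tab["var_max_mathematical"] + 1e-12
        assert -1.0 <= tab["r_reversed"] <= tab["r_preserved"] <= 1.0
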