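import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from daedsr import (
    brier_curve,
    brier_score,
    concordance_index,
    km_censoring,
)
from daedsr.survival import SurvivalCurve


def brute_force_c(risks, times, events):
    conc = comp = 0.0
    for i in range(len(risks)):
        for j in range(len(risks)):
            if times[i] < times[j] and events[i] == 1:
                comp += 1
                if risks[i] > risks[j]:
                    conc += 1
                elif risks[i] == risks[j]:
                    conc += 0.5
    return conc / comp


class TestConcordance:
    def test_perfect_concordance(self):
        r = concordance_index([3, 2, 1], [1, 2, 3], [1, 1, 1])
        assert r.c_index == 1.0 and r.comparable == 3

    def test_perfect_anticoncordance(self):
        assert concordance_index([1, 2, 3], [1, 2, 3], [1, 1, 1]).c_index == 0.0

    def test_censoring_excludes_pairs(self):
        # pair (2,3) excluded because subject 2 is censored
        r = concordance_index([0.8, 0.9, 0.5], [2, 4, 5], [1, 0, 1])
        assert r.comparable == 2
        assert r.c_index == 0.5

    def test_matches_bruteforce_with_ties_and_censoring(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            times = rng.integers(1, 10, n).astype(float)
            events = (rng.random(n) < 0.7).astype(int)
            risks = rng.integers(0, 5, n).astype(float)  # forces risk ties
            try:
                mine = concordance_index(risks, times, events)
            except ValueError:
                continue
            assert mine.c_index == pytest.approx(
                brute_force_c(risks, times, events), abs=1e-12
            )

    def test_agrees_with_lifelines(self):
        from lifelines.utils import concordance_index as ll_c

        rng = np.random.default_rng(1)
        t = rng.exponential(10, 150) + 0.1
        e = (rng.random(150) < 0.6).astype(int)
        r = rng.standard_normal(150)
        # lifelines orients concordance toward longer predicted times
        assert concordance_index(r, t, e).c_index == pytest.approx(
            1 - ll_c(t, r, e), abs=1e-12
        )

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1, 2], [3, 4], [0, 0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_risk_negation_flips_c(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.exponential(10, 20) + 0.1
        e = (rng.random(20) < 0.8).astype(int)
        r = rng.standard_normal(20)  # continuous, no ties a.s.
        if e.sum() == 0:
            e[0] = 1
        a = concordance_index(r, t, e).c_index
        b = concordance_index(-r, t, e).c_index
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 30) + 0.1
        e = (rng.random(30) < 0.7).astype(int)
        e[0] = 1
        r = rng.standard_normal(30)
        perm = rng.permutation(30)
        assert concordance_index(r, t, e).c_index == pytest.approx(
            concordance_index(r[perm], t[perm], e[perm]).c_index
        )


class TestKmCensoring:
    def test_no_censoring_stays_at_one(self):
        g = km_censoring([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.all(g.evaluate([0.5, 1.5, 3.0]) == 1.0)

    def test_single_censoring_drops_to_zero(self):
        g = km_censoring([1.0, 2.0], [1, 0])
        assert g.evaluate(1.9)[0] == 1.0
        assert g.evaluate(2.0)[0] == 0.0

    def test_hand_example_half(self):
        g = km_censoring([1.0, 2.0, 3.0], [1, 0, 1])
        assert g.evaluate(2.0)[0] == pytest.approx(0.5)

    def test_left_limit_convention(self):
        g = km_censoring([1.0, 2.0, 3.0], [1, 0, 1])
        assert g.evaluate(2.0, left_limit=True)[0] == 1.0

    def test_agrees_with_lifelines_product_limit(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        t = rng.exponential(10, 200) + 0.1
        e = (rng.random(200) < 0.6).astype(int)
        g = km_censoring(t, e)
        km = KaplanMeierFitter().fit(t, 1 - e)
        grid = np.quantile(t, [0.1, 0.3, 0.5, 0.7, 0.9])
        np.testing.assert_allclose(
            g.evaluate(grid),
            km.survival_function_at_times(grid).to_numpy(),
            atol=1e-12,
        )


class TestBrierScore:
    def test_oracle_predictor_scores_zero(self):
        times = np.array([1.0, 2.0, 5.0, 6.0])
        events = np.ones(4, int)
        t = 3.0
        surv = (times > t).astype(float)  # perfect foresight
        g = km_censoring(times, events)
        assert brier_score(surv, times, events, t, g) == 0.0

    def test_constant_half_scores_quarter(self):
        times = np.array([1.0, 2.0, 5.0, 6.0])
        events = np.ones(4, int)
        g = km_censoring(times, events)
        assert brier_score(np.full(4, 0.5), times, events, 3.0, g) == pytest.approx(
            0.25
        )

    def test_hand_computed_censored_example(self):
        times = np.array([2.0, 4.0, 5.0])
        events = np.array([1, 0, 1])
        g = km_censoring(times, events)
        s = np.array([0.2, 0.7, 0.9])
        # G(2)=1 (no censoring before 2), G(3)=1; terms: 0.2^2/1,
        # (1-0.7)^2/1, (1-0.9)^2/1 averaged over 3
        expected = (0.04 + 0.09 + 0.01) / 3
        assert brier_score(s, times, events, 3.0, g) == pytest.approx(expected)

    def test_ipcw_reduces_to_mse_without_censoring(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, 50) + 0.1
        events = np.ones(50, int)
        s = rng.random(50)
        t = float(np.quantile(times, 0.5))
        g = km_censoring(times, events)  # identically 1 below max time
        alive = (times > t).astype(float)
        mse = np.mean((alive - s) ** 2)
        assert brier_score(s, times, events, t, g) == pytest.approx(mse)

    def test_agrees_with_scikit_survival(self):
        from sksurv.metrics import brier_score as sk_brier
        from sksurv.util import Surv

        rng = np.random.default_rng(5)
        t = rng.exponential(10, 80) + 0.1
        e = (rng.random(80) < 0.7).astype(int)
        s = rng.random(80)
        y = Surv.from_arrays(e.astype(bool), t)
        horizon = float(np.quantile(t, 0.5))
        g = km_censoring(t, e)
        _, ref = sk_brier(y, y, s, [horizon])
        assert brier_score(s, t, e, horizon, g) == pytest.approx(ref[0], abs=1e-12)

    def test_zero_weight_region_rejected(self):
        # G estimated on one sample and applied to another can vanish
        # where a weight is still needed
        g = km_censoring([1.0, 2.0], [1, 0])  # G = 0 from t = 2 on
        times = np.array([1.0, 3.0])
        events = np.array([1, 1])
        with pytest.raises(ValueError, match="zero"):
            brier_score(np.array([0.5, 0.5]), times, events, 2.5, g)


class TestBrierCurve:
    def _uncensored(self, n=40, seed=6):
        rng = np.random.default_rng(seed)
        times = rng.exponential(10, n) + 0.1
        return times, np.ones(n, int)

    def test_oracle_curve_is_flat_zero(self):
        times, events = self._uncensored()
        grid = np.linspace(0, np.quantile(times, 0.9), 20)
        values = (times[:, None] > grid[None, :]).astype(float)
        curve = SurvivalCurve(grid, values)
        bc = brier_curve(curve, times, events, grid=grid)
        assert np.all(bc.values == 0.0) and bc.integrated == 0.0

    def test_constant_half_curve_is_quarter(self):
        times, events = self._uncensored()
        grid = np.linspace(0, np.quantile(times, 0.9), 20)
        curve = SurvivalCurve(grid, np.full((len(times), 20), 0.5))
        bc = brier_curve(curve, times, events, grid=grid)
        np.testing.assert_allclose(bc.values, 0.25)
        assert bc.integrated == pytest.approx(0.25)
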