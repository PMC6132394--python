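import math

import numpy as np
import pytest
from scipy import stats

from d9assess.synthetic import (
    SeriesGenSpec,
    demo_dataset,
    lognormal_noise,
    simulate_congener_panel,
    simulate_series,
)
from d9assess.teq import TEFTable, compute_teq


class TestSimulateSeries:
    def test_same_seed_bitwise_identical(self):
        spec = SeriesGenSpec(year_start=1995, year_end=2015, c0=3.0,
                             decline_rate=0.05, noise_cv=0.3, loq=0.5, seed=9)
        a, _ = simulate_series(spec)
        b, _ = simulate_series(spec)
        assert a == b

    def test_different_seed_differs(self):
        kw = dict(year_start=1995, year_end=2015, c0=3.0, noise_cv=0.3)
        a, _ = simulate_series(SeriesGenSpec(seed=1, **kw))
        b, _ = simulate_series(SeriesGenSpec(seed=2, **kw))
        assert a != b

    def test_noise_free_constant_series(self):
        spec = SeriesGenSpec(year_start=2000, year_end=2009, c0=2.5)
        recs, truth = simulate_series(spec)
        assert [r.value for r in recs] == [2.5] * 10
        assert truth.n_censored == 0

    def test_loq_above_mean_censors_everything(self):
        spec = SeriesGenSpec(year_start=2000, year_end=2009, c0=1.0,
                             noise_cv=0.1, loq=10.0, seed=4)
        recs, truth = simulate_series(spec)
        assert all(r.censored for r in recs)
        assert all(r.value == 10.0 for r in recs)
        assert truth.n_censored == 10

    def test_decline_detected_by_trend_module(self):
        from conftest import make_series
        from d9assess.trend import linear_trend, trend_anova

        spec = SeriesGenSpec(year_start=2000, year_end=2014, c0=5.0,
                             decline_rate=0.15, noise_cv=0.1, seed=8)
        recs, _ = simulate_series(spec)
        s = make_series([r.year for r in recs], [r.value for r in recs])
        assert linear_trend(s).slope < 0
        assert trend_anova(s).p_linear < 0.05

    def test_biennial_sampling_interval(self):
        spec = SeriesGenSpec(year_start=2003, year_end=2015, c0=1.0,
                             sampling_interval=2)
        recs, _ = simulate_series(spec)
        assert [r.year for r in recs] == list(range(2003, 2016, 2))

    def test_mean_converges_to_curve(self):
        """Law of large numbers: per-year mean over replicates matches the
        generator curve within three standard errors."""
        kw = dict(year_start=2000, year_end=2009, c0=4.0, decline_rate=0.1,
                  noise_cv=0.3)
        reps = 400
        draws = np.array(
            [[r.value for r in simulate_series(SeriesGenSpec(seed=s, **kw))[0]]
             for s in range(reps)]
        )
        curve = SeriesGenSpec(seed=0, **kw).mean_curve()
        se = draws.std(axis=0, ddof=1) / math.sqrt(reps)
        assert np.all(np.abs(draws.mean(axis=0) - curve) <= 3 * se)

    def test_censoring_fraction_matches_lognormal_tail(self):
        """Observed censoring rate agrees with the analytic lognormal
        probability P(c * LN < loq) within Monte-Carlo error."""
        cv, c0, loq = 0.4, 1.0, 0.8
        sigma2 = math.log(1 + cv * cv)
        p_analytic = stats.norm.cdf(
            (math.log(loq / c0) + sigma2 / 2) / math.sqrt(sigma2)
        )
        reps = 300
        n_per = 10
        total = sum(
            simulate_series(
                SeriesGenSpec(year_start=2000, year_end=2009, c0=c0,
                              noise_cv=cv, loq=loq, seed=s)
            )[1].n_censored
            for s in range(reps)
        )
        observed = total / (reps * n_per)
        se = math.sqrt(p_analytic * (1 - p_analytic) / (reps * n_per))
        assert abs(observed - p_analytic) <= 4 * se


class TestSimulateCongenerPanel:
    def test_uncensored_panel_has_equal_bounds(self):
        panel, truth = simulate_congener_panel(censor_prob=0.0, seed=3)
        assert truth.n_censored == 0
        assert truth.teq_upper == truth.teq_lower

    def test_fully_censored_panel_has_zero_lower_bound(self):
        panel, truth = simulate_congener_panel(censor_prob=1.0, seed=3)
        assert truth.teq_lower == 0.0
        assert truth.teq_upper > 0

    def test_generator_bookkeeping_matches_teq_module(self):
        """The aggregation code reproduces the generator's independent
        term-by-term TEQ sums on a full 29-congener panel."""
        tefs = TEFTable.who2005()
        panel, truth = simulate_congener_panel(n_congeners=29, censor_prob=0.4, seed=11)
        assert compute_teq(panel, tefs, "upper") == pytest.approx(truth.teq_upper)
        assert compute_teq(panel, tefs, "middle") == pytest.approx(truth.teq_middle)
        assert compute_teq(panel, tefs, "lower") == pytest.approx(truth.teq_lower)


class TestDemoDataset:
    def test_deterministic_and_structured(self):
        recs_a, ctx_a = demo_dataset(seed=5)
        recs_b, _ = demo_dataset(seed=5)
        assert recs_a == recs_b
        assert set(ctx_a) == {"NS1", "NS2", "BS"}
        sites = {r.site for r in recs_a}
        species = {r.species for r in recs_a}
        assert sites == {"NS1", "NS2", "BS"}
        assert species == {"Mytilus edulis", "Zoarces viviparus"}

    def test_mussel_records_carry_matrix_fractions(self):
        recs, ctx = demo_dataset(seed=5)
        mussels = [r for r in recs if r.species == "Mytilus edulis"]
        assert all(r.water_fraction is not None for r in mussels)
        assert all(r.breathing_water_fraction is not None for r in mussels)


def test_lognormal_noise_mean_one():
    rng = np.random.default_rng(0)
    draws = lognormal_noise(rng, 0.5, 200_000)
    assert draws.mean() == pytest.approx(1.0, abs=0.01)
    assert draws.std() == pytest.approx(0.5, abs=0.02)
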