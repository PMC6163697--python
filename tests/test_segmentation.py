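"""AR(1) fitting, the penalized cost, PELT vs exact oracles, and events."""

import datetime as dt
import itertools
import logging

import numpy as np
import pytest

from elf_expochar import segmentation as seg
from elf_expochar import synthetic
from elf_expochar.recordings import DayRecording
from .conftest import ar1_series


class TestFitAr1:
    def test_constant_segment_degenerate_convention(self):
        p = seg.fit_ar1(np.full(100, 0.05))
        assert (p.mu, p.sigma2, p.phi) == (0.05, 0.0, 0.0)

    def test_parameter_recovery_on_long_segment(self, rng):
        mu, phi, sigma2, n = 0.05, 0.5, 1e-4, 50_000
        y = ar1_series(rng, n, mu, phi, sigma2)
        p = seg.fit_ar1(y)
        assert abs(p.mu - mu) < 3 * np.sqrt(sigma2 / (1 - phi**2) / n * (1 + phi) / (1 - phi))
        assert abs(p.phi - phi) < 3 * np.sqrt((1 - phi**2) / n)
        assert abs(p.sigma2 - sigma2) < 3 * sigma2 * np.sqrt(2 / n)

    def test_alternating_series_hits_phi_boundary(self):
        """+1/-1 alternation has lag-1 slope exactly -1 (later filtered)."""
        y = np.tile([1.0, -1.0], 50)
        p = seg.fit_ar1(y)
        assert p.phi == pytest.approx(-1.0)
        assert abs(p.phi) >= 1.0  # the stationarity filter will drop it

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="short"):
            seg.fit_ar1(np.array([1.0, 2.0, 3.0]))


class TestSegmentCost:
    def test_reduces_to_two_neg_log_likelihood_of_fitted_ar1(self, rng):
        """Independent reconstruction: m*(log(2*pi*sigma2_hat) + 1)."""
        y = rng.normal(0.05, 0.01, 200)
        p = seg.fit_ar1(y)
        m = y.size - 1
        expected = m * (np.log(2 * np.pi * p.sigma2) + 1)
        assert seg.segment_cost(y, 0, y.size) == pytest.approx(expected, rel=1e-9)

    def test_white_noise_cost_matches_classic_mean_variance_cost(self, rng):
        """For iid data the AR(1) cost approaches m*(log sd2 + 1) + m*log(2*pi)."""
        y = rng.normal(0.0, 1.0, 5000)
        p = seg.fit_ar1(y)
        resid_var = p.sigma2
        cost = seg.segment_cost(y, 0, y.size)
        m = y.size - 1
        classic = m * (np.log(resid_var) + 1) + m * np.log(2 * np.pi)
        assert cost == pytest.approx(classic, rel=1e-12)
        assert abs(p.phi) < 0.05  # iid data: fitted phi is near zero

    def test_pure_function_of_window(self, rng):
        y = rng.normal(0.05, 0.01, 300)
        assert seg.segment_cost(y, 10, 200) == seg.segment_cost(y.copy(), 10, 200)

    def test_no_profitable_split_left_at_optimum(self, rng):
        """If any split improved a segment by > penalty, PELT would have cut."""
        y = np.concatenate([ar1_series(rng, 300, 0.05, 0.3, 1e-4),
                            ar1_series(rng, 300, 0.20, 0.3, 1e-4)])
        result = seg.pelt(y, penalty=25.0)
        for a, b in result.segment_slices():
            whole = seg.segment_cost(y, a, b)
            for cut in range(a + 8, b - 8, max(1, (b - a) // 7)):
                halves = seg.segment_cost(y, a, cut) + seg.segment_cost(y, cut, b)
                assert whole <= halves + 25.0 + 1e-8


def _random_piecewise(rng, n, max_k=3):
    k = int(rng.integers(0, max_k + 1))
    taus = np.sort(rng.choice(np.arange(10, n - 10), size=k, replace=False)) if k else np.array([], int)
    bounds = np.concatenate([[0], taus, [n]]).astype(int)
    parts = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        parts.append(ar1_series(rng, b - a, rng.uniform(0.0, 1.0), rng.uniform(-0.5, 0.8),
                                10 ** rng.uniform(-6, -2)))
    return np.concatenate(parts)


class TestPelt:
    def test_infinite_penalty_yields_single_segment(self, rng):
        y = ar1_series(rng, 500, 0.05, 0.5, 1e-4)
        assert seg.pelt(y, penalty=1e10).k == 0

    def test_single_step_located_within_two_samples(self, rng):
        y = np.concatenate([rng.normal(0.01, 1e-4, 300), rng.normal(1.0, 1e-4, 300)])
        result = seg.pelt(y)
        assert result.k == 1
        assert abs(result.changepoints[0] - 300) <= 2

    def test_matches_exact_dynamic_program_on_random_series(self):
        for i in range(15):
            rng = np.random.default_rng(200 + i)
            y = _random_piecewise(rng, int(rng.integers(120, 400)))
            fast = seg.pelt(y)
            exact = seg.brute_force_segment(y)
            assert fast.total_cost == pytest.approx(exact.total_cost, rel=1e-9)
            np.testing.assert_array_equal(fast.taus, exact.taus)

    def test_penalty_monotonicity(self, rng):
        y = _random_piecewise(rng, 400)
        ks = [seg.pelt(y, penalty=b).k for b in (3.0, 10.0, 30.0, 100.0, 1000.0)]
        assert all(a >= b for a, b in zip(ks[:-1], ks[1:]))

    def test_short_series_flagged_single_segment(self):
        result = seg.pelt(np.array([1.0, 2.0, 1.5, 2.5, 2.0]), min_seg_len=4)
        assert result.too_short and result.k == 0

    def test_stored_params_equal_refit(self, rng):
        y = _random_piecewise(rng, 300)
        result = seg.pelt(y)
        for (a, b), p in zip(result.segment_slices(), result.params):
            q = seg.fit_ar1(y[a:b], min_len=2)
            assert (q.mu, q.sigma2, q.phi) == (p.mu, p.sigma2, p.phi)

    def test_total_cost_recomputable_from_segments(self, rng):
        y = _random_piecewise(rng, 300)
        result = seg.pelt(y)
        total = sum(seg.segment_cost(y, a, b) for a, b in result.segment_slices())
        assert result.total_cost == pytest.approx(total + result.penalty * result.k, rel=1e-9)


class TestBruteForce:
    def test_constant_series_has_no_changepoints(self):
        assert seg.brute_force_segment(np.full(20, 0.05)).k == 0

    def test_guard_limit(self):
        with pytest.raises(ValueError, match="limit"):
            seg.brute_force_segment(np.zeros(3000))

    def test_matches_exhaustive_partition_enumeration(self, rng):
        """All partitions of n=12 with min length 3, scored independently."""
        y = rng.normal(0.5, 0.2, 12)
        penalty = 5.0

        def all_partitions(n, min_len):
            def rec(start):
                if start == n:
                    yield []
                for end in range(start + min_len, n + 1):
                    if n - end not in range(1, min_len):
                        for rest in rec(end):
                            yield [(start, end)] + rest
            return rec(0)

        best = min(
            (sum(seg.segment_cost(y, a, b, min_seg_len=3) for a, b in parts)
             + penalty * (len(parts) - 1))
            for parts in all_partitions(12, 3)
        )
        dp = seg.brute_force_segment(y, penalty=penalty, min_seg_len=3)
        assert dp.total_cost == pytest.approx(best, rel=1e-9)


class TestExtractEvents:
    def _day(self, values):
        return DayRecording(subject_id="S1", date=dt.date(2020, 1, 1),
                            sample_interval_s=30, values=values,
                            metadata={"age_years": 7})

    def test_single_segment_day_spans_86400_seconds(self, rng):
        day = self._day(rng.normal(0.05, 0.001, 2880))
        s = seg.Segmentation(n=2880, taus=np.array([0, 2880]),
                             params=[seg.fit_ar1(day.values)], total_cost=0.0,
                             penalty=1.0, min_seg_len=4)
        events = seg.extract_events(day, s)
        assert len(events) == 1
        assert events[0].duration_s == 86_400.0
        assert events[0].labels["age"] == "5-9"

    def test_duration_scales_with_sample_interval(self, rng):
        day3 = DayRecording(subject_id="S1", date=dt.date(2020, 1, 1),
                            sample_interval_s=3, values=rng.normal(0.05, 0.001, 28_800))
        s = seg.Segmentation(n=28_800, taus=np.array([0, 28_800]),
                             params=[seg.fit_ar1(day3.values)], total_cost=0.0,
                             penalty=1.0, min_seg_len=4)
        assert seg.extract_events(day3, s)[0].duration_s == 86_400.0

    def test_nonstationary_fits_filtered_and_logged(self, rng, caplog):
        day = self._day(rng.normal(0.05, 0.001, 2880))
        params = [seg.ARParams(0.05, 1e-6, 1.2), seg.ARParams(0.05, 1e-6, 0.3)]
        s = seg.Segmentation(n=2880, taus=np.array([0, 1000, 2880]), params=params,
                             total_cost=0.0, penalty=1.0, min_seg_len=4)
        with caplog.at_level(logging.INFO, logger="elf_expochar.segmentation"):
            events = seg.extract_events(day, s)
        assert len(events) == 1 and events[0].phi == 0.3
        assert "excluded 1" in caplog.text

    def test_daynight_partition_of_event_counts(self, contrast_events):
        df = contrast_events
        assert (df.daynight.isin(["day", "night"])).all()
        assert df.daynight.value_counts().sum() == len(df)


def test_changepoint_recovery_on_well_separated_days():
    """Well-separated synthetic days: k and every tau recovered within 5."""
    rng = np.random.default_rng(99)
    good = 0
    for _ in range(25):
        plan = synthetic.random_changepoint_day(rng)
        day = synthetic.render_day(plan, rng)
        result = seg.pelt(day.values)
        true = plan.true_changepoints
        det = result.changepoints
        good += len(det) == len(true) and np.max(np.abs(det - true)) <= 5
    assert good >= 23
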