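import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import nestflick as nf
from nestflick.cohort_stats import (bin_rate_classes, build_rate_intensity_table,
                                    chi_square_sign_test, cohort_difference,
                                    class_midpoints, fit_exponential,
                                    rate_class_index, relf_metrics,
                                    spearman_rate_intensity, square_intensity,
                                    square_rate)
from nestflick.flicker_events import FlickerEvent
from nestflick.trigger_map import CohortPartition


def _ev(square, onset, dur=1, amp=5.0):
    return FlickerEvent(square=square, onset_frame=onset, duration_frames=dur,
                        peak_dlum=amp, sum_dlum=amp * dur)


class TestRateAndIntensity:
    def test_no_events_is_zero_rate(self):
        assert square_rate(0, 100.0) == 0.0

    def test_events_per_second(self):
        assert square_rate(27, 200.0) == pytest.approx(0.135)

    def test_events_per_minute_conversion(self):
        assert square_rate(6, 60.0) == pytest.approx(0.1)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            square_rate(5, 0.0)

    def test_intensity_sum_over_tref(self):
        assert square_intensity([3.0, 5.0], 4.0) == pytest.approx(2.0)

    def test_intensity_of_no_events_is_zero(self):
        assert square_intensity([], 10.0) == 0.0

    def test_doubling_tref_halves_intensity(self):
        events = [_ev((0, 0), 5, dur=2, amp=4.0), _ev((0, 0), 100, amp=3.0)]
        assert square_intensity(events, 20.0) == pytest.approx(
            square_intensity(events, 10.0) / 2)


class TestRelF:
    def _partition(self):
        ts = frozenset((0, c) for c in range(30))
        nts = frozenset((r, c) for r in range(1, 10) for c in range(10))
        return CohortPartition(ts_squares=ts, nts_squares=nts)

    def test_no_flicking_squares(self):
        relf = relf_metrics(set(), self._partition(), 100)
        assert (relf.relf_total, relf.relf_ts, relf.relf_nts) == (0, 0, 0)

    def test_field_style_fractions(self):
        part = self._partition()
        active = {(0, c) for c in range(18)} | {(r, 0) for r in range(1, 10)} \
            | {(r, 1) for r in range(1, 10)} | {(1, c) for c in range(2, 6)}
        relf = relf_metrics(active, part, 100)
        assert relf.relf_ts == pytest.approx(0.18)
        assert relf.relf_nts == pytest.approx(0.22)
        assert relf.relf_total == pytest.approx(0.40)

    def test_additivity_is_exact(self, rng):
        part = self._partition()
        pool = sorted(part.ts_squares | part.nts_squares)
        pick = {pool[i] for i in rng.choice(len(pool), size=40, replace=False)}
        relf = relf_metrics(pick, part, 120)
        assert relf.relf_total == relf.relf_ts + relf.relf_nts

    def test_full_occupancy(self):
        part = self._partition()
        relf = relf_metrics(part.ts_squares | part.nts_squares, part, 120)
        assert relf.relf_total == pytest.approx(1.0)

    def test_flicker_outside_partition_rejected(self):
        with pytest.raises(ValueError):
            relf_metrics({(99, 99)}, self._partition(), 100)


class TestRateClasses:
    def test_class_of_field_example_rate(self):
        assert rate_class_index(0.135) == 4

    def test_zero_rate_is_class_zero(self):
        assert rate_class_index(0.0) == 0

    def test_overflow_caps_into_top_class(self):
        assert rate_class_index(5.0) == 29

    def test_binning_mean_sem_and_counts(self):
        records = pd.DataFrame({
            "square_row": [0, 0, 0, 1], "square_col": [0, 1, 2, 0],
            "cohort": ["ts", "ts", "nts", "ts"],
            "n_events": [1, 1, 1, 1],
            "rate_hz": [0.01, 0.02, 0.01, 0.10],
            "intensity_fi": [2.0, 4.0, 5.0, 7.0],
        })
        table = bin_rate_classes(records)
        ts0 = table[(table.class_index == 0) & (table.cohort == "ts")].iloc[0]
        assert ts0.n == 2
        assert ts0.mean_fi == pytest.approx(3.0)
        assert ts0.sem_fi == pytest.approx(np.std([2.0, 4.0], ddof=1) / np.sqrt(2))
        ts3 = table[(table.class_index == 3) & (table.cohort == "ts")].iloc[0]
        assert ts3.n == 1 and ts3.sem_fi == 0.0  # single record: SEM degenerate

    def test_binning_conserves_records(self, rng):
        n = 200
        records = pd.DataFrame({
            "square_row": np.arange(n), "square_col": np.zeros(n, dtype=int),
            "cohort": ["ts" if i % 2 else "nts" for i in range(n)],
            "n_events": np.ones(n, dtype=int),
            "rate_hz": rng.uniform(0.0, 1.2, n),
            "intensity_fi": rng.uniform(0.1, 5.0, n),
        })
        with pytest.warns(UserWarning):
            table = bin_rate_classes(records)
        assert table.n.sum() == (records.rate_hz > 0).sum()
        assert table.class_index.max() == 29

    def test_zero_rate_records_excluded_by_default(self):
        records = pd.DataFrame({
            "square_row": [0, 1], "square_col": [0, 0],
            "cohort": ["ts", "ts"], "n_events": [0, 1],
            "rate_hz": [0.0, 0.05], "intensity_fi": [0.0, 3.0],
        })
        assert bin_rate_classes(records).n.sum() == 1
        assert bin_rate_classes(records, include_zero_rate=True).n.sum() == 2


class TestExponentialFit:
    def test_exact_recovery_of_field_coefficients(self):
        # class midpoints of the first ten 0.03 Hz classes
        x = np.arange(10) * 0.03 + 0.015
        for a, b in [(0.037, 15.457), (0.0325, 14.583), (0.2485, 5.2793),
                     (0.2501, 3.8059)]:
            fit = fit_exponential(x, a * np.exp(b * x))
            assert fit.a == pytest.approx(a, rel=1e-6)
            assert fit.b == pytest.approx(b, rel=1e-6)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_y_gives_flat_curve(self):
        fit = fit_exponential([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])
        assert fit.b == pytest.approx(0.0)
        assert fit.a == pytest.approx(5.0)
        assert fit.r_squared == 1.0

    def test_nonpositive_points_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            fit = fit_exponential([0.0, 1.0, 2.0], [1.0, 0.0, np.e ** 2])
        assert fit.n_dropped == 1
        assert fit.b == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                fit_exponential([0.0, 1.0], [1.0, -1.0])

    def test_parameter_recovery_under_lognormal_noise(self, rng):
        """Simulation oracle: log-linear OLS is unbiased on the log scale."""
        a, b, n = 0.05, 10.0, 40
        x = np.linspace(0.015, 0.6, n)
        estimates = []
        for _ in range(50):
            y = a * np.exp(b * x) * rng.lognormal(0.0, 0.2, n)
            fit = fit_exponential(x, y)
            estimates.append((fit.a, fit.b))
        a_hat = np.exp(np.mean(np.log([e[0] for e in estimates])))
        b_hat = np.mean([e[1] for e in estimates])
        assert a_hat == pytest.approx(a, rel=0.05)
        assert b_hat == pytest.approx(b, rel=0.05)


class TestSpearman:
    def test_monotone_pairs(self):
        rho, _ = spearman_rate_intensity([1, 2, 3, 4], [2, 4, 9, 11])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rate_intensity([1, 2, 3, 4], [11, 9, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 1, 12)
            y = rng.uniform(0, 1, 12)
            rho, _ = spearman_rate_intensity(x, y)
            # oracle: Pearson correlation of mid-ranks
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            expect = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(expect)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rate_intensity([1, 1, 1], [2, 3, 4])


class TestChiSquare:
    def test_balanced_counts(self):
        chi2, p = chi_square_sign_test(15, 15)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_example(self):
        chi2, p = chi_square_sign_test(25, 5)
        assert chi2 == pytest.approx((25 - 5) ** 2 / 30)
        assert p < 0.001

    def test_single_observation(self):
        chi2, p = chi_square_sign_test(1, 0)
        assert chi2 == 1.0
        assert p == pytest.approx(0.3173, abs=1e-4)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_sign_test(0, 0)


class TestCohortDifference:
    def _table(self, ts_means, nts_means):
        rows = []
        for k, m in enumerate(ts_means):
            rows.append({"class_index": k, "cohort": "ts", "class_low_hz": 0.03 * k,
                         "class_high_hz": 0.03 * (k + 1), "n": 5, "mean_fi": m,
                         "sem_fi": 0.1})
        for k, m in enumerate(nts_means):
            rows.append({"class_index": k, "cohort": "nts", "class_low_hz": 0.03 * k,
                         "class_high_hz": 0.03 * (k + 1), "n": 5, "mean_fi": m,
                         "sem_fi": 0.1})
        return pd.DataFrame(rows)

    def test_identical_cohorts_yield_no_signs(self):
        t = self._table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        comp = cohort_difference(t)
        assert comp.n_positive == comp.n_negative == 0

    def test_uniformly_higher_ts(self):
        t = self._table([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        comp = cohort_difference(t)
        assert comp.n_positive == 3 and comp.n_negative == 0
        assert comp.chi2 == pytest.approx(3.0)

    def test_classes_missing_a_cohort_are_excluded(self):
        t = self._table([2.0, 3.0, 4.0], [1.0])
        comp = cohort_difference(t)
        assert len(comp.deltas) == 1

    def test_designed_contrast_on_synthetic_cohorts(self):
        """Generator scene with ts amplitude 8 vs nts 5: positive majority."""
        cfg, registry = nf.cohort_contrast_scene(seed=77)
        gt = nf.sample_scene(cfg)
        events = nf.events_from_truth(gt)
        pooled = nf.pool_trigger_activity(registry, (cfg.grid_rows, cfg.grid_cols))
        active = {(r, c) for r in range(cfg.grid_rows) for c in range(cfg.grid_cols)}
        part = nf.partition_cohorts(pooled, active)
        records = build_rate_intensity_table(events, part, cfg.duration_s)
        comp = cohort_difference(bin_rate_classes(records))
        assert comp.n_positive > comp.n_negative
        assert comp.p_value < 0.05


class TestRecordsTable:
    def test_records_include_quiet_squares(self):
        part = CohortPartition(ts_squares=frozenset({(0, 0)}),
                               nts_squares=frozenset({(1, 1), (2, 2)}))
        events = [_ev((0, 0), 10), _ev((0, 0), 100), _ev((1, 1), 40)]
        records = build_rate_intensity_table(events, part, t_ref=10.0)
        assert len(records) == 3
        quiet = records[(records.square_row == 2) & (records.square_col == 2)].iloc[0]
        assert quiet.rate_hz == 0.0 and quiet.intensity_fi == 0.0
        busy = records[(records.square_row == 0)].iloc[0]
        assert busy.rate_hz == pytest.approx(0.2)
        assert busy.intensity_fi == pytest.approx(1.0)

    def test_masked_square_events_are_ignored(self):
        part = CohortPartition(ts_squares=frozenset({(0, 0)}),
                               nts_squares=frozenset())
        records = build_rate_intensity_table([_ev((5, 5), 10)], part, t_ref=10.0)
        assert records.n_events.sum() == 0
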