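"""The resection-rate estimator: normalization, crossings, regression."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dsbquant import (
    AmpliconPanel,
    ResectionSimConfig,
    estimate_rate,
    fit_resection_rate,
    get_preset,
    normalize_qpcr,
    simulate_resection_qpcr,
    threshold_crossings,
)

TWO_AMP_PANEL = AmpliconPanel.from_entries(
    [("near", 2.0, False), ("far", 4.0, False), ("ctrl", 0.0, True)]
)


def _table(rows):
    return pd.DataFrame(rows, columns=["condition", "replicate", "time_h", "amplicon", "value"])


class TestNormalize:
    def test_signal_is_unity_at_t0_by_construction(self, panel, hourly):
        tab = simulate_resection_qpcr(get_preset("wt_untreated", seed=2), panel, hourly)
        mat = normalize_qpcr(tab.rename(columns={"quantity": "value"}), panel)
        assert np.allclose(mat.mean.loc[0.0], 1.0)

    def test_double_ratio_arithmetic(self):
        tab = _table(
            [
                ("c", 1, 0.0, "near", 80.0),
                ("c", 1, 0.0, "far", 10.0),
                ("c", 1, 0.0, "ctrl", 80.0),
                ("c", 1, 1.0, "near", 50.0),
                ("c", 1, 1.0, "far", 10.0),
                ("c", 1, 1.0, "ctrl", 100.0),
            ]
        )
        mat = normalize_qpcr(tab, TWO_AMP_PANEL)
        # (50/100) / (80/80) = 0.5
        assert mat.mean.loc[1.0, 2.0] == pytest.approx(0.5)

    def test_cq_encoding_one_doubling_halves_signal(self):
        # ddCq = +1 relative to control and t0  ->  s = 0.5
        tab = _table(
            [
                ("c", 1, 0.0, "near", 20.0),
                ("c", 1, 0.0, "far", 20.0),
                ("c", 1, 0.0, "ctrl", 18.0),
                ("c", 1, 1.0, "near", 21.0),
                ("c", 1, 1.0, "far", 20.0),
                ("c", 1, 1.0, "ctrl", 18.0),
            ]
        )
        mat = normalize_qpcr(tab, TWO_AMP_PANEL, encoding="cq")
        assert mat.mean.loc[1.0, 2.0] == pytest.approx(0.5)
        assert mat.mean.loc[1.0, 4.0] == pytest.approx(1.0)

    def test_plate_scale_effect_cancels(self, panel, hourly):
        tab = simulate_resection_qpcr(get_preset("wt_untreated", seed=3), panel, hourly)
        tab = tab.rename(columns={"quantity": "value"})
        scaled = tab.copy()
        scaled.loc[scaled.time_h == 2.0, "value"] *= 13.7  # plate effect at one timepoint
        a = normalize_qpcr(tab, panel)
        b = normalize_qpcr(scaled, panel)
        pd.testing.assert_frame_equal(a.mean, b.mean)

    def test_missing_control_block_is_named_in_error(self):
        tab = _table(
            [
                ("c", 1, 0.0, "near", 1.0),
                ("c", 1, 0.0, "far", 1.0),
                ("c", 1, 0.0, "ctrl", 1.0),
                ("c", 1, 1.0, "near", 1.0),
                ("c", 1, 1.0, "far", 1.0),
            ]
        )
        with pytest.raises(ValueError, match="t=1.*control"):
            normalize_qpcr(tab, TWO_AMP_PANEL)

    def test_missing_t0_rejected(self):
        tab = _table(
            [
                ("c", 1, 1.0, "near", 1.0),
                ("c", 1, 1.0, "far", 1.0),
                ("c", 1, 1.0, "ctrl", 1.0),
            ]
        )
        with pytest.raises(ValueError, match="t=0"):
            normalize_qpcr(tab, TWO_AMP_PANEL)

    def test_nonpositive_quantity_rejected(self):
        tab = _table(
            [
                ("c", 1, 0.0, "near", 0.0),
                ("c", 1, 0.0, "far", 1.0),
                ("c", 1, 0.0, "ctrl", 1.0),
            ]
        )
        with pytest.raises(ValueError, match="non-positive"):
            normalize_qpcr(tab, TWO_AMP_PANEL)


class TestThresholdCrossings:
    def test_linear_interpolation_between_nearest_amplicons(self):
        mat = pd.DataFrame({2.0: [1.0, 0.9], 4.0: [1.0, 0.6]}, index=[0.0, 1.0])
        cs = threshold_crossings(mat, threshold=0.75)
        point = cs.points.set_index("time_h").loc[1.0, "distance_kb"]
        assert point == pytest.approx(2.0 + (0.9 - 0.75) / (0.9 - 0.6) * 2.0)  # 3.0 kb

    def test_unbracketed_timepoints_are_dropped_and_logged(self):
        mat = pd.DataFrame({2.0: [1.0, 0.9], 4.0: [1.0, 0.95]}, index=[0.0, 1.0])
        with pytest.raises(ValueError, match="no crossings"):
            threshold_crossings(mat, threshold=0.75)
        mat.loc[2.0] = [0.3, 0.8]  # this timepoint brackets (rising away from break)
        cs = threshold_crossings(mat, threshold=0.75)
        assert len(cs) == 1
        assert len(cs.dropped) == 2

    def test_step_front_interpolates_within_the_step_cell(self):
        # noise-free population step: 1 before the front, 0.05 after it
        mat = pd.DataFrame({5.0: [1.0, 1.0], 10.0: [1.0, 0.05]}, index=[0.0, 1.0])
        cs = threshold_crossings(mat, threshold=0.75)
        d = cs.points["distance_kb"].iloc[0]
        assert d == pytest.approx(5.0 + (0.25 / 0.95) * 5.0)

    def test_rising_curve_orientation_detected(self):
        # simulator-style curve: resected (low) near the break, intact far out
        mat = pd.DataFrame(
            {2.0: [1.0, 0.1], 8.0: [1.0, 0.5], 14.0: [1.0, 0.9]}, index=[0.0, 2.0]
        )
        cs = threshold_crossings(mat, threshold=0.75)
        d = cs.points["distance_kb"].iloc[0]
        assert d == pytest.approx(8.0 + (0.75 - 0.5) / (0.9 - 0.5) * 6.0)

    def test_time_at_distance_orientation(self):
        mat = pd.DataFrame({2.0: [1.0, 0.5], 4.0: [1.0, 0.9]}, index=[0.0, 2.0])
        cs = threshold_crossings(mat, threshold=0.75, orientation="time_at_distance")
        t_at_2kb = cs.points.set_index("distance_kb").loc[2.0, "time_h"]
        assert t_at_2kb == pytest.approx(1.0)  # halfway from 1.0 down to 0.5

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_outside_open_unit_interval_rejected(self, bad):
        mat = pd.DataFrame({2.0: [1.0], 4.0: [1.0]}, index=[0.0])
        with pytest.raises(ValueError):
            threshold_crossings(mat, threshold=bad)


class TestRateFit:
    def test_exact_collinear_points(self):
        pts = pd.DataFrame({"time_h": [1.0, 2.0, 3.0], "distance_kb": [4.2, 8.4, 12.6]})
        est = fit_resection_rate(pts)
        assert est.rate_kb_h == pytest.approx(4.2)
        assert est.intercept_h == pytest.approx(0.0, abs=1e-12)
        assert est.r_squared == pytest.approx(1.0)

    def test_two_point_line(self):
        pts = pd.DataFrame({"time_h": [1.0, 2.0], "distance_kb": [3.0, 5.0]})
        est = fit_resection_rate(pts)
        assert est.rate_kb_h == pytest.approx(2.0)
        assert est.intercept_h == pytest.approx(-0.5)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            fit_resection_rate(pd.DataFrame({"time_h": [1.0], "distance_kb": [3.0]}))

    def test_identical_times_rejected(self):
        pts = pd.DataFrame({"time_h": [1.0, 1.0], "distance_kb": [3.0, 5.0]})
        with pytest.raises(ValueError, match="identical"):
            fit_resection_rate(pts)


class TestEndToEnd:
    @pytest.mark.parametrize(
        "name,speed",
        [
            ("wt_untreated", 4.2),
            ("caffeine_50mM", 2.4),
            ("caffeine_10_20mM", 2.7),
            ("mec1_tel1", 5.8),
            ("mec1_tel1_caffeine_50mM", 2.7),
        ],
    )
    def test_recovers_preset_speed_within_ten_percent(self, panel, hourly, name, speed):
        tab = simulate_resection_qpcr(get_preset(name, seed=1), panel, hourly)
        est = estimate_rate(tab, panel)
        assert est.rate_kb_h == pytest.approx(speed, rel=0.10)

    def test_replicate_fits_and_range(self, panel, hourly):
        tab = simulate_resection_qpcr(
            get_preset("wt_untreated", seed=5), panel, hourly, n_replicates=3
        )
        est = estimate_rate(tab, panel)
        assert len(est.replicate_rates) == 3
        lo, hi = est.rate_range
        assert lo <= hi
        assert lo == pytest.approx(min(est.replicate_rates.values()))

    def test_no_post_induction_timepoints_is_an_error(self, panel):
        cfg = replace(get_preset("wt_untreated", seed=1), noise_sigma=0.0)
        tab = simulate_resection_qpcr(cfg, panel, [0.0, 0.05])
        # no curve ever brackets 0.75 this early
        with pytest.raises(ValueError, match="crossing"):
            estimate_rate(tab, panel)


class TestEstimatorProperties:
    def test_exactness_bound_in_deterministic_limit(self):
        # noise-free, cv=0, instantaneous cutting, uniform amplicon spacing delta:
        # |fitted slope - v| <= delta / (t_last - t_first)
        v, delta = 4.2, 2.0
        panel = AmpliconPanel.from_entries(
            [(f"a{d}", float(d), False) for d in np.arange(2.0, 32.0, delta)]
            + [("ctrl", 0.0, True)]
        )
        cfg = ResectionSimConfig(
            cut_rate=math.inf, cut_fraction=0.95, speed_mean_kb_h=v,
            speed_cv=0.0, noise_sigma=0.0, n_cells=2000, seed=0,
        )
        times = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        est = estimate_rate(simulate_resection_qpcr(cfg, panel, times), panel)
        assert abs(est.rate_kb_h - v) <= delta / (6.0 - 1.0)

    def test_scale_equivariance_of_fit(self):
        pts = pd.DataFrame({"time_h": [1.0, 2.0, 3.0], "distance_kb": [3.1, 7.9, 11.6]})
        base = fit_resection_rate(pts).rate_kb_h
        scaled = pts.assign(distance_kb=pts.distance_kb * 3.0)
        assert fit_resection_rate(scaled).rate_kb_h == pytest.approx(3.0 * base)
        shifted = pts.assign(time_h=pts.time_h + 2.5)
        assert fit_resection_rate(shifted).rate_kb_h == pytest.approx(base)

    @pytest.mark.parametrize("cv", [0.1, 0.3])
    def test_slope_converges_to_speed_quantile(self, cv):
        # with per-cell speed dispersion the estimator tracks the q-quantile
        # of the speed distribution, q = 1 - (1-threshold)/cut_fraction
        v, p_cut, theta = 4.2, 0.95, 0.75
        q = 1.0 - (1.0 - theta) / p_cut
        shape = 1.0 / cv**2
        v_q = float(stats.gamma.ppf(q, shape, scale=v / shape))
        panel = AmpliconPanel.from_entries(
            [(f"a{i}", d, False) for i, d in enumerate(np.arange(0.5, 40.0, 0.5))]
            + [("ctrl", 0.0, True)]
        )
        cfg = ResectionSimConfig(
            cut_rate=math.inf, cut_fraction=p_cut, speed_mean_kb_h=v, speed_cv=cv,
            noise_sigma=0.0, n_cells=200_000, seed=1,
        )
        est = estimate_rate(
            simulate_resection_qpcr(cfg, panel, [0.0, 1.0, 2.0, 3.0, 4.0]),
            panel,
            threshold=theta,
        )
        assert est.rate_kb_h == pytest.approx(v_q, rel=0.05)

    def test_median_of_seeded_runs_recovers_preset_speed(self, panel, hourly):
        rates = [
            estimate_rate(
                simulate_resection_qpcr(get_preset("caffeine_50mM", seed=s), panel, hourly),
                panel,
            ).rate_kb_h
            for s in range(1, 26)
        ]
        assert np.median(rates) == pytest.approx(2.4, rel=0.05)
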