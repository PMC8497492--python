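"""Tests of normalization, difference curves, Df, and plate processing."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from hrmclock.melt import (
    DEFAULT_WINDOWS,
    DifferenceCurve,
    MeltCurve,
    NormalizationWindows,
    df_value,
    difference_curve,
    normalize_curve,
    process_plate,
)
from hrmclock.simulate import default_cat_cohort, simulate_cohort, simulate_melt_curve

from conftest import series_df_values


def _curve(t, f, **kwargs):
    defaults = dict(sample_id="s", marker_id="ELOVL2", replicate_index=0, well_id="W0")
    defaults.update(kwargs)
    return MeltCurve(temperatures=np.asarray(t, float), fluorescence=np.asarray(f, float), **defaults)


class TestNormalization:
    def test_noiseless_curve_normalizes_to_100_and_0_in_windows(
        self, elovl2_spec_noiseless, elovl2_windows
    ):
        curve = simulate_melt_curve(elovl2_spec_noiseless, 40.0)
        norm = normalize_curve(curve, elovl2_windows)
        t = norm.temperatures
        pre = norm.fluorescence[elovl2_windows.pre_mask(t)]
        post = norm.fluorescence[elovl2_windows.post_mask(t)]
        assert pre.mean() == pytest.approx(100.0, abs=1e-6)
        assert post.mean() == pytest.approx(0.0, abs=1e-6)

    def test_idempotence_exact_when_windows_are_linear(self, elovl2_windows):
        """Re-normalizing changes nothing once window contents sit on lines.

        The rescaling is a ratio of fitted lines, so exact idempotence holds
        when the raw signal is linear inside both windows (the design case);
        transition tails or noise inside a window perturb it only slightly.
        """
        t = np.arange(65.0, 95.0, 0.25)
        pre = 120.0 - 0.4 * t
        post = 8.0 - 0.05 * t
        ramp = np.clip((80.0 - t) / (80.0 - 72.0), 0.0, 1.0)  # linear melt 72->80
        norm = normalize_curve(_curve(t, post + (pre - post) * ramp), elovl2_windows)
        twice = normalize_curve(norm, elovl2_windows)
        np.testing.assert_allclose(twice.fluorescence, norm.fluorescence, atol=1e-9)

    def test_idempotence_near_exact_on_simulated_curves(
        self, elovl2_spec_noiseless, elovl2_windows
    ):
        spec = replace(elovl2_spec_noiseless, noise_sd=0.1)
        norm = normalize_curve(simulate_melt_curve(spec, 55.0), elovl2_windows)
        twice = normalize_curve(norm, elovl2_windows)
        np.testing.assert_allclose(twice.fluorescence, norm.fluorescence, atol=0.05)

    def test_affine_distortion_normalizes_to_same_curve(
        self, elovl2_spec_noiseless, elovl2_windows
    ):
        """alpha*F + beta and an added linear baseline all normalize identically."""
        curve = simulate_melt_curve(elovl2_spec_noiseless, 30.0)
        norm = normalize_curve(curve, elovl2_windows)
        distorted = replace(
            curve, fluorescence=3.7 * curve.fluorescence + 42.0 - 0.8 * (curve.temperatures - 65.0)
        )
        norm_d = normalize_curve(distorted, elovl2_windows)
        np.testing.assert_allclose(norm_d.fluorescence, norm.fluorescence, atol=1e-8)

    def test_pre_window_line_segment_maps_to_100(self, elovl2_windows):
        """Points lying exactly on the fitted pre-melt line normalize to 100."""
        t = np.arange(65.0, 95.0, 0.25)
        f = np.where(t < 75, 200.0 - 0.5 * t, 10.0 - 0.05 * t)
        norm = normalize_curve(_curve(t, f), elovl2_windows)
        np.testing.assert_allclose(
            norm.fluorescence[elovl2_windows.pre_mask(t)], 100.0, atol=1e-9
        )

    def test_window_with_too_few_points_rejected(self):
        t = np.arange(65.0, 95.0, 1.0)
        win = NormalizationWindows(66.0, 66.5, 84.0, 85.0)  # pre window has 1 grid point
        with pytest.raises(ValueError, match=">= 2 grid points"):
            normalize_curve(_curve(t, np.linspace(100, 0, t.size)), win)

    def test_degenerate_signal_rejected(self, elovl2_windows):
        t = np.arange(65.0, 95.0, 0.25)
        norm_input = np.full(t.size, 5.0)  # flat: pre line == post line
        with pytest.raises(ValueError, match="degenerate signal"):
            normalize_curve(_curve(t, norm_input), elovl2_windows)

    def test_window_ordering_enforced(self):
        with pytest.raises(ValueError, match="pre_lo < pre_hi"):
            NormalizationWindows(68.0, 66.0, 84.5, 85.0)


class TestDifferenceAndDf:
    def test_self_difference_is_zero(self, elovl2_spec_noiseless, elovl2_windows):
        norm = normalize_curve(simulate_melt_curve(elovl2_spec_noiseless, 0.0), elovl2_windows)
        for mode in ("derivative", "fluorescence"):
            d = difference_curve(norm, norm, mode=mode)
            assert np.allclose(d.values, 0.0, atol=1e-12)
            assert df_value(d).df_value == 0.0

    def test_100_vs_0_peak_lies_between_the_two_tm(
        self, elovl2_spec_noiseless, elovl2_windows
    ):
        base = normalize_curve(simulate_melt_curve(elovl2_spec_noiseless, 0.0), elovl2_windows)
        top = normalize_curve(simulate_melt_curve(elovl2_spec_noiseless, 100.0), elovl2_windows)
        res = df_value(
            difference_curve(top, base, mode="fluorescence"),
            restrict_to=(elovl2_windows.pre_hi, elovl2_windows.post_lo),
        )
        assert 76.0 < res.peak_temperature < 80.0

    def test_modes_rank_standard_series_identically(self, noiseless_series, elovl2_windows):
        by_mode = {
            mode: series_df_values(noiseless_series, elovl2_windows, mode=mode)
            for mode in ("derivative", "fluorescence")
        }
        for mode, values in by_mode.items():
            order = [lvl for lvl, _ in sorted(values, key=lambda p: p[1])]
            assert order == sorted(lvl for lvl, _ in values), mode

    def test_grid_resampling_and_overlap_check(self, elovl2_spec_noiseless, elovl2_windows):
        base = normalize_curve(simulate_melt_curve(elovl2_spec_noiseless, 0.0), elovl2_windows)
        fine = replace(elovl2_spec_noiseless, temp_grid=np.arange(64.0, 96.0, 0.1))
        sample = normalize_curve(simulate_melt_curve(fine, 50.0), elovl2_windows)
        d = difference_curve(sample, base, mode="fluorescence")
        assert d.temperatures.shape == base.temperatures.shape
        keep = (base.temperatures >= 70.0) & (base.temperatures <= 80.0)
        clipped = replace(
            base,
            temperatures=base.temperatures[keep],
            fluorescence=base.fluorescence[keep],
        )
        with pytest.raises(ValueError, match="does not cover"):
            difference_curve(clipped, base)

    def test_unnormalized_inputs_rejected(self, elovl2_spec_noiseless):
        raw = simulate_melt_curve(elovl2_spec_noiseless, 10.0)
        with pytest.raises(ValueError, match="normalized"):
            difference_curve(raw, raw)

    def test_df_is_max_absolute_value(self):
        t = np.linspace(70, 80, 11)
        d = np.zeros(11)
        d[4] = -0.7
        d[7] = 0.5
        res = df_value(DifferenceCurve(temperatures=t, values=d, mode="fluorescence"))
        assert res.df_value == pytest.approx(0.7)
        assert res.peak_temperature == pytest.approx(t[4])

    def test_df_tie_breaks_to_lower_temperature(self):
        t = np.linspace(70, 80, 11)
        d = np.zeros(11)
        d[3] = 0.4
        d[8] = -0.4
        res = df_value(DifferenceCurve(temperatures=t, values=d, mode="fluorescence"))
        assert res.peak_temperature == pytest.approx(t[3])

    def test_empty_restriction_interval_rejected(self):
        t = np.linspace(70, 80, 11)
        d = DifferenceCurve(temperatures=t, values=np.ones(11), mode="fluorescence")
        with pytest.raises(ValueError, match="no grid points"):
            df_value(d, restrict_to=(85.0, 86.0))


class TestProcessPlate:
    def test_df_strictly_increasing_on_noiseless_standards(
        self, noiseless_series, elovl2_windows
    ):
        values = series_df_values(noiseless_series, elovl2_windows)
        levels, dfs = zip(*values)
        assert dfs[0] == 0.0  # 0% standard against itself
        assert all(b > a for a, b in zip(dfs, dfs[1:]))

    def test_df_invariant_under_affine_distortion_of_raw_curves(self, small_melt_cohort):
        curves = small_melt_cohort.curves
        sheet = small_melt_cohort.sample_sheet
        df1, std1 = process_plate(curves, sheet, DEFAULT_WINDOWS)
        distorted = [
            replace(c, fluorescence=2.5 * c.fluorescence + 17.0) for c in curves
        ]
        df2, std2 = process_plate(distorted, sheet, DEFAULT_WINDOWS)
        np.testing.assert_allclose(df1["df_value"], df2["df_value"], atol=1e-8)
        np.testing.assert_allclose(std1["df_value"], std2["df_value"], atol=1e-8)

    def test_counts_and_replicate_bookkeeping(self, small_melt_cohort):
        df_table, standards = process_plate(
            small_melt_cohort.curves, small_melt_cohort.sample_sheet, DEFAULT_WINDOWS
        )
        assert len(df_table) == 16 * 2 * 2  # samples x markers x replicates
        assert len(standards) == 2 * 9 * 2  # markers x levels x replicates
        reps = df_table.groupby(["sample_id", "marker_id"])["replicate_index"].apply(sorted)
        assert all(r == [0, 1] for r in reps)
        assert df_table["peak_temperature"].between(68.0, 84.5).all()

    def test_standards_only_plate_yields_empty_sample_table(self, elovl2_spec_noiseless):
        from hrmclock.simulate import simulate_standard_series

        series = simulate_standard_series(elovl2_spec_noiseless, marker_id="ELOVL2")
        curves = [c for _, c in series]
        sheet = pd.DataFrame(
            {
                "sample_id": [c.sample_id for c in curves],
                "marker": "ELOVL2",
                "well": [c.well_id for c in curves],
                "replicate": [c.replicate_index for c in curves],
                "standard_level": [lvl for lvl, _ in series],
                "plate_id": "plate1",
            }
        )
        df_table, standards = process_plate(curves, sheet, DEFAULT_WINDOWS)
        assert df_table.empty
        assert len(standards) == 9

    def test_missing_anchor_standard_rejected(self, small_melt_cohort):
        sheet = small_melt_cohort.sample_sheet
        pruned = sheet[~((sheet["standard_level"] == 100.0) & (sheet["marker"] == "ELOVL2"))]
        kept_wells = set(pruned["well"])
        curves = [c for c in small_melt_cohort.curves if c.well_id in kept_wells]
        with pytest.raises(ValueError, match="0% or 100% standard"):
            process_plate(curves, pruned, DEFAULT_WINDOWS)

    def test_orphan_wells_rejected(self, small_melt_cohort):
        sheet = small_melt_cohort.sample_sheet.iloc[:-1]
        with pytest.raises(ValueError, match="without a sample-sheet row"):
            process_plate(small_melt_cohort.curves, sheet, DEFAULT_WINDOWS)

    def test_missing_windows_for_marker_rejected(self, small_melt_cohort):
        with pytest.raises(ValueError, match="no normalization windows"):
            process_plate(
                small_melt_cohort.curves,
                small_melt_cohort.sample_sheet,
                {"ELOVL2": DEFAULT_WINDOWS["ELOVL2"]},
            )
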