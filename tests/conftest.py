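from dataclasses import replace

import numpy as np
import pytest

from hrmclock.melt import DEFAULT_WINDOWS, df_value, difference_curve, normalize_curve
from hrmclock.simulate import (
    MARKER_MELT_SPECS,
    default_cat_cohort,
    simulate_cohort,
    simulate_standard_series,
)


@pytest.fixture(scope="session")
def elovl2_spec_noiseless():
    return replace(MARKER_MELT_SPECS["ELOVL2"], noise_sd=0.0)


@pytest.fixture(scope="session")
def elovl2_windows():
    return DEFAULT_WINDOWS["ELOVL2"]


@pytest.fixture(scope="session")
def noiseless_series(elovl2_spec_noiseless):
    """Noiseless 9-level standard series of the ELOVL2-like marker."""
    return simulate_standard_series(elovl2_spec_noiseless, marker_id="ELOVL2")


def series_df_values(series, windows, mode="derivative", smooth_window=5):
    """Run the normalize -> difference -> Df chain over a (level, curve) series."""
    baseline = normalize_curve(next(c for lvl, c in series if lvl == 0.0), windows)
    out = []
    for level, curve in series:
        diff = difference_curve(
            normalize_curve(curve, windows), baseline, mode=mode, smooth_window=smooth_window
        )
        res = df_value(diff, restrict_to=(windows.pre_hi, windows.post_lo))
        out.append((level, res.df_value))
    return out


@pytest.fixture(scope="session")
def cat_truth_cohort():
    """Default cat-like cohort, ground truth only (no melt simulation)."""
    return simulate_cohort(default_cat_cohort(seed=0), include_melt=False)


@pytest.fixture(scope="session")
def small_melt_cohort():
    """A small cohort with full melt simulation for pipeline-level tests."""
    return simulate_cohort(default_cat_cohort(seed=42, n=16))


def truth_features(cohort):
    """(wide methylation, metadata) aligned tables from a cohort's truth."""
    wide = cohort.truth.pivot(index="sample_id", columns="marker", values="true_methylation")
    meta = cohort.truth.drop_duplicates("sample_id").set_index("sample_id")
    return wide, meta.loc[wide.index]
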