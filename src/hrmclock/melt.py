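"""Melt-curve normalization, difference curves, and the Df statistic.

Raw HRM fluorescence traces are normalised between two user-chosen
temperature windows flanking the major fluorescence drop: a straight line is
least-squares-fitted to the points in each window and the signal is rescaled
so the pre-melt line maps to 100 and the post-melt line to 0.  Difference
curves are then formed against the plate's 0%-methylated standard — either
on the negative first derivative of the normalised signal (default) or on
the normalised fluorescence itself — and the Df value of a well is the
maximum absolute difference inside the inter-window interval.  Df grows
monotonically with the methylated fraction of the template mixture, which
is what the calibration layer exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "MeltCurve",
    "NormalizationWindows",
    "DfResult",
    "DifferenceCurve",
    "normalize_curve",
    "difference_curve",
    "df_value",
    "process_plate",
    "DEFAULT_WINDOWS",
]


@dataclass
class MeltCurve:
    """One well's melt trace with its sample/marker/replicate identity."""

    sample_id: str | None
    marker_id: str | None
    replicate_index: int
    well_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray
    plate_id: str = "plate1"
    normalized: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.size != f.size:
            raise ValueError("temperature and fluorescence vectors differ in length")
        if t.size < 10:
            raise ValueError(f"melt curve needs >= 10 points, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        self.temperatures = t
        self.fluorescence = f


@dataclass(frozen=True)
class NormalizationWindows:
    """Pre-/post-melt line-fit windows (deg C): pre_lo < pre_hi < post_lo < post_hi."""

    pre_lo: float
    pre_hi: float
    post_lo: float
    post_hi: float

    def __post_init__(self) -> None:
        if not (self.pre_lo < self.pre_hi < self.post_lo < self.post_hi):
            raise ValueError(
                "windows must satisfy pre_lo < pre_hi < post_lo < post_hi, got "
                f"({self.pre_lo}, {self.pre_hi}, {self.post_lo}, {self.post_hi})"
            )

    def pre_mask(self, temperatures: np.ndarray) -> np.ndarray:
        return (temperatures >= self.pre_lo) & (temperatures <= self.pre_hi)

    def post_mask(self, temperatures: np.ndarray) -> np.ndarray:
        return (temperatures >= self.post_lo) & (temperatures <= self.post_hi)


#: Normalization windows of the two study markers (deg C).
DEFAULT_WINDOWS: dict[str, NormalizationWindows] = {
    "ELOVL2": NormalizationWindows(66.0, 68.0, 84.5, 85.0),
    "RALYL": NormalizationWindows(67.0, 68.0, 82.0, 83.0),
}


@dataclass(frozen=True)
class DfResult:
    """Peak |difference| of one well against the 0% baseline."""

    df_value: float
    peak_temperature: float
    sample_id: str | None
    marker_id: str | None
    replicate_index: int
    well_id: str = ""
    plate_id: str = "plate1"
    mode: str = "derivative"


@dataclass
class DifferenceCurve:
    """Sample-minus-baseline signal on the baseline's temperature grid."""

    temperatures: np.ndarray
    values: np.ndarray
    mode: str
    sample_id: str | None = None
    marker_id: str | None = None
    replicate_index: int = 0
    well_id: str = ""
    plate_id: str = "plate1"


def _fit_line(t: np.ndarray, f: np.ndarray) -> np.ndarray:
    # degree-1 least squares; returns [slope, intercept]
    return np.polyfit(t, f, 1)


def normalize_curve(curve: MeltCurve, windows: NormalizationWindows) -> MeltCurve:
    """Two-window normalization onto the 0-100 relative-signal scale.

    Lines are fitted to the pre- and post-melt windows and the signal at each
    temperature T becomes ``100 * (F(T) - post(T)) / (pre(T) - post(T))``, so
    the pre-window averages 100 and the post-window 0 up to line-fit
    residuals.  The result is invariant to affine distortions of the raw
    signal, which is the contract downstream Df values rely on.
    """
    t, f = curve.temperatures, curve.fluorescence
    pre_mask, post_mask = windows.pre_mask(t), windows.post_mask(t)
    if pre_mask.sum() < 2 or post_mask.sum() < 2:
        raise ValueError(
            f"each normalization window needs >= 2 grid points "
            f"(pre: {int(pre_mask.sum())}, post: {int(post_mask.sum())})"
        )
    pre_line = np.polyval(_fit_line(t[pre_mask], f[pre_mask]), t)
    post_line = np.polyval(_fit_line(t[post_mask], f[post_mask]), t)
    inside = (t >= windows.pre_lo) & (t <= windows.post_hi)
    denom = pre_line - post_line
    if np.any(denom[inside] <= 0):
        raise ValueError(
            f"degenerate signal in well {curve.well_id}: pre-melt line does not "
            "exceed the post-melt line across the analysis interval"
        )
    norm = 100.0 * (f - post_line) / denom
    return replace(curve, fluorescence=norm, normalized=True)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Odd-window moving average with edge reflection; window<=1 is identity."""
    if window <= 1:
        return values
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    half = window // 2
    padded = np.concatenate([values[half:0:-1], values, values[-2:-2 - half:-1]])
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def _neg_derivative(t: np.ndarray, f: np.ndarray, smooth_window: int) -> np.ndarray:
    return -np.gradient(_smooth(f, smooth_window), t)


def difference_curve(
    sample: MeltCurve,
    baseline: MeltCurve,
    *,
    mode: str = "derivative",
    smooth_window: int = 5,
) -> DifferenceCurve:
    """Difference of the sample against the 0% standard on the baseline grid.

    ``mode="derivative"`` (default) subtracts the melt-rate curves -dF/dT;
    ``mode="fluorescence"`` subtracts the normalised signals directly.  Both
    rank a standard series identically; the choice is recorded in the output.
    If the grids differ the sample is linearly interpolated onto the
    baseline's grid (grids must overlap the baseline's range).
    """
    if mode not in ("derivative", "fluorescence"):
        raise ValueError(f"unknown difference mode {mode!r}")
    if not (sample.normalized and baseline.normalized):
        raise ValueError("difference curves require normalized inputs")
    t = baseline.temperatures
    if np.array_equal(sample.temperatures, t):
        fs = sample.fluorescence
    else:
        if sample.temperatures[0] > t[0] + 1e-9 or sample.temperatures[-1] < t[-1] - 1e-9:
            raise ValueError("sample grid does not cover the baseline grid")
        fs = np.interp(t, sample.temperatures, sample.fluorescence)
    if mode == "derivative":
        d = _neg_derivative(t, fs, smooth_window) - _neg_derivative(
            t, baseline.fluorescence, smooth_window
        )
    else:
        d = fs - baseline.fluorescence
    return DifferenceCurve(
        temperatures=t,
        values=d,
        mode=mode,
        sample_id=sample.sample_id,
        marker_id=sample.marker_id,
        replicate_index=sample.replicate_index,
        well_id=sample.well_id,
        plate_id=sample.plate_id,
    )


def df_value(
    difference: DifferenceCurve,
    restrict_to: tuple[float, float] | None = None,
) -> DfResult:
    """Maximum |difference| (the Df value) and its temperature.

    ``restrict_to`` limits the search to an open-ended (lo, hi) interval —
    normally the gap between the normalization windows, which keeps edge
    artifacts of the line fits out of the statistic.  Argmax ties break
    toward the lower temperature.
    """
    t, d = difference.temperatures, difference.values
    if t.size < 3:
        raise ValueError("difference curve needs >= 3 points")
    if restrict_to is not None:
        lo, hi = restrict_to
        mask = (t > lo) & (t < hi)
        if not mask.any():
            raise ValueError(f"restriction interval ({lo}, {hi}) contains no grid points")
        t, d = t[mask], d[mask]
    idx = int(np.argmax(np.abs(d)))  # argmax returns the first (lowest-T) maximizer
    return DfResult(
        df_value=float(np.abs(d[idx])),
        peak_temperature=float(t[idx]),
        sample_id=difference.sample_id,
        marker_id=difference.marker_id,
        replicate_index=difference.replicate_index,
        well_id=difference.well_id,
        plate_id=difference.plate_id,
        mode=difference.mode,
    )


def _mean_curve(curves: list[MeltCurve]) -> MeltCurve:
    """Pointwise mean of normalized curves on the first curve's grid."""
    base = curves[0]
    stack = [base.fluorescence]
    for c in curves[1:]:
        if np.array_equal(c.temperatures, base.temperatures):
            stack.append(c.fluorescence)
        else:
            stack.append(np.interp(base.temperatures, c.temperatures, c.fluorescence))
    return replace(base, fluorescence=np.mean(stack, axis=0))


def process_plate(
    curves: list[MeltCurve],
    sample_sheet: pd.DataFrame,
    windows: dict[str, NormalizationWindows],
    *,
    mode: str = "derivative",
    smooth_window: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the whole normalization/difference/Df chain over a plate.

    Wells are matched to the sample sheet by the ``well`` column; rows with a
    non-empty ``standard_level`` are calibration standards.  Every marker (and
    plate) must provide 0% and 100% standards: the (averaged) 0% well is the
    difference baseline and the 100% well anchors the calibration's Df_max.

    Returns ``(df_table, standard_series)``: a tidy per-well Df table for the
    samples and a (marker, plate, level, replicate, df) table for the
    standards, all measured against that plate's own 0% baseline.
    """
    sheet = sample_sheet.copy()
    sheet["standard_level"] = pd.to_numeric(sheet.get("standard_level"), errors="coerce")
    by_well = {c.well_id: c for c in curves}
    orphans = sorted(set(by_well) - set(sheet["well"].astype(str)))
    if orphans:
        raise ValueError(f"wells without a sample-sheet row: {orphans}")
    missing = sorted(set(sheet["well"].astype(str)) - set(by_well))
    if missing:
        raise ValueError(f"sample-sheet wells without melt data: {missing}")

    df_rows: list[dict] = []
    std_rows: list[dict] = []
    plate_col = sheet["plate_id"] if "plate_id" in sheet else pd.Series("plate1", index=sheet.index)
    for (marker, plate), group in sheet.groupby([sheet["marker"], plate_col]):
        win = windows.get(marker)
        if win is None:
            raise ValueError(f"no normalization windows configured for marker {marker!r}")
        std = group[group["standard_level"].notna()]
        levels = set(std["standard_level"])
        if 0.0 not in levels or 100.0 not in levels:
            raise ValueError(
                f"plate {plate!r} marker {marker!r} is missing the 0% or 100% standard"
            )
        normed = {
            w: normalize_curve(by_well[w], win) for w in group["well"].astype(str)
        }
        zero_wells = std.loc[std["standard_level"] == 0.0, "well"].astype(str).tolist()
        baseline = _mean_curve([normed[w] for w in zero_wells])
        search = (win.pre_hi, win.post_lo)
        for _, row in group.iterrows():
            well = str(row["well"])
            diff = difference_curve(
                normed[well], baseline, mode=mode, smooth_window=smooth_window
            )
            res = df_value(diff, restrict_to=search)
            if pd.notna(row["standard_level"]):
                std_rows.append(
                    {
                        "marker_id": marker,
                        "plate_id": plate,
                        "level": float(row["standard_level"]),
                        "replicate_index": int(row["replicate"]),
                        "df_value": res.df_value,
                    }
                )
            else:
                df_rows.append(
                    {
                        "sample_id": row["sample_id"],
                        "marker_id": marker,
                        "replicate_index": int(row["replicate"]),
                        "df_value": res.df_value,
                        "peak_temperature": res.peak_temperature,
                        "plate_id": plate,
                        "mode": mode,
                    }
                )
    df_table = pd.DataFrame(
        df_rows,
        columns=[
            "sample_id", "marker_id", "replicate_index",
            "df_value", "peak_temperature", "plate_id", "mode",
        ],
    )
    standards = pd.DataFrame(
        std_rows,
        columns=["marker_id", "plate_id", "level", "replicate_index", "df_value"],
    )
    return df_table, standards
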