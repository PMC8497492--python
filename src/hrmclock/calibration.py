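"""Standard-curve fitting and Df -> methylation inversion.

The plate's standard series (known methylation levels M, observed Df) is
summarised by the one-parameter hyperbolic model

    a * M / (100 - M) = Df / (Df_max - Df)

where Df_max is the observed Df of the 100% methylated standard and ``a``
captures the deviation from mixture linearity (PCR amplification bias
between methylated- and unmethylated-derived templates).  Solved for Df this
is the forward form fitted here by nonlinear least squares:

    Df(M) = Df_max * a * M / (a * M + (100 - M))

At a = 1 this reduces exactly to Df = Df_max * M / 100.  Sample Df values
are inverted through the fitted curve to percent methylation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "StandardSeries",
    "CalibrationFit",
    "forward_df",
    "fit_standard_curve",
    "methylation_from_df",
    "quantify_samples",
]


@dataclass(frozen=True)
class StandardSeries:
    """Observed (level %, Df) pairs of one marker on one plate."""

    marker_id: str
    plate_id: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        levels = [p[0] for p in self.points]
        if any(not (0.0 <= v <= 100.0) for v in levels):
            raise ValueError("standard levels must lie in [0, 100]")
        if 100.0 not in levels:
            raise ValueError("series must contain the 100% level (source of Df_max)")
        if len(set(levels)) < 3:
            raise ValueError("need >= 3 distinct levels to fit the standard curve")
        if any(p[1] < 0 for p in self.points):
            raise ValueError("negative Df values in standard series")

    @classmethod
    def from_dataframe(cls, standards: pd.DataFrame, marker_id: str, plate_id: str) -> "StandardSeries":
        sub = standards[
            (standards["marker_id"] == marker_id) & (standards["plate_id"] == plate_id)
        ]
        return cls(
            marker_id=marker_id,
            plate_id=plate_id,
            points=tuple(zip(sub["level"].astype(float), sub["df_value"].astype(float))),
        )


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted standard-curve coefficient with diagnostics."""

    a: float
    df_max: float
    residual_sum_squares: float
    n_points: int
    marker_id: str
    plate_id: str

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("coefficient a must be > 0")
        if not self.df_max > 0:
            raise ValueError("df_max must be > 0")


def forward_df(methylation, a: float, df_max: float):
    """Df predicted by the standard-curve model at methylation level(s) M."""
    m = np.asarray(methylation, dtype=float)
    out = df_max * a * m / (a * m + (100.0 - m))
    return float(out) if np.isscalar(methylation) else out


def fit_standard_curve(series: StandardSeries, *, a0: float = 1.0) -> CalibrationFit:
    """Fit the coefficient ``a`` to a standard series by least squares on Df.

    Df_max is fixed at the observed Df of the 100% level (mean if replicated)
    rather than co-estimated, and the 100% points are excluded from the
    residuals they would trivially zero.  Positivity of ``a`` is enforced by
    optimising log(a) from ``a0``.
    """
    pts = np.asarray(series.points, dtype=float)
    levels, dfs = pts[:, 0], pts[:, 1]
    df_max = float(dfs[levels == 100.0].mean())
    if not df_max > 0:
        raise ValueError("Df at the 100% level must be positive")
    fit_mask = levels < 100.0
    m, y = levels[fit_mask], dfs[fit_mask]

    def residuals(log_a: np.ndarray) -> np.ndarray:
        return forward_df(m, math.exp(log_a[0]), df_max) - y

    sol = least_squares(
        residuals, x0=[math.log(a0)], method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    if not sol.success:
        raise RuntimeError(f"standard-curve fit did not converge: {sol.message}")
    a_hat = math.exp(sol.x[0])
    rss = float(np.sum(sol.fun**2))
    return CalibrationFit(
        a=a_hat,
        df_max=df_max,
        residual_sum_squares=rss,
        n_points=int(fit_mask.sum()),
        marker_id=series.marker_id,
        plate_id=series.plate_id,
    )


def methylation_from_df(df: float, fit: CalibrationFit) -> tuple[float, str]:
    """Invert the fitted standard curve at one Df value.

    With q = Df/(Df_max - Df) the inverse is M = 100*q/(a + q).  Instrument
    noise routinely pushes sample Df slightly outside [0, Df_max], so those
    cases clamp to 0/100 and are flagged rather than raised.
    """
    if df <= 0.0:
        return 0.0, ("below_zero" if df < 0.0 else "ok")
    if df >= fit.df_max:
        return 100.0, ("above_max" if df > fit.df_max else "ok")
    q = df / (fit.df_max - df)
    m = 100.0 * q / (fit.a + q)
    return float(np.clip(m, 0.0, 100.0)), "ok"


def quantify_samples(
    df_table: pd.DataFrame,
    fits: dict[tuple[str, str], CalibrationFit],
    replicate_policy: str = "mean-of-M",
) -> pd.DataFrame:
    """Convert the per-well Df table into a per-sample methylation table.

    Each replicate is inverted with its own plate's calibration; replicates
    are then combined per sample x marker.  Policies:

    ``"mean-of-M"`` (default)
        invert each replicate, then average the methylation percentages;
    ``"mean-of-Df"``
        average the replicate Df values first, then invert once.

    The two differ whenever the calibration is nonlinear (a != 1).  Output
    columns: sample_id, marker_id, methylation_percent, replicate_sd,
    n_replicates, flags.
    """
    if replicate_policy not in ("mean-of-M", "mean-of-Df"):
        raise ValueError(f"unknown replicate policy {replicate_policy!r}")
    needed = set(zip(df_table["marker_id"], df_table["plate_id"]))
    missing = needed - set(fits)
    if missing:
        raise ValueError(f"no calibration fit for (marker, plate): {sorted(missing)}")

    rows = []
    for (sid, marker), group in df_table.groupby(["sample_id", "marker_id"], sort=True):
        if len(group) == 0:
            raise ValueError(f"sample {sid!r} marker {marker!r} has no usable replicates")
        ms, flags = [], []
        for _, r in group.iterrows():
            fit = fits[(marker, r["plate_id"])]
            m, flag = methylation_from_df(float(r["df_value"]), fit)
            ms.append(m)
            if flag != "ok":
                flags.append(flag)
        if replicate_policy == "mean-of-Df":
            # single-plate aggregation: use the fit of the first replicate's plate
            fit = fits[(marker, group["plate_id"].iloc[0])]
            m_final, flag = methylation_from_df(float(group["df_value"].mean()), fit)
            if flag != "ok":
                flags.append(flag)
        else:
            m_final = float(np.mean(ms))
        rows.append(
            {
                "sample_id": sid,
                "marker_id": marker,
                "methylation_percent": m_final,
                "replicate_sd": float(np.std(ms, ddof=1)) if len(ms) > 1 else 0.0,
                "n_replicates": len(ms),
                "flags": ";".join(sorted(set(flags))),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "marker_id", "methylation_percent",
            "replicate_sd", "n_replicates", "flags",
        ],
    )
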