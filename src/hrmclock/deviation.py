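"""Sources of clock error: OLS of (predicted - chronological) age on covariates.

The per-sample age-estimation difference is modelled by ordinary least
squares on chronological age, sex (reference: female), and health condition
(reference: healthy), and the best covariate subset is chosen by exhaustive
all-subsets comparison under the small-sample-corrected Akaike criterion
(AICc).  A negative age coefficient means older individuals are relatively
underestimated (regression toward the cohort mean age, the typical clock
artefact); positive sex/CKD coefficients mean those groups are overestimated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["DeviationModel", "fit_deviation_model", "select_model", "ALL_COVARIATES"]

ALL_COVARIATES = ("age", "sex", "health")

_TERMS = {
    "age": "age",
    "sex": "C(sex, Treatment('F'))",
    "health": "C(health, Treatment('healthy'))",
}

_TERM_LABELS = {
    "Intercept": "(Intercept)",
    "age": "Age",
    "C(sex, Treatment('F'))[T.M]": "Sex (M)",
    "C(health, Treatment('healthy'))[T.CKD]": "Health condition (CKD)",
}


@dataclass
class DeviationModel:
    """One fitted OLS model of the age-estimation difference."""

    covariates: tuple[str, ...]
    coefficients: pd.DataFrame  # term, estimate, std_error, p_value
    r_squared: float  # NaN when the response is constant
    aicc: float
    n: int

    def coefficient(self, term: str) -> float:
        row = self.coefficients[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in model {self.covariates}")
        return float(row["estimate"].iloc[0])


def _aicc(llf: float, n: int, n_coefficients: int) -> float:
    # K counts the residual variance alongside the regression coefficients,
    # the convention of likelihood-based model selection on lm fits.
    k = n_coefficients + 1
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _prepare(data: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    required = {"difference"} | set(covariates)
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    data = data.copy()
    data["difference"] = pd.to_numeric(data["difference"])
    if "age" in covariates:
        data["age"] = pd.to_numeric(data["age"])  # guard against object dtype
    for col, levels in (("sex", {"F", "M"}), ("health", {"healthy", "CKD"})):
        if col in covariates:
            bad = set(data[col]) - levels
            if bad:
                raise ValueError(f"unknown {col} values: {sorted(bad)}")
    return data


def fit_deviation_model(
    data: pd.DataFrame, covariates: tuple[str, ...] = ALL_COVARIATES
) -> DeviationModel:
    """OLS of the difference on a covariate subset with treatment coding.

    ``data`` needs a ``difference`` column (predicted - chronological age,
    years) plus the requested covariates: ``age`` (years), ``sex`` (F/M,
    reference F) and ``health`` (healthy/CKD, reference healthy).
    """
    covariates = tuple(covariates)
    unknown = set(covariates) - set(ALL_COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    data = _prepare(data, covariates)
    n = len(data)
    if n <= len(covariates) + 2:
        raise ValueError(f"n={n} too small for {len(covariates)} covariates")
    for col in covariates:
        if col != "age" and data[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} has a single level (rank-deficient design)")
    rhs = " + ".join(_TERMS[c] for c in covariates) if covariates else "1"
    res = smf.ols(f"difference ~ {rhs}", data=data).fit()
    coef = pd.DataFrame(
        {
            "term": [_TERM_LABELS.get(t, t) for t in res.params.index],
            "estimate": res.params.to_numpy(),
            "std_error": res.bse.to_numpy(),
            "p_value": res.pvalues.to_numpy(),
        }
    )
    y = data["difference"].to_numpy(dtype=float)
    r2 = float("nan") if np.allclose(y, y[0]) else float(res.rsquared)
    return DeviationModel(
        covariates=covariates,
        coefficients=coef,
        r_squared=r2,
        aicc=_aicc(float(res.llf), n, len(res.params)),
        n=n,
    )


def select_model(data: pd.DataFrame) -> tuple[DeviationModel, pd.DataFrame]:
    """Exhaustive all-subsets AICc selection over {age, sex, health}.

    Fits all 8 subsets (including intercept-only), ranks by AICc, and
    returns the minimum together with the full ranking table (columns:
    covariates, k, aicc, delta_aicc, r_squared).  Near-ties (within 1e-9)
    resolve to the smaller model with a warning.
    """
    fits: list[DeviationModel] = []
    for size in range(len(ALL_COVARIATES) + 1):
        for subset in itertools.combinations(ALL_COVARIATES, size):
            fits.append(fit_deviation_model(data, subset))
    order = sorted(fits, key=lambda f: (f.aicc, len(f.covariates)))
    best = order[0]
    runner = next((f for f in order[1:] if len(f.covariates) < len(best.covariates)), None)
    if runner is not None and abs(runner.aicc - best.aicc) < 1e-9:
        warnings.warn(
            f"AICc tie between {best.covariates} and {runner.covariates}; "
            "returning the smaller model",
            stacklevel=2,
        )
        best = runner
    ranking = pd.DataFrame(
        {
            "covariates": ["+".join(f.covariates) or "(intercept)" for f in order],
            "k": [len(f.covariates) + 2 for f in order],
            "aicc": [f.aicc for f in order],
            "delta_aicc": [f.aicc - order[0].aicc for f in order],
            "r_squared": [f.r_squared for f in order],
        }
    )
    return best, ranking
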