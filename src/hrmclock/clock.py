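"""The epigenetic age clock: SVR fit, tuning, LOOCV, MAD, transfer prediction.

Age is regressed on marker methylation percentages with epsilon-insensitive
support vector regression (RBF kernel, gamma fixed at 0.5 on standardized
features).  Cost and epsilon are tuned by seeded k-fold grid search; the
tuned model is then validated by leave-one-out cross-validation and
summarised by the mean absolute deviation (MAD) between predicted and
chronological age.  Relative-age scaling (dividing by the oldest training
individual's age) supports cross-species comparison, and a fitted clock can
be applied unchanged to a second species to measure transfer error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = [
    "ClockModel",
    "age_correlation",
    "tune_clock",
    "fit_clock",
    "predict_ages",
    "loocv",
    "mad",
    "relative_age_transform",
    "cross_species_predict",
    "save_clock",
    "load_clock",
    "DEFAULT_COST_GRID",
    "DEFAULT_EPSILON_GRID",
]

DEFAULT_COST_GRID = tuple(2.0**k for k in range(-1, 7))  # 0.5 ... 64
DEFAULT_EPSILON_GRID = (0.01, 0.05, 0.1, 0.2, 0.5, 1.0)


@dataclass
class ClockModel:
    """A fitted SVR age clock, self-contained for prediction and transfer.

    Feature standardization parameters (per-marker mean/sd of the training
    data) are frozen at training time so that prediction — including on a
    different species — reproduces the training-time feature scaling.  The
    training matrix is retained so the model can be serialized as plain
    arrays and refitted deterministically on load.
    """

    cost: float
    epsilon: float
    feature_names: tuple[str, ...]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    training_species: str
    oldest_training_age: float
    gamma: float = 0.5
    train_features: np.ndarray | None = None
    train_ages: np.ndarray | None = None
    _svr: SVR | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.cost > 0:
            raise ValueError("cost must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    def standardize(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, dtype=float) - self.feature_means) / self.feature_sds


def _standardization(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = features.mean(axis=0)
    sd = features.std(axis=0, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            "constant feature column(s) carry no age signal; proceeding with unit scale",
            stacklevel=3,
        )
        sd = np.where(degenerate, 1.0, sd)
    return mu, sd


def _as_matrix(features) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    return x


def age_correlation(methylation: pd.DataFrame, ages: pd.Series | np.ndarray) -> pd.DataFrame:
    """Pearson correlation (with two-sided p) of each marker vs age.

    ``methylation`` is a wide table, one column per marker, rows aligned with
    ``ages``.  Raises on fewer than 3 samples or zero variance.
    """
    ages = np.asarray(ages, dtype=float)
    if len(methylation) < 3:
        raise ValueError("need n >= 3 for a correlation test")
    rows = []
    for marker in methylation.columns:
        x = methylation[marker].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(ages) == 0:
            raise ValueError(f"zero variance in marker {marker!r} or ages")
        r, p = stats.pearsonr(x, ages)
        rows.append({"marker_id": marker, "pearson_r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)


def _make_svr(cost: float, epsilon: float, gamma: float) -> SVR:
    return SVR(kernel="rbf", C=cost, epsilon=epsilon, gamma=gamma, tol=1e-5)


def tune_clock(
    features,
    ages,
    cost_grid=DEFAULT_COST_GRID,
    epsilon_grid=DEFAULT_EPSILON_GRID,
    cv_folds: int = 10,
    seed: int = 0,
    gamma: float = 0.5,
) -> tuple[float, float]:
    """Grid-search (cost, epsilon) by seeded k-fold cross-validated MSE.

    Exhaustive over both grids; ties break toward the smaller cost, then the
    smaller epsilon.  Standardization is refitted inside each training fold.
    """
    x, y = _as_matrix(features), np.asarray(ages, dtype=float)
    if len(cost_grid) == 0 or len(epsilon_grid) == 0:
        raise ValueError("tuning grids must be non-empty")
    if not (2 <= cv_folds <= len(y)):
        raise ValueError(f"need n >= cv_folds >= 2, got n={len(y)}, folds={cv_folds}")
    folds = list(KFold(n_splits=cv_folds, shuffle=True, random_state=seed).split(x))
    best = None
    for cost in sorted(cost_grid):
        for eps in sorted(epsilon_grid):
            sse, n_test = 0.0, 0
            for train_idx, test_idx in folds:
                mu, sd = _standardization(x[train_idx])
                svr = _make_svr(cost, eps, gamma)
                svr.fit((x[train_idx] - mu) / sd, y[train_idx])
                pred = svr.predict((x[test_idx] - mu) / sd)
                sse += float(np.sum((pred - y[test_idx]) ** 2))
                n_test += len(test_idx)
            mse = sse / n_test
            if best is None or mse < best[0] - 1e-12:
                best = (mse, cost, eps)
    return best[1], best[2]


def fit_clock(
    features,
    ages,
    cost: float,
    epsilon: float,
    *,
    gamma: float = 0.5,
    feature_names: tuple[str, ...] | None = None,
    species: str = "unknown",
) -> ClockModel:
    """Fit the SVR clock at fixed hyperparameters; stores its own scaling."""
    x, y = _as_matrix(features), np.asarray(ages, dtype=float)
    if np.any(y <= 0):
        raise ValueError("chronological ages must be > 0")
    if feature_names is None:
        feature_names = tuple(
            features.columns if isinstance(features, pd.DataFrame)
            else (f"f{i}" for i in range(x.shape[1]))
        )
    mu, sd = _standardization(x)
    svr = _make_svr(cost, epsilon, gamma)
    svr.fit((x - mu) / sd, y)
    return ClockModel(
        cost=cost,
        epsilon=epsilon,
        feature_names=tuple(feature_names),
        feature_means=mu,
        feature_sds=sd,
        training_species=species,
        oldest_training_age=float(y.max()),
        gamma=gamma,
        train_features=x,
        train_ages=y,
        _svr=svr,
    )


def predict_ages(model: ClockModel, features) -> np.ndarray:
    """Predict ages for a feature matrix using the frozen training scaling."""
    if model._svr is None:
        raise ValueError("model has no fitted SVR (load or fit first)")
    return model._svr.predict(model.standardize(_as_matrix(features)))


def _prediction_frame(sample_ids, predicted, actual) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "predicted_age": np.asarray(predicted, dtype=float),
            "chronological_age": np.asarray(actual, dtype=float),
        }
    )
    out["difference"] = out["predicted_age"] - out["chronological_age"]
    return out


def loocv(
    features,
    ages,
    cost: float,
    epsilon: float,
    *,
    gamma: float = 0.5,
    sample_ids=None,
    retune_in_fold: bool = False,
    cost_grid=DEFAULT_COST_GRID,
    epsilon_grid=DEFAULT_EPSILON_GRID,
    tune_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-out cross-validation of the clock.

    By default the supplied hyperparameters — tuned once on the full data —
    are reused in every fold, mirroring the tune-then-validate protocol.
    ``retune_in_fold=True`` switches to the stricter variant that re-runs the
    grid search inside each training fold.  Per-sample predictions depend
    only on the held-out identity, so sample order is irrelevant.
    """
    x, y = _as_matrix(features), np.asarray(ages, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs n >= 3")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        c, e = cost, epsilon
        if retune_in_fold:
            folds = min(tune_folds, n - 1)
            c, e = tune_clock(
                x[mask], y[mask], cost_grid, epsilon_grid, cv_folds=folds,
                seed=seed, gamma=gamma,
            )
        mu, sd = _standardization(x[mask])
        svr = _make_svr(c, e, gamma)
        svr.fit((x[mask] - mu) / sd, y[mask])
        preds[i] = svr.predict((x[i:i + 1] - mu) / sd)[0]
    return _prediction_frame(sample_ids, preds, y)


def mad(predictions: pd.DataFrame) -> float:
    """Mean absolute deviation |predicted - chronological| in years."""
    if len(predictions) == 0:
        raise ValueError("no predictions")
    return float(np.mean(np.abs(predictions["difference"])))


def relative_age_transform(predictions: pd.DataFrame, oldest_age: float) -> pd.DataFrame:
    """Add relative-age columns: ages divided by the species' oldest study age."""
    if not oldest_age > 0:
        raise ValueError("oldest_age must be > 0")
    out = predictions.copy()
    out["relative_predicted"] = out["predicted_age"] / oldest_age
    out["relative_chronological"] = out["chronological_age"] / oldest_age
    out["relative_difference"] = out["relative_predicted"] - out["relative_chronological"]
    return out


def cross_species_predict(
    model: ClockModel,
    features,
    ages,
    *,
    sample_ids=None,
) -> pd.DataFrame:
    """Apply a clock trained on species A directly to species B samples.

    No refitting and no re-scaling: the training standardization is reused,
    which is exactly how a direct transfer would be deployed.  The returned
    frame supports ``mad`` and the signed mean difference (negative mean
    difference = systematic underestimation of the second species' ages).
    """
    x = _as_matrix(features)
    if x.shape[1] != len(model.feature_names):
        raise ValueError(
            f"marker mismatch: model expects {model.feature_names}, got {x.shape[1]} columns"
        )
    if isinstance(features, pd.DataFrame) and tuple(features.columns) != model.feature_names:
        raise ValueError(
            f"marker mismatch: model expects {model.feature_names}, got {tuple(features.columns)}"
        )
    y = np.asarray(ages, dtype=float)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(y))]
    return _prediction_frame(sample_ids, predict_ages(model, x), y)


# ---------------------------------------------------------------------------
# Serialization: JSON of hyperparameters + arrays; the SVR is refitted on load
# (deterministic for a fixed training set), keeping the file plain text.


def save_clock(model: ClockModel, path) -> None:
    if model.train_features is None or model.train_ages is None:
        raise ValueError("model lacks retained training data; cannot serialize")
    payload = {
        "cost": model.cost,
        "epsilon": model.epsilon,
        "gamma": model.gamma,
        "feature_names": list(model.feature_names),
        "feature_means": model.feature_means.tolist(),
        "feature_sds": model.feature_sds.tolist(),
        "training_species": model.training_species,
        "oldest_training_age": model.oldest_training_age,
        "train_features": model.train_features.tolist(),
        "train_ages": model.train_ages.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_clock(path) -> ClockModel:
    with open(path) as fh:
        p = json.load(fh)
    x = np.asarray(p["train_features"], dtype=float)
    y = np.asarray(p["train_ages"], dtype=float)
    mu = np.asarray(p["feature_means"], dtype=float)
    sd = np.asarray(p["feature_sds"], dtype=float)
    svr = _make_svr(p["cost"], p["epsilon"], p["gamma"])
    svr.fit((x - mu) / sd, y)
    return ClockModel(
        cost=p["cost"],
        epsilon=p["epsilon"],
        feature_names=tuple(p["feature_names"]),
        feature_means=mu,
        feature_sds=sd,
        training_species=p["training_species"],
        oldest_training_age=p["oldest_training_age"],
        gamma=p["gamma"],
        train_features=x,
        train_ages=y,
        _svr=svr,
    )
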