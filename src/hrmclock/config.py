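"""Pipeline configuration: every tunable constant in one validated object.

The defaults collect the study-level constants of the assay and model:
per-marker normalization windows, the nine standard levels, the
difference-curve mode, the SVR kernel settings and tuning grids, and the
LOOCV variant.  Configs load from YAML or JSON and round-trip exactly
through ``to_dict``/``from_dict``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .clock import DEFAULT_COST_GRID, DEFAULT_EPSILON_GRID
from .melt import DEFAULT_WINDOWS, NormalizationWindows
from .simulate import DEFAULT_STANDARD_LEVELS

__all__ = ["PipelineConfig"]


def _default_windows() -> dict[str, tuple[float, float, float, float]]:
    return {
        m: (w.pre_lo, w.pre_hi, w.post_lo, w.post_hi) for m, w in DEFAULT_WINDOWS.items()
    }


@dataclass
class PipelineConfig:
    """Resolved configuration for the end-to-end pipeline."""

    windows: dict[str, tuple[float, float, float, float]] = field(default_factory=_default_windows)
    standard_levels: tuple[float, ...] = DEFAULT_STANDARD_LEVELS
    mode: str = "derivative"
    smooth_window: int = 5
    replicate_policy: str = "mean-of-M"
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    epsilon_grid: tuple[float, ...] = DEFAULT_EPSILON_GRID
    gamma: float = 0.5
    tune_folds: int = 10
    loocv_variant: str = "tune-once"
    species: str = "domestic_cat"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("derivative", "fluorescence"):
            raise ValueError(f"mode must be 'derivative' or 'fluorescence', got {self.mode!r}")
        if self.loocv_variant not in ("tune-once", "tune-in-fold"):
            raise ValueError(
                f"loocv_variant must be 'tune-once' or 'tune-in-fold', got {self.loocv_variant!r}"
            )
        if self.replicate_policy not in ("mean-of-M", "mean-of-Df"):
            raise ValueError(f"invalid replicate_policy {self.replicate_policy!r}")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError(f"smooth_window must be a positive odd integer, got {self.smooth_window}")
        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")
        if not self.windows:
            raise ValueError("at least one marker's normalization windows required")
        # materialize tuples and validate window ordering early
        self.windows = {m: tuple(float(x) for x in w) for m, w in self.windows.items()}
        for marker in self.windows:
            self.normalization_windows(marker)
        self.standard_levels = tuple(float(v) for v in self.standard_levels)
        self.cost_grid = tuple(float(v) for v in self.cost_grid)
        self.epsilon_grid = tuple(float(v) for v in self.epsilon_grid)

    def normalization_windows(self, marker: str) -> NormalizationWindows:
        if marker not in self.windows:
            raise ValueError(f"no normalization windows configured for marker {marker!r}")
        return NormalizationWindows(*self.windows[marker])

    @property
    def windows_objects(self) -> dict[str, NormalizationWindows]:
        return {m: self.normalization_windows(m) for m in self.windows}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["windows"] = {m: list(w) for m, w in self.windows.items()}
        d["standard_levels"] = list(self.standard_levels)
        d["cost_grid"] = list(self.cost_grid)
        d["epsilon_grid"] = list(self.epsilon_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)} (known: {sorted(known)})")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def dump(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
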