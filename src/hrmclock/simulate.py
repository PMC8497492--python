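"""Synthetic MS-HRM melt curves, standard series, and age-structured cohorts.

Methylation-sensitive high-resolution melting (MS-HRM) amplifies
bisulfite-converted DNA and melts the amplicons slowly while recording
fluorescence of a saturating intercalating dye.  Templates that were
methylated retain their CpG cytosines through bisulfite conversion, so the
amplicon keeps its G+C content and melts at a higher temperature than the
amplicon derived from unmethylated template.  A sample at intermediate
methylation is a mixture of the two homoduplex species, and its melt curve
is (to first order) the mixture-weighted sum of the two pure transitions.

This module emulates that physics with a deliberately simple model: each
duplex species melts as a two-state (logistic) transition, the raw signal
rides on linear pre- and post-melt baselines, and Gaussian noise is added
per acquisition point.  It also generates cohorts of individuals whose
marker methylation increases linearly with age, mirroring the structure of
a blood-sample study of domestic cats (n = 79, ages 0.41-21.04 y, with a
chronic-kidney-disease subgroup) and snow leopards (n = 11, ages
2.25-14.67 y), so that every downstream stage of the pipeline can be
exercised against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .melt import MeltCurve

__all__ = [
    "DuplexSpecies",
    "MeltSimSpec",
    "MarkerEffect",
    "CohortSpec",
    "SimulatedCohort",
    "simulate_melt_curve",
    "simulate_standard_series",
    "simulate_cohort",
    "bisulfite_convert",
    "count_cpg",
    "synthetic_marker_sequence",
    "MARKER_MELT_SPECS",
    "DEFAULT_STANDARD_LEVELS",
    "default_cat_cohort",
    "default_leopard_cohort",
]

#: The nine-level standard series run on every plate (percent methylation).
DEFAULT_STANDARD_LEVELS = (0.0, 5.0, 10.0, 15.0, 25.0, 40.0, 50.0, 75.0, 100.0)


@dataclass(frozen=True)
class DuplexSpecies:
    """One homoduplex amplicon species with a two-state melting transition.

    Parameters
    ----------
    melt_temperature:
        Midpoint of the transition (deg C).
    transition_width:
        Scale of the logistic transition (deg C, > 0).  The helix fraction is
        ``1 / (1 + exp((T - Tm) / width))``.
    weight:
        Mixture fraction in [0, 1].  ``None`` for specs where the weight is
        set at simulation time from the methylation level.
    """

    melt_temperature: float
    transition_width: float
    weight: float | None = None

    def __post_init__(self) -> None:
        if not self.transition_width > 0:
            raise ValueError(f"transition_width must be > 0, got {self.transition_width}")
        if self.weight is not None and not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"weight must lie in [0, 1], got {self.weight}")

    def helix_fraction(self, temperatures: np.ndarray) -> np.ndarray:
        """Fraction of duplex still double-stranded at each temperature."""
        z = (np.asarray(temperatures, dtype=float) - self.melt_temperature) / self.transition_width
        return 1.0 / (1.0 + np.exp(z))


def mixture_helix_fraction(species: list[DuplexSpecies], temperatures: np.ndarray) -> np.ndarray:
    """Weighted helix fraction of a mixture; weights must sum to 1 (1e-9)."""
    weights = [s.weight for s in species]
    if any(w is None for w in weights):
        raise ValueError("all species need explicit weights for a mixture evaluation")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"mixture weights must sum to 1, got {sum(weights)}")
    out = np.zeros(len(temperatures))
    for s in species:
        out += s.weight * s.helix_fraction(temperatures)
    return out


def _default_grid() -> np.ndarray:
    # 65 -> 95 deg C window of the melt programme, decimated to 0.25 deg C
    # steps (an instrument-export-like density of 4 points per deg C).
    return np.round(np.arange(65.0, 95.0 + 1e-9, 0.25), 6)


@dataclass(frozen=True)
class MeltSimSpec:
    """Specification of one marker's simulated melt acquisition.

    ``species_list`` holds exactly two species ordered (low-Tm, high-Tm):
    the unmethylated-template amplicon and the methylated-template amplicon.
    Baseline slopes are non-negative downward drifts (fluorescence units per
    deg C), the usual direction of dye-signal drift, so the noiseless curve
    is non-increasing in temperature.

    ``amplification_bias`` is a multiplicative PCR-efficiency distortion of
    the high-Tm species' mixture weight: the effective weight at methylation
    M is ``b*M / (b*M + (100 - M))``.  At ``b = 1`` (default, no bias) the
    mixture is exactly linear in M; ``b != 1`` induces the calibration-curve
    nonlinearity that the standard-curve coefficient ``a`` quantifies.
    """

    species_list: tuple[DuplexSpecies, DuplexSpecies]
    temp_grid: np.ndarray = field(default_factory=_default_grid)
    pre_baseline_slope: float = 0.20
    post_baseline_slope: float = 0.05
    signal_amplitude: float = 100.0
    noise_sd: float = 0.1
    amplification_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.temp_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("temperature grid is empty")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temp_grid", grid)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.species_list) != 2:
            raise ValueError("species_list must hold exactly (low-Tm, high-Tm) species")
        lo, hi = self.species_list
        if lo.melt_temperature >= hi.melt_temperature:
            raise ValueError("species_list must be ordered (low-Tm, high-Tm)")
        if self.amplification_bias <= 0:
            raise ValueError("amplification_bias must be > 0")


def _high_tm_weight(methylation: float, bias: float) -> float:
    """Effective mixture weight of the methylated (high-Tm) species."""
    m = float(methylation)
    return bias * m / (bias * m + (100.0 - m)) if m < 100.0 else 1.0


def simulate_melt_curve(
    spec: MeltSimSpec,
    true_methylation: float,
    *,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
    marker_id: str = "marker",
    replicate_index: int = 0,
    well_id: str = "W000",
    plate_id: str = "plate1",
) -> MeltCurve:
    """Simulate one well's raw melt trace at a known methylation level.

    The noiseless fluorescence is
    ``post(T) + (pre(T) - post(T)) * theta_mix(T)`` where ``pre``/``post``
    are the drifting baselines and ``theta_mix`` the mixture helix fraction,
    so at zero amplification bias the curve is pointwise linear in the
    methylation level.  Deterministic given ``rng`` (or ``spec.seed``).
    """
    if not (0.0 <= true_methylation <= 100.0):
        raise ValueError(f"true_methylation must lie in [0, 100], got {true_methylation}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    grid = spec.temp_grid
    lo, hi = spec.species_list
    w_hi = _high_tm_weight(true_methylation, spec.amplification_bias)
    theta = (1.0 - w_hi) * lo.helix_fraction(grid) + w_hi * hi.helix_fraction(grid)
    dt = grid - grid[0]
    pre_line = spec.signal_amplitude - spec.pre_baseline_slope * dt
    post_line = -spec.post_baseline_slope * dt
    fluor = post_line + (pre_line - post_line) * theta
    if spec.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, spec.noise_sd, size=grid.size)
    return MeltCurve(
        sample_id=sample_id,
        marker_id=marker_id,
        replicate_index=replicate_index,
        well_id=well_id,
        plate_id=plate_id,
        temperatures=grid.copy(),
        fluorescence=fluor,
    )


def simulate_standard_series(
    spec: MeltSimSpec,
    levels: tuple[float, ...] = DEFAULT_STANDARD_LEVELS,
    *,
    replicates: int = 1,
    marker_id: str = "marker",
    plate_id: str = "plate1",
    well_prefix: str = "STD",
) -> list[tuple[float, MeltCurve]]:
    """Simulate the plate's calibration standards, one curve per level/replicate.

    The 0% and 100% levels are mandatory: the former is the difference-curve
    baseline and the latter fixes Df_max in the calibration model.
    """
    levels = tuple(float(v) for v in levels)
    if any(not (0.0 <= v <= 100.0) for v in levels):
        raise ValueError("standard levels must lie within [0, 100]")
    if 0.0 not in levels or 100.0 not in levels:
        raise ValueError("standard series must include the 0% and 100% levels")
    children = np.random.SeedSequence(spec.seed).spawn(len(levels) * replicates)
    out: list[tuple[float, MeltCurve]] = []
    k = 0
    for level in levels:
        for rep in range(replicates):
            curve = simulate_melt_curve(
                spec,
                level,
                rng=np.random.default_rng(children[k]),
                sample_id=f"{well_prefix}_{marker_id}_{level:g}",
                marker_id=marker_id,
                replicate_index=rep,
                well_id=f"{well_prefix}_{marker_id}_{level:g}_r{rep}",
                plate_id=plate_id,
            )
            out.append((level, curve))
            k += 1
    return out


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class MarkerEffect:
    """Age -> methylation generative parameters for one marker.

    ``baseline`` is the mean methylation (%) at age 0, ``slope`` the mean
    increase per year, ``residual_sd`` the between-individual scatter (%).
    ``sex_offset`` is added for males, ``ckd_offset`` for CKD individuals,
    and ``ckd_sd_extra`` widens the residual scatter for CKD individuals —
    the mechanism by which disease degrades clock accuracy here.
    """

    baseline: float
    slope: float
    residual_sd: float
    sex_offset: float = 0.0
    ckd_offset: float = 0.0
    ckd_sd_extra: float = 4.0


@dataclass(frozen=True)
class CohortSpec:
    """Structure of a simulated cohort (sizes, demography, marker effects)."""

    n: int
    age_range: tuple[float, float]
    sex_ratio: float  # fraction female
    ckd_fraction: float
    marker_params: dict[str, MarkerEffect]
    replicate_count: int = 2
    species: str = "domestic_cat"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs n >= 2")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"degenerate age_range {self.age_range}")
        for name, frac in (("sex_ratio", self.sex_ratio), ("ckd_fraction", self.ckd_fraction)):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if not self.marker_params:
            raise ValueError("at least one marker required")


@dataclass
class SimulatedCohort:
    """Sample sheet + melt curves + retained ground truth for one cohort."""

    sample_sheet: pd.DataFrame
    curves: list[MeltCurve]
    truth: pd.DataFrame  # sample_id, species, sex, age_years, health, marker, true_methylation


def _assign_binary(rng: np.random.Generator, n: int, fraction: float,
                   yes: str, no: str) -> np.ndarray:
    """Assign exactly round(n*fraction) 'yes' labels in random order."""
    n_yes = int(round(n * fraction))
    labels = np.array([yes] * n_yes + [no] * (n - n_yes))
    rng.shuffle(labels)
    return labels


def simulate_cohort(
    spec: CohortSpec,
    melt_specs: dict[str, MeltSimSpec] | None = None,
    *,
    include_melt: bool = True,
    standard_levels: tuple[float, ...] = DEFAULT_STANDARD_LEVELS,
    plate_id: str = "plate1",
) -> SimulatedCohort:
    """Generate a cohort sample sheet, its melt curves, and the truth table.

    Ages are uniform on ``age_range``; per-marker true methylation is
    ``baseline + slope*age + offsets + N(0, sd)`` clamped to [0, 100].  Each
    sample receives ``replicate_count`` wells per marker, and each marker's
    standard series is appended so the plate is self-calibrating.  With
    ``include_melt=False`` only the sheet and truth table are produced
    (cheap mode for model-level studies).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    ages = rng.uniform(spec.age_range[0], spec.age_range[1], size=spec.n)
    sexes = _assign_binary(rng, spec.n, spec.sex_ratio, "F", "M")
    healths = _assign_binary(rng, spec.n, spec.ckd_fraction, "CKD", "healthy")
    sample_ids = [f"{spec.species}_{i:03d}" for i in range(spec.n)]

    truth_rows = []
    for i, sid in enumerate(sample_ids):
        for marker, eff in spec.marker_params.items():
            sd = eff.residual_sd + (eff.ckd_sd_extra if healths[i] == "CKD" else 0.0)
            mu = (
                eff.baseline
                + eff.slope * ages[i]
                + (eff.sex_offset if sexes[i] == "M" else 0.0)
                + (eff.ckd_offset if healths[i] == "CKD" else 0.0)
            )
            m = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            truth_rows.append(
                {
                    "sample_id": sid,
                    "species": spec.species,
                    "sex": sexes[i],
                    "age_years": ages[i],
                    "health": healths[i],
                    "marker": marker,
                    "true_methylation": float(np.clip(m, 0.0, 100.0)),
                }
            )
    truth = pd.DataFrame(truth_rows)

    sheet_rows = []
    curves: list[MeltCurve] = []
    if include_melt:
        if melt_specs is None:
            melt_specs = {m: MARKER_MELT_SPECS[m] for m in spec.marker_params}
        missing = set(spec.marker_params) - set(melt_specs)
        if missing:
            raise ValueError(f"no melt spec for markers: {sorted(missing)}")
        well = 0
        child_seeds = np.random.SeedSequence(spec.seed + 1).spawn(
            spec.n * len(spec.marker_params) * spec.replicate_count
        )
        k = 0
        for i, sid in enumerate(sample_ids):
            for marker in spec.marker_params:
                m_true = truth.loc[
                    (truth.sample_id == sid) & (truth.marker == marker), "true_methylation"
                ].iloc[0]
                for rep in range(spec.replicate_count):
                    wid = f"W{well:04d}"
                    curves.append(
                        simulate_melt_curve(
                            melt_specs[marker],
                            m_true,
                            rng=np.random.default_rng(child_seeds[k]),
                            sample_id=sid,
                            marker_id=marker,
                            replicate_index=rep,
                            well_id=wid,
                            plate_id=plate_id,
                        )
                    )
                    sheet_rows.append(
                        {
                            "sample_id": sid,
                            "species": spec.species,
                            "sex": sexes[i],
                            "age_years": round(float(ages[i]), 4),
                            "health": healths[i],
                            "marker": marker,
                            "well": wid,
                            "replicate": rep,
                            "standard_level": "",
                            "plate_id": plate_id,
                        }
                    )
                    well += 1
                    k += 1
        for marker in spec.marker_params:
            series_spec = replace(
                melt_specs[marker], seed=melt_specs[marker].seed + 7919 + spec.seed
            )
            for level, curve in simulate_standard_series(
                series_spec,
                standard_levels,
                replicates=spec.replicate_count,
                marker_id=marker,
                plate_id=plate_id,
            ):
                curves.append(curve)
                sheet_rows.append(
                    {
                        "sample_id": curve.sample_id,
                        "species": spec.species,
                        "sex": "",
                        "age_years": "",
                        "health": "",
                        "marker": marker,
                        "well": curve.well_id,
                        "replicate": curve.replicate_index,
                        "standard_level": level,
                        "plate_id": plate_id,
                    }
                )
    else:
        for i, sid in enumerate(sample_ids):
            for marker in spec.marker_params:
                sheet_rows.append(
                    {
                        "sample_id": sid,
                        "species": spec.species,
                        "sex": sexes[i],
                        "age_years": round(float(ages[i]), 4),
                        "health": healths[i],
                        "marker": marker,
                        "well": "",
                        "replicate": 0,
                        "standard_level": "",
                        "plate_id": plate_id,
                    }
                )
    return SimulatedCohort(pd.DataFrame(sheet_rows), curves, truth)


# ---------------------------------------------------------------------------
# Sequence utilities


def bisulfite_convert(sequence: str, methylated_cpg_positions: set[int] | frozenset[int] = frozenset()) -> str:
    """In-silico bisulfite conversion: unmethylated C -> T (read strand).

    ``methylated_cpg_positions`` are 0-based indices of methylated CpG
    cytosines, which are protected from conversion.  Each protected index
    must point at a C immediately followed by a G.
    """
    seq = sequence.upper()
    allowed = set("ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    protected = set(methylated_cpg_positions)
    for pos in protected:
        if pos < 0 or pos >= len(seq) or seq[pos] != "C" or pos + 1 >= len(seq) or seq[pos + 1] != "G":
            raise ValueError(f"protected position {pos} is not a CpG cytosine")
    out = [
        ("C" if (base == "C" and i in protected) else ("T" if base == "C" else base))
        for i, base in enumerate(seq)
    ]
    return "".join(out)


def count_cpg(sequence: str) -> int:
    """Number of CG dinucleotides in the sequence (empty -> 0)."""
    return sequence.upper().count("CG")


def synthetic_marker_sequence(length: int, n_cpg: int, rng: np.random.Generator) -> str:
    """A random (synthetic) amplicon-like sequence with an exact CpG count.

    Stand-in for a real marker amplicon: the study's markers are only
    characterised by length and CpG count here (e.g. 117 bp / 13 CpGs and
    109 bp / 9 CpGs), so a random background with planted, non-adjacent CpG
    dinucleotides is used.
    """
    if n_cpg * 2 > length:
        raise ValueError("too many CpGs for the requested length")
    while True:
        # C appears only at planted CpG sites, mimicking the C-depletion of
        # a bisulfite-converted template outside methylated CpGs.
        seq = list(rng.choice(list("ATG"), size=length))
        # choose non-overlapping CpG start positions
        starts = sorted(
            rng.choice(length - 1, size=min(4 * n_cpg, length - 1), replace=False).tolist()
        )
        chosen: list[int] = []
        for s in starts:
            if len(chosen) == n_cpg:
                break
            if all(abs(s - c) >= 2 for c in chosen):
                chosen.append(s)
        if len(chosen) < n_cpg:
            continue
        for s in chosen:
            seq[s], seq[s + 1] = "C", "G"
        out = "".join(seq)
        if count_cpg(out) == n_cpg:
            return out


# ---------------------------------------------------------------------------
# Study-shaped defaults

#: Marker melt specifications. Tm gap 4 deg C for the ELOVL2-like amplicon
#: and 3 deg C for the RALYL-like amplicon, placed so the default
#: normalization windows bracket the transitions.
MARKER_MELT_SPECS: dict[str, MeltSimSpec] = {
    "ELOVL2": MeltSimSpec(
        species_list=(
            DuplexSpecies(melt_temperature=76.0, transition_width=1.2),
            DuplexSpecies(melt_temperature=80.0, transition_width=1.2),
        ),
        seed=11,
    ),
    "RALYL": MeltSimSpec(
        species_list=(
            DuplexSpecies(melt_temperature=74.0, transition_width=1.1),
            DuplexSpecies(melt_temperature=77.0, transition_width=1.1),
        ),
        seed=13,
    ),
}

_CAT_MARKERS = {
    "ELOVL2": MarkerEffect(baseline=30.0, slope=2.0, residual_sd=11.0),
    "RALYL": MarkerEffect(baseline=25.0, slope=1.8, residual_sd=10.0),
}

# Leopard slopes reduced to ~70% of the cat's: a plausible between-species
# shift in the methylation-age coupling that makes direct model transfer
# underestimate leopard ages.
_LEOPARD_MARKERS = {
    "ELOVL2": MarkerEffect(baseline=30.0, slope=1.4, residual_sd=3.2, ckd_sd_extra=2.0),
    "RALYL": MarkerEffect(baseline=25.0, slope=1.26, residual_sd=3.0, ckd_sd_extra=2.0),
}


def default_cat_cohort(seed: int = 0, **overrides) -> CohortSpec:
    """Domestic-cat-like cohort: n=79, ages 0.41-21.04 y, F:M 43:36, 41 CKD."""
    kwargs = dict(
        n=79,
        age_range=(0.41, 21.04),
        sex_ratio=43 / 79,
        ckd_fraction=41 / 79,
        marker_params=dict(_CAT_MARKERS),
        replicate_count=2,
        species="domestic_cat",
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def default_leopard_cohort(seed: int = 0, **overrides) -> CohortSpec:
    """Snow-leopard-like cohort: n=11, ages 2.25-14.67 y, 4F:7M, one CKD."""
    kwargs = dict(
        n=11,
        age_range=(2.25, 14.67),
        sex_ratio=4 / 11,
        ckd_fraction=1 / 11,
        marker_params=dict(_LEOPARD_MARKERS),
        replicate_count=2,
        species="snow_leopard",
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)
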