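"""Synthetic case-control morphometry cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort of cases and controls matched on age and non-verbal IQ
(NVIQ), a *homogeneous* case class (single Gaussian with shrunken covariance)
and a *heterogeneous* control class (a two-component mixture of a
developmentally-delayed, NVIQ < 70, and a non-delayed subpopulation whose
feature means are separated along a fixed random sign pattern).  Features are
drawn from a multivariate Gaussian with block covariance by region: the five
measures of one region are correlated (they describe a single structure),
distinct regions are independent.  Effects, heterogeneity and covariate
coupling are specified on the standardized (SD-unit) scale and then mapped to
realistic native units per measure.

Covariates for a case and its intended control partner are sampled jointly
(control = case value + small jitter), so the designed pairing is recoverable
by the matching stage and the leave-pair-out structure is reproducible on
demand.  The DD threshold is fixed at NVIQ 70 and is not configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as mio
from .dkt import DKT_REGIONS, GLOBAL_ENTRIES, MEASURES, FeatureIndex, feature_name

#: Native-unit location and scale per measure (loc, scale); chosen to mimic
#: the magnitude of regional surface statistics in preschool-age cohorts.
NATIVE_SCALES: dict[str, tuple[float, float]] = {
    "Area": (1500.0, 250.0),
    "Volume": (4500.0, 700.0),
    "Thickness": (2.6, 0.25),
    "ThicknessStd": (0.55, 0.08),
    "MeanCurv": (0.15, 0.02),
}
GLOBAL_SCALES: dict[str, tuple[float, float]] = {
    "WhiteSurfArea": (80000.0, 7000.0),
    "MeanThickness": (2.6, 0.15),
}

#: Age and NVIQ population moments used for covariate standardization.
AGE_MOMENTS = (49.0, 12.0)
NVIQ_MOMENTS = (73.0, 22.0)
NVIQ_DD_MOMENTS = (52.0, 10.0)
NVIQ_NODD_MOMENTS = (91.0, 14.0)


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Sample composition and covariate ranges of a synthetic cohort."""

    n_cases: int = 41
    n_controls: int = 40
    n_regions: int = 62  # both hemispheres; must be even
    measures: Sequence[str] = MEASURES
    include_global: bool = True
    sex_ratio: float = 0.5
    age_range_months: tuple[float, float] = (22.0, 72.0)
    nviq_range: tuple[float, float] = (31.0, 123.0)
    control_mixture_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise CohortConfigError("n_cases and n_controls must be >= 1")
        if self.n_regions < 2 or self.n_regions % 2:
            raise CohortConfigError("n_regions counts both hemispheres and must be even")
        if self.n_regions // 2 > len(DKT_REGIONS):
            raise CohortConfigError(f"at most {2 * len(DKT_REGIONS)} regions available")
        if not self.measures:
            raise CohortConfigError("measure list is empty")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise CohortConfigError(f"unknown measure(s) {sorted(unknown)}")
        for name, (lo, hi) in (
            ("age_range_months", self.age_range_months),
            ("nviq_range", self.nviq_range),
        ):
            if lo > hi:
                raise CohortConfigError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise CohortConfigError("sex_ratio must lie in [0, 1]")
        if not 0.0 <= self.control_mixture_weight <= 1.0:
            raise CohortConfigError("control_mixture_weight must lie in [0, 1]")

    @property
    def regions(self) -> tuple[str, ...]:
        return DKT_REGIONS[: self.n_regions // 2]

    @property
    def feature_index(self) -> FeatureIndex:
        return FeatureIndex.build(
            regions=self.regions, measures=self.measures, include_global=self.include_global
        )

    @property
    def n_features(self) -> int:
        return len(self.feature_index)


@dataclass
class EffectSpec:
    """Planted group differences, class homogeneity and covariate coupling.

    All quantities are on the standardized (SD-unit) scale.  The defaults
    encode the designed study condition: no per-feature planted effect, a
    within-subpopulation covariance common to both classes, and a
    two-subpopulation control mixture whose modes are separated by 2.5 SD per
    feature along a seed-fixed sign pattern.  At that separation the expected
    RBF similarity of a case to the control support vectors matches the
    mixture-averaged similarity of a held-out control, so a control-trained
    one-class boundary carries no case-control information, while the extra
    between-subpopulation variance makes the controls the heterogeneous
    class that a case-trained boundary excludes (see docs/methods.md).
    """

    affected_features: Sequence[tuple[str, str, str]] = ()
    effect_sizes: Sequence[float] = ()
    case_within_cov_scale: float = 1.0
    control_heterogeneity: float = 2.5
    covariate_coupling: tuple[float, float] = (0.0, 0.0)
    within_region_corr: float = 0.5

    def __post_init__(self) -> None:
        if len(self.affected_features) != len(self.effect_sizes):
            raise CohortConfigError("affected_features and effect_sizes must have equal length")
        if not np.all(np.isfinite(np.asarray(self.effect_sizes, dtype=float))) and self.effect_sizes:
            raise CohortConfigError("effect_sizes must be finite")
        if self.case_within_cov_scale <= 0:
            raise CohortConfigError("case_within_cov_scale must be positive")
        if self.control_heterogeneity < 0:
            raise CohortConfigError("control_heterogeneity must be non-negative")
        if not -1.0 < self.within_region_corr < 1.0:
            raise CohortConfigError("within_region_corr must lie in (-1, 1)")

    @classmethod
    def null(cls) -> "EffectSpec":
        """No group difference at all: identical case/control distributions."""
        return cls(case_within_cov_scale=1.0, control_heterogeneity=0.0)


def _truncnorm_rvs(mean, sd, lo, hi, size, rng):
    if hi <= lo:
        return np.full(size, lo, dtype=float)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_covariates(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-subject metadata with matched case/control covariates.

    Controls are labelled DD iff NVIQ < 70.  The fraction of matched pairs
    drawn from the DD stratum is ``control_mixture_weight``; within a pair
    the control's age and NVIQ equal the case's value plus a small jitter, so
    case and control marginal distributions coincide up to sampling error.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_pairs = min(config.n_cases, config.n_controls)
    n_total = config.n_cases + config.n_controls
    age_lo, age_hi = config.age_range_months
    nviq_lo, nviq_hi = config.nviq_range

    def draw_nviq(dd: np.ndarray) -> np.ndarray:
        out = np.empty(dd.shape, dtype=float)
        dd_hi = min(mio.DD_NVIQ_THRESHOLD - 1e-9, nviq_hi)
        nodd_lo = max(mio.DD_NVIQ_THRESHOLD, nviq_lo)
        if dd.any():
            if dd_hi <= nviq_lo:  # DD stratum empty within range: fall back to range
                out[dd] = _truncnorm_rvs(*NVIQ_MOMENTS, nviq_lo, nviq_hi, int(dd.sum()), rng)
            else:
                out[dd] = _truncnorm_rvs(*NVIQ_DD_MOMENTS, nviq_lo, dd_hi, int(dd.sum()), rng)
        if (~dd).any():
            if nodd_lo >= nviq_hi:
                out[~dd] = np.full(int((~dd).sum()), nviq_hi)
            else:
                out[~dd] = _truncnorm_rvs(*NVIQ_NODD_MOMENTS, nodd_lo, nviq_hi, int((~dd).sum()), rng)
        return out

    # Stratum assignment per designed pair (and per surplus subject).
    n_units = max(config.n_cases, config.n_controls)
    n_dd = int(round(config.control_mixture_weight * n_units))
    dd_stratum = np.zeros(n_units, dtype=bool)
    dd_stratum[rng.choice(n_units, size=n_dd, replace=False)] = True
    if min(mio.DD_NVIQ_THRESHOLD - 1e-9, nviq_hi) <= nviq_lo:
        dd_stratum[:] = False  # DD unreachable within the NVIQ range

    unit_age = _truncnorm_rvs(*AGE_MOMENTS, age_lo, age_hi, n_units, rng)
    unit_nviq = draw_nviq(dd_stratum)
    unit_sex = np.where(rng.random(n_units) < config.sex_ratio, "M", "F")

    def jitter(values, sd, lo, hi):
        return np.clip(values + rng.normal(0.0, sd, size=len(values)), lo, hi)

    rows = []
    width = max(2, len(str(n_units)))
    for i in range(config.n_cases):
        rows.append(
            dict(
                id=f"case{i + 1:0{width}d}",
                group="case",
                sex=unit_sex[i],
                age_months=float(unit_age[i]),
                nviq=float(unit_nviq[i]),
            )
        )
    for i in range(config.n_controls):
        age = jitter(unit_age[i : i + 1], 2.0, age_lo, age_hi)[0]
        if dd_stratum[i]:
            nviq = jitter(unit_nviq[i : i + 1], 3.0, nviq_lo, min(mio.DD_NVIQ_THRESHOLD - 1e-6, nviq_hi))[0]
        else:
            nviq = jitter(unit_nviq[i : i + 1], 3.0, max(mio.DD_NVIQ_THRESHOLD, nviq_lo), nviq_hi)[0]
        if i >= n_pairs:  # surplus control: independent covariates
            age = float(_truncnorm_rvs(*AGE_MOMENTS, age_lo, age_hi, 1, rng)[0])
        rows.append(
            dict(
                id=f"control{i + 1:0{width}d}",
                group="control",
                sex=unit_sex[i],
                age_months=float(age),
                nviq=float(nviq),
            )
        )
    table = pd.DataFrame(rows).set_index("id")
    table["y"] = table["group"].map(mio.GROUP_LABELS)
    table["dd"] = table["nviq"] < mio.DD_NVIQ_THRESHOLD
    assert len(table) == n_total
    return table[["group", "y", "sex", "age_months", "nviq", "dd"]]


def _region_chol(n_measures: int, corr: float) -> np.ndarray:
    block = np.full((n_measures, n_measures), corr, dtype=float)
    np.fill_diagonal(block, 1.0)
    try:
        return np.linalg.cholesky(block)
    except np.linalg.LinAlgError as exc:
        raise CohortConfigError(
            f"within-region covariance (corr={corr}) is not positive-definite"
        ) from exc


def heterogeneity_pattern(config: CohortConfig) -> np.ndarray:
    """Seed-fixed Rademacher sign pattern of the control-mixture separation."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x48455420)))
    return rng.choice([-1.0, 1.0], size=config.n_features)


def generate_features(
    subjects: pd.DataFrame,
    config: CohortConfig,
    effects: EffectSpec | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the feature matrix for an existing subject table.

    Standardized latent scores are drawn from the block-covariance Gaussian,
    modified per group (case shrinkage and mean shifts, control mixture
    shifts, covariate coupling) and finally mapped to native units.
    """
    if subjects.empty:
        raise CohortConfigError("subject table is empty")
    if effects is None:
        effects = EffectSpec()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x46454154)))
    index = config.feature_index
    names = index.names
    d = len(names)
    n = len(subjects)
    n_measures = len(config.measures)

    chol = _region_chol(n_measures, effects.within_region_corr)
    g = np.empty((n, d), dtype=float)
    pos = 0
    for hemi in ("lh", "rh"):
        for _region in config.regions:
            z = rng.standard_normal((n, n_measures))
            g[:, pos : pos + n_measures] = z @ chol.T
            pos += n_measures
        if config.include_global:
            n_glob = sum(1 for _, m in GLOBAL_ENTRIES if m in set(config.measures))
            g[:, pos : pos + n_glob] = rng.standard_normal((n, n_glob))
            pos += n_glob
    assert pos == d

    is_case = (subjects["group"] == "case").to_numpy()
    g[is_case] *= np.sqrt(effects.case_within_cov_scale)

    if effects.affected_features:
        shift = np.zeros(d)
        for (hemi, region, measure), size in zip(effects.affected_features, effects.effect_sizes):
            name = feature_name(hemi, region, measure)
            if name not in names:
                raise CohortConfigError(f"affected feature {name} not in the feature index")
            shift[names.index(name)] = size
        if len(effects.affected_features) > d:
            raise CohortConfigError("more affected features than features")
        g[is_case] += shift

    if effects.control_heterogeneity > 0:
        pattern = heterogeneity_pattern(config)
        half = 0.5 * effects.control_heterogeneity * pattern
        is_dd_control = (~is_case) & subjects["dd"].to_numpy()
        is_nodd_control = (~is_case) & ~subjects["dd"].to_numpy()
        g[is_dd_control] += half
        g[is_nodd_control] -= half

    c_age, c_nviq = effects.covariate_coupling
    if c_age or c_nviq:
        z_age = (subjects["age_months"].to_numpy() - AGE_MOMENTS[0]) / AGE_MOMENTS[1]
        z_nviq = (subjects["nviq"].to_numpy() - NVIQ_MOMENTS[0]) / NVIQ_MOMENTS[1]
        g += np.outer(c_age * z_age + c_nviq * z_nviq, np.ones(d))

    loc = np.empty(d)
    scale = np.empty(d)
    for k, (hemi, region, measure) in enumerate(index):
        if region in GLOBAL_SCALES:
            loc[k], scale[k] = GLOBAL_SCALES[region]
        else:
            loc[k], scale[k] = NATIVE_SCALES[measure]
    x = loc + scale * g
    matrix = pd.DataFrame(x, index=subjects.index.copy(), columns=names)
    matrix.index.name = "subject"
    matrix.attrs["feature_index"] = index
    return matrix


def write_cohort(
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    directory: str | Path,
    index: FeatureIndex | None = None,
) -> list[Path]:
    """Write the cohort in the exact dialect :mod:`occmap.io` reads back."""
    if len(features) != len(subjects) or not features.index.equals(subjects.index):
        raise CohortConfigError("features and subjects must share the same subject index")
    if index is None:
        index = features.attrs.get("feature_index")
    if index is None:
        raise CohortConfigError("a FeatureIndex is required to lay out the measure tables")
    if len(index) == 0:
        raise CohortConfigError("empty feature index")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    partials = mio.split_feature_matrix(features, index)
    paths = []
    for (hemi, measure), frame in partials.items():
        paths.append(mio.write_measure_table(frame, mio.measure_table_path(directory, hemi, measure)))
    paths.append(mio.write_subject_table(subjects, mio.subject_table_path(directory)))
    return paths


def simulate_cohort(
    config: CohortConfig, effects: EffectSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: covariates + features in one call, seeded from the config."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x434F4E56)))
    subjects = sample_covariates(config, rng)
    features = generate_features(subjects, config, effects, rng)
    return features, subjects
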