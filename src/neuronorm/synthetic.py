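"""Synthetic reference and case-control cohorts with known ground truth.

No individual-level morphometric dataset ships with this package, so every
downstream stage is exercised against simulated cohorts whose generative
process is fully known: each feature follows a smooth, sex-specific
fractional-polynomial age trajectory plus linear loadings on the three
global covariates (ICV, mean cortical thickness, mean surface area) and
i.i.d. Gaussian noise.  Case cohorts can carry per-feature additive effect
shifts, a global brain-age offset (features generated at chronological age +
offset while chronological age is stored unchanged), and clinical scores
with configurable linear dependence on the noise-free brain features.

Because the trajectories are themselves degree-2 fractional polynomials
with powers in the permitted set, the normative engine's model family is
correctly specified for these data, enabling exact parameter-recovery
tests.  The generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import atlas
from .normative import POWER_SET, fp_basis


@dataclass(frozen=True)
class TrajectorySpec:
    """Ground-truth generative model for one feature.

    ``coefficients`` maps sex -> [intercept, b1, b2] on the FP basis of
    ``powers``; ``covariate_loadings`` multiplies the generated global
    covariates (same loading vector for both sexes); ``noise_sd`` is the
    Gaussian residual sd in feature units (0 is the degenerate noiseless
    limit used in tests).
    """

    feature_name: str
    powers: tuple[float, float]
    coefficients: Mapping[str, np.ndarray]
    noise_sd: float
    covariate_loadings: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        for p in self.powers:
            if float(p) not in POWER_SET:
                raise ValueError(f"power {p} outside permitted set {POWER_SET}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for sex, c in self.coefficients.items():
            if len(np.asarray(c)) != 3:
                raise ValueError(
                    f"{self.feature_name}/{sex}: expected 3 FP coefficients "
                    f"(intercept + 2 terms), got {len(np.asarray(c))}"
                )


@dataclass(frozen=True)
class ClinicalModel:
    """Linear generative model for one clinical outcome.

    outcome = intercept + sum_f weights[f] * (noise-free feature value f)
              + N(0, noise_sd), truncated to [lower, upper] if given.
    """

    intercept: float
    weights: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    lower: float | None = None
    upper: float | None = None


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for one cohort."""

    n_subjects: int
    age_range: tuple[float, float]
    sex_ratio: float  # fraction female
    group: str  # one of {"reference", "case", "control"}
    seed: int
    effect_shift: Mapping[str, float] = field(default_factory=dict)
    brainage_offset: float = 0.0
    clinical_models: Mapping[str, ClinicalModel] = field(default_factory=dict)
    age_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be a positive integer")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if lo <= 0:
            raise ValueError("ages must be strictly positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.group not in ("reference", "case", "control"):
            raise ValueError(f"unknown group {self.group!r}")


def ground_truth_mean(
    trajectory: TrajectorySpec,
    age,
    sex: str,
    covariates: Sequence[float] | np.ndarray | None = None,
) -> np.ndarray | float:
    """Deterministic generative mean of a feature at (age, sex, covariates).

    Exported so recovery tests can compare fitted normative curves against
    the exact truth.  Raises for age <= 0 (log-power terms undefined).
    """
    basis = fp_basis(age, trajectory.powers)
    coef = np.asarray(trajectory.coefficients[sex], dtype=float)
    out = coef[0] + np.atleast_2d(basis) @ coef[1:]
    load = np.asarray(trajectory.covariate_loadings, dtype=float)
    if load.size:
        cov = np.zeros(load.size) if covariates is None else np.asarray(covariates, float)
        out = out + np.atleast_2d(cov.reshape(-1, load.size)) @ load
    return out if np.ndim(age) else float(out[0])


# ---------------------------------------------------------------------------
# Default ground-truth trajectory bank


def default_trajectories(seed: int = 7) -> dict[str, TrajectorySpec]:
    """Realistic trajectory bank for the 150 manifest features + 3 covariates.

    Shapes follow the broad strokes of lifespan morphometry: cortical
    thickness declines roughly log-linearly from childhood; surface area
    peaks in adolescence and declines slowly; subcortical volumes shrink
    gradually with age and scale with ICV; ICV plateaus after childhood and
    is larger in males.  Per-region magnitudes and noise levels are drawn
    once from a seeded generator so regions differ but the bank is fixed.
    """
    rng = np.random.default_rng(seed)
    bank: dict[str, TrajectorySpec] = {}

    # Global covariates (no loadings; generated first).
    bank["icv"] = TrajectorySpec(
        "icv",
        powers=(-2.0, -1.0),
        coefficients={
            "F": np.array([1.40e6, 3.0e5, -4.0e5]),
            "M": np.array([1.55e6, 3.0e5, -4.0e5]),
        },
        noise_sd=9.0e4,
    )
    bank["mean_thickness"] = TrajectorySpec(
        "mean_thickness",
        powers=(0.0, 0.0),
        coefficients={
            "F": np.array([3.35, -0.27, 0.012]),
            "M": np.array([3.33, -0.27, 0.012]),
        },
        noise_sd=0.09,
    )
    bank["mean_area"] = TrajectorySpec(
        "mean_area",
        powers=(0.0, 0.0),
        coefficients={
            "F": np.array([2400.0, 260.0, -44.0]),
            "M": np.array([2600.0, 260.0, -44.0]),
        },
        noise_sd=180.0,
    )

    for name in atlas.thickness_features():
        b0 = rng.uniform(1.2, 2.2)
        b1 = rng.uniform(-0.22, -0.10)
        b2 = rng.uniform(0.0, 0.012)
        dm = rng.uniform(-0.05, 0.05)
        load = np.array([0.0, rng.uniform(0.3, 0.7), 0.0])
        bank[name] = TrajectorySpec(
            name,
            powers=(0.0, 0.0),
            coefficients={
                "F": np.array([b0, b1, b2]),
                "M": np.array([b0 + dm, b1, b2]),
            },
            noise_sd=rng.uniform(0.07, 0.12),
            covariate_loadings=load,
        )

    for name in atlas.area_features():
        base = rng.uniform(250.0, 2800.0)
        b0 = 0.45 * base
        b1 = base * rng.uniform(0.08, 0.12)
        b2 = -base * rng.uniform(0.015, 0.022)
        load = np.array([0.0, 0.0, rng.uniform(0.2, 0.5) * base / 2700.0])
        bank[name] = TrajectorySpec(
            name,
            powers=(0.0, 0.0),
            coefficients={
                "F": np.array([b0, b1, b2]),
                "M": np.array([b0 * 1.05, b1, b2]),
            },
            noise_sd=base * rng.uniform(0.05, 0.09),
            covariate_loadings=load,
        )

    typical = {
        "thalamus": 7500.0,
        "caudate": 3800.0,
        "putamen": 5200.0,
        "pallidum": 1800.0,
        "hippocampus": 4200.0,
        "amygdala": 1700.0,
        "accumbens": 600.0,
    }
    for name in atlas.volume_features():
        structure = name.split("_")[1]
        base = typical[structure] * rng.uniform(0.95, 1.05)
        b0 = 0.65 * base
        b1 = -base * rng.uniform(0.002, 0.004)
        b2 = -base * rng.uniform(0.0, 1.0e-5)
        load = np.array([base * 0.35 / 1.45e6, 0.0, 0.0])
        bank[name] = TrajectorySpec(
            name,
            powers=(1.0, 2.0),
            coefficients={
                "F": np.array([b0, b1, b2]),
                "M": np.array([b0 * 1.03, b1, b2]),
            },
            noise_sd=base * rng.uniform(0.05, 0.08),
            covariate_loadings=load,
        )
    return bank


# ---------------------------------------------------------------------------
# Cohort generation


def _check_trajectories(
    trajectories: Mapping[str, TrajectorySpec], features: Sequence[str]
) -> None:
    for f in list(features) + list(atlas.COVARIATES):
        if f not in trajectories:
            raise ValueError(f"missing trajectory for declared feature {f!r}")


def _traj_mean(t: TrajectorySpec, ages: np.ndarray, sexes: np.ndarray) -> np.ndarray:
    basis = fp_basis(ages, t.powers)
    out = np.empty(len(ages))
    for sex in np.unique(sexes):
        m = sexes == sex
        coef = np.asarray(t.coefficients[sex], dtype=float)
        out[m] = coef[0] + basis[m] @ coef[1:]
    return out


def _sample_demographics(spec: CohortSpec, rng: np.random.Generator):
    n = spec.n_subjects
    if spec.age_sampler is not None:
        ages = np.asarray(spec.age_sampler(rng, n), dtype=float)
        if len(ages) != n or np.any(ages <= 0):
            raise ValueError("age_sampler must return n strictly positive ages")
    else:
        ages = rng.uniform(spec.age_range[0], spec.age_range[1], n)
    n_f = int(round(n * spec.sex_ratio))
    sexes = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sexes)
    return ages, sexes


def _generate_block(
    spec: CohortSpec,
    trajectories: Mapping[str, TrajectorySpec],
    features: Sequence[str],
    id_prefix: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One cohort block; returns (table, noise-free feature means)."""
    rng = np.random.default_rng(spec.seed)
    ages, sexes = _sample_demographics(spec, rng)
    eff_ages = ages + spec.brainage_offset
    if np.any(eff_ages <= 0):
        raise ValueError("brainage_offset drives effective age non-positive")

    # Global covariates first, then regional features loaded on them.
    cov_vals = {}
    cov_means = {}
    for c in atlas.COVARIATES:
        t = trajectories[c]
        mu = _traj_mean(t, eff_ages, sexes)
        cov_means[c] = mu
        cov_vals[c] = mu + rng.normal(0.0, t.noise_sd, spec.n_subjects)
    C = np.column_stack([cov_vals[c] for c in atlas.COVARIATES])

    data = {
        "subject_id": [f"{id_prefix}{i:05d}" for i in range(spec.n_subjects)],
        "age": ages,
        "sex": sexes,
        "group": spec.group,
    }
    means = {}
    for f in features:
        t = trajectories[f]
        mu = _traj_mean(t, eff_ages, sexes)
        if t.covariate_loadings.size:
            mu = mu + C @ np.asarray(t.covariate_loadings, dtype=float)
        mu = mu + float(spec.effect_shift.get(f, 0.0))
        means[f] = mu
        data[f] = mu + rng.normal(0.0, t.noise_sd, spec.n_subjects)

    mean_df = pd.DataFrame(means)
    for name in atlas.CLINICAL_COLUMNS:
        data[name] = np.full(spec.n_subjects, np.nan)
    if spec.clinical_models:
        for outcome, cm in spec.clinical_models.items():
            y = np.full(spec.n_subjects, float(cm.intercept))
            for f, w in cm.weights.items():
                if f not in means:
                    raise ValueError(f"clinical model weight on unknown feature {f!r}")
                y = y + w * means[f]
            y = y + rng.normal(0.0, cm.noise_sd, spec.n_subjects)
            y = np.clip(
                y,
                -np.inf if cm.lower is None else cm.lower,
                np.inf if cm.upper is None else cm.upper,
            )
            data[outcome] = y
    if spec.group == "case":
        duration = np.clip(rng.exponential(2.0, spec.n_subjects), 0.1, ages - 12.0)
        data["illness_duration"] = duration
        data["age_of_onset"] = ages - duration
        data["lithium"] = (rng.random(spec.n_subjects) < 0.4).astype(float)

    df = pd.DataFrame(data)
    cols = (
        list(atlas.METADATA_COLUMNS)
        + list(atlas.CLINICAL_COLUMNS)
        + list(atlas.COVARIATES)
        + list(features)
    )
    for c in atlas.COVARIATES:
        df[c] = cov_vals[c]
    return df[cols], mean_df


def make_reference_cohort(
    spec: CohortSpec,
    trajectories: Mapping[str, TrajectorySpec],
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate a healthy normative reference cohort.

    Feature values equal the ground-truth trajectory mean at each subject's
    age/sex plus the covariate loadings applied to the generated global
    covariates, plus Gaussian noise.  Fully determined by (spec, spec.seed).
    """
    if spec.group != "reference":
        raise ValueError("make_reference_cohort requires spec.group == 'reference'")
    if features is None:
        features = atlas.feature_manifest()
    _check_trajectories(trajectories, features)
    df, _ = _generate_block(spec, trajectories, features, id_prefix="ref_")
    return df


def make_study_cohort(
    case_spec: CohortSpec,
    control_spec: CohortSpec,
    trajectories: Mapping[str, TrajectorySpec],
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate a combined case + matched-control study cohort.

    Cases are generated at effective age = chronological age +
    ``brainage_offset`` (chronological age is stored), with ``effect_shift``
    added per feature; controls follow the reference process.
    """
    if case_spec.group != "case":
        raise ValueError("case_spec.group must be 'case'")
    if control_spec.group != "control":
        raise ValueError("control_spec.group must be 'control'")
    if features is None:
        features = atlas.feature_manifest()
    _check_trajectories(trajectories, features)
    bad = set(case_spec.effect_shift) - set(features)
    if bad:
        raise ValueError(f"effect_shift on unknown feature(s): {sorted(bad)}")
    cases, _ = _generate_block(case_spec, trajectories, features, id_prefix="case_")
    controls, _ = _generate_block(
        control_spec, trajectories, features, id_prefix="ctrl_"
    )
    overlap = set(cases["subject_id"]) & set(controls["subject_id"])
    if overlap:
        raise ValueError(f"overlapping subject identifiers across groups: {sorted(overlap)[:5]}")
    return pd.concat([cases, controls], ignore_index=True)


# ---------------------------------------------------------------------------
# Study-condition default specs


def default_clinical_models() -> dict[str, ClinicalModel]:
    """Clinically plausible outcome models for a stabilised first-episode
    mania sample: low residual mania (YMRS), mild depressive symptoms
    (MADRS), average-range IQ; by default none depends on brain features."""
    return {
        "ymrs": ClinicalModel(intercept=3.0, noise_sd=3.0, lower=0.0),
        "madrs": ClinicalModel(intercept=7.0, noise_sd=5.0, lower=0.0),
        "iq": ClinicalModel(intercept=108.0, noise_sd=10.0),
    }


def default_reference_spec(seed: int = 0, n_per_sex: int = 2000) -> CohortSpec:
    """Desk-scale stand-in for a large lifespan healthy reference sample."""
    return CohortSpec(
        n_subjects=2 * n_per_sex,
        age_range=(3.0, 90.0),
        sex_ratio=0.5,
        group="reference",
        seed=seed,
    )


def default_case_spec(
    seed: int = 1,
    brainage_offset: float = 0.0,
    effect_shift: Mapping[str, float] | None = None,
) -> CohortSpec:
    """First-episode mania-like cohort: n=83, ages 14-35."""
    return CohortSpec(
        n_subjects=83,
        age_range=(14.0, 35.0),
        sex_ratio=0.5,
        group="case",
        seed=seed,
        brainage_offset=brainage_offset,
        effect_shift=dict(effect_shift or {}),
        clinical_models=default_clinical_models(),
    )


def default_control_spec(seed: int = 2) -> CohortSpec:
    """Matched healthy comparison cohort: n=61, ages 16-37."""
    return CohortSpec(
        n_subjects=61,
        age_range=(16.0, 37.0),
        sex_ratio=0.5,
        group="control",
        seed=seed,
        clinical_models={"iq": ClinicalModel(intercept=108.0, noise_sd=10.0)},
    )
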