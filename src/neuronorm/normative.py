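"""Sex-specific fractional-polynomial normative models of brain morphometry.

Each regional measure is modelled, separately per sex, as an ordinary
least-squares fit of

    value ~ 1 + age^p1 + age^p2 + ICV + mean_thickness + mean_area

where the degree-2 fractional-polynomial (FP) powers (p1, p2) are drawn from
the conventional set {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, with the conventions
age^0 = ln(age) and, for a repeated power p1 = p2, a second term
age^p1 * ln(age).  The power pair is selected per feature by 5-fold
cross-validated mean squared error over all 36 pairs; the final model is
refit on the full reference sample and its root-mean-square residual (RMSE)
is the denominator of the deviation z-score

    z = (observed - predicted) / RMSE.

A positive z means the measure is larger than the normative expectation at
that age, sex and global covariate profile; |z| > 1.96 marks the tails
outside the central 95% band.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import atlas

#: Permitted fractional-polynomial powers (power 0 denotes ln age).
POWER_SET: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: All 36 degree-2 power pairs, lexicographically ordered (ties in model
#: selection resolve toward the earlier, i.e. lexicographically smaller, pair).
POWER_PAIRS: tuple[tuple[float, float], ...] = tuple(
    combinations_with_replacement(POWER_SET, 2)
)


def fp_basis(age, powers: Sequence[float]) -> np.ndarray:
    """Evaluate the two fractional-polynomial basis terms at ``age``.

    Returns an array with a trailing axis of length 2 holding
    ``(age^p1, age^p2)``; ``age^0`` means ``ln(age)``, and for a repeated
    power the second term is ``age^p1 * ln(age)``.
    """
    x = np.asarray(age, dtype=float)
    if np.any(x <= 0):
        raise ValueError("age must be strictly positive (log-power terms undefined)")
    p1, p2 = (float(p) for p in powers)
    for p in (p1, p2):
        if p not in POWER_SET:
            raise ValueError(f"power {p} outside permitted set {POWER_SET}")
    t1 = np.log(x) if p1 == 0.0 else x**p1
    if p2 == p1:
        t2 = t1 * np.log(x)
    elif p2 == 0.0:
        t2 = np.log(x)
    else:
        t2 = x**p2
    return np.stack([t1, t2], axis=-1)


def fp_design(
    age, powers: Sequence[float], covariates: np.ndarray | None = None
) -> np.ndarray:
    """Full design matrix ``[1 | FP basis | covariates]`` for one power pair."""
    basis = np.atleast_2d(fp_basis(age, powers))
    cols = [np.ones((basis.shape[0], 1)), basis]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != basis.shape[0]:
            cov = cov.reshape(basis.shape[0], -1)
        cols.append(cov)
    return np.hstack(cols)


@dataclass(frozen=True)
class NormativeModel:
    """A fitted per-feature, per-sex normative model.

    ``coefficients`` is ordered [intercept, fp term 1, fp term 2,
    *covariates in covariate_names order]; ``rmse`` is the root mean squared
    residual of the full-sample refit, in the feature's units.
    """

    feature_name: str
    sex: str
    powers: tuple[float, float]
    coefficients: np.ndarray
    rmse: float
    training_n: int
    covariate_names: tuple[str, ...]
    age_range: tuple[float, float]

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        expected = 3 + len(self.covariate_names)
        if len(self.coefficients) != expected:
            raise ValueError(
                f"coefficient vector length {len(self.coefficients)} != {expected}"
            )

    def predict(self, subjects: pd.DataFrame) -> np.ndarray:
        """Normative mean of the feature for each row of ``subjects``."""
        missing = [c for c in self.covariate_names if c not in subjects.columns]
        if missing:
            raise ValueError(f"missing covariate column(s): {missing}")
        age = subjects["age"].to_numpy(dtype=float)
        lo, hi = self.age_range
        if np.any((age < lo) | (age > hi)):
            warnings.warn(
                f"{self.feature_name}/{self.sex}: ages outside training range "
                f"[{lo:.1f}, {hi:.1f}]; predictions are extrapolated",
                stacklevel=2,
            )
        cov = subjects[list(self.covariate_names)].to_numpy(dtype=float)
        X = fp_design(age, self.powers, cov)
        return X @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "feature_name": self.feature_name,
            "sex": self.sex,
            "powers": list(self.powers),
            "coefficients": [float(c) for c in self.coefficients],
            "rmse": float(self.rmse),
            "training_n": int(self.training_n),
            "covariate_names": list(self.covariate_names),
            "age_range": [float(a) for a in self.age_range],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormativeModel":
        return cls(
            feature_name=d["feature_name"],
            sex=d["sex"],
            powers=tuple(d["powers"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            rmse=float(d["rmse"]),
            training_n=int(d["training_n"]),
            covariate_names=tuple(d["covariate_names"]),
            age_range=tuple(d["age_range"]),
        )


@dataclass
class ModelBank:
    """Collection of normative models keyed by (feature, sex)."""

    covariate_names: tuple[str, ...]
    models: dict[tuple[str, str], NormativeModel] = field(default_factory=dict)

    def get(self, feature: str, sex: str) -> NormativeModel:
        try:
            return self.models[(feature, sex)]
        except KeyError:
            raise KeyError(f"no normative model for feature={feature!r}, sex={sex!r}")

    @property
    def features(self) -> list[str]:
        return sorted({f for f, _ in self.models})

    @property
    def sexes(self) -> list[str]:
        return sorted({s for _, s in self.models})

    def save(self, path) -> None:
        payload = {
            "covariate_names": list(self.covariate_names),
            "models": [m.to_dict() for m in self.models.values()],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ModelBank":
        with open(path) as fh:
            payload = json.load(fh)
        bank = cls(covariate_names=tuple(payload["covariate_names"]))
        for d in payload["models"]:
            m = NormativeModel.from_dict(d)
            bank.models[(m.feature_name, m.sex)] = m
        return bank


def _sorted_sex_slice(
    reference: pd.DataFrame, sex: str, features: Sequence[str], covariate_names
) -> pd.DataFrame:
    if sex not in atlas.SEXES:
        raise ValueError(f"sex must be one of {atlas.SEXES}, got {sex!r}")
    sub = reference.loc[reference["sex"] == sex]
    if sub.empty:
        raise ValueError(f"no reference subjects with sex={sex!r}")
    missing = [f for f in features if f not in sub.columns]
    if missing:
        raise ValueError(f"feature column(s) absent from reference table: {missing}")
    missing_cov = [c for c in covariate_names if c not in sub.columns]
    if missing_cov:
        raise ValueError(f"missing covariate column(s): {missing_cov}")
    # Fold assignment and least-squares inputs are taken over subjects sorted
    # by id, so results do not depend on the row order of the input table.
    return sub.sort_values("subject_id", kind="mergesort")


def fit_normative_bank(
    reference: pd.DataFrame,
    features: Sequence[str] | None = None,
    sexes: Iterable[str] = atlas.SEXES,
    covariate_names: Sequence[str] = atlas.COVARIATES,
    n_folds: int = 5,
) -> ModelBank:
    """Fit sex-specific FP normative models for every feature at once.

    All features of one sex share the same design matrices (the regressors
    are age terms and global covariates), so for each of the 36 power pairs a
    single multi-response least-squares solve per cross-validation fold
    scores every feature simultaneously.
    """
    if features is None:
        features = atlas.feature_manifest()
    features = list(features)
    covariate_names = tuple(covariate_names)
    n_coef = 3 + len(covariate_names)
    bank = ModelBank(covariate_names=covariate_names)
    for sex in sexes:
        sub = _sorted_sex_slice(reference, sex, features, covariate_names)
        n = len(sub)
        if n < 10 * n_coef:
            raise ValueError(
                f"need at least {10 * n_coef} {sex} reference subjects for a "
                f"{n_coef}-coefficient model, got {n}"
            )
        age = sub["age"].to_numpy(dtype=float)
        if np.ptp(age) == 0:
            raise ValueError("degenerate design: constant age in reference sample")
        cov = sub[list(covariate_names)].to_numpy(dtype=float)
        Y = sub[features].to_numpy(dtype=float)
        folds = np.arange(n) % n_folds
        cv_mse = np.empty((len(POWER_PAIRS), len(features)))
        designs = []
        for i, pair in enumerate(POWER_PAIRS):
            X = fp_design(age, pair, cov)
            # rank check on unit-norm columns: the raw columns differ by many
            # orders of magnitude (mm vs mm^3), which defeats the default tol
            norms = np.linalg.norm(X, axis=0)
            if np.any(norms == 0) or np.linalg.matrix_rank(X / norms) < X.shape[1]:
                raise ValueError(
                    f"degenerate (rank-deficient) design for power pair {pair}"
                )
            designs.append(X)
            sse = np.zeros(len(features))
            for k in range(n_folds):
                tr = folds != k
                beta, *_ = np.linalg.lstsq(X[tr], Y[tr], rcond=None)
                resid = Y[~tr] - X[~tr] @ beta
                sse += (resid**2).sum(axis=0)
            cv_mse[i] = sse / n
        best = np.argmin(cv_mse, axis=0)  # first minimum = lexicographic tie-break
        age_range = (float(age.min()), float(age.max()))
        for i in np.unique(best):
            cols = np.flatnonzero(best == i)
            X = designs[i]
            beta, *_ = np.linalg.lstsq(X, Y[:, cols], rcond=None)
            resid = Y[:, cols] - X @ beta
            rmse = np.sqrt((resid**2).mean(axis=0))
            for j, c in enumerate(cols):
                m = NormativeModel(
                    feature_name=features[c],
                    sex=sex,
                    powers=POWER_PAIRS[i],
                    coefficients=beta[:, j].copy(),
                    rmse=float(rmse[j]),
                    training_n=n,
                    covariate_names=covariate_names,
                    age_range=age_range,
                )
                bank.models[(features[c], sex)] = m
    return bank


def fit_normative_model(
    reference: pd.DataFrame,
    feature: str,
    sex: str,
    covariate_names: Sequence[str] = atlas.COVARIATES,
    n_folds: int = 5,
) -> NormativeModel:
    """Fit one per-feature, per-sex normative model (see fit_normative_bank)."""
    bank = fit_normative_bank(
        reference,
        features=[feature],
        sexes=[sex],
        covariate_names=covariate_names,
        n_folds=n_folds,
    )
    return bank.get(feature, sex)


def compute_z(model: NormativeModel, subjects: pd.DataFrame) -> pd.Series:
    """Deviation z-scores (observed - predicted) / RMSE for one model.

    Positive z: the observed measure is larger than the normative mean.
    """
    if model.rmse <= 0:
        raise ValueError("model RMSE must be strictly positive to define z")
    if "sex" in subjects.columns:
        other = subjects.loc[subjects["sex"] != model.sex]
        if len(other):
            raise ValueError(
                f"{len(other)} subject(s) do not match model sex {model.sex!r}"
            )
    if model.feature_name not in subjects.columns:
        raise ValueError(f"feature column {model.feature_name!r} absent")
    pred = model.predict(subjects)
    obs = subjects[model.feature_name].to_numpy(dtype=float)
    return pd.Series((obs - pred) / model.rmse, index=subjects.index, name=model.feature_name)


def score_cohort(
    bank: ModelBank, subjects: pd.DataFrame, features: Sequence[str] | None = None
) -> pd.DataFrame:
    """Score every subject on every feature with the sex-matched model.

    Returns a subjects x features table of z-scores indexed like ``subjects``.
    """
    if features is None:
        features = bank.features if bank.features else atlas.feature_manifest()
    z = pd.DataFrame(index=subjects.index, columns=list(features), dtype=float)
    for sex in subjects["sex"].unique():
        rows = subjects.loc[subjects["sex"] == sex]
        for f in features:
            z.loc[rows.index, f] = compute_z(bank.get(f, sex), rows).to_numpy()
    return z
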