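"""Global brain-age-gap (G-brainAGE) estimation and clinical correlates.

A sex-specific brain-age model is a ridge-penalised linear regression of
chronological age on the standardised 150-feature morphometric vector plus
the three global covariates, trained on a healthy reference cohort with the
penalty chosen by internal cross-validation.  For a new subject,

    G-brainAGE = predicted brain age - chronological age,

so positive gaps indicate apparently accelerated and negative gaps
apparently delayed age-related structural change.

Regression-to-the-mean makes raw gaps negatively correlated with age
(predictions shrink toward the training mean), so an age-bias correction is
fitted by default: the raw gap is regressed on a low-order polynomial of age
in out-of-fold reference predictions and that trend is subtracted from every
subsequent gap.  A cubic (degree 3) is the default because a linear map
from morphometry to age leaves a curved mean-gap-versus-age profile —
feature trajectories are steepest in youth — and a purely linear
residualisation would leave a residual age trend exactly in the young age
bands where clinical cohorts concentrate; ``bias_degree=1`` restores the
plain linear variant.

Clinical-correlate helpers cover the analyses run on the gap table: Pearson
correlations with symptom/cognition scores, an independent-samples t-test
between medication subgroups, and an OLS moderation model with a
sex x age-of-onset interaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import Ridge, RidgeCV
from sklearn.model_selection import KFold, cross_val_predict

from . import atlas

ALPHA_GRID = np.logspace(-1.0, 5.0, 13)


@dataclass
class BrainAgeModel:
    sex: str
    feature_names: tuple[str, ...]
    center: np.ndarray  # per-feature training mean
    scale: np.ndarray  # per-feature training sd
    coef: np.ndarray
    intercept: float
    alpha: float
    age_range: tuple[float, float]
    #: polynomial coefficients of the mean gap-vs-age trend, highest degree
    #: first (numpy polyval convention); None disables correction
    bias_poly: np.ndarray | None = None

    def predict_age(self, subjects: pd.DataFrame) -> np.ndarray:
        """Raw (uncorrected) predicted brain age per subject."""
        missing = [f for f in self.feature_names if f not in subjects.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing[:10]}")
        X = subjects[list(self.feature_names)].to_numpy(dtype=float)
        return (X - self.center) / self.scale @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "feature_names": list(self.feature_names),
            "center": [float(v) for v in self.center],
            "scale": [float(v) for v in self.scale],
            "coef": [float(v) for v in self.coef],
            "intercept": float(self.intercept),
            "alpha": float(self.alpha),
            "age_range": [float(a) for a in self.age_range],
            "bias_poly": None
            if self.bias_poly is None
            else [float(v) for v in self.bias_poly],
        }

    @classmethod
    def from_dict(cls, d) -> "BrainAgeModel":
        return cls(
            sex=d["sex"],
            feature_names=tuple(d["feature_names"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            alpha=float(d["alpha"]),
            age_range=tuple(d["age_range"]),
            bias_poly=None
            if d.get("bias_poly") is None
            else np.asarray(d["bias_poly"], dtype=float),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "BrainAgeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_brainage(
    reference: pd.DataFrame,
    sex: str,
    feature_names: Sequence[str] | None = None,
    alphas: np.ndarray = ALPHA_GRID,
    bias_correction: bool = True,
    bias_degree: int = 3,
    n_folds: int = 5,
    seed: int = 0,
) -> BrainAgeModel:
    """Fit a sex-specific ridge brain-age model on a healthy reference."""
    if feature_names is None:
        feature_names = atlas.feature_manifest() + list(atlas.COVARIATES)
    feature_names = tuple(feature_names)
    sub = reference.loc[reference["sex"] == sex].sort_values(
        "subject_id", kind="mergesort"
    )
    n = len(sub)
    if n < max(60, 10 * n_folds):
        raise ValueError(f"too few {sex} reference subjects ({n}) for a stable fit")
    missing = [f for f in feature_names if f not in sub.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing[:10]}")
    X = sub[list(feature_names)].to_numpy(dtype=float)
    age = sub["age"].to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - center) / scale

    ridge_cv = RidgeCV(alphas=alphas).fit(Xs, age)  # efficient LOO-GCV
    alpha = float(ridge_cv.alpha_)
    model = BrainAgeModel(
        sex=sex,
        feature_names=feature_names,
        center=center,
        scale=scale,
        coef=np.asarray(ridge_cv.coef_, dtype=float),
        intercept=float(ridge_cv.intercept_),
        alpha=alpha,
        age_range=(float(age.min()), float(age.max())),
    )
    if bias_correction:
        cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        oof = cross_val_predict(Ridge(alpha=alpha), Xs, age, cv=cv)
        gap = oof - age
        model.bias_poly = np.polyfit(age, gap, bias_degree)
    return model


def compute_gap(model: BrainAgeModel, subjects: pd.DataFrame) -> pd.DataFrame:
    """Per-subject G-brainAGE table.

    Columns: subject_id, age, sex, predicted_age, gap_raw, gap.  ``gap`` is
    bias-corrected when the model carries a correction, otherwise equals
    ``gap_raw``.
    """
    mismatched = subjects.loc[subjects["sex"] != model.sex]
    if len(mismatched):
        raise ValueError(
            f"{len(mismatched)} subject(s) do not match model sex {model.sex!r}"
        )
    pred = model.predict_age(subjects)
    age = subjects["age"].to_numpy(dtype=float)
    gap_raw = pred - age
    if model.bias_poly is not None:
        gap = gap_raw - np.polyval(model.bias_poly, age)
    else:
        gap = gap_raw.copy()
    return pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "age": age,
            "sex": model.sex,
            "predicted_age": pred,
            "gap_raw": gap_raw,
            "gap": gap,
        },
        index=subjects.index,
    )


def compute_gap_by_sex(
    models: dict[str, BrainAgeModel], subjects: pd.DataFrame
) -> pd.DataFrame:
    """Route each subject to the sex-matched model and stack the gap tables."""
    parts = []
    for sex, model in models.items():
        rows = subjects.loc[subjects["sex"] == sex]
        if len(rows):
            parts.append(compute_gap(model, rows))
    return pd.concat(parts).loc[subjects.index[subjects["sex"].isin(models)]]


# ---------------------------------------------------------------------------
# Clinical correlates


def pearson_corr_test(x, y) -> tuple[float, float]:
    """Pearson r with the exact two-sided t-test p on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a sample Pearson r at sample size n (t on n-2 df)."""
    if not -1.0 < r < 1.0:
        return 0.0
    if n < 3:
        raise ValueError("need n >= 3")
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def group_t_test(values, flag, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided independent-samples t-test between flag==True/False groups.

    Equal-variance (Student) by default; ``equal_var=False`` gives Welch.
    """
    values = np.asarray(values, dtype=float)
    flag = np.asarray(flag, dtype=bool)
    a, b = values[flag], values[~flag]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def moderation_regression(gap, age_of_onset, sex) -> pd.DataFrame:
    """OLS of gap on age-of-onset, sex and their interaction.

    ``sex`` may be string labels or numeric codes; any affine recoding leaves
    the interaction t-test unchanged.  Returns a coefficient table with
    columns coef, se, t, p indexed by term.
    """
    gap = np.asarray(gap, dtype=float)
    onset = np.asarray(age_of_onset, dtype=float)
    sex = np.asarray(sex)
    if sex.dtype.kind in "OU":
        levels = sorted(set(sex))
        if len(levels) != 2:
            raise ValueError(f"sex must be two-level, got {levels}")
        sex = (sex == levels[1]).astype(float)
    else:
        sex = sex.astype(float)
    X = np.column_stack([np.ones_like(gap), onset, sex, onset * sex])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design (is sex constant, or onset degenerate?)")
    if len(gap) <= X.shape[1]:
        raise ValueError("need more subjects than model terms")
    fit = sm.OLS(gap, X).fit()
    return pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        },
        index=["intercept", "age_of_onset", "sex", "sex_x_age_of_onset"],
    )
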