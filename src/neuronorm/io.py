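"""Validated loading and saving of the per-subject feature table."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def load_feature_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Load and validate a subjects x (metadata + covariates + 150 features) table.

    Checks: required metadata columns; exactly the 150 manifest feature
    columns (missing or unexpected columns are reported by name); the three
    global covariates; strictly positive numeric ages; sex in {F, M}; unique
    subject ids; numeric, complete feature cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))

    manifest = atlas.feature_manifest()
    known = (
        set(atlas.METADATA_COLUMNS)
        | set(atlas.CLINICAL_COLUMNS)
        | set(atlas.COVARIATES)
        | set(manifest)
    )
    missing_meta = [c for c in atlas.METADATA_COLUMNS if c not in df.columns]
    if missing_meta:
        raise ValueError(f"missing metadata column(s): {missing_meta}")
    missing_cov = [c for c in atlas.COVARIATES if c not in df.columns]
    if missing_cov:
        raise ValueError(f"missing global covariate column(s): {missing_cov}")
    missing = [c for c in manifest if c not in df.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    extra = [c for c in df.columns if c not in known]
    if extra:
        raise ValueError(f"unexpected column(s): {extra}")

    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicated subject_id(s): {dup[:10]}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any() or (ages <= 0).any():
        bad = df.loc[ages.isna() | (ages <= 0), "subject_id"].tolist()
        raise ValueError(f"non-numeric or non-positive age for subject(s): {bad[:10]}")
    df["age"] = ages
    bad_sex = set(df["sex"].unique()) - set(atlas.SEXES)
    if bad_sex:
        raise ValueError(f"sex values outside {atlas.SEXES}: {sorted(bad_sex)}")

    for col in list(atlas.COVARIATES) + manifest:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValueError(
                f"non-numeric or missing cell at row {row}, column {col!r}"
            )
        df[col] = vals
    return df


def save_feature_table(df: pd.DataFrame, path, delimiter: str | None = None) -> None:
    path = Path(path)
    df.to_csv(path, sep=_delimiter_for(path, delimiter), index=False)
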