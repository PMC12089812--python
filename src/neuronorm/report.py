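"""End-to-end workbench run: simulate/load, fit, score, analyse, report.

``run_report`` executes the full pipeline in stage order — reference and
study tables (loaded or simulated), normative model bank, study z-scores,
extreme-deviation tables and group comparisons, outcome prediction and
classification, brain-age gaps and clinical correlates — writing CSV/JSON
artifacts plus a manifest (seed, config hash, package versions, stage
timings) sufficient to reproduce every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas, brainage, deviations, io, normative, prediction, synthetic

log = logging.getLogger("neuronorm")


@dataclass
class RunConfig:
    outdir: str = "neuronorm_out"
    seed: int = 1
    # inputs: either paths to existing tables or simulate=True
    reference_path: str | None = None
    study_path: str | None = None
    simulate: bool = True
    ref_n_per_sex: int = 2000
    case_n: int = 83
    control_n: int = 61
    case_age_range: tuple[float, float] = (14.0, 35.0)
    control_age_range: tuple[float, float] = (16.0, 37.0)
    brainage_offset: float = 0.0
    effect_shift: dict = field(default_factory=dict)
    # thresholds (study defaults)
    z_threshold: float = 1.96
    fdr_q: float = 0.05
    # cross-validation / learners
    folds: int = 10
    n_perm: int = 100_000
    ridge_penalty: float = 1.0
    svm_c: float = 1.0
    outcomes: tuple[str, ...] = ("ymrs", "madrs", "iq")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, v)
        cfg.case_age_range = tuple(cfg.case_age_range)
        cfg.control_age_range = tuple(cfg.control_age_range)
        cfg.outcomes = tuple(cfg.outcomes)
        return cfg


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class _Stage:
    """Times a pipeline stage and rewraps failures with the stage name."""

    def __init__(self, name: str, timings: dict):
        self.name = name
        self.timings = timings

    def __enter__(self):
        log.info("stage %s: start", self.name)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        self.timings[self.name] = round(dt, 3)
        if exc is not None:
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.2fs", self.name, dt)


def run_report(config: RunConfig) -> dict:
    """Run the full pipeline; returns a dict of output paths and summaries."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    rng_seed = int(config.seed)
    outputs: dict = {}

    with _Stage("inputs", timings):
        trajectories = synthetic.default_trajectories()
        if config.simulate:
            ref_spec = synthetic.default_reference_spec(
                seed=rng_seed, n_per_sex=config.ref_n_per_sex
            )
            case_spec = synthetic.CohortSpec(
                n_subjects=config.case_n,
                age_range=config.case_age_range,
                sex_ratio=0.5,
                group="case",
                seed=rng_seed + 1,
                brainage_offset=config.brainage_offset,
                effect_shift=dict(config.effect_shift),
                clinical_models=synthetic.default_clinical_models(),
            )
            control_spec = synthetic.CohortSpec(
                n_subjects=config.control_n,
                age_range=config.control_age_range,
                sex_ratio=0.5,
                group="control",
                seed=rng_seed + 2,
                clinical_models={
                    "iq": synthetic.ClinicalModel(intercept=108.0, noise_sd=10.0)
                },
            )
            reference = synthetic.make_reference_cohort(ref_spec, trajectories)
            study = synthetic.make_study_cohort(case_spec, control_spec, trajectories)
            io.save_feature_table(reference, outdir / "reference.csv")
            io.save_feature_table(study, outdir / "study.csv")
        else:
            reference = io.load_feature_table(config.reference_path)
            study = io.load_feature_table(config.study_path)
        outputs["n_reference"] = len(reference)
        outputs["n_study"] = len(study)

    with _Stage("fit_normative", timings):
        bank = normative.fit_normative_bank(reference)
        bank.save(outdir / "models.json")

    with _Stage("score", timings):
        z = normative.score_cohort(bank, study)
        z_out = pd.concat(
            [study[list(atlas.METADATA_COLUMNS)].reset_index(drop=True),
             z.reset_index(drop=True)],
            axis=1,
        )
        z_out.to_csv(outdir / "zscores.csv", index=False)

    with _Stage("deviations", timings):
        groups = study["group"]
        regions = deviations.compare_extreme_proportions(
            z, groups, threshold=config.z_threshold, q=config.fdr_q
        )
        regions.to_csv(outdir / "region_extremes.csv", index=False)
        burden = deviations.subject_burden(z, threshold=config.z_threshold)
        burden.insert(0, "subject_id", study["subject_id"].to_numpy())
        burden.to_csv(outdir / "burden.csv", index=False)
        burden_cmp = deviations.burden_comparison(
            z, groups, threshold=config.z_threshold
        )
        (outdir / "burden_comparison.json").write_text(json.dumps(burden_cmp, indent=2))
        outputs["n_significant_regions"] = int(regions["significant"].sum())
        outputs["burden_comparison"] = burden_cmp

    with _Stage("predict", timings):
        cases = study.loc[study["group"] == "case"]
        case_z = z.loc[cases.index]
        results = []
        for outcome in config.outcomes:
            y = cases[outcome].to_numpy(dtype=float)
            for feature_set, M in (
                ("observed", cases[atlas.feature_manifest()].to_numpy(dtype=float)),
                ("zscore", case_z.to_numpy(dtype=float)),
            ):
                res = prediction.permutation_significance(
                    M,
                    y,
                    n_perm=config.n_perm,
                    folds=config.folds,
                    penalty=config.ridge_penalty,
                    seed=rng_seed,
                    outcome=outcome,
                    feature_set=feature_set,
                )
                results.append(res.to_dict())
        (outdir / "prediction_results.json").write_text(json.dumps(results, indent=2))
        outputs["prediction"] = results

    with _Stage("classify", timings):
        labels = (study["group"] == "case").astype(int).to_numpy()
        cls_out = {}
        for feature_set, M in (
            ("observed", study[atlas.feature_manifest()].to_numpy(dtype=float)),
            ("zscore", z.to_numpy(dtype=float)),
        ):
            res = prediction.svm_cv_auc(
                M, labels, folds=config.folds, C=config.svm_c, seed=rng_seed
            )
            cls_out[feature_set] = res.auc
            pd.DataFrame({"fpr": res.fpr, "tpr": res.tpr}).to_csv(
                outdir / f"roc_{feature_set}.csv", index=False
            )
        (outdir / "classification.json").write_text(json.dumps(cls_out, indent=2))
        outputs["classification_auc"] = cls_out

    with _Stage("brainage", timings):
        models = {
            sex: brainage.fit_brainage(reference, sex, seed=rng_seed)
            for sex in atlas.SEXES
        }
        for sex, m in models.items():
            m.save(outdir / f"brainage_{sex}.json")
        gaps = brainage.compute_gap_by_sex(models, study)
        gaps = gaps.join(study[["group"] + list(atlas.CLINICAL_COLUMNS)])
        gaps.to_csv(outdir / "gaps.csv", index=False)
        case_gaps = gaps.loc[gaps["group"] == "case"]
        correlates: dict = {
            "mean_gap_case": float(case_gaps["gap"].mean()),
            "sd_gap_case": float(case_gaps["gap"].std()),
            "mean_gap_control": float(
                gaps.loc[gaps["group"] == "control", "gap"].mean()
            ),
        }
        for var in ("ymrs", "madrs", "iq", "illness_duration", "age_of_onset"):
            sub = case_gaps.dropna(subset=[var])
            if len(sub) >= 3 and np.ptp(sub[var].to_numpy(dtype=float)) > 0:
                r, p = brainage.pearson_corr_test(sub["gap"], sub[var])
                correlates[f"r_gap_{var}"] = r
                correlates[f"p_gap_{var}"] = p
        lith = case_gaps.dropna(subset=["lithium"])
        if 2 <= lith["lithium"].sum() <= len(lith) - 2:
            t, p = brainage.group_t_test(lith["gap"], lith["lithium"] > 0)
            correlates["lithium_t"] = t
            correlates["lithium_p"] = p
        mod = case_gaps.dropna(subset=["age_of_onset"])
        if mod["sex"].nunique() == 2:
            table = brainage.moderation_regression(
                mod["gap"], mod["age_of_onset"], mod["sex"]
            )
            correlates["moderation"] = {
                term: {"coef": float(row["coef"]), "p": float(row["p"])}
                for term, row in table.iterrows()
            }
        (outdir / "brainage_correlates.json").write_text(
            json.dumps(correlates, indent=2)
        )
        outputs["brainage"] = correlates

    import sklearn

    manifest = {
        "seed": rng_seed,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "versions": {
            "neuronorm": __import__("neuronorm").__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "stage_seconds": timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    outputs["manifest"] = manifest
    outputs["outdir"] = str(outdir)
    return outputs
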