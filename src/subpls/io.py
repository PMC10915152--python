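"""File formats, pipeline configuration and the end-to-end orchestration.

Formats (all UTF-8 text, header rows required, ``.`` decimal point):

* per-subject ROI time series — TSV, header = region labels plus an optional
  ``fd`` column, one row per frame;
* FC table — TSV, one row per subject, first column ``subject_id``, then one
  ``regionA|regionB`` column per unique pair;
* subject table — CSV with ``subject_id``, the 37 named symptom items,
  covariates and outcome columns;
* model bundle — a directory of ``model.json`` plus TSV matrices for the
  saliences (and loadings/scores when available);
* reports — JSON.

Every file written here carries a provenance header (config hash + seed):
a ``# subpls ...`` comment line in TSVs, a ``meta`` object in JSON.  A full
pipeline run with the same configuration and seed reproduces its outputs
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import prediction as pred
from . import replication as repl
from . import resampling as resamp
from .pls import SYMPTOM_ITEMS, DataBlocks, PlsModel, compute_scores, fit_pls
from .synthetic import OutcomeConfig, SyntheticConfig, generate_cohort

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_fc_table",
    "write_fc_table",
    "read_subject_table",
    "blocks_from_tables",
    "save_model_bundle",
    "load_model_bundle",
    "write_json_report",
    "run_pipeline",
]

logger = logging.getLogger("subpls")

_COMMENT = "#"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Single configuration object driving every pipeline stage."""

    seed: int = 0
    B_perm: int = 5000
    B_boot: int = 5000
    alpha: float = 0.05
    bsr_threshold: float = 2.0
    high_threshold: float = 3.0
    top_fraction: float = 0.05
    standardize: str = "zscore"
    residualize_covariates: bool = False
    scrub_fd_threshold: float = 0.5
    scrub_augment_neighbors: bool = False
    p_enter: float = 0.05
    p_remove: float = 0.10
    # data source: either a synthetic-cohort spec ...
    simulate: dict | None = None
    replication_simulate: dict | None = None
    # ... or paths to prepared tables
    fc_path: str | None = None
    subjects_path: str | None = None
    replication_fc_path: str | None = None
    replication_subjects_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("bsr_threshold", "high_threshold", "top_fraction",
                     "B_perm", "B_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _provenance(config: PipelineConfig | None) -> str:
    if config is None:
        return f"{_COMMENT} subpls"
    return f"{_COMMENT} subpls config={config.digest()} seed={config.seed}"


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    """Strict reader: comment headers skipped, ragged rows named by line."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    rows, width, header_line = [], None, None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(_COMMENT):
            continue
        fields = line.split(sep)
        if width is None:
            width, header_line = len(fields), lineno
        elif len(fields) != width:
            raise ValueError(
                f"{path.name}: line {lineno} has {len(fields)} fields, "
                f"expected {width} (header at line {header_line})"
            )
        rows.append(fields)
    if not rows or len(rows) == 1:
        raise ValueError(f"{path.name}: no data rows")
    df = pd.DataFrame(rows[1:], columns=rows[0])
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        # keep text columns as text; otherwise require clean numeric parsing
        if converted.notna().any() or (df[col] == "").all():
            non_numeric = converted.isna() & (df[col] != "") & df[col].str.lower().ne("nan")
            if not non_numeric.any():
                df[col] = converted
    return df


def write_timeseries_tsv(ts: conn.RoiTimeSeries, path: str | Path,
                         config: PipelineConfig | None = None) -> None:
    path = Path(path)
    cols = dict(zip(ts.region_labels, ts.data.T))
    if ts.fd is not None:
        cols["fd"] = ts.fd
    body = pd.DataFrame(cols).to_csv(sep="\t", index=False, float_format="%.10g")
    path.write_text(_provenance(config) + f" subject={ts.subject_id}\n" + body)


def read_timeseries_tsv(path: str | Path, subject_id: str | None = None) -> conn.RoiTimeSeries:
    path = Path(path)
    df = _read_table(path, sep="\t")
    fd = df.pop("fd").to_numpy(dtype=float) if "fd" in df.columns else None
    return conn.RoiTimeSeries(
        subject_id=subject_id or path.stem,
        data=df.to_numpy(dtype=float),
        region_labels=list(df.columns),
        fd=fd,
    )


def write_fc_table(profiles: list[conn.ConnectivityProfile], path: str | Path,
                   config: PipelineConfig | None = None) -> None:
    if not profiles:
        raise ValueError("no FC profiles to write")
    ref = profiles[0].pair_labels
    for prof in profiles[1:]:
        if prof.pair_labels != ref:
            raise ValueError(f"subject {prof.subject_id}: pair ordering differs")
    df = pd.DataFrame(
        [p.values for p in profiles],
        columns=[f"{a}|{b}" for a, b in ref],
    )
    df.insert(0, "subject_id", [p.subject_id for p in profiles])
    body = df.to_csv(sep="\t", index=False, float_format="%.12g")
    Path(path).write_text(_provenance(config) + "\n" + body)


def read_fc_table(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, sep="\t")
    if "subject_id" not in df.columns:
        raise ValueError("FC table must have a subject_id column")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def read_subject_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = _read_table(path, sep=",")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"subject table missing required columns: {', '.join(missing)}")
    if "subject_id" in df.columns:
        df["subject_id"] = df["subject_id"].astype(str)
    return df


def blocks_from_tables(fc: pd.DataFrame, subjects: pd.DataFrame,
                       item_names: list[str] | None = None,
                       covariate_names: list[str] | None = None) -> DataBlocks:
    """Join an FC table and a subject table on subject_id into DataBlocks."""
    item_names = list(item_names) if item_names else list(SYMPTOM_ITEMS)
    missing = [c for c in item_names if c not in subjects.columns]
    if missing:
        raise ValueError(f"subject table missing symptom items: {', '.join(missing[:5])}")
    merged = fc.merge(subjects, on="subject_id", how="inner", validate="one_to_one")
    if merged.empty:
        raise ValueError("no overlapping subject_ids between FC and subject tables")
    edge_cols = [c for c in fc.columns if c != "subject_id"]
    cov = None
    if covariate_names:
        cov = merged[list(covariate_names)].to_numpy(dtype=float)
    return DataBlocks(
        X=merged[edge_cols].to_numpy(dtype=float),
        Y=merged[item_names].to_numpy(dtype=float),
        subject_ids=merged["subject_id"].tolist(),
        x_names=edge_cols,
        y_names=item_names,
        covariates=cov,
        covariate_names=list(covariate_names) if covariate_names else None,
    )


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------


def _write_matrix_tsv(mat: np.ndarray, names: list[str] | None, path: Path,
                      config: PipelineConfig | None) -> None:
    mat = np.atleast_2d(mat)
    df = pd.DataFrame(mat, columns=[f"LC{j + 1}" for j in range(mat.shape[1])])
    if names is not None:
        df.insert(0, "name", names)
    Path(path).write_text(_provenance(config) + "\n"
                          + df.to_csv(sep="\t", index=False, float_format="%.17g"))


def _read_matrix_tsv(path: Path) -> tuple[np.ndarray, list[str] | None]:
    df = _read_table(path, sep="\t")
    names = df.pop("name").astype(str).tolist() if "name" in df.columns else None
    return df.to_numpy(dtype=float), names


def save_model_bundle(model: PlsModel, out_dir: str | Path,
                      config: PipelineConfig | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "meta": {"format": "subpls-model-bundle/1",
                 "config": config.digest() if config else None,
                 "seed": config.seed if config else None},
        "k": model.k,
        "n_train": model.n_train,
        "standardize": model.standardize,
        "singular_values": model.singular_values.tolist(),
        "explained_cov": model.explained_cov.tolist(),
        "x_mean": model.x_mean.tolist(),
        "x_sd": model.x_sd.tolist(),
        "y_mean": model.y_mean.tolist(),
        "y_sd": model.y_sd.tolist(),
        "x_names": model.x_names,
        "y_names": model.y_names,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=1))
    _write_matrix_tsv(model.fc_saliences, model.x_names, out / "fc_saliences.tsv", config)
    _write_matrix_tsv(model.mood_saliences, model.y_names, out / "mood_saliences.tsv", config)
    if model.fc_loadings is not None:
        _write_matrix_tsv(model.fc_loadings, model.x_names, out / "fc_loadings.tsv", config)
        _write_matrix_tsv(model.mood_loadings, model.y_names, out / "mood_loadings.tsv", config)


def load_model_bundle(in_dir: str | Path) -> PlsModel:
    src = Path(in_dir)
    meta = json.loads((src / "model.json").read_text())
    V, x_names = _read_matrix_tsv(src / "fc_saliences.tsv")
    U, y_names = _read_matrix_tsv(src / "mood_saliences.tsv")
    model = PlsModel(
        fc_saliences=V,
        mood_saliences=U,
        singular_values=np.asarray(meta["singular_values"]),
        explained_cov=np.asarray(meta["explained_cov"]),
        x_mean=np.asarray(meta["x_mean"]),
        x_sd=np.asarray(meta["x_sd"]),
        y_mean=np.asarray(meta["y_mean"]),
        y_sd=np.asarray(meta["y_sd"]),
        standardize=meta["standardize"],
        n_train=meta["n_train"],
        x_names=meta["x_names"] or x_names,
        y_names=meta["y_names"] or y_names,
    )
    if (src / "fc_loadings.tsv").exists():
        model.fc_loadings, _ = _read_matrix_tsv(src / "fc_loadings.tsv")
        model.mood_loadings, _ = _read_matrix_tsv(src / "mood_loadings.tsv")
    return model


def write_json_report(obj: dict, path: str | Path,
                      config: PipelineConfig | None = None) -> None:
    payload = {"meta": {"config": config.digest() if config else None,
                        "seed": config.seed if config else None}}
    payload.update(obj)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=1, default=_default))


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out
        return wrapper
    return deco


def _synthetic_config(spec: dict, seed: int) -> SyntheticConfig:
    spec = dict(spec)
    outcome = spec.pop("outcome", None)
    spec.setdefault("seed", seed)
    if outcome is not None:
        spec["outcome"] = OutcomeConfig(**outcome)
    return SyntheticConfig(**spec)


@_stage("load")
def _load_cohort(config: PipelineConfig, out: Path, which: str = "main"):
    if which == "main":
        sim, fc_path, subj_path, seed = (config.simulate, config.fc_path,
                                         config.subjects_path, config.seed)
    else:
        sim, fc_path, subj_path, seed = (config.replication_simulate,
                                         config.replication_fc_path,
                                         config.replication_subjects_path,
                                         config.seed + 10_000)
    if sim is not None:
        blocks, subjects, truth = generate_cohort(_synthetic_config(sim, seed))
        subjects.to_csv(out / f"subjects_{which}.csv", index=False)
        return blocks, subjects, truth
    if fc_path is None or subj_path is None:
        raise ValueError(f"no {which}-cohort source: set simulate or fc/subjects paths")
    fc = read_fc_table(fc_path)
    subjects = read_subject_table(subj_path, required=["subject_id"])
    cov_names = [c for c in ("age", "sex", "education_years", "bmi", "head_motion")
                 if c in subjects.columns]
    blocks = blocks_from_tables(fc, subjects, covariate_names=cov_names or None)
    return blocks, subjects, None


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage in order; returns the result summary.

    Order: load (or simulate) → fit PLSC → permutation test → bootstrap
    reliability + edge selection → subject scores → optional replication →
    outcome prediction.  All randomness derives from ``config.seed``; a
    re-run with the same configuration reproduces the outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.digest(), "seed": config.seed, "stages": []}

    blocks, subjects, _truth = _load_cohort(config, out, "main")
    summary["stages"].append("load")
    summary["n_subjects"] = blocks.n

    model = _stage("fit")(fit_pls)(
        blocks, standardize=config.standardize,
        residualize_covariates=config.residualize_covariates,
    )
    save_model_bundle(model, out / "model", config)
    summary["stages"].append("fit")
    summary["k"] = model.k
    summary["explained_cov_lc1"] = float(model.explained_cov[0])

    perm = _stage("permutation")(resamp.permutation_test)(
        blocks, B=config.B_perm, seed=config.seed, standardize=config.standardize,
    )
    n_sig = int((perm.p_values < config.alpha).sum())
    write_json_report(
        {"p_values": perm.p_values, "observed_singulars": perm.observed_singulars,
         "B": perm.B, "n_significant": n_sig},
        out / "permutation.json", config,
    )
    summary["stages"].append("permutation")
    summary["p_lc1"] = float(perm.p_values[0])
    summary["n_significant_components"] = n_sig

    boot = _stage("bootstrap")(resamp.bootstrap)(
        blocks, B=config.B_boot, seed=config.seed + 1, standardize=config.standardize,
    )
    edges = resamp.select_edges(
        boot.bsr_fc[:, 0],
        model.fc_loadings[:, 0],
        boot.fc_loading_ci_low[:, 0],
        boot.fc_loading_ci_high[:, 0],
        labels=model.x_names,
        bsr_threshold=config.bsr_threshold,
        high_threshold=config.high_threshold,
        top_fraction=config.top_fraction,
    )
    _write_matrix_tsv(boot.bsr_fc, model.x_names, out / "bsr_fc.tsv", config)
    _write_matrix_tsv(boot.bsr_mood, model.y_names, out / "bsr_mood.tsv", config)
    write_json_report(
        {"reliable_edges": edges.reliable_edges, "robust_edges": edges.robust_edges,
         "B": boot.B, "n_redrawn": boot.n_redrawn},
        out / "edges.json", config,
    )
    summary["stages"].append("bootstrap")
    summary["n_reliable_edges"] = len(edges.reliable_edges)
    summary["n_robust_edges"] = len(edges.robust_edges)

    scores = _stage("scores")(compute_scores)(model, blocks)
    score_df = pd.DataFrame(
        {
            "subject_id": blocks.subject_ids or range(blocks.n),
            "fc_score": scores.fc_scores[:, 0],
            "mood_score": scores.mood_scores[:, 0],
        }
    )
    (out / "scores.tsv").write_text(
        _provenance(config) + "\n"
        + score_df.to_csv(sep="\t", index=False, float_format="%.12g")
    )
    summary["stages"].append("scores")

    if config.replication_simulate is not None or config.replication_fc_path is not None:
        blocks_b, _, _ = _load_cohort(config, out, "replication")
        model_b = _stage("replication")(fit_pls)(blocks_b, standardize=config.standardize)
        report = repl.compare_models(model, model_b, blocks_b)
        write_json_report(asdict(report), out / "replication.json", config)
        summary["stages"].append("replication")
        summary["fc_loading_similarity"] = report.fc_loading_similarity
        summary["mood_loading_similarity"] = report.mood_loading_similarity

    if subjects is not None and "post_hrsd" in subjects.columns:
        table = _stage("prediction")(_run_prediction)(
            config, subjects, score_df, out)
        summary["stages"].append("prediction")
        summary.update(table)

    write_json_report(summary, out / "summary.json", config)
    return summary


def _run_prediction(config: PipelineConfig, subjects: pd.DataFrame,
                    score_df: pd.DataFrame, out: Path) -> dict:
    outcomes = pred.outcome_table(subjects)
    data = outcomes.merge(score_df[["subject_id", "fc_score"]], on="subject_id")
    for extra in ("age_of_onset", "episode_duration"):
        if extra in subjects.columns:
            data = data.merge(subjects[["subject_id", extra]], on="subject_id")
    candidates = [c for c in pred.DEFAULT_CANDIDATES if c in data.columns]
    report: dict = {"n_completers": len(outcomes),
                    "remission_rate_pct": float(100 * outcomes["remission"].mean()),
                    "response_rate_pct": float(100 * outcomes["response"].mean())}
    for outcome, family in (("pct_reduction", "linear"), ("post_hrsd", "linear"),
                            ("response", "logistic"), ("remission", "logistic")):
        work = data.copy()
        if family == "logistic":
            work[outcome] = work[outcome].astype(int)
            if work[outcome].nunique() < 2:
                report[f"{outcome}_skipped"] = "single outcome class"
                continue
        fitted = pred.stepwise_fit(work, outcome, candidates, family=family,
                                   p_enter=config.p_enter, p_remove=config.p_remove)
        entry = {
            "selected": fitted.selected_predictors,
            "coefficients": fitted.coefficients,
            "p_values": fitted.p_values,
        }
        if family == "logistic" and fitted.selected_predictors:
            auc, acc, curve = pred.evaluate_classifier(fitted)
            entry.update(odds_ratios=fitted.odds_ratios, auc=auc, accuracy=acc)
            curve_body = curve.to_csv(sep="\t", index=False, float_format="%.8g")
            (out / f"roc_{outcome}.tsv").write_text(
                _provenance(config) + "\n" + curve_body)
        report[outcome] = entry
    write_json_report(report, out / "prediction.json", config)
    flat = {}
    for key in ("response", "remission"):
        if isinstance(report.get(key), dict) and "auc" in report[key]:
            flat[f"auc_{key}"] = report[key]["auc"]
    flat["remission_rate_pct"] = report["remission_rate_pct"]
    return flat
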