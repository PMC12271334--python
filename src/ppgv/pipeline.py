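"""End-to-end orchestration: simulate/ingest → label → features → fit →
evaluate → compare → profile, with a run manifest for reproducibility.

A run is fully determined by its :class:`RunConfig` (including the seed);
two runs with the same resolved config produce byte-identical CSV artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_io, features, labeling, modeling, synthetic, evaluation, vulnerability

logger = logging.getLogger(__name__)

PACKAGE_VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Resolved configuration for one analysis run."""

    # input
    input_mode: str = "synthetic_scenario"  # or "shanghai_dir"
    shanghai_dir: str | None = None
    scenario: str = "mixed"
    n_participants: int = 30
    days: int = 14
    meals_per_day_mean: float = 3.23
    sampling_min: float = 15.0
    cgm_drop_rate: float = 0.0
    gram_blank_rate: float = 0.0
    # outcome
    window_min: float = 120.0
    anchor_tol_min: float = 20.0
    min_points: int = 5
    min_coverage_min: float = 100.0
    min_obs: int = 20
    # modeling
    train_frac: float = 0.70
    k_folds: int = 4
    threshold: float = 0.5
    fast_grid: bool = False
    seed: int = 0
    # output
    out_dir: str | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class PipelineResult:
    """In-memory artifacts of a full run."""

    config: RunConfig
    observations: pd.DataFrame
    exclusions: pd.DataFrame
    evaluation: pd.DataFrame
    comparison: dict
    gain_profiles: list
    shap_profiles: list
    heterogeneity: dict | None
    truths: list = field(default_factory=list)
    fits: dict = field(default_factory=dict)  # (pid, schema) -> FitResult
    matrices: dict = field(default_factory=dict)  # (pid, schema) -> PersonMatrix
    manifest: dict = field(default_factory=dict)


def _load_records(config: RunConfig):
    if config.input_mode == "synthetic_scenario":
        pairs = synthetic.generate_cohort(
            config.n_participants,
            scenario=config.scenario,
            seed=config.seed,
            days=config.days,
            meals_per_day_mean=config.meals_per_day_mean,
            sampling_min=config.sampling_min,
            cgm_drop_rate=config.cgm_drop_rate,
            gram_blank_rate=config.gram_blank_rate,
        )
        return [r for r, _ in pairs], [t for _, t in pairs]
    if config.input_mode == "shanghai_dir":
        if not config.shanghai_dir:
            raise ValueError("shanghai_dir input mode requires shanghai_dir")
        d = Path(config.shanghai_dir)
        paths = sorted(list(d.glob("*.xlsx")) + list(d.glob("*.csv")))
        records = []
        for p in paths:
            if "summary" in p.stem.lower():
                continue
            try:
                records.append(core_io.read_shanghai_participant(p))
            except core_io.FormatError as e:
                logger.warning("stage=ingest participant=%s skipped: %s", p.stem, e)
        return records, []
    raise ValueError(f"unknown input_mode {config.input_mode!r}")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; write artifacts when out_dir is set."""
    records, truths = _load_records(config)
    logger.info("stage=input n_participants=%d", len(records))

    # --- outcome labeling + eligibility
    cohort_obs = {}
    for rec in records:
        cohort_obs[rec.participant_id] = labeling.label_participant(
            rec,
            window_min=config.window_min,
            anchor_tol_min=config.anchor_tol_min,
            min_points=config.min_points,
            min_coverage_min=config.min_coverage_min,
        )
    included, exclusion_log = labeling.apply_eligibility(cohort_obs, min_obs=config.min_obs)
    logger.info("stage=eligibility included=%d excluded=%d", len(included), len(exclusion_log))

    obs_df = labeling.observations_frame(cohort_obs)
    excl_df = pd.DataFrame(exclusion_log, columns=["participant_id", "reason"])

    rec_by_id = {r.participant_id: r for r in records}
    grid = modeling.FAST_GRID if config.fast_grid else modeling.HyperGrid()

    # --- per-person fits, both schemas
    fits: dict[tuple[str, str], modeling.FitResult] = {}
    matrices: dict[tuple[str, str], features.PersonMatrix] = {}
    eval_rows = []
    pairs: dict[str, tuple[float | None, float | None]] = {}
    for pid, obs in included.items():
        rec = rec_by_id[pid]
        f1s: dict[str, float | None] = {}
        for schema in features.SCHEMAS:
            matrix = features.assemble_matrix(
                obs, rec.meals, rec.meds, schema, train_frac=config.train_frac
            )
            fit = modeling.grid_search_fit(
                matrix, grid=grid, seed=config.seed, k=config.k_folds, threshold=config.threshold
            )
            pred = fit.predict(matrix.X.iloc[matrix.test_idx], threshold=config.threshold)
            ev = evaluation.score(matrix.y[matrix.test_idx], pred, pid, schema)
            f1s[schema] = ev.f1
            fits[(pid, schema)] = fit
            matrices[(pid, schema)] = matrix
            eval_rows.append(
                {
                    "participant_id": pid,
                    "schema": schema,
                    "n_train": len(matrix.train_idx),
                    "n_test": len(matrix.test_idx),
                    "tp": ev.tp,
                    "fp": ev.fp,
                    "tn": ev.tn,
                    "fn": ev.fn,
                    "precision": ev.precision,
                    "recall": ev.recall,
                    "f1": ev.f1,
                    "fallback_majority": fit.fallback_majority,
                    "chosen_params": json.dumps(fit.chosen_params, sort_keys=True),
                }
            )
        pairs[pid] = (f1s["low_burden"], f1s["high_burden"])
        logger.info("stage=fit participant=%s f1_low=%s f1_high=%s", pid, f1s["low_burden"], f1s["high_burden"])

    eval_df = pd.DataFrame(eval_rows)
    comparison = evaluation.subgroup_and_test(pairs) if pairs else {}

    # --- vulnerability profiles of each participant's best model
    gain_profiles = []
    shap_profiles = []
    for pid, (lo, hi) in pairs.items():
        schema, best = evaluation.best_of_two(lo, hi)
        if best is None:
            continue
        if schema == "tie":
            schema = "high_burden"  # richer feature set on exact ties
        fit = fits[(pid, schema)]
        cmap = features.feature_category_map(schema)
        gain_profiles.append(vulnerability.gain_profile(fit, cmap))
        shap_profiles.append(vulnerability.shap_profile(fit, matrices[(pid, schema)].X, cmap))
    heterogeneity = vulnerability.cohort_heterogeneity(gain_profiles) if gain_profiles else None

    result = PipelineResult(
        config=config,
        observations=obs_df,
        exclusions=excl_df,
        evaluation=eval_df,
        comparison=comparison,
        gain_profiles=gain_profiles,
        shap_profiles=shap_profiles,
        heterogeneity=heterogeneity,
        truths=truths,
        fits=fits,
        matrices=matrices,
    )
    result.manifest = _build_manifest(result)
    if config.out_dir:
        write_artifacts(result, Path(config.out_dir))
    return result


def _comparison_jsonable(comparison: dict) -> dict:
    def conv(o):
        if isinstance(o, dict):
            return {k: conv(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [conv(v) for v in o]
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return o

    return conv(comparison)


def _build_manifest(result: PipelineResult) -> dict:
    comp = result.comparison
    return {
        "package_version": PACKAGE_VERSION,
        "config": asdict(result.config),
        "n_participants_input": int(result.observations["participant_id"].nunique()) if len(result.observations) else 0,
        "n_included": int(result.evaluation["participant_id"].nunique()) if len(result.evaluation) else 0,
        "n_excluded": int(len(result.exclusions)),
        "exclusion_reasons": result.exclusions["reason"].value_counts().to_dict() if len(result.exclusions) else {},
        "n_observations": int(len(result.observations)),
        "n_usable_observations": int(result.observations["usable"].sum()) if len(result.observations) else 0,
        "subgroup_counts": comp.get("subgroup_counts", {}),
        "best_f1_mean": comp.get("best_f1_mean"),
        "artifacts": ["observations.csv", "exclusions.csv", "evaluation.csv", "comparison.json", "profiles.csv", "shap_profiles.csv", "heterogeneity.csv", "manifest.json"],
    }


def write_artifacts(result: PipelineResult, out_dir: Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write_csv(name: str, df: pd.DataFrame) -> None:
        p = out_dir / name
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p

    _write_csv("observations.csv", result.observations)
    _write_csv("exclusions.csv", result.exclusions)
    _write_csv("evaluation.csv", result.evaluation)
    _write_csv("profiles.csv", vulnerability.profiles_frame(result.gain_profiles) if result.gain_profiles else pd.DataFrame())
    _write_csv("shap_profiles.csv", vulnerability.profiles_frame(result.shap_profiles) if result.shap_profiles else pd.DataFrame())
    if result.heterogeneity is not None:
        _write_csv("heterogeneity.csv", result.heterogeneity["table"])
    (out_dir / "comparison.json").write_text(json.dumps(_comparison_jsonable(result.comparison), indent=1, sort_keys=True))
    paths["comparison.json"] = out_dir / "comparison.json"

    manifest = dict(result.manifest)
    manifest["artifact_sha256"] = {
        name: hashlib.sha256(p.read_bytes()).hexdigest() for name, p in sorted(paths.items())
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest.json"] = out_dir / "manifest.json"
    return paths
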