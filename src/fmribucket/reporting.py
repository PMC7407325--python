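"""Symptom-correlation analysis, report writers and the end-to-end driver.

``run_pipeline`` executes the whole analysis on one scan day: obtain a
cohort (synthetic generation or on-disk t-maps/tables), extract
atlas-region voxel counts, screen for multicollinearity, run the
iterative bucket-of-models build, compute the consensus curve and the
label-shuffle significance test, and correlate symptom-severity scores
with the selected regions per group.  All artifacts are written to a
versioned output directory as plain-text tables (TSV/CSV/JSON/YAML); the
run log records the seed, a hash of the resolved configuration, and
per-stage wall-clock timings for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bucket import BucketConfig, fast_models, iterate_build, split_cohort
from .consensus import consensus_curve, shuffle_test
from .features import FeatureTable, build_feature_table
from .screen import screen_features
from .synthetic import SyntheticCohortSpec, generate_atlas, generate_cohort, SYMPTOM_NAMES

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "featurize", "screen", "build", "consensus", "shuffle", "symptoms"]

DEFAULT_CONFIG = {
    "seed": 0,
    "day": 1,
    "t_threshold": 3.17,
    "screen_threshold": 0.9,
    "synthetic": {},          # SyntheticCohortSpec overrides
    "mode": "table",          # "table" or "maps"
    "bucket": {},             # BucketConfig overrides
    "fast_bucket": False,     # use the reduced three-model bucket
    "shuffle_reps": 0,        # 0 disables the permutation stage
    "out_dir": None,
}


def symptom_region_correlation(
    table: FeatureTable, selected: list[str], group: str
) -> pd.DataFrame:
    """Pearson r of each symptom-severity score against each selected region.

    Rows are the nine severity items, columns the selected regions,
    computed over the subjects of one group.  Constant columns give NaN
    entries (logged), never an error.
    """
    missing = [r for r in selected if r not in table.counts.columns]
    if missing:
        raise ValueError(f"selected regions absent from table: {missing}")
    members = table.groups == group
    if members.sum() == 0:
        raise ValueError(f"group {group!r} absent from table")
    if members.sum() < 3:
        raise ValueError(f"group {group!r} has fewer than 3 members")
    symptoms = [s for s in SYMPTOM_NAMES if s in table.metadata.columns]
    if not symptoms:
        raise ValueError("no symptom-severity columns in metadata")
    sub_counts = table.counts.loc[members, selected].astype(float)
    sub_sympt = table.metadata.loc[members, symptoms].astype(float)

    out = np.full((len(symptoms), len(selected)), np.nan)
    for i, s in enumerate(symptoms):
        ys = sub_sympt[s].to_numpy()
        if ys.std() == 0:
            logger.info("symptom %s constant within group %s; correlations undefined", s, group)
            continue
        for j, r in enumerate(selected):
            xs = sub_counts[r].to_numpy()
            if xs.std() == 0:
                logger.info("region %s constant within group %s; correlation undefined", r, group)
                continue
            out[i, j] = np.corrcoef(xs, ys)[0, 1]
    return pd.DataFrame(out, index=symptoms, columns=selected)


def correlation_difference(mat_b: pd.DataFrame, mat_a: pd.DataFrame) -> pd.DataFrame:
    """Element-wise difference of two labelled correlation matrices (b - a).

    Missing entries propagate; mismatched row or column labels are an
    error rather than a silent reindex.
    """
    if list(mat_b.index) != list(mat_a.index) or list(mat_b.columns) != list(mat_a.columns):
        raise ValueError("correlation matrices have mismatched labels")
    return mat_b - mat_a


def _resolve_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping or a path to a YAML file")
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    resolved = {**DEFAULT_CONFIG, **config}
    if resolved["day"] not in (1, 2):
        raise ValueError("day must be 1 or 2")
    if resolved["mode"] not in ("table", "maps"):
        raise ValueError("mode must be 'table' or 'maps'")
    return resolved


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config, out_dir=None):
    """Run the full analysis for one scan day and write the report bundle.

    ``config`` is a mapping (or YAML path) following ``DEFAULT_CONFIG``.
    Returns a dict with the key metrics and artifact paths.  Given the
    same config and seed, all artifacts except ``run_log.json`` (which
    holds wall-clock timings) are byte-identical across runs.
    """
    cfg = _resolve_config(config)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    out = Path(cfg["out_dir"]) if cfg["out_dir"] else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    seed = int(cfg["seed"])
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(stage):
        nonlocal t0
        now = time.perf_counter()
        timings[stage] = round(now - t0, 4)
        t0 = now

    # --- simulate ---------------------------------------------------------
    spec = SyntheticCohortSpec(**{**cfg["synthetic"], "seed": seed})
    atlas = generate_atlas(spec.n_regions, spec.grid_shape, seed=seed)
    cohort = generate_cohort(spec, atlas, mode=cfg["mode"], day=cfg["day"])
    tick("simulate")

    # --- featurize --------------------------------------------------------
    if cfg["mode"] == "maps":
        table = build_feature_table(
            cohort.maps, atlas, t_thresh=cfg["t_threshold"], metadata=cohort.metadata
        )
    else:
        table = cohort.table
    tick("featurize")

    # --- screen (on the model-build split) --------------------------------
    bucket_kwargs = dict(cfg["bucket"])
    if cfg["fast_bucket"] and "models" not in bucket_kwargs:
        bucket_kwargs["models"] = fast_models(seed)
    bconfig = BucketConfig(**{**bucket_kwargs, "seed": seed})
    train_idx, test_idx = split_cohort(
        table, bconfig.split_ratio, seed=seed, stratify=bconfig.stratify
    )
    train_scr, test_scr, screen_report = screen_features(
        table.counts.loc[train_idx], table.counts.loc[test_idx],
        threshold=cfg["screen_threshold"],
    )
    screened = table.with_counts(
        pd.concat([train_scr, test_scr]).loc[table.counts.index]
    )
    tick("screen")

    # --- build ------------------------------------------------------------
    outcome = iterate_build(screened, bconfig, seed=seed, split=(train_idx, test_idx))
    tick("build")

    # --- consensus --------------------------------------------------------
    curve = consensus_curve(
        outcome.final_result, table.groups.loc[test_idx], positive=bconfig.positive_label
    )
    tick("consensus")

    # --- shuffle test -----------------------------------------------------
    perm = None
    if cfg["shuffle_reps"] > 0:
        perm = shuffle_test(
            screened, bconfig, n_reps=int(cfg["shuffle_reps"]), seed=seed,
            observed_outcome=outcome,
        )
    tick("shuffle")

    # --- symptom correlations ----------------------------------------------
    selected = [f for f in outcome.final_features if f in table.counts.columns]
    symptom = {}
    if selected and all(s in table.metadata.columns for s in SYMPTOM_NAMES[:1]):
        mat_a = symptom_region_correlation(table, selected, "CFS")
        mat_b = symptom_region_correlation(table, selected, "GWI")
        symptom = {"CFS": mat_a, "GWI": mat_b, "difference": correlation_difference(mat_b, mat_a)}
    tick("symptoms")

    result = outcome.final_result
    final_table = pd.DataFrame(
        {
            "feature": result.features_used,
            "rf_importance": (
                result.rf_importances.reindex(result.features_used)
                if result.rf_importances is not None else np.nan
            ),
            "rf_importance_se": (
                result.rf_importance_se.reindex(result.features_used)
                if result.rf_importance_se is not None else np.nan
            ),
            "svm_coef": (
                result.svm_coef.reindex(result.features_used)
                if result.svm_coef is not None else np.nan
            ),
            "logistic_coef": (
                result.logistic_coef.reindex(result.features_used)
                if result.logistic_coef is not None else np.nan
            ),
            "day": cfg["day"],
        }
    ).reset_index(drop=True)

    report = {
        "seed": seed,
        "day": cfg["day"],
        "n_subjects": table.n_subjects,
        "n_features_initial": len(table.features),
        "n_features_screened": screened.counts.shape[1],
        "n_features_final": len(outcome.final_features),
        "final_features": list(outcome.final_features),
        "converged": outcome.converged,
        "termination": outcome.termination,
        "model_accuracies": dict(result.accuracies),
        "mean_accuracy": curve.mean_accuracy,
        "sd_accuracy": curve.sd_accuracy,
        "n_flagged_pairs": len(screen_report.flagged_pairs),
        "p_value": perm.p_value if perm is not None else None,
    }

    if out is not None:
        table.counts.to_csv(out / "feature_table.tsv", sep="\t")
        table.metadata.to_csv(out / "metadata.tsv", sep="\t")
        _write_json(out / "screen_report.json", screen_report.to_json_dict())
        with open(out / "iteration_log.jsonl", "w") as fh:
            for entry in outcome.log:
                fh.write(json.dumps(entry, sort_keys=True, default=_json_default) + "\n")
        final_table.to_csv(out / "final_features.tsv", sep="\t", index=False)
        curve.table.to_csv(out / "consensus_curve.csv", index=False)
        _write_json(out / "consensus_curve.json", curve.to_json_dict())
        if perm is not None:
            _write_json(out / "permutation.json", perm.to_json_dict())
        for name, mat in symptom.items():
            mat.to_csv(out / f"symptom_correlation_{name}.csv")
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        # the output path is provenance, not configuration: it lives in the
        # run log so the resolved config stays identical across re-runs
        resolved = plain({k: v for k, v in cfg.items() if k != "out_dir"})
        with open(out / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(resolved, fh, sort_keys=True)
        cfg_hash = hashlib.sha256(
            yaml.safe_dump(resolved, sort_keys=True).encode()
        ).hexdigest()
        _write_json(
            out / "run_log.json",
            {
                "seed": seed,
                "out_dir": str(out),
                "config_sha256": cfg_hash,
                "stage_order": STAGE_ORDER,
                "timings_s": timings,
                "converged": outcome.converged,
            },
        )
        _write_json(out / "report.json", report)
        report["out_dir"] = str(out)

    return report
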