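"""Agreement-threshold consensus statistics and the label-shuffle test.

Each of the M models votes on each test subject; the consensus segment at
agreement threshold k is the set of subjects predicted positive by at
least k models.  Per segment we report how many subjects were selected and
the precision (fraction of selected who are truly positive — the segment
"accuracy"), sensitivity, specificity and the false discovery rate
(FDR = 1 - precision).  Significance of the whole build is assessed by a
permutation test that shuffles group labels and re-runs the entire
iterative build, comparing the observed statistic (minimum per-model test
accuracy by default) against the null distribution with the add-one rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bucket import BucketConfig, BucketResult, BuildOutcome, iterate_build
from .features import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class ConsensusCurve:
    """Per-agreement-threshold segment metrics plus model accuracy summary.

    ``table`` has one row per threshold k = 1..M with columns k,
    n_selected, true_positives, false_positives, precision, sensitivity,
    specificity, fdr.  ``sd_accuracy`` is the population (ddof=0) standard
    deviation of the per-model accuracies.  Note the specificity of
    high-k segments is inflated by construction (subjects not selected by
    any model are counted as negatives) and should be read with care.
    """

    table: pd.DataFrame
    model_accuracies: dict[str, float]
    mean_accuracy: float
    sd_accuracy: float

    def row(self, k: int) -> pd.Series:
        return self.table.set_index("k").loc[k]

    def to_json_dict(self) -> dict:
        return {
            "segments": self.table.to_dict(orient="records"),
            "model_accuracies": self.model_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
        }


@dataclass
class PermutationResult:
    """Observed statistic, permutation null, and add-one p-values."""

    n_reps: int
    observed: float
    null_statistics: list[float]
    p_value: float
    per_model_observed: dict[str, float]
    per_model_p: dict[str, float]
    bonferroni_alpha: float
    statistic: str = "min_accuracy"

    def to_json_dict(self, include_null: bool = True) -> dict:
        out = {
            "n_reps": self.n_reps,
            "statistic": self.statistic,
            "observed": self.observed,
            "p_value": self.p_value,
            "per_model_observed": self.per_model_observed,
            "per_model_p": self.per_model_p,
            "bonferroni_alpha": self.bonferroni_alpha,
        }
        if include_null:
            out["null_statistics"] = list(map(float, self.null_statistics))
        return out


def agreement_counts(predictions: pd.DataFrame) -> pd.Series:
    """Number of models voting positive for each subject.

    ``predictions`` is models x subjects (boolean, True = positive class);
    the result ranges 0..M.
    """
    pred = predictions.astype(bool)
    return pred.sum(axis=0)


def segment_metrics(counts: pd.Series, labels: pd.Series, k: int, positive) -> dict:
    """Metrics of the consensus segment selected = {s : counts[s] >= k}.

    precision = TP/|selected| (NaN when nothing is selected), sensitivity
    = TP / all positives, fdr = FP/|selected|, specificity = 1 - FP / all
    negatives.
    """
    M_counts = counts.astype(int)
    if k < 1:
        raise ValueError("agreement threshold k must be >= 1")
    y = labels.loc[M_counts.index] == positive
    selected = M_counts >= k
    n_sel = int(selected.sum())
    tp = int((selected & y).sum())
    fp = n_sel - tp
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    return {
        "k": int(k),
        "n_selected": n_sel,
        "true_positives": tp,
        "false_positives": fp,
        "precision": tp / n_sel if n_sel else float("nan"),
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "specificity": 1.0 - fp / n_neg if n_neg else float("nan"),
        "fdr": fp / n_sel if n_sel else float("nan"),
    }


def consensus_curve(
    result: BucketResult, labels: pd.Series, positive: str = "CFS"
) -> ConsensusCurve:
    """Segment metrics for every agreement threshold k = 1..M.

    M is the number of non-failed models.  The per-model test accuracies
    are summarized as mean +/- population standard deviation.
    """
    if result.predictions.empty:
        raise ValueError("bucket result has no non-failed model predictions")
    counts = agreement_counts(result.predictions)
    M = len(result.predictions)
    rows = [segment_metrics(counts, labels, k, positive) for k in range(1, M + 1)]
    accs = result.accuracies
    values = np.array(list(accs.values()))
    return ConsensusCurve(
        table=pd.DataFrame(rows),
        model_accuracies=dict(accs),
        mean_accuracy=float(values.mean()),
        sd_accuracy=float(values.std(ddof=0)),
    )


def permutation_pvalue(observed: float, null_statistics) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (n + 1)."""
    null = np.asarray(list(null_statistics), dtype=float)
    return float((1 + int((null >= observed).sum())) / (len(null) + 1))


def _statistic(accuracies: dict[str, float], kind: str) -> float:
    values = list(accuracies.values())
    if kind == "min_accuracy":
        return float(min(values))
    if kind == "mean_accuracy":
        return float(np.mean(values))
    raise ValueError(f"unknown permutation statistic {kind!r}")


def _shuffled_table(table: FeatureTable, rng: np.random.Generator) -> FeatureTable:
    meta = table.metadata.copy()
    meta["group"] = rng.permutation(meta["group"].to_numpy())
    return FeatureTable(table.counts.copy(), meta, list(table.region_ids), table.threshold_used)


def shuffle_test(
    table: FeatureTable,
    config: BucketConfig | None = None,
    n_reps: int = 200,
    seed: int = 0,
    statistic: str = "min_accuracy",
    observed_outcome: BuildOutcome | None = None,
) -> PermutationResult:
    """Full-pipeline permutation test of the model build.

    Each rep permutes the group labels uniformly at random and re-runs the
    entire iterative build (split, covariate control, elimination, bucket
    refits) on the shuffled table; the statistic defaults to the minimum
    per-model final test accuracy.  The p-value uses the add-one rule so
    it can never be exactly zero.  Per-model p-values are computed the
    same way, and the Bonferroni-corrected alpha (0.05 / M) is reported
    alongside.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or BucketConfig()
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)

    if observed_outcome is None:
        observed_outcome = iterate_build(table, config, seed=seed)
    obs_acc = observed_outcome.final_result.accuracies
    observed = _statistic(obs_acc, statistic)

    null_stats: list[float] = []
    null_per_model: dict[str, list[float]] = {m: [] for m in obs_acc}
    for rep_seed in rep_seeds:
        shuffled = _shuffled_table(table, rng)
        outcome = iterate_build(table=shuffled, config=config, seed=int(rep_seed))
        acc = outcome.final_result.accuracies
        null_stats.append(_statistic(acc, statistic))
        for m in null_per_model:
            if m in acc:
                null_per_model[m].append(acc[m])

    per_model_p = {
        m: permutation_pvalue(obs_acc[m], null_per_model[m])
        for m in null_per_model
        if null_per_model[m]
    }
    return PermutationResult(
        n_reps=n_reps,
        observed=observed,
        null_statistics=list(map(float, null_stats)),
        p_value=permutation_pvalue(observed, null_stats),
        per_model_observed={m: float(a) for m, a in obs_acc.items()},
        per_model_p=per_model_p,
        bonferroni_alpha=0.05 / max(len(obs_acc), 1),
        statistic=statistic,
    )
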