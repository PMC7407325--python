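"""Multicollinearity screening and optional quartile binning of features.

Pairwise Pearson correlations are computed three times — on the training
set, the testing set, and the combined data — and any feature pair whose
absolute correlation reaches the threshold (default 0.9) in any of the
three is flagged as collinear.  Flagged features are merged by summing
(counts are additive) and the screen is re-run until no pair is flagged,
so the surviving features are guaranteed below the threshold everywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.9


@dataclass
class CorrelationReport:
    """Correlation matrices, flagged pairs and the merge audit trail.

    ``flagged_pairs`` lists ``(feature_i, feature_j, dataset, |r|)``;
    ``missing_pairs`` lists pairs whose correlation is undefined because a
    column is constant (not flagged: a constant column carries no
    collinearity risk and is removed later by importance pruning).
    """

    matrices: dict[str, pd.DataFrame]
    threshold: float = DEFAULT_R_THRESHOLD
    flagged_pairs: list = field(default_factory=list)
    missing_pairs: list = field(default_factory=list)
    merges: list = field(default_factory=list)

    @property
    def flagged_feature_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b, _, _ in self.flagged_pairs}

    def to_json_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "datasets": list(self.matrices),
            "n_features": int(len(next(iter(self.matrices.values())))),
            "flagged_pairs": [
                {"feature_i": a, "feature_j": b, "dataset": d, "abs_r": float(r)}
                for a, b, d, r in self.flagged_pairs
            ],
            "missing_pairs": [list(p) for p in self.missing_pairs],
            "merges": [
                {"members": list(members), "merged_name": name}
                for members, name in self.merges
            ],
        }


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def pearson_matrix(X) -> pd.DataFrame:
    """Sample Pearson correlation matrix of the columns of ``X``.

    Symmetric with unit diagonal.  Constant columns produce NaN entries
    (off-diagonal) rather than raising; fewer than 3 rows is an error
    because a correlation from 2 points is vacuous.
    """
    X = _as_frame(X)
    if len(X) < 3:
        raise ValueError(f"need at least 3 rows to correlate, got {len(X)}")
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    corr = np.atleast_2d(corr)
    const = sd == 0
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=X.columns, columns=X.columns)


def flag_collinear_pairs(
    train_X,
    test_X,
    combined_X=None,
    threshold: float = DEFAULT_R_THRESHOLD,
) -> CorrelationReport:
    """Flag feature pairs with |r| >= threshold in train, test or combined data.

    A tie at exactly the threshold is flagged: only features strictly below
    it pass into the model build.
    """
    train_X = _as_frame(train_X)
    test_X = _as_frame(test_X)
    if list(train_X.columns) != list(test_X.columns):
        raise ValueError("train and test feature sets differ")
    if combined_X is None:
        combined_X = pd.concat([train_X, test_X], axis=0)
    else:
        combined_X = _as_frame(combined_X)
        if list(combined_X.columns) != list(train_X.columns):
            raise ValueError("combined feature set differs from train/test")

    matrices = {
        "train": pearson_matrix(train_X),
        "test": pearson_matrix(test_X),
        "combined": pearson_matrix(combined_X),
    }
    cols = list(train_X.columns)
    flagged, missing = [], set()
    for dataset, mat in matrices.items():
        vals = mat.to_numpy()
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r = vals[i, j]
                if np.isnan(r):
                    missing.add((cols[i], cols[j]))
                elif abs(r) >= threshold:
                    flagged.append((cols[i], cols[j], dataset, abs(float(r))))
    return CorrelationReport(matrices, threshold, flagged, sorted(missing))


def _components(features: list[str], pairs: set[tuple[str, str]]) -> list[list[str]]:
    parent = {f: f for f in features}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict[str, list[str]] = {}
    for f in features:
        groups.setdefault(find(f), []).append(f)
    return [groups[find(f)] for f in features if find(f) == f]


def merge_collinear(X, report: CorrelationReport) -> tuple[pd.DataFrame, CorrelationReport]:
    """Merge flagged collinear features by summing, to a correlation fixed point.

    Connected components of the flagged-pair graph are each replaced by a
    single summed column named by its members ("A+B"); the merged matrix is
    re-screened (same threshold) and merging repeats until no pair is
    flagged, so re-running the flagging step on the result yields zero
    flags.  Column order follows the first member of each component.
    """
    X = _as_frame(X).copy()
    merges = list(report.merges)
    pairs = report.flagged_feature_pairs
    while pairs:
        new_cols = {}
        for comp in _components(list(X.columns), pairs):
            if len(comp) == 1:
                new_cols[comp[0]] = X[comp[0]]
            else:
                name = "+".join(comp)
                new_cols[name] = X[comp].sum(axis=1)
                merges.append((tuple(comp), name))
                logger.info("merged collinear features %s -> %s", comp, name)
        X = pd.DataFrame(new_cols, index=X.index)
        if X.shape[1] < 2:
            break
        mat = pearson_matrix(X)
        vals = mat.to_numpy()
        cols = list(X.columns)
        pairs = {
            (cols[i], cols[j])
            for i in range(len(cols))
            for j in range(i + 1, len(cols))
            if not np.isnan(vals[i, j]) and abs(vals[i, j]) >= report.threshold
        }
    out = CorrelationReport(
        report.matrices, report.threshold, list(report.flagged_pairs),
        list(report.missing_pairs), merges,
    )
    return X, out


def screen_features(
    train_X, test_X, threshold: float = DEFAULT_R_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame, CorrelationReport]:
    """Full screen: flag on train/test/combined, merge consistently in both.

    Iterates flagging and merging until no pair reaches the threshold in
    any of the three datasets, applying identical merges to the training
    and testing matrices.
    """
    train_X = _as_frame(train_X).copy()
    test_X = _as_frame(test_X).copy()
    report = flag_collinear_pairs(train_X, test_X, threshold=threshold)
    first = report
    merges: list = []
    while report.flagged_feature_pairs:
        pairs = report.flagged_feature_pairs
        comps = _components(list(train_X.columns), pairs)

        def apply(X: pd.DataFrame) -> pd.DataFrame:
            cols = {}
            for comp in comps:
                if len(comp) == 1:
                    cols[comp[0]] = X[comp[0]]
                else:
                    cols["+".join(comp)] = X[comp].sum(axis=1)
            return pd.DataFrame(cols, index=X.index)

        for comp in comps:
            if len(comp) > 1:
                merges.append((tuple(comp), "+".join(comp)))
        train_X, test_X = apply(train_X), apply(test_X)
        if train_X.shape[1] < 2:
            break
        report = flag_collinear_pairs(train_X, test_X, threshold=threshold)
    final = CorrelationReport(
        first.matrices, threshold, list(first.flagged_pairs),
        list(first.missing_pairs), merges,
    )
    return train_X, test_X, final


@dataclass
class QuartileBinner:
    """Training-set quartile boundaries, persisted for test-set application."""

    boundaries: pd.DataFrame  # rows q25/q50/q75, one column per feature

    def transform(self, X) -> pd.DataFrame:
        X = _as_frame(X)
        if list(X.columns) != list(self.boundaries.columns):
            raise ValueError("feature set does not match fitted boundaries")
        out = {}
        for col in X.columns:
            b = self.boundaries[col].to_numpy()
            # number of boundaries strictly below the value, +1 -> code 1..4
            out[col] = np.searchsorted(b, X[col].to_numpy(), side="left") + 1
        return pd.DataFrame(out, index=X.index)


def quartile_bin(X, binner: QuartileBinner | None = None) -> tuple[pd.DataFrame, QuartileBinner]:
    """Ordinal quartile codes 1-4 (Q1 < 25%, Q2 25-50%, Q3 50-75%, Q4 > 75%).

    Boundaries are the 25/50/75 percentiles of the data ``X`` when no
    fitted ``binner`` is passed; values tied with a boundary fall into the
    lower bin.  An all-constant column degenerates to code 1 everywhere
    (warned).  Off by default in the pipeline; provided as a tested
    transform.
    """
    X = _as_frame(X)
    if binner is None:
        if len(X) < 4:
            raise ValueError("need at least 4 rows to define quartiles")
        q = X.quantile([0.25, 0.5, 0.75])
        degenerate = [c for c in X.columns if X[c].nunique() == 1]
        if degenerate:
            warnings.warn(
                f"degenerate quartiles for constant columns {degenerate}; all codes 1",
                stacklevel=2,
            )
        binner = QuartileBinner(q)
    return binner.transform(X), binner
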