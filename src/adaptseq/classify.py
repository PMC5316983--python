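"""Random-forest classification of profiling counts with OOB validation.

The classifier follows the standard recipe for count-profile signatures:
a union-of-tests feature screen, then a 1000-tree random forest with
sqrt(p) features per split, scored by the AUC of out-of-bag (OOB) class
probabilities — each sample predicted only by the trees whose bootstrap
excluded it, so no separate held-out split is required.  Significance of
the OOB AUC is assessed by re-running the pipeline on permuted labels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve

from .stats import (
    PermutationResult,
    plus_one_pvalue,
    select_features,
    two_group_tests,
)

__all__ = [
    "RFResult",
    "auc",
    "fit_random_forest_oob",
    "auc_permutation_test",
    "subgroup_analyses",
    "probability_by_covariate",
]


@dataclass
class RFResult:
    """Fitted-forest summary: OOB probabilities, AUC, ROC, features used."""

    n_trees: int
    mtry: int
    oob_probabilities: np.ndarray
    auc: float
    roc: list[tuple[float, float]]
    selected_features: list[str]
    seed: int | None = None
    permutation_p: float | None = None
    excluded_samples: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["oob_probabilities"] = np.asarray(self.oob_probabilities).tolist()
        d["roc"] = [[float(a), float(b)] for a, b in self.roc]
        Path(path).write_text(json.dumps(d, indent=2))


def _as_binary(y: Sequence) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"labels must be binary, got classes {classes!r}")
    return (y == classes[1]).astype(int)  # second sorted class is "positive"


def auc(scores: Sequence[float], labels: Sequence) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals the fraction of (positive, negative) pairs with
    score_pos > score_neg, counting ties as 1/2.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def fit_random_forest_oob(
    X,
    y: Sequence,
    n_trees: int = 1000,
    mtry: int | None = None,
    seed: int | None = None,
    feature_names: Sequence[str] | None = None,
) -> RFResult:
    """Bootstrap-per-tree forest scored on out-of-bag probabilities.

    ``X`` is samples x features.  The OOB probability of a sample is the
    positive-class vote fraction among trees not trained on it; samples
    in-bag for every tree are excluded from the AUC with a warning.
    mtry defaults to floor(sqrt(p)).
    """
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim != 2 or Xa.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one feature")
    yb = _as_binary(y)
    if np.bincount(yb, minlength=2).min() < 2:
        raise ValueError("need at least 2 samples per class")
    p = Xa.shape[1]
    mtry = mtry or max(1, int(np.sqrt(p)))
    if feature_names is None:
        feature_names = (
            list(X.columns) if isinstance(X, pd.DataFrame) else [f"f{i}" for i in range(p)]
        )

    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        forest.fit(Xa, yb)
    pos_col = int(np.nonzero(forest.classes_ == 1)[0][0])
    oob = forest.oob_decision_function_[:, pos_col]

    missing = np.nonzero(np.isnan(oob))[0]
    if len(missing):
        warnings.warn(
            f"{len(missing)} sample(s) were in-bag for every tree; "
            "excluded from the OOB AUC",
            stacklevel=2,
        )
    keep = ~np.isnan(oob)
    auc_val = auc(oob[keep], yb[keep])
    fpr, tpr, _ = roc_curve(yb[keep], oob[keep])
    return RFResult(
        n_trees=n_trees,
        mtry=mtry,
        oob_probabilities=oob,
        auc=auc_val,
        roc=list(zip(fpr.tolist(), tpr.tolist())),
        selected_features=list(feature_names),
        seed=seed,
        excluded_samples=missing.tolist(),
    )


def _pipeline_oob_auc(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int,
    alpha: float,
    fc_threshold: float,
    n_trees: int,
    pseudocount: float,
    fixed_features: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Feature screen (unless fixed) -> forest -> OOB AUC."""
    if fixed_features is None:
        tests = two_group_tests(X.T, y, pseudocount=pseudocount)
        sel = select_features(tests, alpha=alpha, fc_threshold=fc_threshold).selected
        if not sel.any():
            sel = np.ones(X.shape[1], dtype=bool)  # degenerate screen: keep all
    else:
        sel = fixed_features
    res = fit_random_forest_oob(
        X.iloc[:, sel] if isinstance(X, pd.DataFrame) else X[:, sel],
        y,
        n_trees=n_trees,
        seed=seed,
    )
    return res.auc, sel


def auc_permutation_test(
    X,
    y: Sequence,
    n_perm: int = 1000,
    seed: int | None = None,
    fixed_selection: bool = False,
    alpha: float = 0.05,
    fc_threshold: float = 1.2,
    n_trees: int = 1000,
    pseudocount: float = 1.0,
) -> tuple[PermutationResult, RFResult]:
    """Label-permutation significance of the selection+forest OOB AUC.

    Observed: OOB AUC of the full pipeline (feature screen on the true
    labels, then forest).  Null: the same pipeline on permuted labels.  In
    the default *honest* mode the feature screen is re-run inside every
    permutation, so selection bias cannot inflate the null; with
    ``fixed_selection=True`` features are selected once on the original
    labels and reused, reproducing the simpler historical procedure.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_perm + 2) % (2**31)
    rng = np.random.default_rng(int(seeds[0]))

    observed_auc, sel = _pipeline_oob_auc(
        X, y, int(seeds[1]), alpha, fc_threshold, n_trees, pseudocount
    )
    fixed = sel if fixed_selection else None

    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = y[rng.permutation(len(y))]
        null[i], _ = _pipeline_oob_auc(
            X, y_perm, int(seeds[i + 2]), alpha, fc_threshold, n_trees,
            pseudocount, fixed_features=fixed,
        )
    perm = PermutationResult(
        observed=float(observed_auc),
        null_values=null.tolist(),
        p_value=plus_one_pvalue(observed_auc, null),
        n_perm=n_perm,
        seed=seed,
    )
    rf = fit_random_forest_oob(
        X.iloc[:, sel], y, n_trees=n_trees, seed=int(seeds[1]),
        feature_names=list(X.columns[sel]),
    )
    rf.permutation_p = perm.p_value
    return perm, rf


def subgroup_analyses(
    X,
    metadata: pd.DataFrame,
    comparisons: Sequence[tuple[str, Sequence[str] | str, Sequence[str] | str]],
    cohort_column: str = "cohort",
    n_trees: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    fc_threshold: float = 1.2,
    pseudocount: float = 1.0,
) -> dict[str, RFResult]:
    """Run the selection+forest pipeline for each pairwise cohort comparison.

    ``comparisons`` items are (name, positive cohorts, negative cohorts),
    e.g. ``("cancer_vs_all", "cancer", ["biopsy_negative", "healthy"])``.
    Empty comparisons are skipped with a warning; a cohort compared against
    itself is rejected.
    """
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    if len(X) != len(metadata):
        raise ValueError("X rows and metadata rows must align")
    cohorts = metadata[cohort_column].to_numpy()
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(max(1, len(comparisons))) % (2**31)

    results: dict[str, RFResult] = {}
    for k, (name, pos, neg) in enumerate(comparisons):
        pos = [pos] if isinstance(pos, str) else list(pos)
        neg = [neg] if isinstance(neg, str) else list(neg)
        if set(pos) & set(neg):
            raise ValueError(f"comparison {name!r}: cohorts on both sides")
        mask = np.isin(cohorts, pos + neg)
        if not np.isin(cohorts, pos).any() or not np.isin(cohorts, neg).any():
            warnings.warn(f"comparison {name!r} has an empty side; skipped", stacklevel=2)
            continue
        y = np.where(np.isin(cohorts[mask], pos), "pos", "neg")
        Xs = X.loc[mask] if isinstance(X, pd.DataFrame) else X[mask]
        tests = two_group_tests(Xs.T, y, pseudocount=pseudocount, group_order=("pos", "neg"))
        sel = select_features(tests, alpha=alpha, fc_threshold=fc_threshold).selected
        if not sel.any():
            sel = np.ones(Xs.shape[1], dtype=bool)
        results[name] = fit_random_forest_oob(
            Xs.iloc[:, sel], y, n_trees=n_trees, seed=int(seeds[k]),
            feature_names=list(Xs.columns[sel]),
        )
    return results


def probability_by_covariate(
    result: RFResult,
    metadata: pd.DataFrame,
    covariate: str,
    sample_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Predicted positive-class OOB probability grouped by a categorical
    covariate (e.g. a breast-density analogue), for subgroup reporting."""
    meta = metadata if sample_mask is None else metadata.loc[sample_mask]
    if len(meta) != len(result.oob_probabilities):
        raise ValueError("metadata does not align with the fitted samples")
    df = pd.DataFrame(
        {
            covariate: meta[covariate].to_numpy(),
            "oob_probability": result.oob_probabilities,
        }
    )
    return df
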