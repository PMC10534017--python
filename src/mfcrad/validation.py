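"""Cross-validation harness: LOOCV, Monte-Carlo random validation, ROC/AUC
metrics, fold aggregation and model comparison.

LOOCV pools the held-out scores of all n folds into a single ROC (a per-fold
ROC is undefined for one sample).  MCRV draws stratified 70/30 splits — the
per-stratum training count is round-half-to-even(train_frac x stratum size),
the only rounding consistent with the reference cohort counts (53+5 of 83/7,
52+6 of 84/9) — and aggregates per-fold metrics as mean +/- SD, with a
vertically averaged ROC on a fixed 101-point FPR grid.

Every fold re-fits preprocessing (reduction, normalization, oversampling) on
its training rows only; the fold seed derivation is counter-based so any
fold is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .fusion import FeatureTable
from .models import ModelVariant, VariantModel

__all__ = [
    "SplitPlan",
    "EvalResult",
    "stratified_split",
    "run_loocv",
    "run_mcrv",
    "roc_metrics",
    "compare_models_ttest",
    "fold_seed",
    "FPR_GRID",
]

FPR_GRID = np.linspace(0.0, 1.0, 101)

METRICS = ("auc", "sensitivity", "specificity", "accuracy")


@dataclass
class SplitPlan:
    """One train/test assignment."""

    fold: int
    train_ids: list
    test_ids: list
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


@dataclass
class EvalResult:
    """Per-fold and aggregate evaluation metrics for one variant/classifier.

    ``folds`` has one row per fold with columns auc/sensitivity/specificity/
    accuracy; ``mean_roc`` holds the vertically averaged TPR (and SD band)
    on :data:`FPR_GRID` for MCRV, or the single pooled ROC for LOOCV.
    """

    scheme: str  # "loocv" | "mcrv"
    folds: pd.DataFrame
    mean_roc: pd.DataFrame
    pooled_scores: Optional[pd.Series] = None
    pooled_labels: Optional[pd.Series] = None

    @property
    def mean(self) -> pd.Series:
        return self.folds[list(METRICS)].mean()

    @property
    def sd(self) -> pd.Series:
        return self.folds[list(METRICS)].std(ddof=1) if len(self.folds) > 1 else (
            self.folds[list(METRICS)].iloc[0] * 0.0
        )

    def summary(self) -> pd.DataFrame:
        """mean +/- SD per metric, formatted to 3 decimals."""
        rows = {}
        for m in METRICS:
            if self.scheme == "mcrv":
                rows[m] = f"{self.mean[m]:.3f} ± {self.sd[m]:.3f}"
            else:
                rows[m] = f"{self.mean[m]:.3f}"
        return pd.DataFrame.from_dict(rows, orient="index", columns=["value"])


def _stratum_train_count(size: int, train_frac: float) -> int:
    # exact rational round-half-to-even; float 0.7*75 would miss 52.5
    frac = Fraction(train_frac).limit_denominator(10**6)
    return int(round(frac * size))


def stratified_split(
    labels: pd.Series,
    train_frac: float = 0.7,
    seed: int = 0,
    fold: int = 0,
) -> SplitPlan:
    """One stratified random train/test assignment.

    Sampling is uniform within each label stratum; the training count per
    stratum is round-half-to-even(train_frac x stratum size).
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1) — the test set may not be empty")
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for value in sorted(labels.unique()):
        ids = labels.index[labels == value].to_numpy()
        if len(ids) == 0:
            raise ValueError(f"stratum {value} is empty")
        k = _stratum_train_count(len(ids), train_frac)
        k = min(max(k, 1), len(ids) - 1) if len(ids) > 1 else k
        perm = rng.permutation(len(ids))
        train_ids += list(ids[perm[:k]])
        test_ids += list(ids[perm[k:]])
    if not test_ids:
        raise ValueError("empty test set")
    return SplitPlan(fold=fold, train_ids=train_ids, test_ids=test_ids, seed=seed)


def roc_metrics(
    scores: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, float, float, float, float]:
    """ROC points, trapezoidal AUC and confusion metrics at a threshold.

    The trapezoidal AUC over the empirical ROC equals the pairwise
    concordance probability with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute a ROC")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / len(labels)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return points, auc, sens, spec, acc


def fold_seed(master_seed: int, fold: int) -> int:
    """Counter-based per-fold seed (stable, independent of other folds)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(fold,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _fit_and_score(
    table: FeatureTable,
    labels: pd.Series,
    variant: ModelVariant,
    plan: SplitPlan,
) -> pd.Series:
    model = VariantModel(variant)
    train_tab = FeatureTable(table.df.loc[plan.train_ids], table.block_of)
    fitted = model.fit(train_tab, labels, rng=np.random.default_rng(plan.seed))
    test_tab = FeatureTable(table.df.loc[plan.test_ids], table.block_of)
    return fitted.predict_scores(test_tab)


def run_loocv(
    table: FeatureTable,
    labels: pd.Series,
    variant: ModelVariant,
    threshold: float = 0.5,
) -> EvalResult:
    """Leave-one-out CV: n folds, held-out scores pooled into one ROC."""
    labels = pd.Series(labels).loc[table.df.index]
    n = len(table)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if labels.nunique() < 2:
        raise ValueError("both classes must be present")
    pooled = {}
    ids = list(table.df.index)
    for i, test_id in enumerate(ids):
        plan = SplitPlan(
            fold=i,
            train_ids=[x for x in ids if x != test_id],
            test_ids=[test_id],
            seed=fold_seed(variant.fusion.seed, i),
        )
        pooled[test_id] = float(_fit_and_score(table, labels, variant, plan).iloc[0])
    scores = pd.Series(pooled).loc[ids]
    points, auc, sens, spec, acc = roc_metrics(scores, labels, threshold)
    folds = pd.DataFrame(
        [{"fold": 0, "auc": auc, "sensitivity": sens, "specificity": spec, "accuracy": acc}]
    )
    return EvalResult(
        scheme="loocv",
        folds=folds,
        mean_roc=points,
        pooled_scores=scores,
        pooled_labels=labels,
    )


def run_mcrv(
    table: FeatureTable,
    labels: pd.Series,
    variant: ModelVariant,
    n_folds: int = 100,
    seed: int = 0,
    train_frac: float = 0.7,
    threshold: float = 0.5,
) -> EvalResult:
    """Monte-Carlo random validation over repeated stratified splits."""
    labels = pd.Series(labels).loc[table.df.index]
    if labels.nunique() < 2:
        raise ValueError("both classes must be present")
    rows = []
    tprs = []
    for f in range(n_folds):
        fs = fold_seed(seed, f)
        plan = stratified_split(labels, train_frac=train_frac, seed=fs, fold=f)
        plan.seed = fs
        scores = _fit_and_score(table, labels, variant, plan)
        y_test = labels.loc[plan.test_ids]
        points, auc, sens, spec, acc = roc_metrics(scores.loc[plan.test_ids], y_test, threshold)
        rows.append(
            {"fold": f, "auc": auc, "sensitivity": sens, "specificity": spec, "accuracy": acc}
        )
        tprs.append(np.interp(FPR_GRID, points["fpr"], points["tpr"]))
    folds = pd.DataFrame(rows)
    tprs = np.asarray(tprs)
    mean_roc = pd.DataFrame(
        {
            "fpr": FPR_GRID,
            "tpr_mean": tprs.mean(axis=0),
            "tpr_sd": tprs.std(axis=0, ddof=1) if n_folds > 1 else np.zeros_like(FPR_GRID),
        }
    )
    return EvalResult(scheme="mcrv", folds=folds, mean_roc=mean_roc)


def compare_models_ttest(
    auc_folds_a: Sequence[float],
    auc_folds_b: Sequence[float],
    alpha: float = 0.05,
    paired: bool = True,
) -> tuple[float, float, bool]:
    """Two-sided Student's t-test on fold AUC vectors.

    Paired mode requires matched folds (same split seeds across models).
    Identical vectors give (t=0, p=1).
    """
    a = np.asarray(auc_folds_a, dtype=float)
    b = np.asarray(auc_folds_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 folds per model")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired mode requires equal-length fold vectors")
        if np.allclose(a, b):
            return 0.0, 1.0, False
        t, p = stats.ttest_rel(a, b)
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            return 0.0, 1.0, False
        t, p = stats.ttest_ind(a, b)
    return float(t), float(p), bool(p < alpha)
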