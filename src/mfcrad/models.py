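"""Classifier backends and the four model variants (PI / R / DL / MFC).

Backends: L2-penalized logistic regression with an lbfgs solver, an
RBF-kernel SVM (tolerance 1e-3, Platt-calibrated probabilities), and a
random forest whose depth can be chosen by a train-vs-test divergence sweep.

Variants differ only in which feature blocks they consume:

* PI  — clinical covariates only (4 for surgery, 6 for SBRT),
* R   — the 105 handcrafted radiomic features,
* DL  — the frozen-encoder 512-vector through a single sigmoid unit trained
        with Adam on binary cross-entropy,
* MFC — all blocks concatenated.

Each variant model follows the fit/results idiom: ``VariantModel.fit``
returns a :class:`FittedVariant` carrying the fitted preprocessing state and
classifier, which scores new rows via :meth:`FittedVariant.predict_scores`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .fusion import (
    FeatureTable,
    FusionConfig,
    ZScoreStats,
    gaussian_oversample,
    multicollinearity_reduce,
    zscore_normalize,
)

__all__ = [
    "ClassifierSpec",
    "HeadSpec",
    "ModelVariant",
    "VariantModel",
    "FittedVariant",
    "make_classifier",
    "rf_depth_sweep",
    "SigmoidHead",
    "VARIANT_BLOCKS",
]

VARIANT_BLOCKS = {
    "PI": ("clinical",),
    "R": ("handcrafted",),
    "DL": ("deep",),
    "MFC": ("handcrafted", "deep", "clinical"),
}


@dataclass
class ClassifierSpec:
    """One classifier backend and its settings."""

    kind: str = "logistic"  # logistic | svm-rbf | random-forest
    C: float = 1.0
    svm_tol: float = 1e-3
    n_trees: int = 200
    max_depth: Optional[int] = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("logistic", "svm-rbf", "random-forest"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.svm_tol <= 0:
            raise ValueError("svm tolerance must be > 0")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class HeadSpec:
    """Training settings for the DL variant's sigmoid head."""

    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 8
    frozen_encoder: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.frozen_encoder:
            raise ValueError(
                "encoder fine-tuning is not supported; the encoder is frozen "
                "and only the sigmoid head is trained"
            )


@dataclass
class ModelVariant:
    """A named variant plus the classifier/head/fusion settings it trains with."""

    name: str  # PI | R | DL | MFC
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    head: HeadSpec = field(default_factory=HeadSpec)
    fusion: FusionConfig = field(default_factory=FusionConfig)

    def __post_init__(self) -> None:
        if self.name not in VARIANT_BLOCKS:
            raise ValueError(f"unknown variant {self.name!r} (expected PI/R/DL/MFC)")

    @property
    def blocks(self) -> tuple[str, ...]:
        return VARIANT_BLOCKS[self.name]


def make_classifier(spec: ClassifierSpec):
    """Instantiate a scikit-learn classifier from a spec."""
    if spec.kind == "logistic":
        # L2 penalty (the sklearn default) with the lbfgs quasi-Newton solver
        return LogisticRegression(solver="lbfgs", C=spec.C, max_iter=2000)
    if spec.kind == "svm-rbf":
        return SVC(
            kernel="rbf",
            tol=spec.svm_tol,
            probability=True,
            random_state=spec.seed,
        )
    if spec.kind == "random-forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_depth=spec.max_depth,
            random_state=spec.seed,
        )
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


def rf_depth_sweep(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    depths: Sequence[int] = (2, 3, 5, 8, 12),
    spec: ClassifierSpec | None = None,
) -> int:
    """Pick the largest tree depth before train-vs-validation divergence.

    Depths are tried in increasing order; the sweep stops at the first depth
    where validation AUC drops while training AUC keeps rising (overfitting
    onset) and returns the depth just before it.
    """
    spec = spec or ClassifierSpec(kind="random-forest")
    prev_val = prev_train = -np.inf
    chosen = depths[0]
    for d in sorted(depths):
        clf = RandomForestClassifier(
            n_estimators=spec.n_trees, max_depth=d, random_state=spec.seed
        )
        clf.fit(X_train, y_train)
        train_auc = roc_auc_score(y_train, clf.predict_proba(X_train)[:, 1])
        val_auc = roc_auc_score(y_val, clf.predict_proba(X_val)[:, 1])
        if val_auc < prev_val and train_auc > prev_train:
            break
        chosen = d
        prev_val, prev_train = val_auc, train_auc
    return chosen


class SigmoidHead:
    """A single fully-connected sigmoid unit trained with Adam on BCE loss."""

    def __init__(self, spec: HeadSpec | None = None):
        self.spec = spec or HeadSpec()
        self.w: Optional[np.ndarray] = None
        self.b: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SigmoidHead":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        rng = np.random.default_rng(self.spec.seed)
        n, d = X.shape
        w = np.zeros(d)
        b = 0.0
        mw = np.zeros(d); vw = np.zeros(d)
        mb = vb = 0.0
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.spec.learning_rate
        t = 0
        for _ in range(self.spec.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.spec.batch_size):
                idx = order[start:start + self.spec.batch_size]
                z = X[idx] @ w + b
                p = 1.0 / (1.0 + np.exp(-z))
                err = p - y[idx]
                gw = X[idx].T @ err / len(idx)
                gb = float(err.mean())
                t += 1
                mw = beta1 * mw + (1 - beta1) * gw
                vw = beta2 * vw + (1 - beta2) * gw**2
                mb = beta1 * mb + (1 - beta1) * gb
                vb = beta2 * vb + (1 - beta2) * gb**2
                corr1 = 1 - beta1**t
                corr2 = 1 - beta2**t
                w -= lr * (mw / corr1) / (np.sqrt(vw / corr2) + eps)
                b -= lr * (mb / corr1) / (np.sqrt(vb / corr2) + eps)
        self.w, self.b = w, b
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.w is None:
            raise RuntimeError("head is not fitted")
        z = np.asarray(X, dtype=np.float64) @ self.w + self.b
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class FittedVariant:
    """Fitted preprocessing state + classifier for one variant and fold.

    ``save``/``load`` serialize the whole fitted state (variant spec, kept
    feature names, normalization statistics, estimator) to a single pickle
    artifact, one file per fold.
    """

    variant: ModelVariant
    kept_features: list[str]
    zscore: ZScoreStats
    estimator: object  # sklearn classifier or SigmoidHead

    def save(self, path) -> None:
        import pickle

        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "FittedVariant":
        import pickle

        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, FittedVariant):
            raise ValueError(f"{path} does not contain a fitted model artifact")
        return obj

    def predict_scores(self, table: FeatureTable) -> pd.Series:
        """Scores in [0, 1], one per row, deterministic given fitted state."""
        df = table.select_blocks(self.variant.blocks).df
        missing = [c for c in self.kept_features if c not in df.columns]
        if missing:
            raise ValueError(f"test rows missing fitted columns: {missing}")
        X = self.zscore.apply(df[self.kept_features]).to_numpy()
        if isinstance(self.estimator, SigmoidHead):
            scores = self.estimator.predict_proba(X)
        else:
            scores = self.estimator.predict_proba(X)[:, 1]
        return pd.Series(np.clip(scores, 0.0, 1.0), index=df.index, name="score")


class VariantModel:
    """An unfitted variant model; ``fit`` runs the fold-local pipeline."""

    def __init__(self, variant: ModelVariant):
        self.variant = variant

    def fit(
        self,
        table: FeatureTable,
        labels: pd.Series,
        rng: Optional[np.random.Generator] = None,
    ) -> FittedVariant:
        """Fit preprocessing and classifier on training rows only.

        Pipeline: select declared blocks -> multicollinearity reduction ->
        z-score fit -> Gaussian oversampling -> classifier fit.  The DL
        variant skips reduction/oversampling and trains its sigmoid head on
        standardized encoder features.
        """
        v = self.variant
        df = table.select_blocks(v.blocks).df
        y = np.asarray(labels.loc[df.index], dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        rng = rng or np.random.default_rng(v.fusion.seed)

        if v.name == "DL":
            kept = list(df.columns)
            train_norm, _, zstats = zscore_normalize(df)
            head = SigmoidHead(v.head)
            head.fit(train_norm.to_numpy(), y)
            return FittedVariant(v, kept, zstats, head)

        kept, _ = multicollinearity_reduce(df, y, v.fusion)
        reduced = df[kept]
        train_norm, _, zstats = zscore_normalize(reduced)
        aug, aug_labels = gaussian_oversample(train_norm, y, v.fusion, rng=rng)
        clf = make_classifier(v.classifier)
        clf.fit(aug.to_numpy(), aug_labels)
        return FittedVariant(v, kept, zstats, clf)
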