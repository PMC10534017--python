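"""Feature-table assembly and fold-local preprocessing.

The fused table concatenates three tagged blocks per patient — handcrafted
radiomics, deep encoder features, clinical covariates — and the training-time
preprocessing chain applies, in order: multicollinearity reduction (fit on
training rows), z-score normalization (training statistics only), and
Gaussian-noise oversampling of training rows.  Nothing here ever uses test
rows to fit anything; the validation harness asserts that.

Multicollinearity reduction groups features into the connected components of
the |Pearson r| > threshold graph and keeps, per component, the single
feature with the smallest univariate two-group test p-value against the
outcome (ties broken by original column order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "FusionConfig",
    "FeatureTable",
    "ZScoreStats",
    "zscore_normalize",
    "gaussian_oversample",
    "multicollinearity_reduce",
    "assemble_feature_blocks",
]

BLOCK_ORDER = ("handcrafted", "deep", "clinical")


@dataclass
class FusionConfig:
    """Preprocessing settings for the fused feature space."""

    corr_threshold: float = 0.95
    univariate_test: str = "mannwhitney"  # or "welch"
    oversample_multiplicity: int = 4
    oversample_noise_sd: float = 0.05  # fraction of per-feature training SD
    balance_classes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.corr_threshold < 1.0):
            raise ValueError("corr_threshold must be in (0, 1)")
        if self.oversample_multiplicity < 1:
            raise ValueError("oversample multiplicity must be >= 1")
        if self.oversample_noise_sd < 0:
            raise ValueError("oversample noise SD must be >= 0")
        if self.univariate_test not in ("mannwhitney", "welch"):
            raise ValueError(f"unknown univariate test {self.univariate_test!r}")


class FeatureTable:
    """A per-patient feature matrix with block-tagged columns.

    Thin wrapper around a :class:`pandas.DataFrame` indexed by patient id;
    ``block_of`` maps each column name to its block tag.
    """

    def __init__(self, df: pd.DataFrame, block_of: dict[str, str]):
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate column names: {dupes}")
        unknown = [c for c in df.columns if c not in block_of]
        if unknown:
            raise ValueError(f"columns without a block tag: {unknown}")
        self.df = df
        self.block_of = {c: block_of[c] for c in df.columns}

    @property
    def ids(self) -> list[str]:
        return list(self.df.index)

    def columns_for(self, block: str) -> list[str]:
        return [c for c in self.df.columns if self.block_of[c] == block]

    def select_blocks(self, blocks: Sequence[str]) -> "FeatureTable":
        cols = [c for c in self.df.columns if self.block_of[c] in blocks]
        return FeatureTable(self.df[cols], self.block_of)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ZScoreStats:
    """Fitted per-feature training mean/SD plus zero-variance flags."""

    mean: pd.Series
    sd: pd.Series
    zero_variance: list[str]

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        out = (df - self.mean) / self.sd.replace(0.0, 1.0)
        if self.zero_variance:
            out[self.zero_variance] = 0.0
        return out


def zscore_normalize(
    train_df: pd.DataFrame, apply_df: Optional[pd.DataFrame] = None
) -> tuple[pd.DataFrame, Optional[pd.DataFrame], ZScoreStats]:
    """Standardize features using training-set statistics only.

    Zero-variance training features map to 0 everywhere and are flagged.
    """
    if len(train_df) == 0:
        raise ValueError("training table is empty")
    mean = train_df.mean(axis=0)
    sd = train_df.std(axis=0, ddof=0)
    zero_var = sd.index[sd == 0.0].tolist()
    stats_ = ZScoreStats(mean=mean, sd=sd, zero_variance=zero_var)
    train_norm = stats_.apply(train_df)
    apply_norm = stats_.apply(apply_df) if apply_df is not None else None
    return train_norm, apply_norm, stats_


def gaussian_oversample(
    train_df: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    config: FusionConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Augment training rows with Gaussian-noise replicates.

    Every training row is replicated ``oversample_multiplicity`` times with
    independent N(0, (noise_sd * sd_j)^2) noise per feature j, where sd_j is
    the per-feature training SD.  With ``balance_classes``, minority-class
    rows are first replicated (cyclically) to parity.  Never applied to test
    rows.
    """
    labels = np.asarray(labels)
    if len(labels) != len(train_df):
        raise ValueError("labels length does not match table")
    rng = rng or np.random.default_rng(config.seed)

    df = train_df
    if config.balance_classes and len(np.unique(labels)) == 2:
        counts = {c: int((labels == c).sum()) for c in np.unique(labels)}
        minority = min(counts, key=counts.get)
        deficit = max(counts.values()) - counts[minority]
        if deficit > 0:
            min_idx = np.flatnonzero(labels == minority)
            extra = min_idx[np.arange(deficit) % len(min_idx)]
            df = pd.concat([df, df.iloc[extra]], axis=0)
            labels = np.concatenate([labels, labels[extra]])

    k = config.oversample_multiplicity
    sd = df.std(axis=0, ddof=0).to_numpy()
    tiled = pd.concat([df] * k, axis=0)
    out_labels = np.tile(labels, k)
    if config.oversample_noise_sd > 0:
        noise = rng.normal(
            0.0, 1.0, size=tiled.shape
        ) * (config.oversample_noise_sd * sd)
        tiled = tiled + noise
    return tiled, out_labels


def _univariate_pvalues(
    X: np.ndarray, labels: np.ndarray, test: str
) -> np.ndarray:
    """Two-sided two-group p-value per column; degenerate columns give p=1."""
    pos = X[labels == 1]
    neg = X[labels == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        if test == "welch":
            res = stats.ttest_ind(pos, neg, equal_var=False, axis=0)
        else:
            res = stats.mannwhitneyu(pos, neg, alternative="two-sided", axis=0)
    return np.nan_to_num(np.atleast_1d(res.pvalue), nan=1.0)


def multicollinearity_reduce(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    config: FusionConfig | None = None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Drop redundant features via |r| > threshold connected components.

    Returns (kept feature names in original column order, mapping from each
    kept representative to its full component).  Constant features have no
    defined correlation; they are kept and appear as singleton components.
    """
    config = config or FusionConfig()
    labels = np.asarray(labels)
    if len(table) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")

    X = table.to_numpy(dtype=np.float64)
    names = list(table.columns)
    nf = len(names)
    sd = X.std(axis=0)
    nonconst = sd > 0

    adj = np.zeros((nf, nf), dtype=bool)
    if nonconst.sum() >= 2:
        sub = np.flatnonzero(nonconst)
        r = np.corrcoef(X[:, sub], rowvar=False)
        hit = np.abs(r) > config.corr_threshold
        np.fill_diagonal(hit, False)
        adj[np.ix_(sub, sub)] = hit

    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    pvals = _univariate_pvalues(X, labels, config.univariate_test)

    kept_idx: list[int] = []
    subsets: dict[str, list[str]] = {}
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        if len(members) == 1:
            rep = members[0]
        else:
            best_p = pvals[members].min()
            rep = members[pvals[members] == best_p].min()  # tie: smallest index
        kept_idx.append(rep)
        subsets[names[rep]] = [names[m] for m in members]
    kept_idx.sort()
    kept = [names[i] for i in kept_idx]
    return kept, subsets


def cohort_reduce(
    table: FeatureTable,
    labels: np.ndarray | pd.Series,
    config: FusionConfig | None = None,
) -> FeatureTable:
    """Cohort-wide multicollinearity reduction (figure-style reporting only).

    Runs the reduction once over all rows and returns the pruned table.
    This mirrors how a redundancy map of a full cohort is reported; for
    honest validation use the default fold-wise reduction, which refits on
    training rows inside every fold.
    """
    labels = pd.Series(labels).loc[table.df.index]
    kept, _ = multicollinearity_reduce(table.df, labels.to_numpy(), config)
    return FeatureTable(table.df[kept], table.block_of)


def assemble_feature_blocks(
    handcrafted: pd.DataFrame,
    deep: pd.DataFrame,
    clinical: pd.DataFrame,
) -> FeatureTable:
    """Concatenate the three blocks (handcrafted, deep, clinical) by id.

    All blocks must cover exactly the same patient ids; mismatches are
    reported with the offending ids.
    """
    ids = set(handcrafted.index)
    for name, df in (("deep", deep), ("clinical", clinical)):
        other = set(df.index)
        if other != ids:
            offending = sorted(ids ^ other)
            raise ValueError(
                f"patient ids in {name} block do not match handcrafted block: {offending}"
            )
    order = sorted(handcrafted.index)
    parts = [handcrafted.loc[order], deep.loc[order], clinical.loc[order]]
    block_of: dict[str, str] = {}
    for block, df in zip(BLOCK_ORDER, parts):
        for c in df.columns:
            block_of[c] = block
    merged = pd.concat(parts, axis=1)
    return FeatureTable(merged, block_of)
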