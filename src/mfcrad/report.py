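"""Result tables and ROC figures.

The metric table mirrors the reference layout: one column per
variant x classifier combination (PI/R/MFC each under the three backends,
DL as a single column — 10 columns), one row per metric, MCRV cells
formatted ``mean ± sd`` to 3 decimals.  The model-comparison grid holds
paired t-test p-values of each model's MCRV fold AUCs against every other.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .validation import METRICS, EvalResult, compare_models_ttest

__all__ = ["metric_table", "pvalue_grid", "plot_mean_roc", "render_report"]


def _column_label(variant: str, classifier: str) -> str:
    return variant if variant == "DL" else f"{variant}_{classifier}"


def metric_table(results: dict[tuple[str, str], EvalResult]) -> pd.DataFrame:
    """Variant x classifier metric table; keys are (variant, classifier)."""
    cols = {}
    for (variant, clf), res in results.items():
        label = _column_label(variant, clf)
        col = {}
        for m in METRICS:
            if res.scheme == "mcrv":
                col[m] = f"{res.mean[m]:.3f} ± {res.sd[m]:.3f}"
            else:
                col[m] = f"{res.mean[m]:.3f}"
        cols[label] = col
    return pd.DataFrame(cols).reindex(list(METRICS))


def pvalue_grid(
    results: dict[tuple[str, str], EvalResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Symmetric paired-t-test p-value grid on MCRV fold AUCs."""
    mcrv = {k: v for k, v in results.items() if v.scheme == "mcrv"}
    labels = [_column_label(*k) for k in mcrv]
    grid = pd.DataFrame(np.ones((len(mcrv), len(mcrv))), index=labels, columns=labels)
    keys = list(mcrv)
    for i, ka in enumerate(keys):
        for j, kb in enumerate(keys):
            if i < j:
                _, p, _ = compare_models_ttest(
                    mcrv[ka].folds["auc"], mcrv[kb].folds["auc"], alpha=alpha
                )
                grid.iloc[i, j] = grid.iloc[j, i] = p
    return grid


def plot_mean_roc(
    results: dict[tuple[str, str], EvalResult], path: str | Path, title: str = ""
) -> Path:
    """Mean ROC curves with shaded +/- 1 SD bands (MCRV) or pooled ROC (LOOCV)."""
    fig, ax = plt.subplots(figsize=(6, 6))
    for (variant, clf), res in results.items():
        label = _column_label(variant, clf)
        if res.scheme == "mcrv":
            fpr = res.mean_roc["fpr"]
            tpr = res.mean_roc["tpr_mean"]
            sd = res.mean_roc["tpr_sd"]
            line, = ax.plot(fpr, tpr, label=f"{label} (AUC {res.mean['auc']:.3f})")
            ax.fill_between(
                fpr, np.clip(tpr - sd, 0, 1), np.clip(tpr + sd, 0, 1),
                alpha=0.15, color=line.get_color(),
            )
        else:
            ax.plot(
                res.mean_roc["fpr"], res.mean_roc["tpr"],
                label=f"{label} (AUC {res.mean['auc']:.3f})",
            )
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def render_report(
    results: dict[tuple[str, str], EvalResult],
    out_dir: str | Path,
    prefix: str = "results",
    alpha: float = 0.05,
) -> dict[str, Path]:
    """Write metric table CSV, p-value grid CSV and the ROC figure."""
    if not results:
        raise ValueError("no results to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    table = metric_table(results)
    paths["metrics"] = out_dir / f"{prefix}_metrics.csv"
    table.to_csv(paths["metrics"])
    mcrv = {k: v for k, v in results.items() if v.scheme == "mcrv"}
    if len(mcrv) >= 2:
        grid = pvalue_grid(results, alpha=alpha)
        paths["pvalues"] = out_dir / f"{prefix}_pvalues.csv"
        grid.to_csv(paths["pvalues"])
    paths["roc"] = plot_mean_roc(results, out_dir / f"{prefix}_roc.png")
    return paths
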