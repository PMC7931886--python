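"""Classification metrics and table rendering for the experiment results.

AUC follows the Mann-Whitney convention (ties count 1/2) and is macro-averaged
over classes in multi-label mode; precision/recall are micro-averaged at a 0.5
decision threshold; F1 is the harmonic mean of precision and recall, defined as
0 when both are 0.  Degradation is the relative AUC drop (in percent) between a
baseline ``n`` and a reduced-data ``n``.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import precision_score, recall_score, roc_auc_score


def f1(precision: float, recall: float) -> float:
    """F1 = 2PR / (P + R); 0 when P + R = 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def auc(scores: np.ndarray, labels: np.ndarray, mode: str = "binary") -> float:
    """Rank-based ROC AUC; macro mean over classes in multilabel mode.

    Requires at least one positive and one negative (per class in multilabel
    mode); otherwise the AUC is undefined and an error names the class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if mode == "binary":
        if labels.min() == labels.max():
            raise ValueError("AUC undefined: labels contain a single class")
        return float(roc_auc_score(labels, scores))
    if mode != "multilabel":
        raise ValueError(f"unknown mode {mode!r}")
    per_class = []
    for c in range(labels.shape[1]):
        col = labels[:, c]
        if col.min() == col.max():
            raise ValueError(f"AUC undefined for class {c}: single-class labels")
        per_class.append(roc_auc_score(col, scores[:, c]))
    return float(np.mean(per_class))


def precision_recall(scores: np.ndarray, labels: np.ndarray,
                     threshold: float = 0.5) -> tuple[float, float]:
    """(precision, recall) at a threshold; micro-averaged in multilabel mode.

    Precision is 0 when nothing is predicted positive (the usual convention).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    avg = "binary" if labels.ndim == 1 else "micro"
    p = precision_score(labels, pred, average=avg, zero_division=0)
    r = recall_score(labels, pred, average=avg, zero_division=0)
    return float(p), float(r)


def degradation(auc_base: float, auc_reduced: float) -> float:
    """Relative AUC drop in percent, to one decimal: 100 (base - reduced)/base."""
    if auc_base <= 0.0:
        raise ValueError("baseline AUC must be positive")
    return round(100.0 * (auc_base - auc_reduced) / auc_base, 1)


def imbalance_ratio(count_a: int, count_b: int) -> str:
    """Majority:minority label ratio as a '1:r' string with r to 2 d.p."""
    if count_a <= 0 or count_b <= 0:
        raise ValueError("both class counts must be positive")
    r = max(count_a, count_b) / min(count_a, count_b)
    return f"1:{r:.2f}"


def render_results_table(aggregate: pd.DataFrame) -> str:
    """Render an aggregated result frame as CSV, one row per model with
    F1/Precision/Recall/AUC column blocks per n, values to 2 d.p."""
    if aggregate.empty:
        raise ValueError("cannot render an empty result")
    ns = sorted(aggregate["n"].unique())
    models = list(dict.fromkeys(aggregate["model"]))  # first-seen order
    cols = ["model"]
    for n in ns:
        cols += [f"f1_n{n}", f"precision_n{n}", f"recall_n{n}", f"auc_n{n}"]
    rows = []
    for m in models:
        row: dict[str, object] = {"model": m}
        for n in ns:
            sel = aggregate[(aggregate["model"] == m) & (aggregate["n"] == n)]
            if len(sel):
                rec = sel.iloc[0]
                for k in ("f1", "precision", "recall", "auc"):
                    row[f"{k}_n{n}"] = round(float(rec[k]), 2)
        rows.append(row)
    buf = io.StringIO()
    pd.DataFrame(rows, columns=cols).to_csv(buf, index=False)
    return buf.getvalue()


def degradation_report(aggregate: pd.DataFrame, base_n: int = 1,
                       reduced_n: int = 4) -> pd.DataFrame:
    """Per-model relative AUC drop between two values of n."""
    rows = []
    for model in dict.fromkeys(aggregate["model"]):
        sel = aggregate[aggregate["model"] == model].set_index("n")
        if base_n in sel.index and reduced_n in sel.index:
            rows.append({
                "model": model, "base_n": base_n, "reduced_n": reduced_n,
                "auc_base": float(sel.loc[base_n, "auc"]),
                "auc_reduced": float(sel.loc[reduced_n, "auc"]),
                "degradation_pct": degradation(float(sel.loc[base_n, "auc"]),
                                               float(sel.loc[reduced_n, "auc"])),
            })
    return pd.DataFrame(rows)


def plot_auc_by_n(aggregate: pd.DataFrame, out_path: str | Path) -> None:
    """Grouped bar chart of mean AUC per model across n (summary figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ns = sorted(aggregate["n"].unique())
    models = list(dict.fromkeys(aggregate["model"]))
    width = 0.8 / len(ns)
    fig, ax = plt.subplots(figsize=(max(6, 1.2 * len(models)), 4))
    x = np.arange(len(models))
    for i, n in enumerate(ns):
        vals = [float(aggregate[(aggregate["model"] == m) & (aggregate["n"] == n)]
                      ["auc"].iloc[0]) for m in models]
        ax.bar(x + i * width, vals, width, label=f"n={n}")
    ax.set_xticks(x + width * (len(ns) - 1) / 2)
    ax.set_xticklabels(models, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("AUC")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
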