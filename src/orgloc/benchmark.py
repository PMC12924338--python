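"""Scoring localization predictors against a gold standard.

Each tool's calls are tabulated into a confusion matrix (gold class rows x
emitted class columns, with an explicit ``no-call`` column for labeled
proteins the tool did not score), one-vs-rest metrics are derived per
class, and tools are ranked by a chosen metric aggregated over the
organellar classes of interest.  The top-ranked tools feed the consensus
caller.

A protein without a call counts against the tool's sensitivity (it is a
false negative for its gold class) — the conservative reading, since an
unscored organellar protein is a missed organellar protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GOLD_CLASSES

__all__ = [
    "NO_CALL",
    "ConfusionMatrix",
    "confusion_from_calls",
    "compute_metrics",
    "rank_tools",
    "select_top_k",
    "RANKING_METRICS",
]

NO_CALL = "no-call"

#: Metrics offered for ranking; which one defines "best-performing" is a
#: user choice (MCC by default, being robust to class imbalance).
RANKING_METRICS = ("mcc", "accuracy", "f1", "sensitivity", "precision",
                  "specificity")


@dataclass
class ConfusionMatrix:
    """Per-tool count matrix: gold classes (rows) x emitted classes (cols)."""

    tool_id: str
    counts: pd.DataFrame

    @property
    def n_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def confusion_from_calls(
    labels: pd.DataFrame,
    calls: pd.DataFrame,
    tool_id: str,
) -> ConfusionMatrix:
    """Tabulate one tool's calls against the gold standard.

    Counts partition the labeled set: every labeled protein lands in
    exactly one cell, with missing calls in the ``no-call`` column.
    Raises ``ValueError`` on duplicate calls for one protein.
    """
    tool_calls = calls.loc[calls["tool_id"] == tool_id]
    dup = tool_calls["protein_id"].duplicated()
    if dup.any():
        pid = tool_calls.loc[dup, "protein_id"].iloc[0]
        raise ValueError(
            f"duplicate call from tool {tool_id!r} for protein {pid!r}"
        )
    call_map = dict(zip(tool_calls["protein_id"], tool_calls["canonical"]))
    emitted = [
        call_map.get(pid, NO_CALL) for pid in labels["protein_id"]
    ]
    emit_classes = list(GOLD_CLASSES) + ["unassigned", NO_CALL]
    counts = pd.DataFrame(
        0, index=list(GOLD_CLASSES), columns=emit_classes, dtype=int
    )
    for gold, emit in zip(labels["true_class"], emitted):
        counts.loc[gold, emit] += 1
    return ConfusionMatrix(tool_id, counts)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest metrics per gold class for one confusion matrix.

    For class c: TP are gold-c proteins emitted c; FN every other gold-c
    protein (including no-calls); FP non-c proteins emitted c; TN the rest.
    Undefined ratios (zero denominators) are reported as NaN, never as 0.
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    if cm.n_total == 0:
        raise ValueError(f"{cm.tool_id}: empty confusion matrix")
    mat = cm.counts
    n = cm.n_total
    rows = []
    for cls_name in mat.index:
        tp = int(mat.loc[cls_name, cls_name]) if cls_name in mat.columns else 0
        fn = int(mat.loc[cls_name].sum()) - tp
        fp = (int(mat[cls_name].sum()) - tp) if cls_name in mat.columns else 0
        tn = n - tp - fn - fp
        sens = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        prec = _safe_div(tp, tp + fp)
        acc = _safe_div(tp + tn, n)
        f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
        mcc_den = np.sqrt(
            float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan")
        rows.append(
            {
                "tool_id": cm.tool_id, "class": cls_name,
                "TP": tp, "FP": fp, "FN": fn, "TN": tn,
                "sensitivity": sens, "specificity": spec,
                "precision": prec, "accuracy": acc, "f1": f1, "mcc": mcc,
            }
        )
    return pd.DataFrame(rows)


def rank_tools(
    metrics: pd.DataFrame,
    metric: str = "mcc",
    classes: tuple[str, ...] = ("plastid", "mitochondrion"),
    min_precision: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Rank tools by a metric averaged (unweighted) over the given classes.

    ``min_precision`` optionally drops tools whose precision for any listed
    class falls below a floor before ranking — the move that excludes a
    predictor with too many false positives for one organelle.  Ties are
    broken lexicographically by tool_id for reproducibility.
    """
    if metric not in RANKING_METRICS:
        raise ValueError(f"unknown ranking metric {metric!r}")
    subset = metrics.loc[metrics["class"].isin(classes)]
    missing = set(classes) - set(subset["class"])
    if missing:
        raise ValueError(f"metrics missing for class(es) {sorted(missing)}")
    if min_precision:
        bad_tools = set()
        for cls_name, floor in min_precision.items():
            cls_rows = metrics.loc[metrics["class"] == cls_name]
            below = cls_rows.loc[
                cls_rows["precision"].isna() | (cls_rows["precision"] < floor),
                "tool_id",
            ]
            bad_tools.update(below)
        subset = subset.loc[~subset["tool_id"].isin(bad_tools)]
    agg = (
        subset.groupby("tool_id")[metric]
        .mean()
        .rename("aggregate")
        .reset_index()
    )
    agg["metric"] = metric
    agg = agg.sort_values(
        ["aggregate", "tool_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return agg[["tool_id", "metric", "aggregate"]]


def select_top_k(ranking: pd.DataFrame, k: int = 3) -> list[str]:
    """The k best tools, in ranking order."""
    if k > len(ranking):
        raise ValueError(
            f"requested top {k} of only {len(ranking)} ranked tools"
        )
    return ranking["tool_id"].head(k).tolist()
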