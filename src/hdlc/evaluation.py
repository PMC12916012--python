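"""Operating-characteristic metrics: ROC/AUC, TPR at fixed FPR,
rediscovery rate, and null-calibration summaries.

Score orientation is "larger = stronger colocalization evidence"
throughout; p-value columns are mapped to -log10(p) on ingestion with the
LRT statistic as a deterministic tie-break.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "roc_auc",
    "tpr_at_fpr",
    "rediscovery_rate",
    "auc_by_threshold",
    "null_calibration",
    "scores_from_pvalues",
    "read_score_table",
]


def scores_from_pvalues(pvalues, lam=None) -> np.ndarray:
    """Map p-values to ranking scores (-log10 p, larger = stronger).

    With the chi-bar-square p capped at 0.5, many null replicates tie at
    p = 0.5; an optional LRT-statistic tie-break (scaled to never reorder
    distinct p-values) makes rankings deterministic.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    score = -np.log10(p)
    if lam is not None:
        lam = np.asarray(lam, dtype=float)
        span = float(np.max(lam) - np.min(lam))
        if span > 0:
            score = score + 1e-9 * (lam - np.min(lam)) / span
    return score


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney U identity.

    Rank-based with average ranks for ties, so
    ``roc_auc(s, y) + roc_auc(-s, y) == 1`` exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def tpr_at_fpr(scores, labels, fpr_target: float) -> float:
    """True-positive rate at a fixed empirical false-positive rate.

    The decision threshold is the empirical ``1 - fpr_target`` quantile
    of the negative-class scores; positives count only when strictly
    above it (ties with the threshold are not rejected, which matters in
    small samples and is the documented convention).
    """
    if not 0 < fpr_target < 1:
        raise ValueError("fpr_target must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    neg = scores[~labels]
    pos = scores[labels]
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both classes must be present")
    threshold = np.quantile(neg, 1.0 - fpr_target)
    return float(np.mean(pos > threshold))


def rediscovery_rate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    n: int,
    id_col: str = "item_id",
    score_col: str = "score",
) -> float:
    """Overlap of the top-n findings between a training and a test ranking.

    ``|top_n(train) & top_n(test)| / n`` with descending score and the
    item identifier as deterministic tie-break; symmetric in its two
    table arguments.
    """
    for name, df in (("train", train), ("test", test)):
        if len(df) < n:
            raise ValueError(f"{name} table has fewer than n = {n} items")

    def top_ids(df: pd.DataFrame) -> set:
        ordered = df.sort_values(
            [score_col, id_col], ascending=[False, True], kind="mergesort"
        )
        return set(ordered[id_col].iloc[:n])

    return len(top_ids(train) & top_ids(test)) / n


def auc_by_threshold(
    records: pd.DataFrame,
    colocalization_thresholds: Sequence[float],
    score_col: str = "score",
    truth_col: str = "true_rg",
    group_cols: Sequence[str] = (),
) -> pd.DataFrame:
    """AUC against the rG threshold used to define a true colocalization.

    For threshold t > 0 positives are records with ``|true rG| >= t``;
    at t = 0 positives are ``true rG != 0``.  One row per (group,
    threshold); single-class cells are emitted with NaN and a reason
    rather than raised.
    """
    results = []
    groups = (
        records.groupby(list(group_cols)) if group_cols else [((), records)]
    )
    for key, grp in groups:
        if not isinstance(key, tuple):
            key = (key,)
        truth = np.abs(grp[truth_col].to_numpy(dtype=float))
        for t in colocalization_thresholds:
            labels = truth >= t if t > 0 else truth > 0
            row = dict(zip(group_cols, key))
            row["threshold"] = t
            if labels.all() or not labels.any():
                row["auc"] = np.nan
                row["note"] = "single-class cell"
            else:
                row["auc"] = roc_auc(grp[score_col].to_numpy(), labels)
                row["note"] = ""
            results.append(row)
    return pd.DataFrame(results)


def null_calibration(
    records: pd.DataFrame,
    alphas: Sequence[float] = (0.01, 0.05, 0.1),
    lam_col: str = "lambda",
    p_col: str = "pvalue",
    zero_tol: float = 1e-8,
    n_qq: int = 19,
) -> dict:
    """Summaries of boundary-null behaviour of the LRT statistic.

    Reports the fraction of exactly-zero Lambda (the chi-bar-square point
    mass, expected 0.5 at the null boundary), empirical rejection rates at
    the requested alpha levels, and a QQ table of Lambda against the
    0.5*chi2_0 + 0.5*chi2_1 mixture.
    """
    if len(records) == 0:
        raise ValueError("no replicates supplied")
    lam = records[lam_col].to_numpy(dtype=float)
    pvals = records[p_col].to_numpy(dtype=float)
    zero_mass = float(np.mean(lam <= zero_tol))
    rejection = {float(a): float(np.mean(pvals <= a)) for a in alphas}

    probs = np.linspace(0.05, 0.95, n_qq)
    emp_q = np.quantile(lam, probs)
    theo_q = np.where(probs <= 0.5, 0.0, stats.chi2.ppf(2.0 * probs - 1.0, df=1))
    qq = pd.DataFrame(
        {"prob": probs, "empirical": emp_q, "theoretical": theo_q}
    )
    nz = theo_q > 0
    slope = (
        float(np.sum(emp_q[nz] * theo_q[nz]) / np.sum(theo_q[nz] ** 2))
        if nz.any()
        else np.nan
    )
    return {
        "n": int(len(lam)),
        "zero_mass_fraction": zero_mass,
        "rejection_rates": rejection,
        "qq": qq,
        "qq_slope": slope,
    }


def read_score_table(path, p_value_col: str | None = None) -> pd.DataFrame:
    """Read an external per-item score table (TSV).

    Expected columns: ``item_id``, ``method``, ``score`` and optionally a
    truth column.  If ``p_value_col`` is given that column is converted to
    -log10 scores so published p-value tables plug in directly.
    """
    df = pd.read_csv(path, sep="\t")
    if p_value_col is not None:
        df["score"] = scores_from_pvalues(df[p_value_col].to_numpy())
    missing = {"item_id", "method", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns {sorted(missing)}")
    if not np.all(np.isfinite(df["score"].to_numpy(dtype=float))):
        raise ValueError("non-finite scores")
    return df
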