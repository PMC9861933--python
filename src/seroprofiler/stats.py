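"""Per-cluster discriminant statistics: Wilcoxon rank-sum and ROC/AUC.

Each peak cluster is tested for a between-group intensity difference with
the two-sided Wilcoxon rank-sum (Mann-Whitney) test; clusters with
p <= 0.05 are flagged significant (no multiple-testing correction by
default, a Benjamini-Hochberg option is provided).  Discrimination
magnitude is summarised by the area under the ROC curve, reported both in
the fixed orientation "allergy scores higher" and as the orientation-free
max(AUC, 1 - AUC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, mannwhitneyu, rankdata

from .peaks import PeakClusterMatrix

#: Combined sample size at or below which the exact permutation null is used.
EXACT_MAX_N = 20


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation null when n1 + n2 <= ``EXACT_MAX_N`` and the data are
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Degenerate input (all values identical) gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and pooled.size <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    result = mannwhitneyu(x, y, alternative="two-sided", method=method,
                          use_continuity=True)
    return float(min(result.pvalue, 1.0))


def roc_auc(scores, labels, pos_label) -> float:
    """AUC = (concordant pairs + 0.5 * ties) / (n1 * n2).

    Computed from rank sums (the scaled Mann-Whitney U statistic), with
    ties contributing one half.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == pos_label
    n1 = int(pos.sum())
    n2 = int((~pos).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


@dataclass(frozen=True)
class PeakStat:
    """Discriminant statistics of one peak cluster."""

    mz: float
    p: float
    auc_oriented: float  # orientation: allergy-class intensities score higher
    auc_max: float
    mean_allergy: float
    mean_control: float
    significant: bool
    degenerate: bool


def discriminant_table(
    matrix: PeakClusterMatrix,
    alpha: float = 0.05,
    pos_label: str = "allergy",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-cluster Wilcoxon p and AUC, sorted by p ascending.

    A constant (degenerate) cluster is reported with p = 1, AUC = 0.5 and
    flagged.  ``adjust='bh'`` adds a Benjamini-Hochberg column and bases the
    significance flag on it; by default raw p <= alpha is used.
    """
    labels = matrix.labels.to_numpy()
    pos = labels == pos_label
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError("need >= 2 samples per class")
    rows = []
    for center, values in matrix.intensities.items():
        v = values.to_numpy(dtype=float)
        x, y = v[pos], v[~pos]
        degenerate = bool(np.all(v == v[0]))
        if degenerate:
            p, auc = 1.0, 0.5
        else:
            p = wilcoxon_rank_sum(x, y)
            auc = roc_auc(v, labels, pos_label)
        rows.append(
            {
                "mz": float(center),
                "p": p,
                "auc_oriented": auc,
                "auc_max": max(auc, 1.0 - auc),
                "mean_allergy": float(np.mean(x)),
                "mean_control": float(np.mean(y)),
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows)
    if adjust == "bh":
        table["p_adjusted"] = false_discovery_control(table["p"], method="bh")
        table["significant"] = table["p_adjusted"] <= alpha
    elif adjust is None:
        table["significant"] = table["p"] <= alpha
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table.sort_values("p", kind="stable").reset_index(drop=True)
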