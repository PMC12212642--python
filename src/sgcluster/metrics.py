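"""Clustering agreement metrics and marker-gene identification.

ARI and NMI are delegated to scikit-learn (contingency-table formula;
arithmetic-mean NMI normalisation by default, configurable).  Marker genes
are found per predicted cluster with a one-vs-rest two-sided Wilcoxon
rank-sum test (tie-corrected normal approximation) on log-normalised
expression, ranked by ascending p-value with |log-fold-change| and gene id
as tie-breaks; no multiple-testing adjustment is applied to the ranking.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["ari", "nmi", "wilcoxon_markers"]


def _check_pair(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"label lengths differ: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 2:
        raise ValueError("need at least two items")
    return a, b


def ari(true_labels, pred_labels) -> float:
    """Adjusted Rand index in [-1, 1]; 1 iff the partitions coincide."""
    from sklearn.metrics import adjusted_rand_score

    a, b = _check_pair(true_labels, pred_labels)
    return float(adjusted_rand_score(a, b))


def nmi(true_labels, pred_labels, average_method: str = "arithmetic") -> float:
    """Normalised mutual information in [0, 1].

    ``average_method`` selects the entropy normaliser (arithmetic, min,
    geometric or max), arithmetic being the common default.
    """
    from sklearn.metrics import normalized_mutual_info_score

    a, b = _check_pair(true_labels, pred_labels)
    return float(normalized_mutual_info_score(a, b, average_method=average_method))


def wilcoxon_markers(X, labels, n_top: int = 50,
                     gene_ids=None) -> pd.DataFrame:
    """Top differentially expressed genes per cluster (one vs rest).

    Parameters
    ----------
    X : ExpressionMatrix or (N, M) array of log-normalised expression
    labels : per-cell cluster assignment
    n_top : genes kept per cluster (truncation; the full list if n_top > M)

    Returns a DataFrame with columns (cluster, rank, gene, statistic,
    pvalue, log_fc); ``statistic`` is the Mann-Whitney U of the cluster's
    cells and ``log_fc`` the difference of within/without mean log
    expression.  Clusters with fewer than two cells are skipped with a
    warning.
    """
    from scipy.stats import mannwhitneyu

    if isinstance(X, ExpressionMatrix):
        gene_ids = list(X.gene_ids)
        vals = X.values
    else:
        vals = np.asarray(X, dtype=np.float64)
        if gene_ids is None:
            gene_ids = [f"gene_{j}" for j in range(vals.shape[1])]
    labels = np.asarray(labels).ravel()
    if labels.shape[0] != vals.shape[0]:
        raise ValueError("labels length must match the number of cells")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")

    frames = []
    for c in clusters:
        members = labels == c
        if members.sum() < 2:
            warnings.warn(f"cluster {c!r} has fewer than two cells; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        inside, outside = vals[members], vals[~members]
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-tied genes yield p=1 with noise warnings
            stat, pval = mannwhitneyu(inside, outside, axis=0,
                                      alternative="two-sided", method="asymptotic")
        pval = np.nan_to_num(pval, nan=1.0)
        lfc = inside.mean(axis=0) - outside.mean(axis=0)
        df = pd.DataFrame({"cluster": c, "gene": gene_ids, "statistic": stat,
                           "pvalue": pval, "log_fc": lfc})
        df["abs_lfc"] = df["log_fc"].abs()
        df = df.sort_values(["pvalue", "abs_lfc", "gene"],
                            ascending=[True, False, True], kind="stable")
        df = df.head(n_top).drop(columns="abs_lfc").reset_index(drop=True)
        df.insert(1, "rank", np.arange(1, len(df) + 1))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
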