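"""Per-set differential abundance, BH FDR, clustering, ANOVA/Tukey.

Differential abundance between two diagnosis groups uses the pooled-variance
Student's t-test on pairwise-complete observations (Welch available as an
option), Benjamini-Hochberg step-up FDR within the analysis table, and
log2 fold-change = mean(AD) - mean(control).  Top proteins can be clustered
(euclidean distance, complete linkage) for heatmap rendering, and one-way
ANOVA with Tukey's HSD handles multi-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .types import AbundanceMatrix, ConfigurationError, biological_samples


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray          # scipy (n-1) x 4 merge sequence
    leaf_order: list
    metric: str
    linkage: str


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Missing entries are excluded from the family and returned missing.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def ttest_by_group(matrix: AbundanceMatrix, metadata: pd.DataFrame,
                   group_field: str = "diagnosis",
                   groups: tuple[str, str] = ("control", "AD"),
                   equal_var: bool = True) -> pd.DataFrame:
    """Two-sample t-test per protein; log2FC = mean(groups[1]) - mean(groups[0]).

    Observations are pairwise-complete: each protein uses whatever samples it
    was quantified in.  Proteins with fewer than two observed values in
    either group get a missing p (flagged in ``note``); the q column is BH
    across all tested proteins in this table.
    """
    meta = metadata.loc[matrix.sample_ids.intersection(metadata.index)]
    bio = biological_samples(meta)
    meta = meta.loc[bio]
    ref, alt = groups
    a_ids = meta.index[meta[group_field] == ref]
    b_ids = meta.index[meta[group_field] == alt]
    levels = set(meta[group_field].dropna().unique())
    if not {ref, alt} <= levels:
        raise ConfigurationError(f"groups {groups} not both present in {group_field}")
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ConfigurationError("each group needs >= 2 samples")

    A = matrix.values[a_ids].to_numpy()
    B = matrix.values[b_ids].to_numpy()
    na = np.sum(~np.isnan(A), axis=1)
    nb = np.sum(~np.isnan(B), axis=1)
    mean_a = np.nanmean(np.where(na[:, None] > 0, A, np.nan), axis=1)
    mean_b = np.nanmean(np.where(nb[:, None] > 0, B, np.nan), axis=1)

    res = stats.ttest_ind(B, A, axis=1, equal_var=equal_var,
                          nan_policy="omit")
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(res.df, dtype=float)
    enough = (na >= 2) & (nb >= 2)
    t[~enough] = np.nan
    p[~enough] = np.nan

    table = pd.DataFrame({
        "gene_symbol": matrix.gene_symbols,
        "log2fc": mean_b - mean_a,
        "t": t,
        "df": df,
        "p": p,
        "n_" + ref: na,
        "n_" + alt: nb,
    }, index=matrix.protein_ids)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["direction"] = np.sign(table["log2fc"]).fillna(0).astype(int)
    table["note"] = np.where(enough, "", "insufficient observations")
    return table


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _pairwise_complete_euclidean(x: np.ndarray) -> np.ndarray:
    """Euclidean distance over shared-finite coordinates, scaled to full length."""
    n, m = x.shape
    finite = np.isfinite(x)
    d = np.zeros((n, n))
    for i in range(n):
        diff = x[i][None, :] - x[i + 1:]
        both = finite[i][None, :] & finite[i + 1:]
        counts = both.sum(axis=1)
        if (counts == 0).any():
            j = i + 1 + int(np.argmax(counts == 0))
            raise ConfigurationError(
                f"rows {i} and {j} share no observed coordinate")
        ss = np.nansum(np.where(both, diff ** 2, 0.0), axis=1)
        d[i, i + 1:] = d[i + 1:, i] = np.sqrt(ss * m / counts)
    return d


def supervised_cluster(matrix: AbundanceMatrix, protein_subset: list[str],
                       metric: str = "euclidean",
                       linkage: str = "complete") -> tuple[Dendrogram, Dendrogram]:
    """Hierarchically cluster selected proteins and the samples.

    Distances are pairwise-complete euclidean rescaled to the full profile
    length, so missing values neither bias nor abort the clustering.
    Dendrograms are deterministic for a given input order (scipy breaks
    height ties by merge index).
    """
    if metric != "euclidean":
        raise ConfigurationError("only the euclidean metric is supported")
    if not protein_subset:
        raise ConfigurationError("empty protein subset")
    sub = matrix.values.loc[list(protein_subset)]

    out = []
    for axis_vals in (sub.to_numpy(), sub.to_numpy().T):
        d = _pairwise_complete_euclidean(axis_vals)
        Z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
        order = hierarchy.leaves_list(Z).tolist()
        out.append(Dendrogram(linkage_matrix=Z, leaf_order=order,
                              metric=metric, linkage=linkage))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

def anova_tukey(groups: list[np.ndarray]) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA F/p plus Tukey HSD adjusted pairwise p-values.

    Returns ``(F, p, table)`` where ``table`` has one row per group pair
    with the mean difference and the studentized-range adjusted p.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2:
        raise ConfigurationError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ConfigurationError("each group needs >= 2 values")

    within_var = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = [g.mean() for g in groups]
    degenerate = within_var == 0.0
    if degenerate:
        # zero within-group variance: identical means -> no signal (p = 1),
        # unequal means -> infinitely strong signal (p = 0)
        equal = np.allclose(means, means[0])
        F = 0.0 if equal else np.inf
        p = 1.0 if equal else 0.0
        rows = [{"group_a": i, "group_b": j,
                 "mean_diff": float(means[i] - means[j]),
                 "p_adj": 1.0 if np.isclose(means[i], means[j]) else 0.0}
                for i in range(len(groups)) for j in range(i + 1, len(groups))]
        return F, p, pd.DataFrame(rows)

    F, p = stats.f_oneway(*groups)
    hsd = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append({
                "group_a": i,
                "group_b": j,
                "mean_diff": float(means[i] - means[j]),
                "p_adj": float(hsd.pvalue[i, j]),
            })
    return float(F), float(p), pd.DataFrame(rows)
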