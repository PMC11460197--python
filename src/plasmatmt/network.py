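"""Co-expression module projection and set-enrichment statistics.

Modules are taken as given (a consensus brain network is an input, or a
simulated one); this module computes module eigenproteins (first principal
component of the standardized member profiles), projects arbitrary proteins
onto them via the biweight midcorrelation (module membership, kME), assigns
each protein to the module of highest positive kME subject to a minimum
(default 0.30, else "grey"), correlates eigenproteins with cohort traits,
and provides one-tailed Fisher's exact (hypergeometric) over-representation
with a standardized Z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConfigurationError, ModuleNetwork

__all__ = [
    "compute_eigenprotein",
    "bicor",
    "assign_modules",
    "module_trait_correlation",
    "fet_enrichment",
    "overlap_summary",
]


# ---------------------------------------------------------------------------
# Eigenproteins
# ---------------------------------------------------------------------------

def compute_eigenprotein(reference: pd.DataFrame, members: list[str]):
    """First principal component of a module's standardized member profiles.

    Members are z-scored per protein (sample sd); missing values are filled
    with 0 after standardization (the mean).  The eigenprotein is the first
    right-singular vector over samples, unit norm, sign-oriented so its mean
    correlation with the members is positive (ties align to the first
    member).

    Returns ``(eigenprotein: pd.Series, explained_variance_share: float)``.
    """
    usable = [m for m in members if m in reference.index
              and reference.loc[m].notna().sum() >= 3]
    if len(usable) < 2:
        raise ConfigurationError("eigenprotein needs >= 2 usable members")
    x = reference.loc[usable].astype(float)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    x = x.loc[keep]
    if x.shape[0] < 2:
        raise ConfigurationError("eigenprotein needs >= 2 members with variance")
    z = x.sub(mu[keep], axis=0).div(sd[keep], axis=0).fillna(0.0).to_numpy()

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    vec = vt[0]
    share = float(s[0] ** 2 / (s ** 2).sum())

    cors = np.array([_pearson(vec, row) for row in z])
    mean_cor = cors.mean()
    if mean_cor < 0 or (mean_cor == 0 and cors[0] < 0):
        vec = -vec
    return pd.Series(vec, index=reference.columns, name="eigenprotein"), share


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / den) if den > 0 else 0.0


# ---------------------------------------------------------------------------
# Biweight midcorrelation
# ---------------------------------------------------------------------------

def _bicor_weights(x: np.ndarray):
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None, x - np.mean(x)
    u = (x - med) / (9.0 * mad)
    w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
    return w, x - med


def bicor(x, y) -> float:
    """Biweight midcorrelation of two paired vectors.

    Uses Tukey biweights ``w = (1-u^2)^2 1{|u|<1}`` with ``u = (x - med) /
    (9 MAD)`` (raw MAD, no consistency constant).  Pairs with a missing
    value in either vector are dropped.  When a vector has MAD = 0 the
    weights are undefined and that side falls back to Pearson-style
    mean-centering with unit weights; a warning flags the fallback.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ConfigurationError("bicor needs >= 3 paired finite observations")
    x, y = x[ok], y[ok]
    wx, xc = _bicor_weights(x)
    wy, yc = _bicor_weights(y)
    if wx is None or wy is None:
        warnings.warn("zero MAD: bicor falling back to Pearson weighting",
                      stacklevel=2)
        wx = np.ones_like(x) if wx is None else wx
        wy = np.ones_like(y) if wy is None else wy
    num = np.sum(wx * wy * xc * yc)
    den = np.sqrt(np.sum((wx * xc) ** 2) * np.sum((wy * yc) ** 2))
    if den == 0:
        return 0.0
    return float(np.clip(num / den, -1.0, 1.0))


def _cor_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation via the Student transform, df = n-2."""
    if n < 3:
        return np.nan
    r = np.clip(r, -1.0, 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


# ---------------------------------------------------------------------------
# Module assignment (kME projection)
# ---------------------------------------------------------------------------

def assign_modules(target: pd.DataFrame, network: ModuleNetwork,
                   kme_min: float = 0.30) -> pd.DataFrame:
    """Assign each target protein to its best module by bicor kME.

    ``target`` is a protein x sample frame on the reference sample space.
    A protein is assigned to the module with the highest positive kME when
    that kME is >= ``kme_min``; otherwise it is "grey".  Proteins with
    fewer than 3 usable pairs against every eigenprotein are grey with
    reason.  Ties are broken by module label order and flagged.
    """
    labels = network.module_labels
    eig = network.eigenproteins.loc[labels, target.columns]
    rows = []
    eig_np = {lab: eig.loc[lab].to_numpy() for lab in labels}
    tvals = target.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, pid in enumerate(target.index):
            x = tvals[i]
            kmes = np.full(len(labels), np.nan)
            for j, lab in enumerate(labels):
                ok = np.isfinite(x) & np.isfinite(eig_np[lab])
                if ok.sum() >= 3:
                    kmes[j] = bicor(x[ok], eig_np[lab][ok])
            if np.all(np.isnan(kmes)):
                rows.append((pid, "grey", np.nan, False, "insufficient pairs"))
                continue
            best = np.nanmax(kmes)
            hits = [labels[j] for j in range(len(labels))
                    if np.isfinite(kmes[j]) and kmes[j] == best]
            reason = "tie broken by label order" if len(hits) > 1 else ""
            if best >= kme_min and best > 0:
                rows.append((pid, hits[0], float(best), True, reason))
            else:
                rows.append((pid, "grey", float(best), False,
                             reason or f"max kME {best:.3f} < {kme_min}"))
    return pd.DataFrame(rows, columns=["protein_id", "module", "kME",
                                       "assigned", "note"]).set_index("protein_id")


def module_trait_correlation(network: ModuleNetwork,
                             traits: pd.DataFrame) -> pd.DataFrame:
    """bicor of each module eigenprotein with each reference trait.

    Returns a long table (module, trait, bicor, n, p); the p-value uses the
    same Student t transform as a Pearson correlation, df = n - 2.
    Constant traits yield missing cells.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label in network.module_labels:
            e = network.eigenproteins.loc[label]
            for trait in traits.columns:
                t = traits[trait].reindex(e.index).astype(float)
                ok = e.notna() & t.notna()
                n = int(ok.sum())
                if n < 3 or t[ok].nunique() < 2:
                    rows.append((label, trait, np.nan, n, np.nan))
                    continue
                r = bicor(e[ok].to_numpy(), t[ok].to_numpy())
                rows.append((label, trait, r, n, _cor_pvalue(r, n)))
    return pd.DataFrame(rows, columns=["module", "trait", "bicor", "n", "p"])


# ---------------------------------------------------------------------------
# Over-representation (one-tailed FET + Z)
# ---------------------------------------------------------------------------

def fet_enrichment(query: set[str], categories: dict[str, set[str]],
                   background: set[str], min_genes: int = 5) -> pd.DataFrame:
    """One-tailed over-representation of ``query`` in each category.

    For each category with at least ``min_genes`` members inside the
    background: overlap ``k`` out of query size ``n``, category size ``K``,
    universe ``N``; p = hypergeometric upper tail P(X >= k); Z is the
    standardized hypergeometric deviate
    ``(k - nK/N) / sqrt(nK(N-K)(N-n) / (N^2 (N-1)))``; BH q across the
    categories actually tested.  Fold enrichment is ``k N / (n K)``.
    """
    from .differential import bh_adjust

    background = set(background)
    if not background:
        raise ConfigurationError("empty enrichment background")
    query = set(query) & background
    n, N = len(query), len(background)
    rows = []
    for name in sorted(categories):
        cat = set(categories[name]) & background
        K = len(cat)
        if K < min_genes:
            continue
        k = len(query & cat)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        mean = n * K / N
        var = n * K * (N - K) * (N - n) / (N ** 2 * (N - 1)) if N > 1 else 0.0
        z = (k - mean) / np.sqrt(var) if var > 0 else np.nan
        fold = (k * N) / (n * K) if n and K else np.nan
        rows.append((name, k, n, K, N, p, z, fold))
    table = pd.DataFrame(rows, columns=["category", "overlap", "query_size",
                                        "category_size", "background_size",
                                        "p", "z", "fold_enrichment"])
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table.set_index("category")


def overlap_summary(query_symbols: set[str], reference_symbols: set[str],
                    network: ModuleNetwork) -> tuple[int, pd.Series]:
    """Intersection size and per-module coverage of a query symbol set."""
    query_symbols = set(query_symbols)
    reference_symbols = set(reference_symbols)
    inter = len(query_symbols & reference_symbols)
    coverage = {}
    for label, members in network.members.items():
        mem = set(members)
        coverage[label] = len(mem & query_symbols) / len(mem) if mem else np.nan
    return inter, pd.Series(coverage, name="coverage")
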