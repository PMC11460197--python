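"""Biomarker filtering, two-cohort meta-analysis, trait correlation.

Sample inclusion follows CSF biomarker and cognition criteria (AT+ status:
tTau/Abeta42 ratio above 0.226 for AD, below for controls, with MoCA
consistency).  The two sets' per-protein p-values are combined by Fisher's
method (Stouffer's inverse-normal available), fold-changes averaged, and
single-set proteins passed through.  Corrected abundances are Z-transformed
per protein and correlated (Pearson) with immunoassay traits.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import AbundanceMatrix, ConfigurationError, biological_samples


# ---------------------------------------------------------------------------
# Biomarker (AT+) sample filter
# ---------------------------------------------------------------------------

def at_filter(metadata: pd.DataFrame, ratio_cut: float = 0.226,
              moca_ad: float = 24.0, moca_ctl: float = 24.0):
    """Retain biomarker-consistent samples.

    AD samples are kept when CSF tTau/Abeta42 > ``ratio_cut`` and MoCA <=
    ``moca_ad``; controls when the ratio is <= ``ratio_cut`` and MoCA >=
    ``moca_ctl``.  GIS channels are never retained.  Samples missing a
    required trait are excluded with reason (never an abort).

    Returns ``(retained sample ids, exclusion table with reasons)``.
    """
    retained, excluded = [], []
    for sid, row in metadata.iterrows():
        if bool(row.get("is_gis", False)):
            continue
        dx = row.get("diagnosis")
        if dx not in ("control", "AD"):
            excluded.append((sid, f"diagnosis {dx!r} not filterable"))
            continue
        ttau, abeta, moca = row.get("CSF_tTau"), row.get("CSF_Abeta42"), row.get("MoCA")
        if pd.isna(ttau) or pd.isna(abeta) or pd.isna(moca) or abeta == 0:
            excluded.append((sid, "missing trait"))
            continue
        ratio = ttau / abeta
        if dx == "AD":
            if ratio <= ratio_cut:
                excluded.append((sid, f"tTau/Abeta42 {ratio:.3f} <= {ratio_cut}"))
            elif moca > moca_ad:
                excluded.append((sid, f"MoCA > {moca_ad:g}"))
            else:
                retained.append(sid)
        else:
            if ratio > ratio_cut:
                excluded.append((sid, f"tTau/Abeta42 {ratio:.3f} > {ratio_cut}"))
            elif moca < moca_ctl:
                excluded.append((sid, f"MoCA < {moca_ctl:g}"))
            else:
                retained.append(sid)
    report = pd.DataFrame(excluded, columns=["sample_id", "reason"]) \
        .set_index("sample_id")
    return retained, report


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------

def fisher_combine(p_list, method: str = "fisher") -> float:
    """Combine independent p-values (Fisher's chi-square by default).

    ``X^2 = -2 sum(ln p)`` referred to chi-square with 2k df; a single p is
    returned unchanged.  Zeros are clamped to the smallest positive float
    with a warning.  ``method='stouffer'`` uses the inverse-normal sum.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise ConfigurationError("no p-values to combine")
    if ((p < 0) | (p > 1)).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p = 0 clamped to the smallest positive float", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    if p.size == 1:
        return float(p[0])
    return float(stats.combine_pvalues(p, method=method).pvalue)


def combine_sets(stat1: pd.DataFrame, stat2: pd.DataFrame,
                 method: str = "fisher") -> pd.DataFrame:
    """Merge two per-set differential tables into a meta table.

    Per protein: Fisher-combined meta p over the sets where it was tested,
    mean log2FC over the same sets, a sets-present count, and a concordance
    flag (fold-change signs agree, trivially true for single-set proteins).
    """
    all_ids = stat1.index.union(stat2.index)
    rows = []
    for pid in all_ids:
        ps, fcs = [], []
        for tab in (stat1, stat2):
            if pid in tab.index and np.isfinite(tab.at[pid, "p"]):
                ps.append(float(tab.at[pid, "p"]))
                fcs.append(float(tab.at[pid, "log2fc"]))
        if not ps:
            rows.append((pid, np.nan, np.nan, 0, False))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            meta_p = fisher_combine(ps, method=method)
        concord = len(fcs) < 2 or all(np.sign(f) == np.sign(fcs[0]) for f in fcs)
        rows.append((pid, meta_p, float(np.mean(fcs)), len(ps), concord))
    out = pd.DataFrame(rows, columns=["protein_id", "meta_p", "mean_log2fc",
                                      "n_sets", "concordant"]).set_index("protein_id")
    for i, tab in enumerate((stat1, stat2), start=1):
        out[f"p_set{i}"] = tab["p"].reindex(out.index)
        out[f"log2fc_set{i}"] = tab["log2fc"].reindex(out.index)
    sym = pd.concat([stat1.get("gene_symbol"), stat2.get("gene_symbol")])
    out["gene_symbol"] = sym[~sym.index.duplicated()].reindex(out.index)
    return out


# ---------------------------------------------------------------------------
# Z-transform and trait correlation
# ---------------------------------------------------------------------------

def z_transform(matrix: AbundanceMatrix, ddof: int = 1):
    """Standardize each protein to mean 0, sd 1 over its observed samples.

    Zero-variance proteins are excluded (returned in the dropped list).
    The sample (n-1) standard deviation is the default denominator.
    """
    vals = matrix.values
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=ddof)
    ok = (sd > 0) & (vals.notna().sum(axis=1) >= 2)
    dropped = list(vals.index[~ok])
    if dropped:
        warnings.warn(f"{len(dropped)} zero-variance protein(s) excluded "
                      f"from Z-transform", stacklevel=2)
    z = vals.loc[ok].sub(mu[ok], axis=0).div(sd[ok], axis=0)
    return matrix.with_values(z, scale="corrected"), dropped


def correlate_traits(matrix: AbundanceMatrix, metadata: pd.DataFrame,
                     traits: list[str]) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of each protein with each trait.

    Returns a long table (protein_id, trait, r, n, p) with p from the
    Student transform ``t = r sqrt((n-2)/(1-r^2))``, df = n - 2.  Cells
    with fewer than 3 paired observations or a constant trait are missing.
    """
    meta = metadata.loc[matrix.sample_ids.intersection(metadata.index)]
    bio = biological_samples(meta)
    vals = matrix.values[bio]
    rows = []
    for trait in traits:
        if trait not in meta.columns:
            raise ConfigurationError(f"trait {trait!r} absent from metadata")
        t = meta.loc[bio, trait].astype(float).to_numpy()
        x = vals.to_numpy()
        tok = np.isfinite(t)
        for i, pid in enumerate(vals.index):
            ok = np.isfinite(x[i]) & tok
            n = int(ok.sum())
            if n < 3 or np.unique(t[ok]).size < 2 or np.unique(x[i][ok]).size < 2:
                rows.append((pid, trait, np.nan, n, np.nan))
                continue
            r = float(np.corrcoef(x[i][ok], t[ok])[0, 1])
            rows.append((pid, trait, r, n, _student_p(r, n)))
    return pd.DataFrame(rows, columns=["protein_id", "trait", "r", "n", "p"])


def _student_p(r: float, n: int) -> float:
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def concordance(fc_a: pd.Series, fc_b: pd.Series,
                sig_mask: pd.Series | None = None):
    """Cross-set / cross-platform fold-change agreement.

    Returns ``(pearson r, p, discordant fraction)`` over shared finite
    keys; the discordant fraction counts sign-opposed pairs among keys
    passing ``sig_mask`` (all shared keys when no mask is given).
    """
    shared = fc_a.index.intersection(fc_b.index)
    a = fc_a.reindex(shared).astype(float)
    b = fc_b.reindex(shared).astype(float)
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ConfigurationError("concordance needs >= 3 shared finite values")
    r = float(np.corrcoef(a[ok], b[ok])[0, 1])
    p = _student_p(r, int(ok.sum()))
    mask = ok if sig_mask is None else ok & sig_mask.reindex(shared).fillna(False)
    n_mask = int(mask.sum())
    disc = float((np.sign(a[mask]) * np.sign(b[mask]) < 0).sum() / n_mask) \
        if n_mask else np.nan
    return r, p, disc
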