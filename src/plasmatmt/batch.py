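"""Batch harmonization: GIS-anchored median polish and bootstrap regression.

Multiplexed proteomics batches carry protein-specific multiplicative offsets
(additive in log2).  The harmonization here follows the tunable
median-polish-of-ratio idea: express every log2 abundance as a ratio to the
intra-batch reference (the pooled GIS channels, or the batch median when no
GIS exists), run a Tukey two-way median polish on the ratio matrix, discard
the column (sample loading) effects, and re-anchor each protein at its grand
median so central tendency is preserved.  Residual covariate variance
(age, sex, race, residual batch) is removed by non-parametric bootstrap
regression with the diagnosis effect protected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AbundanceMatrix, ConfigurationError, biological_samples


@dataclass
class PolishState:
    """Trace of a converged two-way median polish."""

    n_iter: int
    overall: float
    row_effects: pd.Series
    col_effects: pd.Series
    residuals: pd.DataFrame
    last_delta: float
    converged: bool


@dataclass
class RegressionReport:
    coefficients: pd.DataFrame          # protein x model term (median over resamples)
    n_bootstrap: int
    protected: list[str]
    uncorrected: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Median polish
# ---------------------------------------------------------------------------

def median_polish(x: np.ndarray, tol: float = 1e-6, max_iter: int = 100):
    """Tukey two-way median polish, column sweeps first, NaN-aware.

    Decomposes ``x_ij ~ overall + row_i + col_j + resid_ij`` by alternately
    subtracting column then row medians; the running medians of the effect
    vectors fold into the overall term.  Convergence is declared when the
    largest absolute change of any row or column effect between sweeps
    drops below ``tol``.  Medians of even counts are midpoints of the two
    central values; missing cells are excluded from every median.
    """
    x = np.array(x, dtype=float)
    n_rows, n_cols = x.shape
    resid = x.copy()
    overall = 0.0
    row = np.zeros(n_rows)
    col = np.zeros(n_cols)
    last_delta = np.inf
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for it in range(1, max_iter + 1):
            col_prev, row_prev = col.copy(), row.copy()

            cmed = np.nanmedian(resid, axis=0)
            cmed = np.where(np.isnan(cmed), 0.0, cmed)
            resid -= cmed[None, :]
            col += cmed
            delta = np.nanmedian(row)
            if np.isfinite(delta):
                row -= delta
                overall += delta

            rmed = np.nanmedian(resid, axis=1)
            rmed = np.where(np.isnan(rmed), 0.0, rmed)
            resid -= rmed[:, None]
            row += rmed
            delta = np.nanmedian(col)
            if np.isfinite(delta):
                col -= delta
                overall += delta

            last_delta = max(np.max(np.abs(col - col_prev), initial=0.0),
                             np.max(np.abs(row - row_prev), initial=0.0))
            if last_delta < tol:
                converged = True
                break
    return overall, row, col, resid, it, last_delta, converged


def tampor_correct(matrix: AbundanceMatrix, metadata: pd.DataFrame,
                   use_gis: bool = True, tol: float = 1e-6,
                   max_iter: int = 100) -> tuple[AbundanceMatrix, PolishState]:
    """Remove batch variance by median polish of intra-batch reference ratios.

    Per protein ``i`` and sample ``j`` in batch ``b`` the ratio is
    ``r_ij = log2 x_ij - median over batch-b GIS channels of log2 x_i``
    (batch median over all channels when ``use_gis`` is false).  A two-way
    median polish of ``r`` then separates sample loading (column effects,
    discarded) from protein-level structure; the corrected value is
    ``residual + row effect + per-protein grand median of log2 x``.
    GIS columns are corrected alongside the rest.  Missing cells stay
    missing and never enter a median.
    """
    if matrix.scale not in ("log2", "corrected"):
        raise ConfigurationError("batch correction operates on log2 values")
    meta = metadata.loc[matrix.sample_ids]
    if meta["batch"].isna().any():
        raise ConfigurationError("every sample needs a batch assignment")

    vals = matrix.values
    denom = pd.DataFrame(index=vals.index, columns=vals.columns, dtype=float)
    for batch, members in meta.groupby("batch").groups.items():
        cols = list(members)
        if use_gis:
            gis_cols = [c for c in cols if bool(meta.loc[c, "is_gis"])]
            if not gis_cols:
                raise ConfigurationError(f"batch {batch} has no GIS channel")
            ref = vals[gis_cols].median(axis=1, skipna=True)
        else:
            ref = vals[cols].median(axis=1, skipna=True)
        n_all_missing = ref.isna().sum()
        if n_all_missing and use_gis:
            warnings.warn(
                f"{n_all_missing} protein(s) missing in all GIS channels of "
                f"batch {batch}; their ratios there are set missing",
                stacklevel=2)
        for c in cols:
            denom[c] = ref

    ratios = vals - denom
    overall, row, col, resid, n_iter, last_delta, converged = median_polish(
        ratios.to_numpy(), tol=tol, max_iter=max_iter)

    grand = vals.median(axis=1, skipna=True)
    corrected = pd.DataFrame(resid, index=vals.index, columns=vals.columns) \
        .add(pd.Series(row, index=vals.index), axis=0) \
        .add(grand, axis=0)

    state = PolishState(
        n_iter=n_iter,
        overall=overall,
        row_effects=pd.Series(row, index=vals.index, name="row_effect"),
        col_effects=pd.Series(col, index=vals.columns, name="col_effect"),
        residuals=pd.DataFrame(resid, index=vals.index, columns=vals.columns),
        last_delta=last_delta,
        converged=converged,
    )
    return matrix.with_values(corrected, scale="corrected"), state


# ---------------------------------------------------------------------------
# Bootstrap covariate regression
# ---------------------------------------------------------------------------

def _design_matrix(meta: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Numeric design with one-hot coded categoricals (first level reference)."""
    cols = {}
    for term in terms:
        if term not in meta.columns:
            raise ConfigurationError(f"covariate {term!r} absent from metadata")
        s = meta[term]
        if s.dtype.kind in "biufc":
            cols[term] = s.astype(float)
        else:
            levels = sorted(s.dropna().unique())
            for lev in levels[1:]:
                cols[f"{term}[{lev}]"] = (s == lev).astype(float)
    return pd.DataFrame(cols, index=meta.index)


def bootstrap_regress(matrix: AbundanceMatrix, metadata: pd.DataFrame,
                      covariates: list[str],
                      protected: tuple[str, ...] = ("diagnosis",),
                      B: int = 200, seed: int = 0,
                      resample: bool = True):
    """Subtract covariate effects estimated by bootstrapped OLS.

    Per protein, ordinary least squares of log2 abundance on protected plus
    unprotected terms is fitted on each of ``B`` resamples of the samples
    (with replacement); each coefficient is the median over resamples.  The
    corrected value subtracts only the unprotected contributions, centered
    at the covariate means, so protected (diagnosis) effects survive.  With
    ``resample=False`` and ``B=1`` this reduces to a plain OLS correction.
    Proteins with fewer complete observations than model terms + 2 are left
    uncorrected and flagged.  GIS channels (no covariates) pass through
    unchanged.
    """
    rng = np.random.default_rng(seed)
    meta = metadata.loc[matrix.sample_ids]
    bio = biological_samples(meta)
    Xp = _design_matrix(meta.loc[bio], list(protected))
    Xu = _design_matrix(meta.loc[bio], list(covariates))
    X = pd.concat([Xp, Xu], axis=1)
    u_terms = list(Xu.columns)

    full = np.column_stack([np.ones(len(bio)), X.to_numpy()])
    if np.linalg.matrix_rank(full[~np.isnan(full).any(axis=1)]) < full.shape[1]:
        raise ConfigurationError(
            f"rank-deficient design over terms {['intercept'] + list(X.columns)}")

    Y = matrix.values[bio].to_numpy()
    cov_ok = ~np.isnan(full).any(axis=1)
    obs = ~np.isnan(Y) & cov_ok[None, :]
    min_obs = full.shape[1] + 2

    coef = np.full((Y.shape[0], full.shape[1]), np.nan)
    uncorrected: list[str] = []

    # group proteins by missingness pattern so each pattern is fitted once
    patterns: dict[bytes, list[int]] = {}
    for i in range(Y.shape[0]):
        patterns.setdefault(obs[i].tobytes(), []).append(i)

    for key, prot_idx in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        n = int(mask.sum())
        if n < min_obs:
            uncorrected.extend(matrix.protein_ids[prot_idx])
            continue
        Xm = full[mask]
        Ym = Y[np.ix_(prot_idx, mask)].T          # n x P
        boots = np.empty((B, full.shape[1], len(prot_idx)))
        for b in range(B):
            idx = rng.integers(0, n, size=n) if resample else np.arange(n)
            Xb, Yb = Xm[idx], Ym[idx]
            beta, *_ = np.linalg.lstsq(Xb, Yb, rcond=None)
            boots[b] = beta
        coef[prot_idx] = np.median(boots, axis=0).T

    term_names = ["intercept"] + list(X.columns)
    coef_df = pd.DataFrame(coef, index=matrix.protein_ids, columns=term_names)

    # subtract centered unprotected contributions from biological samples
    corrected = matrix.values.copy()
    Xu_np = Xu.to_numpy()
    centered = Xu_np - np.nanmean(Xu_np, axis=0, keepdims=True)
    adjust = np.nan_to_num(coef_df[u_terms].to_numpy()) @ centered.T
    corrected.loc[:, bio] = corrected[bio].to_numpy() - adjust

    report = RegressionReport(coefficients=coef_df, n_bootstrap=B,
                              protected=list(protected), uncorrected=uncorrected)
    return matrix.with_values(corrected, scale="corrected"), report
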