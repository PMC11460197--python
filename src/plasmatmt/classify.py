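"""ROC panel classification: logistic panels, AUC, DeLong CI and test.

Proteins passing the meta-analysis significance gate with complete
measurements are ranked by single-marker AUC (orientation-corrected), the
top markers combined into a binomial GLM (logistic) panel, and panels
compared against a covariate marker (e.g. plasma pTau181) with DeLong's
test for correlated AUCs.  The AUC is the Mann-Whitney pair-probability
estimate (ties count one half); its variance follows DeLong's structural
components (placement values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_curve

from .types import AbundanceMatrix, ConfigurationError


# ---------------------------------------------------------------------------
# Cohort / protein eligibility
# ---------------------------------------------------------------------------

def eligible_proteins(meta_table: pd.DataFrame, matrix: AbundanceMatrix,
                      metadata: pd.DataFrame | None = None,
                      meta_p_max: float = 1e-4,
                      require_complete: bool = True):
    """Proteins usable for classification, and the deduplicated cohort.

    A protein qualifies when its meta p is strictly below ``meta_p_max``
    and (by default) it has no missing value across the cohort.  When
    ``metadata`` with a ``subject_id`` column is given, duplicate control
    measurements of the same subject are removed first (first occurrence
    kept), mirroring re-assayed bridging controls.

    Returns ``(protein id list, cohort sample id list)``.
    """
    cohort = list(matrix.sample_ids)
    if metadata is not None and "subject_id" in metadata.columns:
        seen: set = set()
        kept = []
        for sid in cohort:
            subj = metadata.at[sid, "subject_id"] if sid in metadata.index else sid
            if subj in seen:
                continue
            seen.add(subj)
            kept.append(sid)
        cohort = kept
    sub = matrix.values[cohort]
    sig = meta_table["meta_p"] < meta_p_max
    ids = [pid for pid in meta_table.index[sig] if pid in sub.index]
    if require_complete:
        complete = sub.notna().all(axis=1)
        ids = [pid for pid in ids if complete.at[pid]]
    if not ids:
        warnings.warn("no protein passes the eligibility gate", stacklevel=2)
    return ids, cohort


# ---------------------------------------------------------------------------
# Logistic (binomial GLM) panel fit
# ---------------------------------------------------------------------------

@dataclass
class PanelModel:
    members: list[str]
    intercept: float
    coefficients: pd.Series          # log-odds per internally-standardized unit
    converged: bool
    separation: bool
    scores: pd.Series                # fitted probabilities per sample
    n_iter: int
    loglik: float
    loglik_path: list[float] = field(default_factory=list)


def fit_logistic_panel(features: pd.DataFrame, labels: pd.Series) -> PanelModel:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Features (samples x proteins) are standardized internally; iteration
    stops when the log-likelihood improves by less than 1e-8 or after 100
    iterations.  Perfect separation (diverging coefficients with fitted
    probabilities saturating) is flagged, and the last iterate's scores are
    still returned.
    """
    y = labels.reindex(features.index).astype(float).to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ConfigurationError("labels contain a single class")
    X = features.astype(float)
    mu_f, sd_f = X.mean(), X.std(ddof=1).replace(0.0, 1.0)
    Xs = ((X - mu_f) / sd_f).to_numpy()
    Xd = np.column_stack([np.ones(len(Xs)), Xs])

    beta = np.zeros(Xd.shape[1])
    path: list[float] = []
    converged = False
    eps = 1e-10
    for it in range(1, 101):
        eta = Xd @ beta
        p = expit(eta)
        ll = float(np.sum(y * np.log(np.clip(p, eps, 1)) +
                          (1 - y) * np.log(np.clip(1 - p, eps, 1))))
        if path and ll - path[-1] < 1e-8 and ll >= path[-1] - 1e-8:
            path.append(ll)
            converged = True
            break
        path.append(ll)
        w = np.clip(p * (1 - p), eps, None)
        z = eta + (y - p) / w
        WX = Xd * w[:, None]
        beta_new, *_ = np.linalg.lstsq(WX.T @ Xd, WX.T @ z, rcond=None)
        beta = beta_new

    p = expit(Xd @ beta)
    saturated = np.all((p > 1 - 1e-6) == (y == 1)) and \
        np.all((p < 1e-6) == (y == 0)) and \
        (np.all(p[y == 1] > 1 - 1e-6) and np.all(p[y == 0] < 1e-6))
    separation = bool(np.max(np.abs(beta[1:]), initial=0.0) > 25.0 or saturated)
    return PanelModel(
        members=list(features.columns),
        intercept=float(beta[0]),
        coefficients=pd.Series(beta[1:], index=features.columns),
        converged=converged and not separation,
        separation=separation,
        scores=pd.Series(p, index=features.index, name="score"),
        n_iter=it,
        loglik=path[-1],
        loglik_path=path,
    )


# ---------------------------------------------------------------------------
# AUC with DeLong variance
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    variance: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int
    threshold_table: pd.DataFrame    # threshold, sensitivity, specificity, accuracy
    youden_threshold: float


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components: per-positive and per-negative placements."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ConfigurationError("both classes must be present")
    psi = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)   # V10 (len m), V01 (len n)


def roc_auc(scores, labels) -> RocResult:
    """ROC curve, Mann-Whitney AUC, DeLong variance and 95% CI.

    Higher scores indicate the positive class.  The threshold table reports
    sensitivity, specificity and accuracy at every distinct cut, with the
    Youden-optimal row (max sensitivity + specificity - 1; ties resolved to
    the lower threshold) marked.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    v10, v01 = _placements(scores, labels)
    m, n = len(v10), len(v01)
    auc = float(v10.mean())
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + \
          (v01.var(ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    sens, spec = tpr, 1 - fpr
    acc = (sens * m + spec * n) / (m + n)
    youden = sens + spec - 1
    best = np.max(youden)
    # ties at the Youden optimum resolve to the lowest threshold
    cand = np.flatnonzero(np.isclose(youden, best))
    pick = cand[np.argmin(thresholds[cand])]
    table = pd.DataFrame({
        "threshold": thresholds,
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "youden": youden,
    })
    table["optimal"] = False
    table.loc[pick, "optimal"] = True
    return RocResult(fpr=fpr, tpr=tpr, auc=auc, variance=float(var), ci=ci,
                     n_pos=m, n_neg=n, threshold_table=table,
                     youden_threshold=float(thresholds[pick]))


def delong_test(scores_a, scores_b, labels):
    """DeLong's test for two correlated AUCs on the same samples.

    Returns ``(z, two-sided p, delta_auc)``.  Identical score rankings give
    a zero-variance difference, reported as p = 1 with z = 0.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores_a.shape != scores_b.shape:
        raise ConfigurationError("paired scores must have equal length")
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    m, n = len(va10), len(va01)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    d10 = va10 - vb10
    d01 = va01 - vb01
    var = (d10.var(ddof=1) / m if m > 1 else 0.0) + \
          (d01.var(ddof=1) / n if n > 1 else 0.0)
    delta = auc_a - auc_b
    if var <= 0:
        return 0.0, 1.0, delta
    z = delta / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p, delta


# ---------------------------------------------------------------------------
# Marker ranking and panel comparison
# ---------------------------------------------------------------------------

@dataclass
class PanelReport:
    ranked: pd.DataFrame
    panel: PanelModel
    panel_roc: RocResult
    covariate_roc: RocResult | None
    combined: PanelModel | None
    combined_roc: RocResult | None
    delong_covariate_vs_combined: tuple[float, float, float] | None


def rank_and_panel(matrix: AbundanceMatrix, labels: pd.Series,
                   covariate: pd.Series | None = None,
                   k: int = 5) -> PanelReport:
    """Rank single markers by AUC, fit the top-k panel, compare to a covariate.

    Single-marker AUCs below 0.5 are sign-flipped (flagged), so ranking
    reflects discriminative ability regardless of direction.  The panel, the
    covariate alone, and covariate + panel are each fitted as logistic
    models; DeLong's test compares the covariate alone against
    covariate + panel.
    """
    samples = matrix.sample_ids
    y = labels.reindex(samples).astype(int)
    rows = []
    for pid in matrix.protein_ids:
        x = matrix.values.loc[pid, samples].to_numpy(dtype=float)
        res = roc_auc(x, y.to_numpy())
        flipped = res.auc < 0.5
        if flipped:
            res = roc_auc(-x, y.to_numpy())
        rows.append((pid, res.auc, flipped, res.ci[0], res.ci[1]))
    ranked = pd.DataFrame(rows, columns=["protein_id", "auc", "flipped",
                                         "ci_low", "ci_high"]) \
        .set_index("protein_id").sort_values("auc", ascending=False)

    if k > len(ranked):
        warnings.warn(f"panel size {k} exceeds {len(ranked)} eligible proteins; "
                      "using all", stacklevel=2)
        k = len(ranked)
    top = list(ranked.index[:k])
    feats = matrix.values.loc[top, samples].T
    panel = fit_logistic_panel(feats, y)
    panel_roc = roc_auc(panel.scores.to_numpy(), y.to_numpy())

    covariate_roc = combined = combined_roc = dl = None
    if covariate is not None:
        cov = covariate.reindex(samples).astype(float)
        if cov.isna().any():
            keep = cov.notna()
            cov, y2 = cov[keep], y[keep]
            feats2 = feats.loc[keep.index[keep]]
        else:
            y2, feats2 = y, feats
        cov_model = fit_logistic_panel(cov.to_frame("covariate"), y2)
        covariate_roc = roc_auc(cov_model.scores.to_numpy(), y2.to_numpy())
        combined = fit_logistic_panel(
            pd.concat([cov.to_frame("covariate"), feats2], axis=1), y2)
        combined_roc = roc_auc(combined.scores.to_numpy(), y2.to_numpy())
        dl = delong_test(combined.scores.to_numpy(),
                         cov_model.scores.to_numpy(), y2.to_numpy())
    return PanelReport(ranked=ranked, panel=panel, panel_roc=panel_roc,
                       covariate_roc=covariate_roc, combined=combined,
                       combined_roc=combined_roc,
                       delong_covariate_vs_combined=dl)
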