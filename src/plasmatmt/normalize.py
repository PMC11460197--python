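"""Loading normalization, missingness filtering, log2 transform, imputation.

TMT reporter-ion totals differ between channels purely through pipetting /
labeling efficiency, so each sample is rescaled so its intensity sum matches
the largest channel sum; proteins quantified in too few samples are dropped
(strictly more than the threshold fraction missing); values are then log2
transformed.  A label-free path additionally offers downshifted-Gaussian
imputation of missing values (per-sample normal centered ``downshift`` sd
below the observed mean with width ``width`` sd), the convention popularized
by interactive proteomics analysis suites; the TMT path never imputes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AbundanceMatrix, ConfigurationError


@dataclass
class ScalingReport:
    """Per-sample channel sums and the factors applied."""

    channel_sums: pd.Series
    max_sum: float
    factors: pd.Series


def channel_sum_scale(matrix: AbundanceMatrix) -> tuple[AbundanceMatrix, ScalingReport]:
    """Scale each sample by (max channel sum) / (its channel sum).

    Sums run over the proteins observed in that sample (missing cells
    contribute no reporter intensity).  Missing cells stay missing.
    """
    if matrix.scale not in ("raw", "scaled"):
        raise ConfigurationError(f"expected raw/scaled intensities, got {matrix.scale}")
    sums = matrix.values.sum(axis=0, skipna=True)
    empty = sums[matrix.values.notna().sum(axis=0) == 0]
    if len(empty):
        raise ConfigurationError(f"sample(s) with no observed protein: "
                                 f"{list(empty.index[:5])}")
    factors = sums.max() / sums
    scaled = matrix.values.mul(factors, axis=1)
    report = ScalingReport(channel_sums=sums, max_sum=float(sums.max()),
                           factors=factors)
    return matrix.with_values(scaled, scale="scaled"), report


def intensity_sum_scale_labelfree(matrix: AbundanceMatrix):
    """Label-free per-sample intensity-sum scaling (same formula as TMT)."""
    return channel_sum_scale(matrix)


def filter_missingness(matrix: AbundanceMatrix, max_missing_frac: float = 0.5):
    """Drop proteins missing in strictly more than ``max_missing_frac`` of samples.

    A protein missing in exactly half the samples survives the default
    threshold.  Returns ``(filtered matrix, dropped protein id list)``.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ConfigurationError("max_missing_frac must lie in [0, 1]")
    frac = matrix.values.isna().mean(axis=1)
    keep = frac <= max_missing_frac
    dropped = list(matrix.protein_ids[~keep])
    return matrix.with_values(matrix.values.loc[keep]), dropped


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2; present values must be strictly positive."""
    vals = matrix.values
    bad = (vals <= 0)
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ConfigurationError(
            f"nonpositive value at protein {vals.index[r]}, sample {vals.columns[c]}")
    return matrix.with_values(np.log2(vals), scale="log2")


def impute_downshifted_normal(matrix: AbundanceMatrix, width: float = 0.3,
                              downshift: float = 1.8,
                              seed: int | np.random.Generator = 0) -> AbundanceMatrix:
    """Impute missing log2 values from a downshifted per-sample normal.

    Missing cells of sample ``j`` are drawn from
    ``Normal(mean_j - downshift * sd_j, (width * sd_j)^2)`` with moments
    over the observed values of that sample.
    """
    if matrix.scale != "log2":
        raise ConfigurationError("imputation operates on the log2 scale")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = matrix.values.copy()
    for col in vals.columns:
        obs = vals[col].dropna()
        n_missing = vals[col].isna().sum()
        if n_missing == 0:
            continue
        if len(obs) < 3:
            raise ConfigurationError(
                f"sample {col} has fewer than 3 observed values; sd undefined")
        mu, sd = obs.mean(), obs.std(ddof=1)
        draws = rng.normal(mu - downshift * sd, width * sd, size=n_missing)
        vals.loc[vals[col].isna(), col] = draws
    return matrix.with_values(vals)
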