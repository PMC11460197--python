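"""Core containers shared by every pipeline stage.

The canonical in-memory representation of a quantified proteome is a
protein-by-sample :class:`pandas.DataFrame` of float intensities with
``NaN`` marking missing measurements.  :class:`AbundanceMatrix` wraps it
together with gene symbols and an explicit *scale* state so that stages
can assert they receive data on the scale they expect (raw reporter-ion
intensities, channel-sum scaled intensities, log2 values, or
batch-corrected log2 values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SCALES = ("raw", "scaled", "log2", "corrected")

#: metadata columns every sample table must provide
REQUIRED_METADATA = ("set", "batch", "is_gis", "diagnosis")

#: biomarker / trait columns (pg/ml except MoCA, a 0-30 score)
TRAIT_COLUMNS = (
    "MoCA",
    "CSF_Abeta42",
    "CSF_tTau",
    "CSF_pTau181",
    "plasma_pTau181",
)


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected dialect."""


class ConfigurationError(ValueError):
    """Raised when a design or run configuration is internally inconsistent."""


@dataclass
class AbundanceMatrix:
    """Protein x sample abundance matrix with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by unique protein accession, columns unique
        sample ids, float values with ``NaN`` for missing.
    gene_symbols
        Series mapping protein accession -> gene symbol.  Symbols may
        repeat (proteoforms such as APOE4 are distinct rows).
    scale
        One of ``raw``, ``scaled``, ``log2``, ``corrected``.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise FormatError(f"duplicate protein ids: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][:3].tolist()
            raise FormatError(f"duplicate sample ids: {dup}")
        self.values = self.values.astype(float)
        self.gene_symbols = self.gene_symbols.reindex(self.values.index)
        if self.scale in ("raw", "scaled"):
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy() < 0).any():
                    raise ConfigurationError(
                        f"negative intensities are not valid on the {self.scale} scale"
                    )

    # -- convenience -----------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "AbundanceMatrix":
        """Return a copy holding ``values`` (and optionally a new scale)."""
        return AbundanceMatrix(
            values=values,
            gene_symbols=self.gene_symbols.reindex(values.index),
            scale=self.scale if scale is None else scale,
        )

    def subset_proteins(self, ids: Iterable[str]) -> "AbundanceMatrix":
        return self.with_values(self.values.loc[list(ids)])

    def subset_samples(self, ids: Iterable[str]) -> "AbundanceMatrix":
        return self.with_values(self.values.loc[:, list(ids)])


def validate_metadata(metadata: pd.DataFrame, matrix: AbundanceMatrix | None = None) -> None:
    """Check the sample table covers the matrix and has the required design columns."""
    missing_cols = [c for c in REQUIRED_METADATA if c not in metadata.columns]
    if missing_cols:
        raise ConfigurationError(f"metadata lacks required columns: {missing_cols}")
    if metadata.index.has_duplicates:
        raise FormatError("duplicate sample ids in metadata")
    if matrix is not None:
        absent = matrix.sample_ids.difference(metadata.index)
        if len(absent):
            raise ConfigurationError(
                f"samples missing from metadata: {absent[:5].tolist()}"
            )


def biological_samples(metadata: pd.DataFrame) -> pd.Index:
    """Sample ids of non-GIS (biological) channels."""
    return metadata.index[~metadata["is_gis"].astype(bool)]


@dataclass
class ModuleNetwork:
    """Consensus co-expression modules with per-module eigenproteins.

    ``members`` maps module label -> member identifiers (gene symbols for a
    brain reference network).  ``eigenproteins`` holds one unit-norm row per
    module over the reference samples; the ``grey`` catch-all has no
    eigenprotein.  ``explained_variance`` is the share of member variance
    captured by each eigenprotein.
    """

    members: dict[str, list[str]]
    eigenproteins: pd.DataFrame
    explained_variance: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        for label in self.eigenproteins.index:
            if label == "grey":
                raise ConfigurationError("grey carries no eigenprotein")

    @property
    def module_labels(self) -> list[str]:
        return list(self.eigenproteins.index)

    def member_lookup(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for label, members in self.members.items():
            for m in members:
                out[m] = label
        return out


@dataclass
class GroundTruth:
    """What the synthetic generator actually injected, for recovery checks."""

    true_log2fc: pd.Series                      # per protein, 0 for non-DE
    batch_offsets: pd.DataFrame                 # protein x batch, log2 units
    covariate_slopes: pd.DataFrame              # protein x covariate
    module_labels: pd.Series                    # per protein, 'grey' = background
    missing_prob: pd.DataFrame | None = None    # protein x sample


def check_frame_alignment(truth: GroundTruth, matrix: AbundanceMatrix) -> None:
    if not truth.true_log2fc.index.equals(matrix.protein_ids):
        raise ConfigurationError("ground truth misaligned with matrix proteins")
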