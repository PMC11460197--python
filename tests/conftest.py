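"""Shared fixtures: small matrices and designs built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plasmatmt.types import AbundanceMatrix


def make_matrix(values, sample_ids=None, protein_ids=None, scale="raw"):
    """Build an AbundanceMatrix from a 2-D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n_p, n_s = values.shape
    protein_ids = protein_ids or [f"P{i}" for i in range(n_p)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_s)]
    df = pd.DataFrame(values, index=protein_ids, columns=sample_ids)
    df.index.name = "protein_id"
    symbols = pd.Series([f"G{i}" for i in range(n_p)], index=df.index,
                        name="gene_symbol")
    return AbundanceMatrix(values=df, gene_symbols=symbols, scale=scale)


def make_metadata(sample_ids, diagnosis=None, batch=None, is_gis=None,
                  set_name="set1", **extra):
    n = len(sample_ids)
    meta = pd.DataFrame({
        "set": set_name,
        "batch": batch if batch is not None else ["b1"] * n,
        "channel": [f"ch{j}" for j in range(n)],
        "is_gis": is_gis if is_gis is not None else [False] * n,
        "diagnosis": diagnosis if diagnosis is not None else ["control"] * n,
    }, index=pd.Index(sample_ids, name="sample_id"))
    for key, vals in extra.items():
        meta[key] = vals
    return meta


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def two_batch_fixture(rng):
    """100-protein, 2-batch log2 matrix with a +1 offset on batch 2 and GIS."""
    n_p, n_per = 100, 8
    base = rng.uniform(10, 25, n_p)
    cols, vals = [], []
    meta_rows = {"batch": [], "is_gis": [], "diagnosis": []}
    for b, off in ((1, 0.0), (2, 1.0)):
        for j in range(n_per):
            cols.append(f"b{b}.s{j}")
            vals.append(base + off)
            meta_rows["batch"].append(f"b{b}")
            meta_rows["is_gis"].append(False)
            meta_rows["diagnosis"].append("control" if j % 2 else "AD")
        cols.append(f"b{b}.gis")
        vals.append(base + off)
        meta_rows["batch"].append(f"b{b}")
        meta_rows["is_gis"].append(True)
        meta_rows["diagnosis"].append("none")
    mat = make_matrix(np.column_stack(vals), sample_ids=cols, scale="log2")
    meta = make_metadata(cols, **meta_rows)
    return mat, meta, base
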