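"""Synthetic two-set, multi-batch TMT-like plasma datasets with known truth.

The generator emulates the design of a heparin-enriched plasma TMT study of
Alzheimer's disease: a discovery set (18 control + 18 AD in 3 batches) and a
replication set (36 control + 49 AD in 5 batches), each batch carrying a
pooled global internal standard (GIS) channel; protein abundances spanning
many orders of magnitude; abundance-dependent (MNAR) missingness; a minority
of proteins differentially abundant between AD and control; batch and
covariate effects; CSF/plasma biomarker traits drawn per diagnosis group;
and a latent block (module) correlation structure.

Every quantity injected is recorded in a :class:`~plasmatmt.types.GroundTruth`
so downstream stages can be tested for recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .types import (
    AbundanceMatrix,
    ConfigurationError,
    GroundTruth,
    ModuleNetwork,
    TRAIT_COLUMNS,
)
from .network import compute_eigenprotein

# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: per-set, per-group trait means and standard deviations (pg/ml; MoCA is a
#: 0-30 cognition score).  The Set-2 control CSF pTau181 cell is a synthetic
#: stand-in chosen to be consistent with the other cells (source table cell
#: unavailable); every other entry reflects the emulated cohort.
DEFAULT_TRAIT_PARAMS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "MoCA": {
        "set1": {"control": (27.1, 1.6), "AD": (13.1, 7.2)},
        "set2": {"control": (26.9, 2.0), "AD": (16.5, 6.7)},
    },
    "CSF_Abeta42": {
        "set1": {"control": (552.1, 95.0), "AD": (223.9, 75.0)},
        "set2": {"control": (499.8, 137.7), "AD": (313.7, 145.6)},
    },
    "CSF_tTau": {
        "set1": {"control": (41.8, 18.3), "AD": (148.5, 70.0)},
        "set2": {"control": (54.9, 26.5), "AD": (108.6, 43.3)},
    },
    "CSF_pTau181": {
        "set1": {"control": (25.4, 9.0), "AD": (58.7, 18.2)},
        "set2": {"control": (27.0, 10.0), "AD": (61.6, 25.6)},
    },
    "plasma_pTau181": {
        "set1": {"control": (1.7, 0.7), "AD": (4.8, 2.0)},
        "set2": {"control": (2.4, 1.0), "AD": (3.8, 1.2)},
    },
}

#: hard physical ranges used to truncate sampled traits
TRAIT_BOUNDS = {
    "MoCA": (0.0, 30.0),
    "CSF_Abeta42": (1.0, np.inf),
    "CSF_tTau": (1.0, np.inf),
    "CSF_pTau181": (0.5, np.inf),
    "plasma_pTau181": (0.05, np.inf),
}

#: per-set, per-group mean ages (years) of the emulated cohort
AGE_PARAMS = {
    "set1": {"control": (68.6, 9.2), "AD": (65.2, 12.1)},
    "set2": {"control": (70.4, 8.9), "AD": (66.1, 6.6)},
}


@dataclass
class SyntheticDesign:
    """Parameters of a two-set synthetic TMT plasma experiment.

    Counts default to the emulated study design (set 1: 18+18 in 3 batches,
    set 2: 36+49 in 5 batches, one GIS channel per batch).  ``frac_de``
    proteins carry a true AD-vs-control log2 fold-change drawn from
    ``Normal(effect_log2fc_mean, effect_log2fc_sd)``; base abundances are
    log10-uniform over ``base_abundance_log10`` (default ten orders of
    magnitude); batch effects are protein-specific additive offsets in log2;
    missingness is logistic in log2 abundance (missing-not-at-random);
    traits are Gaussian per diagnosis group, truncated to plausible ranges,
    and coupled to the differential proteins through a per-sample signal
    score so protein-trait correlations exist by construction.
    """

    n_proteins: int = 2000
    # (n_control, n_AD) per set
    n_samples_per_set: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"set1": (18, 18), "set2": (36, 49)}
    )
    n_batches_per_set: dict[str, int] = field(
        default_factory=lambda: {"set1": 3, "set2": 5}
    )
    gis_per_batch: int = 1
    frac_de: float = 0.10
    effect_log2fc_mean: float = 0.0
    effect_log2fc_sd: float = 0.5
    base_abundance_log10: tuple[float, float] = (0.0, 10.0)
    batch_log2_sd: float = 0.4
    noise_log2_sd: float = 0.3
    # GIS channels re-measure one pooled aliquot, so their spread is
    # technical only (TMT reporter technical CV ~10% => ~0.1 in log2)
    gis_noise_log2_sd: float = 0.1
    # covariate -> sd of the per-protein slope (slopes drawn N(0, sd^2));
    # age in log2 per year, sex/race contrasts in log2 units
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.002, "sex": 0.05, "race": 0.05}
    )
    mnar_intercept: float = 2.0
    mnar_slope: float = 0.3
    trait_params: dict = field(default_factory=lambda: DEFAULT_TRAIT_PARAMS)
    trait_coupling: float = 0.4
    n_modules: int = 10
    module_size: int = 30
    module_purity: float = 0.9
    n_reference_samples: int = 60
    overlap_controls: int = 0  # shared control draws between sets (defaults off)
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigurationError("n_proteins must be positive")
        for s, (nc, na) in self.n_samples_per_set.items():
            if nc <= 0 or na <= 0:
                raise ConfigurationError(f"sample counts for {s} must be positive")
            if s not in self.n_batches_per_set:
                raise ConfigurationError(f"no batch count for {s}")
            if self.n_batches_per_set[s] <= 0:
                raise ConfigurationError(f"batch count for {s} must be positive")
        if self.gis_per_batch < 1:
            raise ConfigurationError("gis_per_batch must be >= 1")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ConfigurationError("frac_de must lie in [0, 1]")
        if not 0.0 < self.module_purity <= 1.0:
            raise ConfigurationError("module_purity must lie in (0, 1]")
        if self.module_size < 2:
            raise ConfigurationError("module_size must be >= 2")
        if self.n_modules * self.module_size > self.n_proteins:
            raise ConfigurationError("modules cannot cover more proteins than exist")
        if self.overlap_controls > min(n[0] for n in self.n_samples_per_set.values()):
            raise ConfigurationError("overlap_controls exceeds a set's control count")


# ---------------------------------------------------------------------------
# Ground-truth effect layers
# ---------------------------------------------------------------------------

def _draw_protein_truth(design: SyntheticDesign, rng: np.random.Generator):
    p = design.n_proteins
    protein_ids = pd.Index([f"P{i:05d}" for i in range(p)], name="protein_id")
    gene_symbols = pd.Series([f"GENE{i:05d}" for i in range(p)], index=protein_ids,
                             name="gene_symbol")

    lo, hi = design.base_abundance_log10
    base_log2 = rng.uniform(lo, hi, size=p) * np.log2(10.0)

    true_lfc = np.zeros(p)
    n_de = int(round(design.frac_de * p))
    de_idx = rng.choice(p, size=n_de, replace=False)
    true_lfc[de_idx] = rng.normal(design.effect_log2fc_mean,
                                  design.effect_log2fc_sd, size=n_de)

    module_labels = np.array(["grey"] * p, dtype=object)
    for m in range(design.n_modules):
        lo_i = m * design.module_size
        module_labels[lo_i:lo_i + design.module_size] = f"M{m + 1}"

    return protein_ids, gene_symbols, base_log2, true_lfc, module_labels


def _sample_table(design: SyntheticDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Per-sample design rows: set, batch, channel, GIS flag, diagnosis, covariates."""
    rows = []
    for set_name, (n_ctl, n_ad) in design.n_samples_per_set.items():
        n_batches = design.n_batches_per_set[set_name]
        diagnoses = ["control"] * n_ctl + ["AD"] * n_ad
        n_bio = len(diagnoses)
        # batch randomization stratified by diagnosis (the emulated study
        # balanced batches on diagnosis), so group-batch counts differ by <= 1
        batch_seq = np.empty(n_bio, dtype=int)
        for n_grp, offset in ((n_ctl, 0), (n_ad, n_ctl)):
            grp_seq = np.tile(np.arange(n_batches),
                              n_grp // n_batches + 1)[:n_grp]
            rng.shuffle(grp_seq)
            batch_seq[offset:offset + n_grp] = grp_seq
        for i, (dx, b) in enumerate(zip(diagnoses, batch_seq)):
            sid = f"{set_name}.{dx}.{i:03d}"
            rows.append({
                "sample_id": sid,
                "subject_id": sid,
                "set": set_name,
                "batch": f"{set_name}.b{b + 1}",
                "channel": f"ch{i + 1}",
                "is_gis": False,
                "diagnosis": dx,
            })
        for b in range(n_batches):
            for g in range(design.gis_per_batch):
                rows.append({
                    "sample_id": f"{set_name}.GIS.b{b + 1}.{g + 1}",
                    "subject_id": f"{set_name}.GIS",
                    "set": set_name,
                    "batch": f"{set_name}.b{b + 1}",
                    "channel": f"GIS{g + 1}",
                    "is_gis": True,
                    "diagnosis": "none",
                })
    meta = pd.DataFrame(rows).set_index("sample_id")

    bio = ~meta["is_gis"]
    n_bio = int(bio.sum())
    ages = np.empty(len(meta))
    ages[:] = np.nan
    for set_name in design.n_samples_per_set:
        for dx in ("control", "AD"):
            sel = bio & (meta["set"] == set_name) & (meta["diagnosis"] == dx)
            mu, sd = AGE_PARAMS[set_name][dx]
            ages[sel.to_numpy()] = np.clip(rng.normal(mu, sd, sel.sum()), 45, 95)
    meta["age"] = np.round(ages, 1)
    meta.loc[bio, "sex"] = rng.choice(["F", "M"], size=n_bio)
    meta.loc[bio, "race"] = rng.choice(["White", "Black", "Other"], size=n_bio,
                                       p=[0.7, 0.25, 0.05])
    return meta


def _draw_traits(design: SyntheticDesign, meta: pd.DataFrame,
                 signal_score: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    """Gaussian per-group traits, coupled to the per-sample DE signal score.

    ``signal_score`` is the standardized (within set x group) mean abundance
    deviation of the differential proteins for each biological sample; a
    coupling of rho means each trait is rho-correlated with that score within
    its group, signed so that traits elevated in AD couple positively.
    """
    rho = float(np.clip(design.trait_coupling, 0.0, 0.99))
    traits = pd.DataFrame(index=meta.index, columns=list(TRAIT_COLUMNS), dtype=float)
    bio = ~meta["is_gis"]
    for trait in TRAIT_COLUMNS:
        per_set = design.trait_params[trait]
        for set_name in design.n_samples_per_set:
            groups = per_set[set_name]
            ad_up = groups["AD"][0] > groups["control"][0]
            sign = 1.0 if ad_up else -1.0
            for dx in ("control", "AD"):
                sel = bio & (meta["set"] == set_name) & (meta["diagnosis"] == dx)
                n = int(sel.sum())
                mu, sd = groups[dx]
                z = signal_score.loc[sel[sel].index].to_numpy()
                eps = rng.normal(size=n)
                vals = mu + sd * (sign * rho * z + np.sqrt(1 - rho ** 2) * eps)
                lo_b, hi_b = TRAIT_BOUNDS[trait]
                traits.loc[sel, trait] = np.clip(vals, lo_b, hi_b)
    return traits.round(2)


# ---------------------------------------------------------------------------
# Main generators
# ---------------------------------------------------------------------------

def simulate_dataset(design: SyntheticDesign):
    """Generate a raw two-set TMT-like dataset.

    Returns
    -------
    (AbundanceMatrix, pandas.DataFrame, GroundTruth)
        Raw-scale intensities (missing cells already imposed per the MNAR
        model), the sample metadata table indexed by sample id, and the
        injected ground truth.

    Notes
    -----
    On the log2 scale each biological measurement is::

        base_i + lfc_i * 1{AD} + sum_c beta_ic * cov_cj + batch_ib + eps_ij

    with residuals ``eps`` correlated within latent modules (correlation =
    ``module_purity``) and independent elsewhere.  Each GIS channel is the
    arithmetic mean of its set's noiseless biological intensities (a pooled
    aliquot), then perturbed by its batch offset and measurement noise.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    protein_ids, gene_symbols, base_log2, true_lfc, module_labels = \
        _draw_protein_truth(design, rng)
    meta = _sample_table(design, rng)

    # optional re-assay of shared control subjects across the two sets
    shared_pairs: list[tuple[str, str]] = []
    if design.overlap_controls > 0 and len(design.n_samples_per_set) >= 2:
        set_names = list(design.n_samples_per_set)
        src = meta.index[(meta["set"] == set_names[0])
                         & (meta["diagnosis"] == "control")]
        dst = meta.index[(meta["set"] == set_names[1])
                         & (meta["diagnosis"] == "control")]
        for a, b in zip(src[:design.overlap_controls], dst[:design.overlap_controls]):
            meta.loc[b, ["subject_id", "age", "sex", "race"]] = \
                meta.loc[a, ["subject_id", "age", "sex", "race"]]
            shared_pairs.append((a, b))

    p = design.n_proteins
    batches = sorted(meta["batch"].unique())
    batch_offsets = pd.DataFrame(
        rng.normal(0.0, design.batch_log2_sd, size=(p, len(batches))),
        index=protein_ids, columns=batches,
    )

    cov_names = sorted(design.covariate_effects)
    slopes = pd.DataFrame(
        {c: rng.normal(0.0, design.covariate_effects[c], size=p) for c in cov_names},
        index=protein_ids,
    )

    bio_ids = meta.index[~meta["is_gis"]]
    # numeric covariate codings: age centered at 70, sex M=1, race non-White=1
    cov_values = pd.DataFrame(index=bio_ids, dtype=float)
    if "age" in cov_names:
        cov_values["age"] = meta.loc[bio_ids, "age"] - 70.0
    if "sex" in cov_names:
        cov_values["sex"] = (meta.loc[bio_ids, "sex"] == "M").astype(float)
    if "race" in cov_names:
        cov_values["race"] = (meta.loc[bio_ids, "race"] != "White").astype(float)

    is_ad = (meta.loc[bio_ids, "diagnosis"] == "AD").astype(float).to_numpy()

    # clean (noiseless, batch-free) biological signal in log2
    clean = (base_log2[:, None]
             + np.outer(true_lfc, is_ad)
             + slopes.to_numpy() @ cov_values[cov_names].to_numpy().T)

    # residual noise with latent module correlation
    purity = design.module_purity
    eps = rng.normal(size=(p, len(bio_ids)))
    factors: dict[tuple[str, str], np.ndarray] = {}
    set_of = meta.loc[bio_ids, "set"].to_numpy()
    for m in range(design.n_modules):
        label = f"M{m + 1}"
        f = rng.normal(size=len(bio_ids))
        members = module_labels == label
        eps[members] = (np.sqrt(purity) * f[None, :]
                        + np.sqrt(1 - purity) * eps[members])
        factors[label] = f
    noise = design.noise_log2_sd * eps
    # shared subjects share their biological signal and person-level residual
    bio_pos = {sid: k for k, sid in enumerate(bio_ids)}
    for a, b in shared_pairs:
        noise[:, bio_pos[b]] = noise[:, bio_pos[a]]
        clean[:, bio_pos[b]] = clean[:, bio_pos[a]]

    log2_bio = clean + noise + batch_offsets[meta.loc[bio_ids, "batch"]].to_numpy()
    raw_bio = np.exp2(log2_bio)

    # GIS channels: pooled mean of the set's clean intensities
    gis_ids = meta.index[meta["is_gis"]]
    raw_gis = np.empty((p, len(gis_ids)))
    for k, gid in enumerate(gis_ids):
        set_name = meta.loc[gid, "set"]
        in_set = set_of == set_name
        pooled = np.exp2(clean[:, in_set]).mean(axis=1)
        gis_noise = design.gis_noise_log2_sd * rng.normal(size=p)
        raw_gis[:, k] = pooled * np.exp2(
            batch_offsets[meta.loc[gid, "batch"]].to_numpy() + gis_noise)

    values = pd.DataFrame(
        np.hstack([raw_bio, raw_gis]),
        index=protein_ids,
        columns=list(bio_ids) + list(gis_ids),
    )[meta.index]  # restore metadata order

    # per-sample DE signal score for trait coupling (standardized within
    # set x diagnosis so it does not re-encode the group difference)
    de = true_lfc != 0
    if de.any():
        contrib = (np.sign(true_lfc[de])[:, None] * noise[de]).mean(axis=0)
    else:
        contrib = np.zeros(len(bio_ids))
    score = pd.Series(contrib, index=bio_ids)
    for set_name in design.n_samples_per_set:
        for dx in ("control", "AD"):
            sel = (meta.loc[bio_ids, "set"] == set_name) & \
                  (meta.loc[bio_ids, "diagnosis"] == dx)
            v = score[sel]
            sd = v.std(ddof=0)
            score[sel] = (v - v.mean()) / sd if sd > 0 else 0.0
    traits = _draw_traits(design, meta, score, rng)
    for a, b in shared_pairs:
        traits.loc[b] = traits.loc[a]
    meta = meta.join(traits)

    truth = GroundTruth(
        true_log2fc=pd.Series(true_lfc, index=protein_ids, name="true_log2fc"),
        batch_offsets=batch_offsets,
        covariate_slopes=slopes,
        module_labels=pd.Series(module_labels, index=protein_ids, name="module"),
    )

    matrix = AbundanceMatrix(values=values, gene_symbols=gene_symbols, scale="raw")
    matrix, truth = impose_missingness(matrix, design, truth=truth, rng=rng)
    return matrix, meta, truth


def impose_missingness(matrix: AbundanceMatrix, design: SyntheticDesign,
                       truth: GroundTruth | None = None,
                       rng: np.random.Generator | None = None):
    """Censor cells missing-not-at-random, logistic in log2 abundance.

    Each cell is set missing independently with probability
    ``expit(mnar_intercept - mnar_slope * log2(x))``, so low-abundance
    measurements vanish preferentially — the dominant missingness pattern of
    intensity-based proteomics.  Probabilities are stored in the ground
    truth when one is supplied.
    """
    if matrix.scale != "raw":
        raise ConfigurationError("missingness is imposed on the raw scale")
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    vals = matrix.values.to_numpy(copy=True)
    with np.errstate(divide="ignore"):
        log2x = np.log2(np.where(vals > 0, vals, np.nan))
    prob = expit(design.mnar_intercept - design.mnar_slope * log2x)
    prob = np.where(np.isnan(prob), 1.0, prob)
    drop = rng.random(vals.shape) < prob
    vals[drop] = np.nan
    out = matrix.with_values(pd.DataFrame(vals, index=matrix.protein_ids,
                                          columns=matrix.sample_ids))
    if truth is not None:
        truth.missing_prob = pd.DataFrame(prob, index=matrix.protein_ids,
                                          columns=matrix.sample_ids)
    return out, truth


def simulate_reference_brain(design: SyntheticDesign,
                             rng: np.random.Generator | None = None):
    """Generate a reference (brain-like) expression matrix with known modules.

    Module members follow ``sqrt(purity) * factor + sqrt(1-purity) * noise``
    around a protein-specific baseline; remaining proteins are uncorrelated
    background.  Returns the log2-scale matrix, a :class:`ModuleNetwork`
    whose eigenproteins are computed from the generated matrix itself, and a
    per-reference-sample trait table (CERAD / Braak / MMSE analogues coupled
    to the first module's latent factor).
    """
    design.validate()
    if rng is None:
        rng = np.random.default_rng(design.seed + 2)
    p, n = design.n_proteins, design.n_reference_samples
    protein_ids = pd.Index([f"P{i:05d}" for i in range(p)], name="protein_id")
    gene_symbols = pd.Series([f"GENE{i:05d}" for i in range(p)], index=protein_ids,
                             name="gene_symbol")
    sample_ids = [f"brain.{j:03d}" for j in range(n)]

    purity = design.module_purity
    base = rng.uniform(*design.base_abundance_log10, size=p) * np.log2(10.0)
    eps = rng.normal(size=(p, n))
    module_labels = np.array(["grey"] * p, dtype=object)
    factors = {}
    for m in range(design.n_modules):
        label = f"M{m + 1}"
        lo = m * design.module_size
        module_labels[lo:lo + design.module_size] = label
        f = rng.normal(size=n)
        factors[label] = f
        eps[lo:lo + design.module_size] = (np.sqrt(purity) * f[None, :]
                                           + np.sqrt(1 - purity)
                                           * eps[lo:lo + design.module_size])
    values = pd.DataFrame(base[:, None] + design.noise_log2_sd * eps,
                          index=protein_ids, columns=sample_ids)
    matrix = AbundanceMatrix(values=values, gene_symbols=gene_symbols, scale="log2")

    members = {f"M{m + 1}": list(protein_ids[m * design.module_size:
                                             (m + 1) * design.module_size])
               for m in range(design.n_modules)}
    eig_rows, ev = {}, {}
    for label, mem in members.items():
        vec, share = compute_eigenprotein(values, mem)
        eig_rows[label] = vec
        ev[label] = share
    network = ModuleNetwork(
        members=members,
        eigenproteins=pd.DataFrame(eig_rows).T,
        explained_variance=pd.Series(ev),
    )

    f1 = factors.get("M1", np.zeros(n))
    z = (f1 - f1.mean()) / (f1.std() or 1.0)
    ref_traits = pd.DataFrame({
        "CERAD": np.clip(np.round(1.5 + 1.0 * z + 0.8 * rng.normal(size=n)), 0, 3),
        "Braak": np.clip(np.round(3.0 + 1.2 * z + 1.0 * rng.normal(size=n)), 0, 6),
        "MMSE": np.clip(np.round(20.0 - 5.0 * z + 4.0 * rng.normal(size=n)), 0, 30),
    }, index=pd.Index(sample_ids, name="sample_id"))

    truth_labels = pd.Series(module_labels, index=protein_ids, name="module")
    return matrix, network, ref_traits, truth_labels
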