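"""On-disk formats, run configuration, and the end-to-end pipeline driver.

Wide TSV is the canonical matrix format: first two columns are the protein
accession and gene symbol, remaining columns one sample each.  Empty cells,
"NA", "NaN" — and, for TMT reporter data, literal zeros — denote missing.
Sample metadata travels as CSV indexed by sample id; gene sets as standard
GMT.  :func:`run_pipeline` chains every stage (simulate/load -> normalize ->
batch-correct -> per-set differential -> meta -> traits -> module mapping ->
enrichment -> ROC) and writes one TSV per result table plus a
machine-readable summary carrying counts, seeds and the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    AbundanceMatrix,
    ConfigurationError,
    FormatError,
    ModuleNetwork,
    TRAIT_COLUMNS,
    validate_metadata,
)

log = logging.getLogger("plasmatmt")

MISSING_MARKERS = {"", "NA", "NaN", "nan", "na"}


# ---------------------------------------------------------------------------
# Abundance matrices
# ---------------------------------------------------------------------------

def read_abundance(path, zero_as_missing: bool = True,
                   scale: str = "raw") -> AbundanceMatrix:
    """Read a wide TSV abundance matrix.

    Expects columns ``protein_id``, ``gene_symbol``, then one column per
    sample.  Empty / "NA" / "NaN" cells are missing; zeros are converted to
    missing when ``zero_as_missing`` (the TMT reporter-ion convention).
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 3:
        raise FormatError(f"{path}: need protein_id, gene_symbol and >= 1 sample")
    samples = header[2:]
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample columns {dup}")

    df = pd.read_csv(path, sep="\t", dtype={header[0]: str, header[1]: str},
                     na_values=list(MISSING_MARKERS), keep_default_na=False)
    for col in samples:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(
                f"{path}: non-numeric value {df.at[row, col]!r} at row "
                f"{row + 2}, column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    values = df.set_index(header[0])[samples].astype(float)
    values.index.name = "protein_id"
    if zero_as_missing:
        values = values.where(values != 0.0)
    symbols = df.set_index(header[0])[header[1]].rename("gene_symbol")
    return AbundanceMatrix(values=values, gene_symbols=symbols, scale=scale)


def read_abundance_long(path, zero_as_missing: bool = True,
                        scale: str = "raw") -> AbundanceMatrix:
    """Read a long-format table (protein_id, gene_symbol, sample_id, value).

    Normalized internally to the same wide representation as
    :func:`read_abundance`; pairs absent from the file are missing.
    """
    df = pd.read_csv(path, sep="\t",
                     na_values=list(MISSING_MARKERS), keep_default_na=False)
    required = {"protein_id", "gene_symbol", "sample_id", "value"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: long format needs columns {sorted(required)}")
    if df.duplicated(["protein_id", "sample_id"]).any():
        raise FormatError(f"{path}: duplicate (protein, sample) pairs")
    values = df.pivot(index="protein_id", columns="sample_id", values="value") \
        .astype(float)
    if zero_as_missing:
        values = values.where(values != 0.0)
    symbols = df.drop_duplicates("protein_id") \
        .set_index("protein_id")["gene_symbol"]
    return AbundanceMatrix(values=values, gene_symbols=symbols, scale=scale)


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    """Write a wide TSV (full float precision, missing as empty cells)."""
    out = matrix.values.copy()
    out.insert(0, "gene_symbol", matrix.gene_symbols)
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="", float_format="%.17g")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col="sample_id")
    meta["is_gis"] = meta["is_gis"].astype(bool)
    validate_metadata(meta)
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Gene sets (GMT) and module tables
# ---------------------------------------------------------------------------

def read_gmt(path, on_duplicate: str = "error") -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, members (tab-separated).

    Duplicate members collapse; duplicate set names raise by default
    (``on_duplicate='suffix'`` appends a counter instead).  Lines with
    fewer than three fields are format errors; sets that end up empty are
    dropped.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name = fields[0]
            members = {m for m in fields[2:] if m}
            if not members:
                continue
            if name in sets:
                if on_duplicate == "error":
                    raise FormatError(f"{path}:{lineno}: duplicate set {name!r}")
                i = 2
                while f"{name}.{i}" in sets:
                    i += 1
                name = f"{name}.{i}"
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description] + sorted(sets[name])) + "\n")


def read_module_table(path) -> dict[str, list[str]]:
    """Read a two-column TSV mapping protein/gene -> module label."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: module table needs id and module columns")
    members: dict[str, list[str]] = {}
    for ident, label in zip(df.iloc[:, 0], df.iloc[:, 1]):
        members.setdefault(str(label), []).append(str(ident))
    return members


def write_module_table(labels: pd.Series, path) -> None:
    labels.rename("module").to_csv(path, sep="\t", index_label="protein_id")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every stage parameter of a pipeline run, serializable to YAML."""

    # normalization
    max_missing_frac: float = 0.5
    zero_as_missing: bool = True
    impute: bool = False
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    # batch correction
    use_gis: bool = True
    polish_tol: float = 1e-6
    polish_max_iter: int = 100
    covariates: tuple[str, ...] = ("age", "sex", "race")
    protected: tuple[str, ...] = ("diagnosis",)
    bootstrap_B: int = 200
    # differential / meta
    fdr: float = 0.05
    heatmap_fdr: float = 0.0005
    equal_var: bool = True
    combine_method: str = "fisher"
    at_ratio_cut: float = 0.226
    moca_ad: float = 24.0
    moca_ctl: float = 24.0
    # network mapping / enrichment
    kme_min: float = 0.30
    min_genes: int = 5
    z_cut: float = 1.96
    # classification
    meta_p_max: float = 1e-4
    panel_size: int = 5
    roc_covariate: str = "plasma_pTau181"
    # synthetic input
    seed: int = 0
    design: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 <= self.max_missing_frac <= 1:
            raise ConfigurationError("max_missing_frac outside [0, 1]")
        for name in ("fdr", "heatmap_fdr", "meta_p_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} outside (0, 1]")
        if self.kme_min < 0 or self.kme_min > 1:
            raise ConfigurationError("kme_min outside [0, 1]")
        if self.bootstrap_B < 1 or self.panel_size < 1 or self.min_genes < 0:
            raise ConfigurationError("counts must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        d["protected"] = list(self.protected)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for k in ("covariates", "protected"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage on a seeded synthetic two-set dataset.

    Writes one TSV per result table under ``out_dir`` plus ``summary.json``
    recording the counts at each filter, the thresholds and seeds used, and
    the config hash.  Returns the summary dict.
    """
    from . import batch, classify, differential, meta as meta_mod, network, normalize
    from .simulate import SyntheticDesign, simulate_dataset, simulate_reference_brain

    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.hash(), "seed": config.seed,
                     "thresholds": {
                         "max_missing_frac": config.max_missing_frac,
                         "at_ratio_cut": config.at_ratio_cut,
                         "moca_ad": config.moca_ad, "moca_ctl": config.moca_ctl,
                         "kme_min": config.kme_min, "meta_p_max": config.meta_p_max,
                         "fdr": config.fdr, "z_cut": config.z_cut,
                     }, "stages": {}}

    def stage(name):
        log.info("stage %s", name)
        summary["stages"][name] = {}
        return summary["stages"][name]

    design_kwargs = dict(config.design)
    design_kwargs.setdefault("seed", config.seed)
    design = SyntheticDesign(**design_kwargs)

    # -- simulate ----------------------------------------------------------
    s = stage("simulate")
    raw, metadata, truth = simulate_dataset(design)
    s["n_proteins"] = raw.n_proteins
    s["n_samples"] = raw.n_samples
    write_abundance(raw, out_dir / "abundance_raw.tsv")
    write_metadata(metadata, out_dir / "metadata.csv")
    truth.true_log2fc.to_csv(out_dir / "truth_log2fc.tsv", sep="\t")
    write_module_table(truth.module_labels, out_dir / "truth_modules.tsv")

    # -- normalize + batch-correct per set ---------------------------------
    corrected = {}
    stats_per_set = {}
    for set_name in sorted(design.n_samples_per_set):
        s = stage(f"normalize.{set_name}")
        ids = metadata.index[metadata["set"] == set_name]
        sub = raw.subset_samples(ids)
        scaled, _ = normalize.channel_sum_scale(sub)
        filtered, dropped = normalize.filter_missingness(
            scaled, config.max_missing_frac)
        s["n_dropped_missingness"] = len(dropped)
        s["n_retained"] = filtered.n_proteins
        logged = normalize.log2_transform(filtered)
        if config.impute:
            logged = normalize.impute_downshifted_normal(
                logged, config.impute_width, config.impute_downshift,
                seed=config.seed + 11)

        s = stage(f"batch_correct.{set_name}")
        tampored, polish = batch.tampor_correct(
            logged, metadata, use_gis=config.use_gis,
            tol=config.polish_tol, max_iter=config.polish_max_iter)
        s["polish_iterations"] = polish.n_iter
        s["polish_converged"] = polish.converged
        regressed, report = batch.bootstrap_regress(
            tampored, metadata, covariates=list(config.covariates),
            protected=tuple(config.protected), B=config.bootstrap_B,
            seed=config.seed + 17)
        s["n_uncorrected"] = len(report.uncorrected)
        corrected[set_name] = regressed
        write_abundance(regressed, out_dir / f"corrected_{set_name}.tsv")

        s = stage(f"differential.{set_name}")
        tab = differential.ttest_by_group(
            regressed, metadata, equal_var=config.equal_var)
        stats_per_set[set_name] = tab
        s["n_tested"] = int(tab["p"].notna().sum())
        s["n_fdr"] = int((tab["q"] < config.fdr).sum())
        tab.to_csv(out_dir / f"differential_{set_name}.tsv", sep="\t",
                   float_format="%.10g")

    # -- AT+ filter + meta -------------------------------------------------
    s = stage("at_filter")
    retained, exclusions = meta_mod.at_filter(
        metadata, config.at_ratio_cut, config.moca_ad, config.moca_ctl)
    s["n_retained"] = len(retained)
    s["n_excluded"] = len(exclusions)
    exclusions.to_csv(out_dir / "at_exclusions.tsv", sep="\t")

    set_names = sorted(design.n_samples_per_set)
    filt_stats = {}
    for set_name in set_names:
        keep = [sid for sid in retained
                if metadata.at[sid, "set"] == set_name
                and sid in corrected[set_name].sample_ids]
        sub = corrected[set_name].subset_samples(
            list(keep) + [sid for sid in corrected[set_name].sample_ids
                          if metadata.at[sid, "is_gis"]])
        filt_stats[set_name] = differential.ttest_by_group(
            sub, metadata, equal_var=config.equal_var)

    s = stage("meta")
    meta_table = meta_mod.combine_sets(filt_stats[set_names[0]],
                                       filt_stats[set_names[1]],
                                       method=config.combine_method)
    s["n_proteins"] = len(meta_table)
    s["n_meta_sig"] = int((meta_table["meta_p"] < config.meta_p_max).sum())
    r, p_conc, disc = meta_mod.concordance(
        filt_stats[set_names[0]]["log2fc"], filt_stats[set_names[1]]["log2fc"])
    s["set_concordance_r"] = r
    s["discordant_fraction"] = disc
    meta_table.to_csv(out_dir / "meta.tsv", sep="\t", float_format="%.10g")

    # -- traits ------------------------------------------------------------
    s = stage("traits")
    bio_retained = [sid for sid in retained]
    joint = pd.concat([corrected[sn].values for sn in set_names], axis=1)
    joint = joint.loc[:, ~joint.columns.duplicated()]
    joint_mat = AbundanceMatrix(
        values=joint[[c for c in joint.columns if c in bio_retained]],
        gene_symbols=raw.gene_symbols, scale="corrected")
    zmat, dropped_z = meta_mod.z_transform(joint_mat)
    sig_ids = meta_table.index[meta_table["meta_p"] < config.meta_p_max]
    zsig = zmat.subset_proteins([i for i in sig_ids if i in zmat.protein_ids])
    trait_tab = meta_mod.correlate_traits(zsig, metadata, list(TRAIT_COLUMNS))
    s["n_proteins"] = zsig.n_proteins
    trait_tab.to_csv(out_dir / "trait_correlations.tsv", sep="\t", index=False,
                     float_format="%.10g")

    # -- module mapping + enrichment --------------------------------------
    s = stage("modules")
    ref_matrix, net, ref_traits, true_labels = simulate_reference_brain(design)
    assignments = network.assign_modules(ref_matrix.values, net, config.kme_min)
    s["n_assigned"] = int(assignments["assigned"].sum())
    assignments.to_csv(out_dir / "module_assignments.tsv", sep="\t")
    mod_trait = network.module_trait_correlation(net, ref_traits)
    mod_trait.to_csv(out_dir / "module_trait.tsv", sep="\t", index=False,
                     float_format="%.10g")

    s = stage("enrichment")
    sym = raw.gene_symbols
    background = set(sym.reindex(meta_table.index).dropna())
    de_up = set(sym.reindex(meta_table.index[
        (meta_table["meta_p"] < config.meta_p_max)
        & (meta_table["mean_log2fc"] > 0)]).dropna())
    categories = {lab: set(sym.reindex(mem).dropna())
                  for lab, mem in net.members.items()}
    enr = network.fet_enrichment(de_up, categories, background,
                                 min_genes=config.min_genes)
    s["n_categories"] = len(enr)
    s["n_enriched"] = int(((enr["z"] > config.z_cut) & (enr["q"] < 0.05)).sum())
    enr.to_csv(out_dir / "enrichment.tsv", sep="\t", float_format="%.10g")

    # -- ROC ---------------------------------------------------------------
    s = stage("roc")
    eligible, cohort = classify.eligible_proteins(
        meta_table, zmat, metadata, meta_p_max=config.meta_p_max)
    s["n_eligible"] = len(eligible)
    s["n_cohort"] = len(cohort)
    if eligible:
        roc_mat = zmat.subset_proteins(eligible).subset_samples(cohort)
        y = (metadata.loc[cohort, "diagnosis"] == "AD").astype(int)
        cov = metadata.loc[cohort, config.roc_covariate] \
            if config.roc_covariate in metadata.columns else None
        report = classify.rank_and_panel(roc_mat, y, covariate=cov,
                                         k=config.panel_size)
        report.ranked.to_csv(out_dir / "roc_ranked.tsv", sep="\t",
                             float_format="%.10g")
        s["panel_members"] = report.panel.members
        s["panel_auc"] = report.panel_roc.auc
        if report.covariate_roc is not None:
            s["covariate_auc"] = report.covariate_roc.auc
            s["combined_auc"] = report.combined_roc.auc
            z, p_dl, dauc = report.delong_covariate_vs_combined
            s["delong_covariate_vs_combined"] = {"z": z, "p": p_dl,
                                                 "delta_auc": dauc}

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return summary


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
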