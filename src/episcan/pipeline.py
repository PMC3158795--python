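"""End-to-end discovery and replication runs driven by a config file.

A discovery run chains QC, trait preparation, the single-SNP scan (focal
SNPs at the consensus genome-wide threshold), the exhaustive pair scan with
retention filtering, the focal SNP-genome scan, gene annotation, and the
enrichment input/enrichment analysis.  A replication run tests discovery
pairs in a second cohort and compares term-level enrichment.  Every output
file carries a header with the config hash and seed so runs are exactly
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import enrich as enr
from . import genotypes as gio
from . import scan as sc
from . import trait as tr

log = logging.getLogger("episcan")


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for one pipeline run."""

    genotype_prefix: str = ""
    genotype_format: str = "plink"
    phenotype_path: str = ""
    gene_models_path: str | None = None
    gmt_path: str | None = None
    output_dir: str = "episcan_out"
    seed: int = 0
    adjacency: int = 2
    chunk_size: int = 512
    qc: gio.QcThresholds = field(default_factory=gio.QcThresholds)
    threshold_overrides: dict = field(default_factory=dict)
    enrichment_report_p: float = 1e-3

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc = gio.QcThresholds(**raw.pop("qc", {}))
        return RunConfig(qc=qc, **raw)

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def validate_paths(self) -> None:
        missing = []
        if self.genotype_format == "plink":
            for suf in (".bed", ".bim", ".fam"):
                p = Path(self.genotype_prefix).with_suffix(suf)
                if not p.exists():
                    missing.append(str(p))
        else:
            for suf in (".geno.tsv", ".map.tsv"):
                if not Path(f"{self.genotype_prefix}{suf}").exists():
                    missing.append(f"{self.genotype_prefix}{suf}")
        for p in (self.phenotype_path, self.gene_models_path, self.gmt_path):
            if p and not Path(p).exists():
                missing.append(str(p))
        if missing:
            raise FileNotFoundError("missing inputs: " + ", ".join(missing))


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# episcan config={config.digest()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _apply_overrides(thresholds: sc.ScanThresholds, overrides: dict) -> sc.ScanThresholds:
    for key, value in overrides.items():
        if not hasattr(thresholds, key):
            raise ValueError(f"unknown threshold override {key!r}")
        setattr(thresholds, key, float(value))
    return thresholds


@_stage("discovery")
def run_discovery(config: RunConfig) -> dict:
    """Run the full discovery pipeline; returns a dict of output paths."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    dataset = gio.load_genotypes(config.genotype_prefix, config.genotype_format)
    dataset, qc_report = gio.qc_filter(dataset, config.qc)
    _write_tsv(qc_report, out / "qc_report.tsv", config)
    log.info("post-QC panel: %d samples x %d SNPs", dataset.n_samples, dataset.n_snps)

    phenotypes = pd.read_csv(config.phenotype_path, sep="\t", dtype={"id": str})
    cov_cols = [c for c in ("age", "sex", "bmi", "cohort") if c in phenotypes.columns]
    if "cohort" in cov_cols and phenotypes["cohort"].nunique() < 2:
        cov_cols.remove("cohort")  # constant cohort column would be collinear
    if "cohort" in cov_cols:
        phenotypes = pd.get_dummies(phenotypes, columns=["cohort"], drop_first=True, dtype=float)
        cov_cols = [c for c in phenotypes.columns if c not in ("id", "sua")]
    kinship = tr.estimate_kinship(dataset)
    prepared = tr.prepare_trait(phenotypes, kinship, covariate_columns=tuple(cov_cols))
    trait_out = pd.DataFrame({"id": prepared.sample_ids, "pgresidual": prepared.values})
    with open(out / "prepared_trait.tsv", "w") as fh:
        fh.write(f"# episcan config={config.digest()} seed={config.seed} h2={prepared.h2:.6f}\n")
        trait_out.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    # align genotypes to the prepared trait's samples
    row_of = {s: i for i, s in enumerate(dataset.sample_ids)}
    dataset = dataset.subset(sample_idx=[row_of[s] for s in prepared.sample_ids])

    single = sc.single_snp_scan(prepared, dataset, sc.ScanThresholds())
    focal = single.loc[single["focal"], "snp_id"].tolist()
    lam = sc.inflation_lambda(single["p"].to_numpy()) if len(single) >= 100 else float("nan")
    _write_tsv(single, out / "single_scan.tsv", config)

    thresholds = sc.derive_thresholds(dataset.n_snps, len(focal))
    thresholds = _apply_overrides(thresholds, config.threshold_overrides)
    retained, accounting = sc.full_pair_scan(prepared, dataset, thresholds, config.chunk_size)
    focal_scan = sc.snp_genome_scan(prepared, dataset, focal, thresholds, config.chunk_size)

    gene_of = {}
    if config.gene_models_path:
        genes = ann.load_gene_models(config.gene_models_path)
        annot = ann.annotate_snps(dataset.snps, genes, window=20_000)
        _write_tsv(annot, out / "annotations.tsv", config)
        gene_of = dict(zip(annot["snp_id"], annot["gene"]))

    chrom_of = dict(zip(dataset.snps["snp_id"], dataset.snps["chromosome"]))

    def table2_style(df: pd.DataFrame) -> pd.DataFrame:
        t = pd.DataFrame(
            {
                "snp_1": df["snp_1"],
                "chr_1": df["snp_1"].map(chrom_of),
                "gene_1": df["snp_1"].map(gene_of).fillna("-") if gene_of else "-",
                "snp_2": df["snp_2"],
                "chr_2": df["snp_2"].map(chrom_of),
                "gene_2": df["snp_2"].map(gene_of).fillna("-") if gene_of else "-",
                "neglog10_p_pair": df["neglog10_p_pair"],
                "neglog10_p_int": df["neglog10_p_int"],
                "mgc": df["mgc"],
            }
        )
        return t

    _write_tsv(table2_style(retained), out / "pair_scan.tsv", config)
    sig = focal_scan[focal_scan["significant"]] if len(focal_scan) else focal_scan
    _write_tsv(table2_style(focal_scan), out / "snp_genome_scan.tsv", config)
    _write_tsv(table2_style(sig), out / "snp_genome_significant.tsv", config)

    # variance explained by the significant SNP-genome pairs
    decomposition_path = None
    if len(sig):
        pairs = list(zip(sig["snp_1"].astype(str), sig["snp_2"].astype(str)))[:10]
        std = tr.standardize(
            phenotypes["sua"].to_numpy(dtype=float), phenotypes[["id", *cov_cols]]
        )
        vd = enr.variance_explained(std, kinship, pairs, dataset)
        decomposition_path = out / "variance_decomposition.json"
        with open(decomposition_path, "w") as fh:
            json.dump(
                {
                    "total_explained": vd.total_explained,
                    "marginal_component": vd.marginal_component,
                    "interaction_component": vd.interaction_component,
                    "n_pairs_used": vd.n_pairs_used,
                    "n_samples_used": vd.n_samples_used,
                    "config": config.digest(),
                    "seed": config.seed,
                },
                fh,
                indent=2,
            )

    # enrichment input: pairs with a moderately high interaction signal
    enrich_pairs = retained[
        (retained["neglog10_p_pair"] > thresholds.enrich_pair)
        & (retained["neglog10_p_int"] > thresholds.enrich_int)
    ]
    enrichment_path = None
    if config.gmt_path and gene_of:
        target = sorted(
            {
                g
                for s in pd.concat([enrich_pairs["snp_1"], enrich_pairs["snp_2"]])
                for g in [gene_of.get(s)]
                if g is not None and not (isinstance(g, float) and pd.isna(g))
            }
        )
        terms = enr.load_gmt(config.gmt_path)
        background = sorted(set().union(*terms.values())) if terms else []
        background = sorted(set(background) | set(target))
        enr_res = enr.hypergeometric_enrich(
            target, background, terms, report_p=config.enrichment_report_p
        )
        enrichment_path = out / "enrichment.tsv"
        _write_tsv(enr_res, enrichment_path, config)

    accounting = dict(
        accounting,
        inflation_lambda=lam,
        h2=prepared.h2,
        n_focal=len(focal),
        n_enrich_pairs=int(len(enrich_pairs)),
        thresholds={
            "consensus_gwa": thresholds.consensus_gwa,
            "pairwise_genomewide": thresholds.pairwise_genomewide,
            "snp_genome": thresholds.snp_genome,
            "retain_pair": thresholds.retain_pair,
            "retain_int": thresholds.retain_int,
        },
        config=config.digest(),
        seed=config.seed,
    )
    with open(out / "accounting.json", "w") as fh:
        json.dump(accounting, fh, indent=2, sort_keys=True, default=float)
    paths = {
        "qc_report": out / "qc_report.tsv",
        "prepared_trait": out / "prepared_trait.tsv",
        "single_scan": out / "single_scan.tsv",
        "pair_scan": out / "pair_scan.tsv",
        "snp_genome_scan": out / "snp_genome_scan.tsv",
        "snp_genome_significant": out / "snp_genome_significant.tsv",
        "accounting": out / "accounting.json",
    }
    if enrichment_path:
        paths["enrichment"] = enrichment_path
    if decomposition_path:
        paths["variance_decomposition"] = decomposition_path
    return paths


@_stage("replication")
def run_replication(config: RunConfig, discovery_dir) -> dict:
    """Replicate discovery pairs and compare enrichment in a second cohort."""
    config.validate_paths()
    discovery_dir = Path(discovery_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    pairs_df = _read_tsv(discovery_dir / "snp_genome_significant.tsv")
    pairs = list(zip(pairs_df["snp_1"].astype(str), pairs_df["snp_2"].astype(str)))

    dataset = gio.load_genotypes(config.genotype_prefix, config.genotype_format)
    dataset, _ = gio.qc_filter(dataset, config.qc)
    phenotypes = pd.read_csv(config.phenotype_path, sep="\t", dtype={"id": str})
    cov_cols = tuple(c for c in ("age", "sex", "bmi") if c in phenotypes.columns)
    kinship = tr.estimate_kinship(dataset)
    prepared = tr.prepare_trait(phenotypes, kinship, covariate_columns=cov_cols)
    row_of = {s: i for i, s in enumerate(dataset.sample_ids)}
    dataset = dataset.subset(sample_idx=[row_of[s] for s in prepared.sample_ids])

    known = set(dataset.snps["snp_id"])
    rows = []
    for snp_a, snp_b in pairs:
        if snp_a not in known and snp_b not in known:
            log.warning("pair %s-%s absent from replication panel", snp_a, snp_b)
            continue
        outcome = enr.replicate_pair(
            (snp_a, snp_b), prepared, dataset, adjacency=config.adjacency
        )
        rows.append(vars(outcome))
    replication = pd.DataFrame(
        rows,
        columns=[
            "snp_1", "snp_2", "best_p_int", "best_partner", "n_tests",
            "threshold_used", "replicated", "fallback_used", "reason",
        ],
    )
    _write_tsv(replication, out / "replication.tsv", config)

    comparison_path = None
    disc_enrichment = discovery_dir / "enrichment.tsv"
    if disc_enrichment.exists() and config.gmt_path and config.gene_models_path:
        rep_paths = run_discovery(config)
        if "enrichment" in rep_paths:
            comparison = enr.compare_enrichment(
                _read_tsv(disc_enrichment).fillna({"genes": ""}),
                _read_tsv(rep_paths["enrichment"]).fillna({"genes": ""}),
                replication_p=config.enrichment_report_p,
            )
            comparison_path = out / "term_comparison.tsv"
            _write_tsv(comparison, comparison_path, config)

    paths = {"replication": out / "replication.tsv"}
    if comparison_path:
        paths["term_comparison"] = comparison_path
    return paths
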