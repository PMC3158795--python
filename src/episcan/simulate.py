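"""Synthetic genotype/phenotype cohorts for testing the epistasis pipeline.

The generator produces the statistical structure the analysis assumes:
Hardy-Weinberg genotypes, family relatedness through non-overlapping
sibships, fixed covariate effects (age, sex, BMI), an infinitesimal
polygenic background built from the simulated genotypes themselves, and
planted two-locus effects specified as 3x3 joint-genotype effect matrices
in units of the covariate-adjusted trait standard deviation.

Defaults emulate a small isolate cohort: n = 1201 individuals, serum trait
mean 5.32 and SD 1.42 mg/dL, trait-BMI correlation 0.38 and polygenic
heritability 0.325.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeDataset, _normalise_minor_allele


class SimulationConfigError(ValueError):
    """Raised for inconsistent simulation settings."""


@dataclass
class PlantedEffect:
    """A two-locus effect planted on a pair of SNPs.

    ``effect_matrix[i, j]`` is the trait shift (in adjusted-trait SD units)
    for individuals carrying genotype ``i`` at the first SNP and ``j`` at
    the second.  ``maf1``/``maf2``, when given, pin the simulated minor
    allele frequencies of the two SNPs so that effect matrices built for a
    target variance fraction realise that fraction.
    """

    snp_index_1: int
    snp_index_2: int
    effect_matrix: np.ndarray
    maf1: float | None = None
    maf2: float | None = None

    def __post_init__(self) -> None:
        self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
        if self.effect_matrix.shape != (3, 3):
            raise SimulationConfigError("effect_matrix must be 3x3")
        if not np.isfinite(self.effect_matrix).all():
            raise SimulationConfigError("effect_matrix must be finite")
        if self.snp_index_1 == self.snp_index_2:
            raise SimulationConfigError("planted pair must use two distinct SNPs")

    @staticmethod
    def pure_interaction(
        snp_index_1: int,
        snp_index_2: int,
        variance: float,
        maf1: float = 0.3,
        maf2: float = 0.3,
    ) -> "PlantedEffect":
        """Additive-by-additive interaction with zero marginal effects.

        The matrix is ``c * (i - 2*maf1) * (j - 2*maf2)``: frequency-weighted
        row and column means vanish under HWE, so per-SNP additive
        regression slopes are zero while the nine cell means differ.  ``c``
        is chosen so the effect contributes ``variance`` (as a fraction of
        the unit adjusted-trait variance).
        """
        c = np.sqrt(variance / (2 * maf1 * (1 - maf1) * 2 * maf2 * (1 - maf2)))
        g = np.arange(3, dtype=float)
        m = c * np.outer(g - 2 * maf1, g - 2 * maf2)
        return PlantedEffect(snp_index_1, snp_index_2, m, maf1=maf1, maf2=maf2)

    @staticmethod
    def with_marginal(
        snp_index_1: int,
        snp_index_2: int,
        marginal_variance: float,
        interaction_variance: float,
        maf1: float = 0.3,
        maf2: float = 0.3,
    ) -> "PlantedEffect":
        """Additive marginal effect on the first SNP plus a pure interaction.

        Under HWE with independent loci the two components are orthogonal,
        so they contribute ``marginal_variance`` and ``interaction_variance``
        separately.
        """
        a = np.sqrt(marginal_variance / (2 * maf1 * (1 - maf1)))
        g = np.arange(3, dtype=float)
        base = PlantedEffect.pure_interaction(
            snp_index_1, snp_index_2, interaction_variance, maf1, maf2
        )
        m = base.effect_matrix + a * (g - 2 * maf1)[:, None]
        return PlantedEffect(snp_index_1, snp_index_2, m, maf1=maf1, maf2=maf2)


@dataclass
class CovariateEffects:
    """Fixed covariate slopes on the adjusted-trait SD scale.

    ``bmi`` defaults to the slope that yields a trait-BMI correlation of
    about 0.38 at the default age/sex contributions (BMI SD 4 kg/m2).
    """

    age: float = 0.008  # per year
    sex: float = 0.25  # male - female contrast
    bmi: float = 0.105  # per kg/m2


@dataclass
class SimulationConfig:
    """Settings for one synthetic cohort.

    ``h2_polygenic`` and the planted-pair variances are fractions of the
    covariate-adjusted trait variance; their sum must stay below 1 so a
    positive environmental variance remains.
    """

    n_individuals: int = 1201
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    sibship_size: int = 1
    sibship_fraction: float = 1.0
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    h2_polygenic: float = 0.0
    planted_pairs: list[PlantedEffect] = field(default_factory=list)
    missing_rate: float = 0.0
    trait_mean: float = 5.32
    trait_sd: float = 1.42
    n_chromosomes: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationConfigError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.h2_polygenic < 1.0:
            raise SimulationConfigError("h2_polygenic must lie in [0, 1)")
        if self.n_individuals < 2 or self.n_snps < 2:
            raise SimulationConfigError("need at least 2 individuals and 2 SNPs")
        if self.sibship_size < 1:
            raise SimulationConfigError("sibship_size must be >= 1")
        if not 0.0 <= self.sibship_fraction <= 1.0:
            raise SimulationConfigError("sibship_fraction must lie in [0, 1]")
        for pe in self.planted_pairs:
            for idx in (pe.snp_index_1, pe.snp_index_2):
                if not 0 <= idx < self.n_snps:
                    raise SimulationConfigError(f"planted SNP index {idx} out of range")


def default_cohort_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Config emulating the study cohort.

    n = 1201 individuals, about 30% of them in full-sib pairs (isolate
    cohorts are mostly unrelated with some close families; this density
    keeps the polygenic correction's genomic inflation factor near 1, as
    observed in the cohort being emulated), polygenic heritability 0.325,
    trait mean 5.32 / SD 1.42 mg/dL, trait-BMI correlation ~0.38.  The
    default panel of 6000 SNPs keeps the genomic relationship matrix
    comfortably full-rank at this sample size.
    """
    base = dict(
        n_individuals=1201,
        n_snps=6000,
        maf_range=(0.05, 0.5),
        sibship_size=2,
        sibship_fraction=0.3,
        h2_polygenic=0.325,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _snp_map(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Marker map with strictly increasing positions per chromosome."""
    m = config.n_snps
    chrom_of = np.minimum(np.arange(m) * config.n_chromosomes // m, config.n_chromosomes - 1)
    gaps = rng.integers(5_000, 15_000, size=m)
    positions = np.empty(m, dtype=int)
    for c in range(config.n_chromosomes):
        idx = np.flatnonzero(chrom_of == c)
        positions[idx] = 10_000 + np.cumsum(gaps[idx])
    alleles = rng.choice(np.array(["A", "C", "G", "T"]), size=(m, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(m)],
            "chromosome": (chrom_of + 1).astype(str),
            "position": positions,
            "allele1": alleles[:, 0],
            "allele2": alleles[:, 1],
        }
    )


def simulate_genotypes(config: SimulationConfig) -> GenotypeDataset:
    """Draw a genotype panel under HWE with optional sibship relatedness.

    Unrelated individuals (``sibship_size == 1``) are drawn directly from
    HWE proportions at a per-SNP MAF sampled uniformly from ``maf_range``.
    Within a sibship, two unobserved parents are drawn from HWE and each
    child receives one Mendelian transmission per parent, giving the usual
    expected genomic relationship of 0.5 between sibs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, m = config.n_individuals, config.n_snps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    for pe in config.planted_pairs:
        if pe.maf1 is not None:
            maf[pe.snp_index_1] = pe.maf1
        if pe.maf2 is not None:
            maf[pe.snp_index_2] = pe.maf2

    n_related = int(round(config.sibship_fraction * n / config.sibship_size)) * config.sibship_size
    if config.sibship_size == 1 or n_related == 0:
        matrix = rng.binomial(2, maf[None, :], size=(n, m)).astype(np.int8)
    else:
        # first n_related individuals form sibships, the rest are unrelated
        n_fam = n_related // config.sibship_size
        fathers = rng.binomial(2, maf[None, :], size=(n_fam, m)).astype(np.int8)
        mothers = rng.binomial(2, maf[None, :], size=(n_fam, m)).astype(np.int8)
        fam_of = np.arange(n_related) // config.sibship_size
        a1 = rng.random((n_related, m)) < fathers[fam_of] / 2.0
        a2 = rng.random((n_related, m)) < mothers[fam_of] / 2.0
        sibs = a1.astype(np.int8) + a2.astype(np.int8)
        singles = rng.binomial(2, maf[None, :], size=(n - n_related, m)).astype(np.int8)
        matrix = np.vstack([sibs, singles])

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        matrix[mask] = MISSING

    # realized allele frequencies can cross 0.5 when the drawn MAF is near
    # it; re-normalise so stored codes always count the sample minor allele
    matrix, snps = _normalise_minor_allele(matrix, _snp_map(config, rng))
    sample_ids = np.array([f"ind{i:05d}" for i in range(n)], dtype=object)
    return GenotypeDataset(sample_ids=sample_ids, snps=snps, matrix=matrix)


# ---------------------------------------------------------------------------
# trait
# ---------------------------------------------------------------------------

def _standardized_column(col: np.ndarray) -> np.ndarray:
    """Genotype column standardized to mean 0 / unit variance, missing -> 0."""
    obs = col != MISSING
    x = col.astype(float)
    mean = x[obs].mean()
    sd = x[obs].std()
    if sd == 0:
        return np.zeros_like(x)
    x = np.where(obs, (x - mean) / sd, 0.0)
    return x


def _exact_scale(values: np.ndarray, variance: float) -> np.ndarray:
    """Center and rescale a draw to the requested sample variance."""
    v = values - values.mean()
    sd = v.std()
    if sd == 0 or variance == 0:
        return np.zeros_like(v)
    return v * (np.sqrt(variance) / sd)


def simulate_trait(genotypes: GenotypeDataset, config: SimulationConfig) -> pd.DataFrame:
    """Simulate the phenotype table (id, sua, age, sex, bmi, cohort).

    The covariate-adjusted part of the trait is built on a unit-variance
    scale: a polygenic value with sample variance exactly ``h2_polygenic``
    (per-SNP infinitesimal effects on the simulated genotypes, so realized
    kinship and the generative model agree), the planted joint-genotype
    effects, and Gaussian noise scaled so the three parts sum to one.  Age,
    sex and BMI effects are added on top and the total is rescaled to
    ``trait_mean`` / ``trait_sd``.

    Planted effects are evaluated on the underlying complete genotypes;
    missingness is an observation process and does not alter the trait.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_individuals
    if genotypes.n_samples != n:
        raise SimulationConfigError("genotype panel does not match config sample count")

    age = rng.uniform(18.0, 90.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    bmi = rng.normal(26.0, 4.0, size=n)

    # polygenic value from infinitesimal effects on the genotyped SNPs
    if config.h2_polygenic > 0:
        Z = np.column_stack(
            [_standardized_column(genotypes.matrix[:, j]) for j in range(genotypes.n_snps)]
        )
        effects = rng.normal(size=genotypes.n_snps)
        g = _exact_scale(Z @ effects, config.h2_polygenic)
    else:
        g = np.zeros(n)

    planted = np.zeros(n)
    planted_var = 0.0
    for pe in config.planted_pairs:
        g1 = genotypes.matrix[:, pe.snp_index_1]
        g2 = genotypes.matrix[:, pe.snp_index_2]
        if (g1 == MISSING).any() or (g2 == MISSING).any():
            # underlying genotypes are complete; only observed copies carry
            # missingness, so this triggers only for user-provided panels
            raise SimulationConfigError("planted SNPs must have complete genotypes")
        for col, name in ((g1, pe.snp_index_1), (g2, pe.snp_index_2)):
            if len(np.unique(col)) < 2:
                raise SimulationConfigError(f"planted SNP index {name} is monomorphic")
        v = pe.effect_matrix[g1, g2]
        v = v - v.mean()
        planted_var += v.var()
        planted = planted + v

    noise_var = 1.0 - config.h2_polygenic - planted_var
    if noise_var <= 0:
        raise SimulationConfigError(
            f"h2 + planted variance = {1 - noise_var:.3f} leaves no noise variance"
        )
    e = _exact_scale(rng.normal(size=n), noise_var)

    ce = config.covariate_effects
    full = (
        ce.age * (age - age.mean())
        + ce.sex * (sex - sex.mean())
        + ce.bmi * (bmi - bmi.mean())
        + g
        + planted
        + e
    )
    sua = config.trait_mean + config.trait_sd * (full - full.mean()) / full.std()

    return pd.DataFrame(
        {
            "id": genotypes.sample_ids,
            "sua": sua,
            "age": age,
            "sex": sex.astype(int),
            "bmi": bmi,
            "cohort": "SIM",
        }
    )


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper returning ``(genotypes, phenotypes)``."""
    genotypes = simulate_genotypes(config)
    phenotypes = simulate_trait(genotypes, config)
    return genotypes, phenotypes


# ---------------------------------------------------------------------------
# annotation / enrichment resources
# ---------------------------------------------------------------------------

def simulate_gene_models(
    genotypes: GenotypeDataset,
    seed: int = 0,
    gene_length: int = 30_000,
    gap: int = 25_000,
) -> pd.DataFrame:
    """Tile synthetic gene models along the chromosomes of a marker map.

    Genes of fixed length are laid end to end with gaps, spanning each
    chromosome's SNP positions, so some SNPs fall inside genes, some within
    the flanking window and some outside.  Purely synthetic symbols.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows = []
    k = 0
    for chrom, grp in genotypes.snps.groupby("chromosome", sort=False):
        start = max(1, int(grp["position"].min()) - gene_length)
        end = int(grp["position"].max()) + gene_length
        pos = start
        while pos < end:
            rows.append(
                {
                    "chromosome": chrom,
                    "tx_start": pos,
                    "tx_end": pos + gene_length - 1,
                    "symbol": f"GENE{k:05d}",
                }
            )
            k += 1
            pos += gene_length + gap + int(rng.integers(0, gap))
    return pd.DataFrame(rows)


def simulate_gene_sets(
    gene_symbols,
    seed: int = 0,
    n_terms: int = 30,
    term_size_range: tuple[int, int] = (10, 50),
) -> dict[str, set]:
    """Random overlapping gene sets in GMT-style term -> genes form."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    genes = np.asarray(list(gene_symbols))
    terms = {}
    for t in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        size = min(size, len(genes))
        members = rng.choice(genes, size=size, replace=False)
        terms[f"TERM{t:04d}"] = set(members.tolist())
    return terms
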