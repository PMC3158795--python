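"""Gene-set enrichment, cross-population comparison, SNP-level pair
replication with adjacent-SNP fallback, and variance decomposition.

Enrichment uses the plain upper-tail hypergeometric test of the overlap
between a target gene list and each term of a GMT map against a fixed
background ("two unranked lists" mode); no ontology-hierarchy propagation
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeDataset
from .scan import fit_pair_models
from .trait import KinshipMatrix, PreparedTrait, reml_variance


# ---------------------------------------------------------------------------
# GMT and hypergeometric enrichment
# ---------------------------------------------------------------------------

def load_gmt(path) -> dict[str, set]:
    """Parse a GMT file into ``{term: set(genes)}`` (description dropped)."""
    terms: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = set(g for g in parts[2:] if g)
    return terms


def save_gmt(terms: dict[str, set], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            genes = "\t".join(sorted(terms[term]))
            fh.write(f"{term}\tna\t{genes}\n")


def hypergeometric_enrich(
    target_genes,
    background_genes,
    terms: dict[str, set],
    report_p: float = 1e-3,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of target genes per term.

    Term gene sets are intersected with the background before testing.
    Returns terms with ``p < report_p`` sorted by p; columns: ``term``,
    ``term_size``, ``overlap``, ``p``, ``genes`` (sorted, ';'-joined).
    """
    target = set(target_genes)
    background = set(background_genes)
    if not target <= background:
        raise ValueError("target genes must be a subset of the background")
    if not target:
        return pd.DataFrame(columns=["term", "term_size", "overlap", "p", "genes"])
    N, n = len(background), len(target)
    rows = []
    for term, genes in terms.items():
        in_bg = genes & background
        K = len(in_bg)
        if K == 0:
            continue
        hits = sorted(in_bg & target)
        k = len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"term": term, "term_size": K, "overlap": k, "p": p, "genes": ";".join(hits)})
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p", "genes"])
    out = out[out["p"] < report_p]
    return out.sort_values(["p", "term"], ignore_index=True)


def compare_enrichment(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    replication_p: float = 1e-3,
) -> pd.DataFrame:
    """Terms significant in both populations, with the shared genes.

    Returns one row per replicated term: the two p-values and the
    intersection of contributing genes.
    """
    a = results_a[results_a["p"] < replication_p].set_index("term")
    b = results_b[results_b["p"] < replication_p].set_index("term")
    shared_terms = sorted(set(a.index) & set(b.index))
    rows = []
    for term in shared_terms:
        ga = set(a.loc[term, "genes"].split(";")) if a.loc[term, "genes"] else set()
        gb = set(b.loc[term, "genes"].split(";")) if b.loc[term, "genes"] else set()
        shared = sorted(ga & gb)
        rows.append(
            {
                "term": term,
                "p_a": float(a.loc[term, "p"]),
                "p_b": float(b.loc[term, "p"]),
                "n_shared_genes": len(shared),
                "shared_genes": ";".join(shared),
            }
        )
    return pd.DataFrame(rows, columns=["term", "p_a", "p_b", "n_shared_genes", "shared_genes"])


# ---------------------------------------------------------------------------
# SNP-level replication
# ---------------------------------------------------------------------------

@dataclass
class ReplicationOutcome:
    """Result of testing one discovery pair in a replication cohort."""

    snp_1: str
    snp_2: str
    best_p_int: float
    best_partner: str
    n_tests: int
    threshold_used: float
    replicated: bool
    fallback_used: bool
    reason: str = ""


def _neighbour_ids(genotypes: GenotypeDataset, snp_id: str, adjacency: int) -> list[str]:
    """Map-order neighbours of a SNP on its chromosome, nearest first."""
    snps = genotypes.snps
    row = snps.index[snps["snp_id"] == snp_id]
    if len(row) == 0:
        return []
    i = int(row[0])
    chrom = snps.at[i, "chromosome"]
    out = []
    for off in range(1, adjacency + 1):
        for j in (i - off, i + off):
            if 0 <= j < len(snps) and snps.at[j, "chromosome"] == chrom:
                out.append(snps.at[j, "snp_id"])
    return out


def replicate_pair(
    pair: tuple[str, str],
    trait: PreparedTrait,
    genotypes: GenotypeDataset,
    adjacency: int = 2,
    fixed_snp: str = "first",
) -> ReplicationOutcome:
    """Test a discovery pair in a replication cohort.

    The exact pair is tested first; a nominal 0.05 applies when that single
    test is significant.  If the exact pair is skipped or not significant,
    the fixed SNP is also tested against the other SNP's map-order
    neighbours up to ``adjacency`` positions away, and the threshold becomes
    0.05 divided by the number of tests actually performed.  The smallest
    interaction p among performed tests is reported.
    """
    if fixed_snp not in ("first", "second"):
        raise ValueError("fixed_snp must be 'first' or 'second'")
    snp_a, snp_b = pair
    fixed, moving = (snp_a, snp_b) if fixed_snp == "first" else (snp_b, snp_a)
    pos_of = {s: i for i, s in enumerate(genotypes.snps["snp_id"])}
    y = trait.values
    G = genotypes.matrix

    def test(id1, id2):
        if id1 not in pos_of or id2 not in pos_of:
            return None
        r = fit_pair_models(y, G[:, pos_of[id1]], G[:, pos_of[id2]], id1, id2)
        return None if r.skipped else r

    performed: list = []
    exact = test(fixed, moving)
    if exact is not None:
        performed.append((moving, exact.p_int))
        if exact.p_int < 0.05:
            return ReplicationOutcome(
                snp_1=snp_a,
                snp_2=snp_b,
                best_p_int=exact.p_int,
                best_partner=moving,
                n_tests=1,
                threshold_used=0.05,
                replicated=True,
                fallback_used=False,
            )
    for nb in _neighbour_ids(genotypes, moving, adjacency):
        r = test(fixed, nb)
        if r is not None:
            performed.append((nb, r.p_int))
    if not performed:
        return ReplicationOutcome(
            snp_1=snp_a,
            snp_2=snp_b,
            best_p_int=float("nan"),
            best_partner="",
            n_tests=0,
            threshold_used=float("nan"),
            replicated=False,
            fallback_used=True,
            reason="no testable combination (all skipped or absent)",
        )
    best_partner, best_p = min(performed, key=lambda t: t[1])
    n_tests = len(performed)
    threshold = 0.05 / n_tests
    return ReplicationOutcome(
        snp_1=snp_a,
        snp_2=snp_b,
        best_p_int=best_p,
        best_partner=best_partner,
        n_tests=n_tests,
        threshold_used=threshold,
        replicated=bool(best_p < threshold),
        fallback_used=n_tests > 1 or exact is None,
    )


# ---------------------------------------------------------------------------
# variance explained
# ---------------------------------------------------------------------------

@dataclass
class VarianceDecomposition:
    """Phenotypic variance explained by a set of SNP pairs.

    Fractions of the standardized trait variance: ``total_explained`` from
    the mixed model with full joint-genotype factors, ``marginal_component``
    from a main-effects-only refit, ``interaction_component`` their
    difference.  ``n_pairs_used`` counts pairs not dropped for empty
    classes.
    """

    total_explained: float
    marginal_component: float
    interaction_component: float
    n_pairs_used: int
    n_samples_used: int


def _joint_dummies(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """8 dummy columns for the 9-level joint genotype factor (cell (0,0) ref)."""
    cell = 3 * g1 + g2
    return np.column_stack([(cell == c).astype(float) for c in range(1, 9)])


def _main_dummies(g: np.ndarray) -> np.ndarray:
    return np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])


def variance_explained(
    standardized_trait: PreparedTrait,
    kinship: KinshipMatrix,
    pairs,
    genotypes: GenotypeDataset,
) -> VarianceDecomposition:
    """Variance of the standardized trait explained by SNP pairs.

    Fits the polygenic mixed model with the pairs' joint-genotype factors
    as fixed effects; since the trait has unit variance, 1 minus the REML
    residual variance (genetic plus environmental) is the fraction
    explained.  The marginal component comes from a refit with per-SNP main
    effects only.  Pairs with an empty joint genotype class are dropped.
    Samples missing any involved genotype are excluded from both fits.
    """
    if standardized_trait.stage != "standardized":
        raise ValueError("variance_explained expects the standardized trait stage")
    pos_of = {s: i for i, s in enumerate(genotypes.snps["snp_id"])}
    id_to_row = {s: i for i, s in enumerate(genotypes.sample_ids)}
    rows = np.array([id_to_row[s] for s in standardized_trait.sample_ids])

    used_pairs = []
    involved: list[int] = []
    for snp_a, snp_b in pairs:
        ia, ib = pos_of[snp_a], pos_of[snp_b]
        g1 = genotypes.matrix[rows, ia]
        g2 = genotypes.matrix[rows, ib]
        ok = (g1 != MISSING) & (g2 != MISSING)
        cells = 3 * g1[ok] + g2[ok]
        if len(np.unique(cells)) < 9:
            continue  # empty joint class: pair dropped
        used_pairs.append((ia, ib))
        involved.extend([ia, ib])

    y = standardized_trait.values
    kin_idx = _match_kinship(standardized_trait.sample_ids, kinship)
    if not used_pairs:
        sigma2, _ = reml_variance(y, np.ones((len(y), 1)), kinship.subset(kin_idx))
        return VarianceDecomposition(
            total_explained=max(0.0, 1.0 - sigma2),
            marginal_component=0.0,
            interaction_component=max(0.0, 1.0 - sigma2),
            n_pairs_used=0,
            n_samples_used=len(y),
        )

    geno = genotypes.matrix[np.ix_(rows, sorted(set(involved)))]
    complete = (geno != MISSING).all(axis=1)
    yc = y[complete]
    kin = kinship.subset(kin_idx[complete])

    col_of = {snp: k for k, snp in enumerate(sorted(set(involved)))}
    Xf = [np.ones((len(yc), 1))]
    Xm = [np.ones((len(yc), 1))]
    for ia, ib in used_pairs:
        g1 = geno[complete][:, col_of[ia]]
        g2 = geno[complete][:, col_of[ib]]
        Xf.append(_joint_dummies(g1, g2))
    for snp in sorted(set(involved)):
        Xm.append(_main_dummies(geno[complete][:, col_of[snp]]))
    sigma2_full, _ = reml_variance(yc, np.hstack(Xf), kin)
    sigma2_main, _ = reml_variance(yc, np.hstack(Xm), kin)

    total = float(np.clip(1.0 - sigma2_full, 0.0, 1.0))
    marginal = float(np.clip(1.0 - sigma2_main, 0.0, 1.0))
    return VarianceDecomposition(
        total_explained=total,
        marginal_component=marginal,
        interaction_component=max(total - marginal, 0.0),
        n_pairs_used=len(used_pairs),
        n_samples_used=int(complete.sum()),
    )


def _match_kinship(sample_ids, kinship: KinshipMatrix) -> np.ndarray:
    pos = {s: i for i, s in enumerate(kinship.sample_ids)}
    try:
        return np.array([pos[s] for s in sample_ids])
    except KeyError as exc:
        raise ValueError(f"sample {exc.args[0]!r} missing from kinship matrix") from exc
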