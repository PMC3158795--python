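"""Enrichment, term-level comparison, pair replication, variance explained."""

import math

import numpy as np
import pandas as pd
import pytest

import episcan as e
from episcan.genotypes import MISSING


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def test_saturated_overlap_closed_form():
    background = {f"g{i}" for i in range(20)}
    target = {f"g{i}" for i in range(5)}
    terms = {"T": set(target)}
    res = e.hypergeometric_enrich(target, background, terms, report_p=1.0)
    assert res["p"].iloc[0] == pytest.approx(1 / 15504, rel=1e-12)
    assert res["overlap"].iloc[0] == 5


def test_zero_overlap_p_one():
    background = {f"g{i}" for i in range(20)}
    res = e.hypergeometric_enrich(
        {"g0"}, background, {"T": {"g10", "g11"}}, report_p=2.0
    )
    assert res["p"].iloc[0] == 1.0


def test_target_equals_background_saturation():
    background = {f"g{i}" for i in range(15)}
    terms = {"A": {"g0", "g1", "g2"}, "B": {"g5"}}
    res = e.hypergeometric_enrich(background, background, terms, report_p=2.0)
    assert (res["p"] == 1.0).all()


def test_target_outside_background_rejected():
    with pytest.raises(ValueError):
        e.hypergeometric_enrich({"x"}, {"a", "b"}, {"T": {"a"}})


def test_empty_target_empty_result():
    res = e.hypergeometric_enrich(set(), {"a", "b"}, {"T": {"a"}})
    assert len(res) == 0


def test_against_combinatorial_oracle():
    """scipy tail probabilities equal the explicit sum of hypergeometric
    terms on small instances."""
    rng = np.random.default_rng(44)
    for _ in range(30):
        N = int(rng.integers(8, 25))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        background = {f"g{i}" for i in range(N)}
        term = set(rng.choice(sorted(background), size=K, replace=False))
        target = set(rng.choice(sorted(background), size=n, replace=False))
        k = len(term & target)
        res = e.hypergeometric_enrich(target, background, {"T": term}, report_p=2.0)
        expected = sum(
            math.comb(K, j) * math.comb(N - K, n - j)
            for j in range(k, min(K, n) + 1)
            if n - j <= N - K
        ) / math.comb(N, n)
        assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# term comparison
# ---------------------------------------------------------------------------

def _enr_frame(terms):
    return pd.DataFrame(
        [
            {"term": t, "term_size": 10, "overlap": 3, "p": p, "genes": genes}
            for t, p, genes in terms
        ]
    )


def test_identical_inputs_all_replicated():
    a = _enr_frame([("T1", 1e-5, "g1;g2"), ("T2", 1e-4, "g3")])
    out = e.compare_enrichment(a, a.copy())
    assert list(out["term"]) == ["T1", "T2"]
    assert list(out["shared_genes"]) == ["g1;g2", "g3"]


def test_disjoint_terms_nothing_replicated():
    a = _enr_frame([("T1", 1e-5, "g1")])
    b = _enr_frame([("T9", 1e-5, "g1")])
    assert len(e.compare_enrichment(a, b)) == 0


def test_partial_overlap_count():
    a = _enr_frame([(f"T{i}", 1e-5, f"g{i};shared") for i in range(20)])
    b = _enr_frame([(f"T{i}", 1e-4, f"h{i};shared") for i in range(7, 27)])
    out = e.compare_enrichment(a, b)
    assert len(out) == 13
    assert set(out["shared_genes"]) == {"shared"}


def test_replication_p_cutoff_applied():
    a = _enr_frame([("T1", 5e-4, "g1"), ("T2", 5e-3, "g2")])
    out = e.compare_enrichment(a, a.copy(), replication_p=1e-3)
    assert list(out["term"]) == ["T1"]


# ---------------------------------------------------------------------------
# pair replication
# ---------------------------------------------------------------------------

def _replication_cohort(seed=50, n=800, m=12, interaction=0.12):
    pe = e.PlantedEffect.pure_interaction(2, 7, variance=interaction, maf1=0.4, maf2=0.4)
    config = e.SimulationConfig(
        n_individuals=n, n_snps=m, maf_range=(0.35, 0.5), seed=seed,
        planted_pairs=[pe], n_chromosomes=1,
        covariate_effects=e.CovariateEffects(age=0.0, sex=0.0, bmi=0.0),
    )
    genotypes, pheno = e.simulate_cohort(config)
    y = pheno["sua"].to_numpy()
    trait = e.PreparedTrait(
        values=(y - y.mean()) / y.std(), sample_ids=genotypes.sample_ids,
        stage="polygenic_residual",
    )
    return genotypes, trait


def test_exact_pair_replicates_single_test():
    genotypes, trait = _replication_cohort()
    ids = genotypes.snps["snp_id"]
    out = e.replicate_pair((ids[2], ids[7]), trait, genotypes)
    assert out.replicated
    assert out.n_tests == 1
    assert out.threshold_used == 0.05
    assert not out.fallback_used


def test_fallback_threshold_is_bonferroni_over_performed_tests():
    genotypes, trait = _replication_cohort()
    # make the exact pair untestable: empty a joint class of (snp2, snp7)
    matrix = genotypes.matrix.copy()
    cell = (matrix[:, 2] == 2) & (matrix[:, 7] == 2)
    matrix[cell, 7] = MISSING
    broken = e.GenotypeDataset(genotypes.sample_ids, genotypes.snps, matrix)
    out = e.replicate_pair(
        (genotypes.snps["snp_id"][2], genotypes.snps["snp_id"][7]), trait, broken
    )
    assert out.fallback_used
    assert out.n_tests >= 1
    assert out.threshold_used == pytest.approx(0.05 / out.n_tests, rel=1e-12)
    assert out.replicated == (out.best_p_int < out.threshold_used)


def test_no_testable_combination():
    genotypes, trait = _replication_cohort()
    out = e.replicate_pair(("absent1", "absent2"), trait, genotypes)
    assert not out.replicated
    assert out.n_tests == 0
    assert "no testable" in out.reason


def test_null_pair_replication_rate_near_nominal():
    """Testing a null pair in independent cohorts replicates ~5% of the time."""
    hits = 0
    n_rep = 40
    for seed in range(n_rep):
        config = e.SimulationConfig(
            n_individuals=300, n_snps=6, maf_range=(0.4, 0.5), seed=1000 + seed
        )
        genotypes, pheno = e.simulate_cohort(config)
        y = pheno["sua"].to_numpy()
        trait = e.PreparedTrait(
            values=(y - y.mean()) / y.std(), sample_ids=genotypes.sample_ids,
            stage="polygenic_residual",
        )
        ids = genotypes.snps["snp_id"]
        out = e.replicate_pair((ids[0], ids[3]), trait, genotypes, adjacency=0)
        hits += int(out.replicated)
    # binomial(40, 0.05): 0..7 covers >99.9% of the mass
    assert hits <= 7


# ---------------------------------------------------------------------------
# variance explained
# ---------------------------------------------------------------------------

def test_no_pairs_explains_nothing():
    config = e.SimulationConfig(n_individuals=300, n_snps=400, maf_range=(0.2, 0.5), seed=60)
    genotypes, pheno = e.simulate_cohort(config)
    kin = e.estimate_kinship(genotypes)
    std = e.standardize(pheno["sua"].to_numpy(), pheno[["id", "age", "sex", "bmi"]])
    vd = e.variance_explained(std, kin, [], genotypes)
    assert vd.total_explained == pytest.approx(0.0, abs=0.05)
    assert vd.n_pairs_used == 0


def test_pure_interaction_pair_decomposition():
    pe = e.PlantedEffect.pure_interaction(10, 200, variance=0.08, maf1=0.35, maf2=0.35)
    config = e.SimulationConfig(
        n_individuals=900, n_snps=400, maf_range=(0.2, 0.5), seed=61,
        planted_pairs=[pe],
    )
    genotypes, pheno = e.simulate_cohort(config)
    kin = e.estimate_kinship(genotypes)
    std = e.standardize(pheno["sua"].to_numpy(), pheno[["id", "age", "sex", "bmi"]])
    ids = genotypes.snps["snp_id"]
    vd = e.variance_explained(std, kin, [(ids[10], ids[200])], genotypes)
    assert vd.marginal_component < 0.03
    assert vd.interaction_component == pytest.approx(0.08, abs=0.04)
    assert vd.total_explained == pytest.approx(
        vd.marginal_component + vd.interaction_component, abs=1e-9
    )


def test_variance_explained_affine_invariant():
    pe = e.PlantedEffect.with_marginal(3, 40, 0.05, 0.05, maf1=0.4, maf2=0.4)
    config = e.SimulationConfig(
        n_individuals=500, n_snps=60, maf_range=(0.3, 0.5), seed=62, planted_pairs=[pe]
    )
    genotypes, pheno = e.simulate_cohort(config)
    kin = e.estimate_kinship(genotypes)
    cov = pheno[["id", "age", "sex", "bmi"]]
    ids = genotypes.snps["snp_id"]
    pair = [(ids[3], ids[40])]
    raw = pheno["sua"].to_numpy()
    a = e.variance_explained(e.standardize(raw, cov), kin, pair, genotypes)
    b = e.variance_explained(e.standardize(-2.0 * raw + 7.0, cov), kin, pair, genotypes)
    assert a.total_explained == pytest.approx(b.total_explained, abs=1e-8)


def test_pair_with_empty_class_dropped():
    genotypes, trait = _replication_cohort()
    matrix = genotypes.matrix.copy()
    cell = (matrix[:, 2] == 2) & (matrix[:, 7] == 2)
    matrix[cell, 7] = 1  # empty (2,2) class
    broken = e.GenotypeDataset(genotypes.sample_ids, genotypes.snps, matrix)
    kin = e.KinshipMatrix(np.eye(len(trait.values)), trait.sample_ids)
    std = e.PreparedTrait(
        values=trait.values / trait.values.std(), sample_ids=trait.sample_ids,
        stage="standardized",
    )
    ids = genotypes.snps["snp_id"]
    vd = e.variance_explained(std, kin, [(ids[2], ids[7])], broken)
    assert vd.n_pairs_used == 0


def test_gmt_round_trip(tmp_path):
    terms = {"T1": {"a", "b", "c"}, "T2": {"b", "d"}}
    path = tmp_path / "sets.gmt"
    e.save_gmt(terms, path)
    assert e.load_gmt(path) == terms
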