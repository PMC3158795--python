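"""The scan engine: thresholds, pair-wise F tests, lambda, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import episcan as e
from episcan.genotypes import MISSING
from episcan.scan import _CELL_DESIGN


def _naive_pair_oracle(y, g1, g2):
    """Reference F statistics from explicit factorial least squares."""
    keep = (g1 != MISSING) & (g2 != MISSING)
    y, g1, g2 = y[keep], g1[keep].astype(int), g2[keep].astype(int)
    n = len(y)
    cells = 3 * g1 + g2

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    X_full = np.column_stack([(cells == c).astype(float) for c in range(9)])
    X_main = np.column_stack(
        [np.ones(n)]
        + [(g1 == k).astype(float) for k in (1, 2)]
        + [(g2 == k).astype(float) for k in (1, 2)]
    )
    rf, rm, rn = rss(X_full), rss(X_main), rss(np.ones((n, 1)))
    f_pair = ((rn - rf) / 8.0) / (rf / (n - 9))
    f_int = ((rm - rf) / 4.0) / (rf / (n - 9))
    return f_pair, f_int


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def test_threshold_derivation_printed_convention():
    t = e.derive_thresholds(300_000, 7)
    assert round(t.pairwise_genomewide, 2) == 11.95
    assert round(t.snp_genome, 2) == 7.62
    assert t.consensus_gwa == 7.3
    assert t.retain_pair == 4.7 and t.retain_int == 3.2
    assert t.enrich_pair == 6.5 and t.enrich_int == 6.5


def test_threshold_small_panel():
    t = e.derive_thresholds(2, 0)
    assert t.pairwise_genomewide == pytest.approx(-np.log10(0.05), abs=1e-9)
    assert not t.snp_genome_defined and np.isnan(t.snp_genome)


def test_threshold_ordering_invariant():
    for m, f in ((1000, 1), (5000, 3), (300_000, 7)):
        t = e.derive_thresholds(m, f)
        assert t.pairwise_genomewide >= t.snp_genome


# ---------------------------------------------------------------------------
# pair model fits
# ---------------------------------------------------------------------------

def test_pair_fit_matches_naive_oracle():
    rng = np.random.default_rng(17)
    for _ in range(25):
        n = int(rng.integers(60, 400))
        g1 = rng.binomial(2, rng.uniform(0.25, 0.5), size=n).astype(np.int8)
        g2 = rng.binomial(2, rng.uniform(0.25, 0.5), size=n).astype(np.int8)
        y = rng.normal(size=n)
        r = e.fit_pair_models(y, g1, g2)
        if r.skipped:
            continue
        f_pair, f_int = _naive_pair_oracle(y, g1, g2)
        assert r.f_pair == pytest.approx(f_pair, rel=1e-8)
        assert r.f_int == pytest.approx(f_int, rel=1e-8)


def test_pair_fit_symmetric_in_arguments():
    rng = np.random.default_rng(18)
    g1 = rng.binomial(2, 0.4, size=300).astype(np.int8)
    g2 = rng.binomial(2, 0.4, size=300).astype(np.int8)
    y = rng.normal(size=300)
    a = e.fit_pair_models(y, g1, g2)
    b = e.fit_pair_models(y, g2, g1)
    assert a.f_pair == pytest.approx(b.f_pair, rel=1e-12)
    assert a.f_int == pytest.approx(b.f_int, rel=1e-12)
    assert a.mgc == b.mgc


def test_rss_nesting_invariant():
    rng = np.random.default_rng(19)
    for _ in range(20):
        g1 = rng.binomial(2, 0.4, size=200).astype(np.int8)
        g2 = rng.binomial(2, 0.4, size=200).astype(np.int8)
        r = e.fit_pair_models(rng.normal(size=200), g1, g2)
        if r.skipped:
            continue
        assert r.rss_full <= r.rss_main + 1e-9
        assert r.rss_main <= r.rss_null + 1e-9
        assert r.f_pair >= 0 and r.f_int >= 0


def test_empty_joint_class_skipped():
    rng = np.random.default_rng(20)
    g1 = rng.binomial(2, 0.4, size=200).astype(np.int8)
    g2 = rng.binomial(2, 0.4, size=200).astype(np.int8)
    g2[(g1 == 2) & (g2 == 2)] = 1  # empty the (2,2) cell
    r = e.fit_pair_models(rng.normal(size=200), g1, g2)
    assert r.skipped
    assert r.reason == "empty joint genotype class"
    assert np.isnan(r.f_pair)


def test_two_level_snp_always_skipped():
    rng = np.random.default_rng(21)
    g1 = rng.integers(0, 2, size=300).astype(np.int8)  # never homozygous minor
    g2 = rng.binomial(2, 0.5, size=300).astype(np.int8)
    r = e.fit_pair_models(rng.normal(size=300), g1, g2)
    assert r.skipped


def test_insufficient_residual_df_skipped():
    g1 = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2], dtype=np.int8)
    g2 = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2], dtype=np.int8)
    r = e.fit_pair_models(np.arange(9.0), g1, g2)
    assert r.skipped
    assert r.reason == "insufficient residual df"


def test_constant_trait_convention():
    rng = np.random.default_rng(22)
    g1 = rng.binomial(2, 0.5, size=300).astype(np.int8)
    g2 = rng.binomial(2, 0.5, size=300).astype(np.int8)
    r = e.fit_pair_models(np.full(300, 1.7), g1, g2)
    if not r.skipped:
        assert r.p_pair == 1.0 and r.p_int == 1.0


def test_model_degrees_of_freedom_structure():
    """F_pair tests 9 cell means vs intercept (8 df); F_int tests cells vs
    the 5-parameter main-effects model (4 df)."""
    assert np.linalg.matrix_rank(_CELL_DESIGN) == 5
    full = np.eye(9)
    assert np.linalg.matrix_rank(full) - 1 == 8
    assert np.linalg.matrix_rank(full) - np.linalg.matrix_rank(_CELL_DESIGN) == 4


def test_additive_only_pair_null_interaction():
    """Marginal-only effects inflate F_pair but leave F_int null."""
    rng = np.random.default_rng(23)
    n = 4000
    g1 = rng.binomial(2, 0.4, size=n).astype(np.int8)
    g2 = rng.binomial(2, 0.4, size=n).astype(np.int8)
    y = 0.3 * g1 + 0.3 * g2 + rng.normal(size=n)
    r = e.fit_pair_models(y, g1, g2)
    assert r.neglog10_p_pair > 10
    assert r.p_int > 1e-3


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def test_full_pair_scan_counts_and_chunk_invariance(null_trait_cohort):
    genotypes, trait = null_trait_cohort
    sub = genotypes.subset(snp_idx=np.arange(40))
    thr = e.ScanThresholds(retain_pair=0.5, retain_int=0.1)
    r1, acc1 = e.full_pair_scan(trait, sub, thr, chunk_size=7)
    r2, acc2 = e.full_pair_scan(trait, sub, thr, chunk_size=1000)
    assert acc1 == acc2
    assert acc1["n_pairs_total"] == 40 * 39 // 2
    pd.testing.assert_frame_equal(r1, r2)


def test_full_pair_scan_retention_filter(null_trait_cohort):
    genotypes, trait = null_trait_cohort
    sub = genotypes.subset(snp_idx=np.arange(60))
    loose, _ = e.full_pair_scan(trait, sub, e.ScanThresholds(retain_pair=-1, retain_int=-1))
    tight, acc = e.full_pair_scan(trait, sub, e.ScanThresholds(retain_pair=1.0, retain_int=1.0))
    kept = loose[(loose["neglog10_p_pair"] > 1.0) & (loose["neglog10_p_int"] > 1.0)]
    assert len(tight) == len(kept) == acc["n_retained"]


def test_snp_genome_scan_count_identity(null_trait_cohort):
    genotypes, trait = null_trait_cohort
    sub = genotypes.subset(snp_idx=np.arange(30))
    focal = list(sub.snps["snp_id"][:7])
    thr = e.derive_thresholds(30, len(focal))
    res = e.snp_genome_scan(trait, sub, focal, thr)
    n_skipped = 0  # clean fixture: high MAF, n=600
    assert len(res) == 7 * (30 - 7) + 7 * 6 // 2 - n_skipped
    assert not res.duplicated(subset=["snp_1", "snp_2"]).any()


def test_snp_genome_scan_empty_focal(null_trait_cohort):
    genotypes, trait = null_trait_cohort
    res = e.snp_genome_scan(trait, genotypes, [], e.derive_thresholds(300, 0))
    assert len(res) == 0


def test_single_snp_scan_allele_flip_symmetry(null_trait_cohort):
    genotypes, trait = null_trait_cohort
    flipped = genotypes.subset()
    flipped.matrix = np.where(
        flipped.matrix == MISSING, MISSING, 2 - flipped.matrix
    ).astype(np.int8)
    a = e.single_snp_scan(trait, genotypes)
    b = e.single_snp_scan(trait, flipped)
    assert np.allclose(a["p"], b["p"], atol=1e-12)
    assert np.allclose(a["slope"], -b["slope"], atol=1e-12)


def test_single_snp_scan_null_uniform_and_planted_power(null_trait_cohort):
    genotypes, trait = null_trait_cohort
    res = e.single_snp_scan(trait, genotypes)
    assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    # a SNP explaining ~5% of variance at n=1200 clears the 7.3 threshold
    rng = np.random.default_rng(40)
    g = rng.binomial(2, 0.3, size=1200).astype(np.int8)
    beta = np.sqrt(0.05 / (2 * 0.3 * 0.7))
    y = beta * (g - g.mean()) + rng.normal(scale=np.sqrt(0.95), size=1200)
    snps = pd.DataFrame(
        {"snp_id": ["s"], "chromosome": ["1"], "position": [1],
         "allele1": ["A"], "allele2": ["G"]}
    )
    ds = e.GenotypeDataset(np.array([f"i{k}" for k in range(1200)], dtype=object), snps, g[:, None])
    tr = e.PreparedTrait(values=y, sample_ids=ds.sample_ids, stage="polygenic_residual")
    out = e.single_snp_scan(tr, ds, e.ScanThresholds())
    assert out["neglog10_p"].iloc[0] > 7.3
    assert bool(out["focal"].iloc[0])


def test_single_snp_scan_monomorphic_flagged(null_trait_cohort):
    genotypes, trait = null_trait_cohort
    mono = genotypes.subset(snp_idx=np.arange(3))
    mono.matrix[:, 0] = 0
    res = e.single_snp_scan(trait, mono)
    assert bool(res["monomorphic"].iloc[0])
    assert res["p"].iloc[0] == 1.0


# ---------------------------------------------------------------------------
# inflation factor
# ---------------------------------------------------------------------------

def test_lambda_null_uniform():
    rng = np.random.default_rng(30)
    p = rng.uniform(size=10_000)
    assert e.inflation_lambda(p) == pytest.approx(1.0, abs=0.05)


def test_lambda_scales_with_chi_square():
    rng = np.random.default_rng(31)
    chi = stats.chi2.rvs(1, size=20_000, random_state=rng)
    p1 = stats.chi2.sf(chi, 1)
    p2 = stats.chi2.sf(2 * chi, 1)
    lam1 = e.inflation_lambda(p1)
    lam2 = e.inflation_lambda(p2)
    assert lam2 / lam1 == pytest.approx(2.0, rel=0.05)


def test_lambda_input_validation():
    with pytest.raises(ValueError):
        e.inflation_lambda(np.full(200, 0.5))
    with pytest.raises(ValueError):
        e.inflation_lambda(np.linspace(0.0, 1.0, 200))  # contains 0
    with pytest.raises(ValueError):
        e.inflation_lambda([0.5] * 50)  # too few


# ---------------------------------------------------------------------------
# KS null calibration
# ---------------------------------------------------------------------------

def test_ks_calibration_null_not_significant(null_trait_cohort):
    genotypes, trait = null_trait_cohort
    ks = e.ks_null_calibration(trait, genotypes, n_sample=120, seed=0)
    assert ks.p_value > 0.05
    assert ks.n_pairs > 5000


def test_ks_calibration_detects_dense_interaction_signal():
    """A trait quadratic in the sampled SNPs shifts every pair's
    interaction statistic; the KS comparison against permutation sees it."""
    config = e.SimulationConfig(
        n_individuals=600, n_snps=60, maf_range=(0.3, 0.5), seed=3
    )
    g = e.simulate_genotypes(config)
    rng = np.random.default_rng(0)
    Z = (g.matrix - g.matrix.mean(axis=0)) / g.matrix.std(axis=0)
    q = Z.sum(axis=1) ** 2
    y = (q - q.mean()) / q.std() + 0.2 * rng.normal(size=600)
    trait = e.PreparedTrait(values=y, sample_ids=g.sample_ids, stage="polygenic_residual")
    ks = e.ks_null_calibration(trait, g, n_sample=60, seed=1)
    assert ks.p_value < 0.05


def test_ks_calibration_rejects_oversampling(null_trait_cohort):
    genotypes, trait = null_trait_cohort
    with pytest.raises(ValueError):
        e.ks_null_calibration(trait, genotypes, n_sample=10_000, seed=0)
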