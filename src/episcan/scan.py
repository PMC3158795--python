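"""The epistasis scan engine.

Single-SNP association scan with the genomic inflation factor, Bonferroni
threshold derivation, the exhaustive pair-wise two-locus ANOVA scan, focal
SNP-genome scans, and permutation-based Kolmogorov-Smirnov null
calibration.

For a pair of SNPs the trait is modelled with genotype factors
(three levels each):

* Model 1 (saturated): ``y = mu + SNP1 + SNP2 + SNP1*SNP2 + e`` - the nine
  joint-genotype cell means;
* Model 2 (main effects): ``y = mu + SNP1 + SNP2 + e``;
* Model 3 (null): ``y = mu + e``.

``F_pair`` tests Model 1 against Model 3 (8 numerator df: 9 cells minus the
intercept) and captures the whole pair effect including interaction;
``F_int`` tests Model 1 against Model 2 (4 numerator df) and isolates the
interaction.  The denominator df is ``n - 9``.  Pairs in which any of the
nine joint genotype classes is empty are skipped rather than tested, which
keeps the type-I error of the factor models under control.

Everything is computed from per-pair 3x3 tables of counts, trait sums and
sums of squares, so an entire block of pairs reduces to three matrix
products plus a batched 5-parameter least-squares solve for the
main-effects model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeDataset
from .trait import PreparedTrait

NEGLOG10_CAP = 320.0  # -log10 p is capped here to avoid floating-point zeros
_LN10 = math.log(10.0)

# design matrix of the two-way main-effects model on the 9 cells
# (cell index c = 3*i + j; columns: intercept, i==1, i==2, j==1, j==2)
_CELL_DESIGN = np.array(
    [[1.0, i == 1, i == 2, j == 1, j == 2] for i in range(3) for j in range(3)],
    dtype=float,
)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def _round_sig(x: float, digits: int) -> float:
    if x <= 0:
        return x
    scale = 10.0 ** (math.floor(math.log10(x)) - digits + 1)
    return round(x / scale) * scale


@dataclass
class ScanThresholds:
    """All significance and retention cutoffs on the -log10 p scale.

    ``pairwise_genomewide`` and ``snp_genome`` follow the printed Bonferroni
    convention: the pair count is rounded to two significant figures and the
    SNP count to one before correction (300,000 SNPs give 4.5e10 pairs and a
    pairwise threshold of 11.95).  ``*_exact`` fields keep the unrounded
    versions; the difference is below 0.01 on the -log10 scale.
    """

    consensus_gwa: float = 7.3  # -log10(5e-8)
    pairwise_genomewide: float = float("nan")
    snp_genome: float = float("nan")
    retain_pair: float = 4.7
    retain_int: float = 3.2
    enrich_pair: float = 6.5
    enrich_int: float = 6.5
    pairwise_genomewide_exact: float = float("nan")
    snp_genome_exact: float = float("nan")
    n_snps: int = 0
    n_focal: int = 0
    snp_genome_defined: bool = True


def derive_thresholds(n_snps: int, n_focal: int = 0) -> ScanThresholds:
    """Bonferroni thresholds for the pair-wise and SNP-genome scans.

    ``pairwise_genomewide = -log10(0.05 / n_pairs)`` with the pair count
    rounded to two significant figures, and ``snp_genome =
    -log10(0.05 / n_snps / n_focal)`` with the SNP count rounded to one.
    With ``n_focal == 0`` the SNP-genome threshold is undefined (NaN,
    flagged).
    """
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    if n_focal < 0:
        raise ValueError("n_focal must be >= 0")
    n_pairs = n_snps * (n_snps - 1) / 2.0
    pairwise = math.log10(_round_sig(n_pairs, 2) / 0.05)
    pairwise_exact = math.log10(n_pairs / 0.05)
    if n_focal > 0:
        snp_genome = math.log10(_round_sig(n_snps, 1) * n_focal / 0.05)
        snp_genome_exact = math.log10(n_snps * n_focal / 0.05)
        defined = True
    else:
        snp_genome = snp_genome_exact = float("nan")
        defined = False
    return ScanThresholds(
        pairwise_genomewide=pairwise,
        snp_genome=snp_genome,
        pairwise_genomewide_exact=pairwise_exact,
        snp_genome_exact=snp_genome_exact,
        n_snps=n_snps,
        n_focal=n_focal,
        snp_genome_defined=defined,
    )


# ---------------------------------------------------------------------------
# single-SNP scan and inflation factor
# ---------------------------------------------------------------------------

def single_snp_scan(
    trait: PreparedTrait,
    genotypes: GenotypeDataset,
    thresholds: ScanThresholds | None = None,
) -> pd.DataFrame:
    """Additive-model score test of each SNP against the prepared residuals.

    For each SNP the score statistic is ``n * r^2`` between the residuals
    and the 0/1/2 genotype code over complete cases, referred to a 1-df
    chi-square.  Monomorphic SNPs get p = 1 and a flag.  When thresholds
    are supplied, SNPs above ``consensus_gwa`` are marked focal.
    """
    if trait.stage != "polygenic_residual":
        raise ValueError("single_snp_scan expects polygenic residuals")
    y = trait.values
    G = genotypes.matrix
    obs = G != MISSING
    Gf = np.where(obs, G, 0).astype(float)
    n = obs.sum(axis=0).astype(float)
    sg = Gf.sum(axis=0)
    sgg = (Gf * Gf).sum(axis=0)
    sy = obs.T.astype(float) @ y
    syy = obs.T.astype(float) @ (y * y)
    sgy = Gf.T @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = sgg - sg * sg / n
        sxy = sgy - sg * sy / n
        syy_c = syy - sy * sy / n
        slope = sxy / sxx
        r2 = sxy * sxy / (sxx * syy_c)
    mono = ~(sxx > 0) | ~(syy_c > 0) | (n < 3)
    score = np.where(mono, 0.0, n * r2)
    p = np.where(mono, 1.0, stats.chi2.sf(score, df=1))
    with np.errstate(divide="ignore"):
        neglog = np.where(mono, 0.0, -stats.chi2.logsf(score, df=1) / _LN10)
    neglog = np.minimum(neglog, NEGLOG10_CAP)
    out = pd.DataFrame(
        {
            "snp_id": genotypes.snps["snp_id"].to_numpy(),
            "chromosome": genotypes.snps["chromosome"].to_numpy(),
            "position": genotypes.snps["position"].to_numpy(),
            "n_used": n.astype(int),
            "slope": np.where(mono, np.nan, slope),
            "p": p,
            "neglog10_p": neglog,
            "monomorphic": mono,
        }
    )
    if thresholds is not None:
        out["focal"] = out["neglog10_p"] > thresholds.consensus_gwa
    return out


def inflation_lambda(p_values) -> float:
    """Genomic inflation factor from a QQ-plot quantile regression.

    P-values are converted to 1-df chi-square quantiles; lambda is the
    slope of the no-intercept regression of the ordered observed quantiles
    on the expected ones.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) < 100:
        raise ValueError("need at least 100 p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if np.unique(p).size < 2:
        raise ValueError("degenerate p-value set (all identical)")
    observed = np.sort(stats.chi2.isf(p, df=1))
    k = len(p)
    expected = np.sort(stats.chi2.isf((np.arange(1, k + 1) - 0.5) / k, df=1))
    return float(observed @ expected / (expected @ expected))


# ---------------------------------------------------------------------------
# pair-scan core
# ---------------------------------------------------------------------------

def _indicators(G: np.ndarray) -> np.ndarray:
    """(n, m) genotype block -> (n, 3m) 0/1 indicator matrix.

    Missing genotypes produce all-zero rows for that SNP, so cross-products
    of two indicator blocks automatically give pair-wise complete-case
    tables.
    """
    n, m = G.shape
    return (G[:, :, None] == np.arange(3, dtype=G.dtype)).astype(float).reshape(n, 3 * m)


def _block_tables(y: np.ndarray, I1: np.ndarray, I2: np.ndarray):
    """3x3 tables of counts / sums / sums of squares for all column pairs."""
    m1, m2 = I1.shape[1] // 3, I2.shape[1] // 3
    Y1 = I1 * y[:, None]
    Q1 = I1 * (y * y)[:, None]

    def cells(A):
        return A.reshape(m1, 3, m2, 3).transpose(0, 2, 1, 3).reshape(m1, m2, 9)

    C = cells(I1.T @ I2)
    S = cells(Y1.T @ I2)
    Q = cells(Q1.T @ I2)
    return C, S, Q


def _pair_tests_from_tables(C: np.ndarray, S: np.ndarray, Q: np.ndarray):
    """Vectorised F_pair / F_int statistics from per-pair 3x3 tables.

    Returns a dict of arrays shaped like ``C[..., 0]``.  Skipped entries
    (an empty joint class, or residual df <= 0) carry NaN statistics.
    """
    n = C.sum(axis=-1)
    mgc = C.min(axis=-1)
    empty_class = mgc <= 0
    dfd = n - 9
    skip = empty_class | (dfd <= 0)

    Sy = S.sum(axis=-1)
    Syy = Q.sum(axis=-1)
    Csafe = np.where(C > 0, C, 1.0)
    cell_ss = (S * S / Csafe).sum(axis=-1)
    rss_full = np.maximum(Syy - cell_ss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_null = np.maximum(Syy - Sy * Sy / np.maximum(n, 1.0), 0.0)

    X = _CELL_DESIGN
    A = np.einsum("...c,ck,cl->...kl", Csafe, X, X)
    b = np.einsum("...c,ck->...k", S, X)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    fit_ss = np.einsum("...k,...k->...", beta, b)
    # cells model nests the main-effects model: the gap is non-negative
    rss_main = rss_full + np.maximum(cell_ss - fit_ss, 0.0)

    tiny = 1e-12
    const_trait = rss_null <= tiny * np.maximum(Syy, 1.0)
    perfect_fit = (rss_full <= tiny * np.maximum(rss_null, 1.0)) & ~const_trait

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = rss_full / np.maximum(dfd, 1.0)
        f_pair = (rss_null - rss_full) / 8.0 / denom
        f_int = (rss_main - rss_full) / 4.0 / denom

    def _p_and_neglog(f, dfn):
        f = np.where(np.isfinite(f) & (f >= 0), f, 0.0)
        p = stats.f.sf(f, dfn, np.maximum(dfd, 1.0))
        with np.errstate(divide="ignore"):
            neglog = -stats.f.logsf(f, dfn, np.maximum(dfd, 1.0)) / _LN10
        neglog = np.minimum(neglog, NEGLOG10_CAP)
        p = np.where(const_trait, 1.0, p)
        neglog = np.where(const_trait, 0.0, neglog)
        p = np.where(perfect_fit, 10.0**-NEGLOG10_CAP, p)
        neglog = np.where(perfect_fit, NEGLOG10_CAP, neglog)
        return p, neglog

    p_pair, nl_pair = _p_and_neglog(f_pair, 8.0)
    p_int, nl_int = _p_and_neglog(f_int, 4.0)
    nan = np.where(skip, np.nan, 1.0)
    return {
        "n_used": n,
        "mgc": mgc,
        "skipped": skip,
        "rss_full": rss_full,
        "rss_main": rss_main,
        "rss_null": rss_null,
        "f_pair": f_pair * nan,
        "p_pair": p_pair * nan,
        "neglog10_p_pair": nl_pair * nan,
        "f_int": f_int * nan,
        "p_int": p_int * nan,
        "neglog10_p_int": nl_int * nan,
    }


@dataclass
class PairTestResult:
    """Two-locus ANOVA result for one SNP pair."""

    snp_1: str
    snp_2: str
    n_used: int
    mgc: int
    skipped: bool
    f_pair: float = float("nan")
    p_pair: float = float("nan")
    neglog10_p_pair: float = float("nan")
    f_int: float = float("nan")
    p_int: float = float("nan")
    neglog10_p_int: float = float("nan")
    rss_full: float = float("nan")
    rss_main: float = float("nan")
    rss_null: float = float("nan")
    reason: str = ""


def fit_pair_models(trait_values, g1, g2, snp_1: str = "snp_1", snp_2: str = "snp_2") -> PairTestResult:
    """Fit Models 1-3 for a single SNP pair and return both F tests.

    ``trait_values`` is any prepared residual vector; ``g1``/``g2`` are
    genotype columns coded 0/1/2 with -1 missing.  Rows missing either
    genotype are dropped.  Pairs with an empty joint genotype class, or with
    ``n_used <= 9`` (no residual df), are returned skipped.
    """
    y = np.asarray(trait_values, dtype=float)
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    keep = (g1 != MISSING) & (g2 != MISSING)
    y, g1, g2 = y[keep], g1[keep], g2[keep]
    C, S, Q = _block_tables(y, _indicators(g1[:, None]), _indicators(g2[:, None]))
    res = _pair_tests_from_tables(C, S, Q)
    out = {k: v[0, 0] for k, v in res.items()}
    reason = ""
    if out["skipped"]:
        reason = (
            "insufficient residual df"
            if out["mgc"] > 0
            else "empty joint genotype class"
        )
    return PairTestResult(
        snp_1=snp_1,
        snp_2=snp_2,
        n_used=int(out["n_used"]),
        mgc=int(out["mgc"]),
        skipped=bool(out["skipped"]),
        f_pair=float(out["f_pair"]),
        p_pair=float(out["p_pair"]),
        neglog10_p_pair=float(out["neglog10_p_pair"]),
        f_int=float(out["f_int"]),
        p_int=float(out["p_int"]),
        neglog10_p_int=float(out["neglog10_p_int"]),
        rss_full=float(out["rss_full"]),
        rss_main=float(out["rss_main"]),
        rss_null=float(out["rss_null"]),
        reason=reason,
    )


def _result_frame(snp_ids_1, snp_ids_2, res, mask) -> pd.DataFrame:
    """Assemble a tidy DataFrame from block results at the masked positions."""
    ii, jj = np.nonzero(mask)
    return pd.DataFrame(
        {
            "snp_1": np.asarray(snp_ids_1)[ii],
            "snp_2": np.asarray(snp_ids_2)[jj],
            "n_used": res["n_used"][ii, jj].astype(int),
            "mgc": res["mgc"][ii, jj].astype(int),
            "f_pair": res["f_pair"][ii, jj],
            "p_pair": res["p_pair"][ii, jj],
            "neglog10_p_pair": res["neglog10_p_pair"][ii, jj],
            "f_int": res["f_int"][ii, jj],
            "p_int": res["p_int"][ii, jj],
            "neglog10_p_int": res["neglog10_p_int"][ii, jj],
        }
    )


def _chunk_ranges(m: int, chunk_size: int):
    return [(a, min(a + chunk_size, m)) for a in range(0, m, chunk_size)]


def full_pair_scan(
    trait: PreparedTrait,
    genotypes: GenotypeDataset,
    thresholds: ScanThresholds,
    chunk_size: int = 512,
):
    """Exhaustive scan of all unordered SNP pairs with retention filtering.

    Iterates chunked blocks of the genotype matrix; only pairs passing both
    retention cutoffs (``neglog10_p_pair > retain_pair`` and
    ``neglog10_p_int > retain_int``) are emitted.  Returns ``(retained,
    accounting)`` where ``accounting`` counts total, skipped and retained
    pairs.  Results are independent of ``chunk_size``.
    """
    y = trait.values
    G = genotypes.matrix
    ids = genotypes.snps["snp_id"].to_numpy()
    m = genotypes.n_snps
    ranges = _chunk_ranges(m, chunk_size)
    retained_frames = []
    n_total = n_skipped = n_retained = 0
    for ai, (a0, a1) in enumerate(ranges):
        Ia = _indicators(G[:, a0:a1])
        for b0, b1 in ranges[ai:]:
            Ib = Ia if b0 == a0 else _indicators(G[:, b0:b1])
            C, S, Q = _block_tables(y, Ia, Ib)
            res = _pair_tests_from_tables(C, S, Q)
            valid = (
                np.triu(np.ones((a1 - a0, b1 - b0), dtype=bool), k=1)
                if b0 == a0
                else np.ones((a1 - a0, b1 - b0), dtype=bool)
            )
            n_total += int(valid.sum())
            n_skipped += int((res["skipped"] & valid).sum())
            keep = (
                valid
                & ~res["skipped"]
                & (res["neglog10_p_pair"] > thresholds.retain_pair)
                & (res["neglog10_p_int"] > thresholds.retain_int)
            )
            if keep.any():
                retained_frames.append(_result_frame(ids[a0:a1], ids[b0:b1], res, keep))
                n_retained += int(keep.sum())
    retained = (
        pd.concat(retained_frames, ignore_index=True)
        if retained_frames
        else _result_frame(ids[:0], ids[:0], _empty_res(), np.zeros((0, 0), dtype=bool))
    )
    retained = retained.sort_values(["snp_1", "snp_2"], ignore_index=True)
    accounting = {
        "n_pairs_total": n_total,
        "n_skipped": n_skipped,
        "skip_fraction": n_skipped / n_total if n_total else 0.0,
        "n_retained": n_retained,
    }
    return retained, accounting


def _empty_res():
    z = np.zeros((0, 0))
    keys = [
        "n_used", "mgc", "f_pair", "p_pair", "neglog10_p_pair",
        "f_int", "p_int", "neglog10_p_int",
    ]
    return {k: z for k in keys}


def snp_genome_scan(
    trait: PreparedTrait,
    genotypes: GenotypeDataset,
    focal_snp_ids,
    thresholds: ScanThresholds,
    chunk_size: int = 1024,
) -> pd.DataFrame:
    """Test each focal SNP against every other SNP in the panel.

    Pairs within the focal set are evaluated once.  Non-skipped pairs with
    both ``neglog10_p_int`` and ``neglog10_p_pair`` above the
    ``snp_genome`` threshold are flagged ``significant``.
    """
    focal_snp_ids = list(focal_snp_ids)
    if not focal_snp_ids:
        return _result_frame([], [], _empty_res(), np.zeros((0, 0), dtype=bool)).assign(
            significant=pd.Series(dtype=bool)
        )
    ids = genotypes.snps["snp_id"].to_numpy()
    pos_of = {s: i for i, s in enumerate(ids)}
    try:
        focal_idx = np.array([pos_of[s] for s in focal_snp_ids])
    except KeyError as exc:
        raise ValueError(f"focal SNP {exc.args[0]!r} not in dataset") from exc
    focal_set = set(focal_idx.tolist())
    y = trait.values
    G = genotypes.matrix
    If = _indicators(G[:, focal_idx])
    frames = []
    for b0, b1 in _chunk_ranges(genotypes.n_snps, chunk_size):
        Ib = _indicators(G[:, b0:b1])
        C, S, Q = _block_tables(y, If, Ib)
        res = _pair_tests_from_tables(C, S, Q)
        valid = np.ones((len(focal_idx), b1 - b0), dtype=bool)
        for fi, fidx in enumerate(focal_idx):
            for j in range(b0, b1):
                if j == fidx or (j in focal_set and j < fidx):
                    valid[fi, j - b0] = False
        frames.append(
            _result_frame(ids[focal_idx], ids[b0:b1], res, valid & ~res["skipped"])
        )
    out = pd.concat(frames, ignore_index=True)
    thr = thresholds.snp_genome
    if thresholds.snp_genome_defined:
        out["significant"] = (out["neglog10_p_int"] > thr) & (out["neglog10_p_pair"] > thr)
    else:
        out["significant"] = False
    return out.sort_values(["snp_1", "snp_2"], ignore_index=True)


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

@dataclass
class KsCalibration:
    """Two-sample KS comparison of observed vs permuted interaction p-values."""

    statistic: float
    p_value: float
    n_pairs: int
    n_snps_sampled: int


def ks_null_calibration(
    trait: PreparedTrait,
    genotypes: GenotypeDataset,
    n_sample: int = 5000,
    seed: int = 0,
    chunk_size: int = 512,
) -> KsCalibration:
    """Compare interaction p-values against a permuted-trait null.

    A random sample of SNPs is drawn; all their pair-wise ``-log10 p_int``
    values are computed with the observed trait and again with a seeded
    permutation of it (skipped pairs, which depend only on the genotypes,
    are excluded from both).  The two distributions are compared with a
    two-sample Kolmogorov-Smirnov test: a non-significant result indicates
    the scan statistics are well calibrated.
    """
    if n_sample > genotypes.n_snps:
        raise ValueError("n_sample exceeds available SNPs")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(genotypes.n_snps, size=n_sample, replace=False))
    y = trait.values
    y_perm = y[rng.permutation(len(y))]
    G = genotypes.matrix[:, idx]
    ranges = _chunk_ranges(n_sample, chunk_size)
    obs_vals, perm_vals = [], []
    for ai, (a0, a1) in enumerate(ranges):
        Ia = _indicators(G[:, a0:a1])
        for b0, b1 in ranges[ai:]:
            Ib = Ia if b0 == a0 else _indicators(G[:, b0:b1])
            C, S, Qo = _block_tables(y, Ia, Ib)
            _, Sp, Qp = _block_tables(y_perm, Ia, Ib)
            res_o = _pair_tests_from_tables(C, S, Qo)
            res_p = _pair_tests_from_tables(C, Sp, Qp)
            valid = (
                np.triu(np.ones((a1 - a0, b1 - b0), dtype=bool), k=1)
                if b0 == a0
                else np.ones((a1 - a0, b1 - b0), dtype=bool)
            ) & ~res_o["skipped"]
            obs_vals.append(res_o["neglog10_p_int"][valid])
            perm_vals.append(res_p["neglog10_p_int"][valid])
    obs = np.concatenate(obs_vals)
    perm = np.concatenate(perm_vals)
    ks = stats.ks_2samp(obs, perm)
    return KsCalibration(
        statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        n_pairs=len(obs),
        n_snps_sampled=n_sample,
    )
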