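"""Trait preparation: covariate adjustment, rank-based inverse-normal
transform, genomic kinship, and the polygenic mixed model.

The association trait used by the scan engine is the GRAMMAR-style
environmental residual: raw trait values are adjusted for fixed covariates
by OLS, rank-inverse-normal transformed, and then the polygenic random
effect (BLUP under a kinship-based mixed model) is removed.  Heritability
is the REML estimate of the variance fraction attached to the kinship
matrix at that mixed-model step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import MISSING, GenotypeDataset

STAGES = ("covariate_adjusted", "normalised", "polygenic_residual", "standardized")


@dataclass
class PreparedTrait:
    """A per-sample trait vector at a named preparation stage.

    ``h2`` is populated at the ``polygenic_residual`` stage;
    ``h2_identifiable`` is False when the kinship matrix carries no
    relatedness information (e.g. the identity), in which case the genetic
    and environmental components cannot be separated.
    """

    values: np.ndarray
    sample_ids: np.ndarray
    stage: str
    h2: float | None = None
    h2_identifiable: bool = True
    n_dropped: int = 0
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if len(self.values) != len(self.sample_ids):
            raise ValueError("values and sample_ids length mismatch")
        if self.h2 is not None and not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix on the relationship scale (sibs ~ 0.5).

    The eigendecomposition is computed lazily and cached: every REML fit
    against the same kinship reuses it.
    """

    values: np.ndarray
    sample_ids: np.ndarray
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample count")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")

    def eig(self):
        """Eigenvalues (clipped to >= 0) and eigenvectors of the matrix."""
        if self._eig is None:
            d, u = np.linalg.eigh(self.values)
            self._eig = (np.clip(d, 0.0, None), u)
        return self._eig

    def subset(self, idx) -> "KinshipMatrix":
        idx = np.asarray(idx)
        return KinshipMatrix(self.values[np.ix_(idx, idx)], self.sample_ids[idx])


# ---------------------------------------------------------------------------
# covariate adjustment and normalisation
# ---------------------------------------------------------------------------

def _design_from_covariates(covariates: pd.DataFrame):
    cols = [c for c in covariates.columns if c != "id"]
    X = np.column_stack(
        [np.ones(len(covariates))]
        + [pd.to_numeric(covariates[c]).to_numpy(dtype=float) for c in cols]
    )
    return X, ["intercept"] + cols


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name a culprit: the first column whose removal restores full rank
        for j in range(1, X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == r:
                raise ValueError(f"collinear covariate column: {names[j]!r}")
        raise ValueError("rank-deficient covariate design")


def covariate_adjust(raw_trait, covariates: pd.DataFrame) -> PreparedTrait:
    """OLS residuals of the raw trait on intercept + covariate columns.

    Rows with a missing trait or covariate value are dropped (count kept in
    ``n_dropped``).  Residuals are exactly orthogonal to the fitted columns.
    """
    y = np.asarray(raw_trait, dtype=float)
    if len(y) != len(covariates):
        raise ValueError("trait and covariate table length mismatch")
    ids = (
        covariates["id"].to_numpy(dtype=object)
        if "id" in covariates.columns
        else np.arange(len(y)).astype(object)
    )
    X, names = _design_from_covariates(covariates)
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    n_dropped = int((~keep).sum())
    y, X, ids = y[keep], X[keep], ids[keep]
    _check_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return PreparedTrait(
        values=resid,
        sample_ids=ids,
        stage="covariate_adjusted",
        n_dropped=n_dropped,
        provenance=[f"covariate_adjust({', '.join(names[1:])})"],
    )


def rank_inverse_normal(values) -> np.ndarray:
    """Rank-based inverse-normal transform.

    Each value maps to the standard-normal quantile of ``(rank - 0.5) / n``
    with average ranks for ties; the result depends only on the ordering of
    the input (invariant to monotone transforms).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-d array of at least 2 values")
    if np.unique(x).size < 2:
        raise ValueError("all values identical; rank transform undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def normalise(trait: PreparedTrait) -> PreparedTrait:
    """Apply the rank-inverse-normal transform to an adjusted trait."""
    return PreparedTrait(
        values=rank_inverse_normal(trait.values),
        sample_ids=trait.sample_ids,
        stage="normalised",
        n_dropped=trait.n_dropped,
        provenance=trait.provenance + ["rank_inverse_normal"],
    )


def standardize(raw_trait, covariates: pd.DataFrame) -> PreparedTrait:
    """Covariate-adjust then scale to mean 0, variance 1 (for variance
    accounting; invariant to affine transforms of the raw trait)."""
    adj = covariate_adjust(raw_trait, covariates)
    sd = adj.values.std()
    scale = float(np.abs(np.asarray(raw_trait, dtype=float)).max(initial=1.0))
    if sd <= 1e-12 * scale:
        raise ValueError("zero residual variance; cannot standardize")
    return PreparedTrait(
        values=(adj.values - adj.values.mean()) / sd,
        sample_ids=adj.sample_ids,
        stage="standardized",
        n_dropped=adj.n_dropped,
        provenance=adj.provenance + ["standardize"],
    )


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def estimate_kinship(genotypes: GenotypeDataset) -> KinshipMatrix:
    """Genomic relationship matrix from standardized genotype columns.

    Missing entries are mean-imputed per SNP (zero after centering);
    monomorphic SNPs carry no information and are skipped.
    """
    if genotypes.n_snps < 2:
        raise ValueError("need at least 2 SNPs to estimate kinship")
    cols = []
    for j in range(genotypes.n_snps):
        col = genotypes.matrix[:, j]
        obs = col != MISSING
        if not obs.any():
            continue
        x = col.astype(float)
        mean = x[obs].mean()
        sd = x[obs].std()
        if sd == 0:
            continue
        cols.append(np.where(obs, (x - mean) / sd, 0.0))
    if not cols:
        raise ValueError("all SNPs monomorphic; kinship undefined")
    Z = np.column_stack(cols)
    K = (Z @ Z.T) / Z.shape[1]
    return KinshipMatrix(values=K, sample_ids=genotypes.sample_ids)


# ---------------------------------------------------------------------------
# REML polygenic model
# ---------------------------------------------------------------------------

def _reml_neg_loglik(h2: float, yt: np.ndarray, Xt: np.ndarray, d: np.ndarray):
    """Negative REML log-likelihood for y = Xb + g + e profiled over h2.

    Works in the kinship eigenbasis: with K = U diag(d) U', the rotated
    model has independent errors with weights w_i = h2*d_i + (1 - h2).
    Rank-deficient fixed-effect designs are handled through the SVD
    (pseudo-inverse solve, pseudo-determinant in the REML term).
    """
    n = len(yt)
    w = h2 * d + (1.0 - h2)
    w = np.maximum(w, 1e-12)
    sw = 1.0 / np.sqrt(w)
    Xw = Xt * sw[:, None]
    yw = yt * sw
    U_, s, Vt = np.linalg.svd(Xw, full_matrices=False)
    tol = max(Xw.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    nz = s > tol
    p = int(nz.sum())
    beta = Vt[nz].T @ ((U_[:, nz].T @ yw) / s[nz])
    r = yw - Xw @ beta
    rss = float(r @ r)
    sigma2 = rss / max(n - p, 1)
    nll = 0.5 * (
        (n - p) * np.log(sigma2)
        + np.log(w).sum()
        + 2.0 * np.log(s[nz]).sum()
        + (n - p)
    )
    return nll, beta, sigma2, p


def _profile_h2(yt, Xt, d, grid_step=0.01, tol=1e-6):
    """Coarse grid then golden-section search over h2 in [0, 0.999]."""
    grid = np.arange(0.0, 0.999 + 1e-12, grid_step)
    nlls = np.array([_reml_neg_loglik(h, yt, Xt, d)[0] for h in grid])
    i = int(np.argmin(nlls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda h: _reml_neg_loglik(h, yt, Xt, d)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol},
        )
        h2 = float(res.x)
        if _reml_neg_loglik(grid[i], yt, Xt, d)[0] < res.fun:
            h2 = float(grid[i])
    else:
        h2 = float(grid[i])
    return h2


def fit_polygenic(trait: PreparedTrait, kinship: KinshipMatrix):
    """REML fit of y = mu + g + e with cov(g) = h2 * sigma2 * K.

    Returns ``(prepared, h2)`` where ``prepared`` holds the environmental
    residuals ``y - mu_hat - BLUP(g)`` (stage ``polygenic_residual``).  When
    the kinship eigenvalues are all equal (identity-like matrix) the model
    is unidentifiable: h2 is reported as 0 with ``h2_identifiable=False``
    and the residuals are the centered input.
    """
    if trait.stage not in ("normalised", "covariate_adjusted", "standardized"):
        raise ValueError("fit_polygenic expects an adjusted or normalised trait")
    if len(trait.values) != len(kinship.sample_ids):
        raise ValueError("kinship dimension does not match trait length")
    y = trait.values
    d, U = kinship.eig()
    if d.max() - d.min() < 1e-8:
        resid = y - y.mean()
        prepared = PreparedTrait(
            values=resid,
            sample_ids=trait.sample_ids,
            stage="polygenic_residual",
            h2=0.0,
            h2_identifiable=False,
            n_dropped=trait.n_dropped,
            provenance=trait.provenance + ["fit_polygenic(unidentifiable)"],
        )
        return prepared, 0.0

    yt = U.T @ y
    Xt = U.T @ np.ones((len(y), 1))
    h2 = _profile_h2(yt, Xt, d)
    _, beta, _, _ = _reml_neg_loglik(h2, yt, Xt, d)
    w = h2 * d + (1.0 - h2)
    rt = yt - Xt @ beta
    env = U @ ((1.0 - h2) / w * rt)  # y - mu - BLUP(g)
    prepared = PreparedTrait(
        values=env,
        sample_ids=trait.sample_ids,
        stage="polygenic_residual",
        h2=h2,
        n_dropped=trait.n_dropped,
        provenance=trait.provenance + [f"fit_polygenic(h2={h2:.4f})"],
    )
    return prepared, h2


def reml_variance(y: np.ndarray, X: np.ndarray, kinship: KinshipMatrix):
    """REML residual variance (genetic + environmental) after fixed effects.

    Fits ``y = X beta + g + e`` with ``cov(g) + cov(e) = sigma2 *
    (h2 K + (1 - h2) I)`` and returns ``(sigma2, h2)``; ``sigma2`` is the
    total residual variance on the scale of ``y``.  Used for variance-
    explained accounting on a standardized trait.
    """
    d, U = kinship.eig()
    yt = U.T @ np.asarray(y, dtype=float)
    Xt = U.T @ np.asarray(X, dtype=float)
    if d.max() - d.min() < 1e-8:
        _, _, sigma2, _ = _reml_neg_loglik(0.0, yt, Xt, d)
        return sigma2, 0.0
    h2 = _profile_h2(yt, Xt, d)
    _, _, sigma2, _ = _reml_neg_loglik(h2, yt, Xt, d)
    return sigma2, h2


# ---------------------------------------------------------------------------
# pipeline wrapper
# ---------------------------------------------------------------------------

def prepare_trait(
    phenotypes: pd.DataFrame,
    kinship: KinshipMatrix,
    trait_column: str = "sua",
    covariate_columns: tuple[str, ...] = ("age", "sex", "bmi"),
) -> PreparedTrait:
    """Full preparation chain: adjust -> rank-normalise -> polygenic residual.

    ``phenotypes`` must carry an ``id`` column aligning with the kinship
    sample ids; rows dropped for missing values subset the kinship matrix.
    """
    covariates = phenotypes[["id", *covariate_columns]]
    adjusted = covariate_adjust(phenotypes[trait_column].to_numpy(dtype=float), covariates)
    normalised = normalise(adjusted)
    id_to_pos = {s: i for i, s in enumerate(kinship.sample_ids)}
    try:
        idx = np.array([id_to_pos[s] for s in normalised.sample_ids])
    except KeyError as exc:
        raise ValueError(f"sample {exc.args[0]!r} missing from kinship matrix") from exc
    prepared, _ = fit_polygenic(normalised, kinship.subset(idx))
    return prepared
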