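"""Genotype containers, PLINK/text I/O and quality-control filters.

Genotypes are held as a dense ``samples x SNPs`` matrix of minor-allele
counts (``0``, ``1``, ``2``) with ``-1`` marking missing calls.  The minor
allele is always determined from the sample allele frequency, so a stored
dataset and a freshly loaded one agree on coding regardless of the on-disk
allele order.

Two on-disk formats are supported:

* PLINK 1 binary (``.bed``/``.bim``/``.fam``, SNP-major, v1 magic bytes);
* a plain-text dialect: a genotype TSV (first column ``id``, one column per
  SNP, values ``0``/``1``/``2``/``NA`` counting copies of ``allele1``) next
  to a map TSV with columns ``snp_id``, ``chromosome``, ``position``,
  ``allele1``, ``allele2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

_SNP_COLUMNS = ["snp_id", "chromosome", "position", "allele1", "allele2"]


class GenotypeFormatError(ValueError):
    """Raised when genotype files are malformed or mutually inconsistent."""


@dataclass
class GenotypeDataset:
    """Sample-by-SNP genotype matrix plus its marker map.

    Attributes
    ----------
    sample_ids
        Array of sample identifiers (length ``n_samples``).
    snps
        DataFrame with columns ``snp_id``, ``chromosome``, ``position``,
        ``allele1`` (minor), ``allele2`` (major), one row per SNP, sorted by
        (chromosome, position); positions are 1-based.
    matrix
        ``int8`` array of shape ``(n_samples, n_snps)`` counting minor
        alleles, ``-1`` for missing.
    """

    sample_ids: np.ndarray
    snps: pd.DataFrame
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.sample_ids), len(self.snps)):
            raise GenotypeFormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.matrix, [MISSING, 0, 1, 2])
        if bad.any():
            raise GenotypeFormatError("genotype codes must be in {-1, 0, 1, 2}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeDataset":
        """Return a copy restricted to the given sample/SNP indices."""
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            sample_ids=self.sample_ids[sample_idx],
            snps=self.snps.iloc[snp_idx].reset_index(drop=True),
            matrix=self.matrix[np.ix_(sample_idx, snp_idx)].copy(),
        )


@dataclass
class QcThresholds:
    """Cohort quality-control cutoffs.

    Defaults follow common GWAS practice for array data: individuals below a
    95% call rate are dropped, then SNPs below a 98% call rate, SNPs whose
    Hardy-Weinberg goodness-of-fit p-value falls below 1e-10, and SNPs with
    minor allele frequency below 2%.
    """

    individual_call_rate: float = 0.95
    snp_call_rate: float = 0.98
    hwe_p_min: float = 1.0e-10
    maf_min: float = 0.02

    def __post_init__(self) -> None:
        for name in ("individual_call_rate", "snp_call_rate", "hwe_p_min", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# summaries and tests
# ---------------------------------------------------------------------------

def hwe_test(counts) -> float:
    """Hardy-Weinberg equilibrium p-value from a genotype count triple.

    ``counts`` is ``(n_major_hom, n_het, n_minor_hom)`` (any orientation
    works; the test is symmetric in the two homozygote classes).  A 1-df
    chi-square goodness-of-fit test compares observed counts against the
    HWE proportions at the sample allele frequency.  Monomorphic samples
    return 1 by convention.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (3,):
        raise ValueError("counts must be a triple (hom, het, hom)")
    if (c < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = c.sum()
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (2 * c[2] + c[1]) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(((c - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _per_snp_counts(matrix: np.ndarray):
    """Genotype count triples (n0, n1, n2) per SNP, ignoring missing."""
    return np.stack([(matrix == g).sum(axis=0) for g in (0, 1, 2)], axis=1).astype(float)


def snp_summary(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-SNP call rate, minor allele frequency and HWE p-value.

    MAF is ``(het + 2 * minor_hom) / (2 * non_missing)``; SNPs with no
    non-missing calls get ``NaN`` MAF/HWE and are flagged in ``all_missing``.
    """
    if dataset.n_samples < 1:
        raise ValueError("dataset must contain at least one sample")
    counts = _per_snp_counts(dataset.matrix)
    non_missing = counts.sum(axis=1)
    call_rate = non_missing / dataset.n_samples
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = (counts[:, 1] + 2 * counts[:, 2]) / (2 * non_missing)
    maf = np.where(non_missing > 0, maf, np.nan)
    hwe_p = np.array(
        [hwe_test(c) if c.sum() >= 1 else np.nan for c in counts]
    )
    return pd.DataFrame(
        {
            "snp_id": dataset.snps["snp_id"].to_numpy(),
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "all_missing": non_missing == 0,
        }
    )


def qc_filter(dataset: GenotypeDataset, thresholds: QcThresholds | None = None):
    """Apply cohort QC: drop low-call-rate individuals, then failing SNPs.

    Individuals below the individual call rate are removed first; SNP
    criteria (call rate, HWE, MAF) are then evaluated on the remaining
    samples.  Returns ``(filtered_dataset, report)`` where ``report`` is a
    DataFrame of removal counts per criterion.  The operation is idempotent:
    re-filtering the output removes nothing.
    """
    thresholds = thresholds or QcThresholds()
    observed = dataset.matrix != MISSING
    ind_call = observed.mean(axis=1) if dataset.n_snps else np.ones(dataset.n_samples)
    keep_ind = ind_call >= thresholds.individual_call_rate
    n_ind_removed = int((~keep_ind).sum())

    inter = dataset.subset(sample_idx=np.flatnonzero(keep_ind))
    if inter.n_samples == 0:
        raise ValueError("no samples left after individual call-rate filtering")
    summary = snp_summary(inter)

    fail_call = summary["call_rate"].to_numpy() < thresholds.snp_call_rate
    maf = summary["maf"].to_numpy()
    hwe = summary["hwe_p"].to_numpy()
    fail_maf = ~(maf >= thresholds.maf_min)  # NaN (all missing) also fails
    fail_hwe = np.where(np.isnan(hwe), True, hwe < thresholds.hwe_p_min)
    keep_snp = ~(fail_call | fail_maf | fail_hwe)

    report = pd.DataFrame(
        {
            "criterion": [
                "individual_call_rate",
                "snp_call_rate",
                "snp_hwe",
                "snp_maf",
                "snps_removed_total",
            ],
            "removed": [
                n_ind_removed,
                int(fail_call.sum()),
                int(fail_hwe.sum()),
                int(fail_maf.sum()),
                int((~keep_snp).sum()),
            ],
        }
    )
    out = inter.subset(snp_idx=np.flatnonzero(keep_snp))
    if out.n_snps == 0:
        raise ValueError("no SNPs left after QC filtering")
    return out, report


# ---------------------------------------------------------------------------
# minor-allele normalisation
# ---------------------------------------------------------------------------

def _normalise_minor_allele(matrix: np.ndarray, snps: pd.DataFrame):
    """Flip coding so the counted allele is the minor one per SNP.

    Frequency ties at exactly 0.5 are broken by lexicographic allele order
    (the alphabetically smaller allele is called minor).
    """
    counts = _per_snp_counts(matrix)
    non_missing = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq1 = (counts[:, 1] + 2 * counts[:, 2]) / (2 * non_missing)
    a1 = snps["allele1"].to_numpy()
    a2 = snps["allele2"].to_numpy()
    flip = np.where(
        np.isnan(freq1) | (freq1 == 0.5),
        a1 > a2,
        freq1 > 0.5,
    )
    matrix = matrix.copy()
    cols = np.flatnonzero(flip)
    sub = matrix[:, cols]
    obs = sub != MISSING
    sub[obs] = 2 - sub[obs]
    matrix[:, cols] = sub
    snps = snps.copy()
    snps.loc[flip, ["allele1", "allele2"]] = snps.loc[flip, ["allele2", "allele1"]].to_numpy()
    return matrix, snps


def _sort_by_map(matrix: np.ndarray, snps: pd.DataFrame, sample_ids):
    def chrom_key(c):
        s = str(c)
        return (0, int(s)) if s.isdigit() else (1, s)

    order = sorted(
        range(len(snps)),
        key=lambda i: (chrom_key(snps["chromosome"].iloc[i]), int(snps["position"].iloc[i])),
    )
    return GenotypeDataset(
        sample_ids=np.asarray(sample_ids, dtype=object),
        snps=snps.iloc[order].reset_index(drop=True),
        matrix=matrix[:, order],
    )


# ---------------------------------------------------------------------------
# PLINK 1 binary I/O
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # v1 magic + SNP-major mode

# 2-bit PLINK codes for the count of allele1 copies: 00=2, 01=missing, 10=1, 11=0
_CODE_TO_GENO = np.array([2, MISSING, 1, 0], dtype=np.int8)
_GENO_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

_BYTE_LUT = np.zeros((256, 4), dtype=np.int8)
for _b in range(256):
    for _i in range(4):
        _BYTE_LUT[_b, _i] = _CODE_TO_GENO[(_b >> (2 * _i)) & 0b11]


def _write_plink(dataset: GenotypeDataset, prefix: Path) -> None:
    n = dataset.n_samples
    fam = pd.DataFrame(
        {
            "fid": dataset.sample_ids,
            "iid": dataset.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chromosome": dataset.snps["chromosome"],
            "snp_id": dataset.snps["snp_id"],
            "cm": 0,
            "position": dataset.snps["position"],
            "allele1": dataset.snps["allele1"],
            "allele2": dataset.snps["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        codes = np.array([_GENO_TO_CODE[g] for g in (0, 1, 2)], dtype=np.uint8)
        for j in range(dataset.n_snps):
            col = dataset.matrix[:, j]
            two_bit = np.full(n, _GENO_TO_CODE[MISSING], dtype=np.uint8)
            obs = col != MISSING
            two_bit[obs] = codes[col[obs]]
            padded = np.zeros(n_bytes * 4, dtype=np.uint8)
            padded[:n] = two_bit
            packed = (
                padded[0::4]
                | (padded[1::4] << 2)
                | (padded[2::4] << 4)
                | (padded[3::4] << 6)
            )
            fh.write(packed.tobytes())


def _read_plink(prefix: Path) -> GenotypeDataset:
    fam_path, bim_path, bed_path = (prefix.with_suffix(s) for s in (".fam", ".bim", ".bed"))
    for p in (fam_path, bim_path, bed_path):
        if not p.exists():
            raise GenotypeFormatError(f"missing PLINK file: {p}")
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise GenotypeFormatError("FAM file must have at least 2 columns")
    sample_ids = fam.iloc[:, 1].to_numpy(dtype=object)
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] != 6:
        raise GenotypeFormatError("BIM file must have 6 columns")
    snps = pd.DataFrame(
        {
            "snp_id": bim.iloc[:, 1],
            "chromosome": bim.iloc[:, 0],
            "position": bim.iloc[:, 3].astype(int),
            "allele1": bim.iloc[:, 4],
            "allele2": bim.iloc[:, 5],
        }
    )
    if (snps["position"] < 1).any():
        raise GenotypeFormatError("BIM positions must be >= 1 (1-based)")

    n, m = len(sample_ids), len(snps)
    n_bytes = (n + 3) // 4
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeFormatError("not a SNP-major PLINK v1 BED file")
    body = raw[3:]
    if body.size != n_bytes * m:
        raise GenotypeFormatError(
            f"BED payload of {body.size} bytes inconsistent with "
            f"{n} samples x {m} SNPs from FAM/BIM"
        )
    decoded = _BYTE_LUT[body.reshape(m, n_bytes)].reshape(m, n_bytes * 4)[:, :n]
    matrix, snps = _normalise_minor_allele(decoded.T.copy(), snps)
    return _sort_by_map(matrix, snps, sample_ids)


# ---------------------------------------------------------------------------
# text dialect I/O
# ---------------------------------------------------------------------------

def _write_text(dataset: GenotypeDataset, prefix: Path) -> None:
    geno = pd.DataFrame(
        np.where(dataset.matrix == MISSING, None, dataset.matrix),
        columns=dataset.snps["snp_id"],
    )
    geno.insert(0, "id", dataset.sample_ids)
    geno.to_csv(Path(f"{prefix}.geno.tsv"), sep="\t", index=False, na_rep="NA")
    dataset.snps[_SNP_COLUMNS].to_csv(Path(f"{prefix}.map.tsv"), sep="\t", index=False)


def _read_text(prefix: Path) -> GenotypeDataset:
    geno_path, map_path = Path(f"{prefix}.geno.tsv"), Path(f"{prefix}.map.tsv")
    for p in (geno_path, map_path):
        if not p.exists():
            raise GenotypeFormatError(f"missing text genotype file: {p}")
    geno = pd.read_csv(geno_path, sep="\t", dtype={"id": str}, na_values=["NA"])
    snps = pd.read_csv(map_path, sep="\t", dtype={"chromosome": str, "allele1": str, "allele2": str})
    if list(snps.columns) != _SNP_COLUMNS:
        raise GenotypeFormatError(f"map file must have columns {_SNP_COLUMNS}")
    if list(geno.columns[1:]) != list(snps["snp_id"]):
        raise GenotypeFormatError("genotype columns do not match map snp_ids")
    values = geno.iloc[:, 1:].to_numpy(dtype=float)
    bad = ~(np.isnan(values) | np.isin(values, [0.0, 1.0, 2.0]))
    if bad.any():
        raise GenotypeFormatError("text genotypes must be 0/1/2/NA")
    matrix = np.where(np.isnan(values), MISSING, values).astype(np.int8)
    matrix, snps = _normalise_minor_allele(matrix, snps)
    return _sort_by_map(matrix, snps, geno["id"].to_numpy(dtype=object))


# ---------------------------------------------------------------------------
# public I/O entry points
# ---------------------------------------------------------------------------

def save_genotypes(dataset: GenotypeDataset, prefix, format: str = "plink") -> None:
    """Write a dataset as PLINK bed/bim/fam or the text dialect."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "plink":
        _write_plink(dataset, prefix)
    elif format == "text":
        _write_text(dataset, prefix)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")


def load_genotypes(prefix, format: str = "plink") -> GenotypeDataset:
    """Load genotypes, normalising minor-allele coding and map order."""
    prefix = Path(prefix)
    if format == "plink":
        return _read_plink(prefix)
    if format == "text":
        return _read_text(prefix)
    raise ValueError(f"unknown genotype format: {format!r}")
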