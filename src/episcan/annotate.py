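"""SNP-to-gene annotation by physical distance.

Each SNP is assigned at most one gene: the nearest gene on the same
chromosome whose transcription boundaries lie within a flanking window
(default 20 kb, inclusive).  The distance is the minimum of the distances
to the transcription start and end, and zero when the SNP lies inside the
gene.  Ties are broken by the lexicographically smaller symbol and flagged
ambiguous.  Linkage disequilibrium is deliberately not considered.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

GENE_COLUMNS = ["chromosome", "tx_start", "tx_end", "symbol"]


class GeneModelFormatError(ValueError):
    pass


def load_gene_models(path) -> pd.DataFrame:
    """Read a BED-like TSV of gene models (chromosome, start, end, symbol).

    Coordinates are 1-based inclusive.  Rows with ``tx_start > tx_end`` or
    a wrong column count raise with the offending line number.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:4] == GENE_COLUMNS:
                continue
            if len(parts) < 4:
                raise GeneModelFormatError(f"{path}:{lineno}: expected >= 4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise GeneModelFormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start > end:
                raise GeneModelFormatError(f"{path}:{lineno}: tx_start > tx_end")
            rows.append({"chromosome": parts[0], "tx_start": start, "tx_end": end, "symbol": parts[3]})
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return genes.sort_values(["chromosome", "tx_start", "tx_end", "symbol"], ignore_index=True)


def save_gene_models(genes: pd.DataFrame, path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def annotate_snps(snps: pd.DataFrame, genes: pd.DataFrame, window: int = 20_000) -> pd.DataFrame:
    """Annotate each SNP with its nearest gene within ``window`` bp.

    ``snps`` needs columns ``snp_id``, ``chromosome``, ``position``;
    ``genes`` the :data:`GENE_COLUMNS`.  Returns a DataFrame with one row
    per SNP: ``gene`` (None when no gene is within the window, inclusive at
    exactly ``window`` bp), ``distance`` and an ``ambiguous`` flag for
    equidistant candidates.  The result is independent of gene row order.
    """
    out_gene: list = []
    out_dist: list = []
    out_amb: list = []
    by_chrom = {c: g for c, g in genes.groupby("chromosome", sort=False)}
    for _, snp in snps.iterrows():
        grp = by_chrom.get(str(snp["chromosome"]))
        if grp is None or len(grp) == 0:
            out_gene.append(None)
            out_dist.append(np.nan)
            out_amb.append(False)
            continue
        pos = int(snp["position"])
        start = grp["tx_start"].to_numpy()
        end = grp["tx_end"].to_numpy()
        inside = (start <= pos) & (pos <= end)
        dist = np.where(inside, 0, np.minimum(np.abs(pos - start), np.abs(pos - end)))
        ok = dist <= window
        if not ok.any():
            out_gene.append(None)
            out_dist.append(np.nan)
            out_amb.append(False)
            continue
        best = dist[ok].min()
        cands = sorted(grp["symbol"].to_numpy()[ok & (dist == best)])
        out_gene.append(cands[0])
        out_dist.append(int(best))
        out_amb.append(len(cands) > 1)
    return pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy(),
            "gene": out_gene,
            "distance": out_dist,
            "ambiguous": out_amb,
        }
    )
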