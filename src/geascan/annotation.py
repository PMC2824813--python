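"""Gene models, strand-aware SNP-to-gene assignment, and the genic-location test.

A SNP belongs to a gene if it lies in the transcribed span or in a strand-aware
upstream window (500 bp for gene-level tallies; 25 kb for network-style mapping).
BED intervals are 0-based half-open; SNP positions are 1-based and converted
internally.  The genic-location test asks whether significant SNPs sit inside genic
regions more often than MAF-matched control SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "GeneModel",
    "read_gene_models",
    "write_gene_models",
    "collapse_gene_models",
    "assign_snps_to_genes",
    "genic_enrichment_test",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene's transcribed span, stored 0-based half-open, with strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.start < 0:
            raise ValidationError(f"gene {self.gene_id!r}: negative start")


def read_gene_models(path: str | Path, collapse: bool = True) -> list[GeneModel]:
    """Read BED6 gene models (chrom, start, end, name, score, strand; score ignored).

    Rows sharing a gene symbol (transcripts) are collapsed to their union span when
    ``collapse`` is true -- the downstream tallies count genes, not transcripts.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype=str,
            comment="#",
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty BED file") from exc
    if df["strand"].isna().any():
        raise FormatError(f"{path}: BED6 required; strand column missing on some rows")
    models = []
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer coordinates for {row.name!r}") from exc
        models.append(GeneModel(str(row.name), str(row.chrom), start, end, str(row.strand)))
    return collapse_gene_models(models) if collapse else models


def collapse_gene_models(models: Sequence[GeneModel]) -> list[GeneModel]:
    """Collapse rows with the same gene_id to the union span (same chrom/strand required)."""
    by_id: dict[str, list[GeneModel]] = {}
    order: list[str] = []
    for m in models:
        if m.gene_id not in by_id:
            order.append(m.gene_id)
        by_id.setdefault(m.gene_id, []).append(m)
    out = []
    for gid in order:
        rows = by_id[gid]
        chroms = {r.chrom for r in rows}
        strands = {r.strand for r in rows}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"gene {gid!r}: transcripts disagree on chromosome or strand"
            )
        out.append(
            GeneModel(
                gid,
                rows[0].chrom,
                min(r.start for r in rows),
                max(r.end for r in rows),
                rows[0].strand,
            )
        )
    return out


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [m.chrom for m in models],
            "start": [m.start for m in models],
            "end": [m.end for m in models],
            "name": [m.gene_id for m in models],
            "score": [0] * len(models),
            "strand": [m.strand for m in models],
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def assign_snps_to_genes(
    snp_meta: pd.DataFrame,
    genes: Sequence[GeneModel],
    upstream_bp: int = 500,
) -> pd.DataFrame:
    """Map SNPs to genes: transcribed span plus a strand-aware upstream window.

    A SNP at 1-based position P (0-based coordinate P-1) maps to a gene iff P-1 lies in
    [start - upstream_bp, end) on the + strand or [start, end + upstream_bp) on the -
    strand (extended starts clamped at 0).  A SNP may map to several overlapping genes.

    Returns a DataFrame with columns ``snp_id``, ``gene_id``, ``rule_used``.
    Chromosomes present among SNPs but absent from the gene set are reported via a
    warning, never silently dropped.
    """
    if upstream_bp < 0:
        raise ConfigurationError(f"upstream_bp must be >= 0, got {upstream_bp}")
    rule = f"tx_plus_{upstream_bp}bp"
    gene_chroms = {g.chrom for g in genes}
    snp_chroms = set(snp_meta["chrom"].astype(str))
    orphan = sorted(snp_chroms - gene_chroms)
    if orphan and genes:
        warnings.warn(
            f"SNP chromosome(s) {orphan} have no gene models; their SNPs map to no gene",
            stacklevel=2,
        )
    pairs_snp: list[np.ndarray] = []
    pairs_gene: list[str] = []
    snp_ids = snp_meta["snp_id"].to_numpy()
    pos0 = snp_meta["pos"].to_numpy(dtype=np.int64) - 1  # 1-based -> 0-based
    chrom_arr = snp_meta["chrom"].astype(str).to_numpy()
    for g in genes:
        if g.strand == "+":
            lo, hi = max(g.start - upstream_bp, 0), g.end
        else:
            lo, hi = g.start, g.end + upstream_bp
        hit = (chrom_arr == g.chrom) & (pos0 >= lo) & (pos0 < hi)
        n = int(hit.sum())
        if n:
            pairs_snp.append(snp_ids[hit])
            pairs_gene.extend([g.gene_id] * n)
    if pairs_snp:
        df = pd.DataFrame(
            {"snp_id": np.concatenate(pairs_snp), "gene_id": pairs_gene}
        )
    else:
        df = pd.DataFrame({"snp_id": pd.Series(dtype=object), "gene_id": pd.Series(dtype=object)})
    df["rule_used"] = rule
    return df.reset_index(drop=True)


def genic_enrichment_test(
    results: pd.DataFrame,
    snp_gene_map: pd.DataFrame,
    maf_window: float = 0.01,
    k: int = 10,
    seed: int = 0,
) -> dict:
    """Are significant SNPs genic more often than MAF-matched controls?

    For each significant SNP, ``k`` control SNPs are sampled without replacement from
    the non-significant SNPs whose MAF lies within ``maf_window`` of the significant
    SNP's.  The 2x2 table (genic / non-genic x significant / control) is tested by
    Pearson chi-square with 1 df and no continuity correction.

    Returns a dict with the table, chi2, p, and the sampling description.
    """
    sig = results[results["final_sig"]]
    if len(sig) == 0:
        raise ValidationError("no significant SNPs; genic test undefined")
    nonsig = results[~results["final_sig"]]
    genic_ids = set(snp_gene_map["snp_id"])
    rng = np.random.default_rng(seed)
    nonsig_maf = nonsig["maf"].to_numpy()
    nonsig_ids = nonsig["snp_id"].to_numpy()
    control_ids: list[str] = []
    for _, row in sig.iterrows():
        cand = np.flatnonzero(np.abs(nonsig_maf - row["maf"]) <= maf_window)
        if cand.size < k:
            raise ValidationError(
                f"SNP {row['snp_id']!r}: only {cand.size} MAF-matched controls available, "
                f"need k={k}; try a smaller k or a wider maf_window"
            )
        control_ids.extend(nonsig_ids[rng.choice(cand, size=k, replace=False)])
    sig_genic = int(sig["snp_id"].isin(genic_ids).sum())
    sig_non = len(sig) - sig_genic
    ctl_genic = sum(1 for s in control_ids if s in genic_ids)
    ctl_non = len(control_ids) - ctl_genic
    table = np.array([[sig_genic, sig_non], [ctl_genic, ctl_non]], dtype=float)
    if table.sum(axis=0).min() == 0:
        # one margin empty (e.g. no genic SNP anywhere): no information
        chi2_stat, p = 0.0, 1.0
    else:
        chi2_stat, p, _, _ = chi2_contingency(table, correction=False)
    return {
        "table": table.astype(int),
        "chi2": float(chi2_stat),
        "p_value": float(p),
        "n_significant": int(len(sig)),
        "n_controls": len(control_ids),
        "k": k,
        "maf_window": maf_window,
        "seed": seed,
        "control_description": f"{k} MAF-matched (+/-{maf_window}) non-significant SNPs "
        "per significant SNP, sampled without replacement",
    }
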