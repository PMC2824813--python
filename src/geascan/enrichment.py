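"""Gene-list enrichment of significant SNPs and the network interaction statistics.

The central procedure is gene resampling: for a list of m genes, the number of
significant SNPs mapping to the list is compared with the count distribution obtained
by drawing m genes at random (without replacement) from the universe of all genes
covered by at least one SNP.  The add-one empirical p (1 + b) / (1 + R) is the default;
the plug-in b / R is available because published values are typically that form.

Also provided: the expected number of "interacting" genes under a background rate, a
1-df goodness-of-fit chi-square on the observed count, and a generic binomial
over-representation test over gene categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, chi2

from .errors import ConfigurationError, ValidationError

__all__ = [
    "EnrichmentResult",
    "InteractionEnrichment",
    "count_list_snps",
    "resampling_empirical_p",
    "expected_interactions",
    "interaction_chisq",
    "binomial_overrepresentation",
    "category_counts",
]


@dataclass
class EnrichmentResult:
    """Result of the gene-resampling enrichment for one gene list."""

    list_name: str
    m_genes: int
    observed_snps: int
    n_resamples: int
    empirical_p: float  # add-one form (1 + b) / (1 + R)
    empirical_p_plugin: float  # plug-in form b / R
    null_mean: float
    null_sd: float
    seed: int
    null_counts: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class InteractionEnrichment:
    """Observed vs expected count of interacting genes in a gene set."""

    n_genes: int
    observed_interacting: int
    background_interacting: int
    background_total: int
    expected: float
    chi2: float
    p_value: float


def _gene_sig_index(
    snp_gene_map: pd.DataFrame, sig_snp_ids: Iterable[str]
) -> dict[str, frozenset[str]]:
    """gene_id -> set of significant SNP ids mapping to it."""
    sig = set(sig_snp_ids)
    sub = snp_gene_map[snp_gene_map["snp_id"].isin(sig)]
    return {
        g: frozenset(grp["snp_id"]) for g, grp in sub.groupby("gene_id", sort=False)
    }


def count_list_snps(
    gene_list: Sequence[str],
    snp_gene_map: pd.DataFrame,
    sig_snp_ids: Iterable[str],
) -> int:
    """Number of distinct significant SNPs mapping to at least one listed gene."""
    if len(gene_list) == 0:
        raise ValidationError("empty gene list")
    listed = set(gene_list)
    sig = set(sig_snp_ids)
    sub = snp_gene_map[
        snp_gene_map["gene_id"].isin(listed) & snp_gene_map["snp_id"].isin(sig)
    ]
    return int(sub["snp_id"].nunique())


def _null_counts_additive(
    per_gene_counts: np.ndarray, m: int, n_resamples: int, rng: np.random.Generator
) -> np.ndarray:
    """Null counts when significant SNPs are gene-exclusive, so counts add."""
    u = per_gene_counts.size
    out = np.empty(n_resamples, dtype=np.int64)
    chunk = max(1, min(n_resamples, int(4e7 // max(u, 1))))
    base = np.arange(u)
    done = 0
    while done < n_resamples:
        r = min(chunk, n_resamples - done)
        idx = np.broadcast_to(base, (r, u)).copy()
        rng.permuted(idx, axis=1, out=idx)
        out[done : done + r] = per_gene_counts[idx[:, :m]].sum(axis=1)
        done += r
    return out


def resampling_empirical_p(
    gene_list: Sequence[str],
    universe: Sequence[str],
    snp_gene_map: pd.DataFrame,
    sig_snp_ids: Iterable[str],
    n_resamples: int = 10_000,
    seed: int = 0,
    list_name: str = "gene_list",
    snp_count_matched: bool = False,
) -> EnrichmentResult:
    """Empirical probability of observing at least as many significant SNPs in a list.

    ``universe`` is the set of genes covered by at least one SNP; each of
    ``n_resamples`` draws samples m = |gene_list intersect universe| genes uniformly
    without replacement from it and counts distinct significant SNPs as
    :func:`count_list_snps` does.  With ``snp_count_matched`` the sampler draws, for
    each listed gene, a random universe gene with a similar total SNP coverage --
    uniform sampling is anti-conservative for SNP-dense lists, but uniform remains the
    default (the convention for this statistic).
    """
    if n_resamples < 1:
        raise ConfigurationError("n_resamples must be >= 1")
    universe = list(dict.fromkeys(universe))
    uni_set = set(universe)
    stray = [g for g in gene_list if g not in uni_set]
    if stray:
        warnings.warn(
            f"{len(stray)} listed gene(s) absent from the SNP-covered universe "
            f"(e.g. {stray[0]!r}); they are ignored",
            stacklevel=2,
        )
    listed = [g for g in dict.fromkeys(gene_list) if g in uni_set]
    m = len(listed)
    if m == 0:
        raise ValidationError("no listed gene overlaps the universe (m = 0)")
    observed = count_list_snps(listed, snp_gene_map, sig_snp_ids)

    gene_sig = _gene_sig_index(snp_gene_map, sig_snp_ids)
    per_gene = np.array([len(gene_sig.get(g, ())) for g in universe], dtype=np.int64)
    # counts add across genes iff no significant SNP maps to two universe genes
    all_snps: list[str] = []
    for g in universe:
        all_snps.extend(gene_sig.get(g, ()))
    additive = len(all_snps) == len(set(all_snps))

    rng = np.random.default_rng(seed)
    if snp_count_matched:
        null = _null_counts_snp_matched(
            listed, universe, snp_gene_map, gene_sig, n_resamples, rng
        )
    elif additive:
        null = _null_counts_additive(per_gene, m, n_resamples, rng)
    else:
        gene_sets = [gene_sig.get(g, frozenset()) for g in universe]
        null = np.empty(n_resamples, dtype=np.int64)
        for r in range(n_resamples):
            sel = rng.choice(len(universe), size=m, replace=False)
            null[r] = len(frozenset().union(*(gene_sets[i] for i in sel)))
    b = int((null >= observed).sum())
    return EnrichmentResult(
        list_name=list_name,
        m_genes=m,
        observed_snps=observed,
        n_resamples=n_resamples,
        empirical_p=(1 + b) / (1 + n_resamples),
        empirical_p_plugin=b / n_resamples,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_resamples > 1 else 0.0,
        seed=seed,
        null_counts=null,
    )


def _null_counts_snp_matched(
    listed: Sequence[str],
    universe: Sequence[str],
    snp_gene_map: pd.DataFrame,
    gene_sig: Mapping[str, frozenset],
    n_resamples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Resample matching each listed gene with a universe gene of similar SNP coverage."""
    cover = snp_gene_map.groupby("gene_id")["snp_id"].nunique()
    n_cov = np.array([int(cover.get(g, 0)) for g in universe])
    order = np.argsort(n_cov, kind="stable")
    sorted_cov = n_cov[order]
    per_gene = np.array([len(gene_sig.get(g, ())) for g in universe], dtype=np.int64)
    null = np.empty(n_resamples, dtype=np.int64)
    list_cov = np.array([int(cover.get(g, 0)) for g in listed])
    # candidate pool per listed gene: the 50 nearest-coverage universe genes
    pools = []
    for c in list_cov:
        centre = int(np.searchsorted(sorted_cov, c))
        lo = max(0, centre - 25)
        hi = min(len(universe), lo + 50)
        lo = max(0, hi - 50)
        pools.append(order[lo:hi])
    for r in range(n_resamples):
        taken: set[int] = set()
        total = 0
        for pool in pools:
            choice = int(rng.choice(pool))
            while choice in taken:
                choice = int(rng.choice(pool))
            taken.add(choice)
            total += per_gene[choice]
        null[r] = total
    return null


def expected_interactions(
    n_genes: int, background_interacting: int, background_total: int
) -> float:
    """Expected count of interacting genes in a set of n_genes under the background rate."""
    if background_total <= 0:
        raise ValidationError("background_total must be positive")
    if not 0 <= background_interacting <= background_total:
        raise ValidationError(
            "background_interacting must lie in [0, background_total]"
        )
    return n_genes * background_interacting / background_total


def interaction_chisq(
    n_genes: int,
    observed_interacting: int,
    background_interacting: int,
    background_total: int,
) -> InteractionEnrichment:
    """1-df goodness-of-fit chi-square of the observed interacting count vs expectation.

    The two cells (interacting, non-interacting) are compared with
    (expected, n_genes - expected); p is the upper tail of chi-square with 1 df.
    """
    if observed_interacting > n_genes:
        raise ValidationError("observed_interacting cannot exceed n_genes")
    expected = expected_interactions(n_genes, background_interacting, background_total)
    if expected <= 0:
        raise ValidationError("expected count is zero; test undefined")
    if expected >= n_genes:
        raise ValidationError(
            f"expected {expected:.3g} >= n_genes {n_genes}: degenerate expectation"
        )
    stat = (observed_interacting - expected) ** 2 / expected
    stat += ((n_genes - observed_interacting) - (n_genes - expected)) ** 2 / (
        n_genes - expected
    )
    p = float(chi2.sf(stat, df=1))
    return InteractionEnrichment(
        n_genes=n_genes,
        observed_interacting=observed_interacting,
        background_interacting=background_interacting,
        background_total=background_total,
        expected=expected,
        chi2=float(stat),
        p_value=p,
    )


def category_counts(genes: Iterable[str], gene_category: pd.DataFrame) -> dict[str, int]:
    """Per-category gene counts from a two-column (gene, category) table."""
    genes = set(genes)
    sub = gene_category[gene_category["gene"].isin(genes)]
    return sub.groupby("category")["gene"].nunique().to_dict()


def binomial_overrepresentation(
    category_counts_in_list: Mapping[str, int],
    list_size: int,
    category_counts_in_reference: Mapping[str, int],
    reference_size: int,
) -> pd.DataFrame:
    """Upper-tail exact binomial over-representation test per category.

    For each category, the list count k is tested against Binomial(list_size, q) with
    q the category's reference fraction; the Bonferroni column multiplies by the number
    of categories actually tested.  Categories with zero members in both the list and
    the reference are skipped with a note; a category present in the list but absent
    from the reference is an error.
    """
    if list_size > reference_size:
        raise ValidationError("list_size cannot exceed reference_size")
    rows = []
    tested = []
    for cat in sorted(set(category_counts_in_list) | set(category_counts_in_reference)):
        k = int(category_counts_in_list.get(cat, 0))
        ref = int(category_counts_in_reference.get(cat, 0))
        if ref == 0:
            if k == 0:
                rows.append((cat, k, ref, np.nan, np.nan, "skipped: empty in reference and list"))
                continue
            raise ValidationError(f"category {cat!r} absent from the reference")
        q = ref / reference_size
        p = float(binom.sf(k - 1, list_size, q)) if k > 0 else 1.0
        rows.append((cat, k, ref, p, np.nan, ""))
        tested.append(len(rows) - 1)
    n_tested = len(tested)
    df = pd.DataFrame(
        rows,
        columns=["category", "list_count", "reference_count", "p_value", "p_bonferroni", "note"],
    )
    if n_tested:
        df.loc[df["note"] == "", "p_bonferroni"] = np.minimum(
            1.0, df.loc[df["note"] == "", "p_value"] * n_tested
        )
    return df
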