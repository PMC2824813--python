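"""Synthetic panels with the statistical structure the scan assumes.

Allele frequencies follow a two-level Balding-Nichols hierarchy: an ancestral
frequency p0 per SNP, a continent frequency drawn from Beta around p0 with drift
intensity F_continent, and a population frequency drawn around its continent value
with F_population.  This reproduces the shared-drift correlation between populations
that inflates raw frequency-environment correlations -- the confounding the
MAF-matched rank null exists to absorb.  The environment is one integer-like value
per country (populations of a country tie exactly, and values repeat across
countries), and an optional fraction of SNPs is spiked: their population frequencies
are shifted linearly in the standardized country environment and clamped.

Defaults mirror the worldwide human panel the method was designed around: 52
populations nested in 21 countries and 7 continental regions, F_continent = 0.09 and
F_population = 0.02 (about 9% of variance among regions and 2% among populations
within regions, total differentiation ~ 0.11), environments in the 39-55 range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, assign_snps_to_genes
from .errors import ConfigurationError, ValidationError
from .io import EnvVector, FrequencyMatrix, PopulationRecord

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SyntheticAnnotation",
    "RecoveryMetrics",
    "simulate_panel",
    "simulate_annotation",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic panel generator.

    fst_continent / fst_population are Balding-Nichols drift intensities in (0, 1);
    frac_selected is the fraction of SNPs whose frequencies track the environment with
    effect size ``beta`` (frequency shift per standard deviation of the country
    environment, clamped to [0.01, 0.99]).
    """

    n_snps: int = 10_000
    n_populations: int = 52
    n_countries: int = 21
    n_continents: int = 7
    fst_continent: float = 0.09
    fst_population: float = 0.02
    frac_selected: float = 0.0
    beta: float = 0.0
    maf_floor: float = 0.05
    env_low: int = 39
    env_high: int = 55
    snp_spacing: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if not (self.n_continents <= self.n_countries <= self.n_populations):
            raise ConfigurationError(
                "need n_continents <= n_countries <= n_populations "
                f"(got {self.n_continents}/{self.n_countries}/{self.n_populations})"
            )
        for name in ("fst_continent", "fst_population"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {f}")
        if not 0.0 <= self.frac_selected < 1.0:
            raise ConfigurationError("frac_selected must be in [0, 1)")
        if not 0.0 < self.maf_floor < 0.5:
            raise ConfigurationError("maf_floor must be in (0, 0.5)")
        if self.env_low >= self.env_high:
            raise ConfigurationError("env_low must be < env_high")

    def country_of_population(self) -> np.ndarray:
        """Population index -> country index (contiguous blocks, sizes as equal as possible)."""
        out = np.empty(self.n_populations, dtype=np.int64)
        for c, block in enumerate(np.array_split(np.arange(self.n_populations), self.n_countries)):
            out[block] = c
        return out

    def continent_of_country(self) -> np.ndarray:
        out = np.empty(self.n_countries, dtype=np.int64)
        for c, block in enumerate(np.array_split(np.arange(self.n_countries), self.n_continents)):
            out[block] = c
        return out


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated panel: which SNPs were spiked and how."""

    selected_snp_ids: tuple[str, ...]
    betas: dict[str, float]  # signed effect per selected SNP
    env: EnvVector
    seed: int
    config: SimConfig

    def neutral_ids(self, all_ids: Sequence[str]) -> list[str]:
        sel = set(self.selected_snp_ids)
        return [s for s in all_ids if s not in sel]


def _beta_draw(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding-Nichols: Beta(p (1-F)/F, (1-p)(1-F)/F) elementwise."""
    c = (1.0 - f) / f
    return rng.beta(p * c, (1.0 - p) * c)


def simulate_panel(
    cfg: SimConfig,
) -> tuple[list[PopulationRecord], FrequencyMatrix, EnvVector, SyntheticTruth]:
    """Generate (panel, frequency matrix, environment vector, truth) from a config.

    Fully determined by ``cfg`` (including its seed): identical configs give
    bit-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    country_of_pop = cfg.country_of_population()
    continent_of_country = cfg.continent_of_country()
    continent_of_pop = continent_of_country[country_of_pop]

    # environment: one integer value per country, Table-1-like range, ties by design
    env_country = rng.integers(cfg.env_low, cfg.env_high + 1, cfg.n_countries).astype(float)
    while np.unique(env_country).size < 2:  # astronomically rare; keep env usable
        env_country = rng.integers(cfg.env_low, cfg.env_high + 1, cfg.n_countries).astype(float)
    env_pop = env_country[country_of_pop]

    p0 = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, cfg.n_snps)
    eps = 1e-9
    cont = np.empty((cfg.n_snps, cfg.n_continents))
    for c in range(cfg.n_continents):
        cont[:, c] = _beta_draw(rng, p0, cfg.fst_continent)
    cont = np.clip(cont, eps, 1.0 - eps)
    freqs = np.empty((cfg.n_snps, cfg.n_populations))
    for j in range(cfg.n_populations):
        freqs[:, j] = _beta_draw(rng, cont[:, continent_of_pop[j]], cfg.fst_population)

    # spiked environment-associated SNPs (a zero effect is no selection at all)
    n_sel = round(cfg.frac_selected * cfg.n_snps) if cfg.beta != 0.0 else 0
    sel_idx = np.sort(rng.choice(cfg.n_snps, size=n_sel, replace=False)) if n_sel else np.array([], dtype=np.int64)
    sel_signs = rng.choice([-1.0, 1.0], size=n_sel)
    if n_sel:
        z = (env_country - env_country.mean()) / env_country.std()
        shift = np.outer(sel_signs * cfg.beta, z[country_of_pop])
        freqs[sel_idx] = np.clip(freqs[sel_idx] + shift, 0.01, 0.99)

    n_sampled = rng.integers(5, 47, cfg.n_populations)

    snp_ids = np.array([f"snp{i:06d}" for i in range(cfg.n_snps)], dtype=object)
    meta = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "chr1",
            "pos": 1 + cfg.snp_spacing * np.arange(cfg.n_snps, dtype=np.int64),
            "coded_allele": "A",
        }
    )
    populations = tuple(f"pop{j:02d}" for j in range(cfg.n_populations))
    panel = [
        PopulationRecord(populations[j], f"country{country_of_pop[j]:02d}", int(n_sampled[j]))
        for j in range(cfg.n_populations)
    ]
    fm = FrequencyMatrix(meta, freqs, populations)
    env = EnvVector(env_pop, "virus_diversity", populations)
    truth = SyntheticTruth(
        selected_snp_ids=tuple(snp_ids[sel_idx]),
        betas={snp_ids[i]: float(s * cfg.beta) for i, s in zip(sel_idx, sel_signs)},
        env=env,
        seed=cfg.seed,
        config=cfg,
    )
    return panel, fm, env, truth


@dataclass(frozen=True)
class SyntheticAnnotation:
    """Gene models plus constructed gene lists and interaction flags."""

    genes: tuple[GeneModel, ...]
    enriched_list: tuple[str, ...]  # preferentially holds genes with spiked SNPs
    control_list: tuple[str, ...]  # same size, drawn at random
    interacting: dict[str, bool]  # per-gene human-virus interaction flag
    seed: int


def simulate_annotation(
    fm: FrequencyMatrix,
    truth: SyntheticTruth,
    n_genes: int = 200,
    genic_fraction: float = 0.4,
    list_size: int | None = None,
    interacting_fraction: float = 1916 / 15280,
    seed: int = 0,
) -> SyntheticAnnotation:
    """Place non-overlapping genes over the synthetic SNPs and build test gene lists.

    Roughly ``genic_fraction`` of the SNPs end up inside a gene span; genes with zero
    assigned SNPs are placed in inter-SNP gaps so the fraction-zero case yields an
    empty map at ``upstream_bp = 0``.  The enriched list contains every gene holding a
    spiked SNP plus random fillers; the control list is a uniform draw of the same
    size.  Interaction flags are independent Bernoulli draws at the background rate of
    interacting genes among SNP-covered genes.
    """
    if not 0.0 <= genic_fraction <= 1.0:
        raise ConfigurationError("genic_fraction must be in [0, 1]")
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    spacing = int(fm.snp_meta["pos"].diff().dropna().min()) if fm.n_snps > 1 else 500
    pos0 = fm.snp_meta["pos"].to_numpy(dtype=np.int64) - 1
    margin = max(1, spacing // 5)
    genes: list[GeneModel] = []
    blocks = np.array_split(np.arange(fm.n_snps), n_genes)
    for g, block in enumerate(blocks):
        n_genic = int(round(genic_fraction * block.size))
        strand = str(rng.choice(["+", "-"]))
        gid = f"gene{g:04d}"
        if n_genic >= 1:
            first, last = int(block[0]), int(block[n_genic - 1])
            start = max(0, int(pos0[first]) - margin)
            end = int(pos0[last]) + margin + 1
        else:
            start = int(pos0[int(block[0])]) + margin
            end = start + margin
        genes.append(GeneModel(gid, "chr1", start, end, strand))

    gmap = assign_snps_to_genes(fm.snp_meta, genes, upstream_bp=0)
    gene_ids = [g.gene_id for g in genes]
    sel = set(truth.selected_snp_ids)
    holding = list(
        dict.fromkeys(gmap.loc[gmap["snp_id"].isin(sel), "gene_id"])
    )
    if list_size is None:
        list_size = max(10, 2 * len(holding))
    list_size = min(list_size, n_genes)
    fillers = [g for g in gene_ids if g not in set(holding)]
    n_fill = max(0, list_size - len(holding))
    filled = list(rng.choice(fillers, size=min(n_fill, len(fillers)), replace=False))
    enriched = tuple(holding[:list_size] + filled)
    control = tuple(rng.choice(gene_ids, size=list_size, replace=False))
    interacting = {g: bool(rng.random() < interacting_fraction) for g in gene_ids}
    return SyntheticAnnotation(
        genes=tuple(genes),
        enriched_list=enriched,
        control_list=control,
        interacting=interacting,
        seed=seed,
    )


@dataclass(frozen=True)
class RecoveryMetrics:
    """Truth-based evaluation of a scan on a simulated panel."""

    power: float  # NaN when no SNP was spiked
    fpr: float
    median_rank_selected: float
    median_rank_neutral: float
    n_selected_tested: int
    n_neutral_tested: int


def evaluate_recovery(truth: SyntheticTruth, results: pd.DataFrame) -> RecoveryMetrics:
    """Power / false-positive rate of ``final_sig`` and rank distributions by class."""
    res_ids = set(results["snp_id"])
    sel = set(truth.selected_snp_ids)
    if res_ids.isdisjoint(sel) and sel:
        raise ValidationError("results share no SNP with the truth's spiked set")
    if not res_ids:
        raise ValidationError("empty results table")
    is_sel = results["snp_id"].isin(sel)
    sel_rows = results[is_sel]
    neu_rows = results[~is_sel]
    power = float(sel_rows["final_sig"].mean()) if len(sel_rows) else float("nan")
    fpr = float(neu_rows["final_sig"].mean()) if len(neu_rows) else float("nan")
    return RecoveryMetrics(
        power=power,
        fpr=fpr,
        median_rank_selected=float(sel_rows["rank"].median()) if len(sel_rows) else float("nan"),
        median_rank_neutral=float(neu_rows["rank"].median()) if len(neu_rows) else float("nan"),
        n_selected_tested=int(len(sel_rows)),
        n_neutral_tested=int(len(neu_rows)),
    )
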