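"""Config-driven orchestration: diversity -> scan -> rank -> call -> annotate -> enrich -> confounders.

All stage outputs are plain TSV so every stage is independently diffable; a JSON
manifest records the seed, parameter echo, input checksums, per-stage timings and the
headline counts.  Reruns with the same config and seed reproduce the result tables
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import assign_snps_to_genes, genic_enrichment_test, read_gene_models
from .confounders import confounder_screen
from .enrichment import (
    expected_interactions,
    interaction_chisq,
    resampling_empirical_p,
)
from .errors import ConfigurationError, FormatError
from .io import (
    broadcast_to_populations,
    compute_diversity,
    read_climate_table,
    read_frequency_matrix,
    read_population_table,
    read_presence_matrix,
)
from .scan import ScanConfig, call_significant, maf_matched_rank, scan_snps

__all__ = ["RunConfig", "run", "ALL_STAGES"]

ALL_STAGES = ("diversity", "scan", "annotate", "enrich", "confound")


@dataclass
class RunConfig:
    """Validated run configuration (paths resolved relative to the config file)."""

    panel: Path
    frequency_matrix: Path
    outdir: Path
    seed: int = 0
    presence_matrix: Path | None = None
    diversity_table: Path | None = None
    gene_models: Path | None = None
    climate: Path | None = None
    gene_lists: dict[str, Path] = dc_field(default_factory=dict)
    interaction_flags: Path | None = None
    scan: ScanConfig = dc_field(default_factory=ScanConfig)
    n_resamples: int = 10_000
    upstream_bp: int = 500
    network_upstream_bp: int = 25_000
    genic_test_k: int = 10
    confounder_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def _p(key, section=None, required=False):
            src = raw if section is None else raw.get(section, {}) or {}
            val = src.get(key)
            if val is None:
                if required:
                    raise ConfigurationError(f"config {path}: missing required input {key!r}")
                return None
            p = (base / val).resolve() if not Path(val).is_absolute() else Path(val)
            if not p.exists():
                raise ConfigurationError(f"config {path}: {key} path does not exist: {p}")
            return p

        inputs = raw.get("inputs", {}) or {}
        lists = {}
        for name, lp in (inputs.get("gene_lists") or {}).items():
            p = (base / lp).resolve() if not Path(lp).is_absolute() else Path(lp)
            if not p.exists():
                raise ConfigurationError(f"config {path}: gene list {name!r} path missing: {p}")
            lists[name] = p
        scan_raw = raw.get("scan", {}) or {}
        cfg = cls(
            panel=_p("panel", "inputs", required=True),
            frequency_matrix=_p("frequency_matrix", "inputs", required=True),
            outdir=(base / raw.get("outdir", "out")).resolve(),
            seed=int(raw.get("seed", 0)),
            presence_matrix=_p("presence_matrix", "inputs"),
            diversity_table=_p("diversity", "inputs"),
            gene_models=_p("gene_models", "inputs"),
            climate=_p("climate", "inputs"),
            gene_lists=lists,
            interaction_flags=_p("interaction_flags", "inputs"),
            scan=ScanConfig(
                alpha=float(scan_raw.get("alpha", 0.05)),
                rank_cutoff=float(scan_raw.get("rank_cutoff", 0.99)),
                maf_window=float(scan_raw.get("maf_window", 0.01)),
                min_window=int(scan_raw.get("min_window", 50)),
                min_populations=int(scan_raw.get("min_populations", 10)),
            ),
            n_resamples=int((raw.get("enrichment", {}) or {}).get("n_resamples", 10_000)),
            upstream_bp=int(raw.get("upstream_bp", 500)),
            network_upstream_bp=int(raw.get("network_upstream_bp", 25_000)),
            genic_test_k=int((raw.get("enrichment", {}) or {}).get("genic_test_k", 10)),
            confounder_alpha=float(raw.get("confounder_alpha", 0.05)),
        )
        if cfg.presence_matrix is None and cfg.diversity_table is None:
            raise ConfigurationError(
                f"config {path}: provide inputs.presence_matrix or inputs.diversity"
            )
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def run(
    config: RunConfig | str | Path,
    stages: tuple[str, ...] | None = None,
    log=print,
) -> dict:
    """Execute the pipeline; returns the manifest dict (also written as manifest.json).

    ``stages`` selects which stage outputs to produce; prerequisites of a requested
    stage are computed in memory regardless.  Any stage failure raises with a
    stage-tagged message.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    stages = tuple(stages) if stages else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "geascan_version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "parameters": {
            "alpha": config.scan.alpha,
            "rank_cutoff": config.scan.rank_cutoff,
            "maf_window": config.scan.maf_window,
            "min_window": config.scan.min_window,
            "min_populations": config.scan.min_populations,
            "n_resamples": config.n_resamples,
            "upstream_bp": config.upstream_bp,
            "network_upstream_bp": config.network_upstream_bp,
            "genic_test_k": config.genic_test_k,
            "confounder_alpha": config.confounder_alpha,
        },
        "inputs": {},
        "timings_s": {},
        "counts": {},
    }
    for name in (
        "panel",
        "frequency_matrix",
        "presence_matrix",
        "diversity_table",
        "gene_models",
        "climate",
        "interaction_flags",
    ):
        p = getattr(config, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
    for lname, lp in config.gene_lists.items():
        manifest["inputs"][f"gene_list:{lname}"] = {"path": str(lp), "sha256": _sha256(lp)}

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log(f"[{name}] start")
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["timings_s"][name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    log(f"[{name}] FAILED: {exc}")
                    raise ConfigurationError(f"stage {name!r} failed: {exc}") from exc
                log(f"[{name}] done in {manifest['timings_s'][name]} s")

        return _Timer()

    # ---- diversity ----------------------------------------------------------
    panel = read_population_table(config.panel)
    with _stage("diversity"):
        if config.presence_matrix is not None:
            pm = read_presence_matrix(config.presence_matrix)
            diversity = compute_diversity(pm)
        else:
            div_df = pd.read_csv(config.diversity_table, sep="\t")
            if not {"country", "diversity"} <= set(div_df.columns):
                raise FormatError("diversity table needs columns country, diversity")
            diversity = dict(zip(div_df["country"], div_df["diversity"].astype(float)))
        env = broadcast_to_populations(panel, diversity, "virus_diversity")
        if "diversity" in stages:
            _write(
                pd.DataFrame({"population": env.populations, "virus_diversity": env.values}),
                out / "env.tsv",
            )
    manifest["counts"]["populations"] = len(panel)
    manifest["counts"]["countries"] = len({r.country for r in panel})

    # ---- scan (correlate + rank + call) ------------------------------------
    fm = read_frequency_matrix(config.frequency_matrix, populations=[r.population_id for r in panel])
    with _stage("scan"):
        results, skipped = scan_snps(fm, env, config.scan)
        if len(results) == 0:
            log("[scan] warning: zero usable SNPs")
        else:
            results = maf_matched_rank(results, config.scan)
            results = call_significant(results, config.scan, n_tests=len(results))
        if "scan" in stages:
            _write(results, out / "scan_results.tsv")
            _write(skipped, out / "scan_skipped.tsv")
    manifest["counts"]["snps_tested"] = int(len(results))
    manifest["counts"]["snps_skipped"] = int(len(skipped))
    manifest["counts"]["snps_significant"] = int(results["final_sig"].sum()) if len(results) else 0
    sig_ids = list(results.loc[results["final_sig"], "snp_id"]) if len(results) else []
    log(f"[scan] {manifest['counts']['snps_significant']} significant of "
        f"{manifest['counts']['snps_tested']} tested SNPs")

    # ---- annotate ------------------------------------------------------------
    gmap = None
    genes = None
    if config.gene_models is not None and (
        {"annotate", "enrich"} & set(stages)
    ):
        with _stage("annotate"):
            genes = read_gene_models(config.gene_models)
            gmap = assign_snps_to_genes(fm.snp_meta, genes, config.upstream_bp)
            if "annotate" in stages:
                _write(gmap, out / "snp_gene_map.tsv")
                if sig_ids:
                    gt = genic_enrichment_test(
                        results, gmap, maf_window=config.scan.maf_window,
                        k=config.genic_test_k, seed=config.seed,
                    )
                    _write(
                        pd.DataFrame(
                            [
                                {
                                    "sig_genic": gt["table"][0][0],
                                    "sig_nongenic": gt["table"][0][1],
                                    "control_genic": gt["table"][1][0],
                                    "control_nongenic": gt["table"][1][1],
                                    "chi2": gt["chi2"],
                                    "p_value": gt["p_value"],
                                    "k": gt["k"],
                                    "seed": gt["seed"],
                                }
                            ]
                        ),
                        out / "genic_test.tsv",
                    )
        manifest["counts"]["genes"] = len(genes)
        sig_genes = sorted(set(gmap.loc[gmap["snp_id"].isin(sig_ids), "gene_id"]))
        manifest["counts"]["genes_with_significant_snp"] = len(sig_genes)
        log(f"[annotate] {len(sig_ids)} significant SNPs mapping to {len(sig_genes)} distinct genes")

    # ---- enrich --------------------------------------------------------------
    if "enrich" in stages and gmap is not None:
        with _stage("enrich"):
            universe = sorted(set(gmap["gene_id"]))
            rows = []
            for i, (lname, lpath) in enumerate(sorted(config.gene_lists.items())):
                gene_list = [
                    line.strip() for line in Path(lpath).read_text().splitlines() if line.strip()
                ]
                res = resampling_empirical_p(
                    gene_list,
                    universe,
                    gmap,
                    sig_ids,
                    n_resamples=config.n_resamples,
                    seed=config.seed + i,
                    list_name=lname,
                )
                rows.append(
                    {
                        "list_name": res.list_name,
                        "m_genes": res.m_genes,
                        "observed_snps": res.observed_snps,
                        "n_resamples": res.n_resamples,
                        "null_mean": res.null_mean,
                        "null_sd": res.null_sd,
                        "empirical_p": res.empirical_p,
                        "empirical_p_plugin": res.empirical_p_plugin,
                        "seed": res.seed,
                    }
                )
            if rows:
                _write(pd.DataFrame(rows), out / "enrichment.tsv")
            if config.interaction_flags is not None:
                flags = pd.read_csv(config.interaction_flags, sep="\t")
                flagged = set(flags.loc[flags["interacting"].astype(bool), "gene"])
                net_map = assign_snps_to_genes(fm.snp_meta, genes, config.network_upstream_bp)
                net_sig_genes = sorted(set(net_map.loc[net_map["snp_id"].isin(sig_ids), "gene_id"]))
                n_set = len(net_sig_genes)
                obs = sum(1 for g in net_sig_genes if g in flagged)
                bg_total = len(set(net_map["gene_id"]))
                bg_int = len(flagged & set(net_map["gene_id"]))
                if n_set and 0 < expected_interactions(n_set, bg_int, bg_total) < n_set:
                    ie = interaction_chisq(n_set, obs, bg_int, bg_total)
                    _write(
                        pd.DataFrame(
                            [
                                {
                                    "n_genes": ie.n_genes,
                                    "observed_interacting": ie.observed_interacting,
                                    "background_interacting": ie.background_interacting,
                                    "background_total": ie.background_total,
                                    "expected": ie.expected,
                                    "chi2": ie.chi2,
                                    "p_value": ie.p_value,
                                }
                            ]
                        ),
                        out / "interaction_enrichment.tsv",
                    )

    # ---- confound ------------------------------------------------------------
    if "confound" in stages and config.climate is not None and sig_ids:
        with _stage("confound"):
            climate = read_climate_table(config.climate)
            rep = confounder_screen(
                fm, sig_ids, climate, panel, alpha=config.confounder_alpha
            )
            _write(rep.table, out / "confounders.tsv")
            manifest["counts"]["confounder_tests"] = rep.n_tests
            manifest["counts"]["confounder_any_significant"] = bool(rep.any_significant)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
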