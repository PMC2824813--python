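"""Packaged reference tables.

The worldwide 52-population panel (population, country, sampled individuals) together
with the per-country virus-diversity totals ships as a TSV fixture: the per-country
presence/absence matrices behind those totals come from a proprietary epidemiology
database and cannot be redistributed, but the printed totals can and suffice to drive
the scan directly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import EnvVector, PopulationRecord, broadcast_to_populations

__all__ = ["load_hgdp_panel", "load_virus_diversity", "hgdp_panel_path"]


def hgdp_panel_path():
    """Filesystem path of the packaged panel TSV (for the readers' benefit in tests)."""
    return resources.files("geascan.data") / "hgdp_panel.tsv"


def load_hgdp_panel() -> list[PopulationRecord]:
    """The 52-population worldwide panel with per-population sample sizes."""
    with resources.as_file(hgdp_panel_path()) as p:
        df = pd.read_csv(p, sep="\t")
    return [
        PopulationRecord(r.population, r.country, int(r.n_sampled))
        for r in df.itertuples(index=False)
    ]


def load_virus_diversity() -> tuple[dict[str, int], EnvVector]:
    """Per-country virus diversity and its broadcast to the 52 populations."""
    with resources.as_file(hgdp_panel_path()) as p:
        df = pd.read_csv(p, sep="\t")
    by_country = (
        df.drop_duplicates("country").set_index("country")["virus_diversity"].astype(int).to_dict()
    )
    panel = [
        PopulationRecord(r.population, r.country, int(r.n_sampled))
        for r in df.itertuples(index=False)
    ]
    return by_country, broadcast_to_populations(panel, by_country, "virus_diversity")
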