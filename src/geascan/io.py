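"""Input tables, per-country pathogen diversity, and country-to-population broadcasting.

All tabular inputs are UTF-8, tab-delimited TSV with mandatory headers.  Country-level
environmental measures (pathogen diversity, climate) are broadcast to the population
panel, so every population of a country carries the identical value: rank correlations
downstream therefore see the same tie structure in every environmental variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "PopulationRecord",
    "PresenceMatrix",
    "EnvVector",
    "FrequencyMatrix",
    "ClimateTable",
    "read_population_table",
    "write_population_table",
    "read_presence_matrix",
    "write_presence_matrix",
    "compute_diversity",
    "broadcast_to_populations",
    "read_frequency_matrix",
    "write_frequency_matrix",
    "read_climate_table",
    "write_climate_table",
]

#: metadata columns preceding the per-population frequency columns
FREQ_META_COLUMNS = ("snp_id", "chrom", "pos", "coded_allele")


@dataclass(frozen=True)
class PopulationRecord:
    """One population of the panel: a label, its country, and the number of sampled individuals."""

    population_id: str
    country: str
    n_sampled: int

    def __post_init__(self) -> None:
        if not self.population_id:
            raise ValidationError("population_id must be non-empty")
        if not self.country:
            raise ValidationError(f"population {self.population_id!r}: country must be non-empty")
        if self.n_sampled < 1:
            raise ValidationError(
                f"population {self.population_id!r}: n_sampled must be >= 1, got {self.n_sampled}"
            )


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary pathogen x country presence matrix (1 = naturally transmitted in the country).

    Pathogen rows are opaque unique keys; they may denote species, genera, or families.
    Curation semantics (tourism-driven cases excluded, recently eradicated species still
    recorded as present) are the matrix curator's responsibility, not enforced here.
    """

    pathogen_ids: tuple[str, ...]
    country_ids: tuple[str, ...]
    cells: np.ndarray  # shape (n_pathogens, n_countries), values in {0, 1}

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.shape != (len(self.pathogen_ids), len(self.country_ids)):
            raise ValidationError(
                f"presence matrix shape {cells.shape} does not match "
                f"{len(self.pathogen_ids)} pathogens x {len(self.country_ids)} countries"
            )
        if len(set(self.pathogen_ids)) != len(self.pathogen_ids):
            raise ValidationError("duplicate pathogen labels in presence matrix")
        if len(set(self.country_ids)) != len(self.country_ids):
            raise ValidationError("duplicate country labels in presence matrix")
        if cells.size and not np.isin(cells, (0, 1)).all():
            bad = cells[~np.isin(cells, (0, 1))].ravel()[0]
            raise ValidationError(f"presence matrix cells must be 0/1, found {bad!r}")
        object.__setattr__(self, "cells", cells.astype(np.int64))


@dataclass(frozen=True)
class EnvVector:
    """One environmental value per population, in panel order."""

    values: np.ndarray
    name: str
    populations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValidationError("EnvVector values must be one-dimensional")
        if self.populations and len(self.populations) != values.size:
            raise ValidationError(
                f"EnvVector {self.name!r}: {values.size} values for "
                f"{len(self.populations)} populations"
            )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FrequencyMatrix:
    """SNP x population allele frequencies plus per-SNP metadata.

    ``freqs[i, j]`` is the frequency of SNP i's coded allele in population j, in [0, 1];
    missing cells are NaN.  The coded-allele orientation is arbitrary, which is why the
    scan ranks |tau| rather than signed tau.
    """

    snp_meta: pd.DataFrame  # columns snp_id, chrom, pos, coded_allele
    freqs: np.ndarray  # shape (n_snps, n_populations), NaN = missing
    populations: tuple[str, ...]

    def __post_init__(self) -> None:
        meta = self.snp_meta
        missing = [c for c in FREQ_META_COLUMNS if c not in meta.columns]
        if missing:
            raise FormatError(f"snp_meta lacks columns: {', '.join(missing)}")
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.shape != (len(meta), len(self.populations)):
            raise ValidationError(
                f"frequency matrix shape {freqs.shape} does not match "
                f"{len(meta)} SNPs x {len(self.populations)} populations"
            )
        dup = meta["snp_id"][meta["snp_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate snp_id: {dup.iloc[0]!r}")
        pos = meta["pos"].to_numpy()
        if (pos < 0).any():
            bad = meta.loc[pos < 0, "snp_id"].iloc[0]
            raise ValidationError(f"SNP {bad!r}: negative position")
        with np.errstate(invalid="ignore"):
            out_of_range = (freqs < 0) | (freqs > 1)
        if out_of_range.any():
            bad = meta["snp_id"].iloc[int(np.where(out_of_range.any(axis=1))[0][0])]
            raise ValidationError(f"SNP {bad!r}: frequency outside [0, 1]")
        self.freqs = freqs
        self.snp_meta = meta.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.snp_meta)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["snp_id"].to_numpy()

    def missing_counts(self) -> np.ndarray:
        """Per-SNP count of missing population cells."""
        return np.isnan(self.freqs).sum(axis=1)


@dataclass(frozen=True)
class ClimateTable:
    """Per-country annual climate summaries: tmin, tmax (degrees C) and shortwave flux (W/m2).

    Values are consumed pre-averaged (annual means); the averaging itself is upstream of
    this package.
    """

    table: pd.DataFrame  # index: country; columns tmin, tmax, sw_flux

    def __post_init__(self) -> None:
        t = self.table
        for col in ("tmin", "tmax", "sw_flux"):
            if col not in t.columns:
                raise FormatError(f"climate table lacks column {col!r}")
        if t.index.duplicated().any():
            raise ValidationError(
                f"duplicate country in climate table: {t.index[t.index.duplicated()][0]!r}"
            )
        bad = t.index[t["tmin"] > t["tmax"]]
        if len(bad):
            raise ValidationError(f"country {bad[0]!r}: tmin exceeds tmax")

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def variable(self, name: str) -> Mapping[str, float]:
        return self.table[name].to_dict()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected a header line") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    return df


def read_population_table(path: str | Path) -> list[PopulationRecord]:
    """Read a panel TSV (columns ``population``, ``country``, ``n_sampled``; extras ignored)."""
    df = _read_tsv(path, ("population", "country", "n_sampled"))
    records = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        pop = getattr(row, "population")
        if pop in seen:
            raise ValidationError(f"{path}: duplicate population {pop!r}")
        seen.add(pop)
        try:
            n = int(getattr(row, "n_sampled"))
        except ValueError as exc:
            raise ValidationError(f"{path}: population {pop!r}: non-integer n_sampled") from exc
        records.append(PopulationRecord(pop, getattr(row, "country"), n))
    return records


def write_population_table(records: Sequence[PopulationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "population": [r.population_id for r in records],
            "country": [r.country for r in records],
            "n_sampled": [r.n_sampled for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_presence_matrix(path: str | Path) -> PresenceMatrix:
    """Read a pathogen x country 0/1 TSV (first column ``pathogen``, one column per country)."""
    df = _read_tsv(path, ("pathogen",))
    countries = tuple(c for c in df.columns if c != "pathogen")
    pathogens = tuple(df["pathogen"])
    if len(countries) == 0:
        raise FormatError(f"{path}: presence matrix has no country columns")
    if len(df) == 0:
        cells = np.zeros((0, len(countries)), dtype=np.int64)
        return PresenceMatrix(pathogens, countries, cells)
    try:
        cells = df[list(countries)].astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric presence cell") from exc
    if not np.isin(cells, (0.0, 1.0)).all():
        raise ValidationError(f"{path}: presence cells must be 0 or 1")
    return PresenceMatrix(pathogens, countries, cells.astype(np.int64))


def write_presence_matrix(m: PresenceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.cells, columns=list(m.country_ids))
    df.insert(0, "pathogen", list(m.pathogen_ids))
    df.to_csv(path, sep="\t", index=False)


def compute_diversity(m: PresenceMatrix) -> dict[str, int]:
    """Pathogen diversity per country: the column sum of the presence matrix.

    This is the environmental variable of the scan -- the number of distinct pathogen
    taxa naturally transmitted in each country.
    """
    sums = m.cells.sum(axis=0) if m.cells.size else np.zeros(len(m.country_ids), dtype=np.int64)
    return {c: int(s) for c, s in zip(m.country_ids, sums)}


def broadcast_to_populations(
    panel: Sequence[PopulationRecord],
    country_values: Mapping[str, float],
    name: str,
) -> EnvVector:
    """Expand a country-level measure to one value per population, preserving within-country ties."""
    values = np.empty(len(panel))
    for i, rec in enumerate(panel):
        if rec.country not in country_values:
            raise ValidationError(
                f"no value for country {rec.country!r} (population {rec.population_id!r})"
            )
        values[i] = country_values[rec.country]
    return EnvVector(values, name, tuple(r.population_id for r in panel))


def read_frequency_matrix(
    path: str | Path, populations: Sequence[str] | None = None
) -> FrequencyMatrix:
    """Read a SNP x population frequency TSV.

    Columns: ``snp_id``, ``chrom``, ``pos``, ``coded_allele``, then one column per
    population.  Cells are frequencies in [0, 1] or ``NA`` for missing.  When
    ``populations`` is given, the file's population columns must match it exactly
    (names and order).
    """
    df = _read_tsv(path, FREQ_META_COLUMNS)
    pop_cols = [c for c in df.columns if c not in FREQ_META_COLUMNS]
    if populations is not None and list(populations) != pop_cols:
        raise FormatError(
            f"{path}: population columns do not match the panel "
            f"(expected {list(populations)}, found {pop_cols})"
        )
    if not pop_cols:
        raise FormatError(f"{path}: no population columns after the metadata columns")
    meta = df[list(FREQ_META_COLUMNS)].copy()
    try:
        meta["pos"] = meta["pos"].astype(np.int64)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-integer SNP position") from exc
    block = df[pop_cols]
    try:
        freqs = block.mask(block.isin(["NA", "", "nan"])).astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric frequency cell") from exc
    return FrequencyMatrix(meta, freqs, tuple(pop_cols))


def write_frequency_matrix(fm: FrequencyMatrix, path: str | Path) -> None:
    df = fm.snp_meta.copy()
    freq_df = pd.DataFrame(fm.freqs, columns=list(fm.populations))
    out = pd.concat([df.reset_index(drop=True), freq_df], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_climate_table(path: str | Path) -> ClimateTable:
    """Read a per-country climate TSV (columns ``country``, ``tmin``, ``tmax``, ``sw_flux``)."""
    df = _read_tsv(path, ("country", "tmin", "tmax", "sw_flux"))
    try:
        body = df[["tmin", "tmax", "sw_flux"]].astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric climate cell") from exc
    body.index = pd.Index(df["country"], name="country")
    return ClimateTable(body)


def write_climate_table(ct: ClimateTable, path: str | Path) -> None:
    ct.table.to_csv(path, sep="\t", float_format="%.12g")
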