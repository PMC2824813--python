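"""Climate-confounder screen for environment-associated SNPs.

Significant SNPs from the primary scan are re-correlated against country-level climate
variables (annual Tmin, Tmax, shortwave radiation flux) broadcast to populations.  If
none survives Bonferroni correction across all SNP x variable tests, the primary
associations are unlikely to be climatic artefacts.  The screen reports; it never
filters -- an optional strict mode lets callers drop failing SNPs themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConstantInputError, ValidationError
from .io import ClimateTable, EnvVector, FrequencyMatrix, PopulationRecord, broadcast_to_populations
from .kendall import kendall_tau_b

__all__ = ["ConfounderReport", "confounder_screen"]

CLIMATE_VARIABLES = ("tmin", "tmax", "sw_flux")


@dataclass
class ConfounderReport:
    """Per-(SNP, climate variable) correlations with Bonferroni flags."""

    table: pd.DataFrame  # columns snp_id, variable, tau, p_value, bonferroni_sig
    alpha: float
    n_tests: int
    any_significant: bool
    skipped_variables: tuple[str, ...] = ()

    def failing_snps(self) -> list[str]:
        """SNPs with at least one Bonferroni-significant climate correlation."""
        t = self.table
        return sorted(t.loc[t["bonferroni_sig"], "snp_id"].unique())


def confounder_screen(
    fm: FrequencyMatrix,
    sig_snp_ids: Iterable[str],
    climate: ClimateTable,
    panel: Sequence[PopulationRecord],
    alpha: float = 0.05,
    variables: Sequence[str] = CLIMATE_VARIABLES,
    min_populations: int = 10,
) -> ConfounderReport:
    """Correlate each significant SNP with each climate variable (Kendall tau-b).

    The Bonferroni denominator is the number of tests in this report (SNPs x usable
    variables).  A variable that is constant across the panel's countries carries no
    rank information and is skipped with a note.
    """
    sig_ids = list(dict.fromkeys(sig_snp_ids))
    id_to_row = {s: i for i, s in enumerate(fm.snp_ids)}
    unknown = [s for s in sig_ids if s not in id_to_row]
    if unknown:
        raise ValidationError(f"significant SNP {unknown[0]!r} not in the frequency matrix")

    env_vectors: list[EnvVector] = []
    skipped: list[str] = []
    for var in variables:
        env = broadcast_to_populations(panel, climate.variable(var), var)
        if np.unique(env.values).size < 2:
            skipped.append(var)
        else:
            env_vectors.append(env)

    rows = []
    for snp in sig_ids:
        x = fm.freqs[id_to_row[snp]]
        for env in env_vectors:
            try:
                keep = ~np.isnan(x)
                if keep.sum() < min_populations:
                    raise ConstantInputError("too few populations")
                tau, p = kendall_tau_b(x, env.values)
            except ConstantInputError:
                tau, p = np.nan, np.nan
            rows.append((snp, env.name, tau, p))
    table = pd.DataFrame(rows, columns=["snp_id", "variable", "tau", "p_value"])
    n_tests = int(table["p_value"].notna().sum())
    if n_tests:
        table["bonferroni_sig"] = table["p_value"] <= alpha / n_tests
    else:
        table["bonferroni_sig"] = False
    table["bonferroni_sig"] = table["bonferroni_sig"].fillna(False).astype(bool)
    return ConfounderReport(
        table=table,
        alpha=alpha,
        n_tests=max(n_tests, 0),
        any_significant=bool(table["bonferroni_sig"].any()),
        skipped_variables=tuple(skipped),
    )
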