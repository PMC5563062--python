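"""Abundance statistics from mapped-read counts.

Genome proportion (GP) of a repeat cluster is the percent of a species'
total reads assigned to that cluster; reads-per-million is the same
quantity scaled (RPM = 10^4 x GP).  The denominator is the species' total
trimmed read count, not the mapped count, so the sum of GPs over clusters
is the repetitive fraction of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUPERFAMILIES = ("Copia", "Gypsy", "unknown")


def genome_proportion(mapped_counts, total_reads: int) -> pd.Series:
    """GP per cluster, in percent of ``total_reads``."""
    counts = pd.Series(mapped_counts, dtype=float)
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if (counts < 0).any():
        raise ValueError("mapped counts must be non-negative")
    if counts.sum() > total_reads:
        raise ValueError("mapped counts exceed total reads")
    return 100.0 * counts / total_reads


def reads_per_million(mapped_counts, total_reads: int) -> pd.Series:
    return 1e4 * genome_proportion(mapped_counts, total_reads)


def repetitive_fraction(mapped_counts, total_reads: int) -> float:
    """Percent of all reads assigned to any repeat cluster."""
    return float(genome_proportion(mapped_counts, total_reads).sum())


def aggregate_by_lineage(gp: pd.DataFrame, annotation: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Sum cluster GPs into lineage and superfamily tables.

    ``gp``: species x cluster GP matrix.  ``annotation``: indexed by
    cluster id with ``superfamily`` and ``lineage`` columns (missing or
    empty lineage counts as that superfamily's own "unknown" category).
    Superfamily totals are the sums of their lineage entries, unknowns
    included, so additivity is exact.
    """
    missing = gp.columns.difference(annotation.index)
    if len(missing):
        raise KeyError(f"clusters missing from annotation: {list(missing)[:5]}")
    ann = annotation.loc[gp.columns]
    lineage = ann["lineage"].fillna("unknown").replace("", "unknown")
    gpT = gp.T.copy()
    gpT.index = pd.MultiIndex.from_arrays(
        [ann["superfamily"].to_numpy(), lineage.to_numpy()],
        names=["superfamily", "lineage"],
    )
    by_lineage = gpT.groupby(level=["superfamily", "lineage"]).sum().T
    by_superfamily = gpT.groupby(level="superfamily").sum().T
    return {"lineage": by_lineage, "superfamily": by_superfamily}


def gypsy_copia_ratio(gypsy_total: float, copia_total: float) -> float:
    """Ratio of Gypsy to Copia genome proportions."""
    if copia_total <= 0:
        raise ValueError("Copia total must be positive for a Gypsy/Copia ratio")
    return gypsy_total / copia_total


def max_percentage_variation(values) -> float:
    """Spread of a lineage's GP across species: 100 * (max - min) / max."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two species")
    if v.max() <= 0:
        raise ValueError("all-zero genome proportions")
    return float(100.0 * (v.max() - v.min()) / v.max())


@dataclass
class AbundanceTable:
    """Species x cluster abundance with annotation.

    Holds raw mapped counts, per-species totals, and derived GP/RPM
    views; aggregation helpers mirror the published table layouts.
    """

    counts: pd.DataFrame = field(repr=False)  # species x cluster
    totals: pd.Series = field(repr=False)  # per-species total reads
    annotation: pd.DataFrame = field(repr=False)  # cluster -> superfamily/lineage[/sublineage]

    def __post_init__(self):
        self.totals = self.totals.reindex(self.counts.index)
        if self.totals.isna().any():
            raise ValueError("every species needs a total read count")

    @property
    def gp(self) -> pd.DataFrame:
        return 100.0 * self.counts.div(self.totals, axis=0)

    @property
    def rpm(self) -> pd.DataFrame:
        return 1e4 * self.gp

    def repetitive_fraction(self) -> pd.Series:
        return self.gp.sum(axis=1)

    def lineage_gp(self) -> pd.DataFrame:
        return aggregate_by_lineage(self.gp, self.annotation)["lineage"]

    def superfamily_gp(self) -> pd.DataFrame:
        return aggregate_by_lineage(self.gp, self.annotation)["superfamily"]

    def gypsy_copia_ratios(self) -> pd.Series:
        sf = self.superfamily_gp()
        return pd.Series(
            {sp: gypsy_copia_ratio(sf.at[sp, "Gypsy"], sf.at[sp, "Copia"])
             for sp in sf.index},
            name="gypsy_copia_ratio",
        )

    def max_percentage_variations(self) -> pd.Series:
        lin = self.lineage_gp()
        return pd.Series(
            {col: max_percentage_variation(lin[col]) for col in lin.columns},
            name="max_percentage_variation",
        )
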