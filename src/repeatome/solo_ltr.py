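"""Solo-LTR detection from LTR / inter-LTR coverage ratios.

For an intact element every insertion contributes two LTR copies and one
internal region.  If reads are mapped onto a reference made of the
5'-LTR plus the internal region only (the 3'-LTR is deliberately
excluded so reads from either LTR collapse onto the single 5' copy),
the expected ratio of mean LTR depth to mean internal depth is

    ratio = (2n + m) / n = 2 + m/n

for n intact and m solo copies.  A family with no solo LTRs sits at 2;
ratios above 2 indicate solo-LTR accumulation by unequal homologous
recombination, which removes internal DNA and shrinks genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import CoverageProfile
from .simulate import MasterElement

SOLO_RATIO_THRESHOLD = 2.0


@dataclass(frozen=True)
class ElementPartition:
    """Reference layout: [0, ltr_end) = 5'-LTR, [ltr_end, total) = internal."""

    element_id: str
    ltr_end: int
    total_length: int

    def __post_init__(self):
        if not 0 < self.ltr_end < self.total_length:
            raise ValueError("partition intervals must be non-empty and contiguous")

    @property
    def ltr_interval(self) -> tuple[int, int]:
        return (0, self.ltr_end)

    @property
    def internal_interval(self) -> tuple[int, int]:
        return (self.ltr_end, self.total_length)


def partition_reference(master: MasterElement) -> tuple[str, ElementPartition]:
    """5'-LTR + internal reference (3'-LTR excluded) with its partition."""
    seq = master.ltr_seq + master.internal_seq
    return seq, ElementPartition(master.id, len(master.ltr_seq), len(seq))


@dataclass(frozen=True)
class SoloLtrRatio:
    element_id: str
    species_id: str
    ltr_depth: float
    internal_depth: float
    ratio: float  # nan when undefined
    defined: bool
    solo_flag: bool


def ltr_internal_ratio(
    coverage: CoverageProfile,
    partition: ElementPartition,
    species_id: str = "",
) -> SoloLtrRatio:
    """Mean 5'-LTR depth over mean internal depth for one element."""
    if coverage.depth.size != partition.total_length:
        raise ValueError("coverage profile does not match the partitioned reference")
    ltr = coverage.mean_depth(partition.ltr_interval)
    internal = coverage.mean_depth(partition.internal_interval)
    if internal == 0:
        return SoloLtrRatio(partition.element_id, species_id, ltr, internal,
                            float("nan"), False, False)
    ratio = ltr / internal
    return SoloLtrRatio(partition.element_id, species_id, ltr, internal,
                        ratio, True, ratio > SOLO_RATIO_THRESHOLD)


def ratios_to_frame(ratios) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.element_id, r.species_id, r.ltr_depth, r.internal_depth,
          r.ratio, r.defined, r.solo_flag) for r in ratios],
        columns=["element_id", "species_id", "ltr_depth", "internal_depth",
                 "ratio", "defined", "solo_flag"],
    )


def summarize_by_species(ratios, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-species ratio distribution summary, ploidy kept separate.

    Undefined ratios are excluded from the quantiles and reported as a
    count.  ``metadata`` (optional, indexed by species) may carry
    ``ploidy`` and ``genome_size`` columns which are joined through.
    """
    df = ratios if isinstance(ratios, pd.DataFrame) else ratios_to_frame(ratios)
    rows = []
    for sp, grp in df.groupby("species_id"):
        ok = grp[grp["defined"]]["ratio"]
        rows.append({
            "species_id": sp,
            "n_elements": len(grp),
            "n_undefined": int((~grp["defined"]).sum()),
            "median": ok.median(),
            "q1": ok.quantile(0.25),
            "q3": ok.quantile(0.75),
            "min": ok.min(),
            "max": ok.max(),
            "n_solo_flagged": int(grp["solo_flag"].sum()),
        })
    out = pd.DataFrame(rows).set_index("species_id")
    if metadata is not None:
        out = out.join(metadata, how="left")
    return out


def correlate_ratio_genome_size(
    mean_ratios,
    genome_sizes,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided permutation p-value.

    Tests whether species with more solo-LTR accumulation (higher mean
    coverage ratios) have smaller genomes.
    """
    x = pd.Series(mean_ratios).astype(float)
    y = pd.Series(genome_sizes).astype(float).reindex(x.index)
    if y.isna().any():
        raise ValueError("genome size missing for some species")
    if len(x) < 4:
        raise ValueError("need at least 4 species")
    if x.nunique() == 1 or y.nunique() == 1:
        raise ValueError("constant input vector")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    yv = y.to_numpy()
    hits = 0
    for _ in range(n_permutations):
        perm = float(stats.spearmanr(x, rng.permutation(yv)).statistic)
        if abs(perm) >= abs(rho) - 1e-12:
            hits += 1
    return rho, (hits + 1) / (n_permutations + 1)
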