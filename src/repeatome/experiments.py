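"""Pre-canned recovery experiments on synthetic repeatomes.

Each function builds a small simulated study with known truth and runs
one analysis stage end to end: the solo-LTR coverage ratio against its
closed form 2 + m/n, burst dating against a planted amplification age,
the conservation index against a young/old burst contrast, and profile
clustering against a planted two-archetype species split.  They are the
package's parameter-recovery harness, used by the test suite and the
reproduction script alike.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .clustering import cluster_species
from .dating import (AgeDistribution, PairwiseDistanceSet, RtHarvest,
                     StringencyCounts, burst_histogram, conservation_index,
                     harvest_rt_reads, pairwise_k2p)
from .mapping import compute_coverage, map_reads
from .simulate import (FamilyModel, GenomeBuild, MasterElement, SpeciesModel,
                       build_genome, random_master, sample_reads)
from .solo_ltr import SoloLtrRatio, ltr_internal_ratio, partition_reference

RATE = 2e-8


def solo_ltr_experiment(
    master: MasterElement,
    n_intact: int,
    n_solo: int,
    seed: int,
    depth: float = 50.0,
    reference: str | None = None,
    partition=None,
) -> SoloLtrRatio:
    """Simulate one family and measure its LTR / inter-LTR coverage ratio.

    Read number is chosen so the internal region of the partitioned
    reference reaches ~``depth``x; the expected ratio is 2 + m/n.
    """
    if reference is None:
        reference, partition = partition_reference(master)
    model = SpeciesModel(
        "S", 2, (FamilyModel(master.id, n_intact, n_solo, 1e6),), 10_000)
    genome = build_genome(model, {master.id: master}, seed=seed)
    n_reads = int(depth / n_intact * len(genome.sequence) / 90)
    reads = sample_reads(genome, n_reads, error_rate=0.0, seed=seed + 1)
    res = map_reads(reads, {master.id: reference}, "high", seed=seed + 2)
    return ltr_internal_ratio(compute_coverage(res, master.id), partition, "S")


def burst_experiment(
    seed: int,
    age_mya: float,
    n_copies: int,
    cap: int = 200,
    n_reads: int = 15_000,
) -> tuple[GenomeBuild, RtHarvest, PairwiseDistanceSet, AgeDistribution]:
    """Simulate a retrotranspositional burst and date it from RT reads.

    Compact Chromovirus-like geometry (150-bp LTRs, 400-bp internal
    region, 90-nt RT window) so the dating statistic — which only sees
    the RT window — runs at desk scale.
    """
    master = random_master("chromo", "Gypsy", "Chromovirus", 150, 400,
                           rt_domain=(155, 245), seed=seed)
    model = SpeciesModel(
        "S", 2, (FamilyModel("chromo", n_copies, 0, age_mya * 1e6),), 5000)
    genome = build_genome(model, {"chromo": master}, seed=seed + 1)
    reads = sample_reads(genome, n_reads, error_rate=0.001, seed=seed + 2)
    harvest = harvest_rt_reads(reads, master.rt_seq, "medium",
                               cap=cap, seed=seed + 3)
    distances = pairwise_k2p(harvest)
    return genome, harvest, distances, burst_histogram(distances, RATE, 0.5)


def conservation_contrast(seed: int, young_mya: float = 1.0,
                          old_mya: float = 10.0) -> dict[str, float]:
    """CI of a young vs an old burst lineage at equal copy number."""
    values = {}
    for age_mya, tag in ((young_mya, "young"), (old_mya, "old")):
        m = random_master(tag, "Gypsy", "Chromovirus", 150, 600, seed=seed)
        model = SpeciesModel(
            "S", 2, (FamilyModel(tag, 20, 0, age_mya * 1e6),), 5000)
        genome = build_genome(model, {tag: m}, seed=seed + 1)
        reads = sample_reads(genome, 2000, seed=seed + 2)
        n = {t: map_reads(reads, {tag: m.rt_seq}, t, seed=0).n_mapped
             for t in ("high", "medium")}
        ci = conservation_index(
            StringencyCounts("S", tag, n["high"], n["medium"], n["medium"]))
        values[tag] = ci.value
    return values


def planted_two_group_matrix(seed: int, noise: float = 0.05) -> pd.DataFrame:
    """11 species, two abundance archetypes, multiplicative noise.

    Annual-like species are Maximus/SIRE-rich, perennial-like species
    Chromovirus-rich, mirroring the contrast seen across sunflowers.
    """
    rng = np.random.default_rng(seed)
    archetypes = {"A": {"sire": 15.0, "chromo": 25.0},
                  "P": {"sire": 5.0, "chromo": 37.0}}
    species = [f"A{i}" for i in range(5)] + [f"P{i}" for i in range(6)]
    cols = [f"sire{j}" for j in range(6)] + [f"chromo{j}" for j in range(6)]
    rows = []
    for sp in species:
        arch = archetypes[sp[0]]
        row = [arch["sire"] / 6] * 6 + [arch["chromo"] / 6] * 6
        rows.append([v + rng.normal(0, noise * v) for v in row])
    return pd.DataFrame(rows, index=species, columns=cols)


def planted_split_support(seed: int, n_boot: int = 1000) -> float:
    """Bootstrap support of the planted top split (0 if not recovered)."""
    matrix = planted_two_group_matrix(seed, noise=0.05)
    tree = cluster_species(matrix, n_boot=n_boot, seed=seed + 1)
    a, b = tree.top_split()
    expected = {frozenset(s for s in matrix.index if s.startswith("A")),
                frozenset(s for s in matrix.index if s.startswith("P"))}
    if {a, b} != expected:
        return 0.0
    return min(tree.clade_support(a), tree.clade_support(b))


def archetype_matrix(k: int, n_per: int = 4, n_sp: int = 10,
                     snr: float = 4.0, seed: int = 0) -> pd.DataFrame:
    """k distinct cross-species abundance archetypes at a set SNR.

    SNR is the minimum distance between normalized archetypes divided by
    the expected within-archetype pair distance.
    """
    rng = np.random.default_rng(seed)
    cuts = np.linspace(0, n_sp, k + 1).astype(int)
    archs = []
    for i in range(k):
        a = np.full(n_sp, 1.0)
        a[cuts[i]:cuts[i + 1]] = 10.0
        archs.append(a / a.sum())
    d_min = min(np.linalg.norm(a - b)
                for a, b in itertools.combinations(archs, 2))
    sigma = d_min / (snr * np.sqrt(2.0 * n_sp))
    rows, names = [], []
    for ai, arch in enumerate(archs):
        for j in range(n_per):
            rows.append(np.clip(arch + rng.normal(0, sigma, n_sp), 0, None))
            names.append(f"c{ai}_{j}")
    return pd.DataFrame(rows, index=names)
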