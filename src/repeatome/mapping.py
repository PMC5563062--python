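"""Stringency-gated read mapping against repeat references.

The alignment model is the unit-cost semi-global one: the whole read is
aligned against any window of the reference (mismatch, insertion and
deletion each cost 1), on both strands, and the minimum-cost placement
wins.  A hit is reported only if it passes two gates:

* ``similarity``        — identity = matches / alignment columns
* ``length_fraction``   — read bases aligned to reference bases / read length

The three published stringency tiers set both gates to 0.9 (high),
0.7 (medium) or 0.5 (low); their acceptance regions are nested, so any
read mapped at a stricter tier is mapped at every looser one.

The DP itself is delegated to edlib (exact Levenshtein in query-global /
target-local mode); gate computation, strand handling, best-hit choice
and tie-breaking live here.  Ties between references are broken by
identity, then aligned fraction, then lexicographically smallest
reference id (deterministic); ties between co-optimal placements within
one reference are broken by a seeded uniform draw, mirroring the random
placement of common read mappers — this matters when a reference carries
two identical LTR copies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .simulate import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

# Ns must never match anything (not even another N): map them to characters
# that cannot occur on the other side of the alignment.
_READ_CLEAN = str.maketrans("acgtnN", "ACGT!!")
_REF_CLEAN = str.maketrans("acgtnN", "ACGT??")


@dataclass(frozen=True)
class AlignmentParams:
    """Mapping gates; edit costs are fixed at 1/1/1 by the model."""

    similarity: float = 0.9
    length_fraction: float = 0.9

    def __post_init__(self):
        for v in (self.similarity, self.length_fraction):
            if not 0 < v <= 1:
                raise ValueError("similarity and length_fraction must be in (0, 1]")


#: The published stringency tiers.
TIERS: dict[str, AlignmentParams] = {
    "high": AlignmentParams(0.9, 0.9),
    "medium": AlignmentParams(0.7, 0.7),
    "low": AlignmentParams(0.5, 0.5),
}


@dataclass(frozen=True)
class Alignment:
    """Best placement of one read on one reference (pre-gating)."""

    cost: int
    identity: float
    aligned_fraction: float
    ref_start: int
    ref_end: int  # half-open
    strand: str
    cigar: str
    locations: tuple[tuple[int, int], ...] = ()  # co-optimal (start, end_incl)


def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(matches, columns, read bases in insertion columns)."""
    matches = columns = ins = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
        elif op == "I":
            ins += n
    return matches, columns, ins


def max_cost_for_similarity(read_length: int, similarity: float) -> int:
    """Largest edit cost compatible with the identity gate.

    With columns = read_length + deletions and cost = non-match columns,
    identity >= s forces cost <= read_length * (1 - s) / s; alignments
    costlier than this can never pass the gate, so they can be pruned
    with a banded distance-only pass.
    """
    return int(read_length * (1.0 - similarity) / similarity)


def align_read(read: str, reference: str, max_cost: int | None = None) -> Alignment | None:
    """Minimum-cost semi-global placement of ``read`` on either strand.

    Gating against a tier is the caller's job; this returns the optimal
    placement, or None when ``max_cost`` is given and no placement on
    either strand costs <= max_cost.  On equal cost the plus strand is
    preferred.
    """
    if not read or not reference:
        raise ValueError("read and reference must be non-empty")
    q = read.translate(_READ_CLEAN)
    t = reference.translate(_REF_CLEAN)
    if set(q) - set("ACGT!") or set(t) - set("ACGT?"):
        raise ValueError("sequences must be over the A,C,G,T,N alphabet")
    qr = revcomp(read).translate(_READ_CLEAN)
    if max_cost is not None:
        # banded distance-only pruning pass (exact: k-bounded edlib)
        df = edlib.align(q, t, mode="HW", task="distance", k=max_cost)["editDistance"]
        dr = edlib.align(qr, t, mode="HW", task="distance", k=max_cost)["editDistance"]
        if df < 0 and dr < 0:
            return None
    fwd = edlib.align(q, t, mode="HW", task="path")
    rev = edlib.align(qr, t, mode="HW", task="path")
    if rev["editDistance"] < fwd["editDistance"]:
        res, strand = rev, "-"
    else:
        res, strand = fwd, "+"
    matches, columns, ins = _cigar_stats(res["cigar"])
    start, end = res["locations"][0]
    return Alignment(
        cost=res["editDistance"],
        identity=matches / columns,
        aligned_fraction=(len(read) - ins) / len(read),
        ref_start=start,
        ref_end=end + 1,
        strand=strand,
        cigar=res["cigar"],
        locations=tuple(res["locations"]),
    )


def passes(aln: Alignment, params: AlignmentParams) -> bool:
    return aln.identity >= params.similarity and aln.aligned_fraction >= params.length_fraction


@dataclass
class MappingResult:
    """Per-read best-hit table for one read set against a reference panel.

    ``table`` columns: read_id, ref_id, strand, ref_start, ref_end,
    identity, aligned_fraction; unmapped reads have ref_id = NA.
    """

    table: pd.DataFrame = field(repr=False)
    tier: str
    ref_lengths: dict[str, int]

    @property
    def n_total(self) -> int:
        return len(self.table)

    @property
    def n_mapped(self) -> int:
        return int(self.table["ref_id"].notna().sum())

    @property
    def n_unmapped(self) -> int:
        return self.n_total - self.n_mapped

    def mapped_counts(self) -> pd.Series:
        """Mapped reads per reference (references with 0 hits included)."""
        counts = self.table["ref_id"].value_counts()
        return counts.reindex(sorted(self.ref_lengths), fill_value=0).astype(int)

    def mapped_ids(self) -> set[str]:
        return set(self.table.loc[self.table["ref_id"].notna(), "read_id"])


def map_reads(
    reads,
    references: dict[str, str],
    tier: str | AlignmentParams = "high",
    seed: int | np.random.Generator = 0,
) -> MappingResult:
    """Assign each read to its best reference passing the tier gates.

    ``reads`` is an iterable of objects with ``id`` and ``seq`` (or
    ``(id, seq)`` pairs).  Each read is assigned to at most one reference
    (genome proportions must sum over disjoint clusters).
    """
    if not references:
        raise ValueError("references must be non-empty")
    params = TIERS[tier] if isinstance(tier, str) else tier
    tier_name = tier if isinstance(tier, str) else f"s{params.similarity}_f{params.length_fraction}"
    rng = np.random.default_rng(seed)
    ref_items = sorted(references.items())
    rows = []
    for read in reads:
        rid, seq = (read.id, read.seq) if hasattr(read, "id") else read
        k = max_cost_for_similarity(len(seq), params.similarity)
        best: tuple | None = None
        best_aln: Alignment | None = None
        for ref_id, ref_seq in ref_items:
            aln = align_read(seq, ref_seq, max_cost=k)
            if aln is None or not passes(aln, params):
                continue
            key = (-aln.identity, -aln.aligned_fraction, ref_id)
            if best is None or key < best:
                best = key
                best_aln = aln
                best_ref = ref_id
        if best_aln is None:
            rows.append((rid, pd.NA, pd.NA, pd.NA, pd.NA, np.nan, np.nan))
        else:
            locs = best_aln.locations
            start, end = locs[rng.integers(len(locs))] if len(locs) > 1 else locs[0]
            rows.append((rid, best_ref, best_aln.strand, int(start), int(end) + 1,
                         best_aln.identity, best_aln.aligned_fraction))
    table = pd.DataFrame(
        rows,
        columns=["read_id", "ref_id", "strand", "ref_start", "ref_end",
                 "identity", "aligned_fraction"],
    )
    return MappingResult(table=table, tier=tier_name,
                         ref_lengths={k: len(v) for k, v in references.items()})


@dataclass
class CoverageProfile:
    """Per-position mapped-read depth along one reference."""

    ref_id: str
    depth: np.ndarray = field(repr=False)

    def mean_depth(self, interval: tuple[int, int] | None = None) -> float:
        if interval is None:
            return float(self.depth.mean())
        s, e = interval
        if not 0 <= s < e <= self.depth.size:
            raise ValueError(f"invalid interval {interval} for length {self.depth.size}")
        return float(self.depth[s:e].mean())


def compute_coverage(mapping: MappingResult, ref_id: str) -> CoverageProfile:
    """Depth profile from the reference spans of mapped reads."""
    if ref_id not in mapping.ref_lengths:
        raise KeyError(f"unknown reference {ref_id!r}")
    depth = np.zeros(mapping.ref_lengths[ref_id] + 1)
    hits = mapping.table[mapping.table["ref_id"] == ref_id]
    np.add.at(depth, hits["ref_start"].astype(int).to_numpy(), 1)
    np.add.at(depth, hits["ref_end"].astype(int).to_numpy(), -1)
    return CoverageProfile(ref_id=ref_id, depth=np.cumsum(depth[:-1]))
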