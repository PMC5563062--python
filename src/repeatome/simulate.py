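"""Synthetic repeatome generator.

Builds multi-species genomes from shared ancestral ("master") LTR
retrotransposon families with species-specific copy numbers, burst ages,
and solo-LTR fractions, then samples uniform fixed-length reads from them.
Every build carries a complete truth table, so downstream statistics
(genome proportions, LTR/inter-LTR coverage ratios, pairwise divergence
ages) can be checked against known parameters.

Sequence divergence follows a Kimura two-parameter substitution process:
transitions and transversions accrue per site at a total rate ``rate``
(substitutions/site/year), with transition/transversion rate ratio
``kappa``.  The exact finite-time transition probabilities of the chain
are used, so multiple hits are modelled and the K2P distance estimator
recovers ``rate * age`` without bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALPHABET = np.frombuffer(b"AGCT", dtype=np.uint8)  # purines first, pyrimidines second
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"AGCT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

DEFAULT_SUBSTITUTION_RATE = 2e-8  # subs/site/year; 2x the host-gene rate (error-prone RT)
DEFAULT_KAPPA = 2.0
DEFAULT_READ_LENGTH = 90
DEFAULT_ERROR_RATE = 0.001
READS_PER_DIPLOID = 1_000_000  # comparative design: read number proportional to ploidy


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 codes (A=0, G=1, C=2, T=3)."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        bad = set(seq) - set("ACGTacgt")
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return arr


def decode(codes: np.ndarray) -> str:
    return ALPHABET[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.int8))


@dataclass(frozen=True)
class MasterElement:
    """Ancestral full-length LTR retrotransposon: LTR + internal region + LTR.

    ``rt_domain`` is a 0-based half-open interval on ``internal_seq`` marking
    the reverse-transcriptase coding stretch used for dating.
    """

    id: str
    superfamily: str  # Gypsy | Copia | unknown
    lineage: str
    ltr_seq: str
    internal_seq: str
    rt_domain: tuple[int, int]

    def __post_init__(self):
        if self.superfamily not in ("Gypsy", "Copia", "unknown"):
            raise ValueError(f"unknown superfamily {self.superfamily!r}")
        if len(self.ltr_seq) < 100:
            raise ValueError("LTR must be at least 100 bp")
        s, e = self.rt_domain
        if not (0 <= s < e <= len(self.internal_seq)):
            raise ValueError("rt_domain must lie within internal_seq")
        encode(self.ltr_seq)
        encode(self.internal_seq)

    @property
    def sequence(self) -> str:
        """Full-length element: 5'-LTR + internal + 3'-LTR."""
        return self.ltr_seq + self.internal_seq + self.ltr_seq

    @property
    def rt_seq(self) -> str:
        s, e = self.rt_domain
        return self.internal_seq[s:e]

    @property
    def length(self) -> int:
        return 2 * len(self.ltr_seq) + len(self.internal_seq)


def random_master(
    id: str,
    superfamily: str,
    lineage: str,
    ltr_length: int,
    internal_length: int,
    rt_domain: tuple[int, int] | None = None,
    *,
    seed: int | np.random.Generator = 0,
) -> MasterElement:
    """Draw a random master element with i.i.d. uniform nucleotides."""
    rng = np.random.default_rng(seed)
    if rt_domain is None:
        # centre a 300 bp (or shorter) RT stretch inside the internal region
        w = min(300, internal_length)
        s = (internal_length - w) // 2
        rt_domain = (s, s + w)
    return MasterElement(
        id=id,
        superfamily=superfamily,
        lineage=lineage,
        ltr_seq=random_sequence(ltr_length, rng),
        internal_seq=random_sequence(internal_length, rng),
        rt_domain=rt_domain,
    )


@dataclass(frozen=True)
class FamilyModel:
    """Per-species dose of one master family."""

    master_id: str
    intact_copies: int  # n
    solo_copies: int  # m
    burst_age: float  # years since the amplification burst

    def __post_init__(self):
        if self.intact_copies < 0 or self.solo_copies < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.burst_age < 0:
            raise ValueError("burst_age must be non-negative")


@dataclass(frozen=True)
class SpeciesModel:
    species_id: str
    ploidy: int
    families: tuple[FamilyModel, ...]
    background_length: int
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self):
        if self.ploidy not in (2, 4, 6):
            raise ValueError("ploidy must be 2, 4 or 6")
        if self.substitution_rate <= 0:
            raise ValueError("substitution rate must be positive")
        object.__setattr__(self, "families", tuple(self.families))


@dataclass
class GenomeBuild:
    """One simulated haploid genome with its locus truth table.

    ``truth`` columns: master_id, start, end (0-based half-open), kind
    (intact | solo_ltr), age_years.
    """

    species_id: str
    sequence: str
    truth: pd.DataFrame = field(repr=False)


def kimura_event_probabilities(divergence: float, kappa: float) -> tuple[float, float]:
    """Finite-time K2P probabilities (P transition, Q total transversion).

    ``divergence`` is the expected number of substitutions per site
    (rate x time) along the branch; ``kappa`` the instantaneous
    transition/transversion rate ratio.
    """
    if divergence < 0:
        raise ValueError("divergence must be non-negative")
    # alpha + 2 beta = total rate; scale so that branch length = divergence
    alpha = divergence * kappa / (kappa + 2.0)
    beta = divergence / (kappa + 2.0)
    p = 0.25 - 0.5 * np.exp(-2.0 * (alpha + beta)) + 0.25 * np.exp(-4.0 * beta)
    q = 0.5 - 0.5 * np.exp(-4.0 * beta)
    return float(p), float(q)


def evolve_sequence(
    seq: str,
    age: float,
    rate: float = DEFAULT_SUBSTITUTION_RATE,
    kappa: float = DEFAULT_KAPPA,
    *,
    rng: np.random.Generator,
) -> str:
    """Evolve a sequence for ``age`` years under the K2P process."""
    if age < 0:
        raise ValueError("age must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    codes = encode(seq).copy()
    p, q = kimura_event_probabilities(rate * age, kappa)
    u = rng.random(codes.size)
    # transition: swap within purines (0<->1) or pyrimidines (2<->3)
    ts = u < p
    codes[ts] ^= 1
    # transversion: jump to the other chemical class, either target equally
    tv = (u >= p) & (u < p + q)
    if tv.any():
        tv_idx = np.flatnonzero(tv)
        codes[tv_idx] = (codes[tv_idx] + 2) % 4  # cross class, keep index parity
        flip = rng.random(tv_idx.size) < 0.5
        codes[tv_idx[flip]] ^= 1
    return decode(codes)


def evolve_copy(
    master: MasterElement,
    age: float,
    rate: float = DEFAULT_SUBSTITUTION_RATE,
    kappa: float = DEFAULT_KAPPA,
    seed: int | np.random.Generator = 0,
) -> str:
    """One diverged full-length copy of ``master`` inserted ``age`` years ago.

    The two LTRs are identical at insertion and diverge independently
    afterwards, as in real elements.
    """
    rng = np.random.default_rng(seed)
    return (
        evolve_sequence(master.ltr_seq, age, rate, kappa, rng=rng)
        + evolve_sequence(master.internal_seq, age, rate, kappa, rng=rng)
        + evolve_sequence(master.ltr_seq, age, rate, kappa, rng=rng)
    )


def build_genome(
    model: SpeciesModel,
    masters: dict[str, MasterElement],
    seed: int | np.random.Generator = 0,
) -> GenomeBuild:
    """Embed diverged intact copies and solo LTRs in random background DNA.

    Loci are placed without overlap at uniformly drawn insertion points of
    the background; neighbouring loci keep at least 1 bp of background
    between them. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    loci: list[tuple[str, str, str, float]] = []  # (master_id, seq, kind, age)
    for fam in model.families:
        master = masters[fam.master_id]
        for _ in range(fam.intact_copies):
            loci.append(
                (fam.master_id, evolve_copy(master, fam.burst_age,
                                            model.substitution_rate, model.kappa, rng),
                 "intact", fam.burst_age)
            )
        for _ in range(fam.solo_copies):
            loci.append(
                (fam.master_id,
                 evolve_sequence(master.ltr_seq, fam.burst_age,
                                 model.substitution_rate, model.kappa, rng=rng),
                 "solo_ltr", fam.burst_age)
            )
    if len(loci) > max(model.background_length - 1, 0):
        raise ValueError(
            f"{len(loci)} loci cannot be spaced >=1 bp apart in "
            f"{model.background_length} bp of background"
        )
    background = random_sequence(model.background_length, rng)
    order = rng.permutation(len(loci))
    points = np.sort(rng.choice(model.background_length - 1, size=len(loci),
                                replace=False) + 1) if loci else np.array([], dtype=int)
    parts: list[str] = []
    rows = []
    prev = 0
    offset = 0
    for k, pt in zip(order, points):
        master_id, seq, kind, age = loci[k]
        parts.append(background[prev:pt])
        offset += pt - prev
        rows.append((master_id, offset, offset + len(seq), kind, age))
        parts.append(seq)
        offset += len(seq)
        prev = pt
    parts.append(background[prev:])
    truth = pd.DataFrame(rows, columns=["master_id", "start", "end", "kind", "age_years"])
    return GenomeBuild(species_id=model.species_id, sequence="".join(parts), truth=truth)


@dataclass(frozen=True)
class Read:
    id: str
    seq: str


def sample_reads(
    genome: GenomeBuild | str,
    n_reads: int,
    read_length: int = DEFAULT_READ_LENGTH,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int | np.random.Generator = 0,
) -> list[Read]:
    """Sample uniform single-end reads from both strands.

    Start positions are uniform over valid offsets; each strand is drawn
    with probability 1/2; sequencing error is i.i.d. per-base substitution
    at ``error_rate``. Read ids record origin as ``<species>:<start>:<strand>:<i>``
    so truth-based checks can locate every read.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if isinstance(genome, GenomeBuild):
        sequence, label = genome.sequence, genome.species_id
    else:
        sequence, label = genome, "genome"
    if read_length > len(sequence):
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    codes = encode(sequence)
    starts = rng.integers(0, len(sequence) - read_length + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    reads: list[Read] = []
    for i in range(n_reads):
        s = int(starts[i])
        chunk = codes[s : s + read_length].copy()
        if error_rate > 0:
            err = rng.random(read_length) < error_rate
            if err.any():
                idx = np.flatnonzero(err)
                chunk[idx] = (chunk[idx] + rng.integers(1, 4, size=idx.size)) % 4
        seq = decode(chunk)
        strand = "+"
        if strands[i]:
            seq = revcomp(seq)
            strand = "-"
        reads.append(Read(f"{label}:{s}:{strand}:{i}", seq))
    return reads


def reads_for_ploidy(ploidy: int, reads_per_diploid: int = READS_PER_DIPLOID) -> int:
    """Read budget proportional to ploidy (1M per diploid by default)."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    return reads_per_diploid * ploidy // 2
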