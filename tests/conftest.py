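"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

import repeatome as rp


def semiglobal_cost_oracle(read: str, reference: str) -> int:
    """Independent unit-cost semi-global DP, both strands.

    Read is aligned globally, the reference locally (free start/end on
    the reference); mismatch, insertion and deletion each cost 1.
    Written directly from the recurrence so it can check the production
    aligner.
    """

    def one_strand(q: str, t: str) -> int:
        prev = [0] * (len(t) + 1)  # free start anywhere on the reference
        for i in range(1, len(q) + 1):
            cur = [i] + [0] * len(t)
            for j in range(1, len(t) + 1):
                sub = prev[j - 1] + (q[i - 1] != t[j - 1])
                cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
            prev = cur
        return min(prev)  # free end anywhere on the reference

    return min(one_strand(read, reference),
               one_strand(rp.revcomp(read), reference))


@pytest.fixture(scope="session")
def master():
    """A mid-sized Gypsy/Chromovirus-like master element."""
    return rp.random_master("chromo1", "Gypsy", "Chromovirus",
                            ltr_length=300, internal_length=1200,
                            rt_domain=(500, 590), seed=101)


@pytest.fixture(scope="session")
def two_family_build():
    """Two unrelated families embedded in background, with truth."""
    m1 = rp.random_master("famA", "Gypsy", "Chromovirus", 300, 1200, seed=11)
    m2 = rp.random_master("famB", "Copia", "Maximus/SIRE", 300, 1200, seed=12)
    masters = {"famA": m1, "famB": m2}
    model = rp.SpeciesModel(
        "SPX", 2,
        (rp.FamilyModel("famA", 6, 0, 1e6), rp.FamilyModel("famB", 3, 0, 1e6)),
        background_length=8000,
    )
    genome = rp.build_genome(model, masters, seed=13)
    return masters, model, genome


def rng_seeds(base: int, n: int) -> list[int]:
    """Deterministic seed list for replicate loops."""
    return [base + 1000 * i for i in range(n)]
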