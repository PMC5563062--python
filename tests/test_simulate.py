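"""Simulator: K2P divergence calibration, genome assembly, read sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import repeatome as rp
from repeatome.simulate import (encode, evolve_sequence,
                                kimura_event_probabilities, random_sequence)

RATE = 2e-8


def k2p_from_pair(a: str, b: str) -> float:
    """Direct P/Q counting between equal-length sequences."""
    ca, cb = encode(a), encode(b)
    differ = ca != cb
    ts = (differ & ((ca >> 1) == (cb >> 1))).mean()
    tv = (differ & ((ca >> 1) != (cb >> 1))).mean()
    return rp.k2p_distance(float(ts), float(tv))


class TestEvolve:
    def test_zero_age_returns_identical_copy(self, master):
        assert rp.evolve_copy(master, 0.0, seed=3) == master.sequence

    def test_negative_age_or_rate_rejected(self, master):
        with pytest.raises(ValueError):
            rp.evolve_copy(master, -1.0, seed=0)
        with pytest.raises(ValueError):
            rp.evolve_copy(master, 1e6, rate=0.0, seed=0)

    def test_divergence_matches_k2p_inversion(self):
        """Mean changed-site fraction at 6 MY equals the K2P expectation.

        A 10,000-site sequence evolved for 6 MY at r = 2e-8 has true
        distance K = 0.12; inverting the K2P model gives the expected
        proportion of changed sites P + Q.  100 replicates, 3 SE band.
        """
        seq = random_sequence(10_000, np.random.default_rng(1))
        base = encode(seq)
        p, q = kimura_event_probabilities(0.12, 2.0)
        rng = np.random.default_rng(2)
        fracs = [
            float((encode(evolve_sequence(seq, 6e6, RATE, rng=rng)) != base).mean())
            for _ in range(100)
        ]
        se = np.std(fracs, ddof=1) / 10
        assert abs(np.mean(fracs) - (p + q)) < 3 * se

    def test_sibling_copies_pairwise_distance_is_2rT(self):
        """Two copies evolved independently for T have mean K2P = 2rT."""
        seq = random_sequence(2_000, np.random.default_rng(3))
        rng = np.random.default_rng(4)
        ks = []
        for _ in range(100):
            a = evolve_sequence(seq, 6e6, RATE, rng=rng)
            b = evolve_sequence(seq, 6e6, RATE, rng=rng)
            ks.append(k2p_from_pair(a, b))
        se = np.std(ks, ddof=1) / 10
        assert abs(np.mean(ks) - 0.24) < 3 * se

    def test_kappa_sets_transition_transversion_balance(self):
        """Observed ts/tv counts follow the finite-time K2P ratio."""
        seq = random_sequence(50_000, np.random.default_rng(5))
        base = encode(seq)
        for kappa in (1.0, 2.0, 5.0):
            p, q = kimura_event_probabilities(0.2, kappa)
            out = encode(evolve_sequence(seq, 1e7, RATE, kappa,
                                         rng=np.random.default_rng(6)))
            differ = out != base
            ts = (differ & ((out >> 1) == (base >> 1))).sum()
            tv = (differ & ((out >> 1) != (base >> 1))).sum()
            assert ts / tv == pytest.approx(p / q, rel=0.15)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 2e7))
    def test_evolution_preserves_length_and_alphabet(self, seed, age):
        seq = random_sequence(200, np.random.default_rng(seed % 1000))
        out = evolve_sequence(seq, age, RATE, rng=np.random.default_rng(seed))
        assert len(out) == len(seq) and set(out) <= set("ACGT")


class TestMasterElement:
    def test_validation(self):
        with pytest.raises(ValueError):
            rp.random_master("x", "Gypsy", "l", ltr_length=50, internal_length=500)
        with pytest.raises(ValueError):
            rp.MasterElement("x", "Gypsy", "l", "A" * 100, "C" * 200, (150, 300))
        with pytest.raises(ValueError):
            rp.random_master("x", "NotAFamily", "l", 150, 500)

    def test_sequence_layout(self, master):
        assert master.sequence == master.ltr_seq + master.internal_seq + master.ltr_seq
        s, e = master.rt_domain
        assert master.rt_seq == master.internal_seq[s:e]


class TestBuildGenome:
    def test_truth_counts_match_model(self, master):
        model = rp.SpeciesModel("S", 2, (rp.FamilyModel("chromo1", 2, 1, 1e6),), 5000)
        g = rp.build_genome(model, {"chromo1": master}, seed=1)
        assert len(g.truth) == 3
        assert (g.truth["kind"] == "intact").sum() == 2
        assert (g.truth["kind"] == "solo_ltr").sum() == 1

    def test_truth_intervals_and_lengths(self, master):
        model = rp.SpeciesModel("S", 2, (rp.FamilyModel("chromo1", 3, 2, 1e6),), 6000)
        g = rp.build_genome(model, {"chromo1": master}, seed=2)
        L, I = len(master.ltr_seq), len(master.internal_seq)
        for row in g.truth.itertuples():
            assert 0 <= row.start < row.end <= len(g.sequence)
            expected = 2 * L + I if row.kind == "intact" else L
            assert row.end - row.start == expected
        assert len(g.sequence) == 6000 + 3 * (2 * L + I) + 2 * L

    def test_empty_model_gives_pure_background(self):
        model = rp.SpeciesModel("S", 2, (), 4000)
        g = rp.build_genome(model, {}, seed=3)
        assert len(g.sequence) == 4000 and g.truth.empty

    def test_same_seed_is_byte_identical(self, master):
        model = rp.SpeciesModel("S", 2, (rp.FamilyModel("chromo1", 2, 2, 1e6),), 5000)
        g1 = rp.build_genome(model, {"chromo1": master}, seed=7)
        g2 = rp.build_genome(model, {"chromo1": master}, seed=7)
        assert g1.sequence == g2.sequence
        assert g1.truth.equals(g2.truth)

    def test_overfull_genome_rejected(self, master):
        model = rp.SpeciesModel("S", 2, (rp.FamilyModel("chromo1", 0, 50, 1e6),), 30)
        with pytest.raises(ValueError, match="background"):
            rp.build_genome(model, {"chromo1": master}, seed=0)


class TestSampleReads:
    def test_error_free_reads_are_genome_substrings(self, master):
        model = rp.SpeciesModel("S", 2, (rp.FamilyModel("chromo1", 3, 0, 0.0),), 3000)
        g = rp.build_genome(model, {"chromo1": master}, seed=5)
        reads = rp.sample_reads(g, 300, error_rate=0.0, seed=6)
        assert len(reads) == 300
        for r in reads:
            assert r.seq in g.sequence or rp.revcomp(r.seq) in g.sequence

    def test_family_fraction_matches_binomial_expectation(self, two_family_build):
        """Reads fully inside famA loci occur at the edge-adjusted rate."""
        _, _, genome = two_family_build
        n = 10_000
        reads = rp.sample_reads(genome, n, error_rate=0.0, seed=21)
        fam_a = genome.truth[genome.truth["master_id"] == "famA"]
        inside = 0
        for r in reads:
            start = int(r.id.split(":")[1])
            inside += bool(((fam_a["start"] <= start)
                            & (start + 90 <= fam_a["end"])).any())
        span = (fam_a["end"] - fam_a["start"] - 89).sum()
        p = span / (len(genome.sequence) - 89)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(inside / n - p) < 3 * se

    def test_ploidy_proportional_read_budget(self):
        assert rp.reads_for_ploidy(2) == 1_000_000
        assert rp.reads_for_ploidy(4) == 2_000_000
        assert rp.reads_for_ploidy(6) == 3_000_000

    def test_bad_inputs_rejected(self, master):
        model = rp.SpeciesModel("S", 2, (), 1000)
        g = rp.build_genome(model, {}, seed=0)
        with pytest.raises(ValueError):
            rp.sample_reads(g, 0, seed=1)
        with pytest.raises(ValueError):
            rp.sample_reads(g, 10, read_length=2000, seed=1)

    def test_error_rate_injects_substitutions(self):
        genome = rp.GenomeBuild("S", "ACGT" * 5000, __import__("pandas").DataFrame())
        reads = rp.sample_reads(genome, 500, error_rate=0.05, seed=9)
        mismatched = sum(
            r.seq not in genome.sequence and rp.revcomp(r.seq) not in genome.sequence
            for r in reads
        )
        # P(read has >=1 error) = 1 - 0.95^90 ~ 0.99
        assert mismatched > 450
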