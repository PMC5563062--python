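"""Read mapper: DP-oracle equivalence, stringency gates, coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import repeatome as rp
from repeatome.mapping import TIERS, max_cost_for_similarity, passes
from repeatome.simulate import random_sequence

from .conftest import semiglobal_cost_oracle

SEQ = st.text(alphabet="ACGT", min_size=5, max_size=30)
REF = st.text(alphabet="ACGT", min_size=10, max_size=60)


class TestAlignRead:
    def test_exact_substring(self, master):
        ref = master.sequence
        aln = rp.align_read(ref[100:190], ref)
        assert (aln.cost, aln.identity, aln.aligned_fraction) == (0, 1.0, 1.0)
        assert (aln.ref_start, aln.ref_end, aln.strand) == (100, 190, "+")

    def test_reverse_complement_maps_minus_strand(self, master):
        ref = master.sequence
        aln = rp.align_read(rp.revcomp(ref[100:190]), ref)
        assert aln.identity == 1.0 and aln.strand == "-"
        assert (aln.ref_start, aln.ref_end) == (100, 190)

    def test_ten_substitutions_pass_medium_not_high(self, master):
        """90-nt read with 10 spread substitutions: identity 80/90."""
        ref = master.sequence
        window = list(ref[300:390])
        for i in range(10):  # spaced transitions keep the diagonal optimal
            p = 4 + 9 * i
            window[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[window[p]]
        aln = rp.align_read("".join(window), ref)
        assert aln.cost == 10
        assert aln.identity == pytest.approx(80 / 90)
        assert not passes(aln, TIERS["high"])
        assert passes(aln, TIERS["medium"])

    def test_n_bases_never_match(self):
        aln = rp.align_read("NNNN", "NNNNNNNN")
        assert aln.identity == 0.0
        with pytest.raises(ValueError):
            rp.align_read("", "ACGT")
        with pytest.raises(ValueError):
            rp.align_read("ACGT", "")
        with pytest.raises(ValueError):
            rp.align_read("ACGU", "ACGT")

    @settings(deadline=None, max_examples=120)
    @given(SEQ, REF)
    def test_cost_equals_dp_oracle(self, read, ref):
        aln = rp.align_read(read, ref)
        assert aln.cost == semiglobal_cost_oracle(read, ref)

    @settings(deadline=None, max_examples=60)
    @given(SEQ, REF)
    def test_max_cost_pruning_is_exact(self, read, ref):
        """Pruned alignment agrees with the full one below the bound."""
        full = rp.align_read(read, ref)
        for s in (0.9, 0.7, 0.5):
            k = max_cost_for_similarity(len(read), s)
            pruned = rp.align_read(read, ref, max_cost=k)
            if full.cost <= k:
                assert pruned is not None and pruned.cost == full.cost
            elif pruned is not None:  # pruning may keep it, never passes gate
                assert pruned.identity < s


@pytest.fixture(scope="module")
def mapped_tiers(two_family_build):
    masters, _, genome = two_family_build
    reads = rp.sample_reads(genome, 1500, error_rate=0.0, seed=31)
    refs = {mid: m.sequence for mid, m in masters.items()}
    return reads, {t: rp.map_reads(reads, refs, t, seed=32) for t in TIERS}


class TestMapReads:

    def test_tier_nesting_counts_and_subsets(self, mapped_tiers):
        _, results = mapped_tiers
        assert (results["high"].n_mapped <= results["medium"].n_mapped
                <= results["low"].n_mapped)
        assert results["high"].mapped_ids() <= results["medium"].mapped_ids()
        assert results["medium"].mapped_ids() <= results["low"].mapped_ids()
        for res in results.values():
            counts = res.mapped_counts()
            assert counts.sum() == res.n_mapped

    def test_conservation_of_reads(self, mapped_tiers):
        reads, results = mapped_tiers
        for res in results.values():
            assert res.n_mapped + res.n_unmapped == len(reads)

    def test_reads_inside_loci_map_to_their_family(self, two_family_build):
        """Error-free reads fully inside famA loci map to famA at high tier."""
        masters, _, genome = two_family_build
        reads = rp.sample_reads(genome, 2000, error_rate=0.0, seed=33)
        refs = {mid: m.sequence for mid, m in masters.items()}
        res = rp.map_reads(reads, refs, "high", seed=34)
        table = res.table.set_index("read_id")
        fam_a = genome.truth[genome.truth["master_id"] == "famA"]
        inside = [r.id for r in reads
                  if ((fam_a["start"] <= int(r.id.split(":")[1]))
                      & (int(r.id.split(":")[1]) + 90 <= fam_a["end"])).any()]
        assert inside
        hits = table.loc[inside, "ref_id"]
        assert (hits == "famA").mean() >= 0.99

    def test_random_reads_never_map_at_high(self):
        rng = np.random.default_rng(35)
        ref = {"r": random_sequence(1000, rng)}
        reads = [rp.Read(f"q{i}", random_sequence(90, rng)) for i in range(50)]
        assert rp.map_reads(reads, ref, "high", seed=0).n_mapped == 0

    def test_reference_id_tie_break(self):
        seq = random_sequence(200, np.random.default_rng(36))
        read = rp.Read("q", seq[50:140])
        res = rp.map_reads([read], {"zzz": seq, "aaa": seq}, "high", seed=0)
        assert res.table.loc[0, "ref_id"] == "aaa"

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            rp.map_reads([rp.Read("q", "ACGT" * 25)], {}, "high")


class TestCoverage:
    def test_single_read_unit_depth(self):
        ref = random_sequence(300, np.random.default_rng(40))
        res = rp.map_reads([rp.Read("q", ref[100:190])], {"r": ref}, "high", seed=0)
        cov = rp.compute_coverage(res, "r")
        assert cov.depth[100:190].tolist() == [1.0] * 90
        assert cov.depth.sum() == 90

    def test_stacked_identical_reads(self):
        ref = random_sequence(300, np.random.default_rng(41))
        reads = [rp.Read(f"q{i}", ref[50:140]) for i in range(7)]
        cov = rp.compute_coverage(rp.map_reads(reads, {"r": ref}, "high", seed=0), "r")
        assert cov.mean_depth((50, 140)) == 7.0
        assert cov.depth.max() == 7.0

    def test_depth_sums_to_aligned_span(self, two_family_build):
        masters, _, genome = two_family_build
        reads = rp.sample_reads(genome, 800, error_rate=0.0, seed=42)
        res = rp.map_reads(reads, {"famA": masters["famA"].sequence}, "high", seed=43)
        cov = rp.compute_coverage(res, "famA")
        hits = res.table.dropna(subset=["ref_id"])
        assert cov.depth.sum() == (hits["ref_end"] - hits["ref_start"]).sum()

    def test_uniform_sampling_recovers_mean_depth(self):
        """~50x uniform sampling of a lone reference lands within 10%."""
        ref = random_sequence(2000, np.random.default_rng(44))
        genome = rp.GenomeBuild("S", ref, __import__("pandas").DataFrame())
        n = int(50 * 2000 / 90)
        reads = rp.sample_reads(genome, n, error_rate=0.0, seed=45)
        cov = rp.compute_coverage(rp.map_reads(reads, {"r": ref}, "high", seed=46), "r")
        assert cov.mean_depth((200, 1800)) == pytest.approx(50.0, rel=0.10)

    def test_unknown_reference_rejected(self):
        ref = random_sequence(200, np.random.default_rng(47))
        res = rp.map_reads([rp.Read("q", ref[:90])], {"r": ref}, "high", seed=0)
        with pytest.raises(KeyError):
            rp.compute_coverage(res, "nope")
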