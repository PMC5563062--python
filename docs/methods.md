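# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that required judgement.

## Substitution model and the simulator

Sequence divergence is modelled as a Kimura two-parameter (K2P) process:
each site evolves independently with total substitution rate *r*
(substitutions/site/year) split between transitions and transversions by
the instantaneous rate ratio κ = α/β (α transitions; two transversion
channels at β each, so r = α + 2β). The simulator draws site outcomes
from the **exact finite-time transition probabilities**

    P(t) = ¼ − ½ e^(−2(α+β)t) + ¼ e^(−4βt)      (transitions)
    Q(t) = ½ − ½ e^(−4βt)                        (transversions, both channels)

so multiple hits are modelled and the K2P distance estimator
K = −½ ln[(1 − 2P̂ − Q̂)√(1 − 2Q̂)] recovers r·t without bias. Two
copies evolved independently for T years are separated by 2rT.

Defaults: r = 2×10⁻⁸ subs/site/year — the rate used for retroelement
dating in sunflowers, twice the host-gene rate because reverse
transcription is itself error-prone; it is a configuration value, not a
constant. κ = 2.0, a common empirical default for plant nuclear DNA;
no sunflower-specific estimate was available, and κ only affects the
transition/transversion split, not the total divergence.

Genome assembly: intact elements are embedded as LTR + internal + LTR
(the two LTRs identical at insertion, diverging independently
afterwards), solo LTRs as a single LTR evolved for the same burst age
(the recombination event itself is not dated). Background DNA is
i.i.d. uniform; loci are placed without overlap at uniformly drawn
insertion points with ≥ 1 bp spacing. Reads are single-end, fixed
length (90 nt), uniform in position and strand, with i.i.d. substitution
errors (default 0.1%, no indels); read budgets are proportional to
ploidy (1,000,000 per diploid under the comparative design; tests and
the demo scale this down to 10³–10⁴ per species).

What the generator does **not** emulate: nested insertions, target-site
duplications, LTR–LTR recombination mechanics, indel mutation, GC bias,
paired ends, organellar contamination, or a spread of insertion times
within one burst (a burst is a point age). Passing recovery tests
therefore demonstrate correctness of the statistics under a clean
substitution-only model, not robustness to every artefact of real
libraries; the mapper's indel handling is exercised separately with its
own oracle tests.

## Read mapping

The alignment model is unit-cost semi-global: the whole read against any
window of the reference, mismatch = insertion = deletion = 1, both
strands, minimum cost wins. The DP itself is delegated to edlib (exact
Levenshtein, query-global/target-local mode); an O(nm) reference DP in
the test suite verifies costs on random short pairs. Gates:
identity = matches / alignment columns ≥ s, and aligned fraction =
read bases aligned to reference bases / read length ≥ f. The published
stringency tiers set (s, f) to (0.9, 0.9) / (0.7, 0.7) / (0.5, 0.5);
their acceptance regions are nested by construction. A provable pruning
bound (cost ≤ R(1−s)/s, from columns = R + deletions) lets a k-bounded
distance pass skip hopeless read/reference pairs exactly.

Each read is assigned to at most one reference — genome proportions must
sum across disjoint clusters. Ties across references are broken by
identity, then aligned fraction, then lexicographically smallest
reference id (deterministic and seed-free). Ties **within** a reference
(co-optimal placements, e.g. two identical LTR copies) are broken by a
seeded uniform draw: this mirrors the random placement of mainstream
mappers and is what makes the "3′-LTR retained" control behave (below).
N bases never match anything, including other Ns.

Coverage is per-reference-position depth of the placed read spans; mean
depth over an interval includes zero-depth positions.

## Solo-LTR statistic

The mapping reference for each element is 5′-LTR + internal region with
the 3′-LTR **excluded**, so reads from either LTR collapse onto the
single retained copy. For n intact and m solo copies the expected
depth ratio LTR/internal is then (2n + m)/n = 2 + m/n; with the 3′-LTR
retained, reads split between the two identical LTR copies and the
intact-element ratio collapses to ~1 — a dedicated test documents this
convention. Ratios are mean per-base depths; the ratio is undefined
(flagged, not numeric) when the internal region has zero coverage.
Mapping uses the high tier by default, consistent with abundance
profiling. The ratio–genome-size association is tested with Spearman's
rank correlation and a seeded two-sided permutation p-value (default
10,000 permutations): a rank-based test because the ratios are bounded
below, heavy-tailed above, and few species are available.

Element-edge effects matter at read scale: positions within one read
length of an unmappable junction (locus/background boundaries, the
internal→3′-LTR junction) lose coverage, biasing the ratio downward by
roughly (R−1)/(2L) per blocked flank. The recovery experiments
therefore use LTRs long relative to the read (1.5 kb vs 90 nt, typical
for Chromovirus elements), keeping the bias within a few percent; with
150-bp LTRs (as in the fast demo config) the intact-element ratio sits
nearer 1.3 than 2 — this is a property of coverage at read scale, not a
defect of the statistic.

## Conservation index

CI = N_medium / N_high per lineage and species, where N_tier counts
reads mapped to that lineage's RT-domain reference at the tier. CI ≥ 1
always (nested gates); CI ≈ 1 means element copies are within ~10% of
their reference (recent amplification), larger values mean the high gate
is losing diverged reads (older proliferation). CI is comparative, not
an absolute clock; both the raw counts and the index are reported.

## Burst dating

Reads homologous to a read-scale (90-nt) RT-domain window are harvested
at the medium tier — the high tier would discard everything older than
~5 MY (a 10-MYA burst leaves reads at ~82% identity) — and must cover
≥ 93% of the window, which keeps pairwise overlaps long. Harvested
reads are **gated** by the semi-global aligner but **profiled** by
ungapped maximum-score placement: minimum-edit-cost alignments absorb
clustered substitutions into spurious indel pairs, silently deleting the
most diverged bases and deflating K (measured: mean K 0.223 vs truth
0.254 at 2rT = 0.24); ungapped placement keeps every substitution
visible and is exact under the no-indel read model. A seeded subsample
cap (default 500 reads) bounds the quadratic pairwise stage.

Pairs overlapping ≥ 30 aligned sites contribute P̂, Q̂ and K over their
overlap; gap/N positions are excluded; saturated pairs (log arguments
≤ 0) are dropped and counted. Ages T = K/(2r) are binned at 0.5 MY.

**Apex location.** With ≤ 90-site overlaps, per-pair K estimates lie on
a coarse lattice of (transition, transversion) counts and their density
is right-skewed, so the raw modal 0.5-MY bin systematically undershoots
a point burst by one to two bins — this holds even for the exact
sampling distribution of the estimator, independent of simulation. The
apex is therefore located as the percent-weighted centroid of the bins
inside the half-maximum band of the main peak (after a 3-bin moving
average): a standard lattice- and skew-robust peak locator that recovers
planted bursts at 2/6/10 MYA to within half a bin. The raw modal bin is
still reported alongside. Secondary peaks — local maxima outside the
main band exceeding half the apex height — flag additional amplification
waves (e.g. a recent wave of identical copies appears as a 0-MYA peak).

Problem sizes: the recovery experiments use bursts of 100 copies (200 at
10 MYA, where per-pair variance is largest), 200 harvested RT reads
(19,900 pairs), and compact element geometry (150-bp LTRs, 400-bp
internal, 90-nt RT window) — the dating statistic only sees the RT
window, so element size does not affect it.

## Profile clustering

Species profiles are row-normalized (relative composition), compared by
Euclidean distance and clustered with average linkage (UPGMA). The
source analysis named neither distance nor linkage; these defaults are
recorded in the output metadata so alternatives remain comparable.
Support is an ordinary column bootstrap (default 1,000 replicates,
seeded): each internal node scores the fraction of replicate trees
containing its exact leaf set; the root scores 1 by construction.
These supports are comparable in rank, but not calibrated like
multiscale-bootstrap p-values. Repeat-cluster grouping cuts the UPGMA
tree at a configurable fraction (default 0.5) of the maximum merge
height; the resulting group count is an outcome, not a constraint.

## Degenerate inputs and numerical conventions

Coordinates are 0-based half-open everywhere. Zero internal coverage,
zero high-tier counts, all-zero variation rows, constant correlation
vectors and saturated pairs are flagged or rejected rather than silently
propagated as infinities. Genome proportions use the species' total
read count as denominator (not the mapped count), so per-species GPs sum
to the repetitive fraction. Internal values are kept unrounded;
rounding (1 d.p. for repetitive fractions, 2 d.p. for ratio tables)
happens only at report time. All stochastic stages consume a single
root seed fanned out through fixed-position seed sequences; reruns are
byte-identical.

## Known limitations

- Best-hit assignment differs from mappers that place multi-hit reads
  randomly across references; abundance estimates on real data may
  shift marginally for families with near-identical clusters.
- The coverage ratio cannot distinguish solo-LTR accumulation from
  internal-region deletions of other origin, and its expectation bends
  below 2 + m/n when LTRs are short relative to the read.
- Burst dating assumes one dominant amplification wave per lineage per
  species; heavily multimodal histories blur the half-height band.
- The bundled survey tables are printed (rounded) values; statistics
  recomputed from them match the published numbers to rounding, not
  exactly (e.g. the maximum-percentage-variation entry reproduces to
  within ±0.02 of the value printed from unrounded inputs).
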