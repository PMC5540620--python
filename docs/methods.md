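# Methods

`seqbias` detects and corrects position-specific nucleotide bias in aligned
short-read data (DNase-seq, ATAC-seq, FAIRE-seq, ChIP-seq and similar
assays). The observable being corrected is the distortion of k-mer
frequencies at fixed offsets relative to read 5' ends — the footprint of
enzymatic cut preference, fragmentation chemistry and adapter ligation —
without erasing genuine assay-level composition trends such as elevated GC
content in open chromatin.

## Model

**Bias signature.** For every offset t in [-u, n+d] relative to each read's
5' end (defaults u = d = 20; n = modal read length), the relative frequency
f^t(m) of each k-mer m in the *reference* context at that offset is
computed, reverse-complemented for minus-strand reads so that offset 0 is
always the 5'-most (cut-site) base. Reference context is used so that bias
flanking the read boundaries is captured; with error-free synthetic reads
the in-body signature computed from read sequences is identical (this is a
tested invariant). Default k = 5; each +1 in k costs a factor ~4 in the
reads needed for equally confident frequency estimates, and the CLI warns
when the read count is clearly underpowered for the chosen k.

**Baseline.** The position-free expectation b(m) is accumulated from
pseudo-reads: for each read with start A and length n, m_r pseudo 5' sites
are placed uniformly in [A - 25, A + n + 25), where m_r is the number of
reads starting in that window. Sampling intensity therefore grows with
local read density, so the baseline reflects the composition of the
enriched regions that actually carry the data, and isolated (possibly
spurious) reads contribute little. Pseudo-reads inherit the parent read's
strand and contribute the reference k-mer at their 5' site.

**Tiles and flagging.** Offsets are partitioned into abutting k-wide tiles
anchored so tile 0 starts at offset 0 (tile -1 ends at offset -1; the two
straddle the cut). A tile's average nucleotide variance (anv) is the mean,
over A/C/G/T, of the population variance of that nucleotide's frequency
across the tile's k positions, with the per-position frequencies
marginalized from the tile's own k-mer table. A tile is biased when its anv
exceeds the null mean by more than two null standard deviations.

**Null calibration.** The anv of an unbiased tile is not zero — it is a
sampling quantity whose scale depends on read depth *and* on read stacking
(reads sharing a cut site carry identical context at every offset). Both
nulls are therefore estimated by Monte-Carlo from 200 pseudo-tile
replicates: in each replicate every distinct cut site draws one uniform
pseudo-offset in its baseline window and all reads stacked there inherit
the same k-mer. The same replicates yield the null for the tile-pair
covariance statistic, using the k-mer pairs at spacing k (abutting
windows), which preserves genuine genomic correlation between adjacent
windows. An i.i.d.-read null underestimates both scales severely on
stacked data; this was the single largest calibration hazard found during
development.

**Covariance grouping.** For two biased tiles, each distinct cut site
(duplicated reads carry no independent information about tile-to-tile
dependence and would couple the two vectors) contributes the pair
(f^A(m_A), f^B(m_B)) of signature frequencies of its own k-mers; the
statistic is their Pearson correlation. The frequencies are
leave-one-site-out — the site's own read stack is subtracted from its
k-mer's count before normalizing — because self-counting inflates both
lookups of a site jointly and otherwise reads as covariance between any
pair of tiles. Two caveats are inherent to the statistic: sites are
observed only when selected, so two tiles with strong but *independent*
preferences acquire a mildly negative correlation (conditioning on
selection), which the positive merge threshold ignores by construction;
and tiles driven by one positively-correlated source remain strongly
positive and merge as intended. Biased tiles are clustered by
greedy average-linkage merging while the best inter-group average
correlation exceeds the null mean + 2 SD, with ties broken toward smaller
tile indices so the partition is deterministic and input-order invariant.
Tiles in one group are treated as reflections of a single bias source.

**Weights.** The tile weight at a genomic 5' site is
(b(m) + p) / (f^t(m) + p) with the pseudocount p (default 0.5) applied to
*counts* before normalization, clamped to [0.01, 100]. Within a group tile
weights are averaged; across groups they are multiplied; the product is the
sequence weight of the site. Each read's weight is its sequence weight
divided by the mean sequence weight of 20 flanking candidate start sites on
its strand, so that stable local composition (e.g. GC) does not masquerade
as bias. Weights are written to the output BAM as the float tag `XW`, and
can alternatively be materialized as integer read copies (floor plus
stochastic rounding of the fractional part) for downstream tools that
cannot consume weights.

### Normalization window

The flanking sites for the normalizer start just beyond the span of the
biased tiles (shifts ±span .. span+9; ±10..19 for the default DNase-like
geometry where tiles -1 and 0 are biased), rather than at ±1. A shift
smaller than the tile span makes the neighbor's tile windows overlap the
read's own, so the read's bias motif leaks into its own normalizer and
partially cancels the correction: measured on the default synthetic
fixture, post-correction anv at flagged tiles was 0.4-2.4x the selection
threshold with ±1..10 shifts versus 0.1-0.6x with the non-overlapping
window. The denominator divides by the number of shifts actually
resolvable, so chromosome edges degrade gracefully. The normalizer
averages over unselected loci while reads preferentially sample
high-multiplier (low-weight) sites, so the raw normalized weights carry an
arbitrary overall scale; since every downstream use (weighted frequencies,
coverage ratios, pileups) is scale-invariant, the reported weights are
rescaled so the corrected reads sum to the raw read count, making `XW`
directly interpretable as a fractional read count. Reads with no
resolvable context keep weight exactly 1 and are counted in the log.

## Synthetic data

The simulator generates (i) an i.i.d. reference of requested GC content (or
a blockwise GC gradient), (ii) non-overlapping enriched regions placed
uniformly, and (iii) reads drawn i.i.d. from candidate 5' sites within
regions, with each site's probability proportional to a cut-preference
multiplier evaluated on the reference motif at a fixed anchor offset. Bias
acts purely on *site selection* — which is how enzymatic preference
operates — so simulated reads match the reference exactly and every site's
true probability is recorded for recovery tests.

Default conditions: 1 Mb reference at GC 0.5, 40 regions of 1-5 kb,
2×10^5 reads of 36 bp, and a hexamer preference anchored at -3 (straddling
the cut, DNase-like; a 9-mer anchored at -4 emulates the symmetric Tn5
geometry). Multipliers are built from independent per-position energies
e_i(a) ~ N(0, sigma^2/6) with sigma = 1, giving log-normal per-motif
multipliers. The position-additive structure matters: a preference drawn
independently per motif leaves every positional nucleotide marginal flat
and is invisible in principle to any marginal k-mer statistic, whereas
measured enzyme preferences are position-additive to first order.

What the generator does not emulate: sequencing errors, PCR duplicates as
a distinct process (stacking arises naturally from discrete site
multinomials), paired-end fragment-size structure, mappability gaps, and
chromatin occupancy. Passing tests therefore demonstrate correct recovery
of site-selection bias under clean alignment, not robustness to those
artifacts.

A note on the GC-preservation measurement: when a randomly drawn
preference happens to carry a net GC loading, the raw reads over-sample
GC-rich start sites and the correction rightly removes that inflation, so
the weighted read GC can move by around a percent even though the regional
GC gradient itself is preserved by the normalizer. The measurement
therefore mixes trend preservation (what it is meant to show) with
legitimate bias removal, and its size varies with the drawn preference.

## Numerical choices

- Coordinates are 0-based half-open internally; SAM's 1-based positions are
  converted at the I/O boundary. k-mer ids are base-4 with the 5'-most base
  most significant, so numeric order is lexicographic.
- Any context window containing N is skipped at that offset; per-offset
  denominators vary accordingly. Reads of non-modal length contribute only
  to offsets they cover.
- Flagging and merging use strict inequalities, so a zero-variance
  degenerate null never flags a tile at exactly the mean.
- Greedy merging tie-breaks toward the smallest tile index; model
  directories serialize frequencies with 17 significant digits so reruns
  are byte-identical.
- With pseudocount 0 the weighting is exactly conservative (the mean
  per-tile weight over reads is 1, since sum over k-mers of f·(b/f) = 1)
  and single-tile correction reproduces the baseline frequencies exactly;
  both identities are asserted to 1e-9 in the tests.

## Problem sizes used in tests

Unit tests run on 100-200 kb references with 20-50k reads; the end-to-end
property tests (flattening across 20 replicates, null calibration across 20
replicates, parameter recovery, GC preservation, naked-DNA profile
smoothing) run at the default 1 Mb / 2×10^5-read conditions. The
acceptance script averages the replicated quantities over 5 replicates at
the same conditions.

## Known limitations

- The covariance statistic is estimated per distinct cut site; extremely
  shallow data (few distinct sites) will produce a noisy grouping.
- Group-averaged weights under-correct when two tiles are merged whose
  biases are not actually redundant; the calibrated covariance null makes
  such merges rare, but a bias source genuinely split across tiles with
  strongly correlated halves will be corrected only approximately.
- The method corrects representation, not base calls; sequencing errors in
  reads are out of scope by design.
- Heterogeneous read lengths are handled by anchoring the signature on the
  modal length; data mixing very different lengths should be corrected per
  run instead.
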