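import numpy as np
import pytest

import seqbias as sb
from seqbias.bias_signature import kmer_id, kmer_string
from seqbias.model_io import WeightedRead, revcomp

from conftest import make_reads, rec


class TestFivePrimeContext:
    def test_plus_strand_definition(self, toy_genome):
        r = rec(start=2, length=8, strand="+")
        assert sb.five_prime_context(r, toy_genome, 0, 5) == toy_genome.sequence("chr1", 2, 7)

    def test_minus_strand_hand_checked(self):
        # genome written out on both strands by hand:
        #   + : A C G T A C G T A C    (positions 0-9)
        #   - : T G C A T G C A T G    (3' <- 5')
        g = sb.GenomeSequence({"chr1": "ACGTACGTAC"})
        r = rec(start=3, length=5, strand="-")  # covers 3..7, 5' end at 7
        assert r.five_prime == 7
        # first 3 bases read 5'->3' on the minus strand: compl(T,G,C) = A,C,G
        assert sb.five_prime_context(r, g, 0, 3) == "ACG"
        assert sb.five_prime_context(r, g, 0, 3) == revcomp(g.sequence("chr1", 5, 8))
        assert sb.five_prime_context(r, g, 2, 3) == revcomp(g.sequence("chr1", 3, 6))
        # upstream of the minus-strand 5' end moves right on the genome
        assert sb.five_prime_context(r, g, -2, 2) == revcomp(g.sequence("chr1", 8, 10))

    def test_out_of_bounds_and_n(self):
        g = sb.GenomeSequence({"chr1": "ACGTNACGTACG"})
        r = rec(start=2, length=5)
        assert sb.five_prime_context(r, g, -5, 3) is None
        assert sb.five_prime_context(r, g, 1, 3) is None  # window holds the N
        with pytest.raises(KeyError):
            sb.five_prime_context(rec(chrom="chrX"), g, 0, 3)


def naive_signature(records, genome, k, upstream, downstream, n):
    """Independent string-scan oracle for the signature."""
    table = {}
    for t in range(-upstream, n + downstream + 1):
        counts = {}
        total = 0
        for r in records:
            if t > r.length + downstream:
                continue
            ctx = sb.five_prime_context(r, genome, t, k)
            if ctx is None:
                continue
            counts[ctx] = counts.get(ctx, 0) + 1
            total += 1
        if total:
            table[t] = {m: c / total for m, c in counts.items()}
    return table


class TestComputeSignature:
    def test_single_read_k1(self):
        g = sb.GenomeSequence({"chr1": "AAAAACGTAAAA"})
        reads = make_reads([rec(start=5, length=3)])
        sig = sb.compute_signature(reads, g, k=1, upstream=2, downstream=2)
        assert sig.frequency(0, "C") == 1.0
        assert sig.frequency(1, "G") == 1.0
        assert sig.frequency(2, "T") == 1.0

    def test_two_reads_split(self):
        g = sb.GenomeSequence({"chr1": "AC" + "A" * 20 + "AG" + "A" * 20})
        reads = make_reads(
            [rec(start=0, length=2, read_id="a"), rec(start=22, length=2, read_id="b")]
        )
        sig = sb.compute_signature(reads, g, k=2, upstream=0, downstream=0)
        assert sig.frequency(0, "AC") == 0.5
        assert sig.frequency(0, "AG") == 0.5

    def test_matches_naive_oracle_exactly(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=300))
        g = sb.GenomeSequence({"chr1": seq})
        records = [
            rec(
                start=int(rng.integers(0, 260)),
                length=20,
                strand="+-"[rng.integers(2)],
                read_id=f"r{i}",
            )
            for i in range(50)
        ]
        k, up, down = 3, 6, 6
        sig = sb.compute_signature(make_reads(records), g, k, up, down)
        oracle = naive_signature(records, g, k, up, down, 20)
        for t, freqs in oracle.items():
            for kmer, f in freqs.items():
                assert sig.frequency(t, kmer) == pytest.approx(f, abs=1e-12)
        # offsets absent from the oracle are unpopulated in the signature too
        for t in range(-up, 20 + down + 1):
            assert sig.has_offset(t) == (t in oracle)

    def test_frequencies_normalized_per_offset(self, small_biased_experiment):
        sig = small_biased_experiment["model"].signature
        for i, t in enumerate(sig.offsets):
            if sig.evaluated[i] > 0:
                assert sig.freq_row(int(t)).sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_reads_near_expected_kmer_freq(self):
        # uniform i.i.d. genome: every k-mer frequency within 5 binomial SE of 4^-k
        g = sb.generate_reference(100_000, 0.5, seed=5)
        rng = np.random.default_rng(6)
        n = 10_000
        records = [
            rec(start=int(s), length=30, read_id=f"r{i}")
            for i, s in enumerate(rng.integers(50, 99_000, n))
        ]
        sig = sb.compute_signature(make_reads(records), g, k=2, upstream=2, downstream=2)
        p = 1 / 16
        se = np.sqrt(p * (1 - p) / n)
        for t in (-2, 0, 10):
            assert np.all(np.abs(sig.freq_row(t) - p) < 5 * se + 1e-12)

    def test_empty_fatal(self, toy_genome):
        with pytest.raises(ValueError):
            sb.compute_signature(make_reads([]), toy_genome, k=1)


class TestWeightedSignature:
    def test_unit_weights_reduce_to_plain(self, small_biased_experiment):
        reads = small_biased_experiment["reads"]
        g = small_biased_experiment["genome"]
        plain = sb.compute_signature(reads, g, k=3, upstream=5, downstream=5)
        w = sb.weighted_signature(reads, g, k=3, upstream=5, downstream=5,
                                  weights=np.ones(reads.total_count))
        assert np.array_equal(plain.counts, w.counts)

    def test_weighted_mean(self):
        g = sb.GenomeSequence({"chr1": "A" + "T" * 20 + "C" + "T" * 20})
        wr = [
            WeightedRead(rec(start=0, length=1, read_id="a"), 3.0),
            WeightedRead(rec(start=21, length=1, read_id="b"), 1.0),
        ]
        sig = sb.weighted_signature(wr, g, k=1, upstream=0, downstream=0)
        assert sig.frequency(0, "A") == pytest.approx(0.75)

    def test_rejects_nonpositive_weights(self, small_biased_experiment):
        reads = small_biased_experiment["reads"]
        g = small_biased_experiment["genome"]
        w = np.ones(reads.total_count)
        w[0] = 0.0
        with pytest.raises(ValueError):
            sb.weighted_signature(reads, g, weights=w)


class TestSampleBaseline:
    def test_isolated_read_all_a(self):
        g = sb.GenomeSequence({"chr1": "A" * 2000})
        reads = make_reads([rec(start=1000, length=36)])
        base = sb.sample_baseline(reads, g, k=5, seed=1)
        assert base.frequency("AAAAA") == 1.0

    def test_density_weighted_sampling_4_to_1(self):
        # two stacked reads (m_r = 2 each -> 4 pseudo-reads) vs one isolated
        # read (1 pseudo-read); distinguishable via per-chromosome alphabet
        g = sb.GenomeSequence({"chr1": "A" * 2000, "chr2": "C" * 2000})
        reads = make_reads(
            [
                rec(chrom="chr1", start=1000, length=36, read_id="s1"),
                rec(chrom="chr1", start=1000, length=36, read_id="s2"),
                rec(chrom="chr2", start=1000, length=36, read_id="i1"),
            ]
        )
        base = sb.sample_baseline(reads, g, k=5, seed=3)
        assert base.counts[kmer_id("AAAAA")] == 4
        assert base.counts[kmer_id("CCCCC")] == 1

    def test_deterministic_given_seed(self, small_biased_experiment):
        reads = small_biased_experiment["reads"]
        g = small_biased_experiment["genome"]
        b1 = sb.sample_baseline(reads, g, k=3, seed=11, null_replicates=20)
        b2 = sb.sample_baseline(reads, g, k=3, seed=11, null_replicates=20)
        assert np.array_equal(b1.counts, b2.counts)
        assert b1.null_tile_anv_mean == b2.null_tile_anv_mean
        assert b1.null_tile_cov_sd == b2.null_tile_cov_sd

    def test_baseline_normalized(self, small_biased_experiment):
        base = small_biased_experiment["model"].baseline
        assert base.frequencies.sum() == pytest.approx(1.0, abs=1e-9)


class TestAlignmentIndependence:
    def test_read_sequence_equals_reference_context(self, tmp_path, small_biased_experiment):
        """With error-free reads, per-offset base frequencies recounted from
        the read sequences equal the reference-context signature exactly."""
        g = small_biased_experiment["genome"]
        reads = small_biased_experiment["reads"]
        sub = make_reads([reads.record(i) for i in range(0, 2000)])
        sam = tmp_path / "sub.sam"
        sb.write_simulated_sam(sub, g, sam)
        import pysam

        counts = np.zeros((36, 4))
        with pysam.AlignmentFile(str(sam)) as af:
            for aln in af.fetch(until_eof=True):
                seq = aln.query_sequence
                if aln.is_reverse:
                    seq = revcomp(seq)
                for i, base in enumerate(seq):
                    counts[i, "ACGT".index(base)] += 1
        sig = sb.compute_signature(sub, g, k=1, upstream=0, downstream=0)
        for t in range(36):
            expected = counts[t] / counts[t].sum()
            assert np.allclose(sig.freq_row(t), expected, atol=1e-12)
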