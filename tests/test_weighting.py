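import numpy as np
import pytest

import seqbias as sb
from seqbias.bias_signature import PositionalKmerFrequencies, kmer_id
from seqbias.tile_analysis import CovarianceGrouping, Tile
from seqbias.weighting import WeightModel, fit_model, normalization_offsets

from conftest import make_reads, rec


def tiny_model(f_rows, b_counts, groups, k=1, pseudocount=0.0, floor=1e-9, cap=1e9,
               normalize=False, read_length=4):
    """Hand-assembled model: f_rows maps offset -> count row."""
    offsets = np.array(sorted(f_rows))
    counts = np.stack([np.asarray(f_rows[int(t)], dtype=float) for t in offsets])
    sig = PositionalKmerFrequencies(k, offsets, counts, counts.sum(axis=1), read_length)
    base = sb.BaselineFrequencies(k=k, counts=np.asarray(b_counts, dtype=float),
                                  n_samples=int(np.sum(b_counts)), seed=0)
    tiles = sorted({i for g in groups for i in g})
    grouping = CovarianceGrouping(
        biased_tiles=[Tile(i, k) for i in tiles],
        cov_matrix=np.eye(len(tiles)),
        expected_cov_mean=0.0,
        expected_cov_sd=0.0,
        groups=[[Tile(i, k) for i in g] for g in groups],
    )
    return WeightModel(k=k, signature=sig, baseline=base, grouping=grouping,
                       pseudocount=pseudocount, weight_floor=floor, weight_cap=cap,
                       normalize=normalize)


class TestTileWeight:
    def test_unbiased_identity(self):
        g = sb.GenomeSequence({"chr1": "ACGT" * 300})
        m = tiny_model({0: [1, 1, 1, 1]}, [1, 1, 1, 1], groups=[[0]])
        assert sb.tile_weight(m, g, "chr1", 100, "+", Tile(0, 1)) == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        g = sb.GenomeSequence({"chr1": "A" * 1200})
        # f_A = 0.5, b_A = 0.25 -> weight 0.5 at an A site
        m = tiny_model({0: [2, 2, 0, 0]}, [1, 1, 1, 1], groups=[[0]])
        assert sb.tile_weight(m, g, "chr1", 100, "+", Tile(0, 1)) == pytest.approx(0.5)

    def test_unobserved_kmer_clamped(self):
        g = sb.GenomeSequence({"chr1": "G" * 1200})
        m = tiny_model({0: [2, 2, 0, 0]}, [1, 1, 1, 1], groups=[[0]], cap=100.0)
        w = sb.tile_weight(m, g, "chr1", 100, "+", Tile(0, 1))
        assert np.isfinite(w) and w <= 100.0

    def test_context_unavailable_signal(self):
        g = sb.GenomeSequence({"chr1": "N" * 1200})
        m = tiny_model({0: [1, 1, 1, 1]}, [1, 1, 1, 1], groups=[[0]])
        with pytest.raises(sb.ContextUnavailable):
            sb.tile_weight(m, g, "chr1", 100, "+", Tile(0, 1))


class TestSequenceWeight:
    def test_no_biased_tiles_is_one(self):
        g = sb.GenomeSequence({"chr1": "ACGT" * 300})
        m = tiny_model({0: [1, 1, 1, 1]}, [1, 1, 1, 1], groups=[])
        assert sb.sequence_weight(m, g, "chr1", 57, "+") == 1.0

    def test_within_group_mean_and_cross_group_product(self):
        # k=1, genome position p has letters A at offsets 0 and C at offset 1
        g = sb.GenomeSequence({"chr1": "AC" * 600})
        # offset 0: f_A=0.5 b_A=0.25 -> 0.5 ; offset 1: f_C=0.25, b_C=0.375 -> 1.5
        rows = {0: [2, 2, 0, 0], 1: [1, 1, 1, 1]}
        b = [1, 1.5, 1, 0.5]
        m_avg = tiny_model(rows, b, groups=[[0, 1]])
        # at even position: tile0 sees A (w=(.25)/(.5)=.5), tile1 sees C (w=.375/.25=1.5)
        assert sb.sequence_weight(m_avg, g, "chr1", 100, "+") == pytest.approx(1.0)
        m_prod = tiny_model(rows, b, groups=[[0], [1]])
        assert sb.sequence_weight(m_prod, g, "chr1", 100, "+") == pytest.approx(0.75)

    def test_clamped_to_cap(self):
        g = sb.GenomeSequence({"chr1": "A" * 1200})
        m = tiny_model({0: [1, 99, 0, 0]}, [99, 1, 0, 0], groups=[[0]], cap=10.0)
        assert sb.sequence_weight(m, g, "chr1", 100, "+") == 10.0


class TestNormalization:
    def test_flat_landscape_self_normalizes_to_one(self):
        g = sb.GenomeSequence({"chr1": "ACGT" * 300})
        m = tiny_model({0: [1, 1, 1, 1]}, [1, 1, 1, 1], groups=[[0]], normalize=True)
        w = sb.normalize_read_weight(m, g, rec(start=600, length=4))
        assert w == pytest.approx(1.0)

    def test_offsets_avoid_biased_span(self):
        m = tiny_model({0: [1, 1, 1, 1], 5: [1, 1, 1, 1]}, [1, 1, 1, 1],
                       groups=[[0], [5]], k=1)
        offs = normalization_offsets(m)
        assert len(offs) == 20
        span = 6  # tiles 0..5 of width 1 -> offsets 0..5
        assert all(abs(j) >= span for j in offs)

    def test_locus_composition_removed_on_gc_gradient(self):
        """A GC-loaded cut preference on a GC-gradient genome makes raw
        sequence weights track the local composition; normalizing by the
        flanking-site mean removes most of that locus-level component."""
        from seqbias.bias_signature import kmer_string
        from seqbias.synthetic import generate_gradient_reference
        from seqbias.weighting import _sequence_weights, normalization_offsets

        mult = {}
        for j in range(4096):
            h = kmer_string(j, 6)
            gc = sum(c in "GC" for c in h)
            mult[h] = float(np.exp(0.8 * (gc - 3)))
        bias = sb.InjectedBiasModel(
            kind="cut-preference", motif_length=6, anchor_offset=-3,
            preference=mult, label="gc-loaded",
        )
        g = generate_gradient_reference(200_000, 0.25, 0.75, 10, seed=41)
        regions = sb.generate_regions(g, 10, 1000, 3000, seed=42)
        reads, _ = sb.simulate_reads(g, regions, 30_000, 36, bias, seed=44)
        model, _ = fit_model(reads, g, seed=45)
        assert model.grouping.groups  # the GC-loaded hexamer must be detected

        # evaluate at uniformly drawn loci (not bias-selected read sites)
        rng = np.random.default_rng(7)
        pos = rng.integers(100, 199_900, 20_000)
        rev = np.zeros(pos.size, bool)
        raw, _ = _sequence_weights(model, g, "chr1", pos, rev)
        dsum = np.zeros(pos.size)
        dcnt = np.zeros(pos.size)
        for j in normalization_offsets(model):
            wj, rj = _sequence_weights(model, g, "chr1", pos + j, rev)
            dsum[rj] += wj[rj]
            dcnt[rj] += 1
        normalized = raw / (dsum / np.maximum(dcnt, 1))
        block = pos // 20_000
        spread = lambda v: np.std(
            [np.log(v[block == b]).mean() for b in range(10)]
        )
        assert spread(normalized) < 0.5 * spread(raw)


class TestAssignReadWeights:
    def test_no_bias_all_ones(self):
        g = sb.GenomeSequence({"chr1": "ACGT" * 600})
        m = tiny_model({0: [1, 1, 1, 1]}, [1, 1, 1, 1], groups=[])
        reads = make_reads([rec(start=10 * i + 5, length=4, read_id=f"r{i}") for i in range(20)])
        out = sb.assign_read_weights(m, reads, g)
        assert all(wr.weight == 1.0 for wr in out)

    def test_context_unavailable_falls_back_to_one(self):
        g = sb.GenomeSequence({"chr1": "N" * 200 + "ACGT" * 100})
        m = tiny_model({0: [1, 2, 3, 4]}, [4, 3, 2, 1], groups=[[0]])
        reads = make_reads([rec(start=50, length=4, read_id="inN"),
                            rec(start=300, length=4, read_id="ok")])
        out = {wr.record.read_id: wr.weight for wr in sb.assign_read_weights(m, reads, g)}
        assert out["inN"] == 1.0
        assert out["ok"] != 1.0


@pytest.fixture(scope="module")
def small_k2_fit():
    """Unbiased small experiment fitted at k=2 with a manually forced single
    biased tile, for the closed-form identities."""
    g = sb.generate_reference(100_000, 0.5, seed=51)
    regions = sb.generate_regions(g, 8, 800, 2000, seed=52)
    reads, _ = sb.simulate_reads(g, regions, 20_000, 30, sb.no_bias(), seed=53)
    sig = sb.compute_signature(reads, g, k=2, upstream=6, downstream=6)
    base = sb.sample_baseline(reads, g, k=2, seed=54, null_replicates=20)
    tile = Tile(0, 2)
    grouping = CovarianceGrouping([tile], np.eye(1), 0.0, 0.0, groups=[[tile]])
    model = WeightModel(k=2, signature=sig, baseline=base, grouping=grouping,
                        pseudocount=0.0, weight_floor=1e-9, weight_cap=1e9,
                        normalize=False)
    return g, reads, model, tile


class TestClosedFormIdentities:
    def test_single_tile_weighted_frequencies_equal_baseline(self, small_k2_fit):
        g, reads, model, tile = small_k2_fit
        w = sb.read_weight_vector(model, reads, g)
        post = sb.weighted_signature(reads, g, k=2, upstream=6, downstream=6, weights=w)
        b = model.baseline.frequencies
        f_post = post.freq_row(tile.start_offset)
        assert np.all(np.abs(f_post - b) < 1e-9)

    def test_mean_per_tile_weight_is_one(self, small_k2_fit):
        g, reads, model, tile = small_k2_fit
        w = sb.read_weight_vector(model, reads, g)
        assert np.mean(w) == pytest.approx(1.0, abs=1e-9)


class TestExpandIntegerCopies:
    def test_exact_integer_cases(self):
        r = rec()
        assert len(sb.expand_integer_copies([sb.WeightedRead(r, 1.0)], scale=1)) == 1
        assert len(sb.expand_integer_copies([sb.WeightedRead(r, 2.5)], scale=2)) == 5

    def test_stochastic_rounding_binomial(self):
        reads = [sb.WeightedRead(rec(read_id=f"r{i}"), 0.5) for i in range(10_000)]
        n = len(sb.expand_integer_copies(reads, scale=1, seed=7))
        assert abs(n - 5000) < 3 * np.sqrt(10_000 * 0.25)

    def test_scale_validation(self):
        with pytest.raises(ValueError):
            sb.expand_integer_copies([], scale=0)


class TestModelPersistence:
    def test_save_load_round_trip(self, tmp_path, small_biased_experiment):
        e = small_biased_experiment
        d = tmp_path / "model"
        sb.save_model(e["model"], d, stats=e["stats"])
        loaded = sb.load_model(d)
        w1 = sb.read_weight_vector(e["model"], e["reads"], e["genome"])
        w2 = sb.read_weight_vector(loaded, e["reads"], e["genome"])
        assert np.allclose(w1, w2, rtol=0, atol=1e-12)
        assert (d / "tiles.tsv").exists()

    def test_fit_determinism(self, small_biased_experiment):
        e = small_biased_experiment
        m2, _ = fit_model(e["reads"], e["genome"], seed=85)
        w1 = sb.read_weight_vector(e["model"], e["reads"], e["genome"])
        w2 = sb.read_weight_vector(m2, e["reads"], e["genome"])
        assert np.array_equal(w1, w2)
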