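import numpy as np
import pytest

import seqbias as sb
from seqbias.model_io import AlignedReadRecord


@pytest.fixture(scope="session")
def toy_genome():
    # 40 bp, hand-checkable on both strands
    return sb.GenomeSequence({"chr1": "ACGTACGTACGTAAACCCGGGTTTACGTACGTACGTACGT"})


def make_reads(records):
    return sb.ReadSet.from_records(records)


def rec(chrom="chr1", start=0, length=5, strand="+", read_id="r", mapq=60):
    return AlignedReadRecord(
        read_id=read_id, chrom=chrom, start=start, length=length, strand=strand, mapq=mapq
    )


@pytest.fixture(scope="session")
def small_biased_experiment():
    """Moderate-size DNase-like simulation with a fitted model, shared by
    tests that only need *a* realistic biased dataset."""
    genome = sb.generate_reference(200_000, 0.5, seed=81)
    regions = sb.generate_regions(genome, 10, 1000, 3000, seed=82)
    bias = sb.dnase_like_bias(seed=83)
    reads, truth = sb.simulate_reads(genome, regions, 50_000, 36, bias, seed=84)
    model, stats = sb.fit_model(reads, genome, seed=85)
    return {
        "genome": genome,
        "regions": regions,
        "bias": bias,
        "reads": reads,
        "truth": truth,
        "model": model,
        "stats": stats,
    }


@pytest.fixture(scope="session")
def small_unbiased_experiment():
    genome = sb.generate_reference(200_000, 0.5, seed=91)
    regions = sb.generate_regions(genome, 10, 1000, 3000, seed=92)
    reads, truth = sb.simulate_reads(genome, regions, 50_000, 36, sb.no_bias(), seed=94)
    return {"genome": genome, "regions": regions, "reads": reads, "truth": truth}
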