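"""Synthetic genomes, enriched regions and site-selection-biased reads.

The simulator reproduces the data regime the correction targets: reads
concentrated in enriched regions, whose 5' start sites are chosen with a
position-specific sequence preference (a nuclease/transposase "cut
preference").  Bias is injected at the site-selection step — it changes
*where* reads start, never the bases that are read — so simulated reads
always match the reference exactly and every site's true sampling
probability is known.

The default preference is DNase-like: a hexamer straddling the cut site
(anchor offset -3), with per-position additive log-preferences (a position
weight matrix energy), giving log-normal per-motif multipliers.  A purely
independent per-motif preference would leave all positional nucleotide
marginals flat and would be invisible to any frequency-based method; enzyme
preferences in this domain are position-additive to first order, which is
the structure the generator emulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .bias_signature import kmer_ids_at, kmer_string, weighted_signature
from .model_io import (
    GenomeSequence,
    ReadSet,
    WeightedRead,
    make_header,
)

DEFAULT_GENOME_LENGTH = 1_000_000
DEFAULT_N_REGIONS = 40
DEFAULT_REGION_MIN = 1_000
DEFAULT_REGION_MAX = 5_000
DEFAULT_N_READS = 200_000
DEFAULT_READ_LENGTH = 36
DEFAULT_MOTIF_LENGTH = 6
DEFAULT_ANCHOR = -3
DEFAULT_SIGMA = 1.0


# ---------------------------------------------------------------------------
# Bias models
# ---------------------------------------------------------------------------

@dataclass
class InjectedBiasModel:
    """A known position-specific cut preference.

    ``preference`` maps every motif of length ``motif_length`` to a positive
    multiplier; multipliers are rescaled on construction so their mean over
    all motifs is 1, preserving the expected total read count.
    ``anchor_offset`` places the motif relative to the 5' cut (e.g. -3 for a
    hexamer straddling the cut, 0 for a within-read preference).
    """

    kind: str  # {"cut-preference", "none"}
    motif_length: int = DEFAULT_MOTIF_LENGTH
    anchor_offset: int = DEFAULT_ANCHOR
    preference: Dict[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("cut-preference", "none"):
            raise ValueError("kind must be 'cut-preference' or 'none'")
        if self.kind == "cut-preference":
            if not self.preference:
                raise ValueError("cut-preference model needs a preference table")
            vals = np.array(list(self.preference.values()), dtype=float)
            if (vals <= 0).any():
                raise ValueError("multipliers must be positive")
            # mean over ALL motifs, counting absent motifs as multiplier 1
            n_total = 4 ** self.motif_length
            mean = (vals.sum() + (n_total - vals.size)) / n_total
            self.preference = {m: v / mean for m, v in self.preference.items()}

    def multiplier_lut(self) -> np.ndarray:
        """Dense multiplier array indexed by motif id (absent motifs -> 1)."""
        lut = np.ones(4 ** self.motif_length)
        if self.kind == "cut-preference":
            from .bias_signature import kmer_id

            for motif, v in self.preference.items():
                lut[kmer_id(motif)] = v
            lut /= lut.mean()
        return lut


def pwm_preference(
    motif_length: int = DEFAULT_MOTIF_LENGTH,
    sigma: float = DEFAULT_SIGMA,
    seed: int = 0,
) -> Dict[str, float]:
    """Position-additive log-preferences over all motifs of a given length.

    Per-position energies e_i(a) ~ N(0, sigma^2 / L) give per-motif
    log-multipliers with standard deviation ~sigma, i.e. log-normal
    multipliers driven by independent per-position contributions."""
    rng = np.random.default_rng(seed)
    energies = rng.normal(0.0, sigma / math.sqrt(motif_length), size=(motif_length, 4))
    energies -= energies.mean(axis=1, keepdims=True)
    n = 4 ** motif_length
    logmult = np.zeros(n)
    ids = np.arange(n)
    for i in range(motif_length):
        digit = (ids >> (2 * (motif_length - 1 - i))) & 3
        logmult += energies[i, digit]
    mult = np.exp(logmult)
    return {kmer_string(int(j), motif_length): float(mult[j]) for j in ids}


def dnase_like_bias(seed: int = 0, sigma: float = DEFAULT_SIGMA) -> InjectedBiasModel:
    """Hexamer cut preference straddling the 5' end (DNase I geometry)."""
    return InjectedBiasModel(
        kind="cut-preference",
        motif_length=DEFAULT_MOTIF_LENGTH,
        anchor_offset=DEFAULT_ANCHOR,
        preference=pwm_preference(DEFAULT_MOTIF_LENGTH, sigma, seed),
        label="dnase-like-hexamer",
    )


def tn5_like_bias(seed: int = 0, sigma: float = DEFAULT_SIGMA) -> InjectedBiasModel:
    """Symmetric 9-bp insertion preference centered on the cut (Tn5 geometry)."""
    return InjectedBiasModel(
        kind="cut-preference",
        motif_length=9,
        anchor_offset=-4,
        preference=pwm_preference(9, sigma, seed),
        label="tn5-like-9mer",
    )


def no_bias(motif_length: int = DEFAULT_MOTIF_LENGTH) -> InjectedBiasModel:
    return InjectedBiasModel(kind="none", motif_length=motif_length, label="none")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation: regions, the injected bias, and the
    exact per-site sampling probabilities (summing to 1)."""

    enriched_regions: List[Tuple[str, int, int]]
    bias: InjectedBiasModel
    site_chrom: List[str]
    site_pos: np.ndarray       # 5' cut coordinate of each candidate site
    site_is_reverse: np.ndarray
    site_prob: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_reference(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    name: str = "chr1",
) -> GenomeSequence:
    """i.i.d. reference with the requested GC fraction."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = "".join(np.array(list("ACGT"))[codes])
    return GenomeSequence({name: seq})


def generate_gradient_reference(
    length: int,
    gc_start: float = 0.3,
    gc_end: float = 0.7,
    n_blocks: int = 20,
    seed: int = 0,
    name: str = "chr1",
) -> GenomeSequence:
    """Reference whose GC content ramps across equal-sized blocks."""
    rng = np.random.default_rng(seed)
    bounds = np.linspace(0, length, n_blocks + 1).astype(int)
    gcs = np.linspace(gc_start, gc_end, n_blocks)
    parts = []
    letters = np.array(list("ACGT"))
    for (s, e), gc in zip(zip(bounds[:-1], bounds[1:]), gcs):
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        parts.append("".join(letters[rng.choice(4, size=e - s, p=p)]))
    return GenomeSequence({name: "".join(parts)})


def generate_regions(
    genome: GenomeSequence,
    n_regions: int = DEFAULT_N_REGIONS,
    min_length: int = DEFAULT_REGION_MIN,
    max_length: int = DEFAULT_REGION_MAX,
    seed: int = 0,
    chrom: Optional[str] = None,
) -> List[Tuple[str, int, int]]:
    """Non-overlapping enriched regions placed uniformly on one chromosome."""
    rng = np.random.default_rng(seed)
    chrom = chrom or genome.chrom_names[0]
    L = genome.chrom_length(chrom)
    lengths = rng.integers(min_length, max_length + 1, size=n_regions)
    # place region starts in sorted gaps so regions never overlap
    total = int(lengths.sum())
    if total >= L:
        raise ValueError("regions do not fit in the chromosome")
    slack = L - total
    cuts = np.sort(rng.choice(slack, size=n_regions, replace=False))
    starts = cuts + np.concatenate(([0], np.cumsum(lengths[:-1])))
    return [
        (chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)
    ]


def simulate_reads(
    genome: GenomeSequence,
    regions: Sequence[Tuple[str, int, int]],
    n_reads: int = DEFAULT_N_READS,
    read_length: int = DEFAULT_READ_LENGTH,
    bias: Optional[InjectedBiasModel] = None,
    strand_fraction: float = 0.5,
    seed: int = 0,
) -> Tuple[ReadSet, SyntheticTruth]:
    """Draw reads i.i.d. from candidate 5' sites inside enriched regions.

    Every position in a region at which a read fits is a candidate site on
    each strand (split by ``strand_fraction``); its probability is
    proportional to the bias multiplier of the reference motif at the bias
    anchor.  Reads carry no sequencing error by construction.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    bias = bias or no_bias()
    rng = np.random.default_rng(seed)
    site_chrom: List[str] = []
    site_pos_parts: List[np.ndarray] = []
    site_rev_parts: List[np.ndarray] = []
    site_w_parts: List[np.ndarray] = []
    lut = bias.multiplier_lut()
    for chrom, start, end in regions:
        if end - start < read_length:
            raise ValueError(
                f"region {chrom}:{start}-{end} shorter than the read length"
            )
        # + strand: 5' site = leftmost position; - strand: 5' site = rightmost
        plus_sites = np.arange(start, end - read_length + 1)
        minus_sites = np.arange(start + read_length - 1, end)
        for sites, rev, sw in (
            (plus_sites, False, strand_fraction),
            (minus_sites, True, 1.0 - strand_fraction),
        ):
            if sw <= 0:
                continue
            mult = np.ones(sites.size)
            if bias.kind == "cut-preference":
                ids = kmer_ids_at(
                    genome,
                    chrom,
                    sites,
                    np.full(sites.size, rev),
                    bias.anchor_offset,
                    bias.motif_length,
                )
                ok = ids >= 0
                mult[ok] = lut[ids[ok]]
            site_chrom.extend([chrom] * sites.size)
            site_pos_parts.append(sites)
            site_rev_parts.append(np.full(sites.size, rev))
            site_w_parts.append(mult * sw)

    pos = np.concatenate(site_pos_parts)
    rev = np.concatenate(site_rev_parts)
    w = np.concatenate(site_w_parts)
    prob = w / w.sum()
    counts = rng.multinomial(n_reads, prob)
    drawn = np.repeat(np.arange(prob.size), counts)

    chroms = sorted({c for c, _, _ in regions})
    chrom_to_idx = {c: i for i, c in enumerate(chroms)}
    chrom_idx_sites = np.array([chrom_to_idx[c] for c in site_chrom], dtype=np.int32)
    d_pos = pos[drawn]
    d_rev = rev[drawn]
    starts = np.where(d_rev, d_pos - read_length + 1, d_pos)
    reads = ReadSet(
        chroms=chroms,
        chrom_index=chrom_idx_sites[drawn],
        start=starts,
        length=np.full(drawn.size, read_length, dtype=np.int32),
        is_reverse=d_rev,
        mapq=np.full(drawn.size, 60, dtype=np.int32),
        is_primary=np.ones(drawn.size, dtype=bool),
        read_ids=[f"sim{i}" for i in range(drawn.size)],
        source_path="<simulated>",
    )
    truth = SyntheticTruth(
        enriched_regions=list(regions),
        bias=bias,
        site_chrom=site_chrom,
        site_pos=pos,
        site_is_reverse=rev,
        site_prob=prob,
        seed=seed,
    )
    return reads, truth


def plant_motif_sites(
    genome: GenomeSequence,
    motif: str,
    regions: Sequence[Tuple[str, int, int]],
    sites_per_region: int = 25,
    pad: int = 300,
    seed: int = 0,
) -> Tuple[GenomeSequence, List[Tuple[str, int, str]]]:
    """Write ``motif`` into the reference at random positions inside regions.

    Returns the modified genome and the planted site list (chrom, motif
    start, '+').  Used for naked-DNA style fixtures where aggregate cut
    profiles around known motif instances isolate pure sequence bias."""
    rng = np.random.default_rng(seed)
    seqs = {
        c: list(genome.sequence(c, 0, genome.chrom_length(c)))
        for c in genome.chrom_names
    }
    L = len(motif)
    sites: List[Tuple[str, int, str]] = []
    for chrom, start, end in regions:
        lo, hi = start + pad, end - pad - L
        if hi <= lo:
            continue
        # one slot per site keeps planted copies from overwriting each other
        bounds = np.linspace(lo, hi, sites_per_region + 1).astype(int)
        for slo, shi in zip(bounds[:-1], bounds[1:]):
            if shi - L <= slo:
                continue
            m = int(rng.integers(slo, shi - L))
            seqs[chrom][m : m + L] = list(motif)
            sites.append((chrom, m, "+"))
    return GenomeSequence({c: "".join(v) for c, v in seqs.items()}), sites


def write_simulated_sam(
    reads: ReadSet,
    genome: GenomeSequence,
    path: str | Path,
) -> Path:
    """Write simulated reads as coordinate-sorted SAM/BAM with reference-exact
    sequences."""
    path = Path(path)
    header = pysam.AlignmentHeader.from_dict(make_header(genome))
    mode = "wb" if path.suffix == ".bam" else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for i in range(reads.total_count):
            r = reads.record(i)
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.reference_id = header.get_tid(r.chrom)
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.flag = 16 if r.strand == "-" else 0
            a.cigarstring = f"{r.length}M"
            a.query_sequence = genome.sequence(r.chrom, r.start, r.start + r.length)
            a.query_qualities = pysam.qualitystring_to_array("I" * r.length)
            out.write(a)
    return path


def write_genome_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom, 0, genome.chrom_length(chrom))
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Parameter recovery report
# ---------------------------------------------------------------------------

def recovery_report(
    truth: SyntheticTruth,
    model,  # WeightModel
    weighted: Sequence[WeightedRead],
    genome: GenomeSequence,
    min_reads_per_motif: int = 5,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Compare the fitted model against the simulation's ground truth.

    Returns a per-tile table (anv before/after correction, flag status) and
    a summary with the correlation between injected log-multipliers and the
    recovered per-motif log correction (from un-normalized sequence
    weights), the fraction of truth-biased tiles flagged, and the weight
    IQR.
    """
    from .tile_analysis import average_nucleotide_variance, tiles_for_signature
    from .weighting import WeightModel, _sequence_weights

    reads = ReadSet.from_records([wr.record for wr in weighted])
    weights = np.array([wr.weight for wr in weighted])
    post = weighted_signature(
        weighted,
        genome,
        k=model.k,
        upstream=int(-model.signature.offsets.min()),
        downstream=int(model.signature.offsets.max() - model.read_length),
    )
    threshold = (
        model.baseline.null_tile_anv_mean + 2 * model.baseline.null_tile_anv_sd
    )
    rows = []
    bias = truth.bias
    span = (
        (bias.anchor_offset, bias.anchor_offset + bias.motif_length)
        if bias.kind == "cut-preference"
        else None
    )
    flagged_indices = {t.index for g in model.grouping.groups for t in g}
    for tile in tiles_for_signature(model.signature):
        lo, hi = tile.start_offset, tile.start_offset + tile.k
        truth_biased = span is not None and lo < span[1] and span[0] < hi
        rows.append(
            {
                "tile_index": tile.index,
                "start_offset": lo,
                "anv_pre": average_nucleotide_variance(model.signature, tile),
                "anv_post": average_nucleotide_variance(post, tile),
                "threshold": threshold,
                "flagged": tile.index in flagged_indices,
                "truth_biased": truth_biased,
            }
        )
    table = pd.DataFrame(rows)

    summary: Dict[str, float] = {}
    tb = table[table.truth_biased]
    summary["fraction_truth_tiles_flagged"] = (
        float(tb.flagged.mean()) if len(tb) else float("nan")
    )
    q1, q3 = np.percentile(weights, [25, 75])
    summary["weight_iqr_low"] = float(q1)
    summary["weight_iqr_high"] = float(q3)

    if bias.kind == "cut-preference":
        lut = bias.multiplier_lut()
        # recovered per-motif correction from un-normalized sequence weights
        unnorm = WeightModel(
            k=model.k,
            signature=model.signature,
            baseline=model.baseline,
            grouping=model.grouping,
            pseudocount=model.pseudocount,
            weight_floor=model.weight_floor,
            weight_cap=model.weight_cap,
            normalize=False,
        )
        neg_log_w = np.full(reads.total_count, np.nan)
        motif_ids = np.full(reads.total_count, -1, dtype=np.int64)
        fp = reads.five_prime
        for ci, chrom in enumerate(reads.chroms):
            sel = np.flatnonzero(reads.chrom_index == ci)
            if sel.size == 0:
                continue
            sw, resolved = _sequence_weights(
                unnorm, genome, chrom, fp[sel], reads.is_reverse[sel]
            )
            neg_log_w[sel[resolved]] = -np.log(sw[resolved])
            motif_ids[sel] = kmer_ids_at(
                genome,
                chrom,
                fp[sel],
                reads.is_reverse[sel],
                bias.anchor_offset,
                bias.motif_length,
            )
        ok = (motif_ids >= 0) & np.isfinite(neg_log_w)
        df = pd.DataFrame({"motif": motif_ids[ok], "nlw": neg_log_w[ok]})
        per_motif = df.groupby("motif")["nlw"].agg(["mean", "size"])
        per_motif = per_motif[per_motif["size"] >= min_reads_per_motif]
        if len(per_motif) >= 3:
            injected = np.log(lut[per_motif.index.to_numpy()])
            recovered = per_motif["mean"].to_numpy()
            summary["recovery_r"] = float(np.corrcoef(injected, recovered)[0, 1])
        else:
            summary["recovery_r"] = float("nan")
    else:
        summary["recovery_r"] = float("nan")
    return table, summary
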