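"""Position-specific k-mer frequency signatures and density-weighted baselines.

The bias signature of an experiment is the table ``f^t_kmer``: for every
offset t relative to the 5' end of the aligned reads (default -20 .. n+20,
n the modal read length), the relative frequency of each k-mer in the
reference context at that offset.  Offset 0 is the 5'-most base of the read
on its own strand; minus-strand context is reverse-complemented, so the
signature is cut-site anchored the way nuclease/transposase preferences are.

The baseline ``b_kmer`` is the position-free expectation: for each observed
read, pseudo-reads are placed uniformly within -margin .. n+margin of its
start, one per aligned read falling in that window, so densely covered loci
contribute proportionally more.  The baseline therefore captures the
compositional trends of the enriched regions (e.g. their GC content) without
any read-relative positional structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model_io import (
    AlignedReadRecord,
    GenomeSequence,
    ReadSet,
    WeightedRead,
    logger,
)

DEFAULT_K = 5
DEFAULT_FLANK = 20
DEFAULT_MARGIN = 25
NULL_REPLICATES = 200


def kmer_string(kmer_id: int, k: int) -> str:
    chars = []
    for i in range(k - 1, -1, -1):
        chars.append("ACGT"[(kmer_id >> (2 * i)) & 3])
    return "".join(chars)


def kmer_id(kmer: str) -> int:
    v = 0
    for c in kmer:
        v = (v << 2) | "ACGT".index(c)
    return v


def kmer_ids_at(
    genome: GenomeSequence,
    chrom: str,
    five_prime: np.ndarray,
    is_reverse: np.ndarray,
    offset: int,
    k: int,
) -> np.ndarray:
    """k-mer ids at a signed 5'-anchored offset for arrays of cut sites.

    Plus strand: id of S[p + offset : p + offset + k].  Minus strand: id of
    the reverse complement of the k-window ending ``offset`` bases 5' of p,
    i.e. revcomp(S[p - offset - k + 1 : p - offset + 1]).  Returns -1 where
    the window leaves the chromosome or contains N.
    """
    fwd, rev = genome.kmer_ids(chrom, k)
    n_windows = fwd.size
    five_prime = np.asarray(five_prime, dtype=np.int64)
    is_reverse = np.asarray(is_reverse, dtype=bool)
    out = np.full(five_prime.size, -1, dtype=np.int64)

    pos_f = five_prime + offset
    sel = (~is_reverse) & (pos_f >= 0) & (pos_f < n_windows)
    out[sel] = fwd[pos_f[sel]]

    pos_r = five_prime - offset - k + 1
    sel = is_reverse & (pos_r >= 0) & (pos_r < n_windows)
    out[sel] = rev[pos_r[sel]]
    return out


def five_prime_context(
    record: AlignedReadRecord,
    genome: GenomeSequence,
    offset: int,
    k: int,
) -> Optional[str]:
    """The k nucleotides at signed ``offset`` from the read's 5' end, read
    5'->3' on the read's strand; None if out of bounds or containing N."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = kmer_ids_at(
        genome,
        record.chrom,
        np.array([record.five_prime]),
        np.array([record.strand == "-"]),
        offset,
        k,
    )
    return None if ids[0] < 0 else kmer_string(int(ids[0]), k)


# ---------------------------------------------------------------------------
# Signature
# ---------------------------------------------------------------------------

class PositionalKmerFrequencies:
    """f^t_kmer over offsets t in [-upstream, n+downstream].

    ``counts`` is (n_offsets, 4^k); for an unweighted signature entries are
    integer-valued, for a weighted one they are weight sums.  ``evaluated``
    holds the per-offset denominator (reads, or weight, evaluable at t)."""

    def __init__(
        self,
        k: int,
        offsets: np.ndarray,
        counts: np.ndarray,
        evaluated: np.ndarray,
        read_length: int,
    ):
        self.k = k
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.counts = np.asarray(counts, dtype=np.float64)
        self.evaluated = np.asarray(evaluated, dtype=np.float64)
        self.read_length = read_length
        self._index = {int(t): i for i, t in enumerate(self.offsets)}

    @property
    def n_kmers(self) -> int:
        return 4 ** self.k

    def has_offset(self, t: int) -> bool:
        return t in self._index and self.evaluated[self._index[t]] > 0

    def freq_row(self, t: int) -> np.ndarray:
        """Relative frequency vector over all 4^k k-mers at offset t."""
        i = self._index[t]
        if self.evaluated[i] <= 0:
            raise ValueError(f"no evaluable reads at offset {t}")
        return self.counts[i] / self.evaluated[i]

    def frequency(self, t: int, kmer: str) -> float:
        return float(self.freq_row(t)[kmer_id(kmer)])

    def count(self, t: int, kmer: str) -> float:
        return float(self.counts[self._index[t]][kmer_id(kmer)])

    def smoothed_freq_row(self, t: int, pseudocount: float) -> np.ndarray:
        """Frequencies after adding ``pseudocount`` to every k-mer's count."""
        i = self._index[t]
        denom = self.evaluated[i] + pseudocount * self.n_kmers
        if denom <= 0:
            raise ValueError(f"no evaluable reads at offset {t}")
        return (self.counts[i] + pseudocount) / denom

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("offset\tkmer\tcount\tfrequency\n")
            for i, t in enumerate(self.offsets):
                ev = self.evaluated[i]
                if ev <= 0:
                    continue
                nz = np.flatnonzero(self.counts[i])
                for j in nz:
                    fh.write(
                        f"{t}\t{kmer_string(int(j), self.k)}\t"
                        f"{self.counts[i, j]:.17g}\t{self.counts[i, j] / ev:.17g}\n"
                    )
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, k: int, read_length: int) -> "PositionalKmerFrequencies":
        rows: Dict[int, np.ndarray] = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                t_s, kmer, count, _freq = line.rstrip("\n").split("\t")
                t = int(t_s)
                if t not in rows:
                    rows[t] = np.zeros(4 ** k)
                rows[t][kmer_id(kmer)] = float(count)
        offsets = np.array(sorted(rows), dtype=np.int64)
        counts = np.stack([rows[int(t)] for t in offsets])
        return cls(k, offsets, counts, counts.sum(axis=1), read_length)


def _accumulate_signature(
    reads: ReadSet,
    genome: GenomeSequence,
    k: int,
    upstream: int,
    downstream: int,
    weights: Optional[np.ndarray],
) -> PositionalKmerFrequencies:
    if reads.total_count == 0:
        raise ValueError("cannot compute a signature from an empty read set")
    n = reads.modal_length
    offsets = np.arange(-upstream, n + downstream + 1)
    counts = np.zeros((offsets.size, 4 ** k))
    evaluated = np.zeros(offsets.size)
    five_prime = reads.five_prime
    w = np.ones(reads.total_count) if weights is None else np.asarray(weights, float)
    for ci, chrom in enumerate(reads.chroms):
        sel = reads.chrom_index == ci
        if not sel.any():
            continue
        fp = five_prime[sel]
        rev = reads.is_reverse[sel]
        lens = reads.length[sel]
        wc = w[sel]
        for i, t in enumerate(offsets):
            ids = kmer_ids_at(genome, chrom, fp, rev, int(t), k)
            # reads shorter than the modal length only cover their own range
            valid = (ids >= 0) & (t <= lens + downstream)
            if not valid.any():
                continue
            counts[i] += np.bincount(ids[valid], weights=wc[valid], minlength=4 ** k)
            evaluated[i] += wc[valid].sum()
    if not (evaluated > 0).any():
        raise ValueError("no evaluable reads at any offset")
    return PositionalKmerFrequencies(k, offsets, counts, evaluated, n)


def compute_signature(
    reads: ReadSet,
    genome: GenomeSequence,
    k: int = DEFAULT_K,
    upstream: int = DEFAULT_FLANK,
    downstream: int = DEFAULT_FLANK,
) -> PositionalKmerFrequencies:
    """The global bias signature: per-offset k-mer frequencies over all reads."""
    if not 1 <= k <= 8:
        raise ValueError("k must be in 1..8")
    return _accumulate_signature(reads, genome, k, upstream, downstream, None)


def weighted_signature(
    reads: Sequence[WeightedRead] | ReadSet,
    genome: GenomeSequence,
    k: int = DEFAULT_K,
    upstream: int = DEFAULT_FLANK,
    downstream: int = DEFAULT_FLANK,
    weights: Optional[np.ndarray] = None,
) -> PositionalKmerFrequencies:
    """As compute_signature, with weight sums as numerator and denominator."""
    if isinstance(reads, ReadSet):
        rs, w = reads, weights
    else:
        rs = ReadSet.from_records([wr.record for wr in reads])
        # from_records re-sorts; map weights through the same order
        order = np.lexsort(
            (
                np.array([wr.record.start for wr in reads]),
                np.array(
                    [rs.chroms.index(wr.record.chrom) for wr in reads]
                ),
            )
        )
        w = np.array([reads[i].weight for i in order])
    if w is not None and (not np.all(np.isfinite(w)) or (w <= 0).any()):
        raise ValueError("weights must be finite and positive")
    return _accumulate_signature(rs, genome, k, upstream, downstream, w)


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

@dataclass
class BaselineFrequencies:
    """b_kmer plus the null-calibration statistics estimated alongside it.

    ``null_tile_anv_mean/sd`` describe the sampling distribution of the
    average-nucleotide-variance statistic for an unbiased tile estimated
    from the same number of (effective) reads; ``null_tile_cov_mean/sd``
    the analogous null for the tile-pair covariance statistic.  Both are
    estimated from the pseudo-read stream during sampling, using the Kish
    effective sample size of the read set so that stacked duplicate reads do
    not make the null overconfident.
    """

    k: int
    counts: np.ndarray
    n_samples: int
    seed: int
    margin: int = DEFAULT_MARGIN
    n_effective: float = 0.0
    null_tile_anv_mean: float = 0.0
    null_tile_anv_sd: float = 0.0
    null_tile_cov_mean: float = 0.0
    null_tile_cov_sd: float = 0.0

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total <= 0:
            raise ValueError("baseline has no samples")
        return self.counts / total

    def frequency(self, kmer: str) -> float:
        return float(self.frequencies[kmer_id(kmer)])

    def smoothed_frequencies(self, pseudocount: float) -> np.ndarray:
        denom = self.counts.sum() + pseudocount * self.counts.size
        return (self.counts + pseudocount) / denom

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        freq = self.frequencies
        with open(path, "w") as fh:
            fh.write("kmer\tcount\tfrequency\n")
            for j in np.flatnonzero(self.counts):
                fh.write(
                    f"{kmer_string(int(j), self.k)}\t{self.counts[j]:.17g}\t{freq[j]:.17g}\n"
                )
        return path

    def meta(self) -> Dict:
        return {
            "k": self.k,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "margin": self.margin,
            "n_effective": self.n_effective,
            "null_tile_anv_mean": self.null_tile_anv_mean,
            "null_tile_anv_sd": self.null_tile_anv_sd,
            "null_tile_cov_mean": self.null_tile_cov_mean,
            "null_tile_cov_sd": self.null_tile_cov_sd,
        }

    @classmethod
    def from_tsv(cls, path: str | Path, meta: Dict) -> "BaselineFrequencies":
        counts = np.zeros(4 ** meta["k"])
        with open(path) as fh:
            next(fh)
            for line in fh:
                kmer, count, _f = line.rstrip("\n").split("\t")
                counts[kmer_id(kmer)] = float(count)
        return cls(
            k=meta["k"],
            counts=counts,
            n_samples=meta["n_samples"],
            seed=meta["seed"],
            margin=meta["margin"],
            n_effective=meta["n_effective"],
            null_tile_anv_mean=meta["null_tile_anv_mean"],
            null_tile_anv_sd=meta["null_tile_anv_sd"],
            null_tile_cov_mean=meta["null_tile_cov_mean"],
            null_tile_cov_sd=meta["null_tile_cov_sd"],
        )


def effective_sample_size(reads: ReadSet) -> float:
    """Kish effective read count under stacking of identical (start, strand).

    Reads sharing a cut site carry identical context at every offset; the
    sampling noise of the signature therefore scales with N_eff = N^2 / sum
    of squared stack sizes, not with N.
    """
    key = (
        reads.chrom_index.astype(np.int64) * (reads.start.max() + 2) * 2
        + reads.start * 2
        + reads.is_reverse
    )
    _, mult = np.unique(key, return_counts=True)
    n = reads.total_count
    return n * n / float((mult.astype(np.float64) ** 2).sum())


def sample_baseline(
    reads: ReadSet,
    genome: GenomeSequence,
    k: int = DEFAULT_K,
    margin: int = DEFAULT_MARGIN,
    seed: int = 0,
    null_replicates: int = NULL_REPLICATES,
) -> BaselineFrequencies:
    """Density-weighted baseline k-mer frequencies from pseudo-reads.

    For each read r with start A(r) and length n, m_r pseudo-read 5' sites
    are placed uniformly in [A(r) - margin, A(r) + n + margin), where m_r is
    the number of aligned reads starting in that window.  Each pseudo-read
    contributes the reference k-mer at its 5' site (on the parent read's
    strand).  Dense loci therefore contribute quadratically more samples,
    damping the influence of isolated reads.  Deterministic given ``seed``.
    """
    if reads.total_count == 0:
        raise ValueError("cannot sample a baseline from an empty read set")
    rng = np.random.default_rng(seed)
    n_kmers = 4 ** k
    counts = np.zeros(n_kmers)
    n_samples = 0
    site_chrom: List[int] = []
    site_parts: List[Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    for ci, chrom in enumerate(reads.chroms):
        sel = reads.chrom_index == ci
        if not sel.any():
            continue
        starts = reads.start[sel]          # already sorted within chrom
        lens = reads.length[sel].astype(np.int64)
        rev = reads.is_reverse[sel]
        lo = np.searchsorted(starts, starts - margin, side="left")
        hi = np.searchsorted(starts, starts + lens + margin, side="left")
        m = (hi - lo).astype(np.int64)
        parent_all = np.repeat(np.arange(starts.size), m)
        fwd, rv = genome.kmer_ids(chrom, k)
        n_windows = fwd.size
        # the stream can be tens of millions of pseudo-reads; chunk it
        for chunk in np.array_split(parent_all, max(1, parent_all.size // 4_000_000)):
            span = lens[chunk] + 2 * margin     # window has n + 2*margin sites
            x = np.floor(rng.random(chunk.size) * span).astype(np.int64) - margin
            p_rev = rev[chunk]
            s_c = starts[chunk]
            p5 = np.where(p_rev, s_c + lens[chunk] - 1 - x, s_c + x)
            # window start of the offset-0 k-mer on each strand
            pos = np.where(p_rev, p5 - k + 1, p5)
            ok = (pos >= 0) & (pos < n_windows)
            pos_ok = pos[ok]
            ids = np.where(p_rev[ok], rv[pos_ok], fwd[pos_ok])
            ids = ids[ids >= 0]
            counts += np.bincount(ids, minlength=n_kmers)
            n_samples += int(ids.size)
        # distinct cut sites with stack multiplicities, for the null replicates
        key = starts * 2 + rev
        _, first, mult = np.unique(key, return_index=True, return_counts=True)
        site_chrom.append(ci)
        site_parts.append(
            (
                np.where(rev[first], starts[first] + lens[first] - 1, starts[first]),
                rev[first],
                lens[first],
                mult.astype(np.float64),
            )
        )
    if n_samples == 0:
        raise ValueError("no valid pseudo-read samples (genome too small?)")

    baseline = BaselineFrequencies(
        k=k,
        counts=counts,
        n_samples=n_samples,
        seed=seed,
        margin=margin,
        n_effective=effective_sample_size(reads),
    )
    _estimate_null_statistics(
        baseline, genome, reads.chroms, site_chrom, site_parts, rng, null_replicates
    )
    return baseline


def _weighted_pearson(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    ma, mb = (w * a).sum() / wsum, (w * b).sum() / wsum
    va = (w * (a - ma) ** 2).sum()
    vb = (w * (b - mb) ** 2).sum()
    if va == 0 or vb == 0:
        return 0.0
    return float((w * (a - ma) * (b - mb)).sum() / np.sqrt(va * vb))


def _estimate_null_statistics(
    baseline: BaselineFrequencies,
    genome: GenomeSequence,
    chroms: Sequence[str],
    site_chrom: Sequence[int],
    site_parts: Sequence[Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    rng: np.random.Generator,
    null_replicates: int,
) -> None:
    """Monte-Carlo null for the tile anv and tile-pair covariance statistics.

    Each replicate builds one unbiased pseudo-tile of the experiment: every
    distinct cut site draws a single uniform pseudo-offset within its
    baseline window, and all reads stacked on that site inherit the same
    pseudo k-mer — exactly as stacked reads share their k-mer at a real
    tile.  The replicate's anv, and the correlation between its 5' k-mer and
    the abutting k-mer one tile downstream, therefore reflect both the
    sampling noise and the read-stacking structure of the data under the
    hypothesis of no positional bias.
    """
    from .tile_analysis import anv_of_freq_vector  # local import, avoids cycle

    k = baseline.k
    n_kmers = 4 ** k
    margin = baseline.margin
    anvs = np.empty(null_replicates)
    covs = np.empty(null_replicates)
    for i in range(null_replicates):
        c0 = np.zeros(n_kmers)
        vals_a: List[np.ndarray] = []
        vals_b: List[np.ndarray] = []
        wts: List[np.ndarray] = []
        ck = np.zeros(n_kmers)
        wk = 0.0
        for ci, (fp, rev, lens, mult) in zip(site_chrom, site_parts):
            x = np.floor(rng.random(fp.size) * (lens + 2 * margin)).astype(np.int64) - margin
            p5 = np.where(rev, fp - x, fp + x)
            ids0 = kmer_ids_at(genome, chroms[ci], p5, rev, 0, k)
            idsk = kmer_ids_at(genome, chroms[ci], p5, rev, k, k)
            ok = ids0 >= 0
            c0 += np.bincount(ids0[ok], weights=mult[ok], minlength=n_kmers)
            both = ok & (idsk >= 0)
            if both.any():
                ck += np.bincount(idsk[both], weights=mult[both], minlength=n_kmers)
                wk += mult[both].sum()
                vals_a.append(ids0[both])
                vals_b.append(idsk[both])
                wts.append(mult[both])
        total = c0.sum()
        anvs[i] = anv_of_freq_vector(c0 / total, k) if total > 0 else 0.0
        if wts and wk > 0:
            a = np.concatenate(vals_a)
            bb = np.concatenate(vals_b)
            w = np.concatenate(wts)
            # match the observed statistic: leave-one-site-out frequencies,
            # unweighted correlation over distinct sites
            va = (c0[a] - w) / np.maximum(total - w, 1.0)
            vb = (ck[bb] - w) / np.maximum(wk - w, 1.0)
            covs[i] = _weighted_pearson(va, vb, np.ones(a.size))
        else:
            covs[i] = 0.0
    baseline.null_tile_anv_mean = float(anvs.mean())
    baseline.null_tile_anv_sd = float(anvs.std())
    baseline.null_tile_cov_mean = float(covs.mean())
    baseline.null_tile_cov_sd = float(covs.std())
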