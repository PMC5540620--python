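"""Tiling of the signature, bias flagging, tile covariance and grouping.

Offsets are partitioned into non-overlapping k-wide "tiles" anchored so that
tile 0 starts at offset 0 (tile -1 covers offsets -k..-1, straddling the cut
site together with tile 0).  A tile is significantly biased when its average
nucleotide variance (anv) exceeds the baseline null by more than two standard
deviations.  Biased tiles whose per-read adjustment values co-vary are merged
into covariance groups, treated downstream as a single bias source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bias_signature import BaselineFrequencies, PositionalKmerFrequencies, kmer_ids_at
from .model_io import GenomeSequence, ReadSet


@dataclass(frozen=True)
class Tile:
    """A non-overlapping k-wide window; tile i covers offsets i*k .. i*k+k-1."""

    index: int
    k: int

    @property
    def start_offset(self) -> int:
        return self.index * self.k


@dataclass(frozen=True)
class TileStats:
    tile: Tile
    anv: float
    threshold: float

    @property
    def biased(self) -> bool:
        return self.anv > self.threshold


@dataclass
class CovarianceGrouping:
    biased_tiles: List[Tile]
    cov_matrix: np.ndarray
    expected_cov_mean: float
    expected_cov_sd: float
    groups: List[List[Tile]]


def tiles_for_signature(freqs: PositionalKmerFrequencies) -> List[Tile]:
    """All complete tiles within the signature's offset range."""
    k = freqs.k
    lo = int(freqs.offsets.min())
    hi = int(freqs.offsets.max())
    first = -(-lo // k)          # ceil division: first index with start >= lo
    last = (hi + 1 - k) // k     # last index whose tile fits entirely
    return [Tile(i, k) for i in range(first, last + 1)]


def nucleotide_marginals(freq_vec: np.ndarray, k: int) -> np.ndarray:
    """(k, 4) matrix of single-nucleotide frequencies by position, from a
    4^k k-mer frequency vector."""
    cube = np.asarray(freq_vec, dtype=np.float64).reshape((4,) * k)
    out = np.empty((k, 4))
    for i in range(k):
        axes = tuple(j for j in range(k) if j != i)
        out[i] = cube.sum(axis=axes) if axes else cube
    return out


def anv_of_freq_vector(freq_vec: np.ndarray, k: int) -> float:
    """Average nucleotide variance of a tile given its k-mer frequencies.

    For each nucleotide, the population variance (denominator k) of its
    frequency across the k positions of the tile, averaged over A, C, G, T —
    a measure of how flat the nucleotide profile is across the tile.
    """
    marg = nucleotide_marginals(freq_vec, k)
    return float(marg.var(axis=0, ddof=0).mean())


def average_nucleotide_variance(freqs: PositionalKmerFrequencies, tile: Tile) -> float:
    for t in range(tile.start_offset, tile.start_offset + tile.k):
        if not freqs.has_offset(t):
            raise ValueError(f"tile {tile.index}: offset {t} is unpopulated")
    return anv_of_freq_vector(freqs.freq_row(tile.start_offset), tile.k)


def select_biased_tiles(
    freqs: PositionalKmerFrequencies,
    baseline: BaselineFrequencies,
    tiles: Optional[Sequence[Tile]] = None,
) -> List[TileStats]:
    """Flag tiles whose anv exceeds the baseline null mean by > 2 SD."""
    if tiles is None:
        tiles = tiles_for_signature(freqs)
    threshold = baseline.null_tile_anv_mean + 2.0 * baseline.null_tile_anv_sd
    return [
        TileStats(tile, average_nucleotide_variance(freqs, tile), threshold)
        for tile in tiles
    ]


# ---------------------------------------------------------------------------
# Covariance
# ---------------------------------------------------------------------------

def _unique_site_mask(reads: ReadSet) -> np.ndarray:
    """Mask selecting one read per distinct (chrom, cut site, strand).

    Reads stacked on the same site carry identical context at every tile, so
    duplicates add no information about tile-to-tile dependence — but they
    would couple the two value vectors and inflate the correlation."""
    fp = reads.five_prime
    key = (
        reads.chrom_index.astype(np.int64) * (int(fp.max()) + 2) * 2
        + fp * 2
        + reads.is_reverse
    )
    _, first = np.unique(key, return_index=True)
    mask = np.zeros(reads.total_count, dtype=bool)
    mask[first] = True
    return mask


def _tile_value_vectors(
    reads: ReadSet,
    genome: GenomeSequence,
    freqs: PositionalKmerFrequencies,
    tiles: Sequence[Tile],
) -> np.ndarray:
    """(n_tiles, n_sites) matrix of the signature frequency of the k-mer at
    each tile for each distinct cut site; NaN where context is unavailable.

    The frequency is leave-one-site-out: the site's own stack of reads is
    subtracted from its k-mer's count before normalizing.  Self-counting
    otherwise couples a site's values at *every* pair of tiles (its stack
    inflates both lookups), which masquerades as tile-to-tile covariance."""
    keep = _unique_site_mask(reads)
    fp_all = reads.five_prime
    key = (
        reads.chrom_index.astype(np.int64) * (int(fp_all.max()) + 2) * 2
        + fp_all * 2
        + reads.is_reverse
    )
    _, inverse, mult_per_site = np.unique(key, return_inverse=True, return_counts=True)
    five_prime = fp_all[keep]
    chrom_index = reads.chrom_index[keep]
    is_reverse = reads.is_reverse[keep]
    mult = mult_per_site[inverse[keep]].astype(np.float64)
    n = int(keep.sum())
    values = np.full((len(tiles), n), np.nan)
    for ci, chrom in enumerate(reads.chroms):
        sel = np.flatnonzero(chrom_index == ci)
        if sel.size == 0:
            continue
        fp = five_prime[sel]
        rev = is_reverse[sel]
        for ti, tile in enumerate(tiles):
            ids = kmer_ids_at(genome, chrom, fp, rev, tile.start_offset, tile.k)
            i = freqs._index[tile.start_offset]
            counts = freqs.counts[i]
            total = freqs.evaluated[i]
            ok = ids >= 0
            m = mult[sel[ok]]
            denom = np.maximum(total - m, 1.0)
            values[ti, sel[ok]] = (counts[ids[ok]] - m) / denom
    return values


def tile_covariance(
    reads: ReadSet,
    genome: GenomeSequence,
    freqs: PositionalKmerFrequencies,
    tileA: Tile,
    tileB: Tile,
) -> float:
    """Correlation, across reads, of the signature frequencies of each
    read's own k-mer at the two tiles; 0 if either vector is constant."""
    v = _tile_value_vectors(reads, genome, freqs, [tileA, tileB])
    ok = ~np.isnan(v).any(axis=0)
    if ok.sum() < 2:
        raise ValueError(
            f"fewer than 2 reads evaluable at tiles {tileA.index}, {tileB.index}"
        )
    va, vb = v[0, ok], v[1, ok]
    if va.std() == 0 or vb.std() == 0:
        return 0.0
    return float(np.corrcoef(va, vb)[0, 1])


def covariance_matrix(
    reads: ReadSet,
    genome: GenomeSequence,
    freqs: PositionalKmerFrequencies,
    tiles: Sequence[Tile],
) -> np.ndarray:
    """Symmetric matrix of pairwise tile covariances (see tile_covariance)."""
    v = _tile_value_vectors(reads, genome, freqs, tiles)
    m = len(tiles)
    cov = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            ok = ~np.isnan(v[i]) & ~np.isnan(v[j])
            if ok.sum() < 2 or v[i, ok].std() == 0 or v[j, ok].std() == 0:
                c = 0.0
            else:
                c = float(np.corrcoef(v[i, ok], v[j, ok])[0, 1])
            cov[i, j] = cov[j, i] = c
    return cov


def cluster_tiles(
    stats: Sequence[TileStats],
    cov: np.ndarray,
    expected_cov_mean: float,
    expected_cov_sd: float,
) -> CovarianceGrouping:
    """Greedy average-linkage merging of biased tiles into covariance groups.

    Starting from singletons, repeatedly merge the pair of groups with the
    highest average pairwise inter-group covariance, as long as that average
    exceeds expected_cov_mean + 2 * expected_cov_sd.  Ties break toward the
    smallest tile indices, making the partition deterministic and invariant
    to input order.
    """
    biased = sorted(
        (s.tile for s in stats if s.biased), key=lambda t: t.index
    )
    # reindex cov to the sorted biased tiles
    order = sorted(range(len(stats)), key=lambda i: stats[i].tile.index)
    biased_pos = [i for i in order if stats[i].biased]
    cov = np.asarray(cov)
    if cov.shape[0] == len(stats):
        cov_b = cov[np.ix_(biased_pos, biased_pos)]
    elif cov.shape[0] == len(biased):
        cov_b = cov
    else:
        raise ValueError("covariance matrix shape matches neither all nor biased tiles")

    threshold = expected_cov_mean + 2.0 * expected_cov_sd
    groups: List[List[int]] = [[i] for i in range(len(biased))]
    while len(groups) > 1:
        best_key: Optional[Tuple[float, int, int]] = None
        best_pair: Tuple[int, int] = (0, 0)
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                link = float(
                    np.mean([cov_b[a, b] for a in groups[gi] for b in groups[gj]])
                )
                key = (link, -biased[groups[gi][0]].index, -biased[groups[gj][0]].index)
                if best_key is None or key > best_key:
                    best_key, best_pair = key, (gi, gj)
        if best_key is None or best_key[0] <= threshold:
            break
        gi, gj = best_pair
        merged = sorted(groups[gi] + groups[gj])
        groups = [g for idx, g in enumerate(groups) if idx not in (gi, gj)]
        groups.append(merged)
        groups.sort(key=lambda g: g[0])
    return CovarianceGrouping(
        biased_tiles=list(biased),
        cov_matrix=cov_b,
        expected_cov_mean=expected_cov_mean,
        expected_cov_sd=expected_cov_sd,
        groups=[[biased[i] for i in g] for g in sorted(groups, key=lambda g: g[0])],
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def tile_stats_to_tsv(stats: Sequence[TileStats], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("tile_index\tstart_offset\tanv\tthreshold\tbiased\n")
        for s in stats:
            fh.write(
                f"{s.tile.index}\t{s.tile.start_offset}\t{s.anv:.17g}\t"
                f"{s.threshold:.17g}\t{int(s.biased)}\n"
            )
    return path


def tile_stats_from_tsv(path: str | Path, k: int) -> List[TileStats]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            idx, _start, anv, threshold, _biased = line.rstrip("\n").split("\t")
            out.append(TileStats(Tile(int(idx), k), float(anv), float(threshold)))
    return out


def covariance_to_tsv(tiles: Sequence[Tile], cov: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("tile\t" + "\t".join(str(t.index) for t in tiles) + "\n")
        for i, t in enumerate(tiles):
            fh.write(
                str(t.index)
                + "\t"
                + "\t".join(f"{cov[i, j]:.17g}" for j in range(len(tiles)))
                + "\n"
            )
    return path


def groups_to_json(grouping: CovarianceGrouping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(
            {
                "expected_cov_mean": grouping.expected_cov_mean,
                "expected_cov_sd": grouping.expected_cov_sd,
                "groups": [[t.index for t in g] for g in grouping.groups],
            },
            fh,
            indent=1,
        )
    return path


def groups_from_json(path: str | Path, k: int, cov: Optional[np.ndarray] = None) -> CovarianceGrouping:
    with open(path) as fh:
        data = json.load(fh)
    groups = [[Tile(i, k) for i in g] for g in data["groups"]]
    biased = sorted((t for g in groups for t in g), key=lambda t: t.index)
    return CovarianceGrouping(
        biased_tiles=biased,
        cov_matrix=cov if cov is not None else np.eye(len(biased)),
        expected_cov_mean=data["expected_cov_mean"],
        expected_cov_sd=data["expected_cov_sd"],
        groups=groups,
    )
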