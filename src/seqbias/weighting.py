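"""Read weight computation: per-tile ratios, group compounding, local
normalization, and attachment of weights to reads.

The correction weight of a tile at a genomic 5' site is the ratio between
the baseline frequency of the k-mer found there and its observed frequency
at that tile of the signature.  Tile weights are averaged within each
covariance group (tiles driven by the same bias source), the group values
are multiplied into a sequence weight, and each read's sequence weight is
finally normalized by the average sequence weight of the 20 flanking start
sites (±10 bp along the read's strand) so that stable local genomic context
(e.g. GC content) does not masquerade as bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bias_signature import (
    BaselineFrequencies,
    PositionalKmerFrequencies,
    kmer_ids_at,
)
from .model_io import (
    AlignedReadRecord,
    GenomeSequence,
    ReadSet,
    WeightedRead,
    logger,
)
from .tile_analysis import CovarianceGrouping, Tile

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_FLOOR = 0.01
DEFAULT_CAP = 100.0
NORMALIZE_HALF_WINDOW = 10


class ContextUnavailable(Exception):
    """Raised when a weight's sequence context cannot be resolved."""


@dataclass
class WeightModel:
    """A fitted bias model: signature + baseline + covariance grouping.

    ``pseudocount`` is a count added to every k-mer in both the signature
    and the baseline before forming the baseline/observed ratio, guarding against
    division by zero for rare k-mers; weights are clamped to
    [weight_floor, weight_cap].
    """

    k: int
    signature: PositionalKmerFrequencies
    baseline: BaselineFrequencies
    grouping: CovarianceGrouping
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    weight_floor: float = DEFAULT_FLOOR
    weight_cap: float = DEFAULT_CAP
    normalize: bool = True
    _luts: Dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if not (0 < self.weight_floor <= 1 <= self.weight_cap):
            raise ValueError("need 0 < weight_floor <= 1 <= weight_cap")

    @property
    def read_length(self) -> int:
        return self.signature.read_length

    def tile_lut(self, tile: Tile) -> np.ndarray:
        """Per-k-mer weight lookup (baseline/observed, smoothed, clamped)."""
        if tile.index not in self._luts:
            f = self.signature.smoothed_freq_row(tile.start_offset, self.pseudocount)
            b = self.baseline.smoothed_frequencies(self.pseudocount)
            with np.errstate(divide="ignore", invalid="ignore"):
                w = b / f
            w[(b == 0) & (f == 0)] = 1.0  # k-mer absent everywhere: no evidence
            w = np.clip(w, self.weight_floor, self.weight_cap)
            self._luts[tile.index] = w
        return self._luts[tile.index]


# ---------------------------------------------------------------------------
# Core weight computations
# ---------------------------------------------------------------------------

def tile_weight(
    model: WeightModel,
    genome: GenomeSequence,
    chrom: str,
    pos: int,
    strand: str,
    tile: Tile,
) -> float:
    """Baseline-over-observed adjustment for one tile at a 5' site (clamped)."""
    ids = kmer_ids_at(
        genome,
        chrom,
        np.array([pos]),
        np.array([strand == "-"]),
        tile.start_offset,
        model.k,
    )
    if ids[0] < 0:
        raise ContextUnavailable(f"{chrom}:{pos}{strand} tile {tile.index}")
    return float(model.tile_lut(tile)[ids[0]])


def _sequence_weights(
    model: WeightModel,
    genome: GenomeSequence,
    chrom: str,
    positions: np.ndarray,
    is_reverse: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized sequence weights for arrays of candidate 5' sites.

    Returns (weights, resolved): a site is resolved when at least one tile of
    at least one group has usable context; unresolved sites get weight 1.
    """
    n = positions.size
    weight = np.ones(n)
    resolved = np.zeros(n, dtype=bool)
    if not model.grouping.groups:
        return weight, np.ones(n, dtype=bool)
    for group in model.grouping.groups:
        gsum = np.zeros(n)
        gcount = np.zeros(n)
        for tile in group:
            ids = kmer_ids_at(
                genome, chrom, positions, is_reverse, tile.start_offset, model.k
            )
            ok = ids >= 0
            if ok.any():
                gsum[ok] += model.tile_lut(tile)[ids[ok]]
                gcount[ok] += 1
        has = gcount > 0
        weight[has] *= gsum[has] / gcount[has]
        resolved |= has
    np.clip(weight, model.weight_floor, model.weight_cap, out=weight)
    weight[~resolved] = 1.0
    return weight, resolved


def sequence_weight(
    model: WeightModel,
    genome: GenomeSequence,
    chrom: str,
    pos: int,
    strand: str,
) -> float:
    """Whole-sequence weight at one 5' site: within-group mean tile weights,
    multiplied across groups, clamped.  Empty grouping returns 1."""
    w, resolved = _sequence_weights(
        model, genome, chrom, np.array([pos]), np.array([strand == "-"])
    )
    if not resolved[0]:
        raise ContextUnavailable(f"{chrom}:{pos}{strand}")
    return float(w[0])


def normalization_offsets(model: WeightModel) -> List[int]:
    """Strand-relative 5' shifts used for the local-context normalizer.

    Twenty shifts, ten per side, starting just beyond the span of the biased
    tiles: a shift of at least the span width guarantees the neighbor's tile
    windows do not overlap the read's own, so the read's bias motif cannot
    leak into its own normalizer (which would partially cancel the
    correction).  With no biased tiles the offsets default to ±1..10.
    """
    tiles = model.grouping.biased_tiles
    if tiles:
        lo = min(t.start_offset for t in tiles)
        hi = max(t.start_offset + t.k for t in tiles)
        start = max(1, hi - lo)
    else:
        start = 1
    return [-j for j in range(start, start + NORMALIZE_HALF_WINDOW)] + [
        j for j in range(start, start + NORMALIZE_HALF_WINDOW)
    ]


def normalize_read_weight(
    model: WeightModel,
    genome: GenomeSequence,
    record: AlignedReadRecord,
) -> float:
    """Sequence weight at the read's own site, normalized by the mean
    sequence weight of flanking 5' sites along the read's strand."""
    pos = record.five_prime
    rev = record.strand == "-"
    own = sequence_weight(model, genome, record.chrom, pos, record.strand)
    offs = normalization_offsets(model)
    shifts = np.array([pos - j if rev else pos + j for j in offs])
    w, resolved = _sequence_weights(
        model, genome, record.chrom, shifts, np.full(len(offs), rev)
    )
    denom = float(w[resolved].mean()) if resolved.any() else 1.0
    return own / denom


def assign_read_weights(
    model: WeightModel,
    reads: ReadSet,
    genome: GenomeSequence,
) -> List[WeightedRead]:
    """One WeightedRead per input record (order preserved).

    Reads whose context is entirely unavailable receive weight 1; their
    count is logged."""
    w = read_weight_vector(model, reads, genome)
    return [WeightedRead(record=reads.record(i), weight=float(w[i])) for i in range(len(w))]


def read_weight_vector(
    model: WeightModel,
    reads: ReadSet,
    genome: GenomeSequence,
) -> np.ndarray:
    """Vectorized weights aligned with the ReadSet's record order."""
    n = reads.total_count
    out = np.ones(n)
    resolved_mask = np.zeros(n, dtype=bool)
    unresolved_total = 0
    five_prime = reads.five_prime
    offs = normalization_offsets(model)
    for ci, chrom in enumerate(reads.chroms):
        sel = np.flatnonzero(reads.chrom_index == ci)
        if sel.size == 0:
            continue
        fp = five_prime[sel]
        rev = reads.is_reverse[sel]
        own, resolved = _sequence_weights(model, genome, chrom, fp, rev)
        if model.normalize and model.grouping.groups:
            denom_sum = np.zeros(sel.size)
            denom_cnt = np.zeros(sel.size)
            for j in offs:
                shifted = np.where(rev, fp - j, fp + j)
                wj, rj = _sequence_weights(model, genome, chrom, shifted, rev)
                denom_sum[rj] += wj[rj]
                denom_cnt[rj] += 1
            denom = np.where(denom_cnt > 0, denom_sum / np.maximum(denom_cnt, 1), 1.0)
            own = own / denom
        own[~resolved] = 1.0
        unresolved_total += int((~resolved).sum())
        out[sel] = own
        resolved_mask[sel] = resolved
    if model.normalize and model.grouping.groups and resolved_mask.any():
        # weights are relative; report them as fractional read counts by
        # rescaling the resolved reads to mean 1
        out[resolved_mask] /= out[resolved_mask].mean()
    if unresolved_total:
        logger.info(
            "%d of %d reads had no resolvable context; weight set to 1",
            unresolved_total,
            n,
        )
    return out


def expand_integer_copies(
    reads: Sequence[WeightedRead],
    scale: int = 1,
    seed: int = 0,
) -> List[AlignedReadRecord]:
    """Represent weights as variable integer copies of each read.

    Each read is emitted floor(weight * scale) times plus one more with
    probability equal to the fractional part (stochastic rounding), so the
    expected emitted count is scale * sum of weights."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    rng = np.random.default_rng(seed)
    out: List[AlignedReadRecord] = []
    for wr in reads:
        value = wr.weight * scale
        copies = int(np.floor(value))
        frac = value - copies
        if frac > 0 and rng.random() < frac:
            copies += 1
        out.extend([wr.record] * copies)
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_model(
    reads: ReadSet,
    genome: GenomeSequence,
    k: int = 5,
    upstream: int = 20,
    downstream: int = 20,
    margin: int = 25,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    weight_floor: float = DEFAULT_FLOOR,
    weight_cap: float = DEFAULT_CAP,
    normalize: bool = True,
):
    """Fit the full bias model on one replicate: signature, baseline,
    flagged tiles, covariance grouping.  Returns (model, tile_stats)."""
    from .bias_signature import compute_signature, sample_baseline
    from .tile_analysis import (
        cluster_tiles,
        covariance_matrix,
        select_biased_tiles,
    )

    signature = compute_signature(reads, genome, k, upstream, downstream)
    baseline = sample_baseline(reads, genome, k, margin, seed)
    stats = select_biased_tiles(signature, baseline)
    biased = [s.tile for s in stats if s.biased]
    cov = covariance_matrix(reads, genome, signature, biased)
    grouping = cluster_tiles(
        [s for s in stats if s.biased],
        cov,
        baseline.null_tile_cov_mean,
        baseline.null_tile_cov_sd,
    )
    model = WeightModel(
        k=k,
        signature=signature,
        baseline=baseline,
        grouping=grouping,
        pseudocount=pseudocount,
        weight_floor=weight_floor,
        weight_cap=weight_cap,
        normalize=normalize,
    )
    return model, stats


# ---------------------------------------------------------------------------
# Model persistence (directory of open TSV/JSON)
# ---------------------------------------------------------------------------

def save_model(model: WeightModel, directory: str | Path, stats=None) -> Path:
    from .tile_analysis import covariance_to_tsv, groups_to_json, tile_stats_to_tsv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if stats is not None:
        tile_stats_to_tsv(stats, directory / "tiles.tsv")
    model.signature.to_tsv(directory / "signature.tsv")
    model.baseline.to_tsv(directory / "baseline.tsv")
    covariance_to_tsv(
        model.grouping.biased_tiles, model.grouping.cov_matrix, directory / "covariance.tsv"
    )
    groups_to_json(model.grouping, directory / "groups.json")
    params = {
        "k": model.k,
        "read_length": model.read_length,
        "pseudocount": model.pseudocount,
        "weight_floor": model.weight_floor,
        "weight_cap": model.weight_cap,
        "normalize": model.normalize,
        "baseline": model.baseline.meta(),
    }
    with open(directory / "params.json", "w") as fh:
        json.dump(params, fh, indent=1, sort_keys=True)
    return directory


def load_model(directory: str | Path) -> WeightModel:
    from .tile_analysis import groups_from_json

    directory = Path(directory)
    with open(directory / "params.json") as fh:
        params = json.load(fh)
    k = params["k"]
    signature = PositionalKmerFrequencies.from_tsv(
        directory / "signature.tsv", k, params["read_length"]
    )
    baseline = BaselineFrequencies.from_tsv(
        directory / "baseline.tsv", params["baseline"]
    )
    grouping = groups_from_json(directory / "groups.json", k)
    return WeightModel(
        k=k,
        signature=signature,
        baseline=baseline,
        grouping=grouping,
        pseudocount=params["pseudocount"],
        weight_floor=params["weight_floor"],
        weight_cap=params["weight_cap"],
        normalize=params["normalize"],
    )
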