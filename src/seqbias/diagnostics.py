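"""Characterization outputs: per-offset nucleotide profiles, the k-mer tile
feature space used to compare experiments, and aggregate cut-site profiles
around genomic sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bias_signature import PositionalKmerFrequencies
from .model_io import WeightedRead
from .tile_analysis import Tile, nucleotide_marginals


@dataclass
class NucleotideProfile:
    """Per-offset single-nucleotide frequencies (columns A, C, G, T)."""

    offsets: np.ndarray
    freq: np.ndarray  # (n_offsets, 4), rows sum to 1
    label: str = "raw"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freq, index=pd.Index(self.offsets, name="offset"), columns=list("ACGT")
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")
        return path


def nucleotide_profile(
    freqs: PositionalKmerFrequencies, label: str = "raw"
) -> NucleotideProfile:
    """Marginalize the k-mer signature to single-nucleotide frequencies.

    Offset t is covered by the k k-mer tables starting at t-k+1 .. t; the
    profile averages the marginal of each available table at the matching
    character position."""
    k = freqs.k
    offsets = []
    rows = []
    for t in freqs.offsets:
        t = int(t)
        acc = np.zeros(4)
        n = 0
        for s in range(t - k + 1, t + 1):
            if freqs.has_offset(s):
                acc += nucleotide_marginals(freqs.freq_row(s), k)[t - s]
                n += 1
        if n:
            offsets.append(t)
            rows.append(acc / n)
    return NucleotideProfile(np.array(offsets), np.stack(rows), label)


@dataclass
class BiasFeatureVector:
    """Concatenated per-tile k-mer frequencies of one experiment, with a
    fixed (tile, lexicographic k-mer) feature ordering."""

    experiment_id: str
    tile_indices: List[int]
    values: np.ndarray  # length n_tiles * 4^k
    k: int


def bias_feature_vector(
    freqs: PositionalKmerFrequencies,
    tiles: Sequence[Tile],
    experiment_id: str = "",
) -> BiasFeatureVector:
    parts = [freqs.freq_row(t.start_offset) for t in tiles]
    return BiasFeatureVector(
        experiment_id=experiment_id,
        tile_indices=[t.index for t in tiles],
        values=np.concatenate(parts),
        k=freqs.k,
    )


def feature_matrix(vectors: Sequence[BiasFeatureVector]) -> pd.DataFrame:
    """Experiments x features matrix, suitable for PCA with standard tools."""
    if not vectors:
        raise ValueError("no feature vectors")
    ref = vectors[0]
    from .bias_signature import kmer_string

    columns = [
        f"tile{ti}:{kmer_string(j, ref.k)}"
        for ti in ref.tile_indices
        for j in range(4 ** ref.k)
    ]
    for v in vectors:
        if v.tile_indices != ref.tile_indices or v.k != ref.k:
            raise ValueError("feature vectors have mismatched tile layouts")
    return pd.DataFrame(
        np.stack([v.values for v in vectors]),
        index=[v.experiment_id for v in vectors],
        columns=columns,
    )


def aggregate_site_profile(
    reads: Sequence[WeightedRead],
    sites: Sequence[Tuple[str, int, str]],
    flank: int = 250,
) -> pd.Series:
    """Weighted 5'-end (cut) counts by offset relative to a set of sites.

    Offsets are strand-oriented: for a minus-strand site, upstream is to the
    right.  Returns a Series indexed by offset in [-flank, flank]."""
    if not sites:
        raise ValueError("no sites given")
    offsets = np.arange(-flank, flank + 1)
    acc = np.zeros(offsets.size)
    by_chrom: Dict[str, List[Tuple[int, float]]] = {}
    for wr in reads:
        by_chrom.setdefault(wr.record.chrom, []).append(
            (wr.record.five_prime, wr.weight)
        )
    chrom_arrays = {
        c: (np.array([p for p, _ in v]), np.array([w for _, w in v]))
        for c, v in by_chrom.items()
    }
    for chrom, pos, strand in sites:
        if chrom not in chrom_arrays:
            continue
        cuts, w = chrom_arrays[chrom]
        rel = cuts - pos if strand == "+" else pos - cuts
        ok = (rel >= -flank) & (rel <= flank)
        if ok.any():
            acc += np.bincount(rel[ok] + flank, weights=w[ok], minlength=offsets.size)
    return pd.Series(acc, index=pd.Index(offsets, name="offset"), name="weight")


def profile_plot(
    profiles: Sequence[NucleotideProfile],
    path: str | Path,
) -> Path:
    """Per-offset nucleotide frequency line plot (one panel per profile)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, len(profiles), figsize=(6 * len(profiles), 4), squeeze=False
    )
    for ax, prof in zip(axes[0], profiles):
        for i, base in enumerate("ACGT"):
            ax.plot(prof.offsets, prof.freq[:, i], label=base)
        ax.set_xlabel("offset from 5' end")
        ax.set_ylabel("frequency")
        ax.set_title(prof.label)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
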