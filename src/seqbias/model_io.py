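"""Domain types and I/O for aligned reads, reference sequences and weighted output.

Coordinates are 0-based, half-open everywhere inside the package; SAM's
1-based positions are converted at the I/O boundary.  Read weights are
attached to alignments as the optional SAM tag ``XW`` (single-precision
float).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pysam

logger = logging.getLogger("seqbias")

WEIGHT_TAG = "XW"

# nucleotide integer codes; N (and every non-ACGT ambiguity code) maps to 4
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_DECODE = np.array(list("ACGTN"))


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedReadRecord:
    """A single aligned read: leftmost 0-based position plus strand.

    ``start`` is always the leftmost reference coordinate, also for minus
    strand reads; the 5' end of a minus strand read is ``start + length - 1``.
    """

    read_id: str
    chrom: str
    start: int
    length: int
    strand: str
    mapq: int = 0
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for read {self.read_id}")
        if self.length <= 0:
            raise ValueError(f"non-positive length for read {self.read_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-' for read {self.read_id}")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' terminal base (the cut site)."""
        return self.start if self.strand == "+" else self.start + self.length - 1


class ReadSet:
    """An ordered collection of aligned reads, sorted by (chrom, start).

    Internally column-oriented (numpy arrays) so that signature and weight
    computations vectorize; `records` iterates dataclass views for callers
    that want per-read objects.
    """

    def __init__(
        self,
        chroms: Sequence[str],
        chrom_index: np.ndarray,
        start: np.ndarray,
        length: np.ndarray,
        is_reverse: np.ndarray,
        mapq: np.ndarray,
        is_primary: np.ndarray,
        read_ids: Optional[Sequence[str]] = None,
        source_path: str = "",
    ):
        order = np.lexsort((start, chrom_index))
        self.chroms = list(chroms)
        self.chrom_index = np.asarray(chrom_index, dtype=np.int32)[order]
        self.start = np.asarray(start, dtype=np.int64)[order]
        self.length = np.asarray(length, dtype=np.int32)[order]
        self.is_reverse = np.asarray(is_reverse, dtype=bool)[order]
        self.mapq = np.asarray(mapq, dtype=np.int32)[order]
        self.is_primary = np.asarray(is_primary, dtype=bool)[order]
        if read_ids is not None:
            self.read_ids: Optional[List[str]] = [read_ids[i] for i in order]
        else:
            self.read_ids = None
        self.source_path = source_path

    @property
    def total_count(self) -> int:
        return int(self.start.size)

    def __len__(self) -> int:
        return self.total_count

    @property
    def five_prime(self) -> np.ndarray:
        """Vector of 5'-end coordinates (cut sites) for all reads."""
        return np.where(self.is_reverse, self.start + self.length - 1, self.start)

    @property
    def modal_length(self) -> int:
        if self.total_count == 0:
            raise ValueError("empty read set has no modal length")
        values, counts = np.unique(self.length, return_counts=True)
        return int(values[np.argmax(counts)])

    def record(self, i: int) -> AlignedReadRecord:
        return AlignedReadRecord(
            read_id=self.read_ids[i] if self.read_ids else f"read{i}",
            chrom=self.chroms[self.chrom_index[i]],
            start=int(self.start[i]),
            length=int(self.length[i]),
            strand="-" if self.is_reverse[i] else "+",
            mapq=int(self.mapq[i]),
            is_primary=bool(self.is_primary[i]),
        )

    @property
    def records(self) -> Iterator[AlignedReadRecord]:
        for i in range(self.total_count):
            yield self.record(i)

    @classmethod
    def from_records(cls, records: Iterable[AlignedReadRecord], source_path: str = "") -> "ReadSet":
        records = list(records)
        chroms: List[str] = []
        chrom_to_idx: Dict[str, int] = {}
        idx = np.empty(len(records), dtype=np.int32)
        for i, r in enumerate(records):
            if r.chrom not in chrom_to_idx:
                chrom_to_idx[r.chrom] = len(chroms)
                chroms.append(r.chrom)
            idx[i] = chrom_to_idx[r.chrom]
        return cls(
            chroms=chroms,
            chrom_index=idx,
            start=np.array([r.start for r in records], dtype=np.int64),
            length=np.array([r.length for r in records], dtype=np.int32),
            is_reverse=np.array([r.strand == "-" for r in records], dtype=bool),
            mapq=np.array([r.mapq for r in records], dtype=np.int32),
            is_primary=np.array([r.is_primary for r in records], dtype=bool),
            read_ids=[r.read_id for r in records],
            source_path=source_path,
        )


class GenomeSequence:
    """Reference sequence store over the alphabet {A,C,G,T,N}.

    Sequences are held as int8 code arrays (A=0, C=1, G=2, T=3, N=4);
    ambiguity codes other than N are mapped to N on load.  Per-k k-mer id
    arrays (forward and reverse-complement) are cached lazily — they are the
    workhorse behind every signature/weight computation.
    """

    def __init__(self, sequences: Dict[str, str]):
        self._codes: Dict[str, np.ndarray] = {}
        for name, seq in sequences.items():
            arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
            self._codes[name] = _CODE[arr]
        self._kmer_cache: Dict[Tuple[str, int], Tuple[np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        return read_reference(path)

    @property
    def chrom_names(self) -> List[str]:
        return list(self._codes)

    def chrom_length(self, chrom: str) -> int:
        return int(self.codes(chrom).size)

    def codes(self, chrom: str) -> np.ndarray:
        try:
            return self._codes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def sequence(self, chrom: str, start: int, end: int) -> str:
        codes = self.codes(chrom)
        if start < 0 or end > codes.size or start > end:
            raise IndexError(
                f"window [{start}, {end}) outside {chrom} of length {codes.size}"
            )
        return "".join(_DECODE[codes[start:end]])

    def kmer_ids(self, chrom: str, k: int) -> Tuple[np.ndarray, np.ndarray]:
        """(forward, revcomp) k-mer id arrays of length L - k + 1.

        forward[p] encodes S[p:p+k] read left-to-right; revcomp[p] encodes the
        reverse complement of the same window read 5'->3' on the minus strand.
        Windows containing N have id -1.  Ids are base-4, first (5'-most)
        base most significant, so numeric order is lexicographic order.
        """
        key = (chrom, k)
        if key not in self._kmer_cache:
            codes = self.codes(chrom).astype(np.int64)
            L = codes.size
            if L < k:
                fwd = np.empty(0, dtype=np.int64)
                rev = np.empty(0, dtype=np.int64)
            else:
                win = np.lib.stride_tricks.sliding_window_view(codes, k)
                pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
                valid = (win < 4).all(axis=1)
                clipped = np.minimum(win, 3)
                fwd = clipped @ pw
                # complement of code c is 3 - c; minus-strand 5'->3' reads the
                # window right-to-left, so reverse the power vector
                rev = (3 - clipped) @ pw[::-1]
                fwd[~valid] = -1
                rev[~valid] = -1
            self._kmer_cache[key] = (fwd, rev)
        return self._kmer_cache[key]


@dataclass(frozen=True)
class WeightedRead:
    record: AlignedReadRecord
    weight: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight) or self.weight <= 0:
            raise ValueError(
                f"weight must be finite and positive, got {self.weight} "
                f"for read {self.record.read_id}"
            )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_alignments(
    path: str | Path,
    min_mapq: int = 0,
    primary_only: bool = True,
) -> ReadSet:
    """Load mapped reads from SAM/BAM into a ReadSet.

    Unmapped reads are always excluded; secondary/supplementary alignments
    are excluded when ``primary_only``.  Malformed records are skipped with a
    logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    records: List[AlignedReadRecord] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), mode) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            primary = not (aln.is_secondary or aln.is_supplementary)
            if primary_only and not primary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            length = aln.query_length or aln.infer_query_length()
            if length is None or length <= 0 or aln.reference_start < 0:
                skipped += 1
                continue
            records.append(
                AlignedReadRecord(
                    read_id=aln.query_name or "",
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    length=length,
                    strand="-" if aln.is_reverse else "+",
                    mapq=aln.mapping_quality,
                    is_primary=primary,
                )
            )
    if skipped:
        logger.warning("skipped %d malformed records in %s", skipped, path)
    return ReadSet.from_records(records, source_path=str(path))


def read_reference(path: str | Path) -> GenomeSequence:
    """Load a FASTA reference; duplicate sequence names are fatal."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences: Dict[str, str] = {}
    name = None
    parts: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(parts)
                name = line[1:].split()[0]
                if name in sequences:
                    raise ValueError(f"duplicate sequence name {name!r} in {path}")
                parts = []
            elif name is not None:
                parts.append(line.strip())
    if name is not None:
        if name in sequences:
            raise ValueError(f"duplicate sequence name {name!r} in {path}")
        sequences[name] = "".join(parts)
    return GenomeSequence(sequences)


def read_sites(path: str | Path) -> List[Tuple[str, int, str]]:
    """Read a BED file of sites; returns (chrom, midpoint, strand) tuples."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            sites.append((chrom, (start + end) // 2, strand))
    return sites


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def make_header(genome: GenomeSequence) -> Dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": c, "LN": genome.chrom_length(c)} for c in genome.chrom_names
        ],
    }


def write_weighted_alignments(
    reads: Sequence[WeightedRead],
    template_header: Dict | pysam.AlignmentHeader,
    path: str | Path,
    genome: Optional[GenomeSequence] = None,
) -> Path:
    """Write reads to SAM/BAM with the XW weight tag.

    Alignment fields are reconstructed from the records; when ``genome`` is
    given the read sequence is filled in from the reference (simulated
    error-free reads), otherwise SEQ is '*'.
    """
    path = Path(path)
    header = (
        template_header
        if isinstance(template_header, pysam.AlignmentHeader)
        else pysam.AlignmentHeader.from_dict(template_header)
    )
    mode = "wb" if path.suffix == ".bam" else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for wr in reads:
            if not np.isfinite(wr.weight) or wr.weight <= 0:
                raise ValueError(
                    f"non-finite or non-positive weight for read {wr.record.read_id}"
                )
            r = wr.record
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.reference_id = header.get_tid(r.chrom)
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.flag = 16 if r.strand == "-" else 0
            if not r.is_primary:
                a.flag |= 256
            a.cigarstring = f"{r.length}M"
            if genome is not None:
                seq = genome.sequence(r.chrom, r.start, r.start + r.length)
                a.query_sequence = seq if r.strand == "+" else seq  # stored on + strand
                a.query_qualities = pysam.qualitystring_to_array("I" * r.length)
            a.set_tag(WEIGHT_TAG, float(wr.weight), value_type="f")
            out.write(a)
    return path


def read_weighted_alignments(path: str | Path) -> List[WeightedRead]:
    """Read back an XW-tagged SAM/BAM (weights default to 1.0 if untagged)."""
    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    out: List[WeightedRead] = []
    with pysam.AlignmentFile(str(path), mode) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            weight = aln.get_tag(WEIGHT_TAG) if aln.has_tag(WEIGHT_TAG) else 1.0
            out.append(
                WeightedRead(
                    record=AlignedReadRecord(
                        read_id=aln.query_name or "",
                        chrom=aln.reference_name,
                        start=aln.reference_start,
                        length=aln.query_length or aln.infer_query_length(),
                        strand="-" if aln.is_reverse else "+",
                        mapq=aln.mapping_quality,
                        is_primary=not (aln.is_secondary or aln.is_supplementary),
                    ),
                    weight=float(weight),
                )
            )
    return out


def write_weighted_coverage(
    reads: Sequence[WeightedRead],
    genome: GenomeSequence,
    path: str | Path,
) -> Path:
    """Weighted coverage to bedGraph (0-based half-open, equal runs merged)."""
    path = Path(path)
    per_chrom: Dict[str, np.ndarray] = {}
    for wr in reads:
        r = wr.record
        if r.chrom not in per_chrom:
            per_chrom[r.chrom] = np.zeros(genome.chrom_length(r.chrom) + 1)
        diff = per_chrom[r.chrom]
        diff[r.start] += wr.weight
        diff[min(r.start + r.length, diff.size - 1)] -= wr.weight
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            if chrom not in per_chrom:
                continue
            cov = np.cumsum(per_chrom[chrom][:-1])
            # run-length encode; emit only non-zero runs
            change = np.flatnonzero(np.diff(cov) != 0) + 1
            bounds = np.concatenate(([0], change, [cov.size]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = cov[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")
    return path


def bedgraph_area(path: str | Path) -> float:
    """Sum of value x interval-length over a bedGraph file."""
    total = 0.0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            _, s, e, v = line.split()
            total += (int(e) - int(s)) * float(v)
    return total
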