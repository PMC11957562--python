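"""Strand-specific signal tracks from alignments on a circular contig.

Two track kinds are produced from the same alignment set:

* ``five_prime`` — base-resolution counts of read 5' ends per strand
  (model training targets). The minus-strand 5' end is the rightmost
  aligned base, ``(start + length - 1) mod n``.
* ``coverage`` — per-base counts of read bodies per strand (screening
  and plotting).

Duplicate handling follows the single/paired-end distinction: paired-end
fragments sharing identical coordinates are collapsed to one
representative (first in file order), single-end reads are all retained.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedRead:
    """A mapped single-end read on the circular contig."""

    start: int  # 0-based leftmost coordinate, already reduced mod n
    length: int
    strand: str  # '+' or '-'

    def five_prime(self, genome_length: int) -> int:
        if self.strand == "+":
            return self.start
        return (self.start + self.length - 1) % genome_length

    @property
    def duplicate_key(self) -> tuple:
        return (self.start, self.strand, self.length)


@dataclass
class AlignmentSet:
    genome_name: str
    genome_length: int
    reads: list[AlignedRead] = field(default_factory=list)
    paired: bool = False
    dedup_applied: bool = False

    def __len__(self) -> int:
        return len(self.reads)

    def rotate(self, r: int) -> "AlignmentSet":
        n = self.genome_length
        return AlignmentSet(
            self.genome_name,
            n,
            [AlignedRead((rd.start + r) % n, rd.length, rd.strand) for rd in self.reads],
            self.paired,
            self.dedup_applied,
        )


@dataclass
class StrandedTrack:
    """Paired per-base plus/minus signal vectors over the circular contig."""

    genome_name: str
    kind: str  # five_prime | coverage | predicted
    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=np.float64)
        self.minus = np.asarray(self.minus, dtype=np.float64)
        if self.plus.shape != self.minus.shape or self.plus.ndim != 1:
            raise ValueError("plus/minus vectors must be 1-D and equal length")
        if (self.plus < 0).any() or (self.minus < 0).any():
            raise ValueError("track values must be non-negative")

    @property
    def length(self) -> int:
        return len(self.plus)

    @property
    def total(self) -> np.ndarray:
        return self.plus + self.minus

    def rotate(self, r: int) -> "StrandedTrack":
        return StrandedTrack(
            self.genome_name, self.kind, np.roll(self.plus, r), np.roll(self.minus, r)
        )


def load_alignments(path: str, genome_name: str, genome_length: int | None = None,
                    paired: bool = False) -> AlignmentSet:
    """Read mapped primary records for one contig from SAM/BAM.

    With ``paired=True`` PCR duplicates (identical fragment coordinates)
    are collapsed to the first record seen; with ``paired=False`` every
    mapped read is retained.
    """
    mode = "rb" if path.endswith(".bam") else "r"
    reads: list[AlignedRead] = []
    seen: set[tuple] = set()
    n_total = n_skipped = n_dup = 0
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        contigs = list(fh.references or [])
        if genome_name not in contigs:
            raise ValueError(
                f"contig {genome_name!r} absent from {path} header "
                f"(found {contigs!r})"
            )
        if genome_length is None:
            genome_length = fh.get_reference_length(genome_name)
        for rec in fh:
            n_total += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                n_skipped += 1
                continue
            if rec.reference_name != genome_name:
                raise ValueError(
                    f"record on contig {rec.reference_name!r}, expected {genome_name!r}"
                )
            strand = "-" if rec.is_reverse else "+"
            length = rec.query_alignment_length or rec.query_length or rec.infer_query_length()
            read = AlignedRead(rec.reference_start % genome_length, length, strand)
            if paired:
                if rec.is_paired:
                    key = (
                        min(rec.reference_start, rec.next_reference_start),
                        abs(rec.template_length),
                        strand,
                        rec.is_read1,
                    )
                else:
                    key = read.duplicate_key
                if key in seen:
                    n_dup += 1
                    continue
                seen.add(key)
            reads.append(read)
    logger.info(
        "loaded %d/%d records from %s (%d skipped, %d duplicates removed)",
        len(reads), n_total, path, n_skipped, n_dup,
    )
    if not reads:
        logger.warning("no mapped reads loaded from %s", path)
    return AlignmentSet(genome_name, genome_length, reads, paired=paired,
                        dedup_applied=paired)


def deduplicate(aln: AlignmentSet) -> AlignmentSet:
    """Collapse reads sharing a duplicate key; idempotent."""
    seen: set[tuple] = set()
    kept = []
    for read in aln.reads:
        if read.duplicate_key in seen:
            continue
        seen.add(read.duplicate_key)
        kept.append(read)
    return AlignmentSet(aln.genome_name, aln.genome_length, kept, aln.paired, True)


def five_prime_track(aln: AlignmentSet) -> StrandedTrack:
    """Base-resolution 5'-end counts per strand, wrap-aware."""
    n = aln.genome_length
    plus = np.zeros(n)
    minus = np.zeros(n)
    for read in aln.reads:
        p = read.five_prime(n)
        if read.strand == "+":
            plus[p] += 1
        else:
            minus[p] += 1
    return StrandedTrack(aln.genome_name, "five_prime", plus, minus)


def coverage_track(aln: AlignmentSet) -> StrandedTrack:
    """Per-base read-body coverage per strand with modular wrap.

    Uses a difference-array accumulator; a read wrapping the origin adds
    +1 at its start and carries the overflow back to position 0.
    """
    n = aln.genome_length
    diff = {"+": np.zeros(n + 1), "-": np.zeros(n + 1)}
    for read in aln.reads:
        d = diff[read.strand]
        end = read.start + read.length
        if end <= n:
            d[read.start] += 1
            d[end] -= 1
        else:
            d[read.start] += 1
            d[n] -= 1
            d[0] += 1
            d[end - n] -= 1
    plus = np.cumsum(diff["+"][:n])
    minus = np.cumsum(diff["-"][:n])
    return StrandedTrack(aln.genome_name, "coverage", plus, minus)


def write_track(track: StrandedTrack, prefix: str) -> tuple[str, str]:
    """Write a stranded track as a bedGraph pair ``<prefix>.{plus,minus}.bedGraph``."""
    from . import bedio

    paths = (f"{prefix}.plus.bedGraph", f"{prefix}.minus.bedGraph")
    bedio.write_bedgraph(track.plus, track.genome_name, paths[0])
    bedio.write_bedgraph(track.minus, track.genome_name, paths[1])
    return paths


def read_track(prefix: str, genome_name: str, length: int,
               kind: str = "coverage") -> StrandedTrack:
    from . import bedio

    plus = bedio.read_bedgraph(f"{prefix}.plus.bedGraph", length, genome_name)
    minus = bedio.read_bedgraph(f"{prefix}.minus.bedGraph", length, genome_name)
    return StrandedTrack(genome_name, kind, plus, minus)
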