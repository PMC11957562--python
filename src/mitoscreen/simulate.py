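"""Synthetic circular genomes and ChIP-like read simulation.

The simulator reproduces the two signal shapes the screening stage
discriminates between:

* *occupancy* sites — sequencing fragments centred on the site, one read
  taken from each fragment end on the matching strand, so plus-strand 5'
  ends pile up about half a fragment length upstream and minus-strand 5'
  ends the same distance downstream;
* *artifact* sites — strand-symmetric enrichment with no offset between
  the plus and minus 5'-end distributions (a D-loop-like shape).

Remaining reads are uniform on the circle. All randomness flows from one
``numpy`` generator seeded in :class:`SimConfig`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .genome import Annotation, CircularGenome, Duplication, reverse_complement
from .tracks import AlignedRead, AlignmentSet


@dataclass(frozen=True)
class TruthSite:
    """A planted ground-truth site."""

    position: int
    strand: str  # '+', '-', 'both'
    motif: str
    enrichment: float
    kind: str  # occupancy | artifact

    def __post_init__(self) -> None:
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if self.kind not in ("occupancy", "artifact"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.kind == "artifact" and self.strand != "both":
            raise ValueError("artifact sites must carry strand 'both'")


@dataclass
class SimConfig:
    n_reads: int
    read_length: int = 36
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 30.0
    background_fraction: float = 0.1
    seed: int = 0
    control: bool = False

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.fragment_length_mean < self.read_length:
            raise ValueError("fragment_length_mean must be >= read_length")
        if not (0.0 <= self.background_fraction <= 1.0):
            raise ValueError("background_fraction must lie in [0, 1]")


def generate_circular_genome(length: int, gc_content: float = 0.5,
                             duplications: list[tuple[int, int, int]] | None = None,
                             seed: int = 0, name: str = "chrM") -> CircularGenome:
    """Random circular genome with optional planted exact repeats.

    ``duplications`` is a list of ``(source_start, length, dest_start)``;
    each copies ``length`` bases (modular) from source to destination.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not (0.0 < gc_content < 1.0):
        raise ValueError("gc_content must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_content) / 2, gc_content / 2, gc_content / 2,
                  (1 - gc_content) / 2])
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=p)
    dup_objs = []
    for (src, dlen, dst) in duplications or []:
        if dlen > length:
            raise ValueError(
                f"duplication of length {dlen} does not fit in genome of length {length}"
            )
        idx_src = (src + np.arange(dlen)) % length
        idx_dst = (dst + np.arange(dlen)) % length
        seq[idx_dst] = seq[idx_src]
        dup_objs.append(Duplication(src % length, dlen, dst % length))
    return CircularGenome(name, "".join(seq), duplications=dup_objs)


def plant_motifs(genome: CircularGenome, motif: str,
                 placements: list[tuple[int, str, float, str]],
                 ) -> tuple[CircularGenome, list[TruthSite]]:
    """Write ``motif`` into the genome at occupancy placements and return
    the matching :class:`TruthSite` records.

    ``placements`` rows are ``(position, strand, enrichment, kind)``;
    ``position`` is the site centre. Artifact placements leave the
    sequence untouched. Overlapping occupancy placements are rejected.
    """
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 bases")
    n = genome.length
    seq = np.array(list(genome.sequence))
    occupied: set[int] = set()
    sites: list[TruthSite] = []
    for position, strand, enrichment, kind in placements:
        position = position % n
        sites.append(TruthSite(position, strand, motif, enrichment, kind))
        if kind != "occupancy":
            continue
        inserted = motif if strand == "+" else reverse_complement(motif)
        start = (position - len(motif) // 2) % n
        idx = (start + np.arange(len(motif))) % n
        overlap = occupied.intersection(idx.tolist())
        if overlap:
            raise ValueError(f"occupancy placement at {position} overlaps a previous one")
        occupied.update(idx.tolist())
        seq[idx] = list(inserted)
    planted = CircularGenome(genome.name, "".join(seq),
                             annotations=list(genome.annotations),
                             duplications=list(genome.duplications))
    return planted, sites


def simulate_reads(genome: CircularGenome, sites: list[TruthSite],
                   config: SimConfig) -> AlignmentSet:
    """Simulate ``config.n_reads`` aligned single-end reads.

    Each read is background with probability ``background_fraction``,
    otherwise assigned to a site with probability proportional to its
    enrichment. ``control=True`` suppresses all site enrichment.
    """
    n = genome.length
    for site in sites:
        if not (0 <= site.position < n):
            raise ValueError(f"site position {site.position} outside genome [0, {n})")
    rng = np.random.default_rng(config.seed)
    n_reads = config.n_reads
    rl = config.read_length

    if config.control or not sites:
        assignment = np.full(n_reads, -1)
    else:
        weights = np.array([s.enrichment for s in sites], dtype=float)
        weights = (1.0 - config.background_fraction) * weights / weights.sum()
        probs = np.concatenate(([config.background_fraction], weights))
        assignment = rng.choice(len(sites) + 1, size=n_reads, p=probs) - 1

    strands = rng.choice(np.array(["+", "-"]), size=n_reads)
    frag_lengths = rng.normal(config.fragment_length_mean,
                              config.fragment_length_sd, size=n_reads)
    frag_lengths = np.maximum(np.round(frag_lengths), rl).astype(int)
    uniform_pos = rng.integers(0, n, size=n_reads)
    artifact_offsets = np.round(
        rng.normal(0.0, config.fragment_length_mean / 2.0, size=n_reads)
    ).astype(int)

    reads: list[AlignedRead] = []
    for i in range(n_reads):
        strand = strands[i]
        a = assignment[i]
        if a < 0:
            five = int(uniform_pos[i])
        else:
            site = sites[a]
            if site.kind == "occupancy":
                L = frag_lengths[i]
                frag_start = site.position - L // 2
                five = frag_start if strand == "+" else frag_start + L - 1
            else:
                five = site.position + int(artifact_offsets[i])
        five %= n
        start = five if strand == "+" else (five - rl + 1) % n
        reads.append(AlignedRead(int(start), rl, str(strand)))
    return AlignmentSet(genome.name, n, reads)


def write_sam(aln: AlignmentSet, genome: CircularGenome, path: str) -> None:
    """Write the alignment set as SAM (single circular contig header).

    Reads whose body crosses the origin keep their modular leftmost start;
    the CIGAR states the full read length even where it extends past the
    linearized reference end.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome.name, "LN": genome.length, "TP": "circular"}],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as fh:
        for i, read in enumerate(aln.reads):
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = f"simread_{i}"
            rec.reference_id = 0
            rec.reference_start = read.start
            rec.mapping_quality = 255
            rec.cigarstring = f"{read.length}M"
            body = genome.fetch(read.start, read.length)
            if read.strand == "-":
                rec.flag = 16
                rec.query_sequence = reverse_complement(body)
            else:
                rec.flag = 0
                rec.query_sequence = body
            fh.write(rec)


def write_truth(sites: list[TruthSite], genome_length: int, path: str,
                width: int | None = None) -> None:
    """Serialize truth sites as BED with kind/enrichment columns.

    Each site becomes an interval of ``width`` (defaults to motif length,
    floor 1) centred on the position; intervals spanning the origin are
    split into two lines sharing one feature name.
    """
    rows = []
    for i, site in enumerate(sites):
        w = width if width is not None else max(len(site.motif), 1)
        start = (site.position - w // 2) % genome_length
        name = f"site_{i}"
        segments = Annotation(start, w).segments(genome_length)
        for j, (s, e) in enumerate(segments):
            part = name if len(segments) == 1 else f"{name}/part{j + 1}"
            rows.append(("chrM", s, e, part, f"{site.enrichment:g}", site.strand,
                         site.kind, site.position))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tenrichment\tstrand\tkind\tposition\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_truth(path: str) -> list[TruthSite]:
    """Inverse of :func:`write_truth` (split features collapse to one site)."""
    sites: dict[str, TruthSite] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            _, _, _, name, enrichment, strand, kind, position = line.rstrip("\n").split("\t")
            base = name.split("/")[0]
            if base not in sites:
                sites[base] = TruthSite(int(position), strand, "", float(enrichment), kind)
    return list(sites.values())
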