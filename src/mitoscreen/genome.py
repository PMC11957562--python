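"""Circular-genome primitives shared by every pipeline stage.

All coordinates in this package are 0-based, half-open and reduced modulo
the genome length. Features that span the origin are represented
canonically by ``(start, length)`` with ``0 <= start < length(genome)``,
never by two separate intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def wrap(pos: int, length: int) -> int:
    """Reduce a coordinate onto the circle ``[0, length)``."""
    return pos % length


@dataclass
class Annotation:
    """A labelled interval on the circle, canonical (start, length) form."""

    start: int
    length: int
    label: str = ""

    def positions(self, genome_length: int) -> np.ndarray:
        return (self.start + np.arange(self.length)) % genome_length

    def segments(self, genome_length: int) -> list[tuple[int, int]]:
        """Linear half-open segments covering the (possibly wrapping) interval."""
        end = self.start + self.length
        if end <= genome_length:
            return [(self.start, end)]
        return [(self.start, genome_length), (0, end - genome_length)]


@dataclass
class Duplication:
    """An exact repeated segment: ``length`` bases copied from
    ``source_start`` to ``dest_start`` (both modular)."""

    source_start: int
    length: int
    dest_start: int


@dataclass
class CircularGenome:
    """A single circular contig with sequence and interval annotations."""

    name: str
    sequence: str
    annotations: list[Annotation] = field(default_factory=list)
    duplications: list[Duplication] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
        for ann in self.annotations:
            if not (0 <= ann.start < len(self.sequence)):
                raise ValueError(
                    f"annotation {ann.label!r} start {ann.start} outside "
                    f"[0, {len(self.sequence)})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, length: int) -> str:
        """Extract ``length`` bases starting at ``start``, wrapping modularly."""
        n = self.length
        if length < 0:
            raise ValueError("length must be non-negative")
        start = start % n
        if length > n:
            # tile the circle as many times as needed
            reps = (start + length + n - 1) // n
            return (self.sequence * reps)[start : start + length]
        end = start + length
        if end <= n:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - n]

    def rotate(self, r: int) -> "CircularGenome":
        """Genome with the origin moved so old position ``r`` becomes 0 shifted:
        new[i] = old[(i - r) mod n], i.e. every feature moves +r."""
        n = self.length
        r = r % n
        seq = self.sequence[n - r :] + self.sequence[: n - r]
        anns = [Annotation((a.start + r) % n, a.length, a.label) for a in self.annotations]
        dups = [
            Duplication((d.source_start + r) % n, d.length, (d.dest_start + r) % n)
            for d in self.duplications
        ]
        return CircularGenome(self.name, seq, anns, dups, self.circular)

    def onehot(self, start: int, length: int) -> np.ndarray:
        """One-hot encode a modular window as a (4, length) float32 array
        (rows A, C, G, T; N encodes as all-zero)."""
        return onehot_sequence(self.fetch(start, length))


_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i


def onehot_sequence(seq: str) -> np.ndarray:
    codes = _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    out = np.zeros((4, len(seq)), dtype=np.float32)
    valid = codes >= 0
    out[codes[valid], np.nonzero(valid)[0]] = 1.0
    return out


def encode_sequence(seq: str) -> np.ndarray:
    """Integer codes A=0 C=1 G=2 T=3, N=-1."""
    return _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def write_fasta(genome: CircularGenome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        topo = "circular" if genome.circular else "linear"
        fh.write(f">{genome.name} topology={topo} length={genome.length}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


def read_fasta(path: str) -> CircularGenome:
    """Read the first record of a FASTA file as a circular genome."""
    from Bio import SeqIO

    record = next(SeqIO.parse(path, "fasta"))
    circular = "topology=linear" not in record.description
    return CircularGenome(record.id, str(record.seq).upper(), circular=circular)
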