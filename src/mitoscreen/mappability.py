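"""k-mer self-mapping mappability tracks on a circular contig.

Every position emits the k-mer starting there (wrapping across the
origin when ``circular_kmers`` is true); each k-mer is then re-placed
against the whole genome under unique-mapping semantics and a base is
fully mappable only when all k k-mers covering it place uniquely.

Two uniqueness semantics are supported:

* ``best_strata=True`` (default, mirrors ``-v N -k 2 -m 1 --best
  --strata``): the k-mer's best stratum is its minimum mismatch count
  over all placements — always 0, since it matches its own origin
  exactly — so it is unique iff no *second* exact placement exists.
* ``best_strata=False`` (mirrors ``-v N -m 1`` without strata): unique
  iff no other placement exists with at most ``mismatches`` mismatches.

Reverse-complement placements count toward multiplicity by default
(double-stranded alignment); switchable via ``count_rc``.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .genome import CircularGenome, encode_sequence


@dataclass
class MappabilityTrack:
    genome_name: str
    k: int
    values: np.ndarray  # per-base uint8 flags, 1 = fully mappable

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mappability values must be 0/1")

    @property
    def length(self) -> int:
        return len(self.values)

    def rotate(self, r: int) -> "MappabilityTrack":
        return MappabilityTrack(self.genome_name, self.k, np.roll(self.values, r))


def _kmer_matrix(genome: CircularGenome, k: int, circular: bool) -> np.ndarray:
    """Integer-coded k-mers as an (n_starts, k) matrix."""
    n = genome.length
    if circular:
        codes = encode_sequence(genome.sequence + genome.sequence[: k - 1])
        starts = n
    else:
        codes = encode_sequence(genome.sequence)
        starts = n - k + 1
    idx = np.arange(starts)[:, None] + np.arange(k)[None, :]
    return codes[idx]


def _retained_exact(fwd: np.ndarray, rc: np.ndarray, count_rc: bool) -> np.ndarray:
    """Uniqueness under exact-duplicate (best-stratum) semantics."""
    fwd_keys = [row.tobytes() for row in fwd]
    counts = Counter(fwd_keys)
    if count_rc:
        rc_counts = Counter(row.tobytes() for row in rc)
    retained = np.empty(len(fwd_keys), dtype=bool)
    for i, key in enumerate(fwd_keys):
        multiplicity = counts[key]
        if count_rc:
            multiplicity += rc_counts.get(key, 0)
        retained[i] = multiplicity == 1
    return retained


def _retained_mismatch(fwd: np.ndarray, rc: np.ndarray, mismatches: int,
                       count_rc: bool, chunk: int = 128) -> np.ndarray:
    """Uniqueness counting every placement within the mismatch budget."""
    n = len(fwd)
    retained = np.empty(n, dtype=bool)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        block = fwd[lo:hi]
        # mismatch counts against every forward placement
        diff = (block[:, None, :] != fwd[None, :, :]).sum(axis=2)
        hits = (diff <= mismatches).sum(axis=1)  # includes the self-placement
        if count_rc:
            diff_rc = (block[:, None, :] != rc[None, :, :]).sum(axis=2)
            hits += (diff_rc <= mismatches).sum(axis=1)
        retained[lo:hi] = hits == 1
    return retained


def compute_mappability(genome: CircularGenome, k: int = 36, mismatches: int = 2,
                        circular_kmers: bool = False, count_rc: bool = True,
                        best_strata: bool = True) -> MappabilityTrack:
    n = genome.length
    if not (1 <= k <= n):
        raise ValueError(f"k={k} must lie in [1, genome length {n}]")
    fwd = _kmer_matrix(genome, k, circular_kmers)
    rc = fwd[:, ::-1]
    rc = np.where(rc >= 0, 3 - rc, rc)  # complement of integer codes

    if best_strata or mismatches == 0:
        retained = _retained_exact(fwd, rc, count_rc)
    else:
        retained = _retained_mismatch(fwd, rc, mismatches, count_rc)

    # base p is fully mappable iff covered by exactly k retained k-mers
    n_starts = len(retained)
    coverage = np.zeros(n, dtype=np.int64)
    good = np.zeros(n, dtype=np.int64)
    for s in np.arange(n_starts):
        span = (s + np.arange(k)) % n if circular_kmers else np.arange(s, s + k)
        coverage[span] += 1
        if retained[s]:
            good[span] += 1
    values = ((coverage == k) & (good == k)).astype(np.uint8)
    return MappabilityTrack(genome.name, k, values)


def write_mappability(track: MappabilityTrack, path: str) -> None:
    from . import bedio

    bedio.write_bedgraph(track.values, track.genome_name, path)


def read_mappability(path: str, genome_name: str, length: int,
                     k: int = 36) -> MappabilityTrack:
    from . import bedio

    values = bedio.read_bedgraph(path, length, genome_name)
    return MappabilityTrack(genome_name, k, values.astype(np.uint8))
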