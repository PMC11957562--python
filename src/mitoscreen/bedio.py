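"""Plain-text interval/track serialization (BED, bedGraph).

bedGraph vectors are merged into maximal equal-value runs on write and
round-trip losslessly; negative values are rejected on read because every
track type in this package is a non-negative count or probability mass.
"""
from __future__ import annotations

import numpy as np


def write_bedgraph(values: np.ndarray, chrom: str, path: str) -> None:
    values = np.asarray(values)
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        change = np.nonzero(np.diff(values) != 0)[0]
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [len(values)]))
        for s, e in zip(starts, ends):
            v = values[s]
            fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(v)}\n")


def _fmt(v) -> str:
    f = float(v)
    if f == int(f):
        return str(int(f))
    return repr(f)


def read_bedgraph(path: str, length: int, chrom: str | None = None,
                  dtype=np.float64) -> np.ndarray:
    values = np.zeros(length, dtype=dtype)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.split("\t")[:4]
            if chrom is not None and c != chrom:
                raise ValueError(f"unexpected contig {c!r} (wanted {chrom!r})")
            v = float(v)
            if v < 0:
                raise ValueError(f"negative value {v} at {c}:{s}-{e}")
            s, e = int(s), int(e)
            if e > length:
                raise ValueError(f"interval {s}-{e} exceeds genome length {length}")
            values[s:e] = v
    return values


def write_bed(rows: list[tuple], path: str, header: str | None = None) -> None:
    """Write rows of (chrom, start, end, *extra) as TSV BED."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            rows.append(fields)
    return rows
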