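"""Readers and writers for the text formats the pipeline consumes and emits.

Supported formats: BED3/BED6 (UCSC, tab-separated), BEDPE (converted to
fragments spanning mate outer coordinates), bedGraph, a gene table (BED6 plus
a seventh numeric FPKM column), and two-column chrom-sizes files. All tables
written by the pipeline are plain TSV.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, List, Sequence, Tuple

import numpy as np

from .types import (
    ChromSizes,
    Fragment,
    GeneModel,
    GenomicInterval,
    ParseError,
    SignalTrack,
    Tag,
    validate_sizes,
)

_SKIP_PREFIXES = ("#", "track", "browser")


def _records(path: str) -> Iterator[Tuple[int, List[str]]]:
    """Yield (1-based line number, fields) for data lines of a BED-like file."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t")


def _coords(fields: Sequence[str], path: str, lineno: int) -> Tuple[str, int, int]:
    if len(fields) < 3:
        raise ParseError("expected at least 3 tab-separated columns", path, lineno)
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise ParseError(
            f"non-integer coordinates {fields[1]!r}, {fields[2]!r}", path, lineno
        ) from None
    if not chrom:
        raise ParseError("empty chromosome name", path, lineno)
    if start < 0 or start >= end:
        raise ParseError(f"invalid interval {start}-{end}", path, lineno)
    return chrom, start, end


def read_intervals(path: str, format: str = "bed6") -> List[GenomicInterval]:
    """Read intervals from a BED3 or BED6 file.

    In ``bed6`` mode the strand is taken from column 6 (``.`` is allowed and
    means unstranded) and the name from column 4; in ``bed3`` mode everything
    beyond the coordinates is ignored.
    """
    if format not in ("bed3", "bed6"):
        raise ValueError(f"unknown interval format {format!r}")
    out = []
    for lineno, fields in _records(path):
        chrom, start, end = _coords(fields, path, lineno)
        name, strand = ".", "."
        if format == "bed6":
            if len(fields) < 6:
                raise ParseError("bed6 record has fewer than 6 columns", path, lineno)
            name, strand = fields[3], fields[5]
            if strand not in ("+", "-", "."):
                raise ParseError(f"invalid strand {strand!r}", path, lineno)
        out.append(GenomicInterval(chrom, start, end, strand=strand, name=name))
    return out


def read_tags(path: str, format: str = "bed6") -> List[Tag]:
    """Read mapped-read records; each becomes the 5' end position of the read.

    Forward reads contribute ``start``; reverse reads contribute ``end - 1``
    (BED end is exclusive). A missing or ``.`` strand is an error.
    """
    if format != "bed6":
        raise ValueError(f"unknown tag format {format!r}")
    out = []
    for lineno, fields in _records(path):
        chrom, start, end = _coords(fields, path, lineno)
        if len(fields) < 6:
            raise ParseError("tag record has fewer than 6 columns", path, lineno)
        strand = fields[5]
        if strand == "+":
            pos5 = start
        elif strand == "-":
            pos5 = end - 1
        else:
            raise ParseError(f"tag strand must be + or -, got {strand!r}", path, lineno)
        out.append(Tag(chrom, pos5, strand))
    return out


def read_fragments(path: str, format: str = "bed3") -> List[Fragment]:
    """Read paired-end fragments.

    ``bed3``: each record is the fragment itself. ``bedpe``: each record holds
    both mates; the fragment spans the outer coordinates of the pair. No
    length filtering happens at this layer.
    """
    out = []
    if format == "bed3":
        for lineno, fields in _records(path):
            chrom, start, end = _coords(fields, path, lineno)
            out.append(Fragment(chrom, start, end))
    elif format == "bedpe":
        for lineno, fields in _records(path):
            if len(fields) < 6:
                raise ParseError("bedpe record has fewer than 6 columns", path, lineno)
            chrom1, s1, e1 = _coords(fields[0:3], path, lineno)
            chrom2, s2, e2 = _coords(fields[3:6], path, lineno)
            if chrom1 != chrom2:
                raise ParseError("bedpe mates on different chromosomes", path, lineno)
            out.append(Fragment(chrom1, min(s1, s2), max(e1, e2)))
    else:
        raise ValueError(f"unknown fragment format {format!r}")
    return out


def read_genes(path: str) -> List[GeneModel]:
    """Read a gene table: BED6 plus a seventh numeric FPKM column."""
    out = []
    for lineno, fields in _records(path):
        chrom, start, end = _coords(fields, path, lineno)
        if len(fields) < 7:
            raise ParseError("gene record needs 7 columns (bed6 + FPKM)", path, lineno)
        strand = fields[5]
        if strand not in ("+", "-"):
            raise ParseError(f"gene strand must be + or -, got {strand!r}", path, lineno)
        try:
            fpkm = float(fields[6])
        except ValueError:
            raise ParseError(f"non-numeric FPKM {fields[6]!r}", path, lineno) from None
        if fpkm < 0:
            raise ParseError(f"negative FPKM {fpkm}", path, lineno)
        out.append(
            GeneModel(
                GenomicInterval(chrom, start, end, strand=strand, name=fields[3]),
                id=fields[3],
                expression=fpkm,
            )
        )
    return out


def read_chrom_sizes(path: str) -> ChromSizes:
    sizes: ChromSizes = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("expected 'chrom<TAB>length'", path, lineno)
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError:
                raise ParseError(f"non-integer length {fields[1]!r}", path, lineno) from None
    return validate_sizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, n in sizes.items():
            fh.write(f"{chrom}\t{n}\n")


def write_intervals(intervals: Iterable[GenomicInterval], path: str, score: int = 0) -> None:
    """Write intervals as BED6 (name from the interval, fixed score column)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def write_tags(tags: Iterable[Tag], path: str, read_length: int = 36) -> None:
    """Write tags as BED6 records of ``read_length`` bp anchored at the 5' end."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags):
            if t.strand == "+":
                start, end = t.pos5, t.pos5 + read_length
            else:
                start, end = max(0, t.pos5 + 1 - read_length), t.pos5 + 1
            fh.write(f"{t.chrom}\t{start}\t{end}\tt{i}\t0\t{t.strand}\n")


def write_fragments(fragments: Iterable[Fragment], path: str) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def write_genes(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.id}\t0\t{iv.strand}\t{g.expression:g}\n"
            )


def write_bedgraph(track: SignalTrack, path: str) -> None:
    """Write a track as 4-column bedGraph with run-length merging.

    Consecutive equal values are merged into a single record; zero runs are
    written too, so the output tiles each chromosome completely and the
    round-trip read reproduces the values exactly.
    """
    res = track.resolution
    with open(path, "w") as fh:
        for chrom in track.chroms():
            values = track[chrom]
            if values.size == 0:
                continue
            change = np.flatnonzero(values[1:] != values[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s * res}\t{e * res}\t{values[s]:g}\n")


def read_bedgraph(path: str, resolution: int = 1, sizes: ChromSizes | None = None) -> SignalTrack:
    """Read a bedGraph written at the given resolution back into a track.

    Record boundaries must fall on resolution multiples. If ``sizes`` is not
    given, each chromosome's length is inferred from its last record.
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, fields in _records(path):
        chrom, start, end = _coords(fields, path, lineno)
        if len(fields) < 4:
            raise ParseError("bedGraph record needs 4 columns", path, lineno)
        try:
            value = float(fields[3])
        except ValueError:
            raise ParseError(f"non-numeric value {fields[3]!r}", path, lineno) from None
        if start % resolution or end % resolution:
            raise ParseError(
                f"record {start}-{end} not aligned to resolution {resolution}", path, lineno
            )
        spans.setdefault(chrom, []).append((start, end, value))
    data = {}
    for chrom, recs in spans.items():
        length = sizes[chrom] if sizes else max(e for _, e, _ in recs)
        arr = np.zeros(-(-length // resolution), dtype=float)
        for s, e, v in recs:
            arr[s // resolution : e // resolution] = v
        data[chrom] = arr
    return SignalTrack(data=data, resolution=resolution)


def write_table(rows: Iterable[dict], path: str, columns: Sequence[str]) -> None:
    """Write a list of dict rows as a TSV with a fixed column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
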