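"""Core domain types shared by every pipeline stage.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``. The 5' end of a read on the
reverse strand is therefore ``end - 1`` of its BED record. Chromosome names
are compared as exact strings; no ``chr`` normalisation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

import numpy as np

#: chromosome name -> length in bp
ChromSizes = Dict[str, int]

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed record in a text input, carrying file and line context."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally stranded and named."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene as a single stranded interval plus an expression value (FPKM)."""

    interval: GenomicInterval
    id: str
    expression: float = 0.0

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -")
        if self.expression < 0:
            raise ValueError(f"gene {self.id}: expression must be >= 0")

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware, 0-based)."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (strand-aware, 0-based)."""
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start


@dataclass(frozen=True)
class Tag:
    """The mapped 5' end of a single sequence read."""

    chrom: str
    pos5: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"tag strand must be + or -, got {self.strand!r}")
        if self.pos5 < 0:
            raise ValueError("tag pos5 must be >= 0")


@dataclass(frozen=True)
class Fragment:
    """A paired-end sequencing fragment spanning mate outer coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(
                f"fragment {self.chrom}:{self.start}-{self.end} has length <= 0"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Dyad proxy: floor of the fragment centre."""
        return (self.start + self.end) // 2


@dataclass
class SignalTrack:
    """Per-chromosome numeric vectors at a fixed bp-per-element resolution."""

    data: Dict[str, np.ndarray] = field(default_factory=dict)
    resolution: int = 1

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")
        for chrom, values in self.data.items():
            arr = np.asarray(values, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in track for {chrom}")
            self.data[chrom] = arr

    def chroms(self) -> Iterator[str]:
        return iter(self.data)

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.data

    @classmethod
    def zeros(cls, sizes: Mapping[str, int], resolution: int = 1) -> "SignalTrack":
        data = {
            c: np.zeros(-(-int(n) // resolution), dtype=float) for c, n in sizes.items()
        }
        return cls(data=data, resolution=resolution)


def validate_sizes(sizes: Mapping[str, int]) -> ChromSizes:
    out: ChromSizes = {}
    for chrom, n in sizes.items():
        if not chrom:
            raise ValueError("empty chromosome name in sizes")
        n = int(n)
        if n <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {n}")
        out[chrom] = n
    return out
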