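"""Genomic interval primitives and BED-style I/O.

All coordinates are 0-based, half-open ``[start, end)`` throughout the
package; readers for 1-based formats convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

DEFAULT_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """Half-open genomic interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        """Strict half-open overlap: bookended intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicRegion") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, order=True)
class ReadPlacement:
    """A deduplicatable sequencing-read placement (strand is part of identity)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("read start must precede end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read a BED3+ file into regions; column 4 (name) becomes the id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = str(row[3]) if len(row) > 3 else f"region_{i}"
        out.append(GenomicRegion(str(row[0]), int(row[1]), int(row[2]), name))
    return out


def write_bed(
    regions: Sequence[GenomicRegion],
    path: str | Path,
    scores: Sequence[float] | None = None,
    names: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = names[i] if names is not None else (r.id or f"region_{i}")
            score = scores[i] if scores is not None else 0
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\n")


def read_read_bed(path: str | Path) -> list[ReadPlacement]:
    """Read a 6-column read-placement BED (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError("read BED requires 6 columns including strand")
    return [
        ReadPlacement(str(c), int(s), int(e), str(st))
        for c, s, e, st in zip(df[0], df[1], df[2], df[5])
    ]


def write_read_bed(reads: Iterable[ReadPlacement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread_{i}\t0\t{r.strand}\n")


def sort_regions(regions: Iterable[GenomicRegion]) -> list[GenomicRegion]:
    return sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
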