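"""Consensus-region construction from per-sample peak calls.

The consolidation contract: per-sample peaks are stretched to a minimum
length, pooled across samples, merged on their outmost coordinates wherever
they overlap, filtered to regions supported by a minimum number of distinct
samples, and finally quantified by overlapping each sample's deduplicated
autosomal reads back onto the common list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import DEFAULT_AUTOSOMES, GenomicRegion, ReadPlacement

logger = logging.getLogger(__name__)


@dataclass
class ConsensusRegion:
    """A merged region with the set of samples whose peaks contributed."""

    region: GenomicRegion
    source_samples: frozenset[str]

    @property
    def support(self) -> int:
        return len(self.source_samples)


@dataclass
class CountsMatrix:
    """Region x sample occupancy counts with per-sample library sizes.

    ``counts`` rows follow ``regions`` order, columns follow ``samples``.
    ``library_size`` holds the total autosomal deduplicated reads per sample
    (the denominator for RPKM/RPM), not only the reads falling in regions.
    """

    regions: list[ConsensusRegion]
    samples: list[str]
    groups: dict[str, str]
    counts: np.ndarray
    library_size: dict[str, int]
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError("counts shape does not match region/sample lists")
        if not self.region_ids:
            self.region_ids = [
                cr.region.id or f"region_{i}" for i, cr in enumerate(self.regions)
            ]

    @property
    def region_lengths(self) -> np.ndarray:
        return np.array([cr.region.length for cr in self.regions])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.region_ids, columns=self.samples)


def collapse_duplicates(reads: Iterable[ReadPlacement]) -> list[ReadPlacement]:
    """Keep one read per (chrom, start, strand) key, sorted by (chrom, start).

    Mirrors duplicate collapsing of mapped reads: placements sharing mapping
    position and strand are counted once; opposite strands are distinct.
    """
    seen: dict[tuple[str, int, str], ReadPlacement] = {}
    for r in reads:
        seen.setdefault((r.chrom, r.start, r.strand), r)
    return sorted(seen.values(), key=lambda r: (r.chrom, r.start, r.strand))


def stretch_region(region: GenomicRegion, min_len: int = 2000) -> GenomicRegion:
    """Extend a region symmetrically about its midpoint to at least ``min_len``.

    Left extension is clipped at coordinate 0 with the deficit redistributed
    rightward, so the output always has length >= min_len. Regions already
    long enough are returned unchanged. On an odd deficit the extra base
    goes to the right.
    """
    if region.length >= min_len:
        return region
    deficit = min_len - region.length
    left = deficit // 2
    right = deficit - left
    start = region.start - left
    end = region.end + right
    if start < 0:
        end -= start  # move the clipped excess to the right
        start = 0
    return GenomicRegion(region.chrom, start, end, region.id)


def merge_regions(
    tagged_regions: Iterable[tuple[GenomicRegion, str]],
) -> list[ConsensusRegion]:
    """Merge overlapping regions from all samples into consensus spans.

    Each output region is the union span (min start, max end) of a maximal
    chain of pairwise-overlapping input regions; support counts the distinct
    source samples in the chain. Overlap is strict half-open (>= 1 shared
    bp); bookended regions do not merge. Output is sorted and disjoint,
    independent of input order.
    """
    items = sorted(tagged_regions, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    merged: list[ConsensusRegion] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    cur_samples: set[str] = set()

    def flush() -> None:
        if cur_chrom is not None:
            rid = f"cons_{len(merged)}"
            merged.append(
                ConsensusRegion(
                    GenomicRegion(cur_chrom, cur_start, cur_end, rid),
                    frozenset(cur_samples),
                )
            )

    for region, sample in items:
        if region.chrom == cur_chrom and region.start < cur_end:
            cur_end = max(cur_end, region.end)
            cur_samples.add(sample)
        else:
            flush()
            cur_chrom, cur_start, cur_end = region.chrom, region.start, region.end
            cur_samples = {sample}
    flush()
    return merged


def filter_by_support(
    consensus: Sequence[ConsensusRegion], min_support: int = 2
) -> list[ConsensusRegion]:
    """Retain consensus regions supported by >= min_support distinct samples."""
    return [cr for cr in consensus if cr.support >= min_support]


def build_consensus(
    peaks_by_sample: Mapping[str, Sequence[GenomicRegion]],
    min_len: int = 2000,
    min_support: int = 2,
) -> list[ConsensusRegion]:
    """Stretch, pool, merge and support-filter per-sample peak calls."""
    tagged = [
        (stretch_region(p, min_len), sample)
        for sample, peaks in peaks_by_sample.items()
        for p in peaks
    ]
    return filter_by_support(merge_regions(tagged), min_support)


def count_occupancy(
    consensus: Sequence[ConsensusRegion],
    reads_by_sample: Mapping[str, Sequence[ReadPlacement]],
    groups: Mapping[str, str],
    autosomes: Sequence[str] = DEFAULT_AUTOSOMES,
) -> CountsMatrix:
    """Count, per region and sample, the deduplicated autosomal reads that
    overlap the region by >= 1 bp.

    Reads on chromosomes outside ``autosomes`` are excluded from both the
    counts and the library size. A read spanning two consensus regions
    contributes once to each (regions are disjoint post-merge); such reads
    are logged. Reads on chromosomes absent from the consensus list but in
    the autosome set still count toward library size.
    """
    autoset = set(autosomes)
    samples = list(reads_by_sample)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    chroms = sorted({cr.region.chrom for cr in consensus})
    for chrom in chroms:
        idx = np.array(
            [i for i, cr in enumerate(consensus) if cr.region.chrom == chrom]
        )
        starts = np.array([consensus[i].region.start for i in idx])
        srt = np.argsort(starts)
        idx = idx[srt]
        starts = starts[srt]
        ends = np.array([consensus[i].region.end for i in idx])
        by_chrom[chrom] = (starts, ends, idx)

    counts = np.zeros((len(consensus), len(samples)), dtype=np.int64)
    library_size: dict[str, int] = {}
    for j, sample in enumerate(samples):
        libsize = 0
        spanning = 0
        for r in reads_by_sample[sample]:
            if r.chrom not in autoset:
                if r.chrom not in by_chrom:
                    logger.debug("skipping non-autosomal read on %s", r.chrom)
                continue
            libsize += 1
            entry = by_chrom.get(r.chrom)
            if entry is None:
                continue
            starts, ends, idx = entry
            # first region whose end > read.start; advance while start < read.end
            k = int(np.searchsorted(ends, r.start, side="right"))
            hits = 0
            while k < len(starts) and starts[k] < r.end:
                counts[idx[k], j] += 1
                hits += 1
                k += 1
            if hits > 1:
                spanning += 1
        library_size[sample] = libsize
        if spanning:
            logger.info(
                "sample %s: %d reads spanned multiple consensus regions", sample, spanning
            )
    return CountsMatrix(
        regions=list(consensus),
        samples=samples,
        groups=dict(groups),
        counts=counts,
        library_size=library_size,
    )
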