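"""Region-to-gene annotation via TSS windows and windowed signal summaries.

Three window kinds are used downstream: the +/-5 kb TSS window for
region-to-gene annotation, the +/-2.5 kb promoter window for
acetylation-expression correlation, and the strand-aware 2.5 kb upstream
window for cell-type marker panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import CountsMatrix
from .regions import GenomicRegion

logger = logging.getLogger(__name__)

TSS_5KB = "tss_5kb"
PROMOTER_2P5KB = "promoter_2p5kb"
UPSTREAM_2P5KB = "upstream_2p5kb"

WINDOW_KINDS = {
    TSS_5KB: (5_000, 5_000),
    PROMOTER_2P5KB: (2_500, 2_500),
    UPSTREAM_2P5KB: (2_500, 0),
}


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        if not self.body_start < self.body_end:
            raise ValueError("body_start must precede body_end")
        expected = self.body_start if self.strand == "+" else self.body_end
        if self.tss != expected:
            raise ValueError("tss must equal body_start (+) or body_end (-)")


@dataclass(frozen=True)
class RegionGeneLink:
    region_id: str
    gene_id: str
    window_kind: str
    overlap_bp: int


def tss_window(gene: GeneModel, flank_up: int, flank_down: int) -> GenomicRegion:
    """Strand-aware window around the TSS, clipped at coordinate 0.

    ``flank_up`` extends against the direction of transcription and
    ``flank_down`` with it; a symmetric window has flank_up == flank_down.
    """
    if gene.strand == "+":
        start, end = gene.tss - flank_up, gene.tss + flank_down
    else:
        start, end = gene.tss - flank_down, gene.tss + flank_up
    start = max(0, start)
    if end <= start:
        end = start + 1  # degenerate zero-flank windows keep 1 bp anchor
    return GenomicRegion(gene.chrom, start, end, f"{gene.gene_id}_window")


def window_for_kind(gene: GeneModel, window_kind: str) -> GenomicRegion:
    up, down = WINDOW_KINDS[window_kind]
    return tss_window(gene, up, down)


def annotate_regions(
    regions: list[GenomicRegion],
    genes: list[GeneModel],
    flank_up: int = 5_000,
    flank_down: int = 5_000,
    window_kind: str = TSS_5KB,
    min_overlap: int = 1,
) -> list[RegionGeneLink]:
    """Link every region to every gene whose TSS window it overlaps.

    Overlap is strict half-open and must reach ``min_overlap`` bp.
    Many-to-many links are allowed; the output is deduplicated and sorted
    by (region_id, gene_id).
    """
    links: set[RegionGeneLink] = set()
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        w = tss_window(g, flank_up, flank_down)
        by_chrom.setdefault(g.chrom, []).append((w.start, w.end, g.gene_id))
    for windows in by_chrom.values():
        windows.sort()
    for r in regions:
        for ws, we, gid in by_chrom.get(r.chrom, ()):
            ov = min(r.end, we) - max(r.start, ws)
            if ov >= min_overlap:
                links.add(RegionGeneLink(r.id, gid, window_kind, ov))
    return sorted(links, key=lambda l: (l.region_id, l.gene_id))


def unannotated_regions(
    regions: list[GenomicRegion], links: list[RegionGeneLink]
) -> list[GenomicRegion]:
    linked = {l.region_id for l in links}
    return [r for r in regions if r.id not in linked]


def window_signal(
    counts_matrix: CountsMatrix,
    genes: list[GeneModel],
    window_kind: str = PROMOTER_2P5KB,
    per_kb: bool = True,
) -> pd.DataFrame:
    """Per-gene, per-sample signal over a TSS window.

    Reads of each overlapping consensus region are attributed pro-rata to
    the overlapped fraction of the region, then scaled to window RPKM
    (``per_kb=True``) or RPM. A window lying entirely inside one region
    therefore reproduces that region's RPKM exactly. Genes with no
    overlapping region get 0 and are logged.
    """
    lib = np.array([counts_matrix.library_size[s] for s in counts_matrix.samples], float)
    rows = []
    n_empty = 0
    region_index: dict[str, list[int]] = {}
    for i, cr in enumerate(counts_matrix.regions):
        region_index.setdefault(cr.region.chrom, []).append(i)
    for gene in genes:
        w = window_for_kind(gene, window_kind)
        attributed = np.zeros(len(counts_matrix.samples))
        hit = False
        for i in region_index.get(gene.chrom, ()):
            reg = counts_matrix.regions[i].region
            ov = min(w.end, reg.end) - max(w.start, reg.start)
            if ov >= 1:
                hit = True
                attributed += counts_matrix.counts[i] * (ov / reg.length)
        if not hit:
            n_empty += 1
        scale = (w.length / 1e3) if per_kb else 1.0
        rows.append(attributed / scale / (lib / 1e6))
    if n_empty:
        logger.info("%d genes had no overlapping region in window %s", n_empty, window_kind)
    return pd.DataFrame(
        rows, index=[g.gene_id for g in genes], columns=counts_matrix.samples
    )


def gene_body_rpkm(
    read_counts: pd.DataFrame, genes: list[GeneModel], library_sizes: dict[str, int]
) -> pd.DataFrame:
    """RPKM over [body_start, body_end) from a per-gene read-count table."""
    genes_by_id = {g.gene_id: g for g in genes}
    lengths = np.array(
        [genes_by_id[g].body_end - genes_by_id[g].body_start for g in read_counts.index],
        dtype=float,
    )
    lib = np.array([library_sizes[s] for s in read_counts.columns], float)
    return read_counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)


# --- gene-model I/O ---------------------------------------------------------


def genes_to_tsv(genes: list[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "symbol": [g.symbol for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "body_start": [g.body_start for g in genes],
            "body_end": [g.body_end for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def genes_from_tsv(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(
            str(r.gene_id), str(r.symbol), str(r.chrom), str(r.strand),
            int(r.tss), int(r.body_start), int(r.body_end),
        )
        for r in df.itertuples(index=False)
    ]


def genes_to_gtf(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene features in minimal GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tacetylome\tgene\t{g.body_start + 1}\t{g.body_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def genes_from_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene features from a minimal GTF; 1-based inclusive coordinates
    are converted to 0-based half-open at this boundary."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in fields[8].rstrip(";").split(";")
                if kv.strip()
            )
            start = int(fields[3]) - 1
            end = int(fields[4])
            strand = fields[6]
            tss = start if strand == "+" else end
            genes.append(
                GeneModel(
                    attrs["gene_id"], attrs.get("gene_name", attrs["gene_id"]),
                    fields[0], strand, tss, start, end,
                )
            )
    return genes


def links_to_tsv(links: list[RegionGeneLink], path: str | Path) -> None:
    pd.DataFrame(
        {
            "region_id": [l.region_id for l in links],
            "gene_id": [l.gene_id for l in links],
            "window_kind": [l.window_kind for l in links],
            "overlap_bp": [l.overlap_bp for l in links],
        }
    ).to_csv(path, sep="\t", index=False)
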