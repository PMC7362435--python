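"""Synthetic input generator with planted ground truth.

Emulates the statistical structure the pipeline assumes: negative-binomially
distributed region counts in two groups of unequal size (patients vs
controls), a planted fraction of hyper-/hypoacetylated regions whose
directions follow a two-state Markov chain along each chromosome (tandem
domain structure), promoter acetylation linearly coupled to gene expression
on the log scale, and motif consensus sites planted into hyperacetylated
sequences. Everything is reproducible from one global seed, fanned out to
named per-component streams so one component's draws never shift another's.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneModel, genes_to_gtf, genes_to_tsv
from .consensus import ConsensusRegion, CountsMatrix
from .motifs import PWM, write_fasta, write_meme
from .regions import GenomicRegion, ReadPlacement, write_bed, write_read_bed

HYPER, HYPO, NULL = "hyper", "hypo", "null"

READ_LENGTH = 75


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Named child stream: independent, reproducible, platform-stable."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


@dataclass
class SimulationConfig:
    n_chromosomes: int = 4
    chrom_length: int = 40_000_000
    n_regions: int = 2_000
    n_samples_case: int = 20
    n_samples_control: int = 5
    baseline_log_mean: float = 6.0   # log2 of the mean occupancy count
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1          # NB alpha
    dar_fraction: float = 0.3
    planted_lfc: float = 1.5
    direction_persistence: float = 0.8
    n_genes: int = 500
    promoter_link_slope: float = 1.0
    promoter_link_noise_sd: float = 1.0
    motif_plant_rate: float = 0.6
    n_decoy_motifs: int = 20
    motif_length: int = 10
    sequence_length: int = 500
    peak_detect_rate: float = 0.85   # chance a sample's peak caller saw a region
    background_read_fraction: float = 0.2
    min_gap: int = 5_000
    region_len_range: tuple[int, int] = (2_000, 4_000)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length", "n_regions", "n_samples_case",
            "n_samples_control", "n_genes", "n_decoy_motifs", "motif_length",
            "sequence_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dar_fraction", "direction_persistence", "motif_plant_rate",
                     "peak_detect_rate", "background_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_genes > self.n_regions:
            raise ValueError("n_genes cannot exceed n_regions")
        if self.motif_length > self.sequence_length:
            raise ValueError("motif longer than sequence")
        per_chrom = -(-self.n_regions // self.n_chromosomes)
        # expected footprint of the gap mixture plus a 6-sigma margin
        mean_step = self.region_len_range[1] + 0.7 * 47_500 + 0.3 * 250_000
        budget = int(per_chrom * mean_step + 6 * np.sqrt(per_chrom) * 120_000 + 100_000)
        if self.chrom_length < budget:
            raise ValueError(
                f"chrom_length {self.chrom_length} too small for {per_chrom} "
                f"regions per chromosome (needs >= {budget}); over-dense configuration"
            )

    @property
    def samples(self) -> list[str]:
        return [f"patient_{i+1}" for i in range(self.n_samples_case)] + [
            f"control_{i+1}" for i in range(self.n_samples_control)
        ]

    @property
    def groups(self) -> dict[str, str]:
        return {
            s: ("patient" if s.startswith("patient") else "control")
            for s in self.samples
        }

    @property
    def autosomes(self) -> list[str]:
        return [f"chr{i+1}" for i in range(self.n_chromosomes)]


@dataclass
class SyntheticTruth:
    region_direction: dict[str, str]
    region_true_lfc: dict[str, float]
    gene_to_region: dict[str, str | None] = field(default_factory=dict)
    motif_planted: dict[str, bool] = field(default_factory=dict)
    planted_motif_id: str | None = None


def simulate_regions(config: SimulationConfig) -> tuple[list[GenomicRegion], SyntheticTruth]:
    """Place sorted, non-overlapping regions and plant DAR directions.

    Inter-region gaps are drawn from a two-component mixture (70% short
    5-90 kb, 30% long 100-400 kb) so that both adjacency distance classes
    occur. DAR directions follow a per-chromosome two-state Markov chain
    with persistence ``direction_persistence``.
    """
    rng = child_rng(config.seed, "regions")
    lens = rng.integers(*config.region_len_range, size=config.n_regions, endpoint=True)
    chrom_of = [i % config.n_chromosomes for i in range(config.n_regions)]

    regions: list[GenomicRegion] = []
    pos = {c: 0 for c in range(config.n_chromosomes)}
    idx_on_chrom = {c: 0 for c in range(config.n_chromosomes)}
    placements = []
    for i in range(config.n_regions):
        c = chrom_of[i]
        if idx_on_chrom[c] == 0:
            gap = int(rng.integers(10_000, 60_000))
        elif rng.random() < 0.7:
            gap = int(rng.integers(config.min_gap, 90_000, endpoint=True))
        else:
            gap = int(rng.integers(100_000, 400_000, endpoint=True))
        start = pos[c] + gap
        end = start + int(lens[i])
        if end > config.chrom_length:
            raise RuntimeError(
                f"placement overflow on chr{c+1}; over-dense configuration"
            )
        placements.append((c, start, end))
        pos[c] = end
        idx_on_chrom[c] += 1

    placements.sort()
    direction: dict[str, str] = {}
    true_lfc: dict[str, float] = {}
    last_dir: dict[int, str] = {}
    for k, (c, start, end) in enumerate(placements):
        rid = f"region_{k:05d}"
        regions.append(GenomicRegion(f"chr{c+1}", start, end, rid))
        if rng.random() < config.dar_fraction:
            prev = last_dir.get(c)
            if prev is None:
                d = HYPER if rng.random() < 0.5 else HYPO
            elif rng.random() < config.direction_persistence:
                d = prev
            else:
                d = HYPO if prev == HYPER else HYPER
            direction[rid] = d
            true_lfc[rid] = config.planted_lfc if d == HYPER else -config.planted_lfc
            last_dir[c] = d
        else:
            direction[rid] = NULL
            true_lfc[rid] = 0.0
    return regions, SyntheticTruth(direction, true_lfc)


def simulate_counts(
    regions: list[GenomicRegion],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> CountsMatrix:
    """NB occupancy counts: mean = s_j * mu_i * 2^(lfc_i * group_j).

    Per-sample size factors are drawn log-uniform in [0.5, 2]; dispersion 0
    degenerates to Poisson. Library size is the in-region total inflated by
    the configured background-read fraction (the synthetic genome's
    off-region reads).
    """
    rng = child_rng(config.seed, "counts")
    n = len(regions)
    mu = 2.0 ** rng.normal(config.baseline_log_mean, config.baseline_log_sd, n)
    lfc = np.array([truth.region_true_lfc[r.id] for r in regions])
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), len(config.samples)))
    group = np.array([1 if g == "patient" else 0 for g in
                      (config.groups[s] for s in config.samples)])
    mean = sf[None, :] * mu[:, None] * 2.0 ** (lfc[:, None] * group[None, :])
    if config.dispersion == 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    consensus = [ConsensusRegion(r, frozenset(config.samples)) for r in regions]
    in_region = counts.sum(axis=0)
    library = np.round(in_region / (1.0 - config.background_read_fraction)).astype(int)
    return CountsMatrix(
        regions=consensus,
        samples=list(config.samples),
        groups=dict(config.groups),
        counts=counts.astype(np.int64),
        library_size={s: int(l) for s, l in zip(config.samples, library)},
    )


def simulate_peaks(
    regions: list[GenomicRegion], config: SimulationConfig
) -> dict[str, list[GenomicRegion]]:
    """Per-sample peak calls: each true region is detected with probability
    ``peak_detect_rate`` and reported with jittered edges."""
    rng = child_rng(config.seed, "peaks")
    peaks: dict[str, list[GenomicRegion]] = {}
    for s in config.samples:
        out = []
        for r in regions:
            if rng.random() > config.peak_detect_rate:
                continue
            j1 = int(rng.integers(-200, 201))
            j2 = int(rng.integers(-200, 201))
            start = max(0, r.start + j1)
            end = max(start + 200, r.end + j2)
            out.append(GenomicRegion(r.chrom, start, end, f"{s}_{r.id}"))
        peaks[s] = out
    return peaks


def simulate_reads(
    regions: list[GenomicRegion],
    counts_matrix: CountsMatrix,
    config: SimulationConfig,
) -> dict[str, list[ReadPlacement]]:
    """Read placements realizing the simulated counts.

    Exactly ``counts[i, j]`` deduplicated reads are placed fully inside
    region i for sample j (distinct (start, strand) keys, so duplicate
    collapsing is a no-op), plus background reads in inter-region gaps up
    to the library size.
    """
    rng = child_rng(config.seed, "reads")
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    reads: dict[str, list[ReadPlacement]] = {}
    for j, s in enumerate(counts_matrix.samples):
        sample_reads: list[ReadPlacement] = []
        for i, r in enumerate(regions):
            k = int(counts_matrix.counts[i, j])
            if k == 0:
                continue
            span = r.length - READ_LENGTH
            n_slots = 2 * span
            k_eff = min(k, n_slots)
            slots = rng.choice(n_slots, size=k_eff, replace=False)
            for slot in slots:
                strand = "+" if slot < span else "-"
                off = int(slot % span)
                sample_reads.append(
                    ReadPlacement(r.chrom, r.start + off, r.start + off + READ_LENGTH, strand)
                )
        n_bg = counts_matrix.library_size[s] - len(sample_reads)
        chroms = list(by_chrom)
        for _ in range(max(0, n_bg)):
            chrom = chroms[int(rng.integers(len(chroms)))]
            regs = by_chrom[chrom]
            # drop background reads into the gap before a random region
            ridx = int(rng.integers(len(regs)))
            gap_end = regs[ridx].start - READ_LENGTH
            gap_start = regs[ridx - 1].end if ridx > 0 else 0
            if gap_end <= gap_start:
                continue
            start = int(rng.integers(gap_start, gap_end))
            strand = "+" if rng.random() < 0.5 else "-"
            sample_reads.append(ReadPlacement(chrom, start, start + READ_LENGTH, strand))
        reads[s] = sample_reads
    return reads


def calibrate_noise_sd(x: np.ndarray, target_r: float) -> float:
    """Noise SD giving Pearson r = target between x and x + noise."""
    if not 0 < target_r <= 1:
        raise ValueError("target_r must lie in (0, 1]")
    sd_x = float(np.std(x))
    return sd_x * np.sqrt(1.0 / target_r**2 - 1.0)


def simulate_genes_and_expression(
    regions: list[GenomicRegion],
    truth: SyntheticTruth,
    config: SimulationConfig,
    counts_matrix: CountsMatrix,
) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame]:
    """Gene models driven by regions, with linked expression.

    Each of ``n_genes`` genes is assigned a distinct driving region; its TSS
    is placed inside that region (hence within the +/-5 kb annotation
    window). Per sample, log2(expression RPKM + 1) =
    slope * log2(promoter acetylation RPKM + 1) + Gaussian noise. Returns
    (gene models, expression RPKM table, expression count table); the count
    table is Poisson around the RPKM-implied mean at a 5e6 library.
    """
    rng = child_rng(config.seed, "genes")
    driver_idx = rng.choice(len(regions), size=config.n_genes, replace=False)
    lib = np.array([counts_matrix.library_size[s] for s in counts_matrix.samples], float)
    lengths = counts_matrix.region_lengths

    genes: list[GeneModel] = []
    rpkm_rows = []
    for g, ridx in enumerate(driver_idx):
        region = regions[ridx]
        gid = f"gene_{g:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(rng.integers(region.start, region.end))
        body_len = int(rng.integers(2_000, 10_000))
        if strand == "+":
            body_start, body_end = tss, tss + body_len
        else:
            body_start, body_end = max(0, tss - body_len), tss
            if body_start == tss:
                body_start = tss - 2_000
        genes.append(GeneModel(gid, gid.upper(), region.chrom, strand, tss, body_start, body_end))
        acet_rpkm = (
            counts_matrix.counts[ridx] / (lengths[ridx] / 1e3) / (lib / 1e6)
        )
        log_expr = config.promoter_link_slope * np.log2(acet_rpkm + 1.0)
        log_expr = log_expr + rng.normal(0.0, config.promoter_link_noise_sd, len(lib))
        rpkm_rows.append(np.maximum(0.0, 2.0**log_expr - 1.0))
        truth.gene_to_region[gid] = regions[ridx].id

    expr_rpkm = pd.DataFrame(
        rpkm_rows, index=[g.gene_id for g in genes], columns=counts_matrix.samples
    )
    body_kb = np.array([(g.body_end - g.body_start) / 1e3 for g in genes])
    mean_counts = expr_rpkm.to_numpy() * body_kb[:, None] * 5.0  # 5e6 / 1e6
    expr_counts = pd.DataFrame(
        rng.poisson(mean_counts),
        index=expr_rpkm.index,
        columns=expr_rpkm.columns,
    )
    return genes, expr_rpkm, expr_counts


def _random_pwm(rng: np.random.Generator, length: int, consensus_p: float = 0.95) -> np.ndarray:
    consensus = rng.integers(0, 4, size=length)
    mat = np.full((length, 4), (1.0 - consensus_p) / 3.0)
    mat[np.arange(length), consensus] = consensus_p
    return mat


def simulate_sequences_and_motifs(
    regions: list[GenomicRegion],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[dict[str, str], list[PWM], dict[str, list[str]]]:
    """Uppercase sequences per region plus a motif library and TF mapping.

    Background is i.i.d. uniform over ACGT. The first motif in the library
    is the planted one: its consensus is inserted at a random offset into
    each hyperacetylated region's sequence with probability
    ``motif_plant_rate``. The remaining motifs are decoys never planted.
    ``truth.motif_planted`` records the per-sequence flag.
    """
    rng = child_rng(config.seed, "motifs")
    pwms = [PWM("motif_planted", _random_pwm(rng, config.motif_length))]
    for k in range(config.n_decoy_motifs):
        pwms.append(PWM(f"motif_decoy_{k:02d}", _random_pwm(rng, config.motif_length)))
    tf_map = {"motif_planted": ["TF_PLANTED"]}
    for k in range(config.n_decoy_motifs):
        tf_map[f"motif_decoy_{k:02d}"] = [f"TF_DECOY_{k:02d}"]

    planted_consensus = pwms[0].consensus
    alphabet = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    for r in regions:
        seq = "".join(alphabet[rng.integers(0, 4, size=config.sequence_length)])
        planted = False
        if truth.region_direction[r.id] == HYPER and rng.random() < config.motif_plant_rate:
            off = int(rng.integers(0, config.sequence_length - config.motif_length + 1))
            seq = seq[:off] + planted_consensus + seq[off + config.motif_length:]
            planted = True
        sequences[r.id] = seq
        truth.motif_planted[r.id] = planted
    truth.planted_motif_id = "motif_planted"
    return sequences, pwms, tf_map


def simulate_markers(
    genes: list[GeneModel], config: SimulationConfig, n_cell_types: int = 3,
    markers_per_type: int = 5,
) -> pd.DataFrame:
    """Synthetic cell-type marker table (cell_type, gene_id) over gene models."""
    rng = child_rng(config.seed, "markers")
    need = n_cell_types * markers_per_type
    chosen = rng.choice(len(genes), size=min(need, len(genes)), replace=False)
    rows = []
    for k, gi in enumerate(chosen):
        rows.append(
            {"cell_type": f"cell_type_{k % n_cell_types}", "gene_id": genes[gi].gene_id}
        )
    return pd.DataFrame(rows).sort_values(["cell_type", "gene_id"]).reset_index(drop=True)


def write_inputs(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full input bundle plus truth tables.

    Returns a manifest of written paths. Layout: peaks/<sample>.bed,
    reads/<sample>.bed, counts.tsv, sample_sheet.tsv, genes.tsv/gtf,
    expression_{rpkm,counts}.tsv, sequences.fa, motifs.meme, motif_tf.tsv,
    markers.tsv, truth_*.tsv, config.yaml.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)

    regions, truth = simulate_regions(config)
    counts = simulate_counts(regions, truth, config)
    peaks = simulate_peaks(regions, config)
    reads = simulate_reads(regions, counts, config)
    genes, expr_rpkm, expr_counts = simulate_genes_and_expression(
        regions, truth, config, counts
    )
    sequences, pwms, tf_map = simulate_sequences_and_motifs(regions, truth, config)
    markers = simulate_markers(genes, config)

    paths: dict[str, Path] = {}
    for s in config.samples:
        p = outdir / "peaks" / f"{s}.bed"
        write_bed(peaks[s], p)
        paths[f"peaks/{s}"] = p
        p = outdir / "reads" / f"{s}.bed"
        write_read_bed(reads[s], p)
        paths[f"reads/{s}"] = p

    paths["counts"] = outdir / "counts.tsv"
    df = counts.to_frame()
    df.insert(0, "chrom", [r.chrom for r in regions])
    df.insert(1, "start", [r.start for r in regions])
    df.insert(2, "end", [r.end for r in regions])
    df.to_csv(paths["counts"], sep="\t", index_label="region_id")

    paths["sample_sheet"] = outdir / "sample_sheet.tsv"
    pd.DataFrame(
        {
            "sample_id": config.samples,
            "group": [config.groups[s] for s in config.samples],
            "library_size": [counts.library_size[s] for s in config.samples],
        }
    ).to_csv(paths["sample_sheet"], sep="\t", index=False)

    paths["genes_tsv"] = outdir / "genes.tsv"
    genes_to_tsv(genes, paths["genes_tsv"])
    paths["genes_gtf"] = outdir / "genes.gtf"
    genes_to_gtf(genes, paths["genes_gtf"])
    paths["expression_rpkm"] = outdir / "expression_rpkm.tsv"
    expr_rpkm.to_csv(paths["expression_rpkm"], sep="\t", index_label="gene_id")
    paths["expression_counts"] = outdir / "expression_counts.tsv"
    expr_counts.to_csv(paths["expression_counts"], sep="\t", index_label="gene_id")

    paths["sequences"] = outdir / "sequences.fa"
    write_fasta(sequences, paths["sequences"])
    paths["motifs"] = outdir / "motifs.meme"
    write_meme(pwms, paths["motifs"])
    paths["motif_tf"] = outdir / "motif_tf.tsv"
    pd.DataFrame(
        [(m, tf) for m, tfs in tf_map.items() for tf in tfs],
        columns=["motif_id", "tf_name"],
    ).to_csv(paths["motif_tf"], sep="\t", index=False)
    paths["markers"] = outdir / "markers.tsv"
    markers.to_csv(paths["markers"], sep="\t", index=False)

    paths["truth_regions"] = outdir / "truth_regions.tsv"
    pd.DataFrame(
        {
            "region_id": [r.id for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "direction": [truth.region_direction[r.id] for r in regions],
            "true_lfc": [truth.region_true_lfc[r.id] for r in regions],
            "motif_planted": [truth.motif_planted[r.id] for r in regions],
        }
    ).to_csv(paths["truth_regions"], sep="\t", index=False)
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    pd.DataFrame(
        {
            "gene_id": list(truth.gene_to_region),
            "driving_region": [truth.gene_to_region[g] for g in truth.gene_to_region],
        }
    ).to_csv(paths["truth_genes"], sep="\t", index=False)

    paths["config"] = outdir / "config.yaml"
    cfg = asdict(config)
    cfg["region_len_range"] = list(cfg["region_len_range"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
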