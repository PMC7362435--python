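"""End-to-end orchestration of the acetylome analysis stages.

Stages run in dependency order (consensus -> differential -> TRCD /
annotation -> motifs / integration) from a single validated config, writing
plain-text outputs plus a JSON run manifest with parameters, seeds and
output digests. Reruns with identical config and inputs are byte-identical
for all deterministic stages (every stochastic stage takes an explicit
seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import consensus as cons
from . import differential as diff
from . import integration as integ
from . import motifs as mot
from . import trcd as trcd_mod
from .regions import GenomicRegion, read_bed, read_read_bed, write_bed
from .synthetic import SimulationConfig, child_rng, write_inputs

logger = logging.getLogger(__name__)

ALL_STAGES = ["consensus", "diff", "trcd", "annotate", "motifs", "integrate"]


@dataclass
class PipelineConfig:
    input_dir: str
    outdir: str
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    autosomes: list[str] | None = None  # None -> chr1..chr22
    min_length: int = 2000
    min_support: int = 2
    alpha: float = 0.05
    lfc_threshold: float = 0.4
    require_significant: bool = True
    short_range: tuple[int, int] = trcd_mod.SHORT_RANGE
    long_range: tuple[int, int] = trcd_mod.LONG_RANGE
    n_shuffles: int = 1000
    distance_mode: str = "midpoint"
    annotation_flank: int = 5000
    motif_threshold: float = 0.05
    n_partitions: int = 1
    n_permutations: int = 1000
    gsea_weight: float = 1.0
    de_p_cutoff: float = 0.05
    seed: int = 0
    use_precomputed_counts: bool = False
    mask_bed: str | None = None

    def validate(self) -> None:
        indir = Path(self.input_dir)
        if not indir.is_dir():
            raise FileNotFoundError(f"input_dir does not exist: {indir}")
        required = ["sample_sheet.tsv"]
        if self.use_precomputed_counts:
            required.append("counts.tsv")
        else:
            required += ["peaks", "reads"]
        for name in required:
            if not (indir / name).exists():
                raise FileNotFoundError(f"missing required input: {indir / name}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "short_range" in raw:
            raw["short_range"] = tuple(raw["short_range"])
        if "long_range" in raw:
            raw["long_range"] = tuple(raw["long_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["short_range"] = list(raw["short_range"])
        raw["long_range"] = list(raw["long_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_sample_sheet(indir: Path) -> pd.DataFrame:
    return pd.read_csv(indir / "sample_sheet.tsv", sep="\t")


def simulate_command(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Write the full synthetic input bundle; returns the path manifest."""
    paths = write_inputs(config, outdir)
    regions_bed = Path(outdir) / "regions.bed"
    truth = pd.read_csv(paths["truth_regions"], sep="\t")
    write_bed(
        [
            GenomicRegion(str(r.chrom), int(r.start), int(r.end), str(r.region_id))
            for r in truth.itertuples(index=False)
        ],
        regions_bed,
    )
    paths["regions_bed"] = regions_bed
    return {k: str(v) for k, v in paths.items()}


def _stage_consensus(cfg: PipelineConfig, out: Path) -> dict:
    indir = Path(cfg.input_dir)
    sheet = _read_sample_sheet(indir)
    samples = [str(s) for s in sheet["sample_id"]]
    groups = dict(zip(samples, sheet["group"].astype(str)))
    autosomes = cfg.autosomes
    if autosomes is None:
        autosomes = [f"chr{i}" for i in range(1, 23)]

    if cfg.use_precomputed_counts:
        counts_df = pd.read_csv(indir / "counts.tsv", sep="\t", index_col=0)
        meta = counts_df[["chrom", "start", "end"]]
        mat = counts_df[samples].to_numpy(dtype=np.int64)
        lib = dict(zip(samples, sheet["library_size"].astype(int)))
        regions = [
            cons.ConsensusRegion(
                GenomicRegion(str(r.chrom), int(r.start), int(r.end), str(idx)),
                frozenset(samples),
            )
            for idx, r in zip(counts_df.index, meta.itertuples(index=False))
        ]
        cm = cons.CountsMatrix(regions, samples, groups, mat, lib,
                               region_ids=[str(i) for i in counts_df.index])
    else:
        peaks = {s: read_bed(indir / "peaks" / f"{s}.bed") for s in samples}
        reads = {
            s: cons.collapse_duplicates(read_read_bed(indir / "reads" / f"{s}.bed"))
            for s in samples
        }
        consensus = cons.build_consensus(
            peaks, min_len=cfg.min_length, min_support=cfg.min_support
        )
        cm = cons.count_occupancy(consensus, reads, groups, autosomes=autosomes)

    write_bed(
        [cr.region for cr in cm.regions],
        out / "consensus.bed",
        scores=[cr.support for cr in cm.regions],
        names=cm.region_ids,
    )
    df = cm.to_frame()
    df.insert(0, "chrom", [cr.region.chrom for cr in cm.regions])
    df.insert(1, "start", [cr.region.start for cr in cm.regions])
    df.insert(2, "end", [cr.region.end for cr in cm.regions])
    df.to_csv(out / "consensus_counts.tsv", sep="\t", index_label="region_id")
    pd.DataFrame(
        {
            "sample_id": samples,
            "group": [groups[s] for s in samples],
            "library_size": [cm.library_size[s] for s in samples],
        }
    ).to_csv(out / "consensus_samples.tsv", sep="\t", index=False)
    return {
        "n_consensus_regions": len(cm.regions),
        "outputs": ["consensus.bed", "consensus_counts.tsv", "consensus_samples.tsv"],
    }


def _load_counts(out: Path) -> tuple[cons.CountsMatrix, pd.DataFrame]:
    df = pd.read_csv(out / "consensus_counts.tsv", sep="\t", index_col=0)
    sheet = pd.read_csv(out / "consensus_samples.tsv", sep="\t")
    samples = [str(s) for s in sheet["sample_id"]]
    groups = dict(zip(samples, sheet["group"].astype(str)))
    lib = dict(zip(samples, sheet["library_size"].astype(int)))
    regions = [
        cons.ConsensusRegion(
            GenomicRegion(str(r.chrom), int(r.start), int(r.end), str(idx)),
            frozenset(samples),
        )
        for idx, r in zip(df.index, df[["chrom", "start", "end"]].itertuples(index=False))
    ]
    cm = cons.CountsMatrix(
        regions, samples, groups, df[samples].to_numpy(np.int64), lib,
        region_ids=[str(i) for i in df.index],
    )
    return cm, df


def _stage_diff(cfg: PipelineConfig, out: Path) -> dict:
    cm, meta = _load_counts(out)
    groups = np.array([cm.groups[s] for s in cm.samples])
    results = diff.nb_test(cm.counts, groups, region_ids=cm.region_ids, alpha_sig=cfg.alpha)
    rdf = diff.results_to_frame(results)
    rdf.insert(1, "chrom", meta["chrom"].to_numpy())
    rdf.insert(2, "start", meta["start"].to_numpy())
    rdf.insert(3, "end", meta["end"].to_numpy())
    rdf.to_csv(out / "differential.tsv", sep="\t", index=False, float_format="%.6g")

    hyper, hypo = diff.classify_dars(results, alpha=cfg.alpha)
    for name, subset in (("hyper", hyper), ("hypo", hypo)):
        ids = {r.region_id for r in subset}
        sel = rdf[rdf["region_id"].isin(ids)]
        write_bed(
            [
                GenomicRegion(str(r.chrom), int(r.start), int(r.end), str(r.region_id))
                for r in sel.itertuples(index=False)
            ],
            out / f"dar_{name}.bed",
        )
    norm = diff.normalize_for_clustering(cm)
    norm.values.to_csv(out / "normalized_matrix.tsv", sep="\t",
                       index_label="region_id", float_format="%.6g")
    return {
        "n_dars": len(hyper) + len(hypo),
        "n_hyper": len(hyper),
        "n_hypo": len(hypo),
        "outputs": [
            "differential.tsv", "dar_hyper.bed", "dar_hypo.bed", "normalized_matrix.tsv",
        ],
    }


def _stage_trcd(cfg: PipelineConfig, out: Path) -> dict:
    rdf = pd.read_csv(out / "differential.tsv", sep="\t")
    directional = trcd_mod.select_directional(
        rdf, lfc_threshold=cfg.lfc_threshold,
        require_significant=cfg.require_significant, alpha=cfg.alpha,
    )
    pairs = trcd_mod.form_pairs(
        directional, cfg.short_range, cfg.long_range, cfg.distance_mode
    )
    runs = trcd_mod.find_runs(
        directional, cfg.short_range, cfg.long_range, cfg.distance_mode
    )
    null = trcd_mod.shuffle_null(
        rdf, cfg.n_shuffles, cfg.seed, cfg.lfc_threshold,
        cfg.require_significant, cfg.alpha, cfg.short_range, cfg.long_range,
    )
    tests = trcd_mod.trcd_test(pairs, null, seed=cfg.seed)

    pd.DataFrame(
        {
            "first": [p.first.region_id for p in pairs],
            "second": [p.second.region_id for p in pairs],
            "distance": [p.distance for p in pairs],
            "distance_class": [p.distance_class for p in pairs],
            "same_direction": [p.same_direction for p in pairs],
        }
    ).to_csv(out / "trcd_pairs.tsv", sep="\t", index=False)

    directional_by_id = {d.region_id: d for d in directional}
    with open(out / "trcd_runs.bed", "w") as fh:
        for klass, run_list in runs.items():
            for run in run_list:
                first = directional_by_id[run.member_ids[0]]
                last = directional_by_id[run.member_ids[-1]]
                fh.write(
                    f"{run.chrom}\t{first.start}\t{last.end}\t"
                    f"{run.direction}_{klass}\t{run.n_members}\n"
                )

    summary = {
        klass: {
            "observed_same_direction_pairs": t.observed_same_direction_pairs,
            "total_pairs": t.total_pairs,
            "null_expectation_p0": t.null_expectation,
            "empirical_p": t.empirical_p,
            "binomial_p": t.binomial_p,
            "binomial_log10_p": t.binomial_log10_p,
            "n_shuffles": t.n_shuffles,
            "seed": cfg.seed,
            "n_runs": len(runs[klass]),
        }
        for klass, t in tests.items()
    }
    with open(out / "trcd_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return {"trcd": summary, "outputs": ["trcd_pairs.tsv", "trcd_runs.bed", "trcd_summary.json"]}


def _stage_annotate(cfg: PipelineConfig, out: Path) -> dict:
    indir = Path(cfg.input_dir)
    genes = ann.genes_from_tsv(indir / "genes.tsv")
    rdf = pd.read_csv(out / "differential.tsv", sep="\t")
    regions = [
        GenomicRegion(str(r.chrom), int(r.start), int(r.end), str(r.region_id))
        for r in rdf.itertuples(index=False)
    ]
    links = ann.annotate_regions(
        regions, genes, flank_up=cfg.annotation_flank, flank_down=cfg.annotation_flank
    )
    ann.links_to_tsv(links, out / "region_gene_links.tsv")
    unann = ann.unannotated_regions(regions, links)
    write_bed(unann, out / "unannotated_regions.bed")

    cm, _ = _load_counts(out)
    for kind, fname in (
        (ann.PROMOTER_2P5KB, "promoter_signal.tsv"),
        (ann.UPSTREAM_2P5KB, "upstream_signal.tsv"),
    ):
        sig = ann.window_signal(cm, genes, window_kind=kind)
        sig.to_csv(out / fname, sep="\t", index_label="gene_id", float_format="%.6g")
    return {
        "n_links": len(links),
        "n_unannotated": len(unann),
        "outputs": [
            "region_gene_links.tsv", "unannotated_regions.bed",
            "promoter_signal.tsv", "upstream_signal.tsv",
        ],
    }


def _stage_motifs(cfg: PipelineConfig, out: Path) -> dict:
    indir = Path(cfg.input_dir)
    sequences = mot.read_fasta(indir / "sequences.fa")
    pwms = mot.read_meme(indir / "motifs.meme")
    tf_map = mot.read_motif_tf_table(indir / "motif_tf.tsv")
    seq_regions = read_bed(indir / "regions.bed")
    if cfg.mask_bed:
        seq_regions = mot.apply_mask(seq_regions, read_bed(cfg.mask_bed))

    results_all: list[mot.MotifEnrichmentResult] = []
    enriched_by_class: dict[str, list[mot.MotifEnrichmentResult]] = {}
    rng_seed = child_rng(cfg.seed, "motif_shuffle").integers(2**31)
    for klass in ("hyper", "hypo"):
        dars = read_bed(out / f"dar_{klass}.bed")
        fg_ids = [
            sr.id
            for sr in seq_regions
            if any(sr.overlaps(d) for d in dars if d.chrom == sr.chrom)
        ]
        fg_seqs = {i: sequences[i] for i in fg_ids if i in sequences}
        if not fg_seqs:
            logger.warning("no %s foreground sequences; class skipped", klass)
            enriched_by_class[klass] = []
            continue
        bg_list = mot.shuffle_sequences(list(fg_seqs.values()), seed=int(rng_seed))
        bg_seqs = {f"shuf_{i}": s for i, s in enumerate(bg_list)}
        fg_scores = mot.score_sequences(fg_seqs, pwms)
        bg_scores = mot.score_sequences(bg_seqs, pwms)
        res = mot.ame_test(
            fg_scores, bg_scores, klass, threshold=cfg.motif_threshold,
            n_partitions=cfg.n_partitions, tf_map=tf_map,
        )
        results_all.extend(res)
        enriched_by_class[klass] = res

    mot.results_to_frame(results_all).to_csv(
        out / "motif_enrichment.tsv", sep="\t", index=False, float_format="%.6g"
    )
    tf_sets = mot.map_motifs_to_tfs(enriched_by_class, tf_map)
    pd.DataFrame(
        [(part, tf) for part, tfs in sorted(tf_sets.items()) for tf in sorted(tfs)],
        columns=["partition", "tf_name"],
    ).to_csv(out / "tf_sets.tsv", sep="\t", index=False)
    return {
        "n_enriched": {k: sum(r.enriched for r in v) for k, v in enriched_by_class.items()},
        "tf_partition_sizes": {k: len(v) for k, v in tf_sets.items()},
        "outputs": ["motif_enrichment.tsv", "tf_sets.tsv"],
    }


def _stage_integrate(cfg: PipelineConfig, out: Path) -> dict:
    indir = Path(cfg.input_dir)
    expr_rpkm = pd.read_csv(indir / "expression_rpkm.tsv", sep="\t", index_col=0)
    expr_counts = pd.read_csv(indir / "expression_counts.tsv", sep="\t", index_col=0)
    genes = ann.genes_from_tsv(indir / "genes.tsv")
    promoter = pd.read_csv(out / "promoter_signal.tsv", sep="\t", index_col=0)
    sheet = pd.read_csv(out / "consensus_samples.tsv", sep="\t")
    groups = dict(zip(sheet["sample_id"].astype(str), sheet["group"].astype(str)))

    expressed = integ.expressed_filter(expr_rpkm)
    corr = integ.per_sample_correlation(promoter, expressed)
    corr.to_csv(out / "correlation_summary.tsv", sep="\t", float_format="%.6g")

    group_vec = np.array([groups[s] for s in expr_counts.columns])
    de = integ.de_test(expr_counts, group_vec, p_cutoff=cfg.de_p_cutoff)
    de.to_csv(out / "de_results.tsv", sep="\t", float_format="%.6g")

    links = pd.read_csv(out / "region_gene_links.tsv", sep="\t")
    rdf = pd.read_csv(out / "differential.tsv", sep="\t")
    gene_sets = {}
    for klass in ("hyper", "hypo"):
        ids = set(rdf.loc[rdf["direction"] == klass, "region_id"].astype(str))
        gene_sets[f"{klass}_dar_genes"] = set(
            links.loc[links["region_id"].astype(str).isin(ids), "gene_id"].astype(str)
        )
    ranked = integ.RankedGeneList(
        [str(g) for g in de.index], de["log2fc"].to_numpy()
    )
    gsea_sets = {
        k: v & set(ranked.gene_ids) for k, v in gene_sets.items()
    }
    gsea_sets = {k: v for k, v in gsea_sets.items() if v}
    gsea_results = []
    if gsea_sets:
        gsea_results = integ.gsea_nes_fdr(
            ranked, gsea_sets, n_permutations=cfg.n_permutations,
            seed=int(child_rng(cfg.seed, "gsea").integers(2**31)),
            weight=cfg.gsea_weight,
        )
        pd.DataFrame(
            {
                "gene_set": [r.gene_set_id for r in gsea_results],
                "es": [r.es for r in gsea_results],
                "nes": [r.nes for r in gsea_results],
                "fdr": [r.fdr for r in gsea_results],
                "n_hits": [len(r.hit_indices) for r in gsea_results],
                "n_permutations": [r.n_permutations for r in gsea_results],
            }
        ).to_csv(out / "gsea_results.tsv", sep="\t", index=False, float_format="%.6g")

    markers = pd.read_csv(indir / "markers.tsv", sep="\t")
    dars = rdf.loc[rdf["direction"] != "none", ["chrom", "start", "end", "direction"]]
    panels = integ.marker_panel(markers, genes, promoter, expr_rpkm, groups, dars, de)
    integ.panels_to_frame(panels).to_csv(
        out / "marker_panels.tsv", sep="\t", index=False, float_format="%.6g"
    )

    tf_sets_df = pd.read_csv(out / "tf_sets.tsv", sep="\t") if (out / "tf_sets.tsv").exists() else pd.DataFrame(columns=["partition", "tf_name"])
    tf_sets = {
        part: set(sub["tf_name"].astype(str))
        for part, sub in tf_sets_df.groupby("partition")
    }
    gene_by_symbol = {g.symbol: g.gene_id for g in genes}
    de_sym = de.copy()
    # TF names in the synthetic map are symbols; harmonize to gene ids when possible
    tf_sets = {
        part: {gene_by_symbol.get(tf, tf) for tf in tfs} for part, tfs in tf_sets.items()
    }
    concordant = integ.concordant_tfs(tf_sets, de_sym)
    pd.DataFrame(
        [(k, tf) for k, tfs in sorted(concordant.items()) for tf in sorted(tfs)],
        columns=["category", "tf_name"],
    ).to_csv(out / "concordant_tfs.tsv", sep="\t", index=False)

    return {
        "n_expressed": int(expressed.shape[0]),
        "median_spearman": float(corr["spearman"].median()),
        "n_de": int(de["de"].sum()),
        "gsea": {
            r.gene_set_id: {"es": r.es, "nes": r.nes, "fdr": r.fdr} for r in gsea_results
        },
        "outputs": [
            "correlation_summary.tsv", "de_results.tsv", "gsea_results.tsv",
            "marker_panels.tsv", "concordant_tfs.tsv",
        ],
    }


_STAGE_FUNCS = {
    "consensus": _stage_consensus,
    "diff": _stage_diff,
    "trcd": _stage_trcd,
    "annotate": _stage_annotate,
    "motifs": _stage_motifs,
    "integrate": _stage_integrate,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; returns and writes
    the run manifest. A stage failure halts the run with the failing stage
    named; prior outputs are retained with a failure marker in the manifest."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "acetylome",
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "stages": {},
    }
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("running stage %s (seed %d)", stage, cfg.seed)
        try:
            info = _STAGE_FUNCS[stage](cfg, out)
        except Exception:
            manifest["stages"][stage] = {"status": "failed"}
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
            logger.exception("stage %s failed", stage)
            raise RuntimeError(f"pipeline stage {stage!r} failed") from None
        info["status"] = "ok"
        info["digests"] = {
            name: _sha256(out / name) for name in info.get("outputs", [])
        }
        manifest["stages"][stage] = info
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def demo_config(workdir: str | Path, seed: int = 0) -> tuple[SimulationConfig, PipelineConfig]:
    """A small, fast synthetic demonstration configuration."""
    workdir = Path(workdir)
    sim = SimulationConfig(
        n_chromosomes=3,
        chrom_length=120_000_000,
        n_regions=600,
        n_genes=200,
        seed=seed,
    )
    pipe = PipelineConfig(
        input_dir=str(workdir / "inputs"),
        outdir=str(workdir / "results"),
        autosomes=sim.autosomes,
        n_shuffles=200,
        n_permutations=200,
        seed=seed,
    )
    return sim, pipe
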