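"""Acetylome-transcriptome integration.

Per-sample correlation of promoter acetylation with expression, a classic
weighted Kolmogorov-Smirnov (GSEA-style) running enrichment score with
gene-set-permutation NES/FDR, cell-type marker panels, the expression-side
differential test, and concordant-TF calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import differential
from .annotation import GeneModel, UPSTREAM_2P5KB, window_for_kind

logger = logging.getLogger(__name__)


@dataclass
class RankedGeneList:
    """Genes ordered by a ranking metric (fold change), descending."""

    gene_ids: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.gene_ids) != len(self.metric):
            raise ValueError("gene_ids and metric lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("ranked list contains duplicate genes")
        if not np.all(np.isfinite(self.metric)):
            raise ValueError("ranking metric must be finite")
        order = np.argsort(-self.metric, kind="mergesort")
        self.gene_ids = [self.gene_ids[i] for i in order]
        self.metric = self.metric[order]


@dataclass
class EnrichmentScoreResult:
    gene_set_id: str
    es: float
    nes: float
    fdr: float
    hit_indices: list[int]
    n_permutations: int
    seed: int | None
    running: np.ndarray | None = field(default=None, repr=False)


@dataclass
class MarkerRecord:
    gene_id: str
    promoter_acetylation: dict[str, float]  # group -> mean signal
    expression: dict[str, float]
    dar_flag: bool
    dar_direction: str
    de_flag: bool
    de_log2fc: float


@dataclass
class MarkerPanel:
    cell_type: str
    markers: list[MarkerRecord]


def expressed_filter(rpkm_table: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Genes whose mean RPKM is strictly above the threshold."""
    return rpkm_table.loc[rpkm_table.mean(axis=1) > threshold]


def per_sample_correlation(
    promoter_signal: pd.DataFrame,
    expression: pd.DataFrame,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Spearman and Pearson correlation per shared sample over shared genes.

    Both matrices are put on the log2(x + 1) scale first (unless already
    transformed). Requires at least 3 shared genes.
    """
    genes = promoter_signal.index.intersection(expression.index)
    samples = promoter_signal.columns.intersection(expression.columns)
    if len(genes) < 3:
        raise ValueError(f"only {len(genes)} shared genes; need >= 3")
    a = promoter_signal.loc[genes, samples].to_numpy(float)
    b = expression.loc[genes, samples].to_numpy(float)
    if log_transform:
        a = np.log2(a + 1.0)
        b = np.log2(b + 1.0)
    rows = []
    for j, s in enumerate(samples):
        rows.append(
            {
                "sample": s,
                "spearman": stats.spearmanr(a[:, j], b[:, j]).statistic,
                "pearson": stats.pearsonr(a[:, j], b[:, j]).statistic,
                "n_genes": len(genes),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def gsea_es(
    ranked: RankedGeneList, gene_set: set[str], weight: float = 1.0
) -> tuple[float, np.ndarray, list[int]]:
    """Classic weighted running-sum enrichment score.

    Hits increment by |metric|^weight normalized by the hit total; misses
    decrement by 1/(N - n_hits). Returns (ES = signed maximum deviation,
    running profile, hit indices). With every gene a hit the miss term is
    degenerate and the ES is the maximum of the hit-only running sum.
    """
    hits = np.array([g in gene_set for g in ranked.gene_ids])
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    n = len(ranked.gene_ids)
    w = np.abs(ranked.metric) ** weight
    hit_total = w[hits].sum()
    if hit_total == 0:
        inc = hits / n_hits  # all-zero metrics fall back to unweighted steps
    else:
        inc = np.where(hits, w / hit_total, 0.0)
    if n > n_hits:
        dec = np.where(hits, 0.0, 1.0 / (n - n_hits))
    else:
        dec = np.zeros(n)
    running = np.cumsum(inc - dec)
    es = float(running[np.argmax(np.abs(running))])
    return es, running, list(np.flatnonzero(hits))


def gsea_nes_fdr(
    ranked: RankedGeneList,
    gene_sets: dict[str, set[str]],
    n_permutations: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> list[EnrichmentScoreResult]:
    """NES and FDR from a gene-set permutation null.

    For each set, ``n_permutations`` random sets of equal size are drawn
    from the ranked genes. NES divides the ES by the mean |null ES| of the
    matching sign; null ES values are normalized the same way, and the FDR
    follows the positive/negative-tail convention, pooling null NES across
    all queried sets.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)
    genes = np.array(ranked.gene_ids)
    n = len(genes)

    observed: dict[str, tuple[float, np.ndarray, list[int]]] = {}
    null_es: dict[str, np.ndarray] = {}
    for set_id, gene_set in gene_sets.items():
        es, running, hit_idx = gsea_es(ranked, gene_set, weight)
        observed[set_id] = (es, running, hit_idx)
        size = len(gene_set & set(ranked.gene_ids))
        es_null = np.empty(n_permutations)
        for k in range(n_permutations):
            perm_set = set(genes[rng.choice(n, size=size, replace=False)])
            es_null[k], _, _ = gsea_es(ranked, perm_set, weight)
        null_es[set_id] = es_null

    def normalize(es_vals: np.ndarray, null: np.ndarray) -> np.ndarray:
        pos = null[null > 0]
        neg = null[null < 0]
        pos_mean = pos.mean() if pos.size else np.nan
        neg_mean = np.abs(neg).mean() if neg.size else np.nan
        out = np.where(es_vals >= 0, es_vals / pos_mean, es_vals / neg_mean)
        return out

    nes_obs = {
        sid: float(normalize(np.array([observed[sid][0]]), null_es[sid])[0])
        for sid in gene_sets
    }
    nes_null_all = np.concatenate(
        [normalize(null_es[sid], null_es[sid]) for sid in gene_sets]
    )
    nes_obs_all = np.array(list(nes_obs.values()))

    results = []
    for sid in gene_sets:
        nes = nes_obs[sid]
        if np.isnan(nes):
            fdr = np.nan
        elif nes >= 0:
            pool = nes_null_all[np.isfinite(nes_null_all)]
            num = np.mean(pool >= nes) if pool.size else 0.0
            den = np.mean(nes_obs_all[np.isfinite(nes_obs_all)] >= nes)
            fdr = min(1.0, num / den) if den > 0 else 0.0
        else:
            pool = nes_null_all[np.isfinite(nes_null_all)]
            num = np.mean(pool <= nes) if pool.size else 0.0
            den = np.mean(nes_obs_all[np.isfinite(nes_obs_all)] <= nes)
            fdr = min(1.0, num / den) if den > 0 else 0.0
        es, running, hit_idx = observed[sid]
        results.append(
            EnrichmentScoreResult(
                gene_set_id=sid,
                es=es,
                nes=nes,
                fdr=float(fdr),
                hit_indices=hit_idx,
                n_permutations=n_permutations,
                seed=seed,
                running=running,
            )
        )
    return results


def de_test(
    counts: pd.DataFrame,
    groups: np.ndarray,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Expression-side differential test: the same NB machinery as the
    acetylome, but called at *raw* p < cutoff (the expression convention,
    deliberately asymmetric to the acetylome's adjusted-p call)."""
    nonzero = counts.sum(axis=1) > 0
    sub = counts.loc[nonzero]
    res = differential.nb_test(
        sub.to_numpy(), groups, region_ids=list(sub.index)
    )
    df = differential.results_to_frame(res).rename(columns={"region_id": "gene_id"})
    df["de"] = np.isfinite(df["p_value"]) & (df["p_value"] < p_cutoff)
    df["de_direction"] = np.where(
        ~df["de"], "none", np.where(df["log2fc"] > 0, "up", "down")
    )
    return df.set_index("gene_id")


def marker_panel(
    markers: pd.DataFrame,
    genes: list[GeneModel],
    promoter_signal: pd.DataFrame,
    expression: pd.DataFrame,
    sample_groups: dict[str, str],
    dars: pd.DataFrame,
    de_results: pd.DataFrame,
) -> list[MarkerPanel]:
    """Cell-type marker summaries.

    ``markers`` has columns cell_type, gene_id. For each marker: group
    means (all / patient / control) of promoter acetylation and expression;
    a DAR flag when the gene's 2.5 kb upstream window overlaps a DAR (with
    the DAR's direction); and the DE flag with fold change at raw p < 0.05.
    Markers absent from the gene models are logged and skipped.
    """
    genes_by_id = {g.gene_id: g for g in genes}
    sample_sets = {
        "all": list(sample_groups),
        "patient": [s for s, g in sample_groups.items() if g == "patient"],
        "control": [s for s, g in sample_groups.items() if g == "control"],
    }
    dar_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for r in dars.itertuples(index=False):
        dar_by_chrom.setdefault(str(r.chrom), []).append(
            (int(r.start), int(r.end), str(r.direction))
        )

    panels = []
    for cell_type, group in markers.groupby("cell_type"):
        records = []
        for gid in group["gene_id"]:
            gene = genes_by_id.get(gid)
            if gene is None:
                logger.warning("marker %s not in gene models; skipped", gid)
                continue
            window = window_for_kind(gene, UPSTREAM_2P5KB)
            dar_flag, dar_dir = False, "none"
            for s, e, d in dar_by_chrom.get(gene.chrom, ()):
                if s < window.end and window.start < e:
                    dar_flag, dar_dir = True, d
                    break
            prom = {
                name: float(promoter_signal.loc[gid, cols].mean())
                if gid in promoter_signal.index
                else np.nan
                for name, cols in sample_sets.items()
            }
            expr = {
                name: float(expression.loc[gid, cols].mean())
                if gid in expression.index
                else np.nan
                for name, cols in sample_sets.items()
            }
            if gid in de_results.index:
                de_flag = bool(de_results.loc[gid, "de"])
                de_lfc = float(de_results.loc[gid, "log2fc"])
            else:
                de_flag, de_lfc = False, np.nan
            records.append(
                MarkerRecord(gid, prom, expr, dar_flag, dar_dir, de_flag, de_lfc)
            )
        if not records:
            logger.warning("cell type %s has no usable markers", cell_type)
        panels.append(MarkerPanel(str(cell_type), records))
    return panels


def concordant_tfs(
    tf_sets: dict[str, set[str]],
    de_results: pd.DataFrame,
    external_gene_set: set[str] | None = None,
) -> dict[str, set[str]]:
    """TFs whose motif enrichment direction matches their expression change.

    Hyper-side TFs (exclusive-hyper plus shared) are intersected with
    upregulated DE genes; hypo-side with downregulated. An optional external
    gene set further restricts both intersections.
    """
    up = set(de_results.index[de_results["de_direction"] == "up"].astype(str))
    down = set(de_results.index[de_results["de_direction"] == "down"].astype(str))
    hyper_side = tf_sets.get("exclusive_hyper", set()) | tf_sets.get("shared", set())
    hypo_side = tf_sets.get("exclusive_hypo", set()) | tf_sets.get("shared", set())
    if not hyper_side and "hyper" in tf_sets:
        hyper_side = tf_sets["hyper"]
    if not hypo_side and "hypo" in tf_sets:
        hypo_side = tf_sets["hypo"]
    out = {
        "concordant_hyper": hyper_side & up,
        "concordant_hypo": hypo_side & down,
    }
    if external_gene_set is not None:
        out["concordant_hyper_external"] = out["concordant_hyper"] & external_gene_set
        out["concordant_hypo_external"] = out["concordant_hypo"] & external_gene_set
    return out


def panels_to_frame(panels: list[MarkerPanel]) -> pd.DataFrame:
    rows = []
    for p in panels:
        for m in p.markers:
            rows.append(
                {
                    "cell_type": p.cell_type,
                    "gene_id": m.gene_id,
                    "promoter_all": m.promoter_acetylation["all"],
                    "promoter_patient": m.promoter_acetylation["patient"],
                    "promoter_control": m.promoter_acetylation["control"],
                    "expression_all": m.expression["all"],
                    "expression_patient": m.expression["patient"],
                    "expression_control": m.expression["control"],
                    "dar_flag": m.dar_flag,
                    "dar_direction": m.dar_direction,
                    "de_flag": m.de_flag,
                    "de_log2fc": m.de_log2fc,
                }
            )
    return pd.DataFrame(rows)
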