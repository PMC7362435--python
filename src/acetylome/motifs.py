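"""PWM motif enrichment in differentially acetylated regions.

AME-style procedure: each sequence is scored by the best log-odds site of a
PWM (both strands), foreground scores are compared against per-sequence
shuffled controls with a one-sided Wilcoxon rank-sum test, and p-values are
Bonferroni-corrected by the number of motifs times the number of sequence
partitions tested. Background frequencies are uniform 0.25 and each motif
column receives a total pseudocount of 0.25, split by the background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .regions import GenomicRegion

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0, 4: 4}  # A<->T, C<->G, N->N

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass
class PWM:
    motif_id: str
    matrix: np.ndarray  # length x 4, per-position probabilities over ACGT
    tf_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("PWM matrix must be length x 4 with length >= 1")
        if np.any(self.matrix < 0):
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1 before pseudocounts")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    rank_sum_p: float
    bonferroni_p: float
    n_tests: int
    enriched: bool
    direction_class: str
    median_fg_score: float = np.nan
    median_bg_score: float = np.nan
    tf_names: list[str] = field(default_factory=list)


def apply_mask(
    regions: list[GenomicRegion], mask: list[GenomicRegion] | None
) -> list[GenomicRegion]:
    """Restrict regions to their intersections with an accessibility mask.

    With no mask this is the identity. A region overlapping several mask
    intervals yields one intersection interval each.
    """
    if mask is None:
        return list(regions)
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for m in mask:
        by_chrom.setdefault(m.chrom, []).append(m)
    out = []
    for r in regions:
        k = 0
        for m in sorted(by_chrom.get(r.chrom, ()), key=lambda x: x.start):
            s, e = max(r.start, m.start), min(r.end, m.end)
            if s < e:
                out.append(GenomicRegion(r.chrom, s, e, f"{r.id}_mask{k}" if k else r.id))
                k += 1
    return out


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence over {A,C,G,T,N} to integer codes (N -> 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, i in _IDX.items():
        codes[arr == ord(base)] = i
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    return codes


def _log_odds(pwm: PWM, background=UNIFORM_BACKGROUND, pseudocount_total: float = 0.25) -> np.ndarray:
    """Per-position log2-odds with background-proportional pseudocounts.

    p'(b) = (p(b) + pc * bg(b)) / (1 + pc); with uniform background the N
    column contributes exactly 0 (the background log-odds of itself).
    """
    bg = np.asarray(background, float)
    adj = (pwm.matrix + pseudocount_total * bg[None, :]) / (1.0 + pseudocount_total)
    lo = np.log2(adj / bg[None, :])
    return np.hstack([lo, np.zeros((pwm.length, 1))])  # column 4: N scores 0


def best_site_score(
    sequence: str | np.ndarray,
    pwm: PWM,
    background=UNIFORM_BACKGROUND,
    pseudocount_total: float = 0.25,
) -> float:
    """Maximum log2-odds site score over all offsets on both strands."""
    codes = encode_sequence(sequence) if isinstance(sequence, str) else sequence
    L, w = len(codes), pwm.length
    if L < w:
        raise ValueError("sequence shorter than motif")
    lo = _log_odds(pwm, background, pseudocount_total)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    fwd = lo[np.arange(w)[None, :], windows].sum(axis=1)
    rc = np.array([_COMPLEMENT[int(c)] for c in range(5)], dtype=np.int8)[codes][::-1]
    windows_rc = np.lib.stride_tricks.sliding_window_view(rc, w)
    rev = lo[np.arange(w)[None, :], windows_rc].sum(axis=1)
    return float(max(fwd.max(), rev.max()))


def shuffle_sequences(sequences: list[str], seed: int) -> list[str]:
    """Per-sequence mononucleotide shuffle preserving length and composition."""
    rng = np.random.default_rng(seed)
    out = []
    for s in sequences:
        chars = np.array(list(s))
        out.append("".join(chars[rng.permutation(len(chars))]))
    return out


def rank_sum_greater(fg: np.ndarray, bg: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p (foreground > background).

    Exact enumeration when both sides have <= 8 observations and no ties
    cross the groups; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    fg, bg = np.asarray(fg, float), np.asarray(bg, float)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("both score lists must be non-empty")
    exact_ok = fg.size <= 8 and bg.size <= 8 and np.unique(np.r_[fg, bg]).size == fg.size + bg.size
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(fg, bg, alternative="greater", method=method)
    return float(res.pvalue)


def ame_test(
    fg_scores: dict[str, np.ndarray],
    bg_scores: dict[str, np.ndarray],
    direction_class: str,
    threshold: float = 0.05,
    n_tests: int | None = None,
    n_partitions: int = 1,
    tf_map: dict[str, list[str]] | None = None,
) -> list[MotifEnrichmentResult]:
    """Per-motif enrichment of foreground over background best-site scores.

    ``n_tests`` defaults to n_motifs * n_partitions; a motif is called
    enriched when its Bonferroni-corrected p falls below ``threshold``.
    """
    motif_ids = list(fg_scores)
    if n_tests is None:
        n_tests = len(motif_ids) * n_partitions
    out = []
    for mid in motif_ids:
        p = rank_sum_greater(fg_scores[mid], bg_scores[mid])
        bp = min(1.0, p * n_tests)
        out.append(
            MotifEnrichmentResult(
                motif_id=mid,
                rank_sum_p=p,
                bonferroni_p=bp,
                n_tests=n_tests,
                enriched=bool(bp < threshold),
                direction_class=direction_class,
                median_fg_score=float(np.median(fg_scores[mid])),
                median_bg_score=float(np.median(bg_scores[mid])),
                tf_names=list(tf_map.get(mid, [])) if tf_map else [],
            )
        )
    return out


def score_sequences(
    sequences: dict[str, str],
    pwms: list[PWM],
    background=UNIFORM_BACKGROUND,
    pseudocount_total: float = 0.25,
) -> dict[str, np.ndarray]:
    """Best-site score of every motif in every sequence (motif -> vector).

    Equal-length sequences are scored in one vectorized pass per motif;
    mixed lengths fall back to per-sequence scoring.
    """
    encoded = [encode_sequence(s) for s in sequences.values()]
    lengths = {len(c) for c in encoded}
    if len(lengths) != 1:
        return {
            pwm.motif_id: np.array(
                [best_site_score(c, pwm, background, pseudocount_total) for c in encoded]
            )
            for pwm in pwms
        }
    codes = np.vstack(encoded)
    comp = np.array([_COMPLEMENT[int(c)] for c in range(5)], dtype=np.int8)
    codes_rc = comp[codes][:, ::-1]
    out: dict[str, np.ndarray] = {}
    for pwm in pwms:
        w = pwm.length
        if codes.shape[1] < w:
            raise ValueError("sequence shorter than motif")
        lo = _log_odds(pwm, background, pseudocount_total)
        best = np.full(codes.shape[0], -np.inf)
        for strand_codes in (codes, codes_rc):
            windows = np.lib.stride_tricks.sliding_window_view(strand_codes, w, axis=1)
            scores = lo[np.arange(w)[None, None, :], windows].sum(axis=2)
            best = np.maximum(best, scores.max(axis=1))
        out[pwm.motif_id] = best
    return out


def map_motifs_to_tfs(
    enriched_by_class: dict[str, list[MotifEnrichmentResult]],
    motif_to_tf: dict[str, list[str]],
) -> dict[str, set[str]]:
    """TF sets per direction class plus their Venn partition.

    Returns keys "<class>" (union of mapped TFs over enriched motifs) and
    the partition keys "exclusive_<class>" and "shared". Motifs without a
    mapping are logged and skipped.
    """
    tf_sets: dict[str, set[str]] = {}
    for klass, results in enriched_by_class.items():
        tfs: set[str] = set()
        for r in results:
            if not r.enriched:
                continue
            mapped = motif_to_tf.get(r.motif_id)
            if not mapped:
                logger.warning("motif %s has no TF mapping; skipped", r.motif_id)
                continue
            tfs.update(mapped)
        tf_sets[klass] = tfs
    classes = list(tf_sets)
    if len(classes) == 2:
        a, b = classes
        tf_sets["shared"] = tf_sets[a] & tf_sets[b]
        tf_sets[f"exclusive_{a}"] = tf_sets[a] - tf_sets[b]
        tf_sets[f"exclusive_{b}"] = tf_sets[b] - tf_sets[a]
    return tf_sets


# --- I/O ---------------------------------------------------------------------


def write_meme(pwms: list[PWM], path: str | Path, background=UNIFORM_BACKGROUND) -> None:
    """Write motifs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            f"A {background[0]:.5f} C {background[1]:.5f} G {background[2]:.5f} T {background[3]:.5f}\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[PWM]:
    """Parse MEME minimal format (strict: raises on malformed matrices)."""
    pwms: list[PWM] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"MOTIF line without identifier: {line!r}")
            motif_id = parts[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                if lines[i].strip().startswith("MOTIF"):
                    raise ValueError(f"motif {motif_id} has no probability matrix")
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {motif_id} has no probability matrix")
            header = lines[i].strip()
            tokens = header.replace(":", " ").split()
            w = int(tokens[tokens.index("w=") + 1]) if "w=" in tokens else None
            i += 1
            rows = []
            while i < len(lines):
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                rows.append([float(x) for x in s.split()])
                i += 1
            mat = np.array(rows)
            if w is not None and mat.shape[0] != w:
                raise ValueError(f"motif {motif_id}: expected {w} rows, got {mat.shape[0]}")
            pwms.append(PWM(motif_id, mat))
        else:
            i += 1
    return pwms


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_motif_tf_table(path: str | Path) -> dict[str, list[str]]:
    """TSV with columns motif_id, tf_name (one row per pair)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.motif_id), []).append(str(r.tf_name))
    return out


def results_to_frame(results: list[MotifEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif_id": [r.motif_id for r in results],
            "direction_class": [r.direction_class for r in results],
            "rank_sum_p": [r.rank_sum_p for r in results],
            "bonferroni_p": [r.bonferroni_p for r in results],
            "n_tests": [r.n_tests for r in results],
            "enriched": [r.enriched for r in results],
            "median_fg_score": [r.median_fg_score for r in results],
            "median_bg_score": [r.median_bg_score for r in results],
            "tf_names": [",".join(r.tf_names) for r in results],
        }
    )
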