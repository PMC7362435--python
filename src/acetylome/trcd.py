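"""Tandem regulated chromatin domains (TRCDs).

Adjacent consensus regions whose acetylation changes in the same direction
(|log2FC| above a threshold, optionally significant) form candidate
regulatory domains. Adjacency is scored in two genomic distance classes —
short (5-100 kb) and long (100 kb-1 Mb) between region midpoints — and the
excess of same-direction adjacent pairs is tested against (a) a shuffle
null that permutes the (fold change, significance) tuples over the fixed
region positions, and (b) an upper-tail binomial with the same-direction
probability implied by the marginal direction frequencies. The binomial
form is the headline p-value (a permutation estimate cannot resolve
extreme tails); the empirical permutation p is always co-reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SHORT = "short"
LONG = "long"
OUT_OF_RANGE = "out_of_range"

SHORT_RANGE = (5_000, 100_000)
LONG_RANGE = (100_000, 1_000_000)

UP = "up"
DOWN = "down"


@dataclass
class DirectionalRegion:
    region_id: str
    chrom: str
    start: int
    end: int
    log2fc: float
    significant: bool

    @property
    def direction(self) -> str:
        return UP if self.log2fc > 0 else DOWN

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class AdjacentPair:
    first: DirectionalRegion
    second: DirectionalRegion
    distance: float
    distance_class: str
    same_direction: bool


@dataclass
class TRCDRun:
    chrom: str
    member_ids: list[str]
    direction: str  # "active" (up) or "repressed" (down)
    span: int
    distance_class: str

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass
class TRCDTestResult:
    distance_class: str
    observed_same_direction_pairs: int
    total_pairs: int
    null_expectation: float  # p0 = f_up^2 + f_down^2
    empirical_p: float
    binomial_p: float
    binomial_log10_p: float
    n_shuffles: int
    seed: int | None = None
    null_counts: np.ndarray | None = field(default=None, repr=False)


def classify_distance(
    distance: float,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
) -> str:
    """Short is inclusive [5 kb, 100 kb]; long is (100 kb, 1 Mb]."""
    if short_range[0] <= distance <= short_range[1]:
        return SHORT
    if long_range[0] < distance <= long_range[1]:
        return LONG
    return OUT_OF_RANGE


def select_directional(
    results_frame: pd.DataFrame,
    lfc_threshold: float = 0.4,
    require_significant: bool = True,
    alpha: float = 0.05,
) -> list[DirectionalRegion]:
    """Filter regions eligible for TRCD analysis, sorted by (chrom, start).

    ``results_frame`` must carry region_id, chrom, start, end, log2fc, p_adj.
    Inclusion requires |log2FC| strictly above ``lfc_threshold``; if
    ``require_significant`` the adjusted p must also fall below ``alpha``.
    """
    df = results_frame
    lfc = df["log2fc"].to_numpy(dtype=float)
    keep = np.abs(lfc) > lfc_threshold
    sig = np.asarray(pd.to_numeric(df["p_adj"], errors="coerce") < alpha)
    if require_significant:
        keep &= sig
    out = [
        DirectionalRegion(
            str(r.region_id), str(r.chrom), int(r.start), int(r.end),
            float(r.log2fc), bool(s),
        )
        for r, s, k in zip(df.itertuples(index=False), sig, keep)
        if k
    ]
    out.sort(key=lambda d: (d.chrom, d.start))
    return out


def form_pairs(
    directional: list[DirectionalRegion],
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
    distance_mode: str = "midpoint",
) -> list[AdjacentPair]:
    """Consecutive eligible regions per chromosome, classified by distance.

    ``distance_mode`` is midpoint-to-midpoint by default, or "edge" for the
    gap between the first region's end and the second's start.
    """
    pairs: list[AdjacentPair] = []
    for a, b in zip(directional, directional[1:]):
        if a.chrom != b.chrom:
            continue
        if distance_mode == "midpoint":
            dist = b.midpoint - a.midpoint
        elif distance_mode == "edge":
            dist = max(0, b.start - a.end)
        else:
            raise ValueError(f"unknown distance mode {distance_mode!r}")
        pairs.append(
            AdjacentPair(
                a, b, dist,
                classify_distance(dist, short_range, long_range),
                a.direction == b.direction,
            )
        )
    return pairs


def find_runs(
    directional: list[DirectionalRegion],
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
    distance_mode: str = "midpoint",
) -> dict[str, list[TRCDRun]]:
    """Maximal same-direction runs (>= 2 members) per distance class.

    A run's consecutive gaps must all fall in the class; the same regions
    may form a short-class run and belong to a longer-span run in the long
    class, mirroring separate short/long tallies.
    """
    pairs = form_pairs(directional, short_range, long_range, distance_mode)
    runs: dict[str, list[TRCDRun]] = {SHORT: [], LONG: []}
    for klass in (SHORT, LONG):
        current: list[DirectionalRegion] = []

        def flush() -> None:
            if len(current) >= 2:
                runs[klass].append(
                    TRCDRun(
                        chrom=current[0].chrom,
                        member_ids=[r.region_id for r in current],
                        direction="active" if current[0].direction == UP else "repressed",
                        span=current[-1].end - current[0].start,
                        distance_class=klass,
                    )
                )

        for p in pairs:
            if p.same_direction and p.distance_class == klass:
                if not current:
                    current = [p.first, p.second]
                elif current[-1] is p.first:
                    current.append(p.second)
                else:
                    flush()
                    current = [p.first, p.second]
            else:
                flush()
                current = []
        flush()
        current = []
    return runs


def _pair_counts_arrays(
    chroms: np.ndarray,
    midpoints: np.ndarray,
    eligible: np.ndarray,
    up: np.ndarray,
    short_range: tuple[int, int],
    long_range: tuple[int, int],
) -> dict[str, tuple[int, int]]:
    """Vectorized same-direction/total pair counts per class over
    position-aligned arrays (used by the shuffle null's inner loop)."""
    idx = np.flatnonzero(eligible)
    out = {SHORT: (0, 0), LONG: (0, 0)}
    if idx.size < 2:
        return out
    a, b = idx[:-1], idx[1:]
    same_chrom = chroms[a] == chroms[b]
    dist = midpoints[b] - midpoints[a]
    same_dir = up[a] == up[b]
    for klass, (lo, hi), lo_open in ((SHORT, short_range, False), (LONG, long_range, True)):
        in_class = same_chrom & (dist <= hi) & ((dist > lo) if lo_open else (dist >= lo))
        out[klass] = (int((in_class & same_dir).sum()), int(in_class.sum()))
    return out


def shuffle_null(
    all_regions: pd.DataFrame,
    n_shuffles: int,
    seed: int,
    lfc_threshold: float = 0.4,
    require_significant: bool = True,
    alpha: float = 0.05,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
    return_permutations: bool = False,
) -> dict[str, np.ndarray] | tuple[dict[str, np.ndarray], list[np.ndarray]]:
    """Null distribution of same-direction pair counts per distance class.

    Each shuffle permutes the (log2fc, significance) tuples uniformly over
    the fixed region positions of the *full* region list, then recomputes
    eligibility, adjacent pairs and same-direction counts. Region
    coordinates and the log2FC multiset are untouched by construction;
    ``return_permutations`` additionally returns the permutation index
    arrays so callers can verify this per shuffle.

    ``all_regions`` needs columns chrom, start, end, log2fc, p_adj covering
    every tested region (not only the eligible ones).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    perms: list[np.ndarray] = []
    df = all_regions.sort_values(["chrom", "start"], kind="mergesort")
    chroms = pd.factorize(df["chrom"])[0]
    midpoints = (df["start"].to_numpy(float) + df["end"].to_numpy(float)) / 2
    lfc = df["log2fc"].to_numpy(float)
    sig = (pd.to_numeric(df["p_adj"], errors="coerce") < alpha).to_numpy()

    rng = np.random.default_rng(seed)
    null: dict[str, list[int]] = {SHORT: [], LONG: []}
    n = len(df)
    for _ in range(n_shuffles):
        perm = rng.permutation(n)
        if return_permutations:
            perms.append(perm)
        l_p, s_p = lfc[perm], sig[perm]
        eligible = np.abs(l_p) > lfc_threshold
        if require_significant:
            eligible &= s_p
        counts = _pair_counts_arrays(
            chroms, midpoints, eligible, l_p > 0, short_range, long_range
        )
        for klass in (SHORT, LONG):
            null[klass].append(counts[klass][0])
    out = {k: np.array(v) for k, v in null.items()}
    if return_permutations:
        return out, perms
    return out


def trcd_test(
    pairs: list[AdjacentPair],
    null: dict[str, np.ndarray],
    seed: int | None = None,
) -> dict[str, TRCDTestResult]:
    """Observed vs null same-direction adjacency, per distance class.

    empirical_p = (1 + #{null >= observed}) / (1 + n_shuffles);
    binomial_p is the upper tail of Binomial(total_pairs, p0) with
    p0 = f_up^2 + f_down^2 from the marginal direction frequencies of the
    eligible regions entering pairs.
    """
    if not pairs:
        raise ValueError("no eligible adjacent pairs")
    regions = {p.first.region_id: p.first for p in pairs}
    regions.update({p.second.region_id: p.second for p in pairs})
    dirs = np.array([r.direction == UP for r in regions.values()])
    f_up = dirs.mean()
    p0 = f_up**2 + (1 - f_up) ** 2

    out: dict[str, TRCDTestResult] = {}
    for klass in (SHORT, LONG):
        klass_pairs = [p for p in pairs if p.distance_class == klass]
        total = len(klass_pairs)
        observed = sum(p.same_direction for p in klass_pairs)
        null_counts = null.get(klass, np.array([]))
        n_shuffles = len(null_counts)
        if n_shuffles:
            emp = (1 + int((null_counts >= observed).sum())) / (1 + n_shuffles)
        else:
            emp = np.nan
        if total:
            log_p = stats.binom.logsf(observed - 1, total, p0)
            binom_p = float(np.exp(log_p))
            log10_p = float(log_p / np.log(10))
        else:
            binom_p, log10_p = np.nan, np.nan
        out[klass] = TRCDTestResult(
            distance_class=klass,
            observed_same_direction_pairs=observed,
            total_pairs=total,
            null_expectation=float(p0),
            empirical_p=float(emp),
            binomial_p=binom_p,
            binomial_log10_p=log10_p,
            n_shuffles=n_shuffles,
            seed=seed,
            null_counts=null_counts if n_shuffles else None,
        )
    return out
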