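"""Detect tandem regulated chromatin domains (TRCDs).

Adjacent DARs (|log2FC| > 0.4) that change in the same direction are
scored in two distance classes: short (5-100 kb) and long (100 kb-1 Mb)
midpoint gaps. The excess of same-direction pairs is tested against a
shuffle null (fold changes permuted over fixed positions) and an upper-
tail binomial with p0 from the marginal direction frequencies.
"""

import numpy as np

from acetylome import SimulationConfig
from acetylome.differential import nb_test, results_to_frame
from acetylome.synthetic import simulate_counts, simulate_regions
from acetylome.trcd import find_runs, form_pairs, select_directional, shuffle_null, trcd_test

config = SimulationConfig(
    n_chromosomes=4, chrom_length=80_000_000, n_regions=1500,
    dar_fraction=0.3, direction_persistence=0.85, seed=12,
)
regions, truth = simulate_regions(config)
cm = simulate_counts(regions, truth, config)
results = nb_test(cm.counts, np.array([cm.groups[s] for s in cm.samples]),
                  region_ids=cm.region_ids)
frame = results_to_frame(results)
frame["chrom"] = [r.chrom for r in regions]
frame["start"] = [r.start for r in regions]
frame["end"] = [r.end for r in regions]

directional = select_directional(frame, lfc_threshold=0.4, require_significant=True)
pairs = form_pairs(directional)
runs = find_runs(directional)
null = shuffle_null(frame, n_shuffles=500, seed=1)
tests = trcd_test(pairs, null, seed=1)

print(f"{len(directional)} significant regions with |log2FC| > 0.4")
for klass in ("short", "long"):
    t = tests[klass]
    print(
        f"{klass}: {t.observed_same_direction_pairs}/{t.total_pairs} same-direction "
        f"pairs (null p0 = {t.null_expectation:.3f}); "
        f"binomial p = 10^{t.binomial_log10_p:.1f}, "
        f"empirical p = {t.empirical_p:.4f} ({t.n_shuffles} shuffles); "
        f"{len(runs[klass])} runs (>= 2 members)"
    )
# Direction persistence 0.85 plants the tandem structure; both tests
# reject the no-clustering null decisively while the shuffle preserves
# every coordinate and the fold-change multiset.
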