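import numpy as np
import pytest

from acetylome.regions import GenomicRegion, ReadPlacement


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def random_tagged_regions(rng):
    """Factory: random per-sample peak sets on a small genome."""

    def make(n_samples=3, n_peaks=12, genome=200_000, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        tagged = []
        for s in range(n_samples):
            for _ in range(n_peaks):
                start = int(r.integers(0, genome - 3000))
                length = int(r.integers(200, 3000))
                tagged.append(
                    (GenomicRegion("chr1", start, start + length), f"S{s}")
                )
        return tagged

    return make


@pytest.fixture
def random_reads(rng):
    def make(n=1000, genome=100_000, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return [
            ReadPlacement(
                "chr1",
                int(s),
                int(s) + 75,
                "+" if r.random() < 0.5 else "-",
            )
            for s in r.integers(0, genome - 75, size=n)
        ]

    return make
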