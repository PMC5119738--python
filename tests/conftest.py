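import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_genome():
    from chipspike.model import GenomeLayout

    return GenomeLayout("test", (("chrA", 10_000), ("chrB", 5_000)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tags(rng, genome, n, mapq_range=(0, 60)):
    """Uniform random tag table on a genome (test helper)."""
    import pandas as pd

    names = genome.names
    lengths = genome.lengths
    p = np.array([lengths[c] for c in names], dtype=float)
    p /= p.sum()
    chroms = rng.choice(names, size=n, p=p)
    chrom_len = np.array([lengths[c] for c in chroms])
    start = (rng.random(n) * (chrom_len - 50)).astype(np.int64)
    end = start + 50
    strand = rng.choice(["+", "-"], size=n)
    mapq = rng.integers(mapq_range[0], mapq_range[1] + 1, size=n)
    return pd.DataFrame(
        {"chrom": chroms, "start": start, "end": end, "strand": strand, "mapq": mapq}
    )


@pytest.fixture
def random_tags_factory():
    return random_tags
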