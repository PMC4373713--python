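import numpy as np
import pytest

from popdiff.pd_measures import PopulationSample, SnpDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20150325)


def make_dataset(genotype_counts, snp_id="snp"):
    """SnpDataset from a list of (n_AA, n_Aa, n_aa) triples."""
    samples = [
        PopulationSample(f"POP{i + 1}", sum(gc), tuple(gc))
        for i, gc in enumerate(genotype_counts)
    ]
    return SnpDataset(snp_id, samples)


def random_dataset(rng, s=3, max_n=80, snp_id="snp"):
    """Random polymorphic dataset with s populations."""
    counts = []
    for _ in range(s):
        n = int(rng.integers(5, max_n))
        p = rng.uniform(0.05, 0.95)
        counts.append(tuple(int(c) for c in rng.multinomial(n, [p * p, 2 * p * (1 - p), (1 - p) ** 2])))
    return make_dataset(counts, snp_id)
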