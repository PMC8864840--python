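import numpy as np
import pytest

from occuqc.model import GenomicInterval, TagSet
from occuqc import simulate


@pytest.fixture
def toy_genome():
    return {"chr1": 100_000, "chr2": 80_000}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_tagset(tags, chrom_sizes=None, **kwargs):
    """TagSet from (chrom, pos5, strand, read_length) tuples."""
    if chrom_sizes is None:
        chrom_sizes = {}
        for chrom, pos, _, _ in tags:
            chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), pos + 1)
    return TagSet.from_tags(tags, chrom_sizes, **kwargs)


def random_tags(rng, n, chrom_sizes, read_length=50):
    """Uniform random tag tuples over a genome."""
    chroms = sorted(chrom_sizes)
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(0, chrom_sizes[chrom]))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append((chrom, pos, strand, read_length))
    return out


def random_intervals(rng, n, chrom_sizes, max_width=2_000):
    out = []
    chroms = sorted(chrom_sizes)
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        width = int(rng.integers(1, max_width))
        start = int(rng.integers(0, max(chrom_sizes[chrom] - width, 1)))
        out.append(GenomicInterval(chrom, start, start + width,
                                   name=f"iv{i}"))
    return out


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """One full synthetic QC fixture shared by end-to-end tests."""
    out = tmp_path_factory.mktemp("fixture")
    return simulate.simulate_fixture(out, seed=11)
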