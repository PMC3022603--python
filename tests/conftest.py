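import random

import pytest

from haploweb.io_model import MarkerDataset, SequenceRecord, collapse_haplotypes
from haploweb import clipperton


def make_dataset(genotypes: dict[str, tuple[str, ...]], marker="m", ploidy=2):
    """MarkerDataset straight from a genotype dict (hap ids as given)."""
    universe = tuple(genotypes)
    return MarkerDataset(marker, ploidy, dict(genotypes), universe)


def records_from(seqs: dict[str, str], marker="m") -> list[SequenceRecord]:
    """One haploid record per (id, sequence) pair."""
    return [SequenceRecord(k, k, marker, v) for k, v in seqs.items()]


def random_diploid_dataset(rng: random.Random, n_max=12, haps_max=6):
    """A random diploid dataset over <= n_max individuals and <= haps_max haps."""
    n = rng.randint(1, n_max)
    n_haps = rng.randint(1, haps_max)
    haps = [f"h{i + 1}" for i in range(n_haps)]
    genotypes = {
        f"I{i + 1:02d}": tuple(sorted(rng.choices(haps, k=2))) for i in range(n)
    }
    return make_dataset(genotypes)


@pytest.fixture(scope="session")
def clipperton_partitions():
    return clipperton.marker_partitions()
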