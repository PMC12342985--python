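import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mixploid.io import MISSING, GenotypeMatrix, SampleSheet

settings.register_profile(
    "default", derandomize=True, max_examples=30, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_matrix(dosages, ploidies, chrom="chr1", positions=None, quals=None,
                alts=None):
    """Small GenotypeMatrix from a list-of-lists dosage table (sites x samples)."""
    dosages = np.asarray(dosages, dtype=np.int16)
    n_sites, n_samples = dosages.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": positions,
        "ref": "A",
        "alt": alts if alts is not None else "T",
        "qual": quals if quals is not None else 100.0,
    })
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples, np.asarray(ploidies), sites, dosages)


def sheet_for(gm, population="P"):
    pops = population if isinstance(population, list) \
        else [population] * gm.n_samples
    return SampleSheet(pd.DataFrame({
        "sample": gm.samples, "population": pops, "lineage": pops,
        "ploidy": gm.ploidies, "source": "synthetic"}))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_mixed_matrix():
    # one diploid + one tetraploid, three sites incl. a missing call
    return make_matrix(
        [[1, 3], [0, 2], [MISSING, 4]],
        [2, 4])
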