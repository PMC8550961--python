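import numpy as np
import pandas as pd
import pytest

from paleodrift.panel import CallMatrix, SitePanel
from paleodrift.simulate import star_scenario


def make_sites(n, chrom="1", transversion=True):
    """Site panel with evenly spaced positions; A/C pairs are transversions."""
    pair = ("A", "C") if transversion else ("A", "G")
    return SitePanel(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.arange(1, n + 1) * 10,
                "ancestral": pair[0],
                "derived": pair[1],
            }
        )
    )


def make_calls(data, samples=None):
    data = np.asarray(data, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(data.shape[0])]
    return CallMatrix(data, samples, make_sites(data.shape[1]))


def random_calls(rng, n_samples, n_sites, missing_rate=0.1):
    """Random pseudo-haploid panel with per-sample allele frequencies."""
    freqs = rng.uniform(0.1, 0.9, size=n_sites)
    data = (rng.random((n_samples, n_sites)) < freqs[None, :]).astype(np.int8)
    mask = rng.random((n_samples, n_sites)) < missing_rate
    data[mask] = -1
    return make_calls(data)


@pytest.fixture(scope="session")
def small_star_panel():
    """A quick 3-population star with an outgroup; shared across tests."""
    return star_scenario(n_per_pop=12, n_admixed=12, n_sites=6000, seed=42)
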