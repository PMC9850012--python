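import numpy as np
import pandas as pd
import pytest

from qstfst.genotypes import GenotypeMatrix
from qstfst.simdata import TRAITS, SimConfig


def make_genotypes(calls, labels):
    """GenotypeMatrix from a raw dosage array and per-sample labels."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_l = calls.shape
    samples = [f"s{i}" for i in range(n_s)]
    loci = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, n_l + 1), "ref": "A", "alt": "C"}
    )
    pops = pd.Series(list(labels), index=samples)
    return GenotypeMatrix(samples=np.array(samples, dtype=object), loci=loci,
                         calls=calls, populations=pops)


def flat_config(**kw):
    """A SimConfig with no fixed structure: unit means, no trends or offsets."""
    base = dict(
        cluster_means=tuple([0.0] * kw.get("n_clusters", 6)),
        ontogeny_slopes={t: 0.0 for t in TRAITS},
        trait_means={t: 1.0 for t in TRAITS},
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture
def small_sim_table():
    """A small but structurally complete phenotype table (2 sites, 6 clusters)."""
    cfg = SimConfig(
        families_per_cluster=8,
        offspring_per_family_per_site=4,
        blocks_per_site=(4, 5),
        ring_range=(3, 6),
        seed=5,
    )
    from qstfst.simdata import simulate_phenotypes

    return simulate_phenotypes(cfg)
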