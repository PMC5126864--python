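import numpy as np
import pandas as pd
import pytest

from clinase.simulate import SimulationConfig, simulate_ase_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """12 genes, 4 genotypes x 4 populations, all replicated (fast fits)."""
    cfg = SimulationConfig(n_genes=12, genotypes_per_population=4,
                           replicated_genotypes_per_population=4,
                           depth_mean=80, seed=42)
    counts, meta, truth = simulate_ase_dataset(cfg)
    return counts, meta, truth


def make_gene_frame(wild, ref, genotypes, **extra):
    """Minimal per-gene count frame for hand-built examples."""
    n = len(wild)
    base = {"gene": ["g"] * n,
            "sample": [f"s{i}" for i in range(n)],
            "genotype": list(genotypes),
            "replicate": ["r1"] * n,
            "population": ["US_temperate"] * n,
            "continent": ["US"] * n,
            "latitude": ["temperate"] * n,
            "wild_count": list(wild), "ref_count": list(ref)}
    base.update(extra)
    return pd.DataFrame(base)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
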