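import numpy as np
import pandas as pd
import pytest

from gendiv import Individual, SnvTable, specify_population
from gendiv import synth


def make_genotype_table(genotypes, chrom="chr1", positions=None, names=None):
    """Small gd_genotype table from a (n_snvs, n_inds) genotype array."""
    g = np.asarray(genotypes, dtype=np.int64)
    n, k = g.shape
    names = names or [f"ind{i + 1}" for i in range(k)]
    positions = positions if positions is not None else np.arange(1, n + 1) * 100
    rng = np.random.default_rng(0)
    ref = np.array(list("ACGT"))[rng.integers(0, 4, n)]
    var = np.array(list("ACGT"))[(rng.integers(0, 4, n) + 1) % 4]
    var = np.where(var == ref, np.char.replace(var, var[0], "A" if ref[0] != "A" else "C"), var)
    # guarantee ref != var
    var = np.array([v if v != r else ("A" if r != "A" else "C") for r, v in zip(ref, var)])
    data = {
        "chrom": [chrom] * n,
        "pos": np.asarray(positions, dtype=np.int64),
        "ref": ref,
        "var": var,
        "qual": np.full(n, -1.0),
    }
    inds = []
    for i, name in enumerate(names):
        data[f"{name}:gt"] = g[:, i]
        inds.append(Individual(name, 6 + i))
    t = SnvTable(pd.DataFrame(data), inds, mode="gd_genotype")
    t.validate()
    return t


@pytest.fixture
def two_pop_table():
    """Deterministic 2-population panel (10 diploids each) with truth freqs."""
    cfg = synth.SimConfig(n_pops=2, n_individuals=10, n_snvs=200, fst=0.2, seed=42)
    table, freqs = synth.simulate_populations(cfg)
    p1 = specify_population(table, [f"pop1_{i}" for i in range(1, 11)], "P1")
    p2 = specify_population(table, [f"pop2_{i}" for i in range(1, 11)], "P2")
    return table, p1, p2, freqs


@pytest.fixture
def chicken_toy():
    return synth.pooled_chicken_toy()
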