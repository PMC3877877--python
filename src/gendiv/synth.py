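"""Synthetic SNV data with known truth, for testing every analysis at desk
scale.

Populations are simulated under a Balding-Nichols drift model: each SNV
draws an ancestral reference-allele frequency from Uniform(0.05, 0.95), each
population draws its own frequency from a Beta distribution with that mean
and variance scaled by a drift parameter F (F = 0 means identical
frequencies, larger F means stronger differentiation), and diploid
genotypes are Binomial(2, p).  Admixed individuals are built from
exponential-length ancestry tracts with recorded truth; pooled read counts
are Poisson-depth draws with a symmetric per-read error rate.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admixture import AncestryState, ancestry_states
from .formats import FIXED_COLUMNS, Individual, SnvTable

__all__ = [
    "SimConfig",
    "TruthTract",
    "simulate_populations",
    "simulate_admixed",
    "simulate_read_counts",
    "attach_read_counts",
    "genotype_table",
    "pooled_chicken_toy",
]

_NUC = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study design for a simulated multi-population SNV panel."""

    n_pops: int = 2
    n_individuals: int = 10  # per population
    n_snvs: int = 1000
    n_chroms: int = 2
    chrom_length: int = 10_000_000  # bp
    fst: float | tuple[float, ...] = 0.1  # Balding-Nichols drift per pop
    depth_mean: float = 20.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pops, self.n_individuals, self.n_snvs, self.n_chroms) < 1:
            raise ValueError("all counts must be >= 1")
        for f in self.drift():
            if not 0 <= f < 1:
                raise ValueError("drift F must lie in [0, 1)")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must lie in [0, 0.5)")

    def drift(self) -> tuple[float, ...]:
        f = self.fst
        return tuple(f for _ in range(self.n_pops)) if np.isscalar(f) else tuple(f)


@dataclass(frozen=True)
class TruthTract:
    chrom: str
    start: int
    end: int
    state: AncestryState


def _positions(rng, n_snvs, n_chroms, chrom_length):
    """Sorted unique positions, SNVs spread evenly over chromosomes."""
    per = np.full(n_chroms, n_snvs // n_chroms)
    per[: n_snvs % n_chroms] += 1
    chroms, pos = [], []
    for c in range(n_chroms):
        p = np.sort(rng.choice(np.arange(1, chrom_length + 1), size=per[c], replace=False))
        chroms.extend([f"chr{c + 1}"] * per[c])
        pos.extend(p.tolist())
    return np.array(chroms), np.array(pos, dtype=np.int64)


def _alleles(rng, n):
    ref = rng.integers(0, 4, size=n)
    var = (ref + rng.integers(1, 4, size=n)) % 4
    return _NUC[ref], _NUC[var]


def genotype_table(
    chroms, pos, ref, var, genotypes: np.ndarray, names: list[str]
) -> SnvTable:
    """Assemble a gd_genotype table from arrays (genotypes: snvs x inds)."""
    data = {
        "chrom": chroms,
        "pos": pos,
        "ref": ref,
        "var": var,
        "qual": np.full(len(pos), -1.0),
    }
    inds = []
    for k, name in enumerate(names):
        data[f"{name}:gt"] = genotypes[:, k].astype(np.int64)
        inds.append(Individual(name, 6 + k))
    t = SnvTable(pd.DataFrame(data), inds, mode="gd_genotype")
    t.validate()
    return t


def simulate_populations(cfg: SimConfig) -> tuple[SnvTable, np.ndarray]:
    """Simulate a multi-population gd_genotype panel.

    Returns the table (individuals named ``pop{i}_{j}``) and the true
    per-population reference-allele frequencies, shape (n_snvs, n_pops).
    """
    rng = np.random.default_rng(cfg.seed)
    chroms, pos = _positions(rng, cfg.n_snvs, cfg.n_chroms, cfg.chrom_length)
    ref, var = _alleles(rng, cfg.n_snvs)
    anc = rng.uniform(0.05, 0.95, size=cfg.n_snvs)
    freqs = np.empty((cfg.n_snvs, cfg.n_pops))
    for k, F in enumerate(cfg.drift()):
        if F == 0:
            freqs[:, k] = anc
        else:
            a = anc * (1 - F) / F
            b = (1 - anc) * (1 - F) / F
            freqs[:, k] = rng.beta(a, b)
    names, cols = [], []
    for k in range(cfg.n_pops):
        p = freqs[:, k]
        g = rng.binomial(2, p[:, None], size=(cfg.n_snvs, cfg.n_individuals))
        cols.append(g)
        names.extend(f"pop{k + 1}_{j + 1}" for j in range(cfg.n_individuals))
    genotypes = np.concatenate(cols, axis=1)
    return genotype_table(chroms, pos, ref, var, genotypes, names), freqs


def simulate_admixed(
    chroms: np.ndarray,
    positions: np.ndarray,
    source_freqs: np.ndarray,
    mix: tuple[float, ...],
    mean_tract_length: float,
    seed: int,
) -> tuple[np.ndarray, list[TruthTract]]:
    """One admixed diploid with known ancestry tracts.

    Each chromosome copy is tiled with exponential-length tracts whose
    source is drawn from ``mix``; alleles are Bernoulli draws from the
    tract source's reference-allele frequency.  The diploid genotype is the
    sum of the two copies; truth tracts record the unordered source pair,
    with adjacent equal-state tracts merged.
    """
    mix = np.asarray(mix, dtype=float)
    if abs(mix.sum() - 1) > 1e-9:
        raise ValueError("mix proportions must sum to 1")
    rng = np.random.default_rng(seed)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    n = len(positions)
    genotype = np.zeros(n, dtype=np.int64)
    copy_src = np.zeros((n, 2), dtype=np.int64)
    seen: list = []
    for c in chroms:
        if c not in seen:
            seen.append(c)
    tracts: list[TruthTract] = []
    for c in seen:
        m = chroms == c
        pos = positions[m]
        lo, hi = int(pos[0]), int(pos[-1])
        # exponential-length tracts for each chromosome copy
        copy_edges, copy_srcs = [], []
        for copy in (0, 1):
            x = lo
            edges, srcs = [lo], []
            while x <= hi:
                srcs.append(int(rng.choice(len(mix), p=mix)))
                x += max(1, int(rng.exponential(mean_tract_length)))
                edges.append(min(x, hi + 1))
            copy_edges.append(np.array(edges))
            copy_srcs.append(np.array(srcs))

        def src_of(copy: int, x) -> np.ndarray:
            i = np.searchsorted(copy_edges[copy], x, side="right") - 1
            i = np.minimum(i, len(copy_srcs[copy]) - 1)
            return copy_srcs[copy][i]

        per_copy_src = np.stack([src_of(0, pos), src_of(1, pos)], axis=1)
        copy_src[m] = per_copy_src
        # alleles per copy, drawn from each tract's source frequency
        p = source_freqs[m]
        g = np.zeros(m.sum(), dtype=np.int64)
        for copy in (0, 1):
            pc = p[np.arange(m.sum()), per_copy_src[:, copy]]
            g += rng.random(m.sum()) < pc
        genotype[m] = g
        # truth tracts at the union of the two copies' breakpoints
        cuts = np.unique(np.concatenate(copy_edges))
        cuts = cuts[(cuts >= lo) & (cuts <= hi + 1)]
        prev_state = None
        seg_start = lo
        for a in cuts[:-1]:
            pair = tuple(sorted((int(src_of(0, a)), int(src_of(1, a)))))
            state = AncestryState(pair)
            if prev_state is None:
                prev_state, seg_start = state, int(a)
            elif state != prev_state:
                tracts.append(TruthTract(str(c), seg_start, int(a) - 1, prev_state))
                prev_state, seg_start = state, int(a)
        if prev_state is not None:
            tracts.append(TruthTract(str(c), seg_start, hi, prev_state))
    return genotype, tracts


def simulate_read_counts(
    genotypes: np.ndarray, depth_mean: float, error_rate: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-style read counts per genotype.

    Depth ~ Poisson(depth_mean); each read reports the reference allele
    with probability (g/2)(1-e) + (1-g/2)e.  Uncalled genotypes get (-1,-1).
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(seed)
    g = np.asarray(genotypes)
    depth = rng.poisson(depth_mean, size=g.shape)
    p_ref = (g / 2.0) * (1 - error_rate) + (1 - g / 2.0) * error_rate
    rr = rng.binomial(depth, np.clip(p_ref, 0, 1))
    vr = depth - rr
    rr = np.where(g >= 0, rr, -1)
    vr = np.where(g >= 0, vr, -1)
    return rr, vr


def attach_read_counts(
    table: SnvTable, depth_mean: float, error_rate: float, seed: int
) -> SnvTable:
    """Upgrade a gd_genotype table to gd_snp by simulating read counts."""
    names = [i.name for i in table.individuals]
    gt = table.genotypes(names)
    rr, vr = simulate_read_counts(gt, depth_mean, error_rate, seed)
    data = {c: table.df[c].to_numpy() for c in FIXED_COLUMNS}
    inds = []
    for k, name in enumerate(names):
        data[f"{name}:ref_reads"] = rr[:, k]
        data[f"{name}:var_reads"] = vr[:, k]
        data[f"{name}:gt"] = gt[:, k]
        data[f"{name}:gq"] = np.where(gt[:, k] >= 0, 40.0, -1.0)
        inds.append(Individual(name, 6 + 4 * k))
    df = pd.DataFrame(data)
    for name in table.extra_columns:
        df[name] = table.df[name].to_numpy()
    t = SnvTable(df, inds, mode="gd_snp", extra_columns=list(table.extra_columns))
    t.validate()
    return t


def pooled_chicken_toy() -> SnvTable:
    """Toy pooled-sample table for the homozygosity sweep worked example.

    One chromosome with a run of 10 SNVs fixed for the major allele (pooled
    counts 30 ref / 0 var), 20 maximally heterozygous spacer SNVs (15/15),
    a run of 100 fixed SNVs, and 20 more spacers.  At shift 0.9 the fixed
    runs score 0.1 per SNV, giving interval totals of 1.0 and 10.0.
    """
    blocks = [(10, (30, 0)), (20, (15, 15)), (100, (30, 0)), (20, (15, 15))]
    ref_tot, var_tot = [], []
    for count, (r, v) in blocks:
        ref_tot += [r] * count
        var_tot += [v] * count
    n = len(ref_tot)
    pos = np.arange(1, n + 1) * 1000
    rng = np.random.default_rng(12345)
    ref, var = _alleles(rng, n)
    data = {
        "chrom": np.array(["chr1"] * n),
        "pos": pos,
        "ref": ref,
        "var": var,
        "qual": np.full(n, -1.0),
        "pool:ref_reads": np.array(ref_tot, dtype=np.int64),
        "pool:var_reads": np.array(var_tot, dtype=np.int64),
        "pool:gt": np.full(n, -1, dtype=np.int64),
        "pool:gq": np.full(n, -1.0),
    }
    t = SnvTable(pd.DataFrame(data), [Individual("pool", 6)], mode="gd_snp")
    t.validate()
    return t
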