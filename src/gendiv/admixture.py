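"""Admixture painting over 2-3 source populations by penalized DP.

Each chromosome of a potentially admixed individual is partitioned into
runs of constant *interval genotype*: an unordered pair of source
populations, one per chromosome copy — 3 states for two sources, 6 for
three.  At each ancestry-informative marker (AIM) the probability of the
observed genotype under each state follows from the source reference-allele
frequencies: with both copies from source i (frequency p), P(g=2) = p^2,
P(g=1) = 2p(1-p), P(g=0) = (1-p)^2; with one copy each from sources i and j,
P(g=2) = p_i p_j, P(g=1) = p_i(1-p_j) + p_j(1-p_i), P(g=0) = (1-p_i)(1-p_j).
Log-probabilities are summed along a segment, and a dynamic program picks
the state sequence maximizing total log-probability minus a per-switch
penalty (in nats).  Larger penalties yield fewer, longer runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .formats import Population, SnvTable, sample_uniform
from .stats import per_snp_fst

__all__ = [
    "AncestryState",
    "PaintedSegment",
    "ancestry_states",
    "select_aims",
    "clamp_frequencies",
    "emission_logprob",
    "emission_matrix",
    "paint_chromosome",
    "paint_genome",
    "ancestry_proportions",
]


@dataclass(frozen=True)
class AncestryState:
    """Unordered pair of source-population indices (0-based)."""

    pair: tuple[int, int]

    def __post_init__(self) -> None:
        i, j = self.pair
        if i > j:
            raise ValueError("state pair must be ordered (i <= j)")

    def __str__(self) -> str:  # display as 1-based, e.g. "(1,2)"
        return f"({self.pair[0] + 1},{self.pair[1] + 1})"


def ancestry_states(n_sources: int) -> list[AncestryState]:
    """All interval genotypes: 3 states for 2 sources, 6 for 3."""
    if n_sources not in (2, 3):
        raise ValueError("2 or 3 source populations supported")
    return [
        AncestryState((i, j))
        for i in range(n_sources)
        for j in range(i, n_sources)
    ]


@dataclass(frozen=True)
class PaintedSegment:
    """A run of consecutive AIMs assigned one interval genotype.

    ``start``/``end`` are the positions of the first/last member SNV;
    ``span_start``/``span_end`` extend to the midpoints between the flanking
    SNVs of each switch (used for bp-span accounting).
    """

    chrom: str
    start: int
    end: int
    state: AncestryState
    n_snvs: int
    log_prob: float
    span_start: int
    span_end: int


def select_aims(
    table: SnvTable,
    sources: list[Population],
    min_fst: float = 0.0,
    min_spacing: int | None = None,
    estimator: str = "reich",
    mode: str = "genotype",
) -> SnvTable:
    """Keep ancestry-informative markers: SNVs whose per-SNV F_ST between
    the source populations exceeds ``min_fst`` (for three sources, the max
    over all pairs), optionally thinned to a minimum spacing."""
    if len(sources) not in (2, 3):
        raise ValueError("2 or 3 source populations required")
    names: set[str] = set()
    for s in sources:
        mem = set(s.member_names)
        if names & mem:
            raise ValueError(f"source populations overlap: {sorted(names & mem)}")
        names |= mem
    best = np.full(table.n_snvs, -np.inf)
    for i in range(len(sources)):
        for j in range(i + 1, len(sources)):
            _, res = per_snp_fst(table, sources[i], sources[j], estimator, mode)
            f = np.where(np.isfinite(res.per_snp), res.per_snp, -np.inf)
            best = np.maximum(best, f)
    out = table.subset_rows(best > min_fst)
    if min_spacing is not None and min_spacing > 1:
        out = sample_uniform(out, min_spacing)
    return out


def clamp_frequencies(freqs: np.ndarray, n_alleles: np.ndarray) -> np.ndarray:
    """Clamp source frequencies into [eps, 1-eps] with eps = 1/(2n+2).

    n is the number of source alleles observed at the site; the clamp keeps
    emission log-probabilities finite when a source sample is fixed.
    """
    freqs = np.asarray(freqs, dtype=float)
    eps = 1.0 / (2.0 * np.asarray(n_alleles, dtype=float) + 2.0)
    return np.clip(freqs, eps, 1.0 - eps)


def emission_logprob(genotype: int, state: AncestryState, freqs) -> float:
    """Natural-log probability of a called genotype under one state.

    ``freqs`` gives the (clamped) reference-allele frequency of each source
    population at this SNV.  Uncalled genotypes (-1) are rejected — the
    caller skips those sites.
    """
    if genotype not in (0, 1, 2):
        raise ValueError(f"genotype must be 0/1/2, got {genotype}")
    i, j = state.pair
    p, q = float(freqs[i]), float(freqs[j])
    if genotype == 2:
        prob = p * q
    elif genotype == 0:
        prob = (1.0 - p) * (1.0 - q)
    else:
        prob = p * (1.0 - q) + q * (1.0 - p)
    return math.log(prob)


def emission_matrix(
    genotypes: np.ndarray, freqs: np.ndarray, states: list[AncestryState]
) -> np.ndarray:
    """Log-emission matrix, shape (n_snvs, n_states); vectorised form of
    :func:`emission_logprob` (genotypes must all be called)."""
    g = np.asarray(genotypes)[:, None]
    p = np.stack([freqs[:, s.pair[0]] for s in states], axis=1)
    q = np.stack([freqs[:, s.pair[1]] for s in states], axis=1)
    prob = np.where(
        g == 2, p * q, np.where(g == 0, (1 - p) * (1 - q), p * (1 - q) + q * (1 - p))
    )
    return np.log(prob)


def paint_chromosome(
    genotypes: np.ndarray,
    positions: np.ndarray,
    freqs: np.ndarray,
    switch_penalty: float,
    chrom: str = "chr",
    n_sources: int | None = None,
) -> list[PaintedSegment]:
    """Optimal ancestry painting of one chromosome.

    Maximizes sum of emission log-probabilities minus
    ``switch_penalty`` x (number of state switches) over all state
    sequences, by DP over (SNV, state) with backtracking.  Ties prefer
    staying in the previous state, then the lowest state index.  Genotypes
    of -1 are skipped (no emission, no switch opportunity).
    """
    if switch_penalty < 0:
        raise ValueError("switch_penalty must be >= 0")
    genotypes = np.asarray(genotypes)
    positions = np.asarray(positions)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 2:
        raise ValueError("freqs must be (n_snvs, n_sources)")
    k = n_sources or freqs.shape[1]
    states = ancestry_states(k)
    usable = genotypes >= 0
    if not usable.any():
        raise ValueError("no usable SNVs (all genotypes uncalled)")
    g = genotypes[usable]
    pos = positions[usable]
    emis = emission_matrix(g, freqs[usable], states)
    n, S = emis.shape

    # dp[t, s]: best score of paths ending in state s at SNV t
    dp = np.empty((n, S))
    back = np.zeros((n, S), dtype=np.int64)
    dp[0] = emis[0]
    back[0] = np.arange(S)
    for t in range(1, n):
        prev = dp[t - 1]
        best_prev = int(np.argmax(prev))  # lowest index on ties (np.argmax)
        for s in range(S):
            stay = prev[s]
            move = prev[best_prev] - switch_penalty
            # prefer no-switch on ties
            if stay >= move or best_prev == s:
                dp[t, s] = emis[t, s] + stay
                back[t, s] = s
            else:
                dp[t, s] = emis[t, s] + move
                back[t, s] = best_prev
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(dp[-1]))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]

    return _segments_from_path(path, pos, emis, states, chrom)


def _segments_from_path(path, pos, emis, states, chrom) -> list[PaintedSegment]:
    segs: list[PaintedSegment] = []
    runs: list[tuple[int, int]] = []  # (first, last) indices of constant runs
    start = 0
    for t in range(1, len(path)):
        if path[t] != path[t - 1]:
            runs.append((start, t - 1))
            start = t
    runs.append((start, len(path) - 1))
    for r, (a, b) in enumerate(runs):
        # bp span: midpoints between flanking SNVs of each switch
        span_start = int(pos[a]) if r == 0 else (int(pos[a - 1]) + int(pos[a])) // 2 + 1
        span_end = (
            int(pos[b]) if r == len(runs) - 1 else (int(pos[b]) + int(pos[b + 1])) // 2
        )
        segs.append(
            PaintedSegment(
                chrom=chrom,
                start=int(pos[a]),
                end=int(pos[b]),
                state=states[int(path[a])],
                n_snvs=b - a + 1,
                log_prob=float(emis[a : b + 1, int(path[a])].sum()),
                span_start=span_start,
                span_end=span_end,
            )
        )
    return segs


def paint_genome(
    table: SnvTable,
    individual: str,
    source_freqs: np.ndarray,
    switch_penalty: float,
) -> list[PaintedSegment]:
    """Paint every chromosome of one individual in an AIM table.

    ``source_freqs`` is (n_snvs, n_sources) of clamped reference-allele
    frequencies aligned with the table rows.  Chromosomes are painted
    independently.
    """
    gt = table.genotypes([individual])[:, 0]
    chroms = table.df["chrom"].to_numpy()
    pos = table.df["pos"].to_numpy()
    segs: list[PaintedSegment] = []
    seen: list = []
    for c in chroms:
        if c not in seen:
            seen.append(c)
    for c in seen:
        m = chroms == c
        if (gt[m] >= 0).any():
            segs.extend(
                paint_chromosome(gt[m], pos[m], source_freqs[m], switch_penalty, str(c))
            )
    return segs


def ancestry_proportions(
    segments: list[PaintedSegment], n_sources: int, weight: str = "bp"
) -> np.ndarray:
    """Per-source ancestry fractions from a painted genome.

    Each segment contributes its bp span (``weight="bp"``, using the
    midpoint spans) or its SNV count (``weight="snv"``); state (i,i) credits
    everything to source i, state (i,j) half to each.  Fractions sum to 1.
    """
    if not segments:
        raise ValueError("empty painting")
    w = np.zeros(n_sources)
    for seg in segments:
        size = (
            seg.span_end - seg.span_start + 1 if weight == "bp" else seg.n_snvs
        )
        i, j = seg.state.pair
        w[i] += size / 2.0
        w[j] += size / 2.0
    return w / w.sum()
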