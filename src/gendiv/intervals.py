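"""Window-free detection of high-scoring SNV runs ("remarkable intervals").

A per-SNV score column (homozygosity, F_ST, LSBL, ...) is shifted by a
user-chosen constant and the all-maximal-scoring-subsequence algorithm of
Ruzzo & Tompa is run on the shifted scores, per chromosome.  Each reported
interval is a contiguous run of SNVs whose summed shifted score cannot be
increased by adding or subtracting SNVs at its ends; intervals are disjoint
and have positive score.  Raising the shift yields fewer, shorter intervals.

Significance is assessed by shuffling the shifted scores, recording the best
interval score of each shuffle, and taking the highest observed score as an
empirical cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import SnvTable

__all__ = [
    "ScoredInterval",
    "SignificanceResult",
    "maximal_segments",
    "max_scoring_segments",
    "remarkable_intervals",
    "percentile_shift",
    "shuffle_significance",
    "intersect_genes",
]


@dataclass(frozen=True)
class ScoredInterval:
    """A maximal run of SNVs: 1-based positions of its first and last SNV."""

    chrom: str
    start: int
    end: int
    score: float
    n_snvs: int
    rank: int = 0
    first_index: int = -1  # row index of the first member SNV
    last_index: int = -1


@dataclass(frozen=True)
class SignificanceResult:
    cutoff: float
    n_shuffles: int
    seed: int
    best_scores: np.ndarray  # best interval score per shuffle (0 if none)

    def empirical_p(self, observed: float) -> float:
        """(1 + #{shuffles with best >= observed}) / (n_shuffles + 1)."""
        c = int((self.best_scores >= observed).sum())
        return (1 + c) / (self.n_shuffles + 1)


def maximal_segments(scores: np.ndarray) -> list[tuple[int, int, float]]:
    """All maximal-scoring subsequences of ``scores`` (Ruzzo-Tompa).

    Returns (start, end, score) with end inclusive, in left-to-right order.
    Linear time: a list of candidate segments is maintained with their
    cumulative sums L (before the segment) and R (through its end); each new
    positive score either merges a suffix of the list or starts a segment.
    """
    segs: list[list] = []  # [start, end, L, R]
    cum = 0.0
    for k, s in enumerate(np.asarray(scores, dtype=float)):
        if s > 0:
            cur = [k, k, cum, cum + s]
            while True:
                # rightmost candidate j with L_j < L_cur
                j = len(segs) - 1
                while j >= 0 and segs[j][2] >= cur[2]:
                    j -= 1
                if j < 0:
                    segs.append(cur)
                    break
                if segs[j][3] >= cur[3]:
                    segs.append(cur)
                    break
                # merge segments j..end into cur and re-test
                cur = [segs[j][0], cur[1], segs[j][2], cur[3]]
                del segs[j:]
        cum += s
    return [(a, b, R - L) for a, b, L, R in segs]


def max_scoring_segments(
    chroms: np.ndarray,
    positions: np.ndarray,
    scores: np.ndarray,
    shift: float,
) -> list[ScoredInterval]:
    """Maximal intervals of shifted scores, per chromosome, ranked by score.

    ``scores - shift`` is segmented per chromosome with
    :func:`maximal_segments`; intervals are ranked by descending score with
    ties broken leftmost (chromosome input order, then start), then shortest.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    shifted = np.asarray(scores, dtype=float) - shift
    out: list[ScoredInterval] = []
    order: dict = {}
    for c in chroms:
        order.setdefault(c, len(order))
    for c in order:
        idx = np.flatnonzero(chroms == c)
        for a, b, sc in maximal_segments(shifted[idx]):
            i, j = int(idx[a]), int(idx[b])
            out.append(
                ScoredInterval(
                    chrom=str(c),
                    start=int(positions[i]),
                    end=int(positions[j]),
                    score=float(sc),
                    n_snvs=j - i + 1,
                    first_index=i,
                    last_index=j,
                )
            )
    out.sort(
        key=lambda iv: (-iv.score, order[iv.chrom], iv.start, iv.end - iv.start)
    )
    return [
        ScoredInterval(
            iv.chrom, iv.start, iv.end, iv.score, iv.n_snvs,
            rank=r + 1, first_index=iv.first_index, last_index=iv.last_index,
        )
        for r, iv in enumerate(out)
    ]


def remarkable_intervals(
    table: SnvTable, score_column: str, shift: float
) -> list[ScoredInterval]:
    """Run the interval finder on a score column of an SNV table."""
    return max_scoring_segments(
        table.df["chrom"].to_numpy(),
        table.df["pos"].to_numpy(),
        table.df[score_column].to_numpy(dtype=float),
        shift,
    )


def percentile_shift(scores, percentile: float) -> float:
    """Shift value at the given percentile of the scores.

    Linear interpolation between order statistics; e.g. percentile 90 gives
    a shift under which at least 90% of shifted scores are <= 0, so SNVs in
    any high-scoring interval lie on average in the top 10%.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    return float(np.percentile(np.asarray(scores, dtype=float), percentile))


def shuffle_significance(
    chroms: np.ndarray,
    positions: np.ndarray,
    scores: np.ndarray,
    shift: float,
    n_shuffles: int,
    seed: int,
    within_chrom: bool = False,
) -> SignificanceResult:
    """Empirical score cutoff from random permutations of the shifted scores.

    Positions stay fixed; scores are permuted uniformly, genome-wide by
    default (``within_chrom=True`` permutes within each chromosome instead).
    Each shuffle's best interval score is recorded; the cutoff is their
    maximum.  Empirical p-values use the +1 correction so p is never 0.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = np.asarray(chroms)
    scores = np.asarray(scores, dtype=float)
    best = np.zeros(n_shuffles)
    for t in range(n_shuffles):
        if within_chrom:
            perm = scores.copy()
            for c in pd.unique(chroms):
                idx = np.flatnonzero(chroms == c)
                perm[idx] = perm[idx][rng.permutation(len(idx))]
        else:
            perm = scores[rng.permutation(len(scores))]
        ivs = max_scoring_segments(chroms, positions, perm, shift)
        best[t] = ivs[0].score if ivs else 0.0
    return SignificanceResult(
        cutoff=float(best.max()), n_shuffles=n_shuffles, seed=seed, best_scores=best
    )


def intersect_genes(
    intervals: list[ScoredInterval], genes: pd.DataFrame
) -> pd.DataFrame:
    """Genes overlapping each interval by >= 1 bp (closed 1-based spans).

    ``genes`` needs columns (gene, chrom, start, end).  Returns one row per
    (interval, gene) overlap, keeping interval rank order.
    """
    need = {"gene", "chrom", "start", "end"}
    if not need.issubset(genes.columns):
        raise ValueError(f"gene table must have columns {sorted(need)}")
    rows = []
    for iv in intervals:
        g = genes[genes["chrom"] == iv.chrom]
        hit = g[(g["start"] <= iv.end) & (g["end"] >= iv.start)]
        for _, r in hit.iterrows():
            rows.append(
                {
                    "rank": iv.rank,
                    "chrom": iv.chrom,
                    "interval_start": iv.start,
                    "interval_end": iv.end,
                    "score": iv.score,
                    "n_snvs": iv.n_snvs,
                    "gene": r["gene"],
                    "gene_start": int(r["start"]),
                    "gene_end": int(r["end"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "chrom", "interval_start", "interval_end",
            "score", "n_snvs", "gene", "gene_start", "gene_end",
        ],
    )
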