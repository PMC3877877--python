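"""Independent brute-force oracles used by the test suite.

Each function here recomputes a quantity by direct enumeration or by a
formula coded straight from its definition, independently of the package's
implementation path.
"""

from itertools import combinations

import numpy as np
from scipy.special import comb


def brute_maximal_segments(scores):
    """All maximal positive-sum runs by recursive max-subarray decomposition.

    O(n^2): find the maximum-sum contiguous run — among ties the shortest,
    then leftmost (so every proper prefix and suffix of the reported run has
    strictly positive sum) — report it if positive, and recurse on the
    flanks.
    """
    scores = np.asarray(scores, dtype=float)

    def rec(lo, hi, out):
        if lo > hi:
            return
        best = None  # (score, length, start, end)
        for i in range(lo, hi + 1):
            s = 0.0
            for j in range(i, hi + 1):
                s += scores[j]
                cand = (s, j - i, i, j)
                if best is None or s > best[0]:
                    best = cand
                elif s == best[0] and (j - i, i) < (best[1], best[2]):
                    best = cand
        s, _, i, j = best
        if s <= 0:
            return
        rec(lo, i - 1, out)
        out.append((i, j, s))
        rec(j + 1, hi, out)

    out = []
    rec(0, len(scores) - 1, out)
    return out


def brute_best_path(emissions, penalty):
    """Best penalised state-path score by exhaustive enumeration.

    emissions: (n, S) log-probabilities.  Score of a path = sum of
    emissions along it minus penalty per state change.  Enumerates all S^n
    paths (vectorised mixed-radix expansion).
    """
    emissions = np.asarray(emissions, dtype=float)
    n, S = emissions.shape
    idx = np.arange(S**n, dtype=np.int64)
    digits = (idx[:, None] // S ** np.arange(n, dtype=np.int64)) % S  # (P, n)
    score = emissions[np.arange(n), digits].sum(axis=1)
    if n > 1:
        score -= penalty * (digits[:, 1:] != digits[:, :-1]).sum(axis=1)
    return float(score.max())


def reich_fst(a1, n1, a2, n2):
    """Reich unbiased F_ST components (N, D) coded from the definition."""
    h1 = a1 * (n1 - a1) / (n1 * (n1 - 1))
    h2 = a2 * (n2 - a2) / (n2 * (n2 - 1))
    N = (a1 / n1 - a2 / n2) ** 2 - h1 / n1 - h2 / n2
    return N, N + h1 + h2


def brute_mean_pairwise_diff(alleles):
    """Mean pairwise difference over all allele pairs at one site."""
    alleles = list(alleles)
    pairs = list(combinations(range(len(alleles)), 2))
    return sum(alleles[i] != alleles[j] for i, j in pairs) / len(pairs)


def fisher_two_tailed(k, K, n, N):
    """Two-tailed Fisher p by exhaustive hypergeometric enumeration.

    Sums P(X = x) over all feasible tables whose probability is <= that of
    the observed table (method of small p-values).  X ~ Hypergeom(N, K, n).
    """
    lo, hi = max(0, n - (N - K)), min(K, n)
    probs = {x: comb(K, x, exact=True) * comb(N - K, n - x, exact=True) for x in range(lo, hi + 1)}
    tot = comb(N, n, exact=True)
    p_obs = probs[k]
    return sum(p for p in probs.values() if p <= p_obs) / tot


def dfs_source_sink_paths(edges, nodes):
    """(count, mean length) of simple source->sink paths via recursive DFS."""
    succ = {u: [] for u in nodes}
    pred = {u: [] for u in nodes}
    for a, b in edges:
        succ[a].append(b)
        pred[b].append(a)
    sources = [u for u in nodes if not pred[u]]
    sinks = {u for u in nodes if not succ[u]}
    count = 0
    total = 0

    def walk(u, seen, length):
        nonlocal count, total
        if u in sinks and length > 0:
            count += 1
            total += length
            return
        for v in succ[u]:
            if v not in seen:
                walk(v, seen | {v}, length + 1)

    for s in sources:
        if s in sinks:
            continue
        walk(s, {s}, 0)
    return count, (total / count if count else None)
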