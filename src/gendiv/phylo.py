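"""Genotype-distance matrices and neighbor-joining trees.

For each pair of individuals, the informative SNVs are those where both
genotypes are called (and, in read mode, both read depths reach a
user-chosen minimum); the distance is the number of genotypic differences
divided by the number of informative sites.  A neighbor-joining tree
(Saitou & Nei) is built from the resulting matrix with a deterministic
lowest-index tie-break; negative branch lengths are clamped to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .formats import SnvTable

log = logging.getLogger(__name__)

__all__ = ["DistanceMatrix", "TreeNode", "pairwise_distances", "neighbor_joining"]


@dataclass
class DistanceMatrix:
    """Symmetric genotype-distance matrix with per-pair informative counts."""

    labels: list[str]
    d: np.ndarray
    informative_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for i, lab in enumerate(self.labels):
            lines.append(lab + "  " + "  ".join(f"{x:.6f}" for x in self.d[i]))
        return "\n".join(lines) + "\n"


@dataclass
class TreeNode:
    """Unrooted tree node; leaves carry labels, edges carry lengths."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(f"{c._newick()}:{ln:.10g}" for c, ln in self.children)
        return f"({inner}){self.name or ''}"

    def leaf_names(self) -> list[str]:
        if not self.children:
            return [self.name] if self.name else []
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaf_names())
        return out


def pairwise_distances(
    table: SnvTable,
    individuals: list[str] | None = None,
    min_depth: int = 0,
    allele_sharing: bool = False,
) -> DistanceMatrix:
    """Genotype distances between individuals.

    Default counts a site as one difference whenever the two called
    genotypes differ; ``allele_sharing=True`` instead scores |g1 - g2| / 2
    per site (a heterozygote vs homozygote difference counts half).
    ``min_depth`` restricts informative sites to those where both
    individuals reach that total read depth (gd_snp mode).
    """
    names = individuals or [i.name for i in table.individuals]
    if len(names) < 2:
        raise ValueError("need >= 2 individuals")
    gt = table.genotypes(names)
    called = gt >= 0
    if min_depth > 0:
        rr, vr = table.read_counts(names)
        deep = (rr >= 0) & (vr >= 0) & (rr + vr >= min_depth)
        called = called & deep
    n = len(names)
    d = np.zeros((n, n))
    info = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no informative sites for pair ({names[i]}, {names[j]})"
                )
            gi, gj = gt[both, i], gt[both, j]
            diff = (
                float(np.abs(gi - gj).sum()) / 2.0
                if allele_sharing
                else float((gi != gj).sum())
            )
            d[i, j] = d[j, i] = diff / m
            info[i, j] = info[j, i] = m
    return DistanceMatrix(list(names), d, info)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair (i, j) minimizing the Q criterion is joined,
    lowest (i, j) index first on ties.  Negative branch lengths are clamped
    to 0 with a warning.  Returns an unrooted tree (trifurcating root).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            log.warning("neighbor_joining: negative branch length %.4g clamped", x)
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                q = (r - 2) * sub[ai, aj] - sums[ai] - sums[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (sums[ai] - sums[aj]) / (2.0 * (r - 2))
        lj = dij - li
        parent = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        # distances from the new node to the remaining taxa
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        k = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[k, :-1] = dnew
        d[:-1, k] = dnew
        d[k, k] = 0.0
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    return TreeNode(
        children=[
            (nodes[i], clamp(li)),
            (nodes[j], clamp(lj)),
            (nodes[k], clamp(lk)),
        ]
    )
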