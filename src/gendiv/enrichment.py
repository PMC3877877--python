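"""Gene-set statistics: Fisher enrichment, pathway disruption, clustering.

Three rankings over an input gene list:

* **fisher_enrichment** — per category (GO term, KEGG pathway, ...), a 2x2
  table of in-list/out-of-list x in-category/out-of-category genes, scored
  with a two-tailed Fisher exact test and ranked by the fraction of the
  category covered, then p.
* **rank_pathways_disruption** — per directed pathway graph, the change in
  the number and mean length of simple paths from sources (no incoming
  edges) to sinks (no outgoing edges) when the nodes carrying input genes
  are deleted.
* **cluster_categories** — single-linkage grouping of categories that share
  at least a threshold fraction of their genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CategoryMap",
    "PathwayGraph",
    "PathCountOverflow",
    "fisher_enrichment",
    "fisher_two_tailed_p",
    "pathway_path_metrics",
    "rank_pathways_disruption",
    "cluster_categories",
    "read_gene_category_map",
    "read_edge_list",
]


@dataclass
class CategoryMap:
    """category id -> gene set, against a background gene universe."""

    categories: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        for cat, genes in self.categories.items():
            extra = genes - self.background
            if extra:
                raise ValueError(
                    f"category {cat!r} has genes outside the background: "
                    f"{sorted(extra)[:5]}"
                )


@dataclass
class PathwayGraph:
    """Directed pathway graph with a node -> gene ids mapping.

    Sources are nodes with no incoming edges, sinks nodes with no outgoing
    edges; both are recomputed after any node removal.
    """

    name: str
    graph: nx.DiGraph
    node_genes: dict[str, set[str]] = field(default_factory=dict)

    @property
    def sources(self) -> list[str]:
        return sorted(n for n, deg in self.graph.in_degree() if deg == 0)

    @property
    def sinks(self) -> list[str]:
        return sorted(n for n, deg in self.graph.out_degree() if deg == 0)

    def nodes_for_genes(self, genes: set[str]) -> list[str]:
        return sorted(n for n, gs in self.node_genes.items() if gs & genes)

    def without_nodes(self, nodes) -> "PathwayGraph":
        g = self.graph.copy()
        g.remove_nodes_from(nodes)
        node_genes = {n: gs for n, gs in self.node_genes.items() if n in g}
        return PathwayGraph(self.name, g, node_genes)


class PathCountOverflow(RuntimeError):
    """Raised when simple-path enumeration exceeds the configured cap."""


def fisher_two_tailed_p(k: int, K: int, n: int, N: int) -> float:
    """Two-tailed Fisher exact p for k input genes in a category.

    The 2x2 table is [[k, n-k], [K-k, N-K-(n-k)]] (input size n, category
    size K, background N); two-tailed = sum of hypergeometric outcomes no
    more probable than the observed one.
    """
    table = [[k, n - k], [K - k, N - K - (n - k)]]
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return float(min(p, 1.0))


def fisher_enrichment(genes: set[str], cmap: CategoryMap) -> pd.DataFrame:
    """Two-tailed Fisher exact enrichment/depletion of a gene list.

    Input genes outside the background are dropped with a warning column in
    the log; per category the table [[k, n-k], [K-k, N-K-(n-k)]] is tested
    (k = input genes in the category, K = background genes in it, n = input
    size, N = background size).  Rows are ranked by the covered fraction
    k/K (descending), then p.
    """
    if not cmap.background:
        raise ValueError("empty background")
    genes = set(genes)
    dropped = genes - cmap.background
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "fisher_enrichment: %d input genes not in background dropped", len(dropped)
        )
    genes &= cmap.background
    n, N = len(genes), len(cmap.background)
    rows = []
    for cat, members in cmap.categories.items():
        K = len(members)
        k = len(genes & members)
        p = fisher_two_tailed_p(k, K, n, N)
        frac = k / K if K else 0.0
        direction = "enriched" if (n > 0 and k / n >= K / N) else "depleted"
        rows.append(
            {
                "category": cat,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fraction": frac,
                "p_two_tailed": float(min(p, 1.0)),
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["fraction", "p_two_tailed", "category"], ascending=[False, True, True]
    ).reset_index(drop=True)


def pathway_path_metrics(
    pw: PathwayGraph, cap: int = 10**6
) -> tuple[int, float | None]:
    """(number, mean length) of simple source->sink paths.

    Length is the edge count; an isolated node (source and sink at once)
    contributes no path.  Enumeration is exhaustive with a hard cap —
    exceeding it raises :class:`PathCountOverflow`, never truncates.
    """
    n_paths = 0
    total_len = 0
    sinks = set(pw.sinks)
    for src in pw.sources:
        targets = sinks - {src}
        if not targets:
            continue
        for path in nx.all_simple_paths(pw.graph, src, targets):
            n_paths += 1
            total_len += len(path) - 1
            if n_paths > cap:
                raise PathCountOverflow(
                    f"pathway {pw.name!r}: more than {cap} source->sink paths"
                )
    return n_paths, (total_len / n_paths if n_paths else None)


def rank_pathways_disruption(
    pathways: list[PathwayGraph], genes: set[str], cap: int = 10**6
) -> pd.DataFrame:
    """Rank pathways by the change in path structure when input genes are cut.

    Per pathway, path metrics are computed with and without the nodes whose
    gene annotation intersects the input list (node deletion; sources and
    sinks are recomputed on the reduced graph).  Delta values are
    before - after; when deletion leaves no path, the after-mean counts
    as 0.  Ranked by |delta mean length| then |delta n paths|, descending.
    """
    rows = []
    for pw in pathways:
        n0, m0 = pathway_path_metrics(pw, cap)
        hit = pw.nodes_for_genes(genes)
        n1, m1 = pathway_path_metrics(pw.without_nodes(hit), cap)
        d_mean = (m0 or 0.0) - (m1 or 0.0)
        rows.append(
            {
                "pathway": pw.name,
                "n_paths_before": n0,
                "n_paths_after": n1,
                "mean_len_before": m0,
                "mean_len_after": m1,
                "delta_n_paths": n0 - n1,
                "delta_mean_len": d_mean,
                "n_nodes_removed": len(hit),
            }
        )
    df = pd.DataFrame(rows)
    df["_am"] = df["delta_mean_len"].abs()
    df["_an"] = df["delta_n_paths"].abs()
    df = df.sort_values(["_am", "_an", "pathway"], ascending=[False, False, True])
    return df.drop(columns=["_am", "_an"]).reset_index(drop=True)


def cluster_categories(
    rows: list[tuple[str, set[str]]], threshold: float
) -> list[list[str]]:
    """Single-linkage clusters of categories sharing genes.

    Two categories link iff |shared genes| / min(|A|, |B|) >= threshold.
    Returns clusters as sorted lists, largest first (ties alphabetical);
    raising the threshold never decreases the number of clusters.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    names = [name for name, _ in rows]
    sets = [set(g) for _, g in rows]
    parent = list(range(len(rows)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            m = min(len(sets[i]), len(sets[j]))
            if m and len(sets[i] & sets[j]) / m >= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, name in enumerate(names):
        groups.setdefault(find(i), []).append(name)
    clusters = [sorted(g) for g in groups.values()]
    clusters.sort(key=lambda c: (-len(c), c))
    return clusters


# ---------------------------------------------------------------------------
# loaders


def read_gene_category_map(path, background: set[str] | None = None) -> CategoryMap:
    """Two-column tab-delimited gene -> category file.

    The background defaults to all genes seen in the file.
    """
    cats: dict[str, set[str]] = {}
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, cat = line.split("\t")[:2]
            cats.setdefault(cat, set()).add(gene)
            seen.add(gene)
    return CategoryMap(cats, background if background is not None else seen)


def read_edge_list(path, name: str | None = None) -> PathwayGraph:
    """Directed pathway from a tab-delimited edge list.

    Lines are ``from<TAB>to``; optional ``#gene<TAB>node<TAB>gene_id`` header
    lines attach gene annotations to nodes.
    """
    g = nx.DiGraph()
    node_genes: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#gene\t"):
                _, node, gene = line.split("\t")[:3]
                node_genes.setdefault(node, set()).add(gene)
                continue
            if line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            g.add_edge(a, b)
    for n in node_genes:
        if n not in g:
            g.add_node(n)
    return PathwayGraph(name or str(path), g, node_genes)
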