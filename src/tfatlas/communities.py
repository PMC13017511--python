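"""TF communities: Leiden partitioning, force-directed layout, enrichment.

The TF-TF association graph is partitioned with the Leiden algorithm under
the (resolution-parametrized) modularity objective; the best of several
seeded restarts by modularity is kept. A Fruchterman-Reingold layout
places the graph for plotting, and a one-sided hypergeometric test scores
each community against user-supplied gene sets (GMT collections), with
significance called at raw P < 0.05 and a Benjamini-Hochberg column
reported alongside.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .assoc import AssociationGraph

__all__ = [
    "Partition",
    "leiden_partition",
    "modularity",
    "fr_layout",
    "community_enrichment",
]


@dataclass
class Partition:
    membership: pd.Series  # node -> community id (0-based)
    resolution: float
    modularity: float
    n_communities: int

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.membership.items():
            out.setdefault(int(c), []).append(node)
        return out


def _to_igraph(graph: AssociationGraph | ig.Graph) -> ig.Graph:
    if isinstance(graph, ig.Graph):
        return graph
    g = ig.Graph()
    g.add_vertices(graph.nodes)
    if len(graph.edges):
        g.add_edges(list(zip(graph.edges["tf_a"], graph.edges["tf_b"])))
        g.es["weight"] = list(graph.edges["partial_corr"])
    return g


def modularity(g: ig.Graph, membership: list[int]) -> float:
    """Standard Newman-Girvan modularity with edge weights (gamma = 1)."""
    if g.ecount() == 0:
        return 0.0
    w = g.es["weight"] if "weight" in g.es.attributes() else None
    return float(g.modularity(membership, weights=w))


def leiden_partition(graph: AssociationGraph | ig.Graph,
                     resolution: float = 0.9, seed: int = 0,
                     n_restarts: int = 10) -> Partition:
    """Leiden partition under the modularity objective at the given
    resolution; best of ``n_restarts`` seeded runs by (standard)
    modularity. Isolated nodes form singleton communities."""
    g = _to_igraph(graph)
    if g.vcount() == 0:
        raise ValueError("graph is empty")
    w = g.es["weight"] if g.ecount() and "weight" in g.es.attributes() else None
    ss = np.random.SeedSequence(seed)
    best_q, best_membership = -np.inf, None
    for child in ss.spawn(n_restarts):
        s = int(child.generate_state(1)[0] % (2**31))
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights=w, resolution_parameter=resolution,
            seed=s, n_iterations=-1)
        q = modularity(g, part.membership)
        if q > best_q:
            best_q, best_membership = q, list(part.membership)
    names = g.vs["name"] if "name" in g.vs.attributes() else list(range(g.vcount()))
    membership = pd.Series(best_membership, index=names, name="community")
    return Partition(membership=membership, resolution=resolution,
                     modularity=best_q,
                     n_communities=len(set(best_membership)))


def fr_layout(graph: AssociationGraph | ig.Graph, seed: int = 0,
              iterations: int = 200) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold coordinates, deterministic given the seed.

    A single node is placed at the origin by convention.
    """
    g = _to_igraph(graph)
    names = g.vs["name"] if "name" in g.vs.attributes() else list(range(g.vcount()))
    if g.vcount() == 1:
        return {names[0]: (0.0, 0.0)}
    random.seed(seed)  # python-igraph draws its randomness from `random`
    w = g.es["weight"] if g.ecount() and "weight" in g.es.attributes() else None
    layout = g.layout_fruchterman_reingold(niter=iterations, weights=w)
    coords = {n: (float(x), float(y)) for n, (x, y) in zip(names, layout.coords)}
    for x, y in coords.values():
        if not (np.isfinite(x) and np.isfinite(y)):
            raise RuntimeError("layout produced non-finite coordinates")
    return coords


def community_enrichment(partition: Partition,
                         gene_sets: dict[str, set[str]],
                         universe: list[str],
                         p_max: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each community in each set.

    P = P(X >= k) for k = |community ∩ set| drawn from a universe of size
    N with K set members, n community members. Significance is called on
    the raw P (< ``p_max``), with BH-adjusted values reported alongside.
    Gene sets disjoint from the universe are skipped with a warning.
    """
    uni = set(universe)
    N = len(uni)
    for comm, members in partition.communities().items():
        extra = set(members) - uni
        if extra:
            raise ValueError(f"community {comm} members outside universe: "
                             f"{sorted(extra)[:5]}")
    rows = []
    for name, genes in gene_sets.items():
        K = len(genes & uni)
        if K == 0:
            warnings.warn(f"gene set {name!r} disjoint from universe; skipped")
            continue
        for comm, members in partition.communities().items():
            n = len(members)
            k = len(set(members) & genes & uni)
            p = float(hypergeom.sf(k - 1, N, K, n))
            rows.append((comm, name, k, n, K, N, p))
    result = pd.DataFrame(rows, columns=["community", "gene_set", "overlap",
                                         "community_size", "set_size",
                                         "universe_size", "p_value"])
    if len(result):
        from statsmodels.stats.multitest import multipletests
        result["p_bh"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result["significant"] = result["p_value"] < p_max
    return result
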