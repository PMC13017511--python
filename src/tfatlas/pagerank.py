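"""Personalized-PageRank TF activity scores.

Each sample's GRN is scored by a personalized PageRank in which the
restart (personalization) vector is the normalized node-weight vector, so
highly expressed genes inject more random-walk mass. Dangling nodes (no
outgoing edges) redistribute their mass to the personalization vector — the
standard personalized variant. TF activity is the steady-state score at the
TF's node; scores over all nodes of a network sum to 1, and TF rows are
extracted without renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .grn import RegulatoryNetwork
from .simulate import AtlasBundle

__all__ = [
    "PageRankMatrix",
    "personalized_pagerank",
    "pagerank_dense_solve",
    "compute_atlas_pagerank",
    "znormalize_rows",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PageRankMatrix:
    """TF x sample activity scores with a row-z-scored companion view."""

    scores: pd.DataFrame
    damping: float
    tol: float
    iterations: dict[str, int] = field(default_factory=dict)

    @property
    def znorm(self) -> pd.DataFrame:
        return znormalize_rows(self.scores)


def _transition(network: RegulatoryNetwork):
    nodes = list(network.node_weight.index)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    src = network.edges["tf"].map(idx).to_numpy()
    dst = network.edges["gene"].map(idx).to_numpy()
    w = network.edges["w"].to_numpy(dtype=float)
    out = np.zeros(n)
    np.add.at(out, src, w)
    dangling = out == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = w / out[src]
    # P[i, j]: probability of stepping i -> j; we iterate with P^T
    P = sp.csr_matrix((p, (src, dst)), shape=(n, n))
    return nodes, P, dangling


def personalized_pagerank(network: RegulatoryNetwork, d: float = 0.85,
                          tol: float = 1e-10, max_iter: int = 1000,
                          ) -> tuple[pd.Series, int]:
    """Fixed point of r = (1-d) e + d (P^T r + dangling_mass * e).

    e is the node-weight vector normalized to sum 1; P row-normalizes
    outgoing edge weights; dangling nodes send their mass to e. Returns the
    score vector over all nodes (sums to 1) and the iteration count.
    """
    if not (0.0 < d < 1.0):
        raise ValueError("damping d must lie in (0, 1)")
    if len(network.node_weight) == 0:
        raise ValueError("network is empty")
    nw = network.node_weight.to_numpy(dtype=float)
    total = nw.sum()
    if total <= 0:
        raise ValueError("all node weights are zero; personalization undefined")
    e = nw / total
    nodes, P, dangling = _transition(network)
    r = e.copy()
    PT = P.T.tocsr()
    for it in range(1, max_iter + 1):
        dang_mass = r[dangling].sum()
        r_new = (1.0 - d) * e + d * (PT @ r + dang_mass * e)
        delta = np.abs(r_new - r).max()
        r = r_new
        if delta < tol:
            return pd.Series(r, index=nodes, name=network.sample), it
    raise ConvergenceError(
        f"PageRank did not converge in {max_iter} iterations "
        f"(residual {delta:.3e})")


def pagerank_dense_solve(network: RegulatoryNetwork, d: float = 0.85,
                         ) -> pd.Series:
    """Direct dense linear-system solution of the same fixed point,
    (I - d M^T) r = (1-d) e with dangling rows of M replaced by e.

    Exact up to linear-algebra round-off; intended as the small-network
    cross-check for the power iteration.
    """
    nw = network.node_weight.to_numpy(dtype=float)
    e = nw / nw.sum()
    nodes, P, dangling = _transition(network)
    M = P.toarray()
    M[dangling, :] = e
    n = len(nodes)
    r = np.linalg.solve(np.eye(n) - d * M.T, (1.0 - d) * e)
    return pd.Series(r, index=nodes, name=network.sample)


def znormalize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row z-scores with population sd; constant rows map to all zeros."""
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population sd
    # a constant row can still yield sd ~ 1e-17 from round-off in the mean;
    # detect constancy by exact range so such rows map to 0, not noise
    constant = np.ptp(x, axis=1, keepdims=True) == 0
    ok = (sd > 0) & ~constant
    out = np.zeros_like(x)
    np.divide(x - mean, sd, out=out, where=ok)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def compute_atlas_pagerank(atlas: AtlasBundle,
                           networks: dict[str, RegulatoryNetwork],
                           d: float = 0.85, tol: float = 1e-10,
                           max_iter: int = 1000) -> PageRankMatrix:
    """Score every sample's network and assemble the TF x sample matrix.

    Columns follow the atlas design order; rows are the atlas TF set.
    """
    missing = [s for s in atlas.samples if s not in networks]
    if missing:
        raise ValueError(f"missing network for sample(s): {missing}")
    tfs = atlas.tfs
    cols = {}
    iters = {}
    for s in atlas.samples:
        r, it = personalized_pagerank(networks[s], d=d, tol=tol,
                                      max_iter=max_iter)
        cols[s] = r.reindex(tfs)
        iters[s] = it
    scores = pd.DataFrame(cols, columns=atlas.samples)
    scores.index.name = "tf"
    return PageRankMatrix(scores=scores, damping=d, tol=tol, iterations=iters)
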