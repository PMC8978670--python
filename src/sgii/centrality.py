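"""Node centrality measures on the full heterogeneous network.

Four normalized measures are computed for every node — degree (DC),
betweenness (BC), closeness (CC) and eigenvector (EC) centrality — on the
complete graph, proteins and dummy lncRNAs included: dummies carry no score
of their own but they shape shortest paths, degrees and the spectrum.

Conventions:

* DC: ``d_i = s_i / (n - 1)``.
* BC: ``b_i = 1/((n-1)(n-2)) * sum over ordered pairs u != i != v of
  sigma_uv(i)/sigma_uv`` — shortest paths are unweighted (hop counts);
  pairs in different components contribute 0. The center of a star scores
  exactly 1 under this normalization.
* CC: the reachable-set-corrected form, valid on disconnected graphs:
  ``c_i = (|R(i)|-1)^2 / ((n-1) * sum of d_ij over j in R(i))`` where R(i)
  is the set of nodes reachable from i. Isolated nodes score 0.
* EC: the i-th entry of the non-negative (Perron) eigenvector of the
  adjacency matrix, L2-normalized, computed by shifted power iteration.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConvergenceError, GraphError
from .network import LPPINetwork

logger = logging.getLogger(__name__)

EIG_TOL = 1e-9
EIG_MAX_ITER = 1000


def degree_centrality(network: LPPINetwork) -> dict[str, float]:
    """d_i = s_i / (n-1) for every node."""
    n = network.n
    if n < 2:
        raise GraphError(f"degree centrality needs n >= 2 nodes, got {n}")
    return {v: d / (n - 1) for v, d in network.graph.degree()}


def betweenness_centrality(network: LPPINetwork) -> dict[str, float]:
    """Normalized shortest-path betweenness over ordered node pairs."""
    n = network.n
    if n < 3:
        raise GraphError(f"betweenness centrality needs n >= 3 nodes, got {n}")
    # networkx's normalized undirected betweenness sums unordered pairs and
    # scales by 2/((n-1)(n-2)); by path-count symmetry this equals the
    # ordered-pair sum scaled by 1/((n-1)(n-2)).
    return nx.betweenness_centrality(network.graph, normalized=True)


def closeness_centrality(network: LPPINetwork) -> dict[str, float]:
    """Reachable-set-corrected closeness (Wasserman-Faust form)."""
    n = network.n
    if n < 2:
        raise GraphError(f"closeness centrality needs n >= 2 nodes, got {n}")
    return nx.closeness_centrality(network.graph, wf_improved=True)


def eigenvector_centrality(
    network: LPPINetwork,
    tol: float = EIG_TOL,
    max_iter: int = EIG_MAX_ITER,
) -> dict[str, float]:
    """Perron eigenvector of the adjacency matrix, L2-normalized.

    Power iteration on the shifted matrix A + I: the shift makes the
    dominant eigenvalue strictly largest in magnitude (plain iteration on A
    oscillates on bipartite graphs, where -lambda_max is also an
    eigenvalue) without changing the eigenvectors. On disconnected graphs
    the vector concentrates on the component with the largest eigenvalue.
    """
    g = network.graph
    if g.number_of_edges() < 1:
        raise GraphError("eigenvector centrality needs at least one edge")
    nodes = list(g.nodes())
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, dtype=float, format="csr")
    n = len(nodes)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = a @ x + x
        norm = np.linalg.norm(y)
        if norm == 0.0:  # cannot happen with >=1 edge and positive start
            raise ConvergenceError("power iteration collapsed to the zero vector")
        y /= norm
        residual = np.linalg.norm(y - x)
        x = y
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"eigenvector power iteration did not converge in {max_iter} "
            f"iterations (residual {residual:.3e}, tol {tol:.1e})"
        )
    x[x < 0] = 0.0  # Perron limit is non-negative; clip rounding noise
    return dict(zip(nodes, x.tolist()))


def compute_centralities(network: LPPINetwork) -> pd.DataFrame:
    """All four measures for every node of the full heterogeneous graph.

    Returns a DataFrame indexed by node id with columns ``kind``, ``degree``
    (raw s_i), ``dc``, ``bc``, ``cc``, ``ec``.
    """
    logger.info("computing centralities on %d nodes / %d edges",
                network.n, network.n_edges)
    dc = degree_centrality(network)
    bc = betweenness_centrality(network)
    cc = closeness_centrality(network)
    ec = eigenvector_centrality(network)
    nodes = list(network.graph.nodes())
    frame = pd.DataFrame(
        {
            "kind": [network.graph.nodes[v]["kind"] for v in nodes],
            "degree": [network.graph.degree[v] for v in nodes],
            "dc": [dc[v] for v in nodes],
            "bc": [bc[v] for v in nodes],
            "cc": [cc[v] for v in nodes],
            "ec": [ec[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return frame
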