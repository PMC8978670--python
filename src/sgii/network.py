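"""Heterogeneous lncRNA-protein-protein interaction (LPPI) network construction.

The network merges two edge lists — lncRNA-protein interactions (NPInter-style
TSV) and protein-protein interactions (BioGRID-style TSV) — by exact protein
name matching into a single undirected, unweighted graph with typed nodes.
Self-interactions are dropped and duplicate edges collapsed. lncRNAs whose
sequence is unavailable or too long for secondary-structure folding are kept
in the graph as *dummy nodes*: they contribute to topology but are excluded
from scoring and ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .errors import ConfigError, GraphError, InputFormatError, NamespaceCollisionError

logger = logging.getLogger(__name__)

#: Node type tags stored in the graph's ``kind`` attribute.
LNCRNA = "lncRNA"
PROTEIN = "protein"

#: Default folding-length cap (nt): sequences at or above this length cannot
#: be folded and the lncRNA becomes a dummy node.
DEFAULT_LENGTH_CAP = 20000


def _read_edge_file(path, what: str) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    try:
        handle = open(path, "rt", encoding="utf-8")
    except OSError as exc:
        raise InputFormatError(f"cannot read {what} edge list {path!s}: {exc}") from exc
    with handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 2:
                raise InputFormatError(
                    f"{path!s}: line {lineno}: expected at least 2 tab-separated "
                    f"fields, got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise InputFormatError(f"{path!s}: line {lineno}: empty identifier")
            pairs.append((a, b))
    return pairs


def read_lpi_edges(path) -> list[tuple[str, str]]:
    """Read a lncRNA-protein edge list (TSV; ``#`` lines are comments).

    Returns ``(lncRNA id, protein id)`` pairs in file order, duplicates
    preserved; extra columns are ignored. Deduplication and self-loop
    removal happen in :func:`merge_networks`.
    """
    return _read_edge_file(path, "lncRNA-protein")


def read_ppi_edges(path) -> list[tuple[str, str]]:
    """Read a protein-protein edge list (TSV; ``#`` lines are comments)."""
    return _read_edge_file(path, "protein-protein")


@dataclass
class LPPINetwork:
    """The merged heterogeneous graph.

    Wraps an undirected :class:`networkx.Graph` whose nodes carry a ``kind``
    attribute (``lncRNA`` or ``protein``) and, for lncRNAs, a ``dummy`` flag
    marking nodes excluded from scoring.
    """

    graph: nx.Graph

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_kind(self, kind: str) -> list[str]:
        return [v for v, k in self.graph.nodes(data="kind") if k == kind]

    @property
    def lncrnas(self) -> list[str]:
        return self.nodes_of_kind(LNCRNA)

    @property
    def proteins(self) -> list[str]:
        return self.nodes_of_kind(PROTEIN)

    @property
    def dummy_lncrnas(self) -> list[str]:
        return [v for v in self.lncrnas if self.graph.nodes[v].get("dummy", False)]

    @property
    def scoreable_lncrnas(self) -> list[str]:
        """lncRNAs that participate in ranking and essentiality calls."""
        return [v for v in self.lncrnas if not self.graph.nodes[v].get("dummy", False)]

    def is_dummy(self, node: str) -> bool:
        return bool(self.graph.nodes[node].get("dummy", False))

    def degree(self, node: str) -> int:
        """Raw degree s_i: number of incident edges of any type."""
        if node not in self.graph:
            raise GraphError(f"unknown node: {node!r}")
        return self.graph.degree[node]

    def edge_lists(self) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
        """Split edges back into (LPI, PPI) pair lists for round-tripping."""
        lpi, ppi = [], []
        kinds = dict(self.graph.nodes(data="kind"))
        for u, v in self.graph.edges():
            if kinds[u] == LNCRNA:
                lpi.append((u, v))
            elif kinds[v] == LNCRNA:
                lpi.append((v, u))
            else:
                ppi.append((u, v))
        return lpi, ppi

    def summary(self) -> dict:
        lpi, ppi = self.edge_lists()
        return {
            "n_nodes": self.n,
            "n_lncrna": len(self.lncrnas),
            "n_protein": len(self.proteins),
            "n_edges": self.n_edges,
            "n_lpi_edges": len(lpi),
            "n_ppi_edges": len(ppi),
            "n_dummy": len(self.dummy_lncrnas),
        }


def merge_networks(
    lpi: Iterable[tuple[str, str]], ppi: Iterable[tuple[str, str]]
) -> LPPINetwork:
    """Merge LPI and PPI pair lists into one heterogeneous network.

    Protein namespaces are unified by exact (case-sensitive) string match.
    Self-interactions are dropped and duplicate edges (either orientation)
    collapsed. An identifier appearing both as a lncRNA and as a protein is
    a namespace collision and raises :class:`NamespaceCollisionError`.
    """
    lpi = list(lpi)
    ppi = list(ppi)
    lnc_ids = {l for l, _ in lpi}
    prot_ids = {p for _, p in lpi}
    prot_ids.update(p for pair in ppi for p in pair)
    clash = lnc_ids & prot_ids
    if clash:
        examples = ", ".join(sorted(clash)[:5])
        raise NamespaceCollisionError(
            f"{len(clash)} identifier(s) appear as both lncRNA and protein: {examples}"
        )

    g = nx.Graph()
    g.add_nodes_from(sorted(lnc_ids), kind=LNCRNA, dummy=False)
    g.add_nodes_from(sorted(prot_ids), kind=PROTEIN)
    g.add_edges_from(lpi)  # lncRNA-protein: self-loops impossible across namespaces
    g.add_edges_from((p, q) for p, q in ppi if p != q)

    net = LPPINetwork(g)
    s = net.summary()
    logger.info(
        "merged LPPI network: %d lncRNAs, %d proteins, %d LPI edges, %d PPI edges",
        s["n_lncrna"], s["n_protein"], s["n_lpi_edges"], s["n_ppi_edges"],
    )
    return net


def mark_overlength(
    network: LPPINetwork,
    sequences: Mapping[str, str],
    cap: int = DEFAULT_LENGTH_CAP,
) -> LPPINetwork:
    """Flag over-length and sequence-less lncRNAs as dummy nodes.

    A lncRNA whose sequence length is >= ``cap`` nt cannot be folded, and a
    lncRNA with no sequence record has no computable sequence score; both
    stay in the graph (they shape topology) but are excluded from the rank
    universe. Returns the same network with flags set.
    """
    if cap <= 0:
        raise ConfigError(f"length cap must be positive, got {cap}")
    n_dummy = 0
    for v in network.lncrnas:
        seq = sequences.get(v)
        dummy = seq is None or len(seq) >= cap
        network.graph.nodes[v]["dummy"] = dummy
        n_dummy += dummy
    logger.info("flagged %d of %d lncRNAs as dummy (cap=%d nt)",
                n_dummy, len(network.lncrnas), cap)
    return network


def node_degree(network: LPPINetwork, node: str) -> int:
    """Raw degree s_i of a node (lncRNA-protein plus protein-protein edges)."""
    return network.degree(node)


def write_edge_tsvs(network: LPPINetwork, lpi_path, ppi_path) -> None:
    """Dump the merged network back to two sorted edge-list TSVs."""
    lpi, ppi = network.edge_lists()
    with open(lpi_path, "wt", encoding="utf-8") as fh:
        fh.write("#lncRNA\tprotein\n")
        for a, b in sorted(lpi):
            fh.write(f"{a}\t{b}\n")
    with open(ppi_path, "wt", encoding="utf-8") as fh:
        fh.write("#protein_a\tprotein_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in ppi):
            fh.write(f"{a}\t{b}\n")
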