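"""Graph representation, edge-list I/O, and summary statistics.

Networks are undirected, unweighted simple graphs held as dense symmetric
0/1 adjacency matrices with a label mapping back to the original node ids.
The statistics mirror the usual benchmark-table columns: node/edge counts,
link density, average degree, average shortest path length, mean inverse
farness ("closeness"), average local clustering, degree assortativity, and
the correlation between common-neighbour counts and local-community links
(LCP correlation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NetworkStats",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "network_stats",
    "lcp_corr",
    "karate_network",
    "synthetic_network",
    "average_degree",
    "link_density",
    "from_networkx",
    "to_networkx",
    "stats_to_tsv",
    "STAT_COLUMNS",
]

STAT_COLUMNS = ("NN", "NE", "LD", "AD", "APL", "C", "CC", "P", "LCP-corr")


class EdgeListParseError(ValueError):
    """Raised for malformed or empty edge-list input."""


@dataclass(frozen=True)
class Network:
    """Undirected simple graph: symmetric binary adjacency plus node labels.

    ``labels[i]`` is the original id of internal node ``i``; internal
    indices are 0-based and dense.
    """

    adjacency: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if len(self.labels) != a.shape[0]:
            raise ValueError("labels must match adjacency dimension")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        object.__setattr__(self, "adjacency", a.astype(np.uint8, copy=False))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges as sorted (i, j) internal-index pairs, i < j."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(ii.tolist(), jj.tolist()))

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def with_adjacency(self, adjacency: np.ndarray) -> "Network":
        """Same node set/labels, different edges."""
        return Network(adjacency=adjacency, labels=self.labels)


@dataclass(frozen=True)
class NetworkStats:
    """Summary statistics; fields undefined for the input are None."""

    nn: int
    ne: int
    ld: float
    ad: float
    apl: float | None
    c: float | None
    cc: float
    p: float | None
    lcp_corr: float | None


def average_degree(nn: int, ne: int) -> float:
    """2·NE/NN."""
    if nn < 1:
        raise ValueError("need at least one node")
    return 2.0 * ne / nn


def link_density(nn: int, ne: int) -> float:
    """2·NE/(NN·(NN−1))."""
    if nn < 2:
        raise ValueError("need at least two nodes")
    return 2.0 * ne / (nn * (nn - 1))


def _parse_line(line: str, lineno: int) -> tuple[str, str]:
    body = line.split("#", 1)[0].strip()
    if not body:
        return ()
    tokens = body.replace(",", " ").split()
    if len(tokens) != 2:
        raise EdgeListParseError(
            f"line {lineno}: expected two node ids, got {len(tokens)}: {line!r}"
        )
    return (tokens[0], tokens[1])


def read_edge_list(source: str | Path | Iterable[str]) -> Network:
    """Parse an undirected edge list into a Network.

    ``source`` may be a file path, a string containing newlines, or an
    iterable of lines. Tokens are whitespace- or comma-delimited; lines
    starting with '#' (or trailing '#' comments) are ignored. Duplicate
    edges and reversed orientations are merged; self-loops are dropped
    with a logged warning.
    """
    if isinstance(source, Path):
        lines = source.read_text().splitlines()
    elif isinstance(source, str):
        p = Path(source)
        if "\n" not in source and p.is_file():
            lines = p.read_text().splitlines()
        else:
            lines = source.splitlines()
    else:
        lines = [str(l) for l in source]

    labels: list = []
    index: dict = {}
    edges: set[tuple[int, int]] = set()
    n_self_loops = 0
    seen_any = False
    for lineno, line in enumerate(lines, start=1):
        parsed = _parse_line(line, lineno)
        if not parsed:
            continue
        seen_any = True
        u, v = parsed
        if u == v:
            n_self_loops += 1
            continue
        for t in (u, v):
            if t not in index:
                index[t] = len(labels)
                labels.append(t)
        i, j = index[u], index[v]
        edges.add((min(i, j), max(i, j)))
    if not seen_any:
        raise EdgeListParseError("empty edge-list input")
    if n_self_loops:
        logger.warning("dropped %d self-loop(s)", n_self_loops)

    n = len(labels)
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return Network(adjacency=a, labels=tuple(labels))


def write_edge_list(net: Network, path: str | Path | None = None) -> str:
    """Render one "u v" line per edge, sorted by internal index pair."""
    lines = [f"{net.labels[i]} {net.labels[j]}" for i, j in net.edges()]
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


def _distance_matrix(net: Network) -> np.ndarray:
    """All-pairs geodesic distances; np.inf for unreachable pairs."""
    return shortest_path(csr_matrix(net.adjacency), method="D", unweighted=True)


def network_stats(net: Network) -> NetworkStats:
    """Summary statistics of a network.

    APL and closeness are averaged over reachable (ordered) pairs only;
    both are None for an edgeless graph. Assortativity is the Pearson
    correlation of endpoint degrees over the 2M ordered edge endpoints
    (None under zero degree variance).
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("network_stats requires at least 2 nodes")
    m = net.n_edges
    ld = link_density(n, m)
    ad = average_degree(n, m)

    apl: float | None = None
    c: float | None = None
    if m > 0:
        d = _distance_matrix(net)
        off = ~np.eye(n, dtype=bool)
        reach = np.isfinite(d) & off
        if reach.any():
            apl = float(d[reach].mean())
            row_sums = np.where(reach, d, 0.0).sum(axis=1)
            has_reach = reach.any(axis=1)
            c = float(np.mean(1.0 / row_sums[has_reach]))

    cc = _average_clustering(net)
    p = _degree_assortativity(net)
    return NetworkStats(
        nn=n, ne=m, ld=ld, ad=ad, apl=apl, c=c, cc=cc, p=p, lcp_corr=lcp_corr(net)
    )


def _average_clustering(net: Network) -> float:
    a = net.adjacency.astype(np.float64)
    deg = net.degrees().astype(np.float64)
    triangles = np.diag(a @ a @ a) / 2.0
    possible = deg * (deg - 1) / 2.0
    local = np.where(possible > 0, triangles / np.where(possible > 0, possible, 1.0), 0.0)
    return float(local.mean())


def _degree_assortativity(net: Network) -> float | None:
    deg = net.degrees().astype(np.float64)
    edges = net.edges()
    if not edges:
        return None
    # ordered endpoint pairs: each undirected edge contributes both ways
    x = np.array([deg[i] for i, j in edges] + [deg[j] for i, j in edges])
    y = np.array([deg[j] for i, j in edges] + [deg[i] for i, j in edges])
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def lcp_corr(net: Network) -> float | None:
    """Pearson correlation of CN vs LCL over linked pairs with CN ≥ 1.

    For each edge (x, y) with at least one common neighbour, CN is the
    common-neighbour count and LCL the number of edges among those common
    neighbours. None when fewer than two qualifying pairs exist or either
    series has zero variance.
    """
    if net.n_nodes < 2:
        raise ValueError("lcp_corr requires at least 2 nodes")
    a = net.adjacency.astype(np.int64)
    cn_matrix = a @ a
    cns: list[int] = []
    lcls: list[int] = []
    for i, j in net.edges():
        cn = int(cn_matrix[i, j])
        if cn < 1:
            continue
        common = np.nonzero((a[i] == 1) & (a[j] == 1))[0]
        lcl = int(a[np.ix_(common, common)].sum()) // 2
        cns.append(cn)
        lcls.append(lcl)
    if len(cns) < 2:
        return None
    x = np.asarray(cns, dtype=np.float64)
    y = np.asarray(lcls, dtype=np.float64)
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def from_networkx(g: "nx.Graph") -> Network:
    """Convert an undirected networkx graph (self-loops dropped)."""
    nodes = list(g.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n), dtype=np.uint8)
    for u, v in g.edges():
        if u == v:
            continue
        a[index[u], index[v]] = a[index[v], index[u]] = 1
    return Network(adjacency=a, labels=tuple(nodes))


def to_networkx(net: Network) -> "nx.Graph":
    g = nx.Graph()
    g.add_nodes_from(net.labels)
    g.add_edges_from((net.labels[i], net.labels[j]) for i, j in net.edges())
    return g


def karate_network() -> Network:
    """The bundled Zachary karate club graph (34 nodes, 78 edges)."""
    text = resources.files("nmflink.data").joinpath("karate.edg").read_text()
    return read_edge_list(text)


def is_connected(net: Network) -> bool:
    n_comp, _ = connected_components(csr_matrix(net.adjacency), directed=False)
    return n_comp == 1


def synthetic_network(model: str, seed: int, **params) -> Network:
    """Seeded synthetic test graphs.

    model="erdos_renyi" takes n, p; model="barabasi_albert" takes n, m.
    """
    if model == "erdos_renyi":
        n, p = int(params["n"]), float(params["p"])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {p}")
        g = nx.gnp_random_graph(n, p, seed=int(seed))
    elif model == "barabasi_albert":
        n, m = int(params["n"]), int(params["m"])
        if not 1 <= m < n:
            raise ValueError(f"need 1 <= m < n, got m={m}, n={n}")
        g = nx.barabasi_albert_graph(n, m, seed=int(seed))
    else:
        raise ValueError(f"unknown model {model!r}")
    return from_networkx(g)


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.4f}"
    return str(v)


def stats_to_tsv(stats: NetworkStats) -> str:
    """Render stats as a two-line TSV with the standard nine columns."""
    values = (
        stats.nn,
        stats.ne,
        stats.ld,
        stats.ad,
        stats.apl,
        stats.c,
        stats.cc,
        stats.p,
        stats.lcp_corr,
    )
    return (
        "\t".join(STAT_COLUMNS) + "\n" + "\t".join(_fmt(v) for v in values) + "\n"
    )
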