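"""Social-network ingestion, distance matrices and d-path Laplacians.

The diffusion machinery in this package works on an undirected, connected,
simple graph of participants.  Influence is organised in *circles*: the set
of nodes at exact shortest-path distance d from a focal node is its d-th
circle of influence (d = 1 being the nearest neighbours).  For each d up to
the network diameter D we build the d-path Laplacian L_d — the Laplacian of
the auxiliary graph whose edges join node pairs at distance exactly d —
which drives the distance-d component of the consensus dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

log = logging.getLogger(__name__)

__all__ = [
    "SocialNetwork",
    "DistanceMatrix",
    "PathLaplacianSet",
    "read_pajek",
    "write_pajek",
    "write_edge_csv",
    "apply_study_modification",
    "generate_constrained_network",
    "distance_matrix",
    "path_laplacian",
    "path_laplacian_set",
]


class PajekParseError(ValueError):
    """Malformed Pajek .net input, with the offending line number."""


@dataclass(frozen=True)
class SocialNetwork:
    """Undirected simple graph of participants with integer node labels.

    ``nodes`` fixes the ordering used by every matrix in the package
    (row/column i corresponds to ``nodes[i]``); for Pajek input this is the
    file's vertex order, so matrix indices map one-to-one onto the 1-based
    labels used in the source data.
    """

    nodes: tuple[int, ...]
    edges: frozenset[frozenset[int]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node identifiers must be unique")
        nodeset = set(self.nodes)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not e <= nodeset:
                raise ValueError(f"edge {set(e)} references unknown node")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node: int) -> int:
        return self.nodes.index(node)

    def has_edge(self, u: int, v: int) -> bool:
        return frozenset((u, v)) in self.edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    @classmethod
    def from_networkx(cls, g: nx.Graph, order: list[int] | None = None) -> "SocialNetwork":
        nodes = tuple(order) if order is not None else tuple(sorted(g.nodes()))
        edges = frozenset(frozenset((u, v)) for u, v in g.edges() if u != v)
        return cls(nodes=nodes, edges=edges)


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path distances, indexed by the network node order."""

    entries: np.ndarray  # (n, n) int array
    nodes: tuple[int, ...]

    @property
    def diameter(self) -> int:
        return int(self.entries.max())

    @property
    def n(self) -> int:
        return len(self.nodes)

    def distance(self, u: int, v: int) -> int:
        i, j = self.nodes.index(u), self.nodes.index(v)
        return int(self.entries[i, j])

    def nodes_at_distance(self, u: int, d: int) -> list[int]:
        i = self.nodes.index(u)
        return [self.nodes[j] for j in np.flatnonzero(self.entries[i] == d)]


@dataclass(frozen=True)
class PathLaplacianSet:
    """The family {L_d : d = 1..D} for one network.

    Each L_d is symmetric positive semidefinite with zero row sums;
    (L_d)_ij = −1 exactly when d(i,j) = d, and the diagonal counts the
    nodes in i's d-th circle.  Summing over all d gives n·I − J (the
    complete-graph Laplacian), since every node pair sits at exactly one
    distance.
    """

    laplacians: dict[int, np.ndarray]
    nodes: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def diameter(self) -> int:
        return max(self.laplacians)

    def __getitem__(self, d: int) -> np.ndarray:
        return self.laplacians[d]


# ---------------------------------------------------------------------------
# Pajek I/O

def read_pajek(path: str | Path) -> SocialNetwork:
    """Read an undirected simple graph from a Pajek .net file.

    Arcs are symmetrized, parallel edges collapsed and self-loops dropped
    (logged).  Vertex labels are preserved as the 1-based integer ids given
    in the file, and the internal node order is the file's vertex order.
    A disconnected graph is accepted with a warning; connectivity is
    enforced later, by the operations that require it.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_idx = next(
        (i for i, ln in enumerate(lines) if ln.strip() and not ln.lstrip().startswith("%")),
        None,
    )
    if header_idx is None or not lines[header_idx].lstrip().lower().startswith("*vertices"):
        lineno = 1 if header_idx is None else header_idx + 1
        raise PajekParseError(
            f"{path}:{lineno}: expected '*Vertices <n>' header, "
            f"got {lines[header_idx]!r}" if header_idx is not None
            else f"{path}:1: empty file, expected '*Vertices <n>' header"
        )

    multi = nx.read_pajek(path)
    order = sorted(multi.nodes(), key=lambda v: int(multi.nodes[v]["id"]))
    relabel = {v: int(multi.nodes[v]["id"]) for v in multi.nodes()}

    edges: set[frozenset[int]] = set()
    for u, v in multi.edges():
        iu, iv = relabel[u], relabel[v]
        if iu == iv:
            log.warning("dropping self-loop on node %d in %s", iu, path)
            continue
        edges.add(frozenset((iu, iv)))

    net = SocialNetwork(nodes=tuple(relabel[v] for v in order), edges=frozenset(edges))
    if net.n > 0 and not net.is_connected():
        log.warning("graph read from %s is disconnected", path)
    return net


def write_pajek(net: SocialNetwork, path: str | Path) -> None:
    """Write the network in Pajek .net format (1-based indices by position)."""
    idx = {v: i + 1 for i, v in enumerate(net.nodes)}
    out = [f"*Vertices {net.n}"]
    out += [f'{idx[v]} "{v}"' for v in net.nodes]
    out.append("*Edges")
    for e in sorted(tuple(sorted(e)) for e in net.edges):
        out.append(f"{idx[e[0]]} {idx[e[1]]}")
    Path(path).write_text("\n".join(out) + "\n")


def write_edge_csv(net: SocialNetwork, path: str | Path) -> None:
    rows = ["source,target"]
    rows += [f"{a},{b}" for a, b in sorted(tuple(sorted(e)) for e in net.edges)]
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Study modification and synthetic networks

def apply_study_modification(net: SocialNetwork) -> SocialNetwork:
    """Rewire the source friendship network as done for the experiment.

    Removes the edge {10, 30} and adds {2, 17}, leaving the edge count
    unchanged.  The swap ensures every node has at least two nodes at
    distance one and two at distance four, the property the display
    protocol of settings I–IV relies on.
    """
    for v in (2, 10, 17, 30):
        if v not in net.nodes:
            raise ValueError(f"network lacks node {v}; cannot apply study modification")
    if not net.has_edge(10, 30):
        raise ValueError("edge {10, 30} is absent; modification already applied or wrong network")
    if net.has_edge(2, 17):
        raise ValueError("edge {2, 17} is already present; wrong network variant")
    edges = set(net.edges)
    edges.discard(frozenset((10, 30)))
    edges.add(frozenset((2, 17)))
    return SocialNetwork(nodes=net.nodes, edges=frozenset(edges))


def _ring_candidate(n: int, k: int, p: float, rng: np.random.Generator) -> nx.Graph:
    # ring lattice + seeded random rewiring: keeps long cycles, hence
    # a spread of shortest-path distances up to ~n/(k) while staying sparse
    g = nx.watts_strogatz_graph(n, k, p, seed=int(rng.integers(2**31)))
    return g


def generate_constrained_network(
    n: int,
    seed: int,
    *,
    min_at_d1: int = 2,
    min_at_d4: int = 2,
    max_attempts: int = 200,
) -> SocialNetwork:
    """Generate a connected simple graph matching the study network's stated
    display-protocol constraints: every node has at least ``min_at_d1`` nodes
    at distance 1 and ``min_at_d4`` at distance 4 (so diameter ≥ 4).

    Deterministic per (n, seed).  Raises if the constraints are not reached
    within ``max_attempts`` candidate graphs.
    """
    if n < 10:
        raise ValueError(f"n={n}: constraints need at least 10 nodes (distance-4 circle of size 2)")
    rng = np.random.default_rng(seed)
    k = 4 if n >= 20 else 2
    for attempt in range(max_attempts):
        p = 0.08 if attempt % 2 == 0 else 0.04
        g = _ring_candidate(n, k, p, rng)
        if not nx.is_connected(g):
            continue
        net = SocialNetwork.from_networkx(g, order=list(range(n)))
        dist = distance_matrix(net)
        if dist.diameter < 4:
            continue
        at1 = (dist.entries == 1).sum(axis=1)
        at4 = (dist.entries == 4).sum(axis=1)
        # the display protocol also needs ≥2 picks in the intermediate circles
        at2 = (dist.entries == 2).sum(axis=1)
        at3 = (dist.entries == 3).sum(axis=1)
        if (
            (at1 >= min_at_d1).all()
            and (at4 >= min_at_d4).all()
            and (at2 >= 2).all()
            and (at3 >= 2).all()
        ):
            return net
    raise RuntimeError(
        f"no graph with ≥{min_at_d1} distance-1 and ≥{min_at_d4} distance-4 "
        f"neighbours per node found in {max_attempts} attempts (n={n}, seed={seed})"
    )


# ---------------------------------------------------------------------------
# Distances and Laplacians

def distance_matrix(net: SocialNetwork) -> DistanceMatrix:
    """All-pairs shortest-path distances (unweighted BFS)."""
    g = net.to_networkx()
    if not nx.is_connected(g):
        raise ValueError("graph is disconnected: some distances are infinite")
    adj = nx.to_scipy_sparse_array(g, nodelist=list(net.nodes), format="csr")
    d = shortest_path(adj, method="D", unweighted=True)
    return DistanceMatrix(entries=d.astype(np.int64), nodes=net.nodes)


def path_laplacian(dist: DistanceMatrix, d: int) -> np.ndarray:
    """The d-path Laplacian L_d: acting on a node function f,
    (L_d f)(v) = Σ_{w : d(v,w)=d} [f(v) − f(w)] (sign convention such that
    L_d is positive semidefinite and u̇ = −L_d u relaxes to consensus).
    """
    if not 1 <= d < dist.n:
        raise ValueError(f"d={d} outside [1, {dist.n - 1}]")
    # d beyond the diameter has no pairs: L_d is the zero matrix
    mask = dist.entries == d
    lap = -mask.astype(float)
    np.fill_diagonal(lap, mask.sum(axis=1))
    return lap


def path_laplacian_set(net_or_dist: SocialNetwork | DistanceMatrix) -> PathLaplacianSet:
    """Build the full family {L_d : d = 1..D} for a connected network."""
    dist = net_or_dist if isinstance(net_or_dist, DistanceMatrix) else distance_matrix(net_or_dist)
    laps = {d: path_laplacian(dist, d) for d in range(1, dist.diameter + 1)}
    return PathLaplacianSet(laplacians=laps, nodes=dist.nodes)
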