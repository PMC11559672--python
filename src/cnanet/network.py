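"""PPI subnetwork construction, centrality computation and HBS labeling.

The interaction source is a multi-channel edge table in the layout of the
STRING protein-links-full file: two node identifiers plus one integer score
per evidence channel on a 0-1000 scale.  Edges are retained when a selected
channel reaches the confidence cutoff (0.4, i.e. 400), the subnetwork
induced on a sample's gene set is simplified (self-loops and duplicate
edges removed) and restricted to its largest connected component, and three
centralities are computed per node:

* degree — number of incident edges;
* betweenness — Brandes shortest-path pair-dependency accumulation over
  unordered node pairs, endpoints excluded, unnormalized;
* eigenvector — principal eigenvector of the adjacency matrix by power
  iteration, scaled so the maximum entry is 1.

A node strictly above the network mean on degree is a *hub*, on betweenness
a *bottleneck*, on eigenvector a *switch*; a node above the mean on all
three is a *hub-bottleneck-switch* (HBS), the pipeline's candidate
regulator class.  The betweenness and eigenvector conventions are pinned
here because library normalizations differ and would move the mean
thresholds.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genome import GeneSet

__all__ = [
    "ALL_CHANNELS",
    "DEFAULT_CHANNELS",
    "InteractionRecord",
    "Network",
    "CentralityTable",
    "HBSLabels",
    "EmptyNetworkError",
    "PowerIterationError",
    "load_interactions",
    "induce_network",
    "compute_centralities",
    "classify_hbs",
    "brandes_betweenness",
    "eigenvector_power_iteration",
]

#: every evidence channel of the protein-links-full layout
ALL_CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurrence",
    "coexpression",
    "coexpression_transferred",
    "experiments",
    "experiments_transferred",
    "database",
    "database_transferred",
    "textmining",
    "textmining_transferred",
)

#: the six channels used by the pipeline by default
DEFAULT_CHANNELS = frozenset(
    {
        "coexpression",
        "coexpression_transferred",
        "database",
        "database_transferred",
        "experiments",
        "experiments_transferred",
    }
)

DEFAULT_MIN_SCORE = 400  # 0.4 on the 0-1000 integer confidence scale


class EmptyNetworkError(ValueError):
    """Raised when a gene set induces no edges at all."""


class PowerIterationError(RuntimeError):
    """Eigenvector power iteration failed to converge."""


@dataclass(frozen=True)
class InteractionRecord:
    """An undirected candidate edge with per-channel integer scores (0-1000)."""

    node_a: str
    node_b: str
    channel_scores: Mapping[str, int]

    def __post_init__(self) -> None:
        for channel, score in self.channel_scores.items():
            if not 0 <= score <= 1000:
                raise ValueError(
                    f"score for channel {channel!r} out of [0, 1000]: {score}"
                )


def load_interactions(
    path: str | Path,
    selected_channels: Iterable[str] = DEFAULT_CHANNELS,
    min_score: int = DEFAULT_MIN_SCORE,
    mode: str = "any",
    aliases: Mapping[str, str] | None = None,
) -> list[InteractionRecord]:
    """Read a whitespace-separated multi-channel edge file and filter by score.

    The header must name ``protein1`` and ``protein2``; channel columns may
    appear in any order and unknown columns are ignored.  With
    ``mode='any'`` (default) an edge is retained iff at least one selected
    channel scores >= ``min_score``; ``mode='all'`` requires every selected
    channel to reach the cutoff.  Unselected channels never qualify an edge
    either way.  ``aliases`` optionally maps file identifiers to gene
    symbols before any downstream matching.
    """
    selected = frozenset(selected_channels)
    unknown = selected - set(ALL_CHANNELS)
    if unknown:
        raise ValueError(
            f"unknown channel(s) {sorted(unknown)}; valid channels: "
            f"{', '.join(ALL_CHANNELS)}"
        )
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")

    path = Path(path)
    records: list[InteractionRecord] = []
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty file, expected a header")
        header = header_line.split()
        for required in ("protein1", "protein2"):
            if required not in header:
                raise ValueError(f"{path}: missing required column {required!r}")
        channel_cols = {c: header.index(c) for c in ALL_CHANNELS if c in header}
        missing_selected = selected - set(channel_cols)
        if missing_selected:
            raise ValueError(
                f"{path}: selected channel(s) absent from header: "
                f"{sorted(missing_selected)}"
            )
        ia, ib = header.index("protein1"), header.index("protein2")

        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            try:
                scores = {c: int(fields[i]) for c, i in channel_cols.items()}
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer channel score"
                ) from None
            passing = [c for c in selected if scores[c] >= min_score]
            if mode == "any" and not passing:
                continue
            if mode == "all" and len(passing) < len(selected):
                continue
            a, b = fields[ia], fields[ib]
            if aliases is not None:
                a, b = aliases.get(a, a), aliases.get(b, b)
            records.append(InteractionRecord(a, b, scores))
    return records


@dataclass(frozen=True)
class Network:
    """Simple undirected graph restricted to its main connected component."""

    sample_id: str
    condition: str
    graph: nx.Graph

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.graph.edges)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def induce_network(
    gene_set: GeneSet | Iterable[str],
    interactions: Sequence[InteractionRecord],
    sample_id: str | None = None,
    condition: str | None = None,
) -> Network:
    """Induce the simplified main-component subnetwork on a gene set.

    Edges with both endpoints in the gene set are kept; self-loops are
    dropped and duplicate/reciprocal records merge into one undirected
    edge.  Only the largest connected component survives (ties broken by
    the component containing the lexicographically smallest symbol), and
    nodes with no retained edge are removed with it.
    """
    if isinstance(gene_set, GeneSet):
        genes = gene_set.genes
        sample_id = sample_id if sample_id is not None else gene_set.sample_id
        condition = condition if condition is not None else gene_set.condition
    else:
        genes = frozenset(gene_set)
    sample_id = sample_id or ""
    condition = condition or "pre"

    g = nx.Graph()
    for rec in interactions:
        if rec.node_a == rec.node_b:
            continue
        if rec.node_a in genes and rec.node_b in genes:
            g.add_edge(rec.node_a, rec.node_b)
    if g.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"gene set for sample={sample_id!r} condition={condition!r} "
            "induces no edges"
        )
    components = list(nx.connected_components(g))
    max_size = max(len(c) for c in components)
    tied = [c for c in components if len(c) == max_size]
    main = min(tied, key=lambda c: min(c))  # deterministic tie-break
    return Network(
        sample_id=sample_id,
        condition=condition,
        graph=g.subgraph(main).copy(),
    )


# ---------------------------------------------------------------------------
# centralities


def brandes_betweenness(adjacency: Mapping[str, Sequence[str]]) -> dict[str, float]:
    """Unnormalized betweenness over unordered pairs, endpoints excluded.

    Single-source shortest-path counting with backward dependency
    accumulation on an unweighted undirected graph; the ordered-pair
    accumulation is halved so each unordered source-target pair contributes
    once.
    """
    nodes = sorted(adjacency)
    bc = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        order: list[str] = []
        preds: dict[str, list[str]] = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0.0)
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in adjacency[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(nodes, 0.0)
        while order:
            w = order.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return {v: bc[v] / 2.0 for v in nodes}


def eigenvector_power_iteration(
    adjacency_matrix: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """Principal eigenvector of a nonnegative adjacency, max-normalized.

    Iterates on A + I (same principal eigenvector as A for a connected
    nonnegative matrix; the shift removes the +/-lambda oscillation of
    bipartite graphs).  Convergence is measured in the infinity norm on the
    max-normalized iterate.  Raises :class:`PowerIterationError` with the
    iteration count on failure.
    """
    n = adjacency_matrix.shape[0]
    if n == 0:
        raise ValueError("empty adjacency matrix")
    x = np.ones(n, dtype=float)
    x /= x.max()
    for iteration in range(1, max_iter + 1):
        y = x + adjacency_matrix @ x
        m = y.max()
        if m <= 0:
            raise PowerIterationError(
                f"iterate collapsed to zero at iteration {iteration}"
            )
        y /= m
        if np.max(np.abs(y - x)) < tol:
            return y
        x = y
    raise PowerIterationError(
        f"power iteration did not converge within {max_iter} iterations"
    )


@dataclass(frozen=True)
class CentralityTable:
    """Per-node degree, betweenness and eigenvector scores for one network."""

    sample_id: str
    condition: str
    nodes: tuple[str, ...]
    degree: Mapping[str, int]
    betweenness: Mapping[str, float]
    eigenvector: Mapping[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.nodes,
                "degree": [self.degree[v] for v in self.nodes],
                "betweenness": [self.betweenness[v] for v in self.nodes],
                "eigenvector": [self.eigenvector[v] for v in self.nodes],
            }
        )


def compute_centralities(network: Network) -> CentralityTable:
    """Degree, betweenness and eigenvector centrality of a connected network.

    Conventions: betweenness unnormalized over unordered pairs with
    endpoints excluded; eigenvector by power iteration (inf-norm tolerance
    1e-10, at most 1000 iterations) scaled so the maximum entry is 1.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot compute centralities of an empty network")
    nodes = tuple(sorted(g.nodes))
    adjacency = {v: sorted(g.neighbors(v)) for v in nodes}

    degree = {v: g.degree(v) for v in nodes}
    betweenness = brandes_betweenness(adjacency)

    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=float)
    for u, v in g.edges:
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    eig = eigenvector_power_iteration(a)
    eigenvector = {v: float(eig[index[v]]) for v in nodes}

    return CentralityTable(
        sample_id=network.sample_id,
        condition=network.condition,
        nodes=nodes,
        degree=degree,
        betweenness=betweenness,
        eigenvector=eigenvector,
    )


@dataclass(frozen=True)
class HBSLabels:
    """Hub/bottleneck/switch/HBS flags plus the mean thresholds used."""

    sample_id: str
    condition: str
    nodes: tuple[str, ...]
    is_hub: Mapping[str, bool]
    is_bottleneck: Mapping[str, bool]
    is_switch: Mapping[str, bool]
    is_hbs: Mapping[str, bool]
    mean_degree: float
    mean_betweenness: float
    mean_eigenvector: float

    @property
    def hubs(self) -> frozenset[str]:
        return frozenset(v for v in self.nodes if self.is_hub[v])

    @property
    def bottlenecks(self) -> frozenset[str]:
        return frozenset(v for v in self.nodes if self.is_bottleneck[v])

    @property
    def switches(self) -> frozenset[str]:
        return frozenset(v for v in self.nodes if self.is_switch[v])

    @property
    def hbs(self) -> frozenset[str]:
        return frozenset(v for v in self.nodes if self.is_hbs[v])


def classify_hbs(table: CentralityTable) -> HBSLabels:
    """Label nodes strictly above the network mean on each centrality.

    The thresholds are the arithmetic means over all nodes of the network;
    comparisons are strict, so on a vertex-transitive graph (every metric
    constant) no node is labeled.  HBS is the conjunction of the three
    flags.
    """
    if not table.nodes:
        raise ValueError("cannot classify an empty centrality table")
    n = len(table.nodes)
    mean_degree = sum(table.degree[v] for v in table.nodes) / n
    mean_betweenness = sum(table.betweenness[v] for v in table.nodes) / n
    mean_eigenvector = sum(table.eigenvector[v] for v in table.nodes) / n

    is_hub = {v: table.degree[v] > mean_degree for v in table.nodes}
    is_bottleneck = {
        v: table.betweenness[v] > mean_betweenness for v in table.nodes
    }
    is_switch = {v: table.eigenvector[v] > mean_eigenvector for v in table.nodes}
    is_hbs = {
        v: is_hub[v] and is_bottleneck[v] and is_switch[v] for v in table.nodes
    }
    return HBSLabels(
        sample_id=table.sample_id,
        condition=table.condition,
        nodes=table.nodes,
        is_hub=is_hub,
        is_bottleneck=is_bottleneck,
        is_switch=is_switch,
        is_hbs=is_hbs,
        mean_degree=mean_degree,
        mean_betweenness=mean_betweenness,
        mean_eigenvector=mean_eigenvector,
    )


def write_centrality_table(
    table: CentralityTable, labels: HBSLabels, path: str | Path
) -> None:
    """Export per-node centralities and HBS flags as TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "node\tdegree\tbetweenness\teigenvector\t"
            "is_hub\tis_bottleneck\tis_switch\tis_hbs\n"
        )
        for v in table.nodes:
            fh.write(
                f"{v}\t{table.degree[v]}\t{table.betweenness[v]:.6f}\t"
                f"{table.eigenvector[v]:.8f}\t"
                f"{int(labels.is_hub[v])}\t{int(labels.is_bottleneck[v])}\t"
                f"{int(labels.is_switch[v])}\t{int(labels.is_hbs[v])}\n"
            )


def write_edge_list(network: Network, path: str | Path) -> None:
    """Export the network as a sorted two-column edge TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("node_a\tnode_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{u}\t{v}\n")
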