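"""Interactome loading, cleaning and degree-binned sampling.

The interactome is a simple undirected graph over opaque gene-identifier
strings, held as a :class:`networkx.Graph`.  All distances are unweighted
hop counts.  Degree bins support the degree-matched null model used to
turn raw set-to-set distances into z-scores: random gene sets are drawn
so that they preserve both the size and the degree profile of the
observed set.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "DegreeBins",
    "load_interactome",
    "largest_connected_component",
    "shortest_path_lengths",
    "degree_bins",
    "sample_degree_matched",
]


def load_interactome(path: str | Path) -> nx.Graph:
    """Read a two-column tab-separated edge table into an undirected graph.

    Lines starting with ``#`` are treated as comments.  Self-loops are
    dropped with a warning; duplicate edges (in either orientation) are
    collapsed.

    Parameters
    ----------
    path
        Path to a TSV file with exactly two columns of gene identifiers.

    Returns
    -------
    networkx.Graph
        Simple undirected graph; may have several components (use
        :func:`largest_connected_component` before distance queries).

    Raises
    ------
    ValueError
        If the file has no parseable rows, or a row does not have
        exactly two non-empty fields (the error names the line).
    """
    path = Path(path)
    g = nx.Graph()
    n_rows = 0
    n_self_loops = 0
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated tables
                fields = line.split()
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            u, v = fields
            n_rows += 1
            if u == v:
                n_self_loops += 1
                g.add_node(u)
                continue
            g.add_edge(u, v)
    if n_rows == 0:
        raise ValueError(f"{path}: no parseable edge rows")
    if n_self_loops:
        warnings.warn(
            f"{path}: dropped {n_self_loops} self-loop(s)", stacklevel=2
        )
    return g


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Return the induced subgraph on the largest connected component.

    Ties on component size are broken by the smallest lexicographic node
    identifier in the component, so the result is deterministic.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    return g.subgraph(components[0]).copy()


def _adjacency(g: nx.Graph) -> Mapping[str, list]:
    return {u: list(g.adj[u]) for u in g}


def _multi_source_bfs(
    adj: Mapping[str, Sequence], sources: Iterable
) -> dict:
    """Hop distances from the nearest source, via a plain queue BFS."""
    dist = {s: 0 for s in sources}
    queue = deque(dist)
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


def shortest_path_lengths(g: nx.Graph, sources: Iterable) -> dict:
    """Hop distance from each node to the nearest member of *sources*.

    Nodes unreachable from every source are absent from the mapping.

    Raises
    ------
    KeyError
        If any source is not a node of ``g`` (the message lists them).
    """
    sources = set(sources)
    missing = sources - set(g.nodes)
    if missing:
        raise KeyError(
            "sources not in graph: " + ", ".join(sorted(map(str, missing)))
        )
    return _multi_source_bfs(_adjacency(g), sources)


@dataclass(frozen=True)
class DegreeBins:
    """Partition of the nodes of a graph into contiguous degree ranges.

    Each bin holds every node whose degree falls in its (inclusive)
    range and, except possibly when the whole graph is small, at least
    ``min_bin_size`` members.  Built by :func:`degree_bins`.
    """

    bins: tuple[tuple[tuple[int, int], tuple], ...]
    min_bin_size: int
    _node_to_bin: dict = field(hash=False, compare=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        for idx, (_rng, members) in enumerate(self.bins):
            for node in members:
                self._node_to_bin[node] = idx

    def bin_of(self, node) -> int:
        """Index of the bin containing *node*."""
        return self._node_to_bin[node]

    def members(self, idx: int) -> tuple:
        return self.bins[idx][1]

    def __len__(self) -> int:
        return len(self.bins)


def degree_bins(g: nx.Graph, min_bin_size: int = 100) -> DegreeBins:
    """Group nodes by degree, merging adjacent groups to reach a minimum size.

    Nodes are first grouped by exact degree; groups are then merged in
    ascending degree order until each bin holds at least
    ``min_bin_size`` nodes.  A short final bin is merged backwards into
    its predecessor.  The default of 100 follows common practice for
    degree-preserving null models on genome-scale interactomes.
    """
    if min_bin_size < 1:
        raise ValueError("min_bin_size must be >= 1")
    by_degree: dict[int, list] = {}
    for node in sorted(g.nodes):
        by_degree.setdefault(g.degree(node), []).append(node)

    bins: list[tuple[tuple[int, int], list]] = []
    current: list = []
    lo: int | None = None
    for deg in sorted(by_degree):
        if lo is None:
            lo = deg
        current.extend(by_degree[deg])
        if len(current) >= min_bin_size:
            bins.append(((lo, deg), current))
            current, lo = [], None
    if current:
        if bins:
            (prev_lo, _), prev_members = bins.pop()
            bins.append(((prev_lo, max(by_degree)), prev_members + current))
        else:
            bins.append(((lo, max(by_degree)), current))
    return DegreeBins(
        bins=tuple(((rng, tuple(members)) for rng, members in bins)),
        min_bin_size=min_bin_size,
    )


def sample_degree_matched(
    g: nx.Graph,
    node_set: Iterable,
    bins: DegreeBins,
    rng: np.random.Generator | int | None = None,
) -> set:
    """Draw a random node set matching *node_set* in size and degree profile.

    Each original node is replaced by a node drawn uniformly, without
    replacement, from its degree bin.  If a bin is exhausted (the set
    demands more nodes than the bin holds) the draw widens to adjacent
    bins with a warning; sampling with replacement is never used.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    node_set = sorted(node_set)
    missing = [n for n in node_set if n not in set(g.nodes)]
    if missing:
        raise KeyError("nodes not in graph: " + ", ".join(map(str, missing)))

    # how many draws each bin must supply
    demand: dict[int, int] = {}
    for node in node_set:
        idx = bins.bin_of(node)
        demand[idx] = demand.get(idx, 0) + 1

    chosen: set = set()
    for idx in sorted(demand):
        pool = [n for n in bins.members(idx) if n not in chosen]
        need = demand[idx]
        if len(pool) < need:
            warnings.warn(
                f"degree bin {idx} exhausted ({len(pool)} available, "
                f"{need} needed); widening to adjacent bins",
                stacklevel=2,
            )
            offset = 1
            while len(pool) < need and (
                idx - offset >= 0 or idx + offset < len(bins)
            ):
                for j in (idx - offset, idx + offset):
                    if 0 <= j < len(bins):
                        pool.extend(
                            n for n in bins.members(j) if n not in chosen and n not in pool
                        )
                offset += 1
            if len(pool) < need:
                raise ValueError(
                    f"cannot sample {need} nodes for bin {idx}: graph too small"
                )
        picked = rng.choice(len(pool), size=need, replace=False)
        chosen.update(pool[i] for i in picked)
    return chosen
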