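"""Set-to-set network proximity and degree-matched z-scores.

The closest-distance proximity between a source gene set S and a target
gene set T on an interactome G is

    d(S, T) = (1 / |S|) * sum_{u in S} min_{v in T} d(u, v),

the average hop distance from each source gene to its nearest target
gene.  The raw distance is converted into a z-score against a null
distribution obtained by resampling BOTH endpoints as random gene sets
that match the originals in size and degree (1000 realizations by
default).  Pathways whose genes reach z <= -2 against a disease's genes
form the disease's *pathway span*.

A random-walk-with-restart (RWR) engine is provided as an alternative
proximity statistic; its z-score is negated so that "more proximal"
means "more negative" under both engines and a single threshold serves
both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .core_network import (
    DegreeBins,
    _adjacency,
    _multi_source_bfs,
    degree_bins,
    sample_degree_matched,
)

__all__ = [
    "ProximityResult",
    "PathwaySpan",
    "closest_distance",
    "proximity_z",
    "pathway_span",
    "rwr_scores",
    "rwr_proximity_z",
]


@dataclass(frozen=True)
class ProximityResult:
    """Observed proximity with its degree-matched null summary.

    ``z`` is ``nan`` when the null distribution is degenerate
    (``sigma == 0``); :attr:`z_defined` flags this, and significance
    decisions on an undefined z must be treated as "not significant".
    """

    d_obs: float
    mu: float
    sigma: float
    z: float
    n_random: int
    seed: int | None
    dropped_genes: frozenset = frozenset()

    @property
    def z_defined(self) -> bool:
        return not np.isnan(self.z)

    def is_significant(self, z_cut: float = -2.0) -> bool:
        return self.z_defined and self.z <= z_cut


@dataclass(frozen=True)
class PathwaySpan:
    """Pathways significantly proximal (z <= z_cut) to one disease.

    ``entries`` is sorted ascending by z (most proximal first).
    """

    disease_id: str
    entries: tuple[tuple[str, ProximityResult], ...]
    z_cut: float = -2.0

    @property
    def pathway_ids(self) -> set[str]:
        return {pid for pid, _ in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


def _z_or_nan(obs: float, mu: float, sigma: float) -> float:
    """z-score, or nan when the null is degenerate.

    A sigma that is zero up to floating-point noise relative to the
    statistic's scale counts as degenerate.
    """
    if sigma <= 1e-9 * max(abs(mu), abs(obs)):
        return float("nan")
    return (obs - mu) / sigma


def _filter_to_graph(g: nx.Graph, genes: Iterable, label: str) -> tuple[set, set]:
    genes = set(genes)
    present = genes & set(g.nodes)
    dropped = genes - present
    if not present:
        raise ValueError(f"{label}: no genes present in the interactome")
    return present, dropped


def _closest_distance_from_dist(dist: Mapping, S: Iterable) -> float:
    total = 0.0
    for u in S:
        if u not in dist:
            raise ValueError(f"gene {u!r} unreachable from the target set")
        total += dist[u]
    return total / len(S)  # type: ignore[arg-type]


def closest_distance(g: nx.Graph, S: Iterable, T: Iterable) -> float:
    """Average hop distance from each gene in S to its nearest gene in T.

    Asymmetric in (S, T) by design: S is averaged over, T supplies the
    nearest neighbours.  Genes absent from the graph are dropped; an
    error is raised if either side empties out, or if some retained
    source cannot reach any target (impossible on a connected graph).
    """
    S, _ = _filter_to_graph(g, S, "S")
    T, _ = _filter_to_graph(g, T, "T")
    dist = _multi_source_bfs(_adjacency(g), T)
    return _closest_distance_from_dist(dist, S)


def proximity_z(
    g: nx.Graph,
    S: Iterable,
    T: Iterable,
    n_random: int = 1000,
    min_bin_size: int = 100,
    seed: int | None = None,
    bins: DegreeBins | None = None,
) -> ProximityResult:
    """Closest-distance proximity z-score against a degree-matched null.

    Both S and T are resampled in every null realization
    (d_random(S, T) = d(S_random, T_random)); the z-score is

        z = (d_obs - mu_random) / sigma_random.

    Parameters
    ----------
    n_random
        Number of null realizations (1000 by default).
    min_bin_size
        Minimum degree-bin occupancy for the matched sampling; ignored
        when ``bins`` is given.
    bins
        Precomputed :class:`DegreeBins` for ``g``; pass when scoring
        many sets against the same graph.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    S_used, dropped_s = _filter_to_graph(g, S, "S")
    T_used, dropped_t = _filter_to_graph(g, T, "T")
    adj = _adjacency(g)
    d_obs = _closest_distance_from_dist(_multi_source_bfs(adj, T_used), S_used)

    if bins is None:
        bins = degree_bins(g, min_bin_size=min_bin_size)
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for i in range(n_random):
            s_rand = sample_degree_matched(g, S_used, bins, rng)
            t_rand = sample_degree_matched(g, T_used, bins, rng)
            null[i] = _closest_distance_from_dist(
                _multi_source_bfs(adj, t_rand), s_rand
            )
    mu = float(null.mean())
    sigma = float(null.std())
    z = _z_or_nan(d_obs, mu, sigma)
    return ProximityResult(
        d_obs=d_obs,
        mu=mu,
        sigma=sigma,
        z=z,
        n_random=n_random,
        seed=seed,
        dropped_genes=frozenset(dropped_s | dropped_t),
    )


def pathway_span(
    g: nx.Graph,
    disease_genes: Iterable,
    pathways,
    z_cut: float = -2.0,
    n_random: int = 1000,
    min_bin_size: int = 100,
    seed: int | None = None,
    disease_id: str = "disease",
    engine: str = "shortest_path",
) -> PathwaySpan:
    """Pathways significantly proximal to a disease's genes.

    Runs one proximity z-score per pathway with S = disease genes and
    T = pathway genes, and keeps pathways with z <= ``z_cut``.
    Pathways with no gene in the interactome are skipped with a
    warning.  ``pathways`` is any iterable of ``(pathway_id, genes)``
    pairs, e.g. a :class:`pxea.io.GmtCollection`.
    """
    score = proximity_z if engine == "shortest_path" else rwr_proximity_z
    if engine not in ("shortest_path", "rwr"):
        raise ValueError(f"unknown engine {engine!r}")
    bins = degree_bins(g, min_bin_size=min_bin_size)
    ss = np.random.SeedSequence(seed)
    nodes = set(g.nodes)
    items = list(pathways)
    entries: list[tuple[str, ProximityResult]] = []
    for (pid, genes), child in zip(items, ss.spawn(max(len(items), 1))):
        genes = set(genes)
        if not genes & nodes:
            warnings.warn(
                f"pathway {pid!r}: no genes in the interactome; skipped",
                stacklevel=2,
            )
            continue
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        res = score(
            g, disease_genes, genes, n_random=n_random, seed=sub_seed, bins=bins
        )
        if res.is_significant(z_cut):
            entries.append((pid, res))
    entries.sort(key=lambda e: (e[1].z, e[0]))
    return PathwaySpan(disease_id=disease_id, entries=tuple(entries), z_cut=z_cut)


class RwrConvergenceError(RuntimeError):
    """Random walk with restart failed to converge within max_iter."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"RWR did not converge in {max_iter} iterations "
            f"(last L1 change {residual:.3g})"
        )
        self.residual = residual
        self.max_iter = max_iter


def rwr_scores(
    g: nx.Graph,
    seed_set: Iterable,
    restart: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> dict:
    """Stationary visit probabilities of a random walk with restart.

    Iterates ``s <- r * e + (1 - r) * W^T s`` with W the
    column-normalized adjacency matrix and e uniform over the seed set,
    until the L1 change drops below ``tol``.  Scores sum to 1.
    """
    if not (0 < restart <= 1):
        raise ValueError("restart must be in (0, 1]")
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    seeds, _ = _filter_to_graph(g, seed_set, "seed_set")

    A = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr", dtype=float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    # W column-normalized => W^T row-normalized: divide rows of A by degree
    WT = sp.diags(1.0 / deg) @ A
    WT = WT.T.tocsr()

    e = np.zeros(len(nodes))
    for s in seeds:
        e[index[s]] = 1.0 / len(seeds)
    s_vec = e.copy()
    residual = np.inf
    for _ in range(max_iter):
        s_new = restart * e + (1.0 - restart) * (WT @ s_vec)
        residual = float(np.abs(s_new - s_vec).sum())
        s_vec = s_new
        if residual < tol:
            return {n: float(s_vec[index[n]]) for n in nodes}
    raise RwrConvergenceError(residual, max_iter)


def rwr_proximity_z(
    g: nx.Graph,
    S: Iterable,
    T: Iterable,
    n_random: int = 1000,
    min_bin_size: int = 100,
    seed: int | None = None,
    bins: DegreeBins | None = None,
    restart: float = 0.5,
    tol: float = 1e-6,
) -> ProximityResult:
    """RWR-based proximity z-score against a degree-matched null.

    The statistic is the mean RWR visit probability over T when the
    walk restarts on S.  High scores mean proximal, so the z-score is
    negated to match the shortest-path convention: more proximal =>
    more negative, and z <= -2 flags significance under both engines.
    ``d_obs`` holds the raw (un-negated) mean visit probability.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    S_used, dropped_s = _filter_to_graph(g, S, "S")
    T_used, dropped_t = _filter_to_graph(g, T, "T")

    def statistic(seeds: set, targets: set) -> float:
        scores = rwr_scores(g, seeds, restart=restart, tol=tol)
        return float(np.mean([scores[t] for t in sorted(targets)]))

    obs = statistic(S_used, T_used)
    if bins is None:
        bins = degree_bins(g, min_bin_size=min_bin_size)
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    for i in range(n_random):
        s_rand = sample_degree_matched(g, S_used, bins, rng)
        t_rand = sample_degree_matched(g, T_used, bins, rng)
        null[i] = statistic(s_rand, t_rand)
    mu = float(null.mean())
    sigma = float(null.std())
    z = -_z_or_nan(obs, mu, sigma)
    return ProximityResult(
        d_obs=obs,
        mu=mu,
        sigma=sigma,
        z=z,
        n_random=n_random,
        seed=seed,
        dropped_genes=frozenset(dropped_s | dropped_t),
    )
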