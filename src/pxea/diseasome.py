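"""Multi-evidence disease-disease networks (diseasomes).

Two diseases are linked when at least one evidence channel fires:
shared genes (two-sided Fisher, p <= alpha), shared symptoms after
TF-IDF filtering (same test over the symptom universe), comorbidity
(relative risk > 1 from co-occurrence counts), or shared pathway spans
(two-sided Fisher over the pathway collection).  Channels are
independent: each is evaluated only from its own inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .enrichment_stats import ContingencyTable, fisher_exact
from .proximity import PathwaySpan

__all__ = [
    "DiseaseProfile",
    "DiseasomeEdge",
    "ComorbidityTable",
    "shared_set_link",
    "symptom_filter",
    "relative_risk",
    "build_diseasome",
    "network_metrics",
]


@dataclass(frozen=True)
class DiseaseProfile:
    """Everything known about one disease: genes, symptoms, pathway span."""

    disease_id: str
    genes: frozenset
    symptoms: Optional[Mapping[str, float]] = None  # symptom id -> TF-IDF
    pathway_span: Optional[PathwaySpan] = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"{self.disease_id}: empty gene set")
        if self.symptoms is not None and any(v < 0 for v in self.symptoms.values()):
            raise ValueError(f"{self.disease_id}: negative TF-IDF score")


@dataclass(frozen=True)
class DiseasomeEdge:
    """One disease pair and the evidence channels connecting it."""

    pair: tuple[str, str]  # sorted
    evidence: frozenset  # subset of the four channel names
    stats: Mapping[str, float]  # channel -> p-value or relative risk


@dataclass(frozen=True)
class ComorbidityTable:
    """Disease co-occurrence counts from patient records.

    ``counts`` maps a sorted disease-id pair to the number of patients
    with both diagnoses; ``prevalence`` maps each disease to its
    patient count; ``n_patients`` is the cohort size.
    """

    counts: Mapping[tuple[str, str], int]
    prevalence: Mapping[str, int]
    n_patients: int


def shared_set_link(
    a: Iterable, b: Iterable, universe: Iterable, alpha: float = 0.05
) -> tuple[bool, float]:
    """Two-sided Fisher test on the overlap of two sets in a universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    p = fisher_exact(
        ContingencyTable.from_sets(set(a), set(b), universe), "two-sided"
    )
    return p <= alpha, p


def symptom_filter(profile: DiseaseProfile, tfidf_min: float = 3.5) -> set:
    """Symptoms whose TF-IDF score is strictly above the threshold."""
    if profile.symptoms is None:
        raise ValueError(f"{profile.disease_id}: no symptom scores")
    return {s for s, score in profile.symptoms.items() if score > tfidf_min}


def relative_risk(c_ij: int, p_i: int, p_j: int, n: int) -> float:
    """Relative risk of disease co-occurrence given each prevalence.

    RR = (c_ij * n) / (p_i * p_j): the observed number of patients with
    both diagnoses over the expectation under independence.  RR > 1
    (strict) marks a comorbidity link.
    """
    if p_i <= 0 or p_j <= 0:
        raise ValueError("prevalence must be positive")
    if not (0 <= c_ij <= min(p_i, p_j) <= n):
        raise ValueError("counts inconsistent: need 0 <= c_ij <= min(p_i, p_j) <= n")
    return (c_ij * n) / (p_i * p_j)


def build_diseasome(
    profiles: Sequence[DiseaseProfile],
    gene_universe: Optional[Iterable] = None,
    comorbidity: Optional[ComorbidityTable] = None,
    pathway_universe_size: Optional[int] = None,
    alpha: float = 0.05,
    tfidf_min: float = 3.5,
) -> list[DiseasomeEdge]:
    """Evaluate every evidence channel for every disease pair.

    An edge is emitted when any available channel fires.  Defaults when
    a universe is not supplied: genes — union of all profile genes;
    symptoms — union of post-filter symptoms across profiles; pathways
    — ``pathway_universe_size`` is required whenever spans are present.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two disease profiles")
    if gene_universe is None:
        gene_universe = set().union(*(p.genes for p in profiles))
    gene_universe = set(gene_universe)

    with_symptoms = [p for p in profiles if p.symptoms is not None]
    symptom_universe: set = set()
    filtered: dict[str, set] = {}
    for p in with_symptoms:
        filtered[p.disease_id] = symptom_filter(p, tfidf_min)
        symptom_universe |= filtered[p.disease_id]

    spans = {p.disease_id: p.pathway_span for p in profiles if p.pathway_span}
    if spans and pathway_universe_size is None:
        raise ValueError("pathway_universe_size required when spans are present")

    edges: list[DiseasomeEdge] = []
    for pa, pb in combinations(sorted(profiles, key=lambda p: p.disease_id), 2):
        evidence: set[str] = set()
        stats: dict[str, float] = {}

        sig, p = shared_set_link(pa.genes, pb.genes, gene_universe, alpha)
        stats["shared_genes"] = p
        if sig:
            evidence.add("shared_genes")

        if pa.disease_id in filtered and pb.disease_id in filtered and symptom_universe:
            sig, p = shared_set_link(
                filtered[pa.disease_id],
                filtered[pb.disease_id],
                symptom_universe,
                alpha,
            )
            stats["shared_symptoms"] = p
            if sig:
                evidence.add("shared_symptoms")

        if comorbidity is not None:
            key = tuple(sorted((pa.disease_id, pb.disease_id)))
            if key in comorbidity.counts:
                rr = relative_risk(
                    comorbidity.counts[key],
                    comorbidity.prevalence[pa.disease_id],
                    comorbidity.prevalence[pb.disease_id],
                    comorbidity.n_patients,
                )
                stats["comorbidity"] = rr
                if rr > 1:
                    evidence.add("comorbidity")

        if pa.disease_id in spans and pb.disease_id in spans:
            ids_a = spans[pa.disease_id].pathway_ids
            ids_b = spans[pb.disease_id].pathway_ids
            both = len(ids_a & ids_b)
            neither = pathway_universe_size - len(ids_a | ids_b)
            if neither < 0:
                raise ValueError("pathway_universe_size smaller than observed spans")
            p = fisher_exact(
                ContingencyTable(
                    both=both,
                    only_a=len(ids_a) - both,
                    only_b=len(ids_b) - both,
                    neither=neither,
                ),
                "two-sided",
            )
            stats["shared_pathways"] = p
            if p <= alpha:
                evidence.add("shared_pathways")

        if evidence:
            edges.append(
                DiseasomeEdge(
                    pair=tuple(sorted((pa.disease_id, pb.disease_id))),
                    evidence=frozenset(evidence),
                    stats=stats,
                )
            )
    return edges


def network_metrics(
    edges: Iterable[tuple], n_nodes: int
) -> tuple[float, float]:
    """Average degree and average local clustering of an edge list.

    ``avg_degree = 2|E| / n``; clustering is the mean over all
    ``n_nodes`` nodes of the local clustering coefficient, with nodes
    of degree < 2 contributing 0 (isolated nodes included in the mean).
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    g = nx.Graph()
    for e in edges:
        u, v = e.pair if isinstance(e, DiseasomeEdge) else e
        g.add_edge(u, v)
    if g.number_of_nodes() > n_nodes:
        raise ValueError("edge list names more nodes than n_nodes")
    avg_degree = 2 * g.number_of_edges() / n_nodes
    clustering_sum = sum(nx.clustering(g).values())
    return avg_degree, clustering_sum / n_nodes
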