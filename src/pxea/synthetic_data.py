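"""Synthetic interactomes, planted modules and the pathway-noise experiment.

The generators here produce every input the analysis needs at desk
scale: scale-free or Erdős–Rényi toy interactomes, connected "disease
modules" planted by snowball sampling, gold-standard pathways built
from a fraction k% of a disease's genes, and size-matched random
control pathways.  :func:`noise_experiment` wires them together to
measure how pathway-detection robustness degrades with annotation
noise, for both the shortest-path and the random-walk proximity
engines.

:func:`inpaper_fixtures` returns the curated gene associations for
nine autoimmune disorders and the corresponding 9-disease diseasome
topology (complete but for three missing links) used as a compact,
fully-determined test bed.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .proximity import proximity_z, rwr_proximity_z
from .core_network import degree_bins

__all__ = [
    "toy_interactome",
    "plant_disease_module",
    "gold_standard_pathways",
    "control_pathways",
    "noise_experiment",
    "inpaper_fixtures",
    "AUTOIMMUNE_DISEASE_GENES",
    "DISEASOME_MISSING_LINKS",
]


def _label(i: int) -> str:
    return f"G{i:04d}"


def toy_interactome(
    n_nodes: int,
    model: str = "barabasi_albert",
    param: float = 2,
    seed: Optional[int] = None,
) -> nx.Graph:
    """Generate a connected toy interactome with string gene ids.

    ``model`` is ``"barabasi_albert"`` (``param`` = edges per new node,
    giving the right-skewed degree distribution of real interactomes)
    or ``"erdos_renyi"`` (``param`` = edge probability).  Disconnected
    draws are regenerated with a shifted seed until connected, so the
    result is deterministic under a fixed seed.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    attempt_seed = seed
    for _ in range(100):
        if model == "barabasi_albert":
            g = nx.barabasi_albert_graph(n_nodes, int(param), seed=attempt_seed)
        elif model == "erdos_renyi":
            g = nx.gnp_random_graph(n_nodes, float(param), seed=attempt_seed)
        else:
            raise ValueError(f"unknown model {model!r}")
        if nx.is_connected(g):
            return nx.relabel_nodes(g, {i: _label(i) for i in g.nodes})
        attempt_seed = (attempt_seed or 0) + 1
    raise RuntimeError(
        f"could not generate a connected {model} graph in 100 attempts"
    )


def plant_disease_module(
    g: nx.Graph, size: int, seed: Optional[int] = None
) -> set:
    """Grow a connected node set by seeded snowball sampling.

    Starts from a random node and repeatedly absorbs a uniformly
    chosen frontier neighbour, so the induced subgraph is connected —
    the topology expected of a disease module.
    """
    if size > g.number_of_nodes():
        raise ValueError("module size exceeds graph size")
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    start = nodes[int(rng.integers(len(nodes)))]
    module = {start}
    frontier = set(g.adj[start])
    while len(module) < size:
        if not frontier:  # cannot happen on a connected graph
            raise RuntimeError("snowball frontier exhausted")
        pick = sorted(frontier)[int(rng.integers(len(frontier)))]
        module.add(pick)
        frontier |= set(g.adj[pick])
        frontier -= module
    return module


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def gold_standard_pathways(
    disease_genes: Iterable,
    k_percent: float,
    n_reps: int = 10,
    seed: Optional[int] = None,
) -> list[set]:
    """Noisy gold-standard pathways: random k% subsets of disease genes.

    Each of the ``n_reps`` sets holds ``round(k/100 * n)`` genes
    (half-up, minimum 1) sampled without replacement, emulating pathway
    annotations that capture only part of the true disease biology.
    """
    genes = sorted(set(disease_genes))
    if not genes:
        raise ValueError("disease_genes is empty")
    if not 0 < k_percent <= 100:
        raise ValueError("k_percent must be in (0, 100]")
    size = max(1, _round_half_up(k_percent / 100 * len(genes)))
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        picked = rng.choice(len(genes), size=size, replace=False)
        out.append({genes[i] for i in picked})
    return out


def control_pathways(
    g: nx.Graph, sizes: Sequence[int], seed: Optional[int] = None
) -> list[set]:
    """Uniform random node sets of the given sizes (no degree matching)."""
    nodes = sorted(g.nodes)
    if any(s > len(nodes) for s in sizes):
        raise ValueError("control size exceeds graph size")
    rng = np.random.default_rng(seed)
    out = []
    for size in sizes:
        picked = rng.choice(len(nodes), size=size, replace=False)
        out.append({nodes[i] for i in picked})
    return out


def noise_experiment(
    g: nx.Graph,
    disease_gene_sets: Mapping[str, Iterable],
    k_values: Sequence[float] = (10, 25, 50, 75, 90),
    n_reps: int = 10,
    engines: Sequence[str] = ("shortest_path", "rwr"),
    n_random: int = 1000,
    min_bin_size: int = 100,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Full-factorial noise-robustness experiment.

    For each disease, each noise level k and each replicate, a gold
    pathway (k% of the disease genes) and a size-matched random control
    are scored for proximity to the disease genes (pathway as the
    source set, disease genes as the target set) under each engine.
    With 2 diseases, 5 k values and 10 replicates this yields 100 gold
    pathways per engine.  Columns: disease_id, k, replicate,
    pathway_kind (gold|control), engine, d_obs, z.
    """
    for name in engines:
        if name not in ("shortest_path", "rwr"):
            raise ValueError(f"unknown engine {name!r}")
    bins = degree_bins(g, min_bin_size=min_bin_size)
    ss = np.random.SeedSequence(seed)
    rows = []
    for disease_id in sorted(disease_gene_sets):
        genes = set(disease_gene_sets[disease_id]) & set(g.nodes)
        if not genes:
            raise ValueError(f"{disease_id}: no genes in the interactome")
        for k in k_values:
            child = ss.spawn(1)[0]
            gold_seed, ctrl_seed, *score_seeds = (
                int(s.generate_state(1)[0] % (2**31))
                for s in child.spawn(2 + 2 * n_reps * len(engines))
            )
            golds = gold_standard_pathways(genes, k, n_reps=n_reps, seed=gold_seed)
            ctrls = control_pathways(g, [len(s) for s in golds], seed=ctrl_seed)
            score_iter = iter(score_seeds)
            for rep, (gold, ctrl) in enumerate(zip(golds, ctrls), start=1):
                for engine in engines:
                    score = proximity_z if engine == "shortest_path" else rwr_proximity_z
                    for kind, pset in (("gold", gold), ("control", ctrl)):
                        res = score(
                            g, pset, genes, n_random=n_random,
                            seed=next(score_iter), bins=bins,
                        )
                        rows.append(
                            {
                                "disease_id": disease_id,
                                "k": k,
                                "replicate": rep,
                                "pathway_kind": kind,
                                "engine": engine,
                                "d_obs": res.d_obs,
                                "z": res.z,
                            }
                        )
    return pd.DataFrame(rows)


# Curated gene associations for nine autoimmune disorders (primary
# literature-backed associations; gene symbols).
AUTOIMMUNE_DISEASE_GENES: dict[str, tuple[str, ...]] = {
    "celiac disease": (
        "IL21 CCR4 HLA-DQA1 BACH2 RUNX3 ICOSLG SH2B3 CTLA4 MYO9B ZMIZ1 ETS1"
    ).split(),
    "Crohn's disease": (
        "DNMT3A IL12B IRGM IL10 CCL2 FUT2 SMAD3 TYK2 ATG16L1 BACH2 "
        "IL2RA NKX2-3 PTPN2 NOD2 TAGAP MST1 DENND1B IL23R ERAP2"
    ).split(),
    "diabetes mellitus, insulin-dependent": (
        "IL10 GLIS3 HLA-DQA1 HLA-DRB1 PTPN22 SLC29A3 INS BACH2 CLEC16A "
        "PAX4 HLA-DQB1 IL2RA CD69 IL27 HNF1A CTSH SH2B3 C1QTNF6"
    ).split(),
    "Graves' disease": "RNASET2 CTLA4 FCRL3 TSHR".split(),
    "lupus erythematosus, systemic": (
        "IKZF1 CFB RASGRP3 PDCD1 RASGRP1 DNASE1 HLA-DRB1 PTPN22 ETS1 TNIP1 "
        "FCGR2B TNFSF4 IRF5 C2 PRDM1 PXK TLR5 TREX1 TNFAIP3 SLC15A4 PHRF1 "
        "HLA-DQA1 STAT4 ITGAX ITGAM BLK C4A BANK1 CR2"
    ).split(),
    "multiple sclerosis": (
        "CD58 CD6 IRF8 HLA-DQB1 CBLB HLA-DRA KIF1B IL2RA "
        "TNFSF14 VCAM1 IL7R HLA-DRB1 CD24 TNFRSF1A PTPRC"
    ).split(),
    "psoriasis": (
        "IL12B TNIP1 LCE3D IL13 IL23R TYK2 HLA-DQB1 HLA-C FBXL19 "
        "ERAP1 TRAF3IP2 TNFAIP3 TNF REL NOS2"
    ).split(),
    "rheumatoid arthritis": (
        "MIF CD40 ANKRD55 HLA-DRB1 PTPN22 RBPJ IL2RA AFF3 CCL21 REL SLC22A4 CCR6 "
        "IRF5 SPRED2 CTLA4 PADI4 TNFAIP3 NFKBIL1 HLA-DQA2 STAT4 IL6 BLK TRAF1"
    ).split(),
    "ulcerative colitis": (
        "IL12B JAK2 ICOSLG IL1R2 LSP1 CXCR2 IL10 IL7R CXCR1 DAP NKX2-3 CARD9 GNA12 "
        "IRF5 PRDM1 HNF4A SLC26A3 FCGR2A IL23R IL17REL MST1 TNFSF15 CDH3 CCNY"
    ).split(),
}

# Disease pairs with no supporting evidence in the 9-disease diseasome;
# all other 33 of the 36 possible pairs are linked.
DISEASOME_MISSING_LINKS: tuple[tuple[str, str], ...] = (
    ("ulcerative colitis", "rheumatoid arthritis"),
    ("ulcerative colitis", "Graves' disease"),
    ("Graves' disease", "diabetes mellitus, insulin-dependent"),
)


def inpaper_fixtures() -> tuple[dict[str, set], list[tuple[str, str]]]:
    """Nine autoimmune disease gene sets and the diseasome topology.

    Returns ``(disease -> gene set, diseasome edge list)`` where the
    edge list is the complete graph on the nine diseases minus the
    three unsupported pairs (33 edges).
    """
    genes = {d: set(g) for d, g in AUTOIMMUNE_DISEASE_GENES.items()}
    diseases = sorted(genes)
    missing = {frozenset(pair) for pair in DISEASOME_MISSING_LINKS}
    edges = [
        (a, b)
        for i, a in enumerate(diseases)
        for b in diseases[i + 1 :]
        if frozenset((a, b)) not in missing
    ]
    return genes, edges
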