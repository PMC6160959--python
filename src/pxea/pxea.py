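"""PxEA: running-sum enrichment of proximal pathways.

A drug is scored against a set of pathways of interest C (typically the
pathways shared by two comorbid diseases) as follows.  Every pathway in
the collection D is ranked by the proximity z-score of the drug's
targets to the pathway genes (most proximal first).  Walking down the
ranking, a running sum is incremented by (|D|-|C|)/|C| at each pathway
in C and decremented by |C|/(|D|-|C|) otherwise; the enrichment score
ES is the maximum of the running sum over all prefixes, floored at 0.
The increments make the full-ranking sum equal |D|-2|C|, so ES lies in
[0, |D|-|C|] and reaches the upper bound exactly when all of C occupies
the top |C| ranks.  Significance comes from shuffling the ranking
(10,000 permutations by default): p is the fraction of permutations
whose ES strictly exceeds the observed one, BH-adjusted across drugs
in a screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_network import degree_bins
from .enrichment_stats import bh_adjust
from .proximity import PathwaySpan, ProximityResult, proximity_z

__all__ = [
    "RankedPathways",
    "PxeaResult",
    "rank_pathways_for_drug",
    "common_span",
    "running_sum_es",
    "permutation_p",
    "pxea_screen",
]


@dataclass(frozen=True)
class RankedPathways:
    """Pathway ids ordered ascending by proximity z (most proximal first).

    Ties are broken ascending by observed distance, then by pathway id,
    so rankings are reproducible.
    """

    entries: tuple[tuple[str, float], ...]  # (pathway_id, z)
    name: str = "D"

    @classmethod
    def from_results(
        cls, results: Iterable[tuple[str, ProximityResult]], name: str = "D"
    ) -> "RankedPathways":
        ordered = sorted(results, key=lambda e: (e[1].z, e[1].d_obs, e[0]))
        entries = tuple((pid, res.z) for pid, res in ordered)
        return cls(entries=entries, name=name)

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate pathway ids in ranking")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PxeaResult:
    """Enrichment score with permutation significance for one drug."""

    es: float
    p: float
    p_adj: float
    n_perm: int
    seed: Optional[int]

    def p_text(self) -> str:
        """Textual p, reporting 0 as a resolution bound."""
        return f"< {1.0 / self.n_perm:g}" if self.p == 0 else f"{self.p:g}"


def common_span(span_a: PathwaySpan, span_b: PathwaySpan) -> set[str]:
    """Pathways in the span of both diseases (C for a disease pair).

    For a single disease, pass the same span twice.
    """
    return span_a.pathway_ids & span_b.pathway_ids


def _increments(n_total: int, n_hits: int) -> tuple[float, float]:
    if not (0 < n_hits < n_total):
        raise ValueError(
            f"need 0 < |C| < |D|, got |C|={n_hits}, |D|={n_total}"
        )
    return (n_total - n_hits) / n_hits, -n_hits / (n_total - n_hits)


def running_sum_es(D: RankedPathways, C: Iterable[str]) -> float:
    """Maximum prefix of the PxEA running sum, floored at 0."""
    C = set(C)
    if not C <= set(D.ids):
        missing = sorted(C - set(D.ids))
        raise ValueError(f"pathways of C absent from D: {missing}")
    hit, miss = _increments(len(D), len(C))
    best = total = 0.0
    for pid in D.ids:
        total += hit if pid in C else miss
        if total > best:
            best = total
    return best


def _es_from_hit_positions(
    positions: np.ndarray, n_total: int, hit: float, miss: float
) -> float:
    """ES given the sorted 1-based ranks occupied by C.

    The running sum attains its prefix maxima at hit positions, where
    the sum after the h-th hit (at rank r_h) is h*hit - (r_h - h)*miss'.
    """
    positions = np.sort(positions)
    h = np.arange(1, positions.size + 1)
    prefix_at_hits = h * hit + (positions - h) * miss
    best = prefix_at_hits.max() if positions.size else 0.0
    return float(max(0.0, best))


def permutation_p(
    D: RankedPathways,
    C: Iterable[str],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for the observed enrichment score.

    Shuffles the ranking D uniformly (equivalently, places |C| hits
    uniformly among the |D| ranks) and counts permutations whose ES
    strictly exceeds the observed score:

        p = #(ES_random > ES_obs) / n_perm.

    A p of exactly 0 is stored as 0 and reported in text as the
    resolution bound "< 1/n_perm".  Returns (p, null ES sample).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    C = set(C)
    running_sum_es(D, C)  # validate C against D
    hit, miss = _increments(len(D), len(C))
    obs_positions = np.array(
        [i + 1 for i, pid in enumerate(D.ids) if pid in C]
    )
    # same computation path as the null so permutation ties compare exactly
    es_obs = _es_from_hit_positions(obs_positions, len(D), hit, miss)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n, k = len(D), len(C)
    for i in range(n_perm):
        positions = rng.choice(n, size=k, replace=False) + 1
        null[i] = _es_from_hit_positions(positions, n, hit, miss)
    p = float(np.count_nonzero(null > es_obs) / n_perm)
    return p, null


def rank_pathways_for_drug(
    g: nx.Graph,
    drug_targets: Iterable,
    pathways,
    n_random: int = 1000,
    min_bin_size: int = 100,
    seed: Optional[int] = None,
    name: str = "D",
) -> RankedPathways:
    """Rank a full pathway collection by proximity to a drug's targets.

    One proximity z-score per pathway with S = drug targets and
    T = pathway genes; the entire collection is ranked, not only the
    significant part.  Pathways with no gene in the interactome are
    skipped with a warning.
    """
    import warnings

    targets = set(drug_targets) & set(g.nodes)
    if not targets:
        raise ValueError("drug has no targets in the interactome")
    bins = degree_bins(g, min_bin_size=min_bin_size)
    ss = np.random.SeedSequence(seed)
    items = list(pathways)
    results: list[tuple[str, ProximityResult]] = []
    for (pid, genes), child in zip(items, ss.spawn(max(len(items), 1))):
        genes = set(genes) & set(g.nodes)
        if not genes:
            warnings.warn(
                f"pathway {pid!r}: no genes in the interactome; skipped",
                stacklevel=2,
            )
            continue
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        results.append(
            (pid, proximity_z(g, targets, genes, n_random=n_random,
                              seed=sub_seed, bins=bins))
        )
    return RankedPathways.from_results(results, name=name)


def pxea_screen(
    g: nx.Graph,
    drug_target_table: Mapping[str, Iterable],
    pathways,
    C: Iterable[str],
    n_random: int = 1000,
    n_perm: int = 10_000,
    min_bin_size: int = 100,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Score every drug in a target table against a pathway set of interest.

    Drugs sharing an identical usable target set are scored once and
    receive identical results.  Returns a DataFrame sorted by ES
    descending (ties by drug id) with BH-adjusted p-values across the
    scored drugs; drugs with no target in the interactome appear with
    NaN scores.
    """
    C = set(C)
    if not C:
        raise ValueError("pathway set of interest C is empty")
    nodes = set(g.nodes)
    items = list(pathways)

    # score one representative per unique usable target set
    groups: dict[frozenset, list[str]] = {}
    unusable: list[str] = []
    for drug, targets in drug_target_table.items():
        usable = frozenset(set(targets) & nodes)
        if usable:
            groups.setdefault(usable, []).append(drug)
        else:
            unusable.append(drug)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(len(groups), 1))
    rows = []
    for (targets, drugs), child in zip(
        sorted(groups.items(), key=lambda kv: sorted(kv[1])[0]), children
    ):
        s1, s2 = (int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(2))
        D = rank_pathways_for_drug(
            g, targets, items, n_random=n_random,
            min_bin_size=min_bin_size, seed=s1,
        )
        es = running_sum_es(D, C)
        p, _ = permutation_p(D, C, n_perm=n_perm, seed=s2)
        for drug in drugs:
            rows.append(
                {
                    "drug_id": drug,
                    "es": es,
                    "p": p,
                    "n_targets_used": len(targets),
                    "dropped_targets": len(set(drug_target_table[drug])) - len(targets),
                }
            )
    df = pd.DataFrame(
        rows, columns=["drug_id", "es", "p", "n_targets_used", "dropped_targets"]
    )
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].tolist())
        df = df.sort_values(
            ["es", "drug_id"], ascending=[False, True]
        ).reset_index(drop=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
    for drug in sorted(unusable):
        df = pd.concat(
            [df, pd.DataFrame([{"drug_id": drug, "es": np.nan, "p": np.nan,
                                "p_adj": np.nan, "n_targets_used": 0,
                                "dropped_targets": len(set(drug_target_table[drug]))}])],
            ignore_index=True,
        )
    return df[["drug_id", "es", "p", "p_adj", "n_targets_used", "dropped_targets"]]
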