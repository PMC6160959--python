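"""Overlap-based enrichment: Fisher's exact test and BH adjustment.

Conventional pathway enrichment asks whether a query gene set overlaps
a pathway's members more than expected by chance in a fixed gene
universe, via the hypergeometric (Fisher's exact) test.  This is the
baseline the proximity-based pathway span is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "EnrichmentRecord",
    "fisher_exact",
    "overlap_enrichment",
    "bh_adjust",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 membership table for two sets in a common universe."""

    both: int
    only_a: int
    only_b: int
    neither: int

    def __post_init__(self) -> None:
        cells = (self.both, self.only_a, self.only_b, self.neither)
        if any(c < 0 for c in cells):
            raise ValueError(f"negative cell in contingency table: {cells}")
        if sum(cells) == 0:
            raise ValueError("contingency table is all zeros")

    @classmethod
    def from_sets(cls, a: set, b: set, universe: set) -> "ContingencyTable":
        a, b = set(a) & set(universe), set(b) & set(universe)
        both = len(a & b)
        return cls(
            both=both,
            only_a=len(a) - both,
            only_b=len(b) - both,
            neither=len(universe) - len(a | b),
        )


@dataclass(frozen=True)
class EnrichmentRecord:
    set_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    p_adj: float
    significant: bool


def fisher_exact(
    table: ContingencyTable, alternative: str = "greater"
) -> float:
    """Fisher's exact test p-value on a 2x2 table.

    ``alternative="greater"`` gives the one-sided upper hypergeometric
    tail (enrichment); ``"two-sided"`` sums the probabilities of all
    tables with the same margins whose point probability does not
    exceed the observed one.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unsupported alternative {alternative!r}")
    _, p = scipy.stats.fisher_exact(
        [[table.both, table.only_a], [table.only_b, table.neither]],
        alternative=alternative,
    )
    return float(p)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    Returns adjusted p-values in the input order, monotonicity
    enforced and capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in p_adj]


def overlap_enrichment(
    query: Iterable,
    pathways,
    universe: Iterable,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """One-sided Fisher overlap enrichment of a query set in each pathway.

    All sets are restricted to the universe; query genes outside it are
    dropped with a warning.  Records carry BH-adjusted p-values and are
    sorted by p, ties broken by set id.
    """
    import warnings

    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
    query &= universe

    rows: list[tuple[str, int, int, float]] = []
    for pid, genes in pathways:
        members = set(genes) & universe
        table = ContingencyTable.from_sets(query, members, universe)
        rows.append((pid, table.both, len(members), fisher_exact(table, "greater")))

    p_adj = bh_adjust([r[3] for r in rows])
    records = [
        EnrichmentRecord(
            set_id=pid,
            overlap=overlap,
            set_size=size,
            query_size=len(query),
            universe_size=len(universe),
            p=p,
            p_adj=pa,
            significant=p <= alpha,
        )
        for (pid, overlap, size, p), pa in zip(rows, p_adj)
    ]
    records.sort(key=lambda r: (r.p, r.set_id))
    return records
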