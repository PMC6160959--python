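"""Readers and writers for GMT pathway collections and two-column TSVs.

Readers reject malformed input with the offending line number rather
than silently coercing; writers emit deterministic column order and
row sort so runs are byte-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "GmtCollection",
    "read_gmt",
    "write_gmt",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "write_span_tsv",
    "write_diseasome_tsv",
    "write_sif",
]


@dataclass
class GmtCollection:
    """Ordered collection of named gene sets (MSigDB GMT dialect).

    Iterating yields ``(set_id, gene_list)`` pairs so a collection can
    be passed anywhere an iterable of pathways is expected; the
    description line is kept in :attr:`descriptions`.
    """

    sets: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add(self, set_id: str, description: str, genes: Sequence[str]) -> None:
        if set_id in self.descriptions:
            raise ValueError(f"duplicate set id {set_id!r}")
        deduped: list[str] = []
        seen = set()
        for gene in genes:
            if gene not in seen:
                seen.add(gene)
                deduped.append(gene)
        if len(deduped) < len(genes):
            warnings.warn(
                f"set {set_id!r}: {len(genes) - len(deduped)} duplicate gene(s) removed",
                stacklevel=2,
            )
        self.sets.append((set_id, tuple(deduped)))
        self.descriptions[set_id] = description

    def __iter__(self) -> Iterator[tuple[str, tuple[str, ...]]]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> tuple[str, ...]:
        for sid, genes in self.sets:
            if sid == set_id:
                return genes
        raise KeyError(set_id)

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.sets]


def read_gmt(path: str | Path) -> GmtCollection:
    """Parse a GMT file: tab-separated name, description, member genes."""
    path = Path(path)
    collection = GmtCollection()
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >= 3 fields, "
                    f"got {len(fields)}"
                )
            set_id, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}: line {lineno}: set {set_id!r} has no genes")
            collection.add(set_id, description, genes)
    return collection


def write_gmt(collection: GmtCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        for set_id, genes in collection:
            desc = collection.descriptions.get(set_id, "")
            handle.write("\t".join([set_id, desc, *genes]) + "\n")


def read_pairs_tsv(path: str | Path) -> dict[str, set]:
    """Read a two-column TSV into a mapping id -> set of genes.

    Rows are grouped by the first column; duplicated rows count once.
    Lines starting with ``#`` are comments.
    """
    path = Path(path)
    mapping: dict[str, set] = {}
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping


def write_pairs_tsv(mapping: Mapping[str, set], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        for key in sorted(mapping):
            for gene in sorted(mapping[key]):
                handle.write(f"{key}\t{gene}\n")


def write_span_tsv(span, path: str | Path) -> None:
    """Write a pathway span as TSV: pathway_id, d_obs, mu, sigma, z, n_random, seed."""
    rows = [
        {
            "pathway_id": pid,
            "d_obs": res.d_obs,
            "mu": res.mu,
            "sigma": res.sigma,
            "z": res.z,
            "n_random": res.n_random,
            "seed": res.seed,
        }
        for pid, res in span.entries
    ]
    pd.DataFrame(
        rows,
        columns=["pathway_id", "d_obs", "mu", "sigma", "z", "n_random", "seed"],
    ).to_csv(path, sep="\t", index=False)


def write_diseasome_tsv(edges, path: str | Path) -> None:
    """Write diseasome edges as TSV with one column per evidence stat."""
    rows = []
    for e in edges:
        rows.append(
            {
                "disease_a": e.pair[0],
                "disease_b": e.pair[1],
                "evidence": ",".join(sorted(e.evidence)),
                "p_genes": e.stats.get("shared_genes", ""),
                "p_symptoms": e.stats.get("shared_symptoms", ""),
                "rr": e.stats.get("comorbidity", ""),
                "p_pathways": e.stats.get("shared_pathways", ""),
            }
        )
    pd.DataFrame(
        rows,
        columns=["disease_a", "disease_b", "evidence", "p_genes",
                 "p_symptoms", "rr", "p_pathways"],
    ).to_csv(path, sep="\t", index=False)


def write_sif(edges, path: str | Path, relation: str = "dd") -> None:
    """Write an edge list in SIF format for network viewers."""
    path = Path(path)
    with path.open("w") as handle:
        for e in edges:
            pair = e.pair if hasattr(e, "pair") else e
            handle.write(f"{pair[0]}\t{relation}\t{pair[1]}\n")
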