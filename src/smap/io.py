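"""Plain-text readers and writers shared across the pipeline.

Formats handled here are deliberately simple: GMT gene-set files, SIF
network edge lists, one-gene-per-line lists, and two-column TSV maps.
Everything heavier (BLAST tabular, manifests) lives next to its consumer.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class GmtRecord:
    """One GMT line: a named gene set with a free-text description."""

    __slots__ = ("name", "description", "genes")

    def __init__(self, name: str, description: str, genes: Sequence[str]):
        self.name = name
        self.description = description
        self.genes = list(genes)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GmtRecord({self.name!r}, n={len(self.genes)})"


def read_gmt(path: str | Path) -> list[GmtRecord]:
    """Read a GMT file: ``name <tab> description <tab> gene1 <tab> gene2 ...``."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=2 tab-separated fields")
            genes = [g for g in parts[2:] if g]
            records.append(GmtRecord(parts[0], parts[1], genes))
    return records


def write_gmt(records: Iterable[tuple[str, str, Iterable[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in records:
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene per line; only the first tab-separated column is used."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.append(line.split("\t")[0])
    return genes


def read_two_column_map(path: str | Path) -> dict[str, str]:
    """TSV ``key <tab> value`` map (protein->gene, clone->gene, orthologs)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            mapping[parts[0]] = parts[1]
    return mapping


def write_sif(edges: Iterable[tuple[str, str, float]], path: str | Path,
              relation: str = "sim") -> None:
    """SIF with a numeric weight appended: ``a <tab> rel <tab> b <tab> w``."""
    with open(path, "w") as fh:
        for a, b, w in edges:
            fh.write(f"{a}\t{relation}\t{b}\t{w:.6g}\n")


def read_sif(path: str | Path) -> list[tuple[str, str, float]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            w = float(parts[3]) if len(parts) > 3 else 1.0
            edges.append((parts[0], parts[2], w))
    return edges


def write_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
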