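"""Gene-module construction.

Two kinds of modules are assembled into one non-redundant collection:

* **Homolog modules** — connected components of a gene-level protein
  similarity graph.  All-against-all protein alignments are reduced to one
  best record per unordered gene pair; pairs aligning with E-value below
  1e-70 and over half their length covered are linked, and components of
  that graph become modules.  Remaining singletons are then folded into the
  module of their best-matching gene under a relaxed cutoff (E < 1e-10,
  coverage >= 50%), iterating to a fixed point.
* **Functional modules** — pathway / complex / interaction gene sets read
  from GMT files, passed through a redundancy filter: walking from the
  smallest set up, a set is dropped if it shares >= 25% of its genes with an
  already-retained functional set, or if more than half of its genes sit in
  a single homolog module (in which case the signal is evolutionary, not
  functional).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io import GmtRecord, read_gmt, write_gmt

log = logging.getLogger(__name__)

# strict thresholds for linking gene pairs into homolog modules
BUILD_EVALUE_MAX = 1e-70
BUILD_COVERAGE_MIN = 0.5  # strict: coverage must exceed this
# relaxed thresholds for folding singletons into existing modules
EXPAND_EVALUE_MAX = 1e-10
EXPAND_COVERAGE_MIN = 0.5  # inclusive: coverage may equal this

SIZE_CLASSES = ("1", "2", "3", "4", "5-10", ">10")


def size_class(n: int) -> str:
    """Module size class used for size-matched null distributions."""
    if n < 1:
        raise ValueError("module size must be >= 1")
    if n <= 4:
        return str(n)
    if n <= 10:
        return "5-10"
    return ">10"


@dataclass(frozen=True)
class ProteinAlignment:
    """One pairwise protein alignment (BLASTP-style)."""

    query_protein: str
    subject_protein: str
    e_value: float
    coverage: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must be in (0, 1]")


@dataclass(frozen=True)
class Module:
    """A named gene set scored as one unit."""

    id: str
    genes: frozenset
    source: str = "homolog"

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"module {self.id!r} has no genes")

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def size_class(self) -> str:
        return size_class(self.size)


@dataclass
class ModuleCollection:
    """Modules plus the gene universe they cover and an exclusion log."""

    modules: list = field(default_factory=list)
    gene_universe: set = field(default_factory=set)
    redundancy_log: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.modules)

    def __len__(self):
        return len(self.modules)

    def by_id(self) -> dict:
        return {m.id: m for m in self.modules}

    def extend(self, modules: Iterable[Module]) -> None:
        for m in modules:
            self.modules.append(m)
            self.gene_universe.update(m.genes)

    def write_gmt(self, path: str | Path) -> None:
        write_gmt(((m.id, m.source, m.genes) for m in self.modules), path)

    def write_redundancy_log(self, path: str | Path) -> None:
        pd.DataFrame(
            self.redundancy_log, columns=["module", "reason", "offending_module"]
        ).to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        counts: dict[str, int] = {}
        for m in self.modules:
            counts[m.source] = counts.get(m.source, 0) + 1
        return {
            "n_modules": len(self.modules),
            "n_genes": len(self.gene_universe),
            "by_source": counts,
            "n_excluded": len(self.redundancy_log),
        }


# ---------------------------------------------------------------------------
# BLAST tabular input


def read_blast_tabular(path: str | Path, coverage_columns: str = "qlen_slen"
                       ) -> list[ProteinAlignment]:
    """Parse 12-column BLAST tabular output plus coverage extension columns.

    ``coverage_columns`` is either ``"qlen_slen"`` (columns 13/14 are query
    and subject sequence lengths; coverage = aligned length / length) or
    ``"qcovs_scovs"`` (columns 13/14 are percent coverages).  The pairwise
    coverage is the minimum of the query- and subject-side values.
    """
    alignments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 14:
                raise ValueError(f"{path}:{lineno}: expected >=14 columns, got {len(parts)}")
            try:
                q, s = parts[0], parts[1]
                alen = float(parts[3])
                evalue = float(parts[10])
                if coverage_columns == "qlen_slen":
                    qlen, slen = float(parts[12]), float(parts[13])
                    cov = min(alen / qlen, alen / slen)
                elif coverage_columns == "qcovs_scovs":
                    cov = min(float(parts[12]), float(parts[13])) / 100.0
                else:
                    raise ValueError(f"unknown coverage_columns {coverage_columns!r}")
                cov = min(cov, 1.0)
            except (ValueError, ZeroDivisionError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            alignments.append(ProteinAlignment(q, s, evalue, cov))
    return alignments


# ---------------------------------------------------------------------------
# homolog modules


def reduce_alignments(alignments: Sequence[ProteinAlignment],
                      protein_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse protein-level alignments to one best record per gene pair.

    The retained record is the most significant one: smallest E-value, ties
    broken by larger coverage, then by lexicographic protein-pair order so
    the reduction is deterministic.  Self gene pairs are dropped; alignments
    naming an unmapped protein are skipped (counted in ``.attrs["n_skipped"]``).
    """
    rows = []
    n_skipped = 0
    for aln in alignments:
        ga = protein_to_gene.get(aln.query_protein)
        gb = protein_to_gene.get(aln.subject_protein)
        if ga is None or gb is None:
            n_skipped += 1
            continue
        if ga == gb:
            continue
        pa, pb = sorted((aln.query_protein, aln.subject_protein))
        if gb < ga:
            ga, gb = gb, ga
        rows.append((ga, gb, aln.e_value, aln.coverage, pa, pb))
    if n_skipped:
        log.warning("reduce_alignments: skipped %d alignments with unmapped proteins",
                    n_skipped)
    df = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "e_value", "coverage", "protein_a", "protein_b"]
    )
    if not df.empty:
        df = df.sort_values(
            ["gene_a", "gene_b", "e_value", "coverage", "protein_a", "protein_b"],
            ascending=[True, True, True, False, True, True],
            kind="mergesort",
        ).drop_duplicates(["gene_a", "gene_b"], keep="first")
    df = df.reset_index(drop=True)
    df.attrs["n_skipped"] = n_skipped
    return df


def _module_id(genes: Iterable[str], prefix: str = "HOM") -> str:
    return f"{prefix}:{min(genes)}"


def build_homolog_modules(best_pairs: pd.DataFrame,
                          genes: Iterable[str] | None = None,
                          e_value_max: float = BUILD_EVALUE_MAX,
                          coverage_min: float = BUILD_COVERAGE_MIN,
                          ) -> tuple[list[Module], set]:
    """Connected components of the strict similarity graph.

    Edges are kept iff ``e_value < e_value_max`` and ``coverage > coverage_min``
    (both strict).  Returns ``(modules, singletons)`` where singletons are the
    genes incident to no kept edge.  ``genes`` extends the universe with genes
    that appear in no pair at all.
    """
    universe = set(genes) if genes is not None else set()
    if not best_pairs.empty:
        universe.update(best_pairs["gene_a"])
        universe.update(best_pairs["gene_b"])

    g = nx.Graph()
    if not best_pairs.empty:
        kept = best_pairs[(best_pairs["e_value"] < e_value_max)
                          & (best_pairs["coverage"] > coverage_min)]
        g.add_edges_from(zip(kept["gene_a"], kept["gene_b"]))

    modules = []
    covered: set = set()
    for comp in nx.connected_components(g):
        covered.update(comp)
        modules.append(Module(_module_id(comp), frozenset(comp), "homolog"))
    modules.sort(key=lambda m: m.id)
    singletons = universe - covered
    return modules, singletons


def expand_singletons(modules: Sequence[Module], singletons: Iterable[str],
                      best_pairs: pd.DataFrame,
                      e_value_max: float = EXPAND_EVALUE_MAX,
                      coverage_min: float = EXPAND_COVERAGE_MIN,
                      ) -> tuple[list[Module], set]:
    """Fold singletons into the module of their best-matching gene.

    A singleton joins the module containing its most similar partner among
    pairs with ``e_value < e_value_max`` and ``coverage >= coverage_min``.
    Module membership is frozen at the start of each sweep, so a singleton
    whose only good partner is another singleton waits until that partner
    has been absorbed; sweeps repeat until no assignment is possible.
    Within a sweep, assignment order is ascending best E-value then gene id
    (deterministic, though under frozen membership order does not matter).
    """
    if best_pairs.empty:
        return list(modules), set(singletons)

    eligible = best_pairs[(best_pairs["e_value"] < e_value_max)
                          & (best_pairs["coverage"] >= coverage_min)]
    # adjacency: gene -> [(e_value, partner)]
    partners: dict[str, list[tuple[float, str]]] = {}
    for ga, gb, ev in zip(eligible["gene_a"], eligible["gene_b"], eligible["e_value"]):
        partners.setdefault(ga, []).append((ev, gb))
        partners.setdefault(gb, []).append((ev, ga))

    membership: dict[str, str] = {}
    genes_of: dict[str, set] = {}
    for m in modules:
        genes_of[m.id] = set(m.genes)
        for gn in m.genes:
            membership[gn] = m.id

    remaining = set(singletons)
    while True:
        snapshot = dict(membership)
        assignments = []  # (best_e, gene, module_id)
        for gene in remaining:
            best = None
            for ev, partner in partners.get(gene, ()):
                mid = snapshot.get(partner)
                if mid is None:
                    continue
                key = (ev, partner)
                if best is None or key < best[0]:
                    best = (key, mid)
            if best is not None:
                assignments.append((best[0][0], gene, best[1]))
        if not assignments:
            break
        for _, gene, mid in sorted(assignments):
            genes_of[mid].add(gene)
            membership[gene] = mid
            remaining.discard(gene)

    out = [Module(m.id, frozenset(genes_of[m.id]), m.source) for m in modules]
    return out, remaining


def build_homolog_collection(best_pairs: pd.DataFrame,
                             genes: Iterable[str] | None = None,
                             include_singletons: bool = True) -> ModuleCollection:
    """Full homolog pipeline: strict components, then singleton expansion."""
    modules, singles = build_homolog_modules(best_pairs, genes)
    modules, singles = expand_singletons(modules, singles, best_pairs)
    coll = ModuleCollection()
    coll.extend(modules)
    if include_singletons:
        coll.extend(Module(f"SGT:{g}", frozenset([g]), "singleton")
                    for g in sorted(singles))
    else:
        coll.gene_universe.update(singles)
    return coll


# ---------------------------------------------------------------------------
# functional modules


def load_functional_modules(paths: Sequence[str | Path],
                            sources: Sequence[str]) -> list[Module]:
    """Load GMT collections, tagging each set with its source label.

    Set names colliding across files are disambiguated by prefixing the
    source label (``GO:cellcycle`` vs ``KEGG:cellcycle``).  Empty sets are
    skipped with a warning.
    """
    if len(paths) != len(sources):
        raise ValueError("paths and sources must have equal length")
    raw: list[tuple[str, str, GmtRecord]] = []
    for path, source in zip(paths, sources):
        for rec in read_gmt(path):
            if not rec.genes:
                log.warning("%s: gene set %r is empty, skipped", path, rec.name)
                continue
            raw.append((rec.name, source, rec))
    name_counts: dict[str, int] = {}
    for name, _, _ in raw:
        name_counts[name] = name_counts.get(name, 0) + 1
    modules = []
    for name, source, rec in raw:
        mid = f"{source}:{name}" if name_counts[name] > 1 else name
        modules.append(Module(mid, frozenset(rec.genes), source))
    return modules


def filter_redundant(functional: Sequence[Module],
                     homolog: Sequence[Module],
                     functional_overlap_max: float = 0.25,
                     homolog_overlap_max: float = 0.5) -> ModuleCollection:
    """Drop redundant functional modules.

    Walking the functional modules from smallest to largest (ties broken by
    id), a module is excluded if it shares >= 25% of its genes with an
    already-retained functional module, or if any single homolog module
    contains strictly more than half of its genes.
    """
    coll = ModuleCollection()
    retained: list[Module] = []
    hom = list(homolog)
    for m in sorted(functional, key=lambda m: (m.size, m.id)):
        excluded = False
        for r in retained:
            if len(m.genes & r.genes) / m.size >= functional_overlap_max:
                coll.redundancy_log.append((m.id, "functional_overlap", r.id))
                excluded = True
                break
        if not excluded:
            for h in hom:
                if len(m.genes & h.genes) / m.size > homolog_overlap_max:
                    coll.redundancy_log.append((m.id, "homolog_overlap", h.id))
                    excluded = True
                    break
        if not excluded:
            retained.append(m)
    coll.extend(retained)
    return coll


def build_collection(homolog: ModuleCollection,
                     functional: Sequence[Module]) -> ModuleCollection:
    """Assemble the non-redundant scoring collection (homolog + functional)."""
    filtered = filter_redundant(functional, homolog.modules)
    coll = ModuleCollection(redundancy_log=list(filtered.redundancy_log))
    coll.extend(homolog.modules)
    coll.extend(filtered.modules)
    return coll
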