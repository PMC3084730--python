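"""The gene-list compendium: studies, redundancy groups, event matrices.

Each study contributes a stem-cell gene list (SGL: genes up-regulated in
the stem population) and usually a differentiated gene list (DGL: genes up
in the differentiated comparison population), each with the universe of
genes the study's platform actually tested.  Highly overlapping lists —
typically the same stem-cell type profiled repeatedly — are clustered into
*groups* so that a heavily re-profiled cell type casts a single vote in
downstream recurrence scoring.

The event matrix for a direction records, per gene and experiment, whether
the gene was up-regulated (1), tested but not up (0), or untested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.stats import hypergeom

from .io import read_gene_list, read_two_column_map, write_sif

log = logging.getLogger(__name__)

SGL = "SGL"
DGL = "DGL"
DIRECTIONS = (SGL, DGL)


@dataclass(frozen=True)
class GeneList:
    """One study's gene list in one direction, with its tested universe."""

    study: str
    cell_type: str
    direction: str
    genes: frozenset
    tested_universe: frozenset

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not self.genes <= self.tested_universe:
            raise ValueError(
                f"{self.study}/{self.direction}: genes must be a subset of the "
                "tested universe")

    @property
    def size(self) -> int:
        return len(self.genes)


class Compendium:
    """All gene lists of a study collection, with group partitions."""

    def __init__(self, gene_lists: Iterable[GeneList],
                 cell_types: Sequence[str] | None = None):
        self._lists: dict[tuple[str, str], GeneList] = {}
        for gl in gene_lists:
            key = (gl.direction, gl.study)
            if key in self._lists:
                raise ValueError(f"duplicate study id {gl.study!r} for {gl.direction}")
            self._lists[key] = gl
        seen_types = sorted({gl.cell_type for gl in self._lists.values()})
        if cell_types is None:
            self.cell_types = seen_types
        else:
            unknown = set(seen_types) - set(cell_types)
            if unknown:
                raise ValueError(f"unknown cell-type labels: {sorted(unknown)}")
            self.cell_types = list(cell_types)
        # direction -> ordered list of frozensets of study ids
        self.groups: dict[str, list[frozenset]] = {}

    # -- access ------------------------------------------------------------

    def studies(self, direction: str) -> list[str]:
        return sorted(s for d, s in self._lists if d == direction)

    def get(self, direction: str, study: str) -> GeneList:
        return self._lists[(direction, study)]

    def lists(self, direction: str) -> list[GeneList]:
        return [self._lists[(direction, s)] for s in self.studies(direction)]

    def universe(self, direction: str | None = None) -> set:
        out: set = set()
        for (d, _), gl in self._lists.items():
            if direction is None or d == direction:
                out.update(gl.tested_universe)
        return out

    @property
    def genome_size(self) -> int:
        return len(self.universe())

    def paired_studies(self) -> list[str]:
        """Studies that have both an SGL and a DGL."""
        return sorted(s for d, s in self._lists
                      if d == SGL and (DGL, s) in self._lists)

    # -- construction helpers ---------------------------------------------

    def subset(self, studies: Iterable[str]) -> "Compendium":
        keep = set(studies)
        sub = Compendium(
            (gl for (d, s), gl in self._lists.items() if s in keep),
            cell_types=self.cell_types)
        for direction, groups in self.groups.items():
            sub.groups[direction] = [g & keep for g in groups if g & keep]
        return sub

    def with_swapped_lists(self, studies: Iterable[str]) -> "Compendium":
        """Replace the SGL of each named study with its DGL (swap control)."""
        swapped = set(studies)
        out_lists = []
        for (d, s), gl in self._lists.items():
            if d == SGL and s in swapped:
                dgl = self._lists.get((DGL, s))
                if dgl is None:
                    raise ValueError(f"study {s!r} has no DGL partner to swap in")
                gl = replace(gl, genes=dgl.genes,
                             tested_universe=gl.tested_universe | dgl.genes)
            out_lists.append(gl)
        out = Compendium(out_lists, cell_types=self.cell_types)
        out.groups = {d: list(g) for d, g in self.groups.items()}
        return out

    def set_groups(self, direction: str, groups: Sequence[Iterable[str]]) -> None:
        studies = set(self.studies(direction))
        flat: list = []
        norm = [frozenset(g) for g in groups]
        for g in norm:
            flat.extend(g)
        if len(flat) != len(set(flat)) or set(flat) != studies:
            raise ValueError("groups must partition the studies of the direction")
        self.groups[direction] = norm

    def groups_for(self, direction: str) -> list[frozenset]:
        """Group partition for a direction; defaults to all-singletons."""
        if direction in self.groups:
            return self.groups[direction]
        return [frozenset([s]) for s in self.studies(direction)]


# ---------------------------------------------------------------------------
# manifest reading


def read_compendium(manifest_path: str | Path) -> Compendium:
    """Load a compendium from a YAML/JSON manifest.

    Manifest schema::

        cell_types: [HSC, ESC, ...]          # optional declared label set
        default_universe: path               # optional platform-wide universe
        gene_map: path                       # optional clone->gene 2-col TSV
        studies:
          - id: study1
            cell_type: HSC
            sgl: sgl1.txt                    # one gene per line
            dgl: dgl1.txt                    # optional
            universe: universe1.txt          # optional, else default_universe

    Genes listed but absent from the declared universe are kept and the
    universe extended (union semantics), with a warning.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "studies" not in manifest:
        raise ValueError(f"{manifest_path}: manifest must define 'studies'")
    base = manifest_path.parent

    gene_map = None
    if manifest.get("gene_map"):
        gene_map = read_two_column_map(base / manifest["gene_map"])

    def load_genes(path):
        genes = read_gene_list(base / path)
        if gene_map is not None:
            mapped = [gene_map[g] for g in genes if g in gene_map]
            dropped = len(genes) - len(mapped)
            if dropped:
                log.warning("%s: %d identifiers without a gene mapping dropped",
                            path, dropped)
            genes = mapped
        return set(genes)

    default_universe = None
    if manifest.get("default_universe"):
        default_universe = load_genes(manifest["default_universe"])

    gene_lists = []
    seen_ids = set()
    for entry in manifest["studies"]:
        sid = str(entry["id"])
        if sid in seen_ids:
            raise ValueError(f"duplicate study id {sid!r}")
        seen_ids.add(sid)
        if entry.get("universe"):
            universe = load_genes(entry["universe"])
        elif default_universe is not None:
            universe = set(default_universe)
        else:
            raise ValueError(f"study {sid!r}: no universe and no default_universe")
        for direction, key in ((SGL, "sgl"), (DGL, "dgl")):
            if not entry.get(key):
                continue
            genes = load_genes(entry[key])
            extra = genes - universe
            if extra:
                log.warning("study %s/%s: %d genes outside declared universe; "
                            "universe extended", sid, direction, len(extra))
            gene_lists.append(GeneList(sid, str(entry["cell_type"]), direction,
                                       frozenset(genes),
                                       frozenset(universe | genes)))
    return Compendium(gene_lists, cell_types=manifest.get("cell_types"))


def write_compendium(compendium: Compendium, outdir: str | Path) -> Path:
    """Write a compendium as per-study gene-list files plus a YAML manifest
    (the same format :func:`read_compendium` loads).  Returns the manifest
    path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    studies = []
    for sid in sorted({s for d in DIRECTIONS for s in compendium.studies(d)}):
        entry: dict = {"id": sid}
        universe: set = set()
        for direction, key in ((SGL, "sgl"), (DGL, "dgl")):
            try:
                gl = compendium.get(direction, sid)
            except KeyError:
                continue
            entry["cell_type"] = gl.cell_type
            fname = f"{sid}_{key}.txt"
            (outdir / fname).write_text("\n".join(sorted(gl.genes)) + "\n")
            entry[key] = fname
            universe |= set(gl.tested_universe)
        uname = f"{sid}_universe.txt"
        (outdir / uname).write_text("\n".join(sorted(universe)) + "\n")
        entry["universe"] = uname
        studies.append(entry)
    manifest = {"cell_types": list(compendium.cell_types), "studies": studies}
    path = outdir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# list-overlap statistics and grouping


def overlap_pvalue(n: int, m: int, k: int, genome: int) -> float:
    """Upper-tail hypergeometric P(K >= k) for the overlap of two gene sets
    of sizes ``n`` and ``m`` drawn from a genome of ``genome`` genes."""
    if n > genome or m > genome:
        raise ValueError("list sizes cannot exceed the genome size")
    if k < 0 or k > min(n, m):
        raise ValueError("overlap must satisfy 0 <= k <= min(n, m)")
    return float(hypergeom.sf(k - 1, genome, n, m))


def detect_groups(compendium: Compendium, direction: str = SGL,
                  threshold: float = 1e-50,
                  genome: int | None = None,
                  force_singletons: Iterable[str] = (),
                  ) -> tuple[list[frozenset], nx.Graph]:
    """Cluster redundant gene lists by overlap significance.

    All list pairs are compared with the hypergeometric overlap P-value; pairs
    with P below ``threshold`` are linked.  Groups are the connected
    components of the subgraph restricted to edges between lists of the same
    cell type; cross-type edges stay in the returned graph (for export) but
    never merge groups.  Studies named in ``force_singletons`` are pinned to
    their own degenerate group regardless of edges, preserving any manual
    curation.  The graph's edges carry ``weight = -log10 P``.
    """
    lists = compendium.lists(direction)
    if genome is None:
        genome = len(compendium.universe(direction))
    g = nx.Graph()
    for gl in lists:
        g.add_node(gl.study, cell_type=gl.cell_type, size=gl.size)
    for i, a in enumerate(lists):
        for b in lists[i + 1:]:
            k = len(a.genes & b.genes)
            p = overlap_pvalue(a.size, b.size, k, genome)
            if p < threshold:
                with np.errstate(divide="ignore"):
                    w = float(-np.log10(p)) if p > 0 else np.inf
                g.add_edge(a.study, b.study, weight=w,
                           same_type=a.cell_type == b.cell_type)

    pinned = set(force_singletons)
    same = nx.Graph()
    same.add_nodes_from(s for s in g.nodes if s not in pinned)
    for a, b, data in g.edges(data=True):
        if data["same_type"] and a not in pinned and b not in pinned:
            same.add_edge(a, b)
    groups = [frozenset(c) for c in nx.connected_components(same)]
    groups.extend(frozenset([s]) for s in sorted(pinned))
    groups.sort(key=lambda c: min(c))
    return groups, g


def export_group_network(graph: nx.Graph, path: str | Path) -> None:
    """Write the list-overlap network as SIF (edge weight = -log10 P)."""
    edges = sorted((a, b, d.get("weight", 1.0)) for a, b, d in graph.edges(data=True))
    write_sif(edges, path, relation="overlap")


def groups_table(groups: Sequence[frozenset]) -> pd.DataFrame:
    rows = [(f"B{i + 1}", s) for i, grp in enumerate(groups) for s in sorted(grp)]
    return pd.DataFrame(rows, columns=["group", "study"])


# ---------------------------------------------------------------------------
# event matrices


class EventMatrix:
    """Genes x experiments up-regulation events for one direction.

    ``X[i, j]`` is True when gene *i* is in experiment *j*'s list;
    ``tested[i, j]`` is True when gene *i* is in experiment *j*'s tested
    universe.  An entry is *untested* (missing) iff ``tested`` is False.
    ``group_ids[j]`` indexes the redundancy group of each experiment and
    ``cell_types[j]`` its stem-cell type.
    """

    def __init__(self, genes: Sequence[str], experiments: Sequence[str],
                 X: np.ndarray, tested: np.ndarray,
                 cell_types: Sequence[str], group_ids: np.ndarray,
                 direction: str = SGL):
        self.genes = list(genes)
        self.experiments = list(experiments)
        self.X = np.asarray(X, dtype=bool)
        self.tested = np.asarray(tested, dtype=bool)
        self.cell_types = list(cell_types)
        self.group_ids = np.asarray(group_ids, dtype=int)
        self.direction = direction
        if self.X.shape != (len(self.genes), len(self.experiments)):
            raise ValueError("X shape mismatch")
        if self.tested.shape != self.X.shape:
            raise ValueError("tested shape mismatch")
        if np.any(self.X & ~self.tested):
            raise ValueError("up-regulated entries must be tested")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def values(self) -> np.ndarray:
        """Float view: 1 up, 0 tested-not-up, NaN untested."""
        out = self.X.astype(float)
        out[~self.tested] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.experiments)

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of the given genes; genes absent from the matrix are
        untested everywhere and simply have no row."""
        return np.array(sorted(self._gene_index[g] for g in genes
                               if g in self._gene_index), dtype=int)

    def subset(self, genes: Iterable[str]) -> "EventMatrix":
        idx = self.gene_indices(genes)
        return EventMatrix([self.genes[i] for i in idx], self.experiments,
                           self.X[idx], self.tested[idx],
                           self.cell_types, self.group_ids, self.direction)

    def with_events(self, X: np.ndarray) -> "EventMatrix":
        return EventMatrix(self.genes, self.experiments, X, self.tested,
                           self.cell_types, self.group_ids, self.direction)


def build_event_matrix(genes: Iterable[str] | None, compendium: Compendium,
                       direction: str = SGL) -> EventMatrix:
    """Assemble the event matrix for a gene set (or, with ``genes=None``,
    the full union universe) over all experiments of a direction."""
    lists = compendium.lists(direction)
    if genes is None:
        gene_order = sorted(compendium.universe(direction))
    else:
        gene_order = sorted(set(genes))
    gidx = {g: i for i, g in enumerate(gene_order)}
    n, j = len(gene_order), len(lists)
    X = np.zeros((n, j), dtype=bool)
    tested = np.zeros((n, j), dtype=bool)
    for col, gl in enumerate(lists):
        rows = [gidx[g] for g in gl.tested_universe if g in gidx]
        tested[rows, col] = True
        rows = [gidx[g] for g in gl.genes if g in gidx]
        X[rows, col] = True
    groups = compendium.groups_for(direction)
    gid = {}
    for i, grp in enumerate(groups):
        for s in grp:
            gid[s] = i
    group_ids = np.array([gid[gl.study] for gl in lists], dtype=int)
    return EventMatrix(gene_order, [gl.study for gl in lists], X, tested,
                       [gl.cell_type for gl in lists], group_ids, direction)
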