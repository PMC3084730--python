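"""Orchestration: expression-map network, category enrichment, pipeline.

`run_pipeline` chains the full analysis — load modules and compendium,
detect gene-list groups, score and classify every module, build the
stemness signature, optionally score query pairs, export the
module-correlation network and per-module category enrichments — writing
every result table under a single output directory together with a
MANIFEST recording the completed stages and the exact parameter set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.stats import hypergeom

from . import __version__
from .compendium import (DGL, SGL, Compendium, build_event_matrix, detect_groups,
                         export_group_network, groups_table, read_compendium)
from .inference import ScoringParams, score_and_classify
from .io import read_gene_list, read_gmt, write_json, write_sif
from .modulekit import Module
from .stemness import Signature, build_signature, score_query_pair

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# module expression profiles and the correlation network


def module_profiles(modules: Sequence[Module], compendium: Compendium,
                    direction: str = SGL) -> pd.DataFrame:
    """Per-module vector of up-regulated fractions per cell type.

    Entry (M, l) is the pooled fraction of 1-entries among module M's tested
    entries across the experiments of cell type l (NaN when untested)."""
    em = build_event_matrix(None, compendium, direction)
    ct = np.asarray(em.cell_types)
    out = pd.DataFrame(index=[m.id for m in modules],
                       columns=compendium.cell_types, dtype=float)
    for m in modules:
        sub = em.subset(m.genes)
        for lab in compendium.cell_types:
            cols = np.flatnonzero(ct == lab)
            n_tested = int(sub.tested[:, cols].sum())
            out.loc[m.id, lab] = (sub.X[:, cols].sum() / n_tested
                                  if n_tested else np.nan)
    return out


def correlation_network(profiles: pd.DataFrame,
                        recurrent: Mapping[str, bool],
                        r_min: float = 0.8,
                        status: Mapping[str, str] | None = None) -> nx.Graph:
    """Pearson-correlation network over module expression profiles.

    An edge is kept iff r strictly exceeds ``r_min`` and at least one
    endpoint is recurrent.  Zero-variance or all-NaN profiles cannot be
    correlated and are excluded with a warning.  Node attributes carry the
    recurrence flag and, when given, the stemness status.
    """
    vals = profiles.to_numpy(dtype=float)
    if vals.size == 0:
        return nx.Graph()
    any_data = ~np.isnan(vals).all(axis=1)
    row_mean = np.zeros((vals.shape[0], 1))
    row_mean[any_data, 0] = [np.nanmean(row) for row in vals[any_data]]
    filled = np.where(np.isnan(vals), row_mean, vals)
    ok = any_data & (filled.std(axis=1) > 0)
    dropped = [mid for mid, keep in zip(profiles.index, ok) if not keep]
    if dropped:
        log.warning("correlation_network: %d zero-variance/empty profiles "
                    "excluded: %s ...", len(dropped), dropped[:5])
    ids = [mid for mid, keep in zip(profiles.index, ok) if keep]
    g = nx.Graph()
    for mid in ids:
        g.add_node(mid, recurrent=bool(recurrent.get(mid, False)),
                   status=(status or {}).get(mid, "none"))
    if len(ids) < 2:
        return g
    r = np.corrcoef(filled[ok])
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            if r[i, j] > r_min and (recurrent.get(a, False)
                                    or recurrent.get(b, False)):
                g.add_edge(a, b, weight=float(r[i, j]))
    return g


def export_network(g: nx.Graph, sif_path: str | Path,
                   graphml_path: str | Path | None = None) -> None:
    edges = sorted((a, b, d["weight"]) for a, b, d in g.edges(data=True))
    write_sif(edges, sif_path, relation="corr")
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)


# ---------------------------------------------------------------------------
# category enrichment


def enrich_categories(module: Module, categories: Sequence[Module],
                      annotated_universe: Iterable[str],
                      max_category_size: int = 100,
                      alpha: float = 0.01) -> pd.DataFrame:
    """Hypergeometric enrichment of one module against functional categories.

    Categories larger than ``max_category_size`` are excluded before
    testing; Bonferroni correction multiplies by the number of categories
    actually tested for this module; significance is corrected P < alpha.
    """
    columns = ["module", "category", "overlap", "module_size", "category_size",
               "universe", "p", "p_bonferroni", "significant"]
    universe = set(annotated_universe)
    N = len(universe)
    mod_genes = module.genes & universe
    rows = []
    tested = [c for c in categories if 0 < len(c.genes & universe) <= max_category_size]
    if not mod_genes or not tested:
        return pd.DataFrame(columns=columns)
    n = len(mod_genes)
    n_tests = len(tested)
    for cat in tested:
        cat_genes = cat.genes & universe
        k = len(mod_genes & cat_genes)
        p = float(hypergeom.sf(k - 1, N, n, len(cat_genes)))
        p_adj = min(1.0, p * n_tests)
        rows.append({"module": module.id, "category": cat.id, "overlap": k,
                     "module_size": n, "category_size": len(cat_genes),
                     "universe": N, "p": p, "p_bonferroni": p_adj,
                     "significant": bool(p_adj < alpha)})
    return pd.DataFrame(rows, columns=columns).sort_values("p").reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Everything one full run needs; loadable from YAML/JSON."""

    compendium_manifest: str
    modules_gmt: str
    output_dir: str = "smap_out"
    params: ScoringParams = field(default_factory=ScoringParams)
    group_threshold: float = 1e-50
    group_force_singletons: tuple = ()
    reuse_sgl_groups_for_dgl: bool = False
    network_r_min: float = 0.8
    categories_gmt: str | None = None
    max_category_size: int = 100
    enrichment_alpha: float = 0.01
    queries: tuple = ()            # of dicts: id, plus, minus[, universe]
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: pipeline config must be a mapping")
        for key in ("compendium_manifest", "modules_gmt"):
            if key not in raw:
                raise ValueError(f"{path}: config missing required key {key!r}")
        base = Path(path).parent

        def resolve(p):
            return str((base / p)) if p and not Path(p).is_absolute() else p

        params = raw.get("params", {})
        cfg = cls(
            compendium_manifest=resolve(raw["compendium_manifest"]),
            modules_gmt=resolve(raw["modules_gmt"]),
            output_dir=resolve(raw.get("output_dir", "smap_out")),
            params=ScoringParams(**{**params,
                                    "seed": params.get("seed", raw.get("seed", 0))}),
            group_threshold=float(raw.get("group_threshold", 1e-50)),
            group_force_singletons=tuple(raw.get("group_force_singletons", ())),
            reuse_sgl_groups_for_dgl=bool(raw.get("reuse_sgl_groups_for_dgl", False)),
            network_r_min=float(raw.get("network_r_min", 0.8)),
            categories_gmt=resolve(raw.get("categories_gmt")),
            max_category_size=int(raw.get("max_category_size", 100)),
            enrichment_alpha=float(raw.get("enrichment_alpha", 0.01)),
            queries=tuple({**q, "plus": resolve(q["plus"]),
                           "minus": resolve(q["minus"])}
                          for q in raw.get("queries", ())),
            seed=int(raw.get("seed", 0)),
        )
        return cfg


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_modules_gmt(path: str | Path) -> list[Module]:
    """Modules from GMT; the description column carries the source tag."""
    return [Module(rec.name, frozenset(rec.genes), rec.description or "homolog")
            for rec in read_gmt(path)]


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Execute the full analysis and write all result tables.

    Returns a dict with the in-memory results (``calls``, ``signature``,
    ``network``, ``enrichment``, ``queries``, ``outputs``).  Any stage
    failure raises :class:`PipelineError`; partial outputs are kept and the
    MANIFEST lists the stages that completed.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    outputs: dict[str, str] = {}
    results: dict = {"outputs": outputs}

    def manifest():
        write_json({"schema_version": SCHEMA_VERSION,
                    "smap_version": __version__,
                    "stages_completed": completed,
                    "params": config.params.to_dict(),
                    "seed": config.seed,
                    "outputs": outputs}, outdir / "MANIFEST.json")

    def stage(name):
        def deco(fn):
            try:
                fn()
            except PipelineError:
                raise
            except Exception as exc:
                manifest()
                raise PipelineError(name, exc) from exc
            completed.append(name)
            manifest()
        return deco

    state: dict = {}

    @stage("load")
    def _load():
        state["compendium"] = read_compendium(config.compendium_manifest)
        state["modules"] = load_modules_gmt(config.modules_gmt)

    @stage("groups")
    def _groups():
        comp = state["compendium"]
        for direction in (SGL, DGL):
            if not comp.studies(direction):
                continue
            if direction == DGL and config.reuse_sgl_groups_for_dgl:
                dgl = set(comp.studies(DGL))
                groups = [g & dgl for g in comp.groups_for(SGL) if g & dgl]
                comp.set_groups(DGL, groups)
                continue
            groups, graph = detect_groups(
                comp, direction, threshold=config.group_threshold,
                force_singletons=config.group_force_singletons)
            comp.set_groups(direction, groups)
            sif = outdir / f"gene_list_network_{direction}.sif"
            export_group_network(graph, sif)
            outputs[f"group_network_{direction}"] = sif.name
            tsv = outdir / f"groups_{direction}.tsv"
            groups_table(groups).to_csv(tsv, sep="\t", index=False)
            outputs[f"groups_{direction}"] = tsv.name

    @stage("score_classify")
    def _score():
        calls = score_and_classify(state["modules"], state["compendium"],
                                   config.params)
        state["calls"] = results["calls"] = calls
        path = outdir / "module_calls.tsv"
        calls.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs["module_calls"] = path.name

    @stage("signature")
    def _signature():
        calls = state["calls"]
        by_id = {m.id: m for m in state["modules"]}
        try:
            sig = build_signature(calls, by_id, state["compendium"].universe())
        except ValueError as exc:
            log.warning("signature not built: %s", exc)
            results["signature"] = None
            return
        results["signature"] = sig
        path = outdir / "signature.json"
        sig.to_json(path)
        outputs["signature"] = path.name

    @stage("queries")
    def _queries():
        sig: Signature | None = results.get("signature")
        if not config.queries or sig is None:
            return
        rows = []
        for i, q in enumerate(config.queries):
            qp = set(read_gene_list(q["plus"]))
            qm = set(read_gene_list(q["minus"]))
            universe = (set(read_gene_list(q["universe"]))
                        if q.get("universe") else None)
            rec = score_query_pair(qp, qm, sig, tested_universe=universe,
                                   seed=config.seed + i)
            rec["query"] = q.get("id", f"query{i + 1}")
            rows.append(rec)
        table = pd.DataFrame(rows)
        results["queries"] = table
        path = outdir / "query_scores.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs["queries"] = path.name

    @stage("network")
    def _network():
        calls = state["calls"]
        profiles = module_profiles(state["modules"], state["compendium"], SGL)
        recurrent = dict(zip(calls["module"],
                             calls["FDR_S"] < config.params.fdr_max))
        status = dict(zip(calls["module"], calls["status"]))
        g = correlation_network(profiles, recurrent, config.network_r_min, status)
        results["network"] = g
        sif = outdir / "module_network.sif"
        export_network(g, sif, outdir / "module_network.graphml")
        outputs["network_sif"] = sif.name
        outputs["network_graphml"] = "module_network.graphml"

    @stage("enrichment")
    def _enrichment():
        if not config.categories_gmt:
            return
        categories = load_modules_gmt(config.categories_gmt)
        universe = set().union(*(c.genes for c in categories))
        tables = [enrich_categories(m, categories, universe,
                                    config.max_category_size,
                                    config.enrichment_alpha)
                  for m in state["modules"]]
        table = pd.concat([t for t in tables if not t.empty],
                          ignore_index=True) if tables else pd.DataFrame()
        results["enrichment"] = table
        path = outdir / "enrichment.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs["enrichment"] = path.name

    return results
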