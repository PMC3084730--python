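"""Significance and pattern calls for module recurrence.

Empirical FDRs come from label permutations of the event matrix that
preserve (a) each experiment's number of up-regulated genes and (b) the
correlation structure of redundant gene-list groups: within a group, gene
labels are permuted jointly over the genes tested by every member, and
privately within each member's remaining tested genes.  Because module
scores scale with module size, nulls are stratified into six size classes
(1, 2, 3, 4, 5-10, >10).

Diversity scores are entropies of a module's pooled up-regulation events:
*cell-diversity* (bits) over stem-cell types — high when a similar fraction
of the module is up across many cell types — and *gene-diversity*
(normalised to [0, 1]) over member genes — high when many genes share the
events rather than one dominant gene.  Together with a specificity call
from the DGL-side FDR these place each recurrent module into one of six
idealised patterns (AFA, OFA, CM, CG, AFO, OFO); cell-type-diverse and
specific AFA/OFA modules are the stemness calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .compendium import DGL, SGL, Compendium, EventMatrix, build_event_matrix
from .modulekit import SIZE_CLASSES, size_class
from .scoring import (DEFAULT_Q, DEFAULT_SCHEME, experiment_weights, gene_score,
                      module_index_arrays, module_recurrences, signal_strengths)

PATTERNS = ("AFA", "OFA", "CM", "CG", "AFO", "OFO")
CELL_DIVERSITY_BITS = 2.5
GENE_DIVERSITY_MIN = 0.5


# ---------------------------------------------------------------------------
# permutation null


def permute_events(em: EventMatrix, rng: np.random.Generator) -> np.ndarray:
    """One permuted event matrix (bool array, same shape as ``em.X``).

    Per group: a single random permutation of gene labels over the
    intersection of the members' tested universes is applied jointly to all
    member experiments; genes tested only by some members are permuted
    within each member's private tested set.  Per-experiment up-counts are
    preserved exactly, as is duplication structure within groups.
    """
    X = em.X
    out = np.zeros_like(X)
    for gid in np.unique(em.group_ids):
        cols = np.flatnonzero(em.group_ids == gid)
        common = em.tested[:, cols].all(axis=1)
        idx = np.flatnonzero(common)
        if idx.size:
            perm = idx[rng.permutation(idx.size)]
            out[np.ix_(idx, cols)] = X[np.ix_(perm, cols)]
        for col in cols:
            priv = np.flatnonzero(em.tested[:, col] & ~common)
            if priv.size:
                perm = priv[rng.permutation(priv.size)]
                out[priv, col] = X[perm, col]
    return out


@dataclass
class FdrResult:
    """Per-module empirical FDRs plus per-size-class critical values."""

    observed: np.ndarray
    fdr: np.ndarray
    classes: list
    critical_values: dict
    permutations: int


def _fdr_at(c: float, sorted_perm: np.ndarray, sorted_obs: np.ndarray,
            P: int) -> float:
    """FDR(c) = (mean permuted count >= c) / (observed count >= c)."""
    num = (sorted_perm.size - np.searchsorted(sorted_perm, c, side="left")) / P
    den = sorted_obs.size - np.searchsorted(sorted_obs, c, side="left")
    if den == 0:
        return np.nan
    return float(min(max(num / den, 0.0), 1.0))


def recurrence_fdr(em: EventMatrix, z: np.ndarray, modules: Sequence,
                   q: float = DEFAULT_Q, permutations: int = 1000,
                   rng: np.random.Generator | None = None,
                   fdr_target: float = 0.05) -> FdrResult:
    """Observed recurrence and size-class empirical FDR for each module."""
    if rng is None:
        rng = np.random.default_rng(0)
    u = experiment_weights(em)
    scores = gene_score(em, u, z)
    scored = scores.T > 0
    w = u * np.asarray(z, dtype=float)[None, :]
    T = scores.T
    idx_arrays = module_index_arrays(em, modules)
    observed = module_recurrences(scores.ratio, scored, idx_arrays, q)
    classes = [m.size_class for m in modules]

    by_class: dict[str, np.ndarray] = {
        k: np.flatnonzero([c == k for c in classes]) for k in SIZE_CLASSES}
    perm_scores: dict[str, list] = {k: [] for k in SIZE_CLASSES}
    with np.errstate(invalid="ignore", divide="ignore"):
        for _ in range(permutations):
            Xp = permute_events(em, rng)
            G = (w * Xp).sum(axis=1)
            ratio = np.where(scored, G / np.where(T > 0, T, 1.0), 0.0)
            powered = ratio ** q
            r = np.array([powered[idx].sum() if idx.size else 0.0
                          for idx in idx_arrays])
            for k, rows in by_class.items():
                if rows.size:
                    perm_scores[k].append(r[rows])

    fdr = np.full(len(modules), np.nan)
    critical: dict[str, float] = {}
    for k, rows in by_class.items():
        if not rows.size:
            continue
        sorted_obs = np.sort(observed[rows])
        sorted_perm = np.sort(np.concatenate(perm_scores[k]))
        for i in rows:
            fdr[i] = _fdr_at(observed[i], sorted_perm, sorted_obs, permutations)
        c_star = np.inf
        for c in np.unique(sorted_obs):
            val = _fdr_at(c, sorted_perm, sorted_obs, permutations)
            if not np.isnan(val) and val <= fdr_target:
                c_star = float(c)
                break
        critical[k] = c_star
    return FdrResult(observed, fdr, classes, critical, permutations)


# ---------------------------------------------------------------------------
# diversity


@dataclass
class DiversityScores:
    """Entropy of a module's pooled event fractions."""

    bits: float
    normalized: float
    fractions: dict = field(default_factory=dict)
    no_signal: bool = False


def cell_diversity(em: EventMatrix, n_cell_types: int | None = None
                   ) -> DiversityScores:
    """Entropy (bits) of a module's up-events across stem-cell types.

    For each cell type *l*, ``f_l`` is the pooled fraction of 1-entries
    among the module genes' tested entries across the experiments of type
    *l*; cell types with no tested entries are excluded.  The relative
    frequencies f_l / sum(f) enter a Shannon entropy, normalised by
    log2(number of cell types) for the [0, 1] version.
    """
    labels = sorted(set(em.cell_types))
    if n_cell_types is None:
        n_cell_types = len(labels)
    ct = np.asarray(em.cell_types)
    f: dict[str, float] = {}
    for lab in labels:
        cols = np.flatnonzero(ct == lab)
        n_tested = int(em.tested[:, cols].sum())
        if n_tested == 0:
            continue
        f[lab] = float(em.X[:, cols].sum()) / n_tested
    total = sum(f.values())
    if total == 0 or not f:
        return DiversityScores(0.0, 0.0, f, no_signal=True)
    probs = np.array([v / total for v in f.values()])
    probs = probs[probs > 0]
    bits = float(max(0.0, -(probs * np.log2(probs)).sum()))
    norm = bits / np.log2(n_cell_types) if n_cell_types > 1 else 0.0
    return DiversityScores(bits, float(norm), f)


def gene_diversity(em: EventMatrix) -> DiversityScores:
    """Entropy of event spread across a module's member genes (the same
    calculation on the transpose of the event matrix), normalised by
    log2(module size); 0 by convention for single-gene modules."""
    n = len(em.genes)
    tested_per_gene = em.tested.sum(axis=1)
    ups = em.X.sum(axis=1)
    f = np.zeros(n)
    ok = tested_per_gene > 0
    f[ok] = ups[ok] / tested_per_gene[ok]
    total = f.sum()
    fractions = {g: float(v) for g, v in zip(em.genes, f)}
    if total == 0:
        return DiversityScores(0.0, 0.0, fractions, no_signal=True)
    probs = f / total
    probs = probs[probs > 0]
    bits = float(max(0.0, -(probs * np.log2(probs)).sum()))
    norm = bits / np.log2(n) if n > 1 else 0.0
    return DiversityScores(bits, float(norm), fractions)


def cell_diversity_fdr(em: EventMatrix, modules: Sequence,
                       n_cell_types: int | None = None,
                       permutations: int = 100,
                       rng: np.random.Generator | None = None,
                       step: float = 0.1) -> pd.DataFrame:
    """Empirical FDR for cell-diversity cutoffs, per module size class.

    Sweeps cutoffs from 0 to the entropy ceiling log2(L) and compares, per
    size class, how many permuted versus observed modules reach each
    cutoff.  In practice the curves for different sizes are similar enough
    that a single overall cutoff (2.5 bits for 12 cell types) is used
    operationally; this sweep is the machinery that justifies it.
    Returns a tidy frame: size_class, cutoff, fdr (NaN where no observed
    module reaches the cutoff).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    labels = sorted(set(em.cell_types))
    if n_cell_types is None:
        n_cell_types = len(labels)

    def bits_per_module(X):
        ct = np.asarray(em.cell_types)
        ups = np.column_stack([X[:, np.flatnonzero(ct == lab)].sum(axis=1)
                               for lab in labels]).astype(float)
        tst = np.column_stack([em.tested[:, np.flatnonzero(ct == lab)].sum(axis=1)
                               for lab in labels]).astype(float)
        out = np.zeros(len(modules))
        for i, idx in enumerate(idx_arrays):
            if not idx.size:
                continue
            t = tst[idx].sum(axis=0)
            ok = t > 0
            if not ok.any():
                continue
            f = ups[idx].sum(axis=0)[ok] / t[ok]
            total = f.sum()
            if total <= 0:
                continue
            p = f[f > 0] / total
            out[i] = max(0.0, -(p * np.log2(p)).sum())
        return out

    idx_arrays = module_index_arrays(em, modules)
    observed = bits_per_module(em.X)
    permuted = np.column_stack([bits_per_module(permute_events(em, rng))
                                for _ in range(permutations)])
    classes = np.asarray([m.size_class for m in modules])
    grid = np.arange(0.0, np.log2(n_cell_types) + step / 2, step)
    rows = []
    for k in SIZE_CLASSES:
        sel = classes == k
        if not sel.any():
            continue
        obs_k = observed[sel]
        perm_k = permuted[sel].ravel()
        for c in grid:
            den = (obs_k >= c).sum()
            num = (perm_k >= c).sum() / permutations
            fdr = min(1.0, num / den) if den else np.nan
            rows.append({"size_class": k, "cutoff": float(c), "fdr": fdr})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# specificity and pattern classification


def specificity_class(fdr_s: float, fdr_d: float,
                      recurrent_max: float = 0.05,
                      nonrecurrent_min: float = 0.95) -> str:
    """Stemness specificity from the two recurrence FDRs.

    ``high``: recurrent on the scored side (FDR < 5%) and clearly not on the
    opposite side (FDR > 95%); ``moderate``: recurrent with intermediate
    opposite-side FDR (5%-95%); ``none`` otherwise — including modules
    recurrent on both sides, which are constitutive rather than specific.
    """
    if np.isnan(fdr_s) or np.isnan(fdr_d):
        return "none"
    if fdr_s < recurrent_max:
        if fdr_d > nonrecurrent_min:
            return "high"
        if fdr_d >= recurrent_max:
            return "moderate"
    return "none"


def classify_module(fdr: float, d_cell_bits: float, d_gene_norm: float,
                    specificity: str,
                    fdr_max: float = 0.05,
                    cell_bits_min: float = CELL_DIVERSITY_BITS,
                    gene_div_min: float = GENE_DIVERSITY_MIN) -> str | None:
    """Six-way pattern call for one recurrent module (None if not recurrent).

    Cell-diverse modules (>= 2.5 bits) split into AFA/OFA when specific and
    CM/CG when not, by gene-diversity (>= 0.5 -> many genes contribute);
    lineage-restricted modules split into AFO/OFO by gene-diversity alone.
    """
    if np.isnan(fdr) or fdr >= fdr_max:
        return None
    cell_div = d_cell_bits >= cell_bits_min
    gene_div = d_gene_norm >= gene_div_min
    specific = specificity in ("high", "moderate")
    if cell_div:
        if specific:
            return "AFA" if gene_div else "OFA"
        return "CM" if gene_div else "CG"
    return "AFO" if gene_div else "OFO"


# ---------------------------------------------------------------------------
# full scoring + classification sweep


@dataclass
class ScoringParams:
    """Tunable parameters of the scoring and classification sweep."""

    q: float = DEFAULT_Q
    scheme: str = DEFAULT_SCHEME
    permutations: int = 1000
    fdr_max: float = 0.05
    cell_bits_min: float = CELL_DIVERSITY_BITS
    gene_div_min: float = GENE_DIVERSITY_MIN
    specificity_nonrecurrent_min: float = 0.95
    seed: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def score_and_classify(modules: Sequence, compendium: Compendium,
                       params: ScoringParams | None = None) -> pd.DataFrame:
    """Score every module on both compendia and call stemness patterns.

    Returns one row per module: recurrence and FDR per direction, diversity
    scores, specificity, the SGL- and DGL-side pattern calls, and the final
    ``status`` (stemness_on / stemness_off / none).  A stemness-on call
    requires an AFA/OFA pattern from the SGLs, high or moderate specificity,
    and no pattern call from the DGL side (the DGL veto).
    """
    if params is None:
        params = ScoringParams()
    modules = list(modules)
    ss = np.random.SeedSequence(params.seed)
    rngs = {d: np.random.default_rng(s) for d, s in
            zip((SGL, DGL), ss.spawn(2))}

    per_direction: dict[str, dict] = {}
    for direction in (SGL, DGL):
        if not compendium.studies(direction):
            raise ValueError(f"compendium has no {direction} lists")
        em = build_event_matrix(None, compendium, direction)
        z = signal_strengths(compendium, direction, params.scheme).z
        fdr_res = recurrence_fdr(em, z, modules, q=params.q,
                                 permutations=params.permutations,
                                 rng=rngs[direction],
                                 fdr_target=params.fdr_max)
        n_types = len(compendium.cell_types)
        cell_bits, gene_norm = [], []
        for m in modules:
            sub = em.subset(m.genes)
            if sub.shape[0] == 0:
                cell_bits.append(0.0)
                gene_norm.append(0.0)
                continue
            cell_bits.append(cell_diversity(sub, n_cell_types=n_types).bits)
            gene_norm.append(gene_diversity(sub).normalized)
        per_direction[direction] = {
            "R": fdr_res.observed, "FDR": fdr_res.fdr,
            "D_cell": np.array(cell_bits), "D_gene_norm": np.array(gene_norm),
            "critical": fdr_res.critical_values,
        }

    s, d = per_direction[SGL], per_direction[DGL]
    rows = []
    for i, m in enumerate(modules):
        spec_s = specificity_class(s["FDR"][i], d["FDR"][i],
                                   params.fdr_max,
                                   params.specificity_nonrecurrent_min)
        spec_d = specificity_class(d["FDR"][i], s["FDR"][i],
                                   params.fdr_max,
                                   params.specificity_nonrecurrent_min)
        pattern_s = classify_module(s["FDR"][i], s["D_cell"][i],
                                    s["D_gene_norm"][i], spec_s,
                                    params.fdr_max, params.cell_bits_min,
                                    params.gene_div_min)
        pattern_d = classify_module(d["FDR"][i], d["D_cell"][i],
                                    d["D_gene_norm"][i], spec_d,
                                    params.fdr_max, params.cell_bits_min,
                                    params.gene_div_min)
        status = "none"
        if (pattern_s in ("AFA", "OFA") and spec_s in ("high", "moderate")
                and pattern_d is None):
            status = "stemness_on"
        elif (pattern_d in ("AFA", "OFA") and spec_d in ("high", "moderate")
              and pattern_s is None):
            status = "stemness_off"
        rows.append({
            "module": m.id, "source": m.source, "size": m.size,
            "size_class": m.size_class,
            "R_S": s["R"][i], "FDR_S": s["FDR"][i],
            "R_D": d["R"][i], "FDR_D": d["FDR"][i],
            "D_cell_S": s["D_cell"][i], "D_gene_S_norm": s["D_gene_norm"][i],
            "D_cell_D": d["D_cell"][i], "D_gene_D_norm": d["D_gene_norm"][i],
            "specificity": spec_s, "specificity_D": spec_d,
            "pattern_S": pattern_s, "pattern_D": pattern_d,
            "status": status,
        })
    calls = pd.DataFrame(rows)
    calls.attrs["params"] = params.to_dict()
    calls.attrs["critical_values"] = {SGL: s["critical"], DGL: d["critical"]}
    return calls
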