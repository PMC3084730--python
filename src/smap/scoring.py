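"""Recurrence scoring: signal strengths, group weights, gene scores.

Recurrence is a weighted vote count of a module's up-regulation events
across the compendium.  Each experiment *j* carries a signal strength
``z_j``, a decreasing function of its relative list size ``v_j`` so that
small, specific lists weigh more than broad ones.  Redundant experiments
share a single vote: within a gene-list group, each experiment testing a
gene contributes ``u_ij = 1 / (number of group members testing that gene)``.
The per-gene score

    G_i = sum_j z_j * u_ij * X_ij      with normaliser   T_i = sum_j z_j * u_ij

yields a frequency ratio ``G_i / T_i`` in [0, 1], and module recurrence is

    R(M) = sum_{i in M, T_i > 0} (G_i / T_i) ** q

where the exponent ``q`` controls how much frequently up-regulated genes
dominate.  The default configuration is ``q = 2`` with ``z_j = -log v_j``,
the combination selected by simulation (see :mod:`smap.simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .compendium import Compendium, EventMatrix

Z_SCHEMES = ("neglog", "one_minus", "inverse", "unit")
DEFAULT_SCHEME = "neglog"
DEFAULT_Q = 2.0


def z_from_v(v: np.ndarray, scheme: str = DEFAULT_SCHEME) -> np.ndarray:
    """Signal strength as a function of relative list size v in (0, 1]."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0) or np.any(v > 1):
        raise ValueError("v must lie in (0, 1]")
    if scheme == "neglog":
        return -np.log(v)
    if scheme == "one_minus":
        return 1.0 - v
    if scheme == "inverse":
        return 1.0 / v
    if scheme == "unit":
        return np.ones_like(v)
    raise ValueError(f"unknown z scheme {scheme!r}; choose from {Z_SCHEMES}")


@dataclass
class SignalWeights:
    """Per-experiment relative list sizes and signal strengths."""

    experiments: list
    v: np.ndarray
    z: np.ndarray
    scheme: str


def signal_strengths(compendium: Compendium, direction: str = "SGL",
                     scheme: str = DEFAULT_SCHEME) -> SignalWeights:
    """Compute v_j = |list_j| / |tested universe_j| and z_j per experiment.

    Experiments with an empty list have undefined signal strength; they are
    kept with z = 0 so they carry no weight (equivalent to exclusion).
    """
    lists = compendium.lists(direction)
    experiments = [gl.study for gl in lists]
    v = np.array([gl.size / len(gl.tested_universe) for gl in lists], dtype=float)
    z = np.zeros_like(v)
    ok = v > 0
    z[ok] = z_from_v(v[ok], scheme)
    return SignalWeights(experiments, v, z, scheme)


def experiment_weights(em: EventMatrix) -> np.ndarray:
    """Group weights u_ij = t_ij / (number of experiments in j's group that
    test gene i); 0 where the gene is untested in the whole group."""
    t = em.tested.astype(float)
    n_genes, n_exp = t.shape
    u = np.zeros_like(t)
    for gid in np.unique(em.group_ids):
        cols = np.flatnonzero(em.group_ids == gid)
        counts = t[:, cols].sum(axis=1)  # per-gene tested count within group
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(counts > 0, 1.0 / counts, 0.0)
        u[:, cols] = t[:, cols] * w[:, None]
    return u


@dataclass
class GeneScores:
    """Weighted up-regulation mass G_i and normaliser T_i per gene."""

    genes: list
    G: np.ndarray
    T: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        """G_i / T_i in [0, 1]; 0 where the gene is untested everywhere."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(self.T > 0, self.G / self.T, 0.0)
        return r


def gene_score(em: EventMatrix, u: np.ndarray, z: np.ndarray) -> GeneScores:
    """G_i = sum_j z_j u_ij X_ij and T_i = sum_j z_j u_ij."""
    z = np.asarray(z, dtype=float)
    w = u * z[None, :]
    G = (w * em.X).sum(axis=1)
    T = w.sum(axis=1)
    return GeneScores(list(em.genes), G, T)


def gene_scores_for(em: EventMatrix, z: np.ndarray) -> GeneScores:
    """Convenience: group weights + gene scores in one call."""
    return gene_score(em, experiment_weights(em), z)


@dataclass
class RecurrenceResult:
    """Module recurrence with the configuration that produced it."""

    module_id: str
    value: float
    n_scored: int
    untested: bool
    q: float
    scheme: str


def recurrence(module, scores: GeneScores, q: float = DEFAULT_Q,
               scheme: str = DEFAULT_SCHEME) -> RecurrenceResult:
    """R(M) = sum over the module's tested genes of (G_i/T_i)^q."""
    index = {g: i for i, g in enumerate(scores.genes)}
    idx = np.array([index[g] for g in module.genes if g in index], dtype=int)
    if idx.size:
        T = scores.T[idx]
        ok = T > 0
        ratios = scores.ratio[idx[ok]]
        value = float(np.sum(ratios ** q))
        n_scored = int(ok.sum())
    else:
        value, n_scored = 0.0, 0
    return RecurrenceResult(module.id, value, n_scored, n_scored == 0, q, scheme)


def module_recurrences(ratio: np.ndarray, scored_mask: np.ndarray,
                       module_indices: Sequence[np.ndarray],
                       q: float = DEFAULT_Q) -> np.ndarray:
    """Vectorised recurrence for many modules over a shared ratio vector.

    ``ratio`` and ``scored_mask`` (T_i > 0) are per-gene over the event
    matrix's gene order; ``module_indices`` holds each module's row indices.
    """
    powered = np.where(scored_mask, ratio, 0.0) ** q
    return np.array([powered[idx].sum() if idx.size else 0.0
                     for idx in module_indices])


def module_index_arrays(em: EventMatrix, modules: Iterable) -> list[np.ndarray]:
    """Precompute each module's row indices into an event matrix."""
    return [em.gene_indices(m.genes) for m in modules]
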