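"""Stemness-index scoring of new experiments against the learned signature.

The signature is the pair of module sets called stemness-on (M+) and
stemness-off (M-), each module weighted in proportion to its cell-diversity
so that broadly stemness-general modules dominate.  For a query gene list Q
drawn from a universe of N genes, the weighted overlap with a module set is

    SO(Q) = sum_M w_M * log2( (|M n Q| / |Q|) / (|M n U| / N) )

over modules actually overlapping Q (zero-overlap modules contribute 0) —
a log-likelihood-ratio-style contrast of observed versus chance overlap.
DO is the same score against M-.  Derived scores for a query pair
(Q+ up-regulated, Q- down-regulated):

    SE(Q)  = (SO(Q) - DO(Q)) / 2
    SI     = SE(Q+) - SE(Q-)
    TMO    = (SO(Q+) + SO(Q-) + DO(Q+) + DO(Q-)) / 2

SI is positive when the up list looks stem-like relative to the down list;
TMO measures how much module evidence backs the call at all.  Significance
is judged against size-matched random query pairs via a TMO-windowed null
band, and self-consistency via cross-validation over the compendium.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from hashlib import sha256
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compendium import DGL, SGL, Compendium

log = logging.getLogger(__name__)


@dataclass
class Signature:
    """Weighted stemness-on (M+) and stemness-off (M-) module sets."""

    on_modules: dict      # id -> frozenset of genes
    on_weights: dict      # id -> weight, summing to 1
    off_modules: dict
    off_weights: dict
    universe: frozenset

    def __post_init__(self):
        for weights in (self.on_weights, self.off_weights):
            total = sum(weights.values())
            if weights and not np.isclose(total, 1.0):
                raise ValueError("module weights must sum to 1")
            if any(w < 0 for w in weights.values()):
                raise ValueError("module weights must be nonnegative")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "on": {mid: {"genes": sorted(g), "weight": self.on_weights[mid]}
                   for mid, g in self.on_modules.items()},
            "off": {mid: {"genes": sorted(g), "weight": self.off_weights[mid]}
                    for mid, g in self.off_modules.items()},
            "universe_size": len(self.universe),
            "universe_sha256": sha256(
                "\n".join(sorted(self.universe)).encode()).hexdigest(),
            "universe": sorted(self.universe),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "Signature":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            {mid: frozenset(rec["genes"]) for mid, rec in payload["on"].items()},
            {mid: rec["weight"] for mid, rec in payload["on"].items()},
            {mid: frozenset(rec["genes"]) for mid, rec in payload["off"].items()},
            {mid: rec["weight"] for mid, rec in payload["off"].items()},
            frozenset(payload["universe"]),
        )


def _diversity_weights(ids: Sequence[str], d_cell: Mapping[str, float]) -> dict:
    total = sum(d_cell[m] for m in ids)
    if total <= 0:
        # degenerate: no diversity signal at all -> uniform weights
        return {m: 1.0 / len(ids) for m in ids}
    return {m: d_cell[m] / total for m in ids}


def build_signature(calls: pd.DataFrame, modules_by_id: Mapping,
                    universe: Iterable[str],
                    homolog_only: bool = False) -> Signature:
    """Assemble the signature from a module-call table.

    Weights are proportional to cell-diversity on the side the module was
    called (SGL side for stemness-on, DGL side for stemness-off); modules
    with zero cell-diversity get weight 0.  ``homolog_only`` restricts the
    signature to homolog(+singleton) modules.
    """
    df = calls
    if homolog_only:
        df = df[df["source"].isin(["homolog", "singleton"])]
    on = df[df["status"] == "stemness_on"]
    off = df[df["status"] == "stemness_off"]
    if on.empty or off.empty:
        raise ValueError("signature needs at least one stemness-on and one "
                         "stemness-off module")
    on_ids = list(on["module"])
    off_ids = list(off["module"])
    on_w = _diversity_weights(on_ids, dict(zip(on["module"], on["D_cell_S"])))
    off_w = _diversity_weights(off_ids, dict(zip(off["module"], off["D_cell_D"])))
    get = lambda mid: frozenset(modules_by_id[mid].genes)
    return Signature({m: get(m) for m in on_ids}, on_w,
                     {m: get(m) for m in off_ids}, off_w,
                     frozenset(universe))


# ---------------------------------------------------------------------------
# overlap scores


def overlap_score(query: Iterable[str], module_sets: Mapping,
                  weights: Mapping, universe: frozenset) -> float:
    """Weighted log2 observed/expected overlap of a query with a module set.

    Query genes outside the universe are dropped (with a warning); modules
    with no overlap contribute 0 rather than -inf (absence of evidence).
    """
    q = set(query)
    outside = q - universe
    if outside:
        log.warning("overlap_score: %d query genes outside the universe dropped",
                    len(outside))
        q &= universe
    if not q:
        raise ValueError("query has no genes in the signature universe")
    n_univ = len(universe)
    score = 0.0
    for mid, genes in module_sets.items():
        k = len(genes & q)
        if k == 0:
            continue
        obs = k / len(q)
        exp = len(genes & universe) / n_univ
        score += weights[mid] * np.log2(obs / exp)
    return float(score)


def stemness_overlap(query: Iterable[str], signature: Signature) -> float:
    return overlap_score(query, signature.on_modules, signature.on_weights,
                         signature.universe)


def differentiation_overlap(query: Iterable[str], signature: Signature) -> float:
    return overlap_score(query, signature.off_modules, signature.off_weights,
                         signature.universe)


def stemness_enrichment(query: Iterable[str], signature: Signature) -> float:
    """SE(Q) = (SO(Q) - DO(Q)) / 2."""
    return (stemness_overlap(query, signature)
            - differentiation_overlap(query, signature)) / 2.0


@dataclass
class SIResult:
    """All component scores for one query pair."""

    so_plus: float
    so_minus: float
    do_plus: float
    do_minus: float

    @property
    def se_plus(self) -> float:
        return (self.so_plus - self.do_plus) / 2.0

    @property
    def se_minus(self) -> float:
        return (self.so_minus - self.do_minus) / 2.0

    @property
    def si(self) -> float:
        return self.se_plus - self.se_minus

    @property
    def tmo(self) -> float:
        return (self.so_plus + self.so_minus + self.do_plus + self.do_minus) / 2.0

    def to_dict(self) -> dict:
        return {"SO+": self.so_plus, "SO-": self.so_minus,
                "DO+": self.do_plus, "DO-": self.do_minus,
                "SE+": self.se_plus, "SE-": self.se_minus,
                "SI": self.si, "TMO": self.tmo}


def stemness_index(q_plus: Iterable[str], q_minus: Iterable[str],
                   signature: Signature,
                   ortholog_map: Mapping[str, str] | None = None) -> SIResult:
    """SI for a query pair (up-regulated list Q+, down-regulated list Q-).

    With ``ortholog_map``, query genes are translated before scoring and
    unmapped genes dropped (cross-species queries).
    """
    q_plus, q_minus = set(q_plus), set(q_minus)
    if not q_plus or not q_minus:
        raise ValueError("both query lists must be nonempty")
    if ortholog_map is not None:
        q_plus = translate_query(q_plus, ortholog_map)
        q_minus = translate_query(q_minus, ortholog_map)
        if not q_plus or not q_minus:
            raise ValueError("no query genes survived ortholog translation")
    return SIResult(
        stemness_overlap(q_plus, signature),
        stemness_overlap(q_minus, signature),
        differentiation_overlap(q_plus, signature),
        differentiation_overlap(q_minus, signature),
    )


def translate_query(genes: Iterable[str], ortholog_map: Mapping[str, str]) -> set:
    genes = set(genes)
    mapped = {ortholog_map[g] for g in genes if g in ortholog_map}
    dropped = len(genes) - sum(1 for g in genes if g in ortholog_map)
    if dropped:
        log.warning("translate_query: %d genes without an ortholog dropped", dropped)
    return mapped


# ---------------------------------------------------------------------------
# null band


@dataclass
class NullBand:
    """Size-matched random query pairs: (SI, TMO) points and window stats."""

    si: np.ndarray
    tmo: np.ndarray
    window_width: float = 1.0

    def window_stats(self, tmo: float, min_points: int = 3) -> tuple[float, float]:
        """Mean and sd of null SI in the TMO window centred at ``tmo``;
        the window widens symmetrically until it holds >= ``min_points``."""
        half = self.window_width / 2.0
        while True:
            mask = np.abs(self.tmo - tmo) <= half
            if mask.sum() >= min(min_points, self.si.size):
                break
            half *= 1.5
        vals = self.si[mask]
        sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
        return float(vals.mean()), sd

    def curve(self, step: float = 0.1) -> pd.DataFrame:
        """Windowed mean/sd of SI swept across the null TMO range."""
        lo, hi = self.tmo.min(), self.tmo.max()
        grid = np.arange(lo, hi + step / 2, step)
        rows = [(t, *self.window_stats(t)) for t in grid]
        return pd.DataFrame(rows, columns=["tmo", "mean", "sd"])

    def z_position(self, si: float, tmo: float) -> float:
        mean, sd = self.window_stats(tmo)
        if not sd or np.isnan(sd):
            return np.nan
        return (si - mean) / sd


def null_band(n_plus: int, n_minus: int, tested_universe: Iterable[str],
              signature: Signature, reps: int = 20,
              seed: int | np.random.Generator = 0) -> NullBand:
    """Draw ``reps`` size-matched random query pairs (without replacement
    from the experiment's tested universe) and score them."""
    if n_plus < 1 or n_minus < 1:
        raise ValueError("query sizes must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pool = np.array(sorted(set(tested_universe) & signature.universe))
    if pool.size < max(n_plus, n_minus):
        raise ValueError("tested universe too small for the query sizes")
    si, tmo = [], []
    for _ in range(reps):
        qp = rng.choice(pool, size=n_plus, replace=False)
        qm = rng.choice(pool, size=n_minus, replace=False)
        res = stemness_index(qp, qm, signature)
        si.append(res.si)
        tmo.append(res.tmo)
    return NullBand(np.array(si), np.array(tmo))


def score_query_pair(q_plus: Iterable[str], q_minus: Iterable[str],
                     signature: Signature,
                     tested_universe: Iterable[str] | None = None,
                     reps: int = 20, seed: int = 0) -> dict:
    """SI plus its position in the matched-random null band, as a flat dict."""
    q_plus, q_minus = set(q_plus), set(q_minus)
    res = stemness_index(q_plus, q_minus, signature)
    if tested_universe is None:
        tested_universe = signature.universe
    band = null_band(len(q_plus & signature.universe),
                     len(q_minus & signature.universe),
                     tested_universe, signature, reps=reps, seed=seed)
    mean, sd = band.window_stats(res.tmo)
    out = res.to_dict()
    out.update({"null_mean": mean, "null_sd": sd,
                "z": band.z_position(res.si, res.tmo)})
    return out


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(compendium: Compendium, modules: Sequence,
                   params=None, folds: int = 5, seed: int = 0,
                   scoring_fn=None) -> dict:
    """K-fold self-consistency check of the SE score.

    SGLs with a DGL partner are split into folds; for each fold the full
    module-calling pipeline runs on the remaining studies, a signature is
    built, and SE is computed for every held-out SGL and DGL.  Returns the
    per-list SE table and a Welch two-sample t between held-out SGL and DGL
    SE values (positive t = stem lists score higher).
    """
    from .inference import ScoringParams, score_and_classify
    if params is None:
        params = ScoringParams()
    if scoring_fn is None:
        scoring_fn = score_and_classify
    paired = compendium.paired_studies()
    if len(paired) < folds:
        raise ValueError(f"need >= {folds} paired studies for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(paired))
    fold_of = {paired[i]: int(f) for f, chunk in
               enumerate(np.array_split(order, folds)) for i in chunk}
    all_studies = set(compendium.studies(SGL)) | set(compendium.studies(DGL))
    modules_by_id = {m.id: m for m in modules}

    rows = []
    for fold in range(folds):
        held = sorted(s for s, f in fold_of.items() if f == fold)
        train = compendium.subset(all_studies - set(held))
        fold_params = ScoringParams(**{**params.to_dict(),
                                       "seed": params.seed + fold + 1})
        calls = scoring_fn(modules, train, fold_params)
        try:
            sig = build_signature(calls, modules_by_id, train.universe())
        except ValueError:
            log.warning("fold %d: empty signature, skipped", fold)
            continue
        for study in held:
            for direction in (SGL, DGL):
                gl = compendium.get(direction, study)
                genes = set(gl.genes) & sig.universe
                if not genes:
                    continue
                rows.append({"fold": fold, "study": study,
                             "direction": direction,
                             "SE": stemness_enrichment(genes, sig)})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("cross-validation produced no scored lists")
    se_s = table.loc[table["direction"] == SGL, "SE"]
    se_d = table.loc[table["direction"] == DGL, "SE"]
    t, p = stats.ttest_ind(se_s, se_d, equal_var=False)
    per_study = table.pivot_table(index="study", columns="direction", values="SE")
    both = per_study.dropna() if {SGL, DGL} <= set(per_study.columns) else per_study.iloc[:0]
    frac = float((both[SGL] > both[DGL]).mean()) if len(both) else np.nan
    return {"table": table, "t": float(t), "p": float(p),
            "frac_sgl_above_dgl": frac}
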