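"""Permutation nulls, empirical FDR, diversity scores, pattern calls."""

import numpy as np
import pytest

from smap.compendium import EventMatrix
from smap.inference import (cell_diversity, cell_diversity_fdr, classify_module,
                            gene_diversity, permute_events, recurrence_fdr,
                            specificity_class)
from smap.modulekit import Module


def make_em(X, tested=None, groups=None, cell_types=None):
    X = np.asarray(X, dtype=bool)
    n, j = X.shape
    tested = np.ones_like(X) if tested is None else np.asarray(tested, dtype=bool)
    groups = np.arange(j) if groups is None else np.asarray(groups)
    cell_types = cell_types or [f"ct{c}" for c in range(j)]
    return EventMatrix([f"g{i}" for i in range(n)], [f"e{c}" for c in range(j)],
                       X, tested, cell_types, groups)


class TestPermutation:
    def test_column_sums_preserved(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 6)) < 0.3
        tested = rng.random((30, 6)) < 0.9
        X &= tested
        em = make_em(X, tested=tested, groups=[0, 0, 1, 1, 2, 3])
        Xp = permute_events(em, np.random.default_rng(1))
        assert (Xp.sum(axis=0) == X.sum(axis=0)).all()
        assert not (Xp & ~tested).any()

    def test_group_duplication_preserved(self):
        # two identical lists in one group stay identical after permutation
        rng = np.random.default_rng(2)
        col = rng.random(40) < 0.4
        X = np.column_stack([col, col])
        em = make_em(X, groups=[0, 0])
        Xp = permute_events(em, np.random.default_rng(3))
        assert (Xp[:, 0] == Xp[:, 1]).all()
        assert Xp[:, 0].sum() == col.sum()

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        X = rng.random((25, 5)) < 0.3
        em = make_em(X)
        a = permute_events(em, np.random.default_rng(7))
        b = permute_events(em, np.random.default_rng(7))
        assert (a == b).all()

    def test_private_universe_shuffled_within_itself(self):
        # gene untested by one group member is never "up" there after permuting
        tested = np.array([[1, 1], [1, 0], [1, 1]], dtype=bool)
        X = np.array([[1, 1], [1, 0], [0, 0]], dtype=bool)
        em = make_em(X, tested=tested, groups=[0, 0])
        for seed in range(5):
            Xp = permute_events(em, np.random.default_rng(seed))
            assert not Xp[1, 1]


class TestRecurrenceFdr:
    def test_planted_module_is_significant(self):
        # 20 modules of 4 genes; one has all genes up in all experiments
        rng = np.random.default_rng(1)
        n_modules, size, J = 20, 4, 8
        X = rng.random((n_modules * size, J)) < 0.1
        X[:size] = True
        em = make_em(X)
        modules = [Module(f"m{i}", frozenset(f"g{j}" for j in
                                             range(i * size, (i + 1) * size)))
                   for i in range(n_modules)]
        res = recurrence_fdr(em, np.ones(J), modules, q=2, permutations=100,
                             rng=np.random.default_rng(1))
        assert res.fdr[0] < 0.05
        assert np.nanmean(res.fdr[1:]) > 0.3

    def test_null_self_consistency(self):
        # observed data indistinguishable from its permutations -> high FDRs
        rng = np.random.default_rng(5)
        X = rng.random((60, 10)) < 0.2
        em = make_em(X)
        modules = [Module(f"m{i}", frozenset(f"g{j}" for j in
                                             range(i * 3, (i + 1) * 3)))
                   for i in range(20)]
        res = recurrence_fdr(em, np.ones(10), modules, q=2, permutations=200,
                             rng=np.random.default_rng(6))
        assert np.nanmedian(res.fdr) > 0.4

    def test_fdr_definition_matches_direct_recount(self):
        # FDR at a module's score equals the defining ratio, recomputed
        rng = np.random.default_rng(8)
        X = rng.random((30, 6)) < 0.3
        em = make_em(X)
        modules = [Module(f"m{i}", frozenset(f"g{j}" for j in
                                             range(i * 3, (i + 1) * 3)))
                   for i in range(10)]
        P = 50
        res = recurrence_fdr(em, np.ones(6), modules, q=2, permutations=P,
                             rng=np.random.default_rng(9))
        # recompute the permuted score multiset with the same stream
        from smap.scoring import gene_scores_for, module_recurrences, module_index_arrays
        rng2 = np.random.default_rng(9)
        idx = module_index_arrays(em, modules)
        perms = []
        for _ in range(P):
            Xp = permute_events(em, rng2)
            s = gene_scores_for(em.with_events(Xp), np.ones(6))
            perms.append(module_recurrences(s.ratio, s.T > 0, idx, 2))
        perms = np.concatenate(perms)
        for i in range(10):
            c = res.observed[i]
            num = (perms >= c).sum() / P
            den = (res.observed >= c).sum()
            assert res.fdr[i] == pytest.approx(min(1.0, num / den))


class TestDiversity:
    def test_uniform_twelve_types_reaches_entropy_maximum(self):
        em = make_em(np.ones((3, 12)), cell_types=[f"T{i}" for i in range(12)])
        d = cell_diversity(em)
        assert d.bits == pytest.approx(np.log2(12))
        assert d.normalized == pytest.approx(1.0)

    def test_single_type_zero_bits(self):
        X = np.zeros((3, 6), dtype=bool)
        X[:, 0] = True
        em = make_em(X, cell_types=["A", "A", "B", "B", "C", "C"])
        assert cell_diversity(em).bits == 0.0

    def test_two_equal_types_one_bit(self):
        X = np.zeros((2, 4), dtype=bool)
        X[:, :2] = [[1, 0], [0, 1]]
        X[:, 2:] = [[0, 1], [1, 0]]
        em = make_em(X, cell_types=["A", "A", "B", "B"])
        assert cell_diversity(em).bits == pytest.approx(1.0)

    def test_untested_cell_type_excluded(self):
        tested = np.array([[1, 1, 0], [1, 1, 0]])
        X = np.array([[1, 0, 0], [0, 1, 0]])
        em = make_em(X, tested=tested, cell_types=["A", "B", "C"])
        d = cell_diversity(em)
        assert set(d.fractions) == {"A", "B"}
        assert d.bits == pytest.approx(1.0)

    def test_no_signal_flag(self):
        em = make_em(np.zeros((2, 3)))
        d = cell_diversity(em)
        assert d.bits == 0.0 and d.no_signal

    def test_gene_diversity_extremes(self):
        even = make_em([[1, 0], [0, 1]])
        assert gene_diversity(even).normalized == pytest.approx(1.0)
        skewed = make_em([[1, 1], [0, 0], [0, 0], [0, 0]])
        assert gene_diversity(skewed).normalized == 0.0

    def test_singleton_module_convention(self):
        em = make_em([[1, 0]])
        assert gene_diversity(em).normalized == 0.0


@pytest.mark.parametrize("fdr_s,fdr_d,expected", [
    (0.01, 0.99, "high"),
    (0.01, 0.50, "moderate"),
    (0.01, 0.05, "moderate"),
    (0.01, 0.02, "none"),       # recurrent on both sides: constitutive
    (0.20, 0.99, "none"),       # fails the recurrence gate
    (np.nan, 0.99, "none"),
])
def test_specificity_rules(fdr_s, fdr_d, expected):
    assert specificity_class(fdr_s, fdr_d) == expected


@pytest.mark.parametrize("fdr,d_cell,d_gene,spec,expected", [
    (0.01, 3.0, 0.7, "high", "AFA"),
    (0.01, 3.0, 0.2, "moderate", "OFA"),
    (0.01, 3.0, 0.7, "none", "CM"),
    (0.01, 3.0, 0.2, "none", "CG"),
    (0.01, 1.0, 0.7, "high", "AFO"),
    (0.01, 1.0, 0.2, "high", "OFO"),
    (0.20, 3.0, 0.7, "high", None),   # not recurrent -> unclassified
    (0.01, 2.5, 0.5, "high", "AFA"),  # boundary values are inclusive
])
def test_pattern_classification(fdr, d_cell, d_gene, spec, expected):
    assert classify_module(fdr, d_cell, d_gene, spec) == expected


class TestCellDiversityFdr:
    def test_sweep_supports_the_constant_cutoff(self, synth):
        # at the 2.5-bit cutoff the planted signal stands out: the FDR for
        # large cutoffs is far below the FDR near zero in every size class
        from smap.compendium import build_event_matrix
        em = build_event_matrix(None, synth.compendium, "SGL")
        curve = cell_diversity_fdr(em, synth.modules, n_cell_types=12,
                                   permutations=30,
                                   rng=np.random.default_rng(0))
        assert set(curve.columns) == {"size_class", "cutoff", "fdr"}
        assert curve["cutoff"].max() == pytest.approx(np.log2(12), abs=0.1)
        at_25 = curve[np.isclose(curve["cutoff"], 2.5)].set_index("size_class")
        at_0 = curve[np.isclose(curve["cutoff"], 0.0)].set_index("size_class")
        shared = at_25.index.intersection(at_0.index)
        assert (at_25.loc[shared, "fdr"].fillna(1.0)
                <= at_0.loc[shared, "fdr"]).all()


class TestScoreAndClassify:
    def test_planted_modules_recovered(self, synth, calls):
        merged = calls.merge(synth.truth, on="module")
        on = merged["role"] == "on"
        called = merged["status"] == "stemness_on"
        recall = (on & called).sum() / on.sum()
        precision = (on & called).sum() / max(called.sum(), 1)
        assert recall >= 0.85 and precision >= 0.85

    def test_stemness_on_requires_specificity_and_no_dgl_pattern(self, calls):
        on = calls[calls["status"] == "stemness_on"]
        assert on["specificity"].isin(["high", "moderate"]).all()
        assert on["pattern_S"].isin(["AFA", "OFA"]).all()
        assert on["pattern_D"].isna().all()

    def test_off_calls_mirror_on_rules(self, calls):
        off = calls[calls["status"] == "stemness_off"]
        assert off["pattern_D"].isin(["AFA", "OFA"]).all()
        assert off["specificity_D"].isin(["high", "moderate"]).all()
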