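from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

import ddr
from ddr import DDRError


def brute_force_fisher(table) -> float:
    """Independent oracle: exact rational enumeration of all margin-fixed tables."""
    t = np.asarray(table, dtype=int)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    row = t.sum(axis=1).tolist()
    col = t.sum(axis=0).tolist()
    n = int(t.sum())

    def prob(cells) -> Fraction:
        num = 1
        for r in row:
            num *= factorial(r)
        for c in col:
            num *= factorial(c)
        den = factorial(n)
        for x in cells:
            den *= factorial(x)
        return Fraction(num, den)

    def row_fills(margin, caps):
        if len(caps) == 1:
            if margin <= caps[0]:
                yield (margin,)
            return
        for a in range(min(margin, caps[0]) + 1):
            for rest in row_fills(margin - a, caps[1:]):
                yield (a,) + rest

    def all_tables(i, caps):
        if i == len(row) - 1:
            yield tuple(caps)
            return
        for fill in row_fills(row[i], caps):
            remaining = tuple(c - v for c, v in zip(caps, fill))
            for rest in all_tables(i + 1, remaining):
                yield fill + rest

    p_obs = prob(t.ravel().tolist())
    total = Fraction(0)
    for cells in all_tables(0, tuple(col)):
        p = prob(cells)
        if p <= p_obs:
            total += p
    return float(total)


def random_table(rng, shape, max_total=30):
    while True:
        t = rng.integers(0, 6, size=shape)
        if t.sum() == 0 or t.sum() > max_total:
            continue
        if (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all():
            return t


class TestFisherExact:
    def test_worked_2x2_example(self):
        # margin-fixed 2x2 with both diagonals extreme: probs {1,9,9,1}/20
        res = ddr.fisher_exact(np.array([[3, 0], [0, 3]]))
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.test_method == "exact_enumeration"

    def test_identical_rows_give_p_one(self):
        assert ddr.fisher_exact(np.array([[2, 2], [2, 2]])).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("shape", [(2, 2), (2, 4), (3, 3)])
    def test_enumeration_matches_brute_force_oracle(self, shape):
        rng = np.random.default_rng(17)
        for _ in range(15):
            t = random_table(rng, shape)
            p = ddr.fisher_exact(t).p_value
            assert p == pytest.approx(brute_force_fisher(t), abs=1e-12)

    def test_2x2_matches_scipy(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            t = random_table(rng, (2, 2))
            p = ddr.fisher_exact(t).p_value
            assert p == pytest.approx(scipy_fisher(t)[1], abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(31)
        t = random_table(rng, (3, 4))
        p = ddr.fisher_exact(t).p_value
        assert ddr.fisher_exact(t[::-1]).p_value == pytest.approx(p, abs=1e-12)
        assert ddr.fisher_exact(t[:, ::-1]).p_value == pytest.approx(p, abs=1e-12)
        assert ddr.fisher_exact(t.T).p_value == pytest.approx(p, abs=1e-12)

    def test_zero_margins_dropped_before_testing(self):
        with_zero = np.array([[3, 0, 0], [0, 0, 3]])
        plain = np.array([[3, 0], [0, 3]])
        assert ddr.fisher_exact(with_zero).p_value == pytest.approx(
            ddr.fisher_exact(plain).p_value, abs=1e-12
        )

    def test_degenerate_table_flagged_not_raised(self):
        res = ddr.fisher_exact(np.array([[3, 0], [2, 0]]))
        assert res.p_value == 1.0
        assert res.test_method == "degenerate"

    def test_monte_carlo_agrees_with_enumeration(self):
        rng = np.random.default_rng(41)
        for i in range(10):
            t = random_table(rng, (2, 3))
            p = ddr.fisher_exact(t).p_value
            mc = ddr.fisher_exact(t, mc_threshold=0, mc_reps=50_000, seed=i)
            assert mc.test_method == "monte_carlo"
            bound = 3 * np.sqrt(p * (1 - p) / 50_000) + 2 / 50_000
            assert abs(mc.p_value - p) <= bound

    def test_monte_carlo_three_row_path(self):
        rng = np.random.default_rng(43)
        t = random_table(rng, (3, 3))
        p = ddr.fisher_exact(t).p_value
        mc = ddr.fisher_exact(t, mc_threshold=0, mc_reps=50_000, seed=7)
        assert abs(mc.p_value - p) <= 3 * np.sqrt(p * (1 - p) / 50_000) + 2 / 50_000


class TestExpressionDistance:
    def _table(self, counts):
        counts = np.asarray(counts)
        return ddr.TierContingencyTable("g", ["A", "B"], counts)

    def test_pure_shift(self):
        # A all in tier 2, B all in tier 0 -> ED = 2 regardless of group sizes
        assert ddr.expression_distance(self._table([[0, 0, 3], [4, 0, 0]])) == pytest.approx(2)
        assert ddr.expression_distance(self._table([[0, 0, 7], [2, 0, 0]])) == pytest.approx(2)

    def test_identical_distributions_give_zero(self):
        assert ddr.expression_distance(self._table([[1, 2, 1], [2, 4, 2]])) == pytest.approx(0)

    def test_antisymmetry_and_offset_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(0, 5, size=(2, 4))
            if (t.sum(axis=1) == 0).any():
                continue
            ed = ddr.expression_distance(t)
            assert ddr.expression_distance(t[::-1]) == pytest.approx(-ed)
            # direct evaluation with 1-based tier indices
            j = np.arange(1, 5)
            direct = (t[0] * j).sum() / t[0].sum() - (t[1] * j).sum() / t[1].sum()
            assert ed == pytest.approx(direct)
            # shifting all tiers right by padding a zero column changes nothing
            padded = np.hstack([np.zeros((2, 1), dtype=int), t])
            assert ddr.expression_distance(padded) == pytest.approx(ed)

    def test_requires_two_conditions(self):
        with pytest.raises(DDRError, match="2 conditions"):
            ddr.expression_distance(np.array([[1, 2], [3, 4], [5, 6]]))


class TestAdjustFdr:
    def test_bh_step_up(self):
        np.testing.assert_allclose(ddr.adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_unit_values(self):
        np.testing.assert_allclose(ddr.adjust_fdr([0.2]), [0.2])
        np.testing.assert_allclose(ddr.adjust_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(DDRError, match="0, 1"):
            ddr.adjust_fdr([0.5, 1.5])


class TestRunDE:
    def test_planted_genes_recovered(self, planted_sim, planted_refs):
        _, _, metadata, truth = planted_sim
        norm, refs = planted_refs
        res = ddr.run_de(norm, metadata, refs, "A", "B", seed=1)
        sig = {r.gene_id for r in res if r.fdr < 0.1}
        planted = set(truth.de_genes)
        assert len(sig & planted) / len(planted) >= 0.8
        assert len(sig & planted) / len(sig) >= 0.9

    def test_ed_sign_tracks_planted_direction(self, planted_sim, planted_refs):
        _, _, metadata, truth = planted_sim
        norm, refs = planted_refs
        res = {r.gene_id: r for r in ddr.run_de(norm, metadata, refs, "A", "B", seed=1)}
        # condition A is first: positive lfc (B up) must give negative ED
        for gene, lfc in truth.de_genes.items():
            if res[gene].fdr < 0.1:
                assert np.sign(res[gene].ed) == -np.sign(lfc)

    def test_deterministic_given_seed(self, planted_sim, planted_refs):
        _, _, metadata, _ = planted_sim
        norm, refs = planted_refs
        r1 = ddr.run_de(norm, metadata, refs, "A", "B", seed=9)
        r2 = ddr.run_de(norm, metadata, refs, "A", "B", seed=9)
        assert [(r.gene_id, r.p_value, r.fdr, r.ed) for r in r1] == [
            (r.gene_id, r.p_value, r.fdr, r.ed) for r in r2
        ]

    def test_output_sorted_by_fdr_then_ed(self, planted_sim, planted_refs):
        _, _, metadata, _ = planted_sim
        norm, refs = planted_refs
        res = ddr.run_de(norm, metadata, refs, "A", "B", seed=1)
        keys = [(r.fdr, -abs(r.ed), r.gene_id) for r in res]
        assert keys == sorted(keys)

    def test_sample_column_permutation_is_irrelevant(self, multiclass_fixture):
        matrix, metadata, refs, _ = multiclass_fixture
        sub = ddr.SampleMetadata(metadata.table[metadata.table.isin(["C1", "C2"])])
        r1 = ddr.run_de(matrix, sub, refs, "C1", "C2", seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.sample_ids)
        shuffled = ddr.ExpressionMatrix(values=matrix.values[perm], platform_kind="normalized")
        r2 = ddr.run_de(shuffled, sub, refs, "C1", "C2", seed=4)
        assert [(r.gene_id, r.p_value, r.ed) for r in r1] == [
            (r.gene_id, r.p_value, r.ed) for r in r2
        ]

    def test_missing_condition_rejected(self, planted_sim, planted_refs):
        _, _, metadata, _ = planted_sim
        norm, refs = planted_refs
        with pytest.raises(DDRError, match="not present"):
            ddr.run_de(norm, metadata, refs, "A", "Z", seed=0)


class TestMarkerWorkflows:
    def test_pairwise_union_is_deduplicated(self, multiclass_fixture):
        matrix, metadata, refs, truth = multiclass_fixture
        merged = ddr.pairwise_markers(matrix, metadata, refs, fdr_cut=0.01, ed_cut=1.0, seed=2)
        assert len(merged) == len(set(merged))
        # every planted marker separates its class from the 3 others
        planted = {g for genes in truth.values() for g in genes}
        assert planted <= set(merged)
        # a C1 marker passes in 3 pairs yet appears exactly once
        assert sum(g == truth["C1"][0] for g in merged) == 1

    def test_pairwise_equals_union_of_per_pair_runs(self, multiclass_fixture):
        matrix, metadata, refs, _ = multiclass_fixture
        merged = ddr.pairwise_markers(matrix, metadata, refs, fdr_cut=0.01, ed_cut=1.0, seed=2)
        manual = set()
        conds = metadata.conditions
        for i, a in enumerate(conds):
            for b in conds[i + 1 :]:
                res = ddr.run_de(matrix, metadata, refs, a, b, seed=0)
                manual |= {r.gene_id for r in res if r.fdr <= 0.01 and abs(r.ed) >= 1.0}
        assert set(merged) == manual

    def test_one_vs_rest_recovers_planted_sets(self, multiclass_fixture):
        matrix, metadata, refs, truth = multiclass_fixture
        markers = ddr.one_vs_rest_markers(
            matrix, metadata, refs, per_class_top_k=5, ed_direction="up", seed=5
        )
        for cls, genes in truth.items():
            assert set(markers[cls]) == set(genes)

    def test_exclude_list_removes_and_backfills(self):
        from conftest import make_multiclass_dataset

        matrix, metadata, refs, truth = make_multiclass_dataset(markers_per_class=6, seed=5)
        excluded = truth["C1"][0]
        markers = ddr.one_vs_rest_markers(
            matrix, metadata, refs, per_class_top_k=5, ed_direction="up",
            exclude=[excluded], seed=5,
        )
        assert excluded not in markers["C1"]
        assert len(markers["C1"]) == 5
        assert set(markers["C1"]) <= set(truth["C1"])

    def test_top_k_zero_gives_empty_lists(self, multiclass_fixture):
        matrix, metadata, refs, _ = multiclass_fixture
        markers = ddr.one_vs_rest_markers(matrix, metadata, refs, per_class_top_k=0, seed=1)
        assert all(v == [] for v in markers.values())
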