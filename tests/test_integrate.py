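"""DEG selection, Venn arithmetic, Fisher exact test, correlation mining."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import rankdata

from gselexmine.integrate import (
    IntegrationRecord,
    bh_adjust,
    build_records,
    correlate_parameters,
    expression_mining_run,
    fisher_from_table,
    fisher_motif_presence,
    intersect_sets,
    select_degs,
)
from gselexmine.motifscan import MotifCountVector
from gselexmine.synthetic_data import ExpressionTable


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Integer weights C(r1,k)*C(r2,c1-k) share a common denominator, so the
    'probability <= observed' tie comparison is exact.
    """
    r1, r2, c1 = a + b, c + d, a + c
    ks = range(max(0, c1 - r2), min(r1, c1) + 1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in ks}
    w_obs = weights[a]
    return float(Fraction(sum(w for w in weights.values() if w <= w_obs), sum(weights.values())))


def spearman_oracle(x, y):
    """Average-rank Spearman: product-moment correlation on ranks."""
    rx, ry = rankdata(x), rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def make_record(gene, ratio, n_aa=0, n_ga=0, n_ag=0, fe=None, pos=None, inter=False):
    counts = MotifCountVector(gene, {"GGCTAA": n_aa, "GGCTGA": n_ga, "GGCTAG": n_ag})
    return IntegrationRecord(gene, ratio, counts, fe, pos, inter)


class TestSelectDegs:
    def test_threshold_is_strict(self):
        expr = ExpressionTable({"a": 5.0, "b": 5.1, "c": 0.2})
        assert select_degs(expr, 5.0).genes == {"b"}

    def test_empty_table(self):
        assert select_degs(ExpressionTable({})).genes == set()


class TestIntersectSets:
    def test_basic_set_algebra(self):
        venn, inter = intersect_sets({"A", "B", "C"}, select_degs(
            ExpressionTable({"B": 9, "C": 9, "D": 9})))
        assert venn == (1, 1, 2) and inter == {"B", "C"}

    def test_disjoint_sets(self):
        venn, inter = intersect_sets({"A"}, select_degs(ExpressionTable({"B": 9})))
        assert venn == (1, 1, 0) and inter == set()


class TestFisher:
    def test_printed_contingency_table_is_significant(self):
        res = fisher_from_table(44, 7, 12, 9)
        assert res.p_value < 0.05
        assert 44 / 51 == pytest.approx(0.863, abs=5e-4)
        assert 12 / 21 == pytest.approx(0.571, abs=5e-4)

    def test_degenerate_single_table(self):
        assert fisher_from_table(1, 0, 0, 1).p_value == pytest.approx(1.0)

    def test_diagonal_five_table(self):
        # enumeration over C(10,5) tables: only the two extremes are as unlikely
        assert fisher_from_table(5, 0, 0, 5).p_value == pytest.approx(2 / 252)

    def test_matches_enumeration_oracle_for_all_small_tables(self):
        """Exhaustive check against rational-arithmetic enumeration, N <= 30."""
        for n in range(1, 31):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        res = fisher_from_table(a, b, c, d)
                        assert res.p_value == pytest.approx(
                            fisher_oracle(a, b, c, d), abs=1e-9
                        ), (a, b, c, d)

    def test_partition_both_sides_required(self):
        records = [make_record("a", 9.0, n_aa=1, inter=True)]
        with pytest.raises(ValueError):
            fisher_motif_presence(records)

    def test_motif_presence_table_built_from_records(self):
        records = (
            [make_record(f"i{k}", 9, n_aa=1, inter=True) for k in range(4)]
            + [make_record("i4", 9, inter=True)]
            + [make_record(f"o{k}", 9, n_ga=1) for k in range(2)]
            + [make_record("o2", 9)]
        )
        res = fisher_motif_presence(records)
        assert res.table == ((4, 1), (2, 1))


class TestCorrelations:
    def test_monotone_function_of_expression_has_rho_one(self):
        records = [make_record(f"g{i}", math.exp(i), n_aa=i) for i in range(10)]
        res = {c.parameter: c for c in correlate_parameters(records)}
        assert res["GGCTAA"].spearman_rho == pytest.approx(1.0)

    def test_constant_parameter_flagged_undefined(self):
        records = [make_record(f"g{i}", float(i + 1), n_aa=2) for i in range(5)]
        res = {c.parameter: c for c in correlate_parameters(records)}
        assert not res["GGCTAA"].defined and math.isnan(res["GGCTAA"].spearman_rho)

    def test_spearman_matches_rank_oracle_with_ties(self):
        """500 random tied datasets of n=20 agree with the oracle to 1e-12."""
        rng = np.random.default_rng(99)
        for _ in range(500):
            x = rng.integers(0, 5, size=20).astype(float)
            y = rng.integers(0, 8, size=20).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            records = [make_record(f"g{i}", math.exp(yi), n_aa=int(xi))
                       for i, (xi, yi) in enumerate(zip(x, y))]
            res = {c.parameter: c for c in correlate_parameters(records)}
            assert res["GGCTAA"].spearman_rho == pytest.approx(
                spearman_oracle(x, y), abs=1e-12
            )

    def test_spearman_invariant_pearson_not_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        ratios = np.exp(rng.normal(size=30))
        n_aa = rng.poisson(1.0, size=30)
        rec_lin = [make_record(f"g{i}", r, n_aa=int(k)) for i, (r, k) in enumerate(zip(ratios, n_aa))]
        res_log = {c.parameter: c for c in correlate_parameters(rec_lin, "log")}
        res_lin = {c.parameter: c for c in correlate_parameters(rec_lin, "linear")}
        assert res_log["GGCTAA"].spearman_rho == pytest.approx(
            res_lin["GGCTAA"].spearman_rho, abs=1e-12
        )
        assert res_log["GGCTAA"].pearson_r != pytest.approx(
            res_lin["GGCTAA"].pearson_r, abs=1e-6
        )

    def test_records_without_peaks_dropped_pairwise_for_fe(self):
        records = [make_record(f"g{i}", float(i + 1), n_aa=i, fe=float(i) if i < 5 else None)
                   for i in range(10)]
        res = {c.parameter: c for c in correlate_parameters(records)}
        assert res["fold_enrichment"].n == 5 and res["GGCTAA"].n == 10

    def test_bh_adjustment_monotone_and_bounded(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.5, math.nan])
        assert adj[0] <= adj[1] <= adj[2] <= adj[3] <= 1.0
        assert math.isnan(adj[4])


class TestBuildRecords:
    def test_largest_fe_hit_kept_per_gene(self, small_genome):
        from gselexmine.promannot import PromoterHit
        from gselexmine.tagproc import TagWindow

        win = TagWindow("A" * 50, "chr1", 0, 50, 1)
        hits = [
            PromoterHit(win, "g01", 50, 1.0, 400, fold_enrichment=3.0),
            PromoterHit(win, "g01", 50, 1.0, 600, fold_enrichment=9.0),
        ]
        expr = ExpressionTable({"g01": 7.0})
        counts = {"g01": MotifCountVector("g01", {"GGCTAA": 1})}
        [rec] = build_records(expr, counts, hits, intersection={"g01"})
        assert rec.fold_enrichment == 9.0 and rec.summit_pos == 600
        assert rec.in_intersection


def test_coexistence_flag_dominates_correlation_ordering():
    """Default effect model: GGCTAA & GGCTGA coexistence is the top Spearman."""
    wins = 0
    n_seeds = 25
    for seed in range(n_seeds):
        res = expression_mining_run(72, seed)
        defined = [c for c in res if c.defined]
        best = max(defined, key=lambda c: c.spearman_rho)
        wins += best.parameter == "coex_GGCTGA_GGCTAA"
    assert wins / n_seeds >= 0.8
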