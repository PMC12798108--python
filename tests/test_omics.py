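import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from saltscreen.omics import (
    AnnotationSets,
    bh_adjust,
    hypergeometric_enrichment,
    multiway_overlap,
    screen_dams,
    screen_degs,
)


def gene_stats(rows):
    return pd.DataFrame(rows, columns=["feature", "log2fc", "adj_p"]).assign(kind="gene")


def metab_stats(rows):
    return pd.DataFrame(rows, columns=["feature", "log2fc", "adj_p", "vip"]).assign(
        kind="metabolite"
    )


class TestScreenDegs:
    def test_empty(self):
        assert screen_degs(pd.DataFrame(columns=["feature", "log2fc", "adj_p"])) == (
            set(),
            set(),
        )

    def test_toy_table(self):
        stats = gene_stats(
            [
                ("g1", 2.0, 0.01),
                ("g2", -1.0, 0.04),
                ("g3", 0.5, 0.001),
                ("g4", 3.0, 0.2),
            ]
        )
        up, down = screen_degs(stats)
        assert up == {"g1"}
        assert down == {"g2"}

    def test_boundaries(self):
        stats = gene_stats(
            [
                ("at_fc", 1.0, 0.01),  # |lfc| >= 1 inclusive -> in
                ("below_fc", 0.999, 0.01),  # out
                ("at_p", 2.0, 0.05),  # p < 0.05 strict -> out
                ("just_under_p", 2.0, 0.049999),  # in
                ("neg_at_fc", -1.0, 0.01),  # in (down)
            ]
        )
        up, down = screen_degs(stats)
        assert up == {"at_fc", "just_under_p"}
        assert down == {"neg_at_fc"}

    def test_disjoint(self):
        rng = np.random.default_rng(0)
        stats = gene_stats(
            [(f"g{i}", rng.normal(0, 2), rng.uniform()) for i in range(500)]
        )
        up, down = screen_degs(stats)
        assert not up & down

    def test_malformed_rows_listed(self):
        stats = gene_stats([("good", 2.0, 0.01), ("bad", 2.0, 1.5)])
        with pytest.raises(ValueError, match="bad"):
            screen_degs(stats)

    def test_non_gene_rows_rejected(self):
        stats = gene_stats([("m1", 2.0, 0.01)]).assign(kind="metabolite")
        with pytest.raises(ValueError, match="m1"):
            screen_degs(stats)

    @given(
        stn.lists(
            stn.tuples(stn.floats(-4, 4), stn.floats(0, 1)), min_size=0, max_size=60
        ),
        stn.floats(1.0, 3.0),
        stn.floats(0.001, 0.1),
    )
    @settings(max_examples=60, deadline=None)
    def test_threshold_monotonicity(self, rows, fc_min, p_max):
        stats = gene_stats([(f"g{i}", lfc, p) for i, (lfc, p) in enumerate(rows)])
        up0, down0 = screen_degs(stats, fc_min=1.0, p_max=0.1)
        up1, down1 = screen_degs(stats, fc_min=fc_min, p_max=p_max)
        # tightening both thresholds never adds features
        assert up1 <= up0
        assert down1 <= down0


class TestScreenDams:
    def test_vip_boundary_exclusive_below(self):
        stats = metab_stats([("m1", 5.0, 0.001, 0.99)])
        assert screen_dams(stats) == (set(), set())

    def test_all_boundaries_inclusive(self):
        stats = metab_stats([("m1", -1.0, 0.049, 1.0)])
        up, down = screen_dams(stats)
        assert down == {"m1"} and up == set()

    def test_all_vip_zero(self):
        stats = metab_stats([(f"m{i}", 3.0, 0.001, 0.0) for i in range(5)])
        assert screen_dams(stats) == (set(), set())

    def test_missing_vip_column(self):
        stats = gene_stats([("m1", 2.0, 0.01)]).assign(kind="metabolite")
        with pytest.raises(ValueError, match="VIP"):
            screen_dams(stats)

    def test_missing_vip_value(self):
        stats = metab_stats([("m1", 2.0, 0.01, np.nan)])
        with pytest.raises(ValueError, match="m1"):
            screen_dams(stats)


class TestMultiwayOverlap:
    def test_identical_sets(self):
        s = set(range(17))
        regions = multiway_overlap({"a": s, "b": s, "c": s, "d": s})
        assert regions[frozenset("abcd")] == 17
        assert sum(v for k, v in regions.items() if k != frozenset("abcd")) == 0

    def test_disjoint_sets(self):
        regions = multiway_overlap(
            {"a": {1}, "b": {2}, "c": {3}, "d": {4}}
        )
        assert regions[frozenset("abcd")] == 0
        assert regions[frozenset("a")] == 1

    def test_enumeration(self):
        regions = multiway_overlap(
            {"A": {1, 2, 3}, "B": {2, 3}, "C": {3, 4}, "D": {3}}
        )
        assert regions[frozenset("ABCD")] == 1  # {3}
        assert regions[frozenset("A")] == 1  # {1}
        assert regions[frozenset("AB")] == 1  # {2}
        assert regions[frozenset("C")] == 1  # {4}

    def test_region_count_and_union(self):
        rng = np.random.default_rng(3)
        sets = {
            lab: set(rng.choice(50, size=rng.integers(5, 30), replace=False).tolist())
            for lab in "wxyz"
        }
        regions = multiway_overlap(sets)
        assert len(regions) == 2**4 - 1
        assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_fewer_than_two(self):
        with pytest.raises(ValueError, match="at least 2"):
            multiway_overlap({"a": {1}})


def brute_force_hypergeom_p(n_bg, n_set, n_sel, k):
    """Upper-tail probability by exact enumeration over overlap sizes."""
    total = math.comb(n_bg, n_sel)
    acc = 0
    for j in range(k, min(n_set, n_sel) + 1):
        acc += math.comb(n_set, j) * math.comb(n_bg - n_set, n_sel - j)
    return acc / total


class TestHypergeometricEnrichment:
    @staticmethod
    def make_instance(n_bg, n_set, n_sel, k):
        background = set(range(n_bg))
        members = set(range(n_set))
        selected = set(range(k)) | set(range(n_set, n_set + (n_sel - k)))
        ann = AnnotationSets(sets={"s": members}, background=background)
        return selected, ann

    def test_set_equals_background(self):
        ann = AnnotationSets(sets={"s": set(range(8))}, background=set(range(8)))
        out = hypergeometric_enrichment({0, 1, 2}, ann)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_worked_example(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)*C(5,0)/C(10,4) = 5/210
        selected, ann = self.make_instance(10, 5, 4, 4)
        out = hypergeometric_enrichment(selected, ann)
        assert out.loc[0, "overlap"] == 4
        assert out.loc[0, "p"] == pytest.approx(5 / 210)

    def test_zero_overlap_p_one(self):
        selected, ann = self.make_instance(10, 4, 3, 0)
        out = hypergeometric_enrichment(selected, ann)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_stray_features_rejected(self):
        ann = AnnotationSets(sets={"s": {1, 2}}, background={1, 2, 3})
        with pytest.raises(ValueError, match="99"):
            hypergeometric_enrichment({1, 99}, ann)

    def test_annotation_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside background"):
            AnnotationSets(sets={"s": {1, 9}}, background={1, 2})

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            AnnotationSets(sets={"s": set()}, background={1})

    def test_matches_enumeration_sample(self):
        for n_bg, n_set, n_sel, k in [(12, 6, 5, 3), (9, 4, 4, 2), (11, 7, 6, 5)]:
            selected, ann = self.make_instance(n_bg, n_set, n_sel, k)
            out = hypergeometric_enrichment(selected, ann)
            assert out.loc[0, "p"] == pytest.approx(
                brute_force_hypergeom_p(n_bg, n_set, n_sel, k), abs=1e-12
            )


def naive_bh(p):
    """Quadratic textbook definition: adj_i = min over p_j >= p_i of
    min(1, m * p_j / rank_j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    ranks = np.empty(m, dtype=int)
    order = np.argsort(p, kind="stable")
    ranks[order] = np.arange(1, m + 1)
    out = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * p[j] / ranks[j]) for j in range(m) if p[j] >= p[i]
        ]
        out[i] = min(candidates)
    return out


class TestBHAdjust:
    def test_single(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_two_values(self):
        assert bh_adjust([0.005, 0.05]) == pytest.approx([0.01, 0.05])

    def test_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.2])

    def test_empty(self):
        assert len(bh_adjust([])) == 0

    def test_matches_naive_random(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 30))
            assert bh_adjust(p) == pytest.approx(naive_bh(p), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        p = rng.uniform(size=100)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)

    @given(stn.lists(stn.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=80, deadline=None)
    def test_properties(self, p):
        adj = bh_adjust(p)
        p = np.asarray(p)
        assert np.all(adj >= 0) and np.all(adj <= 1)
        # order-preserving: smaller raw p never gets larger adjusted p
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)
        # never below raw p
        assert np.all(adj >= p - 1e-15)
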