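"""Linkage-map construction: segregation tests, EM recombination, grouping, ordering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from silicomap.linkmap import (
    TwoPointResult,
    build_map,
    estimate_rf_f2,
    group_loci,
    group_sweep,
    haldane_cM,
    haldane_r,
    map_report,
    order_group,
    segregation_chisq,
    two_point_all,
    two_point_loglik,
    _observed_classes,
    validate_genotypes,
    LinkageMap,
)
from silicomap.simdata import make_truth_map, simulate_f2
from tests.conftest import grid_argmax_r


class TestHaldane:
    def test_closed_form_values(self):
        assert haldane_cM(0.0) == 0.0
        assert haldane_cM(0.25) == pytest.approx(34.657, abs=1e-3)
        assert haldane_r(0.0) == 0.0

    def test_inverse_identity(self):
        for r in np.linspace(0.0, 0.49, 50):
            assert haldane_r(haldane_cM(r)) == pytest.approx(r, abs=1e-12)

    def test_unlinked_signals_infinite_distance(self):
        assert haldane_cM(0.5) == np.inf
        with pytest.raises(ValueError):
            haldane_cM(-0.1)


class TestSegregation:
    def test_perfect_codominant_fit(self):
        col = pd.Series(["a"] * 25 + ["h"] * 50 + ["b"] * 25)
        chi2, p, df = segregation_chisq(col)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 2

    def test_dominant_3to1(self):
        # 77 dominant-phenotype : 17 recessive against 3:1
        col = pd.Series(["d"] * 77 + ["b"] * 17)
        chi2, p, df = segregation_chisq(col)
        assert chi2 == pytest.approx(2.397, abs=1e-3)
        assert p == pytest.approx(0.122, abs=1e-3)
        assert df == 1

    def test_upper_tail_chi2_printed_value(self):
        # analytic upper-tail probability at statistic 0.12, df 1
        assert stats.chi2.sf(0.12, 1) == pytest.approx(0.73, abs=5e-3)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            segregation_chisq(pd.Series(["-", "-"]))

    def test_mixed_codes_rejected(self):
        with pytest.raises(ValueError):
            validate_genotypes(pd.DataFrame({"L1": ["a", "h", "c"]}))


def _f2_pair(r, n, seed, dominant=None):
    tm = {"G1": [("L1", 0.0), ("L2", haldane_cM(r) if r > 0 else 0.001)]} if r < 0.5 else {
        "G1": [("L1", 0.0)], "G2": [("L2", 0.0)]}
    return simulate_f2(tm, n, seed=seed, dominant_loci=dominant)


class TestEstimateRf:
    def test_perfect_cosegregation(self):
        gm = _f2_pair(0.0, 60, seed=1)
        gm["L2"] = gm["L1"]
        tp = estimate_rf_f2(gm["L1"], gm["L2"])
        assert tp.r == pytest.approx(0.0, abs=1e-6)
        # LOD at r=0 for fully informative parental classes, checked numerically
        classes, n = _observed_classes(gm["L1"], gm["L2"])
        expected = (two_point_loglik(classes, 1e-12) - two_point_loglik(classes, 0.5)) / np.log(10)
        assert tp.lod == pytest.approx(expected, abs=1e-3)
        counts = gm["L1"].value_counts()
        analytic = (counts.get("a", 0) + counts.get("b", 0)) * np.log10(4) + counts.get("h", 0) * np.log10(2)
        assert tp.lod == pytest.approx(analytic, abs=1e-6)

    def test_independent_loci_near_half(self):
        gm = _f2_pair(0.5, 200, seed=2)
        tp = estimate_rf_f2(gm["L1"], gm["L2"])
        se = np.sqrt(0.25 / (2 * 200))
        assert abs(tp.r - 0.5) <= 3 * se
        assert tp.lod < 1.0

    def test_symmetry_argument_and_label_swap(self):
        gm = _f2_pair(0.1, 150, seed=3)
        a = estimate_rf_f2(gm["L1"], gm["L2"])
        b = estimate_rf_f2(gm["L2"], gm["L1"])
        assert a.r == pytest.approx(b.r, abs=1e-9)
        assert a.lod == pytest.approx(b.lod, abs=1e-9)
        swapped = gm.replace({"a": "b", "b": "a", "c": "d", "d": "c"})
        c = estimate_rf_f2(swapped["L1"], swapped["L2"])
        assert a.r == pytest.approx(c.r, abs=1e-9)
        assert a.lod == pytest.approx(c.lod, abs=1e-9)

    @pytest.mark.parametrize("dominant", [None, {"L1": "c"}, {"L1": "c", "L2": "d"}])
    @pytest.mark.parametrize("r_true", [0.05, 0.2, 0.4])
    def test_grid_oracle_equivalence(self, r_true, dominant):
        gm = _f2_pair(r_true, 150, seed=int(r_true * 100), dominant=dominant)
        tp = estimate_rf_f2(gm["L1"], gm["L2"])
        classes, _ = _observed_classes(gm["L1"], gm["L2"])
        r_grid, ll_grid = grid_argmax_r(classes)
        assert tp.r == pytest.approx(r_grid, abs=1e-4)
        assert two_point_loglik(classes, tp.r) >= ll_grid - 1e-6

    def test_dominant_repulsion_flagged(self):
        gm = _f2_pair(0.2, 100, seed=5, dominant={"L1": "c", "L2": "d"})
        tp = estimate_rf_f2(gm["L1"], gm["L2"])
        assert tp.non_identifiable

    def test_preconditions(self):
        gm = _f2_pair(0.2, 100, seed=6)
        mono = pd.Series(["a"] * 100)
        with pytest.raises(ValueError):
            estimate_rf_f2(gm["L1"], mono)
        short = gm.iloc[:5]
        with pytest.raises(ValueError):
            estimate_rf_f2(short["L1"], short["L2"])


def _tp(l1, l2, r, lod):
    return TwoPointResult(l1, l2, r, lod, 100)


class TestGrouping:
    def test_high_threshold_isolates_everything(self):
        results = [_tp("A", "B", 0.1, 5.0), _tp("B", "C", 0.1, 5.0)]
        assert group_loci(results, lod_threshold=100.0) == [["A"], ["B"], ["C"]]

    def test_rf_cap_blocks_weak_edges(self):
        results = [_tp("A", "B", 0.45, 50.0)]
        assert group_loci(results, lod_threshold=4.0) == [["A"], ["B"]]

    def test_monotone_refinement_under_threshold_sweep(self, small_f2):
        _, gm = small_f2
        results = two_point_all(gm)
        sweep = group_sweep(results)
        for lo, hi in zip(range(4, 10), range(5, 11)):
            fine = {frozenset(g) for g in sweep[hi]}
            for g in fine:
                # every group at the higher threshold is inside one group at the lower
                assert any(g <= frozenset(c) for c in sweep[lo])

    def test_two_chromosome_recovery(self, small_f2):
        truth_map, gm = small_f2
        results = two_point_all(gm)
        groups = group_loci(results, lod_threshold=4.0)
        assert len(groups) == 2
        truth_groups = {frozenset(l for l, _ in loci) for loci in truth_map.values()}
        assert {frozenset(g) for g in groups} == truth_groups


class TestOrdering:
    def test_three_locus_order(self):
        results = [_tp("A", "B", 0.05, 10), _tp("B", "C", 0.05, 10), _tp("A", "C", 0.095, 8)]
        order, pos = order_group(["A", "B", "C"], results)
        assert order == ["A", "B", "C"]
        assert pos[0] == 0.0 and pos[1] < pos[2]

    def test_group_of_two_positions(self):
        results = [_tp("A", "B", 0.1, 10)]
        order, pos = order_group(["A", "B"], results)
        assert order == ["A", "B"]
        assert pos == [0.0, pytest.approx(haldane_cM(0.1))]

    def test_sarf_optimal_vs_exhaustive(self):
        # 6 loci on a chain: 2-opt must reach the exhaustive SARF optimum
        tm = make_truth_map(1, 6, 12.0)
        gm = simulate_f2(tm, 200, seed=9)
        results = two_point_all(gm)
        loci = list(gm.columns)
        order, _ = order_group(loci, results)
        rf = {}
        for tp in results:
            rf[(tp.locus1, tp.locus2)] = tp.r
            rf[(tp.locus2, tp.locus1)] = tp.r

        def sarf(o):
            return sum(rf[a, b] for a, b in zip(o, o[1:]))

        best = min(itertools.permutations(loci), key=sarf)
        assert sarf(order) <= sarf(best) + 1e-9

    def test_orientation_normalized(self):
        results = [_tp("Z", "A", 0.05, 10)]
        order, _ = order_group(["Z", "A"], results)
        assert order[0] == "A"

    def test_twelve_locus_recovery(self):
        tm = make_truth_map(1, 12, 10.0)
        gm = simulate_f2(tm, 200, seed=10)
        results = two_point_all(gm)
        order, _ = order_group(list(gm.columns), results)
        truth_order = [l for l, _ in tm["G1"]]
        adj_true = {frozenset(p) for p in zip(truth_order, truth_order[1:])}
        adj_got = {frozenset(p) for p in zip(order, order[1:])}
        assert len(adj_true & adj_got) / len(adj_true) >= 0.95


class TestMapAssembly:
    def test_end_to_end_recovery(self, small_f2):
        truth_map, gm = small_f2
        lm, results = build_map(gm)
        assert len(lm.groups) == 2
        # per-interval distances within 3 binomial s.e. of truth
        n_gametes = 2 * len(gm)
        for loci in lm.groups.values():
            for (l1, p1), (l2, p2) in zip(loci, loci[1:]):
                r_hat = haldane_r(p2 - p1)
                r_true = haldane_r(10.0)
                se = np.sqrt(r_true * (1 - r_true) / n_gametes)
                assert abs(r_hat - r_true) <= 3 * se
        total = sum(loci[-1][1] for loci in lm.groups.values())
        assert abs(total - 280.0) / 280.0 <= 0.15

    @pytest.mark.parametrize(
        "length,n_loci,expected",
        [(79.9, 8, 11.4), (199.8, 38, 5.4), (10.0, 2, 10.0)],
    )
    def test_report_density_per_interval(self, length, n_loci, expected):
        spacing = length / (n_loci - 1)
        groups = {"LG": [(f"L{i}", i * spacing) for i in range(n_loci)]}
        lm = LinkageMap(groups=groups)
        rep = map_report(lm)
        assert float(rep["density_cM_per_interval"].iloc[0]) == expected

    def test_single_locus_group_density_blank(self):
        lm = LinkageMap(groups={"LG": [("L0", 0.0)]})
        rep = map_report(lm)
        assert np.isnan(rep["density_cM_per_interval"].iloc[0])

    def test_distortion_percentage(self):
        tm = make_truth_map(1, 4, 20.0)
        gm = simulate_f2(tm, 300, seed=12, distortion={"M000": {"a": 0.15, "h": 1.0, "b": 1.0}})
        lm, _ = build_map(gm)
        assert bool(lm.segregation.loc["M000", "distorted"])
        rep = map_report(lm)
        assert float(rep["distortion_pct"].iloc[0]) >= 25.0
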