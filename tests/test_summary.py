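"""Group summary networks, ROI categorization, neighbor clusters."""

import itertools

import numpy as np
import pytest

from fcnfusion.datatypes import Fcn, TopRoiList
from fcnfusion.summary import (
    SummaryFcn,
    categorize_rois,
    extract_clusters,
    group_summary,
)


def fcn_from_edges(n, edges, labels=None):
    adj = np.zeros((n, n), dtype=int)
    for j, k in edges:
        adj[j, k] = adj[k, j] = 1
    labels = labels or [f"R{i}" for i in range(n)]
    return Fcn(adjacency=adj, roi_labels=labels)


class TestGroupSummary:
    def test_identical_fcns_preserved_at_any_threshold(self):
        f = fcn_from_edges(4, [(0, 1), (2, 3)])
        for t in (0.1, 0.5, 1.0):
            s = group_summary([f, f, f], threshold=t)
            np.testing.assert_array_equal(s.ratio, f.adjacency.astype(float))
            np.testing.assert_array_equal(s.adjacency, f.adjacency)

    def test_toy_cohort_manual_count(self):
        # 3 subjects, 4 nodes; with threshold 0.2 an edge survives iff
        # present in >= ceil(0.2 * 3) = 1 subject
        subs = [
            fcn_from_edges(4, [(0, 1), (1, 2)]),
            fcn_from_edges(4, [(0, 1)]),
            fcn_from_edges(4, [(2, 3)]),
        ]
        s = group_summary(subs, threshold=0.2)
        expected = fcn_from_edges(4, [(0, 1), (1, 2), (2, 3)]).adjacency
        np.testing.assert_array_equal(s.adjacency, expected)
        assert s.ratio[0, 1] == pytest.approx(2 / 3)
        assert s.ratio[1, 2] == pytest.approx(1 / 3)
        # at threshold 0.5 only the edge in 2 of 3 subjects survives
        np.testing.assert_array_equal(
            group_summary(subs, threshold=0.5).adjacency,
            fcn_from_edges(4, [(0, 1)]).adjacency,
        )

    def test_threshold_subject_count_equivalence(self):
        # exhaustive: for every edge pattern over 4 subjects, ratio >= t is
        # the same as presence in >= ceil(t * N) subjects
        n_subj = 4
        for t in (0.2, 0.25, 0.5, 0.75, 1.0):
            need = int(np.ceil(t * n_subj))
            for pattern in itertools.product([0, 1], repeat=n_subj):
                fcns = [fcn_from_edges(2, [(0, 1)] if p else []) for p in pattern]
                s = group_summary(fcns, threshold=t)
                assert bool(s.adjacency[0, 1]) == (sum(pattern) >= need)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        fcns = []
        for _ in range(6):
            a = rng.integers(0, 2, size=(5, 5))
            a = np.triu(a, 1)
            fcns.append(Fcn(adjacency=a + a.T,
                            roi_labels=[f"R{i}" for i in range(5)]))
        lo = group_summary(fcns, threshold=0.2)
        hi = group_summary(fcns, threshold=0.6)
        assert np.all(lo.adjacency >= hi.adjacency)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(1)
        fcns = []
        for _ in range(5):
            a = np.triu(rng.integers(0, 2, size=(4, 4)), 1)
            fcns.append(Fcn(adjacency=a + a.T,
                            roi_labels=[f"R{i}" for i in range(4)]))
        s1 = group_summary(fcns, 0.4)
        s2 = group_summary(fcns[::-1], 0.4)
        np.testing.assert_array_equal(s1.ratio, s2.ratio)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_summary([], 0.2)

    def test_default_threshold(self):
        f = fcn_from_edges(3, [(0, 1)])
        assert group_summary([f]).threshold == 0.2


def top_list(labels, group):
    return TopRoiList(labels=list(labels), group=group)


class TestCategorize:
    UNIVERSE = [f"R{i}" for i in range(8)]

    def test_decision_table_cases(self):
        cats = categorize_rois(
            top_list(["R0", "R1", "R2"], "AD"),
            top_list(["R0", "R1", "R3"], "MCI"),
            near_origin_a={"R0", "R1", "R4"},
            near_origin_b={"R0"},
            roi_labels=self.UNIVERSE,
        )
        assert cats["R0"] == "both"                # both lists, both origins
        assert cats["R1"] == "more_reactive_AD"    # both lists, one origin
        assert cats["R2"] == "only_AD"             # one list only
        assert cats["R3"] == "only_MCI"
        assert cats["R5"] == "none"                # in neither list

    def test_matches_brute_force_table(self):
        rng = np.random.default_rng(2)
        universe = [f"R{i}" for i in range(20)]
        ta = [r for r in universe if rng.random() < 0.4]
        tb = [r for r in universe if rng.random() < 0.4]
        na = {r for r in universe if rng.random() < 0.5}
        nb = {r for r in universe if rng.random() < 0.5}
        cats = categorize_rois(top_list(ta, "g"), top_list(tb, "h"),
                               na, nb, universe)
        for r in universe:  # exhaustive re-evaluation of the table
            if r in ta and r in tb:
                if r in na and r in nb:
                    want = "both"
                elif r in na:
                    want = "more_reactive_g"
                elif r in nb:
                    want = "more_reactive_h"
                else:
                    want = "none"
            elif r in ta:
                want = "only_g"
            elif r in tb:
                want = "only_h"
            else:
                want = "none"
            assert cats[r] == want

    def test_one_category_per_roi_and_counts_sum(self):
        rng = np.random.default_rng(3)
        universe = [f"R{i}" for i in range(15)]
        cats = categorize_rois(
            top_list([r for r in universe if rng.random() < 0.3], "A"),
            top_list([r for r in universe if rng.random() < 0.3], "B"),
            set(universe[:5]), set(universe[5:10]), universe,
        )
        assert sorted(cats) == sorted(universe)
        assert len(cats) == 15

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            categorize_rois(top_list(["X"], "A"), top_list([], "B"),
                            set(), set(), self.UNIVERSE)


class TestClusters:
    def summary(self):
        ratio = np.zeros((6, 6))
        for j, k in [(0, 1), (0, 2), (3, 4)]:
            ratio[j, k] = ratio[k, j] = 1.0
        return SummaryFcn(ratio=ratio, threshold=0.2, group="A",
                          roi_labels=[f"R{i}" for i in range(6)])

    def test_neighbor_lists_match_adjacency(self):
        cats = {"R0": "only_A", "R3": "both", "R5": "only_B"}
        clusters = extract_clusters(self.summary(), cats)
        by_roi = {c["roi"]: c for c in clusters}
        assert by_roi["R0"]["members"] == ["R0", "R1", "R2"]  # star center
        assert by_roi["R3"]["members"] == ["R3", "R4"]
        assert by_roi["R5"]["members"] == ["R5"]              # isolated
        assert [c["name"] for c in clusters] == ["A", "B", "C"]

    def test_none_category_excluded(self):
        clusters = extract_clusters(self.summary(), {"R0": "none"})
        assert clusters == []
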