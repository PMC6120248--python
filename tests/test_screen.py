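"""Tests for the fold-change screen, SNR ranking, arm collapsing and
cross-cohort intersection."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirmeta import screen
from mirmeta.datatypes import ExpressionCohort, ValidationError


def make_cohort(feature_rows: dict, groups: dict) -> ExpressionCohort:
    """feature_rows: name -> {group: list of values}; groups gives order."""
    cols, labels = [], {}
    for g, n in groups.items():
        for j in range(n):
            c = f"{g}{j}"
            cols.append(c)
            labels[c] = g
    data = {
        name: sum((list(by_group[g]) for g in groups), []) for name, by_group in feature_rows.items()
    }
    values = pd.DataFrame(data, index=cols).T
    return ExpressionCohort(values=values, sample_groups=pd.Series(labels))


@pytest.fixture()
def simple_cohort():
    return make_cohort(
        {
            "up4x": {"normal": [99, 101, 100, 100], "tumor": [399, 401, 400, 400]},
            "flat": {"normal": [50, 52, 48, 50], "tumor": [50, 48, 52, 50]},
            "edge2x": {"normal": [98, 100, 98, 100], "tumor": [198, 200, 198, 200]},
        },
        {"normal": 4, "tumor": 4},
    )


class TestLog2fcScreen:
    def test_fourfold_change_is_retained(self, simple_cohort):
        de = screen.log2fc_screen(simple_cohort, "normal", "tumor").set_index("feature")
        row = de.loc["up4x"]
        assert row["log2fc"] == pytest.approx(np.log2(401 / 101), abs=1e-9)
        assert row["direction"] == "up"
        assert bool(row["retained"])

    def test_flat_feature_not_retained(self, simple_cohort):
        de = screen.log2fc_screen(simple_cohort, "normal", "tumor").set_index("feature")
        assert de.loc["flat", "log2fc"] == pytest.approx(0.0)
        assert not bool(de.loc["flat", "retained"])

    def test_exact_twofold_boundary_excluded(self, simple_cohort):
        # mean + pseudocount is exactly 100 vs 200: |log2fc| == 1, strict rule
        de = screen.log2fc_screen(simple_cohort, "normal", "tumor").set_index("feature")
        assert de.loc["edge2x", "log2fc"] == pytest.approx(1.0, abs=1e-12)
        assert not bool(de.loc["edge2x", "retained"])

    def test_q_at_least_p_and_in_unit_interval(self, simple_cohort):
        de = screen.log2fc_screen(simple_cohort, "normal", "tumor")
        assert (de["q"] >= de["p"] - 1e-12).all()
        assert de["q"].between(0, 1).all()

    def test_sample_order_invariance(self, simple_cohort, rng):
        base = screen.log2fc_screen(simple_cohort, "normal", "tumor")
        perm = list(rng.permutation(simple_cohort.values.columns))
        shuffled = ExpressionCohort(
            values=simple_cohort.values[perm],
            sample_groups=simple_cohort.sample_groups,
        )
        again = screen.log2fc_screen(shuffled, "normal", "tumor")
        pd.testing.assert_frame_equal(base, again)

    def test_singleton_group_rejected(self):
        cohort = make_cohort({"f": {"a": [1], "b": [2, 3]}}, {"a": 1, "b": 2})
        with pytest.raises(ValidationError):
            screen.log2fc_screen(cohort, "a", "b")


class TestSnr:
    def test_direct_formula(self):
        cohort = make_cohort(
            {"f": {"a": [0.5, 1.0, 1.5], "b": [2.5, 3.0, 3.5]}}, {"a": 3, "b": 3}
        )
        out = screen.snr_rank(cohort, "a", "b")
        assert out.loc[0, "snr"] == pytest.approx(2.0 / 1.0)

    def test_equal_means_give_zero(self):
        cohort = make_cohort({"f": {"a": [1, 2, 3], "b": [3, 2, 1]}}, {"a": 3, "b": 3})
        assert screen.snr_rank(cohort, "a", "b").loc[0, "snr"] == pytest.approx(0.0)

    def test_antisymmetry_under_group_swap(self, simple_cohort):
        fwd = screen.snr_rank(simple_cohort, "normal", "tumor").set_index("feature")
        rev = screen.snr_rank(simple_cohort, "tumor", "normal").set_index("feature")
        for f in fwd.index:
            assert fwd.loc[f, "snr"] == pytest.approx(-rev.loc[f, "snr"])

    def test_zero_sd_feature_flagged_with_warning(self):
        cohort = make_cohort({"f": {"a": [5, 5, 5], "b": [5, 5, 5]}}, {"a": 3, "b": 3})
        with pytest.warns(UserWarning, match="zero SD"):
            out = screen.snr_rank(cohort, "a", "b")
        assert out.loc[0, "snr"] == 0.0
        assert bool(out.loc[0, "degenerate"])


class TestTopK:
    @staticmethod
    def scores(n, rng):
        return pd.DataFrame(
            {"feature": [f"m{i:04d}" for i in range(n)], "snr": rng.normal(size=n)}
        )

    def test_two_hundred_fifty_each_direction(self, rng):
        assert len(screen.top_k_bidirectional(self.scores(600, rng), k=250)) == 500

    def test_short_list_returned_whole(self, rng):
        assert len(screen.top_k_bidirectional(self.scores(300, rng), k=250)) == 300

    def test_boundary_ties_resolved_deterministically(self):
        df = pd.DataFrame(
            {"feature": ["b", "a", "c", "d", "e"], "snr": [1.0, 1.0, 1.0, -1.0, 0.0]}
        )
        sel = screen.top_k_bidirectional(df, k=2)
        assert len(sel) == 4
        assert {"a", "b"} <= sel  # lexicographically smallest of the tied top

    def test_group_swap_selects_same_features(self, simple_cohort):
        fwd = screen.snr_rank(simple_cohort, "normal", "tumor")
        rev = screen.snr_rank(simple_cohort, "tumor", "normal")
        assert screen.top_k_bidirectional(fwd, k=1) == screen.top_k_bidirectional(rev, k=1)

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValidationError):
            screen.top_k_bidirectional(self.scores(10, rng), k=0)


class TestCollapseArms:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("hsa-miR-17-5p", "hsa-miR-17"),
            ("hsa-miR-17-3p", "hsa-miR-17"),
            ("hsa-miR-17", "hsa-miR-17"),
            ("hsa-miR-5p-something", "hsa-miR-5p-something"),
            ("hsa-miR-21-5P", "hsa-miR-21"),
        ],
    )
    def test_suffix_stripping(self, name, expected):
        canon, mapping = screen.collapse_arms([name])
        assert mapping[name] == expected

    def test_both_arms_merge(self):
        canon, _ = screen.collapse_arms(["hsa-miR-17-5p", "hsa-miR-17-3p"])
        assert canon == {"hsa-miR-17"}

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            screen.collapse_arms([])


class TestIntersect:
    def test_pairwise(self):
        rep = screen.intersect_cohorts([{"A", "B"}, {"B", "C"}])
        assert rep["intersection"] == {"B"}

    def test_disjoint(self):
        rep = screen.intersect_cohorts([{"A"}, {"B"}])
        assert rep["intersection"] == set()

    def test_four_sets_venn_regions_enumerate(self, rng):
        universe = [f"g{i}" for i in range(40)]
        sets = {}
        common = {"g0", "g1", "g2"}
        for name in "ABCD":
            extra = set(rng.choice(universe[3:], size=10, replace=False))
            sets[name] = common | extra
        rep = screen.intersect_cohorts(sets)
        assert common <= rep["intersection"]
        union = set().union(*sets.values())
        assert sum(rep["venn"].values()) == len(union)
        # brute-force every region against the venn report
        keys = sorted(sets)
        for members, count in rep["venn"].items():
            inside = set.intersection(*(sets[k] for k in members))
            outside = set().union(*(sets[k] for k in keys if k not in members))
            assert count == len(inside - outside)

    def test_arm_collapsing_applied_before_intersection(self):
        rep = screen.intersect_cohorts([{"hsa-miR-17-5p"}, {"hsa-miR-17-3p"}])
        assert rep["intersection"] == {"hsa-miR-17"}

    def test_single_set_rejected(self):
        with pytest.raises(ValidationError):
            screen.intersect_cohorts([{"A"}])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.sets(st.sampled_from([f"f{i}" for i in range(12)]), max_size=12),
            min_size=2,
            max_size=4,
        )
    )
    def test_intersection_bounded_and_commutative(self, sets):
        rep = screen.intersect_cohorts(sets)
        sizes = [v for v in rep["set_sizes"].values()]
        assert len(rep["intersection"]) <= min(sizes)
        rev = screen.intersect_cohorts(list(reversed(sets)))
        assert rep["intersection"] == rev["intersection"]
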