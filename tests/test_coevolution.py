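"""Pairwise co-evolution scoring, threshold calibration and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloprof import (
    calibrate_threshold,
    cluster_profiles,
    correlation_matrix,
    family_top_matches,
    joint_profile,
    profile_pearson,
    recurrent_families,
)
from phyloprof.coevolution import CalibrationResult, CorrelationMatrix

from conftest import CODES4


def phi_from_table(x, y):
    """Independent oracle: phi coefficient from the 2x2 co-occurrence table."""
    x = np.asarray(x)
    y = np.asarray(y)
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return (a * d - b * c) / np.sqrt(denom)


def worked_example_matrix():
    """The 4-protein matrix used for the calibration examples."""
    names = ("A", "B", "C", "D")
    vals = {
        ("A", "B"): 0.9,
        ("C", "D"): 0.8,
        ("A", "C"): 0.5,
        ("A", "D"): 0.3,
        ("B", "C"): 0.2,
        ("B", "D"): 0.1,
    }
    r = np.eye(4)
    idx = {n: i for i, n in enumerate(names)}
    for (a, b), v in vals.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return CorrelationMatrix(names, r, np.zeros(4, dtype=bool))


class TestProfilePearson:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 1, 0, 0], [1, 1, 0, 0], 1.0),
            ([1, 1, 0, 0], [0, 0, 1, 1], -1.0),
            ([1, 1, 0, 0], [1, 0, 1, 0], 0.0),  # phi of the balanced 2x2 table
        ],
    )
    def test_binary_examples(self, a, b, expected):
        assert profile_pearson(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_returns_zero(self):
        assert profile_pearson([1, 1, 1], [1, 0, 1]) == 0.0

    def test_length_mismatch_and_short_input_rejected(self):
        with pytest.raises(ValueError):
            profile_pearson([1, 0], [1, 0, 1])
        with pytest.raises(ValueError):
            profile_pearson([1], [0])

    @settings(max_examples=200, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=60
        )
    )
    def test_equals_phi_coefficient(self, data):
        x = np.array([int(a) for a, _ in data])
        y = np.array([int(b) for _, b in data])
        if len(set(x)) < 2 or len(set(y)) < 2:
            return  # phi undefined for constant vectors
        assert profile_pearson(x, y) == pytest.approx(phi_from_table(x, y), abs=1e-12)


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal_and_matches_pairwise_oracle(
        self, profile_factory
    ):
        profiles = [
            profile_factory("A", [1, 1, 0, 0]),
            profile_factory("B", [1, 0, 1, 0]),
            profile_factory("C", [0, 1, 1, 0]),
        ]
        cm = correlation_matrix(profiles)
        assert np.array_equal(cm.r, cm.r.T)
        assert np.allclose(np.diag(cm.r), 1.0)
        for i, p in enumerate(profiles):
            for j, q in enumerate(profiles):
                if i != j:
                    assert cm.r[i, j] == pytest.approx(
                        profile_pearson(p.presence, q.presence), abs=1e-12
                    )

    def test_constant_profile_row_zeroed_and_flagged(self, profile_factory):
        profiles = [
            profile_factory("A", [1, 1, 0, 0]),
            profile_factory("allon", [1, 1, 1, 1]),
        ]
        cm = correlation_matrix(profiles)
        i = cm.proteins.index("allon")
        assert cm.constant_flags[i]
        assert np.all(cm.r[i, :] == 0) and np.all(cm.r[:, i] == 0)

    def test_mixed_catalogs_rejected(self, profile_factory):
        p1 = profile_factory("A", [1, 0, 0, 0])
        p2 = profile_factory("B", [1, 0], codes=("Aaaa", "Bbbb"))
        with pytest.raises(ValueError, match="catalog"):
            correlation_matrix([p1, p2])


class TestJointProfile:
    def test_union_of_presences(self, profile_factory):
        j = joint_profile(
            [profile_factory("A", [1, 0, 1, 0]), profile_factory("B", [0, 1, 1, 0])],
            name="AorB",
        )
        assert j.presence.tolist() == [1, 1, 1, 0]
        assert j.copy_number.tolist() == [1, 1, 2, 0]

    def test_idempotent_on_identical_profiles(self, profile_factory):
        p = profile_factory("A", [1, 0, 1, 0])
        j = joint_profile([p, p], name="A")
        assert np.array_equal(j.presence, p.presence)

    def test_empty_component_list_rejected(self):
        with pytest.raises(ValueError):
            joint_profile([])

    def test_enzyme_matching_union_correlates_at_least_as_well(self, profile_factory):
        a = profile_factory("A", [1, 0, 1, 0])
        b = profile_factory("B", [0, 1, 1, 0])
        enzyme = profile_factory("E", [1, 1, 1, 0])  # = union: the retention rule
        j = joint_profile([a, b])
        r_joint = profile_pearson(enzyme.presence, j.presence)
        assert r_joint == pytest.approx(1.0)
        assert r_joint >= profile_pearson(enzyme.presence, a.presence)
        assert r_joint >= profile_pearson(enzyme.presence, b.presence)


class TestCalibrateThreshold:
    def test_worked_example_fold_2(self):
        res = calibrate_threshold(worked_example_matrix(), [("A", "B"), ("C", "D")], fold=2)
        assert res.threshold == pytest.approx(0.5)
        assert res.fold == pytest.approx(2.0)
        assert res.base_rate == pytest.approx(1 / 3)

    def test_worked_example_fold_6_sentinel(self):
        res = calibrate_threshold(worked_example_matrix(), [("A", "B"), ("C", "D")], fold=6)
        assert not res.attained
        assert res.threshold == CalibrationResult.SENTINEL
        assert max(e for _, e in res.sweep) == pytest.approx(3.0)

    def test_matches_exhaustive_sweep_oracle(self):
        cm = worked_example_matrix()
        ref = {frozenset(p) for p in [("A", "B"), ("C", "D")]}
        pairs = cm.informative_pairs()
        rvals = np.array([r for *_, r in pairs])
        flags = np.array([frozenset((a, b)) in ref for a, b, _ in pairs])
        base = flags.mean()
        for fold in (1.5, 2, 2.5, 3, 4):
            feasible = [
                t
                for t in sorted(set(rvals))
                if flags[rvals >= t].mean() / base >= fold
            ]
            expected = min(feasible) if feasible else CalibrationResult.SENTINEL
            assert calibrate_threshold(cm, ref, fold=fold).threshold == pytest.approx(
                expected
            )

    def test_reference_all_pairs_gives_sentinel_above_fold_1(self):
        cm = worked_example_matrix()
        all_pairs = [(a, b) for a, b, _ in cm.informative_pairs()]
        res = calibrate_threshold(cm, all_pairs, fold=1.5)
        assert not res.attained
        assert all(e == pytest.approx(1.0) for _, e in res.sweep)

    def test_empty_reference_and_bad_fold_rejected(self):
        cm = worked_example_matrix()
        with pytest.raises(ValueError):
            calibrate_threshold(cm, [], fold=2)
        with pytest.raises(ValueError):
            calibrate_threshold(cm, [("A", "B")], fold=0)

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_threshold_monotone_in_fold(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 2, size=(6, 12))
        profiles = []
        from phyloprof import PhyloProfile

        codes = tuple(f"Sp{i:02d}"[:4].replace("0", "o").replace("1", "l") for i in range(12))
        codes = tuple(f"{chr(65+i)}aaa" for i in range(12))
        for i in range(6):
            profiles.append(PhyloProfile.from_presence(f"P{i}", codes, mat[i]))
        cm = correlation_matrix(profiles)
        if not cm.informative_pairs():
            return
        ref = [("P0", "P1"), ("P2", "P3")]
        prev = None
        for fold in (1.0, 1.5, 2.0, 3.0, 6.0):
            t = calibrate_threshold(cm, ref, fold=fold).threshold
            if prev is not None and prev != CalibrationResult.SENTINEL:
                assert t >= prev or t == CalibrationResult.SENTINEL
            if t == CalibrationResult.SENTINEL:
                prev = np.inf
            else:
                prev = t


class TestClusterProfiles:
    def test_identical_profiles_merge_at_zero(self, profile_factory):
        profiles = [
            profile_factory("A", [1, 1, 0, 0]),
            profile_factory("B", [1, 1, 0, 0]),
            profile_factory("C", [0, 0, 1, 1]),
        ]
        res = cluster_profiles(correlation_matrix(profiles))
        assert res.merges[0, 2] == pytest.approx(0.0)

    def test_three_protein_average_linkage_by_hand(self):
        # r(AB)=0.9, r(AC)=r(BC)=0.1: merge {A,B} at d=0.1, then C at mean d=0.9
        r = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
        cm = CorrelationMatrix(("A", "B", "C"), r, np.zeros(3, dtype=bool))
        res = cluster_profiles(cm)
        assert res.merges[0, 2] == pytest.approx(0.1)
        assert sorted(res.merges[0, :2]) == [0, 1]  # A and B first
        assert res.merges[1, 2] == pytest.approx(0.9)

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_merge_heights_non_decreasing(self, seed):
        from phyloprof import PhyloProfile

        rng = np.random.default_rng(seed)
        codes = tuple(f"{chr(65 + i)}aaa" for i in range(10))
        profiles = [
            PhyloProfile.from_presence(f"P{i}", codes, rng.integers(0, 2, 10))
            for i in range(5)
        ]
        res = cluster_profiles(correlation_matrix(profiles))
        heights = res.merges[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)
        assert res.merges.shape[0] == len(profiles) - 1

    def test_non_finite_distances_rejected(self):
        r = np.array([[1.0, np.nan], [np.nan, 1.0]])
        cm = CorrelationMatrix(("A", "B"), r, np.zeros(2, dtype=bool))
        with pytest.raises(ValueError, match="finite"):
            cluster_profiles(cm)


class TestFamilyMatching:
    def make_families(self, profile_factory, n=8):
        # distinct non-constant 4-bit patterns (1..14), so every family is informative
        fams = {}
        for i in range(n):
            bits = i + 1
            vec = [(bits >> j) & 1 for j in range(4)]
            fams[f"FAM{i:03d}"] = profile_factory(f"FAM{i:03d}", vec)
        return fams

    def test_identical_family_ranks_first_with_r_1(self, profile_factory):
        fams = self.make_families(profile_factory)
        query = profile_factory("q", fams["FAM003"].presence)
        top = family_top_matches(query, fams, k=3)
        assert top[0] == ("FAM003", pytest.approx(1.0))

    def test_k_larger_than_family_count_returns_all(self, profile_factory):
        fams = self.make_families(profile_factory)
        assert len(family_top_matches(fams["FAM000"], fams, k=100)) == len(fams)

    def test_ranking_matches_brute_force_sort(self, profile_factory):
        fams = self.make_families(profile_factory)
        query = profile_factory("q", [1, 0, 1, 0])
        expected = sorted(
            ((f, profile_pearson(query.presence, p.presence)) for f, p in fams.items()),
            key=lambda t: (-t[1], t[0]),
        )
        assert family_top_matches(query, fams, k=len(fams)) == expected

    def test_nonpositive_k_rejected(self, profile_factory):
        fams = self.make_families(profile_factory)
        with pytest.raises(ValueError):
            family_top_matches(fams["FAM000"], fams, k=0)


class TestRecurrentFamilies:
    def test_counts_match_brute_tally(self):
        toplists = {
            f"q{i}": [(f"FAM{j}", 0.5) for j in range(i % 3 + 1)] for i in range(10)
        }
        result = dict(recurrent_families(toplists, min_count=3))
        for fam, count in result.items():
            brute = sum(
                any(f == fam for f, _ in ranked) for ranked in toplists.values()
            )
            assert count == brute and count >= 3

    def test_min_count_above_list_count_is_empty(self):
        toplists = {"q": [("FAM0", 1.0)]}
        assert recurrent_families(toplists, min_count=2) == []

    def test_invalid_min_count_rejected(self):
        with pytest.raises(ValueError):
            recurrent_families({"q": [("F", 1.0)]}, min_count=0)
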