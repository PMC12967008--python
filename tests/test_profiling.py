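"""Match classification, distance, location, and profile assembly."""

import random

import pytest

from heleval.corpus_io import NIL, AlignedPair, Span
from heleval.ontology import Entity, HierVocabulary, NoCommonAncestorError
from heleval.profiling import (
    MatchType,
    PerformanceProfile,
    build_profile,
    classify,
    distance_matrix,
    match_distance,
    match_location,
    profile_by_location,
)
from heleval.synthetic import random_dag

from .conftest import brute_match_distance, parent_map


def _aligned(target, predicted, doc="d1", start=0, oov=False):
    span = Span(doc, start, start + 5, "tok")
    return AlignedPair(span, target, predicted, predicted_oov=oov)


class TestClassify:
    @pytest.mark.parametrize(
        "target,predicted,expected",
        [
            ("Apple", "Apple", MatchType.EXACT),
            ("Apple", "Dessert apple", MatchType.OVERSPECIFIC),
            ("Conference pear", "Fruit", MatchType.UNDERSPECIFIC),
            ("Granny Smith", "Conference pear", MatchType.ORTHOGONAL),
        ],
    )
    def test_fruit_examples(self, fruit, target, predicted, expected):
        assert classify(fruit, target, predicted) is expected

    def test_antisymmetry_of_nested_types(self, fruit):
        for t in fruit:
            for p in fruit:
                if classify(fruit, t, p) is MatchType.OVERSPECIFIC:
                    assert classify(fruit, p, t) is MatchType.UNDERSPECIFIC

    def test_orthogonal_symmetric(self, fruit):
        assert classify(fruit, "Conference pear", "Granny Smith") is MatchType.ORTHOGONAL

    def test_disconnected_pair(self):
        vocab = HierVocabulary({i: Entity(i) for i in "ABCD"}, [("B", "A"), ("D", "C")])
        assert classify(vocab, "B", "D") is MatchType.NO_COMMON_ANCESTOR


class TestMatchDistance:
    def test_exact_is_zero(self, fruit):
        for e in fruit:
            assert match_distance(fruit, e, e) == 0

    def test_direct_parent_is_one(self, fruit):
        assert match_distance(fruit, "Apple", "Fruit") == 1
        assert match_distance(fruit, "Fruit", "Apple") == 1

    def test_orthogonal_through_lca(self, fruit):
        assert match_distance(fruit, "Granny Smith", "Conference pear") == 4
        assert match_distance(fruit, "Pink Lady", "Granny Smith") == 3

    def test_symmetric(self, fruit):
        for t in fruit:
            for p in fruit:
                assert match_distance(fruit, t, p) == match_distance(fruit, p, t)

    def test_type_distance_coherence(self, fruit):
        for t in fruit:
            for p in fruit:
                mtype = classify(fruit, t, p)
                dist = match_distance(fruit, t, p)
                if mtype is MatchType.EXACT:
                    assert dist == 0
                elif mtype in (MatchType.OVERSPECIFIC, MatchType.UNDERSPECIFIC):
                    assert dist >= 1
                else:
                    assert dist >= 2
                    # up-up bound through the root as a common ancestor
                    assert dist <= fruit.depth(t) + fruit.depth(p)

    def test_disconnected_raises(self):
        vocab = HierVocabulary({i: Entity(i) for i in "ABCD"}, [("B", "A"), ("D", "C")])
        with pytest.raises(NoCommonAncestorError):
            match_distance(vocab, "B", "D")

    @pytest.mark.parametrize("seed", range(25))
    def test_against_brute_force(self, seed):
        vocab = random_dag(n_nodes=35, max_parents=3, seed=seed + 100)
        parents = parent_map(vocab)
        nodes = sorted(vocab)
        rnd = random.Random(seed)
        for _ in range(25):
            t, p = rnd.choice(nodes), rnd.choice(nodes)
            assert match_distance(vocab, t, p) == brute_match_distance(parents, t, p)


class TestMatchLocation:
    def test_root_zero_leaf_one(self, fruit):
        assert match_location(fruit, "Fruit") == 0.0
        for leaf in fruit.leaves:
            assert match_location(fruit, leaf) == 1.0

    def test_mid_branch_value(self, fruit):
        # Apple: depth 1, nearest leaf descendant Granny Smith one step below
        assert match_location(fruit, "Apple") == 0.5
        assert match_location(fruit, "Dessert apple") == pytest.approx(2 / 3)

    def test_bounds_and_monotonicity_on_random_dags(self):
        for seed in range(15):
            vocab = random_dag(40, 3, seed=seed)
            for e in vocab:
                loc = match_location(vocab, e)
                assert 0.0 <= loc <= 1.0
                for child in vocab.children(e):
                    # monotone along a chain realising the shortest
                    # root-to-leaf path through both nodes; other DAG steps
                    # can legitimately jump to a shallower branch
                    if (
                        vocab.depth(child) == vocab.depth(e) + 1
                        and vocab.leaf_distance(child) == vocab.leaf_distance(e) - 1
                    ):
                        assert match_location(vocab, child) >= loc

    def test_global_min_leaf_denominator(self, fruit):
        # shallowest leaf is Conference pear / Granny Smith at depth 2
        assert match_location(fruit, "Pink Lady", "global-min-leaf") == pytest.approx(1.5)

    def test_single_node_vocab(self):
        vocab = HierVocabulary({"A": Entity("A")}, [])
        assert match_location(vocab, "A") == 0.0


class TestBuildProfile:
    def test_all_correct(self, fruit):
        aligned = [_aligned("Apple", "Apple"), _aligned("Pear", "Pear"), _aligned("Fruit", "Fruit")]
        profile = build_profile(fruit, aligned)
        assert [r.type for r in profile.records] == [MatchType.EXACT] * 3
        assert [r.distance for r in profile.records] == [0, 0, 0]

    def test_fruit_sample(self, fruit):
        aligned = [
            _aligned("Apple", "Dessert apple"),
            _aligned("Conference pear", "Fruit", start=10),
            _aligned("Pink Lady", "Pink Lady", start=20),
        ]
        profile = build_profile(fruit, aligned)
        assert [r.type for r in profile.records] == [
            MatchType.OVERSPECIFIC,
            MatchType.UNDERSPECIFIC,
            MatchType.EXACT,
        ]
        assert [r.distance for r in profile.records] == [1, 2, 0]

    def test_empty_subset(self, fruit):
        assert len(build_profile(fruit, [], subset=[])) == 0

    def test_out_of_band_records(self, fruit):
        aligned = [
            _aligned("Apple", NIL),
            _aligned("Apple", "Durian", start=10, oov=True),
        ]
        profile = build_profile(fruit, aligned)
        assert [r.type for r in profile.records] == [MatchType.MISSING, MatchType.OOV]
        assert all(r.distance is None for r in profile.records)

    def test_subset_order_preserved(self, fruit):
        aligned = [_aligned("Apple", "Apple", start=i * 10) for i in range(4)]
        profile = build_profile(fruit, aligned, subset=[3, 1])
        assert [r.index for r in profile.records] == [3, 1]

    def test_tsv_round_trip(self, fruit, tmp_path):
        aligned = [
            _aligned("Apple", "Dessert apple"),
            _aligned("Pink Lady", NIL, start=10),
        ]
        profile = build_profile(fruit, aligned)
        path = tmp_path / "profile.tsv"
        profile.to_tsv(path)
        loaded = PerformanceProfile.from_tsv(path)
        assert [r.type for r in loaded.records] == [r.type for r in profile.records]
        assert [r.distance for r in loaded.records] == [r.distance for r in profile.records]
        assert [r.location for r in loaded.records] == pytest.approx(
            [r.location for r in profile.records]
        )


class TestProfileByLocation:
    def _profile(self, fruit):
        aligned = [
            _aligned("Apple", "Dessert apple"),  # O at loc 0.5
            _aligned("Conference pear", "Fruit", start=10),  # U at loc 1.0
            _aligned("Pink Lady", "Pink Lady", start=20),  # exact, excluded
        ]
        return build_profile(fruit, aligned)

    def test_single_bin_marginals(self, fruit):
        table = profile_by_location(self._profile(fruit), bins=[0.0, 1.0])
        assert table.loc["overspecific"].sum() == 1
        assert table.loc["underspecific"].sum() == 1
        assert table.loc["orthogonal"].sum() == 0

    def test_two_bins_right_closed(self, fruit):
        table = profile_by_location(self._profile(fruit), bins=[0.0, 0.5, 1.0])
        assert table.loc["overspecific", "(0.00,0.50]"] == 1
        assert table.loc["underspecific", "(0.50,1.00]"] == 1

    def test_no_mismatches_all_zero(self, fruit):
        profile = build_profile(fruit, [_aligned("Apple", "Apple")])
        assert profile_by_location(profile).to_numpy().sum() == 0

    def test_invalid_bins_rejected(self, fruit):
        for bad in ([0.0], [0.0, 0.5], [0.5, 1.0], [0.0, 0.7, 0.7, 1.0]):
            with pytest.raises(ValueError):
                profile_by_location(self._profile(fruit), bins=bad)

    def test_location_zero_in_first_bin(self, fruit):
        profile = build_profile(fruit, [_aligned("Fruit", "Apple")])  # O at loc 0
        table = profile_by_location(profile, bins=[0.0, 0.5, 1.0])
        assert table.loc["overspecific", "(0.00,0.50]"] == 1


class TestDistanceMatrix:
    def test_counts(self, fruit):
        aligned = [
            _aligned("Granny Smith", "Conference pear"),
            _aligned("Apple", "Fruit", start=10),
            _aligned("Apple", "Apple", start=20),
        ]
        matrix = distance_matrix(build_profile(fruit, aligned))
        assert matrix.loc["orthogonal", 4] == 1
        assert matrix.loc["underspecific", 1] == 1

    def test_empty_when_no_mismatches(self, fruit):
        assert distance_matrix(build_profile(fruit, [_aligned("Apple", "Apple")])).empty

    def test_heatmap_render(self, fruit, tmp_path):
        from heleval.profiling import plot_profile_heatmap

        profile = build_profile(fruit, [_aligned("Granny Smith", "Conference pear")])
        out = tmp_path / "heatmap.png"
        plot_profile_heatmap(profile, out)
        assert out.stat().st_size > 0
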