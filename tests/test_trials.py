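import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viewmatch.trials import (
    TrialSpec,
    ZooCorrectness,
    assign_batches,
    bin_pairs_by_zoo,
    build_pairs,
    expand_pairs_to_trials,
    frame_to_trials,
    read_trials_csv,
    select_adversarial_pairs,
    trials_to_frame,
    write_trials_csv,
)


def catalog(n_cats=3, n_objs=6, n_views=4):
    objs_by_cat = {
        f"cat{c}": [f"c{c}_o{o}" for o in range(n_objs)] for c in range(n_cats)
    }
    views = [f"v{v:02d}" for v in range(n_views)]
    vcat = {o: list(views) for objs in objs_by_cat.values() for o in objs}
    category_of = {o: c for c, objs in objs_by_cat.items() for o in objs}
    return objs_by_cat, vcat, category_of


class TestBuildPairs:
    def test_unique_pair_from_two_objects(self):
        pairs = build_pairs({"c": ["a", "b"]}, n_pairs=1, seed=0)
        assert pairs == ["a|b"]

    def test_all_pairs_within_category(self):
        objs_by_cat, _, category_of = catalog(n_cats=4, n_objs=12)
        pairs = build_pairs(objs_by_cat, n_pairs=20, seed=1)
        assert len(set(pairs)) == 20
        for p in pairs:
            a, b = p.split("|")
            assert category_of[a] == category_of[b]

    def test_category_counts_roughly_uniform(self):
        # 100 pairs over 13 categories of 20 objects: multinomial 3-sigma
        # check (object-disjoint pairing caps each category at 10 pairs)
        objs_by_cat = {f"cat{c}": [f"c{c}_o{o}" for o in range(20)] for c in range(13)}
        pairs = build_pairs(objs_by_cat, n_pairs=100, seed=2)
        counts = pd.Series([p.split("|")[0].split("_")[0][1:] for p in pairs]).value_counts()
        expected = 100 / 13
        sd = np.sqrt(100 * (1 / 13) * (12 / 13))
        assert counts.max() < expected + 3 * sd
        assert counts.min() > expected - 3 * sd

    def test_pairs_are_object_disjoint(self):
        objs_by_cat, _, _ = catalog(n_cats=4, n_objs=10)
        pairs = build_pairs(objs_by_cat, n_pairs=15, seed=13)
        used = [o for p in pairs for o in p.split("|")]
        assert len(used) == len(set(used))

    def test_small_category_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            pairs = build_pairs({"tiny": ["only"], "ok": ["a", "b"]}, 1, seed=0)
        assert pairs == ["a|b"]

    def test_too_many_pairs_rejected(self):
        with pytest.raises(ValueError):
            build_pairs({"c": ["a", "b"]}, n_pairs=2, seed=0)


class TestExpandPairs:
    def test_two_trials_with_swapped_roles(self):
        _, vcat, category_of = catalog()
        trials = expand_pairs_to_trials(["c0_o0|c0_o1"], vcat, seed=0, category_of=category_of)
        assert len(trials) == 2
        first, second = trials
        assert first.sample[0] == first.target[0] == "c0_o0"
        assert first.lure[0] == "c0_o1"
        assert second.sample[0] == second.target[0] == "c0_o1"
        assert second.lure[0] == "c0_o0"

    def test_trials_to_pairs_ratio(self):
        objs_by_cat, vcat, category_of = catalog(n_cats=4, n_objs=10)
        pairs = build_pairs(objs_by_cat, 12, seed=3)
        trials = expand_pairs_to_trials(pairs, vcat, seed=4, category_of=category_of)
        assert len(trials) == 2 * len(pairs)

    def test_seeded_determinism(self):
        objs_by_cat, vcat, category_of = catalog()
        pairs = build_pairs(objs_by_cat, 8, seed=5)
        a = expand_pairs_to_trials(pairs, vcat, seed=6, category_of=category_of)
        b = expand_pairs_to_trials(pairs, vcat, seed=6, category_of=category_of)
        assert trials_to_frame(a).equals(trials_to_frame(b))

    def test_single_viewpoint_object_rejected(self):
        with pytest.raises(ValueError, match="viewpoints"):
            expand_pairs_to_trials(["a|b"], {"a": ["v0"], "b": ["v0", "v1"]}, seed=0)

    def test_type_invariants_enforced(self):
        with pytest.raises(ValueError):
            TrialSpec("t", "c", ("a", "v0"), ("b", "v1"), ("c", "v0"), "p")
        with pytest.raises(ValueError):
            TrialSpec("t", "c", ("a", "v0"), ("a", "v0"), ("b", "v0"), "p")
        with pytest.raises(ValueError):
            TrialSpec("t", "c", ("a", "v0"), ("a", "v1"), ("a", "v0"), "p")

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_emitted_trials_satisfy_invariants(self, seed):
        objs_by_cat, vcat, category_of = catalog(n_cats=2, n_objs=4, n_views=3)
        rng = np.random.default_rng(seed)
        pairs = build_pairs(objs_by_cat, int(rng.integers(1, 5)), seed=seed)
        trials = expand_pairs_to_trials(pairs, vcat, seed=seed, category_of=category_of)
        for t in trials:
            assert t.sample[0] == t.target[0]
            assert t.sample[1] != t.target[1]
            assert t.lure[0] != t.sample[0]
            assert category_of[t.lure[0]] == category_of[t.sample[0]]


class TestAssignBatches:
    def test_equal_batches_and_pair_split(self):
        objs_by_cat, vcat, category_of = catalog(n_objs=12)
        pairs = build_pairs(objs_by_cat, 150 // 10, seed=7)  # 15 pairs
        trials = expand_pairs_to_trials(pairs, vcat, seed=8, category_of=category_of)
        mapping = assign_batches(trials)
        frame = trials_to_frame(trials)
        sizes = frame.groupby("batch").size()
        assert sizes[0] == sizes[1] == len(pairs)
        for _, grp in frame.groupby("pair_id"):
            assert set(grp["batch"]) == {0, 1}
        assert set(mapping.values()) == {0, 1}

    def test_session_never_repeats_an_object(self):
        # exhaustive check on a 10-pair toy set: within one batch no object
        # appears in two different trials
        objs_by_cat, vcat, category_of = catalog(n_cats=5, n_objs=4)
        pairs = build_pairs(objs_by_cat, 10, seed=9)
        trials = expand_pairs_to_trials(pairs, vcat, seed=10, category_of=category_of)
        assign_batches(trials)
        for batch in (0, 1):
            seen: set[str] = set()
            for t in trials:
                if t.batch != batch:
                    continue
                objs = {t.sample[0], t.lure[0]}
                assert not objs & seen
                seen |= objs

    def test_unpaired_trials_rejected(self):
        _, vcat, category_of = catalog()
        trials = expand_pairs_to_trials(["c0_o0|c0_o1"], vcat, 0, category_of)
        with pytest.raises(ValueError):
            assign_batches(trials[:1])


def toy_zoo():
    # 10 pairs with mean accuracies 0.0, 0.1, ..., 0.9 across 2 models
    pair_ids = [f"p{i}" for i in range(10)]
    accs = np.arange(10) / 10
    return ZooCorrectness(np.stack([accs, accs]), ["m1", "m2"], pair_ids)


class TestZooOps:
    def test_quantile_partition_hand_case(self):
        bins = bin_pairs_by_zoo(toy_zoo(), n_bins=5)
        expected = {f"p{i}": i // 2 + 1 for i in range(10)}
        assert bins == expected

    def test_degenerate_equal_accuracy_warns(self):
        zoo = ZooCorrectness(np.ones((2, 4)), ["a", "b"], list("wxyz"))
        with pytest.warns(UserWarning, match="degenerate"):
            bin_pairs_by_zoo(zoo, 2)

    def test_fewer_pairs_than_bins_rejected(self):
        zoo = ZooCorrectness(np.ones((1, 3)), ["m"], list("abc"))
        with pytest.raises(ValueError):
            bin_pairs_by_zoo(zoo, 4)

    def test_select_hardest_pairs(self):
        assert select_adversarial_pairs(toy_zoo(), 2) == ["p0", "p1"]

    def test_select_everything(self):
        assert set(select_adversarial_pairs(toy_zoo(), 10)) == {f"p{i}" for i in range(10)}

    def test_selection_consistent_with_binning(self):
        zoo = toy_zoo()
        bins = bin_pairs_by_zoo(zoo, 5)
        hardest = select_adversarial_pairs(zoo, 4)
        assert all(bins[p] <= 2 for p in hardest)

    def test_tie_break_lexicographic(self):
        zoo = ZooCorrectness(np.array([[0.5, 0.5, 0.1]]), ["m"], ["b", "a", "c"])
        assert select_adversarial_pairs(zoo, 2) == ["c", "a"]

    def test_invalid_entries_rejected(self):
        with pytest.raises(ValueError):
            ZooCorrectness(np.array([[1.5]]), ["m"], ["p"])


class TestCsvRoundTrip:
    def test_exact_round_trip(self, tmp_path):
        objs_by_cat, vcat, category_of = catalog()
        pairs = build_pairs(objs_by_cat, 6, seed=11)
        trials = expand_pairs_to_trials(pairs, vcat, seed=12, category_of=category_of)
        assign_batches(trials)
        path = tmp_path / "trials.csv"
        write_trials_csv(trials, path)
        back = read_trials_csv(path)
        assert trials_to_frame(back).equals(trials_to_frame(trials))

    def test_frame_conversion_preserves_fields(self):
        _, vcat, category_of = catalog()
        trials = expand_pairs_to_trials(["c0_o0|c0_o1"], vcat, 0, category_of)
        assign_batches(trials)
        back = frame_to_trials(trials_to_frame(trials))
        assert back[0] == trials[0]
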