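"""Oracle suite for the alignment statistics: every closed-form example is
checked against an independent brute-force computation."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viewmatch import alignment
from viewmatch.alignment import (
    RandomObserverBand,
    ZeroVectorError,
    accuracy,
    match_trial,
    noise_ceiling,
    random_observer_band,
    stds_to_human,
    trialwise_similarity,
)


def brute_cosine(a, b):
    """Independent scalar-loop cosine."""
    num = sum(x * y for x, y in zip(a, b))
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(y * y for y in b))
    return num / (na * nb)


class TestMatchTrial:
    def test_identical_sample_target(self):
        assert match_trial([1, 0], [1, 0], [0, 1]) is True

    def test_hand_computed_cosines(self):
        # cos(sample,target) = 1/sqrt(2) ~ 0.707 > cos(sample,lure) = 0.5
        s, t, l = [1, 1, 0], [1, 0, 0], [0, 1, 1]
        assert abs(brute_cosine(s, t) - 1 / math.sqrt(2)) < 1e-12
        assert abs(brute_cosine(s, l) - 0.5) < 1e-12
        assert match_trial(s, t, l) is True

    def test_exact_tie_is_incorrect(self):
        # target and lure equidistant from the sample
        assert match_trial([1, 0], [1, 1], [1, -1]) is False

    def test_zero_vector_error_names_stimulus(self):
        with pytest.raises(ZeroVectorError, match="lure"):
            match_trial([1, 0], [0, 1], [0, 0])


class TestAccuracy:
    def test_basic_counting(self):
        assert accuracy([1, 1, 1]) == 1.0
        assert accuracy([1, 0, 1, 0]) == 0.5
        v = np.zeros(150)
        v[:135] = 1
        assert accuracy(v) == pytest.approx(0.9)

    def test_missing_entries_excluded(self):
        assert accuracy([1.0, np.nan, 0.0, np.nan]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy([])


class TestTrialwiseSimilarity:
    def test_perfect_agreement(self):
        assert trialwise_similarity([1, 1, 1], [1, 1, 1]) == pytest.approx(1.0)

    def test_hand_cosine(self):
        assert trialwise_similarity([1, 0], [1, 1]) == pytest.approx(1 / math.sqrt(2))

    def test_orthogonal(self):
        assert trialwise_similarity([0, 1], [1, 0]) == pytest.approx(0.0)

    def test_zero_model_vector_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert trialwise_similarity([0, 0], [1, 0.5]) == 0.0

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 40))
    def test_invariant_to_joint_permutation(self, seed, n):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 2, size=n).astype(float)
        if m.sum() == 0:
            m[0] = 1
        h = rng.random(n) + 0.01
        perm = rng.permutation(n)
        assert trialwise_similarity(m, h) == pytest.approx(
            trialwise_similarity(m[perm], h[perm]), abs=1e-12
        )

    def test_against_brute_force(self, rng):
        m = rng.integers(0, 2, size=20).astype(float)
        m[0] = 1
        h = rng.random(20)
        assert trialwise_similarity(m, h) == pytest.approx(
            brute_cosine(m, h), abs=1e-10
        )


def cohort_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "batch", "trial_id", "correct"])


class TestNoiseCeiling:
    def test_identical_all_correct(self):
        rows = [(p, 0, t, 1) for p in "abc" for t in ("t1", "t2")]
        nc, sd, per = noise_ceiling(cohort_frame(rows))
        assert nc == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)
        assert len(per) == 3

    def test_two_participant_hand_case(self):
        # p1 = (1, 0), p2 = (1, 1): both leave-one-out cosines are 1/sqrt(2)
        rows = [("p1", 0, "t1", 1), ("p1", 0, "t2", 0),
                ("p2", 0, "t1", 1), ("p2", 0, "t2", 1)]
        nc, sd, per = noise_ceiling(cohort_frame(rows))
        assert nc == pytest.approx(1 / math.sqrt(2))
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_private_trial_dropped_with_warning(self):
        rows = [("p1", 0, "t1", 1), ("p1", 0, "t2", 1),
                ("p2", 0, "t1", 1)]
        with pytest.warns(UserWarning, match="held-out"):
            nc, _, _ = noise_ceiling(cohort_frame(rows))
        assert nc == pytest.approx(1.0)


class TestStdsToHuman:
    def test_zero_at_reference(self):
        assert stds_to_human(0.89, 0.89, 0.05) == 0.0

    def test_arithmetic(self):
        assert stds_to_human(0.70, 0.89, 0.051) == pytest.approx(-3.7255, abs=1e-3)
        assert stds_to_human(0.93, 0.89, 0.051) == pytest.approx(0.7843, abs=1e-3)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            stds_to_human(0.5, 0.5, 0.0)


class TestRandomObserverBand:
    def test_full_accuracy_degenerate(self):
        h = np.array([0.8, 0.9, 1.0, 0.7])
        band = random_observer_band(h, n_sims=50, grid=np.array([1.0]), seed=0)
        assert band.lower[0] == pytest.approx(band.upper[0])
        # all-ones vector similarity
        expected = trialwise_similarity(np.ones(4), h)
        assert band.lower[0] == pytest.approx(expected)

    def test_constant_reference_closed_form(self):
        # with h constant, similarity of any k-correct vector is sqrt(k/n)
        n = 20
        h = np.full(n, 0.73)
        band = random_observer_band(h, n_sims=200, grid=np.array([0.25, 0.6]), seed=1)
        for gi, a in enumerate((0.25, 0.6)):
            k = round(a * n)
            expected = math.sqrt(k / n)
            assert band.lower[gi] == pytest.approx(expected, abs=1e-12)
            assert band.upper[gi] == pytest.approx(expected, abs=1e-12)

    def test_exhaustive_enumeration_small_n(self, rng):
        # n <= 12 trials: enumerate all C(n, k) placements exactly and check
        # the Monte-Carlo band edges carry the nominal 2.5% tail mass
        n, k = 9, 4
        h = rng.random(n) + 0.05
        sims_exact = np.array([
            brute_cosine(np.isin(np.arange(n), idx).astype(float), h)
            for idx in itertools.combinations(range(n), k)
        ])
        band = random_observer_band(h, n_sims=20_000, grid=np.array([k / n]), seed=3)
        assert np.mean(sims_exact < band.lower[0] - 1e-12) <= 0.035
        assert np.mean(sims_exact <= band.lower[0] + 1e-12) >= 0.015
        assert np.mean(sims_exact > band.upper[0] + 1e-12) <= 0.035
        assert np.mean(sims_exact >= band.upper[0] - 1e-12) >= 0.015

    def test_midpoint_nondecreasing_in_accuracy(self, rng):
        h = rng.random(40) + 0.2
        grid = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        band = random_observer_band(h, n_sims=2000, grid=grid, seed=4)
        mid = (band.lower + band.upper) / 2
        assert np.all(np.diff(mid) > -0.02)

    def test_contains_nearest_gridpoint(self):
        band = RandomObserverBand(
            np.array([0.4, 0.5]), np.array([0.2, 0.3]), np.array([0.6, 0.7]), 10
        )
        assert band.contains(0.41, 0.5)
        assert not band.contains(0.51, 0.2)

    def test_shuffled_outcomes_fall_inside_band(self, rng):
        # a vector with randomly placed correct responses is exactly the
        # band's null hypothesis: coverage should be near the 95% level
        n = 60
        h = np.clip(rng.beta(8, 2, size=n), 0.05, 1.0)
        band = random_observer_band(h, n_sims=1500, seed=5)
        hits = 0
        trials = 200
        for _ in range(trials):
            k = int(rng.integers(10, n))
            v = np.zeros(n)
            v[rng.choice(n, size=k, replace=False)] = 1
            hits += band.contains(k / n, trialwise_similarity(v, h))
        assert hits / trials >= 0.90
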