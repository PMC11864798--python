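"""Match-to-sample scoring and human-alignment statistics.

The central quantities:

* a trial is *correct* when cos(sample, target) strictly exceeds
  cos(sample, lure) in feature space (ties count as incorrect);
* *trial-wise similarity* between a responder and the cohort is the cosine
  between the responder's binary outcome vector and the cohort's per-trial
  mean accuracies;
* the *noise ceiling* is the leave-one-participant-out average of that
  similarity within the cohort;
* distances of a model score to the human distribution are reported in
  units of the human standard deviation (z-like "STD" scores);
* the *random-observer band* is the 95% interval of trial-wise similarity
  for responders whose k correct trials are placed uniformly at random, as
  a function of accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ZeroVectorError",
    "match_trial",
    "accuracy",
    "trialwise_similarity",
    "human_accuracy_vector",
    "noise_ceiling",
    "stds_to_human",
    "random_observer_band",
    "RandomObserverBand",
    "evaluate_feature_set",
]


class ZeroVectorError(ValueError):
    """Cosine similarity is undefined for an all-zero vector."""


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ZeroVectorError("cosine undefined for zero vector")
    return float(a @ b / (na * nb))


def match_trial(sample_f: np.ndarray, target_f: np.ndarray, lure_f: np.ndarray) -> bool:
    """One 2AFC decision in feature space.

    Correct iff cos(sample, target) > cos(sample, lure); an exact tie is
    counted incorrect.  Raises :class:`ZeroVectorError` naming the offending
    stimulus if any embedding is all-zero.
    """
    vecs = {"sample": np.asarray(sample_f, float),
            "target": np.asarray(target_f, float),
            "lure": np.asarray(lure_f, float)}
    for name, v in vecs.items():
        if np.linalg.norm(v) == 0:
            raise ZeroVectorError(f"all-zero embedding for {name} stimulus")
    cos_t = _cosine(vecs["sample"], vecs["target"])
    cos_l = _cosine(vecs["sample"], vecs["lure"])
    return cos_t > cos_l


def accuracy(outcomes: np.ndarray) -> float:
    """Mean of observed binary outcomes (NaN entries are unseen trials)."""
    v = np.asarray(outcomes, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("accuracy of an empty outcome vector")
    return float(v.mean())


def trialwise_similarity(model: np.ndarray, human_means: np.ndarray) -> float:
    """Cosine between a binary outcome vector and per-trial human means.

    Both vectors are non-negative so the value lies in [0, 1].  An all-zero
    model vector (accuracy 0) returns 0 with a warning instead of raising,
    so that baseline sweeps over the full accuracy grid stay defined.
    """
    m = np.asarray(model, dtype=float)
    h = np.asarray(human_means, dtype=float)
    if m.shape != h.shape:
        raise ValueError(f"trial count mismatch: {m.shape} vs {h.shape}")
    if np.linalg.norm(m) == 0:
        warnings.warn("all-zero outcome vector: similarity defined as 0", stacklevel=2)
        return 0.0
    return _cosine(m, h)


def human_accuracy_vector(responses: pd.DataFrame, trial_ids: list[str]) -> np.ndarray:
    """Per-trial mean correctness over the participants who saw each trial.

    ``responses`` is the long-format table (participant_id, trial_id,
    correct).  Every trial id must be observed at least once.
    """
    means = responses.groupby("trial_id")["correct"].mean()
    missing = [t for t in trial_ids if t not in means.index]
    if missing:
        raise ValueError(f"trials never observed by any participant: {missing[:5]}")
    return means.reindex(trial_ids).to_numpy(dtype=float)


def noise_ceiling(responses: pd.DataFrame) -> tuple[float, float, np.ndarray]:
    """Leave-one-participant-out agreement within a cohort.

    For each participant: cosine between their binary outcome vector (over
    the trials they saw) and the mean accuracies of all *other* participants
    on those same trials.  Trials seen only by the held-out participant are
    dropped from that comparison with a warning.

    Returns (mean, sd, per-participant array); sd is the population sd
    across participants (ddof 0).
    """
    pivot = responses.pivot_table(
        index="participant_id", columns="trial_id", values="correct", aggfunc="first"
    )
    mat = pivot.to_numpy(dtype=float)  # NaN = unseen
    n_obs = (~np.isnan(mat)).sum(axis=0)
    sums = np.nansum(mat, axis=0)
    per_participant = []
    for i in range(mat.shape[0]):
        seen = ~np.isnan(mat[i])
        others_n = n_obs - seen.astype(int)
        usable = seen & (others_n > 0)
        if usable.sum() < seen.sum():
            warnings.warn(
                "trial(s) observed only by the held-out participant dropped "
                "from the noise-ceiling comparison",
                stacklevel=2,
            )
        if usable.sum() == 0:
            raise ValueError("participant shares no trials with the rest of the cohort")
        loo_means = (sums[usable] - np.where(seen[usable], mat[i][usable], 0.0)) / others_n[usable]
        per_participant.append(trialwise_similarity(mat[i][usable], loo_means))
    per = np.asarray(per_participant)
    return float(per.mean()), float(per.std()), per


def stds_to_human(score: float, reference_mean: float, reference_sd: float) -> float:
    """Signed distance of a model score from the human reference, in human
    standard deviations: (score - mean) / sd."""
    if reference_sd <= 0:
        raise ValueError("reference sd must be positive")
    return (score - reference_mean) / reference_sd


@dataclass
class RandomObserverBand:
    accuracies: np.ndarray  # grid
    lower: np.ndarray  # 2.5th percentile of similarity
    upper: np.ndarray  # 97.5th percentile
    n_sims: int

    def contains(self, acc: float, similarity: float) -> bool:
        """Is (accuracy, similarity) inside the band at the nearest grid point?"""
        i = int(np.argmin(np.abs(self.accuracies - acc)))
        return bool(self.lower[i] <= similarity <= self.upper[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"accuracy": self.accuracies, "lower": self.lower, "upper": self.upper}
        )


def random_observer_band(
    human_means: np.ndarray,
    n_sims: int = 1000,
    grid: np.ndarray | None = None,
    seed: int = 0,
    level: float = 95.0,
) -> RandomObserverBand:
    """Null distribution of trial-wise similarity for random responders.

    For each accuracy ``a`` on the grid (default 0.01 ... 1.00 step 0.01),
    ``k = round(a * n_trials)`` (at least 1) correct responses are placed at
    uniformly random trial positions, the trial-wise similarity against the
    human means is computed, and the 2.5th/97.5th percentiles over ``n_sims``
    simulations form the band.  Percentiles use linear interpolation between
    order statistics (numpy default).
    """
    h = np.asarray(human_means, dtype=float)
    n_trials = h.size
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0001, 0.01), 2)
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (100 - level) / 2, 100 - (100 - level) / 2
    lower = np.empty(grid.size)
    upper = np.empty(grid.size)
    hn = h / np.linalg.norm(h)
    for gi, a in enumerate(grid):
        k = max(1, int(round(a * n_trials)))
        sims = np.empty(n_sims)
        for s in range(n_sims):
            idx = rng.choice(n_trials, size=k, replace=False)
            # cosine of a 0/1 vector with k ones against h
            sims[s] = hn[idx].sum() / np.sqrt(k)
        lower[gi] = np.percentile(sims, lo_q)
        upper[gi] = np.percentile(sims, hi_q)
    return RandomObserverBand(np.asarray(grid, dtype=float), lower, upper, n_sims)


def evaluate_feature_set(
    features,
    trials: pd.DataFrame,
) -> np.ndarray:
    """Run every trial of a trial table through feature-space matching.

    ``features`` maps (object_id, viewpoint_id) -> vector (the FeatureSet
    protocol from :mod:`viewmatch.observers`).  Returns the binary outcome
    vector in the table's row order.
    """
    out = np.empty(len(trials), dtype=float)
    for i, row in enumerate(trials.itertuples(index=False)):
        out[i] = match_trial(
            features[(row.sample_object, row.sample_view)],
            features[(row.target_object, row.target_view)],
            features[(row.lure_object, row.lure_view)],
        )
    return out
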