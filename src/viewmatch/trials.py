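"""Match-to-sample trial construction and adversarial selection.

Trials are built from within-category object pairs: each pair yields two
trials with the sample/target and lure roles swapped, the two trials of a
pair are always assigned to different participant batches (so no participant
ever sees an object twice), and pairs can be binned or filtered by the mean
accuracy of a model zoo to construct adversarial difficulty conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrialSpec",
    "ZooCorrectness",
    "build_pairs",
    "expand_pairs_to_trials",
    "assign_batches",
    "bin_pairs_by_zoo",
    "select_adversarial_pairs",
    "trials_to_frame",
    "frame_to_trials",
]

TRIAL_COLUMNS = [
    "trial_id",
    "pair_id",
    "category",
    "sample_object",
    "sample_view",
    "target_object",
    "target_view",
    "lure_object",
    "lure_view",
    "batch",
    "condition",
]


@dataclass
class TrialSpec:
    """One 2AFC trial: which rendered views play sample, target and lure."""

    trial_id: str
    category: str
    sample: tuple[str, str]  # (object_id, viewpoint_id)
    target: tuple[str, str]
    lure: tuple[str, str]
    pair_id: str
    batch: int = -1
    condition: str = ""

    def __post_init__(self) -> None:
        if self.sample[0] != self.target[0]:
            raise ValueError("sample and target must depict the same object")
        if self.lure[0] == self.sample[0]:
            raise ValueError("lure must be a different object")
        if self.sample[1] == self.target[1]:
            raise ValueError("sample and target must use different viewpoints")


@dataclass
class ZooCorrectness:
    """Models x pairs matrix of per-pair accuracy in [0, 1]."""

    matrix: np.ndarray
    model_ids: list[str]
    pair_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.model_ids), len(self.pair_ids)):
            raise ValueError("zoo matrix shape does not match id lists")
        if np.any((self.matrix < 0) | (self.matrix > 1)):
            raise ValueError("zoo entries must lie in [0, 1]")

    def mean_accuracy(self) -> pd.Series:
        return pd.Series(self.matrix.mean(axis=0), index=self.pair_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ZooCorrectness":
        """Rows = models, columns = pair ids, first column = model_id."""
        df = df.set_index("model_id")
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.matrix, columns=self.pair_ids)
        out.insert(0, "model_id", self.model_ids)
        return out


def pair_key(a: str, b: str) -> str:
    """Canonical unordered pair id."""
    lo, hi = sorted((a, b))
    return f"{lo}|{hi}"


def build_pairs(
    objects_by_category: dict[str, list[str]],
    n_pairs: int,
    seed: int,
    balance_categories: bool = False,
) -> list[str]:
    """Sample ``n_pairs`` object-disjoint within-category pairs.

    Each object joins at most one pair, so a participant batch built from
    these pairs never shows the same object twice (the novelty guarantee of
    the two-batch design).  Within each category objects are shuffled and
    paired up; the pooled candidate pairs are then drawn uniformly without
    replacement, or cycled per category with ``balance_categories``.
    Categories with fewer than two objects are skipped with a warning.
    Seeded and deterministic (object lists are id-sorted before shuffling).
    """
    rng = np.random.default_rng(seed)
    per_cat: dict[str, list[tuple[str, str]]] = {}
    for cat in sorted(objects_by_category):
        objs = sorted(objects_by_category[cat])
        if len(objs) < 2:
            warnings.warn(f"category {cat!r} has < 2 objects; skipped", stacklevel=2)
            continue
        rng.shuffle(objs)
        per_cat[cat] = [(objs[i], objs[i + 1]) for i in range(0, len(objs) - 1, 2)]
    total = sum(len(c) for c in per_cat.values())
    if n_pairs > total:
        raise ValueError(
            f"requested {n_pairs} object-disjoint pairs but only {total} are possible"
        )
    if balance_categories:
        chosen: list[tuple[str, str]] = []
        cats = sorted(per_cat)
        i = 0
        while len(chosen) < n_pairs:
            cat = cats[i % len(cats)]
            if per_cat[cat]:
                chosen.append(per_cat[cat].pop())
            i += 1
    else:
        pooled = [p for cat in sorted(per_cat) for p in per_cat[cat]]
        idx = rng.choice(len(pooled), size=n_pairs, replace=False)
        chosen = [pooled[i] for i in idx]
    return [pair_key(a, b) for a, b in chosen]


def expand_pairs_to_trials(
    pairs: list[str],
    viewpoint_catalog: dict[str, list[str]],
    seed: int,
    category_of: dict[str, str] | None = None,
) -> list[TrialSpec]:
    """Two trials per pair with sample/target and lure roles swapped.

    Viewpoints are drawn uniformly from each object's catalog with
    sample != target; the lure viewpoint is unconstrained.  Objects with a
    single rendered viewpoint are a structural error.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    for pid in pairs:
        a, b = pid.split("|")
        for o in (a, b):
            if len(viewpoint_catalog.get(o, [])) < 2:
                raise ValueError(f"object {o!r} has fewer than 2 rendered viewpoints")
        for sample_obj, lure_obj in ((a, b), (b, a)):
            views = sorted(viewpoint_catalog[sample_obj])
            sv, tv = rng.choice(len(views), size=2, replace=False)
            lure_views = sorted(viewpoint_catalog[lure_obj])
            lv = int(rng.integers(len(lure_views)))
            cat = category_of.get(sample_obj, "") if category_of else ""
            trials.append(
                TrialSpec(
                    trial_id=f"{pid}#{sample_obj}",
                    category=cat,
                    sample=(sample_obj, views[sv]),
                    target=(sample_obj, views[tv]),
                    lure=(lure_obj, lure_views[lv]),
                    pair_id=pid,
                )
            )
    return trials


def assign_batches(trials: list[TrialSpec]) -> dict[str, int]:
    """Split trials into two equal batches, the two trials of each pair in
    different batches.  The lexicographically first trial of each pair goes
    to batch 0."""
    by_pair: dict[str, list[TrialSpec]] = {}
    for t in trials:
        by_pair.setdefault(t.pair_id, []).append(t)
    mapping: dict[str, int] = {}
    for pid in sorted(by_pair):
        group = sorted(by_pair[pid], key=lambda t: t.trial_id)
        if len(group) != 2:
            raise ValueError(f"pair {pid!r} has {len(group)} trials (expected 2)")
        mapping[group[0].trial_id] = 0
        mapping[group[1].trial_id] = 1
    for t in trials:
        t.batch = mapping[t.trial_id]
    return mapping


def bin_pairs_by_zoo(zoo: ZooCorrectness, n_bins: int = 5) -> dict[str, int]:
    """Partition pairs into contiguous near-equal-count difficulty bins by
    mean zoo accuracy.  Bin 1 is the hardest (lowest accuracy); ties broken
    by pair id."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(zoo.pair_ids) < n_bins:
        raise ValueError("fewer pairs than bins")
    means = zoo.mean_accuracy()
    order = sorted(means.index, key=lambda p: (means[p], p))
    if means.nunique() == 1:
        warnings.warn("all pairs have identical zoo accuracy; binning is degenerate",
                      stacklevel=2)
    chunks = np.array_split(np.asarray(order, dtype=object), n_bins)
    return {pid: bi + 1 for bi, chunk in enumerate(chunks) for pid in chunk}


def select_adversarial_pairs(zoo: ZooCorrectness, k: int = 150) -> list[str]:
    """The ``k`` pairs with lowest mean zoo accuracy (hardest for the zoo),
    ties broken lexicographically by pair id."""
    if k > len(zoo.pair_ids):
        raise ValueError("k exceeds number of pairs")
    means = zoo.mean_accuracy()
    order = sorted(means.index, key=lambda p: (means[p], p))
    return order[:k]


# -- CSV round trip ----------------------------------------------------------


def trials_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    rows = [
        (
            t.trial_id,
            t.pair_id,
            t.category,
            t.sample[0],
            t.sample[1],
            t.target[0],
            t.target[1],
            t.lure[0],
            t.lure[1],
            t.batch,
            t.condition,
        )
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialSpec]:
    out = []
    for r in df.itertuples(index=False):
        out.append(
            TrialSpec(
                trial_id=str(r.trial_id),
                category="" if pd.isna(r.category) else str(r.category),
                sample=(str(r.sample_object), str(r.sample_view)),
                target=(str(r.target_object), str(r.target_view)),
                lure=(str(r.lure_object), str(r.lure_view)),
                pair_id=str(r.pair_id),
                batch=int(r.batch),
                condition="" if pd.isna(r.condition) else str(r.condition),
            )
        )
    return out


def write_trials_csv(trials: list[TrialSpec], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> list[TrialSpec]:
    return frame_to_trials(pd.read_csv(path, dtype=str).assign(
        batch=lambda d: d["batch"].astype(int)
    ))
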