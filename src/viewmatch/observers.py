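"""Synthetic cohorts and synthetic model features.

The response generator produces participant x trial binary correctness
tables with the structure the alignment statistics assume: per-trial
difficulty heterogeneity, per-participant skill offsets, and a two-batch
design in which each participant sees only the trials of their batch.

The feature generators produce the two idealised endpoints of the
viewpoint-invariance spectrum: embeddings that depend only on object
identity (plus isotropic noise), and embeddings scrambled by a shared
per-viewpoint rotation, which carry object information but are useless for
cross-view matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrialDifficultyProfile",
    "simulate_responses",
    "FeatureSet",
    "make_invariant_features",
    "make_entangled_features",
    "human_default_profile",
]


@dataclass
class TrialDifficultyProfile:
    """Per-trial probability that a typical participant answers correctly,
    plus a Gaussian per-participant skill-offset scale."""

    p: np.ndarray  # (n_trials,) in [0, 1]
    skill_sd: float = 0.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size == 0:
            raise ValueError("empty trial difficulty profile")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("trial probabilities must lie in [0, 1]")


def human_default_profile(
    n_trials: int,
    seed: int,
    mean_accuracy: float = 0.89,
    concentration: float = 10.0,
    skill_sd: float = 0.043,
) -> TrialDifficultyProfile:
    """Human-like difficulty profile.

    Per-trial difficulties are Beta(c*m, c*(1-m)) so their mean is
    ``mean_accuracy`` with heterogeneity set by the concentration ``c``.
    With 150 trials, binomial sampling alone gives a participant-accuracy sd
    of ~0.026; the default ``skill_sd`` of 0.043 brings the combined spread
    to ~0.05, matching a high-performing online cohort.
    """
    rng = np.random.default_rng(seed)
    a = concentration * mean_accuracy
    b = concentration * (1.0 - mean_accuracy)
    return TrialDifficultyProfile(rng.beta(a, b, size=n_trials), skill_sd=skill_sd)


def simulate_responses(
    profile: TrialDifficultyProfile,
    n_participants: int,
    batch_map: dict[str, int] | pd.Series,
    seed: int,
    trial_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate a two-batch cohort.

    Participants alternate between batches; participant ``i`` responds only
    to trials in their batch, with P(correct on trial t) =
    clamp(p_t + skill_i, 0, 1).  Returns the long-format response table
    (participant_id, batch, trial_id, correct), one row per observed
    response.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    batch_map = dict(batch_map)
    if not batch_map:
        raise ValueError("empty trial list")
    if trial_ids is None:
        trial_ids = sorted(batch_map)
    if len(trial_ids) != len(profile.p):
        raise ValueError("difficulty profile length does not match trial count")
    batches = sorted(set(batch_map.values()))
    rng = np.random.default_rng(seed)
    skills = rng.normal(0.0, profile.skill_sd, size=n_participants) if profile.skill_sd else np.zeros(n_participants)
    p_by_trial = dict(zip(trial_ids, profile.p))
    rows = []
    for i in range(n_participants):
        batch = batches[i % len(batches)]
        pid = f"p{i:04d}"
        for t in trial_ids:
            if batch_map[t] != batch:
                continue
            p = float(np.clip(p_by_trial[t] + skills[i], 0.0, 1.0))
            rows.append((pid, batch, t, int(rng.random() < p)))
    return pd.DataFrame(rows, columns=["participant_id", "batch", "trial_id", "correct"])


# -- features ----------------------------------------------------------------


@dataclass
class FeatureSet:
    """Per-stimulus embeddings: (object_id, viewpoint_id) -> vector."""

    vectors: dict[tuple[str, str], np.ndarray]
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent embedding dimensions: {dims}")

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        return self.vectors[key]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def dim(self) -> int:
        return next(iter(self.vectors.values())).size

    def matrix(self) -> tuple[np.ndarray, list[tuple[str, str]]]:
        keys = sorted(self.vectors)
        return np.stack([self.vectors[k] for k in keys]), keys

    # CSV + JSON-index container
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        mat, keys = self.matrix()
        np.savetxt(prefix.with_suffix(".csv"), mat, delimiter=",")
        index = {
            "provenance": self.provenance,
            "rows": [{"object_id": o, "viewpoint_id": v} for o, v in keys],
        }
        prefix.with_suffix(".json").write_text(json.dumps(index, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "FeatureSet":
        prefix = Path(prefix)
        mat = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", ndmin=2)
        index = json.loads(prefix.with_suffix(".json").read_text())
        vectors = {
            (r["object_id"], r["viewpoint_id"]): mat[i] for i, r in enumerate(index["rows"])
        }
        return cls(vectors, index.get("provenance", "loaded"))


def make_invariant_features(
    objects: list[str],
    viewpoints: list[str],
    dim: int = 32,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FeatureSet:
    """Viewpoint-invariant endpoint: one anchor vector per object, each view
    perturbed by isotropic Gaussian noise of scale ``noise_sd``."""
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)
    anchors = {o: rng.normal(size=dim) for o in objects}
    vectors = {
        (o, v): anchors[o] + (rng.normal(size=dim) * noise_sd if noise_sd else 0.0)
        for o in objects
        for v in viewpoints
    }
    return FeatureSet(vectors, "synthetic-invariant")


def make_entangled_features(
    objects: list[str],
    viewpoints: list[str],
    dim: int = 32,
    seed: int = 0,
) -> FeatureSet:
    """Viewpoint-entangled endpoint: embedding(o, v) = R_v u_o with a random
    rotation R_v shared across objects.  Within a viewpoint the object
    geometry is intact; across viewpoints vectors are scrambled, so 2AFC
    matching falls to chance."""
    if dim < 3:
        raise ValueError("dim must be >= 3")
    rng = np.random.default_rng(seed)
    anchors = {o: rng.normal(size=dim) for o in objects}
    rotations = {v: _random_rotation(dim, rng) for v in viewpoints}
    vectors = {(o, v): rotations[v] @ anchors[o] for o in objects for v in viewpoints}
    return FeatureSet(vectors, "synthetic-entangled")


def _random_rotation(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-distributed rotation via QR with sign fix, determinant +1."""
    a = rng.normal(size=(dim, dim))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# -- response-table I/O ------------------------------------------------------


def save_responses(responses: pd.DataFrame, path: str | Path) -> None:
    responses.to_csv(path, index=False)


def load_responses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "trial_id": str})
    required = {"participant_id", "batch", "trial_id", "correct"}
    if not required.issubset(df.columns):
        raise ValueError(f"response table must have columns {sorted(required)}")
    return df
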