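"""End-to-end experiment recipes.

One config drives the whole chain: procedural corpus -> renders -> trial
construction (two trials per pair, two-batch assignment) -> model training
and/or synthetic reference features -> simulated cohort -> alignment report
(accuracy, trial-wise similarity, STD distances, random-observer band).

Recipes supported: in-distribution (held-out objects of trained
categories), hold-one-category-out, and adversarial difficulty binning via
a model-zoo correctness matrix.  Per-stage seeds are derived from the
master seed by hashing the stage name so stages can be re-run
independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment
from .corpus import CorpusSpec, make_corpus
from .models import ModelConfig, StimulusDataset, extract_features, reduce_weights_pca, train_model
from .observers import (
    FeatureSet,
    human_default_profile,
    make_entangled_features,
    make_invariant_features,
    simulate_responses,
)
from .trials import (
    ZooCorrectness,
    assign_batches,
    bin_pairs_by_zoo,
    build_pairs,
    expand_pairs_to_trials,
    select_adversarial_pairs,
    trials_to_frame,
)

__all__ = ["ExperimentConfig", "run_experiment", "stage_seed", "load_mochi", "make_synthetic_zoo"]

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Independent per-stage seed: hash of (master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class ModelEntry:
    kind: str
    objective: str
    layer: str = "embedding"
    pca_components: int = 0  # 0 = no reduction
    config: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.kind}/{self.objective}/{self.layer}"


@dataclass
class ExperimentConfig:
    seed: int = 0
    n_categories: int = 6
    objects_per_category: int = 20
    views_per_object: int = 24
    resolution: tuple[int, int] = (32, 32)
    jitter: float = 0.35
    train_fraction: float = 0.75
    n_pairs: int = 30
    n_bins: int = 5
    select_k: int = 0  # 0 = keep all pairs
    holdout_category: str = ""
    n_participants: int = 40
    cohort_mean: float = 0.89
    cohort_concentration: float = 10.0
    cohort_skill_sd: float = 0.043
    band_sims: int = 1000
    models: list[ModelEntry] = field(
        default_factory=lambda: [
            ModelEntry("contrastive", "multi_view", "embedding"),
            ModelEntry("autoencoder", "single_view", "embedding"),
        ]
    )
    out_dir: str = "runs/experiment"

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        raw = json.loads(Path(path).read_text())
        raw["models"] = [ModelEntry(**m) for m in raw.get("models", [])]
        if "resolution" in raw:
            raw["resolution"] = tuple(raw["resolution"])
        return cls(**raw)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full recipe; returns the run manifest (also written to
    ``<out_dir>/manifest.json`` beside the stage CSVs)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "stages": {},
        "files": {},
    }
    (out / "config.json").write_text(config.to_json())

    def finish_stage(name: str, t0: float) -> None:
        manifest["stages"][name] = round(time.time() - t0, 3)
        log.info("stage %s done in %.1fs", name, manifest["stages"][name])

    # ---- corpus ----
    t0 = time.time()
    spec = CorpusSpec(
        n_categories=config.n_categories,
        objects_per_category=config.objects_per_category,
        views_per_object=config.views_per_object,
        resolution=tuple(config.resolution),
        jitter=config.jitter,
        seed=stage_seed(config.seed, "corpus"),
    )
    stimuli, categories = make_corpus(spec)
    dataset = StimulusDataset.from_stimuli(stimuli, categories)
    finish_stage("corpus", t0)

    # ---- object split ----
    n_train = int(round(config.train_fraction * config.objects_per_category))
    train_idx, test_idx = [], []
    for i, oid in enumerate(dataset.object_ids):
        (train_idx if int(oid.split("_o")[1]) < n_train else test_idx).append(i)
    train_ds = dataset.subset(train_idx)
    test_ds = dataset.subset(test_idx)
    if config.holdout_category:
        if config.holdout_category not in set(dataset.categories):
            raise ValueError(f"unknown holdout category {config.holdout_category!r}")
        train_ds = train_ds.without_categories({config.holdout_category})
        test_ds = test_ds.only_categories({config.holdout_category})

    # ---- trials ----
    t0 = time.time()
    objs_by_cat: dict[str, list[str]] = {}
    for i, oid in enumerate(test_ds.object_ids):
        objs_by_cat.setdefault(test_ds.categories[i], []).append(oid)
    pairs = build_pairs(objs_by_cat, config.n_pairs, stage_seed(config.seed, "pairs"))
    vcat = {o: dataset.viewpoint_ids[i] for i, o in enumerate(dataset.object_ids)}
    trials = expand_pairs_to_trials(
        pairs, vcat, stage_seed(config.seed, "trials"), category_of=categories
    )
    assign_batches(trials)
    trial_frame = trials_to_frame(trials)
    trial_frame.to_csv(out / "trials.csv", index=False)
    finish_stage("trials", t0)

    # ---- cohort ----
    t0 = time.time()
    trial_ids = list(trial_frame["trial_id"])
    profile = human_default_profile(
        len(trial_ids),
        stage_seed(config.seed, "difficulty"),
        mean_accuracy=config.cohort_mean,
        concentration=config.cohort_concentration,
        skill_sd=config.cohort_skill_sd,
    )
    batch_map = dict(zip(trial_frame["trial_id"], trial_frame["batch"]))
    responses = simulate_responses(
        profile,
        config.n_participants,
        batch_map,
        stage_seed(config.seed, "cohort"),
        trial_ids=trial_ids,
    )
    responses.to_csv(out / "responses.csv", index=False)
    finish_stage("cohort", t0)

    # ---- models / features ----
    t0 = time.time()
    eval_stimuli = [s for s in stimuli if s.object_id in set(test_ds.object_ids)]
    feature_sets: dict[str, FeatureSet] = {}
    for entry in config.models:
        mcfg = ModelConfig(seed=stage_seed(config.seed, f"train/{entry.name}"),
                           **entry.config)
        model = train_model(entry.kind, entry.objective, train_ds, mcfg)  # type: ignore[arg-type]
        fs = extract_features(model, eval_stimuli, entry.layer)
        if entry.pca_components:
            fs = reduce_weights_pca(fs, entry.pca_components)
        feature_sets[entry.name] = fs
    # idealised reference features bracket the model zoo
    objs = sorted({s.object_id for s in eval_stimuli})
    views = sorted({s.viewpoint_id for s in eval_stimuli})
    feature_sets["reference/invariant"] = make_invariant_features(
        objs, views, noise_sd=0.05, seed=stage_seed(config.seed, "ref-inv")
    )
    feature_sets["reference/entangled"] = make_entangled_features(
        objs, views, seed=stage_seed(config.seed, "ref-ent")
    )
    finish_stage("models", t0)

    # ---- evaluation ----
    t0 = time.time()
    human_means = alignment.human_accuracy_vector(responses, trial_ids)
    nc_mean, nc_sd, _ = alignment.noise_ceiling(responses)
    acc_by_participant = responses.groupby("participant_id")["correct"].mean()
    mu_h, sd_h = float(acc_by_participant.mean()), float(acc_by_participant.std(ddof=0))
    band = alignment.random_observer_band(
        human_means, n_sims=config.band_sims, seed=stage_seed(config.seed, "band")
    )
    band.to_frame().to_csv(out / "random_observer_band.csv", index=False)

    rows = []
    outcome_vectors: dict[str, np.ndarray] = {}
    for name, fs in feature_sets.items():
        outcomes = alignment.evaluate_feature_set(fs, trial_frame)
        outcome_vectors[name] = outcomes
        acc = alignment.accuracy(outcomes)
        sim = alignment.trialwise_similarity(outcomes, human_means)
        rows.append(
            {
                "model": name,
                "accuracy": acc,
                "similarity": sim,
                "stds_to_human_accuracy": alignment.stds_to_human(acc, mu_h, sd_h),
                "stds_to_noise_ceiling": alignment.stds_to_human(sim, nc_mean, nc_sd),
                "inside_random_band": band.contains(acc, sim),
            }
        )
    report = pd.DataFrame(rows)
    report.to_csv(out / "alignment_report.csv", index=False)

    # difficulty conditions defined by the trained zoo
    zoo = zoo_from_outcomes(outcome_vectors, trial_frame)
    condition_frame = None
    if len(pairs) >= config.n_bins:
        bins = bin_pairs_by_zoo(zoo, config.n_bins)
        trial_frame["condition"] = [f"bin{bins[p]}" for p in trial_frame["pair_id"]]
        trial_frame.to_csv(out / "trials.csv", index=False)
        cond_rows = []
        tmean = dict(zip(trial_ids, human_means))
        for cond, grp in trial_frame.groupby("condition"):
            row = {"condition": cond, "n_trials": len(grp),
                   "human_accuracy": float(np.mean([tmean[t] for t in grp["trial_id"]]))}
            for name, vec in outcome_vectors.items():
                sel = trial_frame["condition"].to_numpy() == cond
                row[f"acc[{name}]"] = float(vec[sel].mean())
            cond_rows.append(row)
        condition_frame = pd.DataFrame(cond_rows).sort_values("condition")
        condition_frame.to_csv(out / "condition_report.csv", index=False)
    if config.select_k and config.select_k <= len(pairs):
        hardest = select_adversarial_pairs(zoo, config.select_k)
        (out / "adversarial_pairs.json").write_text(json.dumps(hardest, indent=1))
    finish_stage("evaluate", t0)

    manifest["summary"] = {
        "human_accuracy_mean": mu_h,
        "human_accuracy_sd": sd_h,
        "noise_ceiling_mean": nc_mean,
        "noise_ceiling_sd": nc_sd,
        "n_trials": len(trial_ids),
        "n_pairs": len(pairs),
        "models": {r["model"]: {"accuracy": r["accuracy"], "similarity": r["similarity"]}
                   for r in rows},
    }
    for f in sorted(out.glob("*.csv")):
        manifest["files"][f.name] = _checksum(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def zoo_from_outcomes(outcome_vectors: dict[str, np.ndarray],
                      trial_frame: pd.DataFrame) -> ZooCorrectness:
    """Per-pair accuracy matrix (mean over each pair's two trials) from
    trial-level model outcomes."""
    pair_ids = sorted(trial_frame["pair_id"].unique())
    pair_pos = {p: i for i, p in enumerate(pair_ids)}
    model_ids = sorted(outcome_vectors)
    mat = np.zeros((len(model_ids), len(pair_ids)))
    pair_col = trial_frame["pair_id"].to_numpy()
    for mi, name in enumerate(model_ids):
        vec = outcome_vectors[name]
        sums = np.zeros(len(pair_ids))
        cnt = np.zeros(len(pair_ids))
        for t, p in enumerate(pair_col):
            sums[pair_pos[p]] += vec[t]
            cnt[pair_pos[p]] += 1
        mat[mi] = sums / np.maximum(cnt, 1)
    return ZooCorrectness(mat, model_ids, pair_ids)


def make_synthetic_zoo(pair_ids: list[str], n_models: int = 25, seed: int = 0,
                       mean: float = 0.55, concentration: float = 4.0) -> ZooCorrectness:
    """Synthetic stand-in for a pretrained model zoo: per-pair difficulty is
    Beta-distributed and shared across models, with independent binomial
    noise per model (two trials per pair, so accuracy in {0, .5, 1})."""
    rng = np.random.default_rng(seed)
    p = rng.beta(concentration * mean, concentration * (1 - mean), size=len(pair_ids))
    mat = rng.binomial(2, p, size=(n_models, len(pair_ids))) / 2.0
    return ZooCorrectness(mat, [f"zoo{m:02d}" for m in range(n_models)], list(pair_ids))


# -- optional loader for deposited behavioural data --------------------------

_PARTICIPANT_COLS = ("participant_id", "participant", "subject", "subj", "worker_id", "prolific_id")
_TRIAL_COLS = ("trial_id", "trial", "trial_index", "stimulus_id")
_CORRECT_COLS = ("correct", "accuracy", "acc", "is_correct")


def load_mochi(path: str | Path) -> pd.DataFrame:
    """Map a locally deposited behavioural response table into the long
    response schema (participant_id, batch, trial_id, correct).

    Optional: the pipeline never requires this.  Raises a format error
    listing the expected columns if the file is missing or unrecognised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found; expected a local copy of the deposited behavioural "
            "responses (CSV with participant, trial and correctness columns)"
        )
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}

    def pick(options: tuple[str, ...]) -> str | None:
        for o in options:
            if o in cols:
                return cols[o]
        return None

    pcol, tcol, ccol = pick(_PARTICIPANT_COLS), pick(_TRIAL_COLS), pick(_CORRECT_COLS)
    if not (pcol and tcol and ccol):
        raise ValueError(
            "unrecognised behavioural file format: need participant "
            f"({'/'.join(_PARTICIPANT_COLS)}), trial ({'/'.join(_TRIAL_COLS)}) and "
            f"correctness ({'/'.join(_CORRECT_COLS)}) columns; found {list(df.columns)}"
        )
    bcol = pick(("batch", "batch_id", "experiment_batch"))
    correct = df[ccol].astype(float)
    if not correct.isin((0.0, 1.0)).all():
        raise ValueError("correctness column does not binarise to {0, 1}")
    return pd.DataFrame(
        {
            "participant_id": df[pcol].astype(str),
            "batch": df[bcol] if bcol else 0,
            "trial_id": df[tcol].astype(str),
            "correct": correct.astype(int),
        }
    )
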