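"""Desk-scale single-view and multi-view networks.

Four model kinds, each structurally faithful to its full-scale counterpart
but narrow enough to train on a CPU:

* ``lfn`` — a conditional light field network: a convolutional encoder
  infers a shape latent from one image, per-field-layer two-layer
  hypernetworks map the latent to the weights of a ray-field MLP, and the
  field renders views by mapping the Plucker coordinates of one ray per
  pixel to that pixel's colour.  The multi-view objective renders a
  *different* view of the object (camera pose given at render time only);
  the single-view objective re-renders the input view.
* ``autoencoder`` — encoder to latent, MLP decoder back to pixels.  The
  multi-view variant appends a learned embedding of the target camera
  extrinsics to the latent and reconstructs the target view.
* ``contrastive`` — the encoder trained with in-batch InfoNCE to pull two
  views of the same object together against other objects in the minibatch
  (multi-view by construction).
* ``classifier`` — encoder plus linear readout trained with cross-entropy
  on category labels (single-view by construction).

Feature extraction returns the latents, the flattened field weights, the
contrastive embedding, or the classifier's penultimate layer, matching how
the corresponding layers are read out at full scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from sklearn.decomposition import PCA

from .camera import CameraPose, all_pixel_rays
from .nn import MLP, Adam, Conv2d, Linear, Module, Tensor, concat, logsumexp
from .observers import FeatureSet
from .render import Stimulus

__all__ = [
    "ModelConfig",
    "StimulusDataset",
    "ConvEncoder",
    "LightFieldNetwork",
    "Autoencoder",
    "ContrastiveEncoder",
    "Classifier",
    "train_model",
    "extract_features",
    "reduce_weights_pca",
    "info_nce",
]

Kind = Literal["lfn", "autoencoder", "contrastive", "classifier"]
Objective = Literal["single_view", "multi_view"]


@dataclass
class ModelConfig:
    """Training and architecture hyperparameters (mini defaults)."""

    seed: int = 0
    epochs: int = 20
    batch_size: int = 8
    lr: float = 2e-3
    latent_dim: int = 32
    enc_channels: tuple[int, ...] = (8, 16, 32)
    field_hidden: int = 32
    field_layers: int = 4
    hyper_hidden: int = 64
    cam_embed_dim: int = 16
    temperature: float = 0.07
    rays_per_image: int = 96
    decoder_hidden: int = 128
    mask_background: bool = False


# -- data --------------------------------------------------------------------


@dataclass
class StimulusDataset:
    """Rendered views grouped by object: images (n_obj, n_view, H, W)."""

    images: np.ndarray
    poses: list[list[CameraPose]]
    object_ids: list[str]
    viewpoint_ids: list[list[str]]
    categories: list[str]

    @property
    def n_objects(self) -> int:
        return self.images.shape[0]

    @property
    def n_views(self) -> int:
        return self.images.shape[1]

    @property
    def resolution(self) -> tuple[int, int]:
        return self.images.shape[2], self.images.shape[3]

    @classmethod
    def from_stimuli(cls, stimuli: list[Stimulus], categories: dict[str, str] | None = None
                     ) -> "StimulusDataset":
        by_obj: dict[str, list[Stimulus]] = {}
        for s in stimuli:
            by_obj.setdefault(s.object_id, []).append(s)
        object_ids = sorted(by_obj)
        n_views = {len(v) for v in by_obj.values()}
        if len(n_views) != 1:
            raise ValueError("all objects must have the same number of views")
        for oid in object_ids:
            by_obj[oid].sort(key=lambda s: s.viewpoint_id)
        images = np.stack([np.stack([s.image for s in by_obj[o]]) for o in object_ids])
        poses = [[s.pose for s in by_obj[o]] for o in object_ids]
        vids = [[s.viewpoint_id for s in by_obj[o]] for o in object_ids]
        cats = [categories.get(o, "") if categories else "" for o in object_ids]
        return cls(images, poses, object_ids, vids, cats)

    def subset(self, object_indices: list[int]) -> "StimulusDataset":
        idx = list(object_indices)
        return StimulusDataset(
            self.images[idx],
            [self.poses[i] for i in idx],
            [self.object_ids[i] for i in idx],
            [self.viewpoint_ids[i] for i in idx],
            [self.categories[i] for i in idx],
        )

    def without_categories(self, held_out: set[str]) -> "StimulusDataset":
        return self.subset([i for i, c in enumerate(self.categories) if c not in held_out])

    def only_categories(self, kept: set[str]) -> "StimulusDataset":
        return self.subset([i for i, c in enumerate(self.categories) if c in kept])


# -- building blocks ---------------------------------------------------------


class ConvEncoder(Module):
    """Strided conv stack with a linear latent readout; input (N, 1, H, W)."""

    def __init__(self, resolution: tuple[int, int], latent_dim: int,
                 channels: tuple[int, ...], rng: np.random.Generator):
        h, w = resolution
        self.convs = []
        c_in = 1
        for c_out in channels:
            self.convs.append(Conv2d(c_in, c_out, kernel=3, stride=2, rng=rng))
            h = (h - 3) // 2 + 1
            w = (w - 3) // 2 + 1
            if h < 1 or w < 1:
                raise ValueError("resolution too small for the encoder stack")
            c_in = c_out
        self.flat_dim = c_in * h * w
        self.readout = Linear(self.flat_dim, latent_dim, rng)
        self.latent_dim = latent_dim
        self.resolution = resolution

    def __call__(self, images: Tensor) -> Tensor:
        if images.shape[2:] != self.resolution:
            raise ValueError(
                f"encoder expects resolution {self.resolution}, got {images.shape[2:]}"
            )
        x = images
        for conv in self.convs:
            x = conv(x).relu()
        x = x.reshape(x.shape[0], self.flat_dim)
        return self.readout(x)


def _field_dims(config: ModelConfig) -> list[int]:
    """Ray-field MLP layer sizes: 6 Plucker inputs -> hidden -> 3 RGB."""
    return [6] + [config.field_hidden] * (config.field_layers - 1) + [3]


class HyperNetwork(Module):
    """One two-layer MLP per field layer, mapping latent -> that layer's
    weights and bias (emitted as a (fan_in + 1, fan_out) block)."""

    def __init__(self, latent_dim: int, field_dims: list[int], hidden: int,
                 rng: np.random.Generator):
        self.field_dims = field_dims
        self.heads = []
        for fan_in, fan_out in zip(field_dims[:-1], field_dims[1:]):
            head = MLP([latent_dim, hidden, (fan_in + 1) * fan_out], rng)
            # start the emitted field near zero so early renders are stable
            head.layers[-1].weight.data *= 0.05
            self.heads.append(head)

    def __call__(self, latent: Tensor) -> list[Tensor]:
        out = []
        for head, fan_in, fan_out in zip(self.heads, self.field_dims[:-1], self.field_dims[1:]):
            w = head(latent)
            out.append(w.reshape(latent.shape[0], fan_in + 1, fan_out))
        return out


def field_forward(layer_weights: list[Tensor], rays: Tensor) -> Tensor:
    """Evaluate the ray field: rays (B, R, 6) -> colours (B, R, 3).

    ``layer_weights[l]`` is (B, fan_in + 1, fan_out); the last row is the
    bias.  ReLU between layers; the RGB head is linear (a squashing output
    saturates against the constant-background solution and kills the
    gradient before any ray structure is learned).
    """
    x = rays
    n = len(layer_weights)
    for l, wb in enumerate(layer_weights):
        w = wb[:, :-1, :]
        b = wb[:, -1:, :]
        x = x @ w + b
        if l < n - 1:
            x = x.relu()
    return x


# -- models ------------------------------------------------------------------


class LightFieldNetwork(Module):
    def __init__(self, resolution: tuple[int, int], config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.encoder = ConvEncoder(resolution, config.latent_dim, config.enc_channels, rng)
        self.field_dims = _field_dims(config)
        self.hyper = HyperNetwork(config.latent_dim, self.field_dims, config.hyper_hidden, rng)
        self.kind = "lfn"
        self.objective: str = ""
        self.loss_trace: list[float] = []

    def encode(self, images: np.ndarray) -> Tensor:
        x = Tensor(images[:, None, :, :])
        return self.encoder(x)

    def forward(self, images: np.ndarray) -> tuple[Tensor, list[Tensor]]:
        """Images -> (latents, per-layer field weights); no cameras needed."""
        latent = self.encode(images)
        return latent, self.hyper(latent)

    def weights_flat(self, layer_weights: list[Tensor]) -> np.ndarray:
        """Flatten field weights in fixed order: for each layer, the weight
        matrix row-major then the bias."""
        return np.concatenate(
            [wb.data.reshape(wb.shape[0], -1) for wb in layer_weights], axis=1
        )

    def unflatten_weights(self, flat: np.ndarray) -> list[Tensor]:
        out = []
        pos = 0
        for fan_in, fan_out in zip(self.field_dims[:-1], self.field_dims[1:]):
            size = (fan_in + 1) * fan_out
            out.append(Tensor(flat[pos : pos + size].reshape(1, fan_in + 1, fan_out)))
            pos += size
        if pos != flat.size:
            raise ValueError(f"flat weight vector has {flat.size} entries, expected {pos}")
        return out

    def render(self, layer_weights: list[Tensor], pose: CameraPose) -> np.ndarray:
        """Render one view from field weights: (H, W, 3) in [0, 1]."""
        rays = Tensor(all_pixel_rays(pose)[None, :, :])
        colours = field_forward(layer_weights, rays)
        h, w = pose.resolution
        return colours.data.reshape(h, w, 3)


def lfn_render(model: LightFieldNetwork, flat_weights: np.ndarray, pose: CameraPose) -> np.ndarray:
    """Deterministic per-pixel rendering from a flattened weight vector."""
    return model.render(model.unflatten_weights(np.asarray(flat_weights, float)), pose)


class Autoencoder(Module):
    def __init__(self, resolution: tuple[int, int], config: ModelConfig,
                 objective: Objective = "single_view"):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.objective = objective
        self.kind = "autoencoder"
        self.resolution = resolution
        self.encoder = ConvEncoder(resolution, config.latent_dim, config.enc_channels, rng)
        dec_in = config.latent_dim
        if objective == "multi_view":
            self.cam_embed = Linear(12, config.cam_embed_dim, rng)
            dec_in += config.cam_embed_dim
        h, w = resolution
        self.decoder = MLP([dec_in, config.decoder_hidden, h * w], rng)
        self.loss_trace: list[float] = []

    def embed_camera(self, poses: list[CameraPose]) -> Tensor:
        mats = np.stack([p.extrinsic().ravel() for p in poses])
        return self.cam_embed(Tensor(mats))

    def decode(self, latent: Tensor, target_poses: list[CameraPose] | None = None) -> Tensor:
        z = latent
        if self.objective == "multi_view":
            if target_poses is None:
                raise ValueError("multi-view decoder needs target camera poses")
            z = concat([z, self.embed_camera(target_poses)], axis=1)
        h, w = self.resolution
        return self.decoder(z).sigmoid().reshape(z.shape[0], h, w)

    def encode(self, images: np.ndarray) -> Tensor:
        return self.encoder(Tensor(images[:, None, :, :]))


class ContrastiveEncoder(Module):
    def __init__(self, resolution: tuple[int, int], config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.kind = "contrastive"
        self.objective = "multi_view"
        self.encoder = ConvEncoder(resolution, config.latent_dim, config.enc_channels, rng)
        self.loss_trace: list[float] = []

    def encode(self, images: np.ndarray) -> Tensor:
        return self.encoder(Tensor(images[:, None, :, :]))


class Classifier(Module):
    def __init__(self, resolution: tuple[int, int], config: ModelConfig, n_classes: int):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.kind = "classifier"
        self.objective = "single_view"
        self.encoder = ConvEncoder(resolution, config.latent_dim, config.enc_channels, rng)
        self.head = Linear(config.latent_dim, n_classes, rng)
        self.loss_trace: list[float] = []

    def encode(self, images: np.ndarray) -> Tensor:
        return self.encoder(Tensor(images[:, None, :, :]))

    def logits(self, images: np.ndarray) -> Tensor:
        return self.head(self.encode(images))


# -- losses ------------------------------------------------------------------


def info_nce(anchors: Tensor, candidates: Tensor, positive_idx: np.ndarray,
             temperature: float = 0.07) -> Tensor:
    """InfoNCE over cosine similarities.

    Row ``i`` of ``anchors`` is scored against every row of ``candidates``;
    ``candidates[positive_idx[i]]`` is its positive, the rest are negatives:
    ``-log softmax(cos / temperature)`` averaged over anchors.
    """
    a = _l2_normalize(anchors)
    c = _l2_normalize(candidates)
    logits = (a @ c.transpose()) * (1.0 / temperature)
    lse = logsumexp(logits, axis=1)
    pos = logits[np.arange(logits.shape[0]), np.asarray(positive_idx)]
    return (lse - pos).mean()


def _l2_normalize(x: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=1, keepdims=True) + eps) ** 0.5
    return x / norm


def _mse(pred: Tensor, target: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    diff = pred - Tensor(target)
    if mask is not None:
        diff = diff * Tensor(mask)
        return (diff * diff).sum() / float(max(mask.sum(), 1.0) * _trailing(pred, mask))
    return (diff * diff).mean()


def _trailing(pred: Tensor, mask: np.ndarray) -> float:
    # channels broadcast against a (B, R, 1) mask
    return float(np.prod(pred.shape) / np.prod(mask.shape))


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    lse = logsumexp(logits, axis=1)
    true = logits[np.arange(logits.shape[0]), np.asarray(labels)]
    return (lse - true).mean()


# -- training ----------------------------------------------------------------


def train_model(
    kind: Kind,
    objective: Objective,
    dataset: StimulusDataset,
    config: ModelConfig,
    class_labels: list[str] | None = None,
) -> Module:
    """Train a mini model; returns it with a per-epoch loss trace attached.

    ``contrastive`` requires the multi-view objective and ``classifier`` the
    single-view objective.  Multi-view objectives require at least two views
    per object.  Single-view paths index exactly one view per sample and
    never touch a second.
    """
    if kind == "contrastive" and objective != "multi_view":
        raise ValueError("the contrastive model is multi-view by construction")
    if kind == "classifier" and objective != "single_view":
        raise ValueError("the classifier is single-view by construction")
    if objective == "multi_view" and dataset.n_views < 2:
        raise ValueError("multi-view objective needs >= 2 views per object")

    res = dataset.resolution
    if kind == "lfn":
        model: Module = LightFieldNetwork(res, config)
        model.objective = objective
    elif kind == "autoencoder":
        model = Autoencoder(res, config, objective)
    elif kind == "contrastive":
        model = ContrastiveEncoder(res, config)
    elif kind == "classifier":
        cats = sorted(set(dataset.categories))
        labels = class_labels if class_labels is not None else cats
        model = Classifier(res, config, n_classes=max(len(labels), 2))
        model.class_labels = labels  # type: ignore[attr-defined]
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.parameters(), lr=config.lr)
    n_obj = dataset.n_objects
    steps_per_epoch = max(1, n_obj // config.batch_size)

    for _epoch in range(config.epochs):
        epoch_losses = []
        for _step in range(steps_per_epoch):
            objs = rng.choice(n_obj, size=min(config.batch_size, n_obj), replace=False)
            loss = _training_step(model, kind, objective, dataset, objs, rng, config)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        model.loss_trace.append(float(np.mean(epoch_losses)))
    return model


def _training_step(model, kind, objective, dataset, objs, rng, config) -> Tensor:
    if kind == "contrastive":
        v = rng.integers(dataset.n_views, size=(len(objs), 2))
        # ensure the two views differ
        clash = v[:, 0] == v[:, 1]
        v[clash, 1] = (v[clash, 1] + 1) % dataset.n_views
        im1 = dataset.images[objs, v[:, 0]]
        im2 = dataset.images[objs, v[:, 1]]
        z1 = model.encode(im1)
        z2 = model.encode(im2)
        idx = np.arange(len(objs))
        return (
            info_nce(z1, z2, idx, config.temperature)
            + info_nce(z2, z1, idx, config.temperature)
        ) * 0.5

    if kind == "classifier":
        v = rng.integers(dataset.n_views, size=len(objs))
        images = dataset.images[objs, v]
        labels = np.array(
            [model.class_labels.index(dataset.categories[o]) for o in objs]
        )
        return _cross_entropy(model.logits(images), labels)

    # rendering objectives (lfn, autoencoder)
    v_in = rng.integers(dataset.n_views, size=len(objs))
    if objective == "multi_view":
        v_out = rng.integers(dataset.n_views, size=len(objs))
        clash = v_in == v_out
        v_out[clash] = (v_out[clash] + 1) % dataset.n_views
    else:
        v_out = v_in
    images_in = dataset.images[objs, v_in]
    images_out = dataset.images[objs, v_out]
    poses_out = [dataset.poses[o][vo] for o, vo in zip(objs, v_out)]

    if kind == "autoencoder":
        latent = model.encode(images_in)
        pred = model.decode(latent, poses_out if objective == "multi_view" else None)
        return _mse(pred, images_out)

    # lfn: render a random subset of the target view's rays
    latent, layer_weights = model.forward(images_in)
    h, w = dataset.resolution
    n_pix = h * w
    ray_idx = rng.choice(n_pix, size=min(config.rays_per_image, n_pix), replace=False)
    rays = np.stack([all_pixel_rays(p)[ray_idx] for p in poses_out])
    target = images_out.reshape(len(objs), n_pix)[:, ray_idx]
    target_rgb = np.repeat(target[:, :, None], 3, axis=2)
    pred = field_forward(layer_weights, Tensor(rays))
    mask = None
    if config.mask_background:
        mask = (target > 0).astype(float)[:, :, None]
    return _mse(pred, target_rgb, mask)


# -- feature extraction ------------------------------------------------------

_VALID_LAYERS = {
    "lfn": {"latents", "field_weights"},
    "autoencoder": {"embedding"},
    "contrastive": {"embedding"},
    "classifier": {"penultimate"},
}


def extract_features(model: Module, stimuli: list[Stimulus], layer: str) -> FeatureSet:
    """One embedding vector per stimulus from the requested layer."""
    kind = model.kind
    if layer not in _VALID_LAYERS[kind]:
        raise ValueError(f"layer {layer!r} invalid for model kind {kind!r}; "
                         f"choose from {sorted(_VALID_LAYERS[kind])}")
    images = np.stack([s.image for s in stimuli])
    if kind == "lfn":
        latent, layer_weights = model.forward(images)
        mat = latent.data if layer == "latents" else model.weights_flat(layer_weights)
    else:
        mat = model.encode(images).data
    vectors = {
        (s.object_id, s.viewpoint_id): mat[i].copy() for i, s in enumerate(stimuli)
    }
    return FeatureSet(vectors, provenance=f"{kind}/{model.objective}/{layer}")


def reduce_weights_pca(features: FeatureSet, n_components: int,
                       fit_keys: list[tuple[str, str]] | None = None) -> FeatureSet:
    """Centered PCA projection of a feature set onto its top components.

    Fit on ``fit_keys`` (default: all keys, i.e. the evaluation stimuli
    themselves) and applied to every vector; the projection matrix is kept
    on the result as ``projection``.
    """
    mat, keys = features.matrix()
    if n_components > min(mat.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, dim)={min(mat.shape)}"
        )
    if fit_keys is None:
        fit = mat
    else:
        key_to_row = {k: i for i, k in enumerate(keys)}
        fit = mat[[key_to_row[k] for k in fit_keys]]
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(fit)
    reduced = pca.transform(mat)
    out = FeatureSet(
        {k: reduced[i].copy() for i, k in enumerate(keys)},
        provenance=f"{features.provenance}+pca{n_components}",
    )
    out.projection = pca  # type: ignore[attr-defined]
    return out
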