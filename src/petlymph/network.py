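"""Multi-resolution-pathway 3D patch CNN for lymphoma segmentation.

The architecture follows the DeepMedic design: per resolution pathway,
eight valid (unpadded) 3x3x3 convolutions; the down-sampled pathways see
the same world location at coarser resolution (block-averaged by factors
such as 3 and 5), their outputs are upsampled by nearest-neighbour
repetition and aligned with the normal-resolution output tile; the
concatenated features pass through two 1x1x1 "fully connected" layers and
a final per-voxel 2-class softmax.  With eight valid convolutions a
25^3 input segment yields a 9^3 output tile.

Implementation notes
--------------------
* Pure NumPy (see :mod:`petlymph.nn`): im2col + BLAS matmul, explicit
  backprop, Adam.  Sized for CPU-scale experiments.
* The coarse grid of each down-sampled pathway is anchored at the volume
  origin (cell ``j`` covers voxels ``[k*j, k*j + k)``), for training
  patches and dense inference alike.  Dense inference is therefore exactly
  equal to tiled inference, tile by tile, regardless of tiling.
* Input channels are z-scored PET and CT (CT clipped to [-1000, 1000] HU
  before normalization); both normalized against the CT-derived body mask.
* Out-of-volume context is edge-padded (clamped indexing), never shrunk.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .image_model import CaseRecord, Modality, Volume, body_mask, normalize

__all__ = [
    "NetworkConfig",
    "TrainingPatch",
    "PreparedCase",
    "MultiResCNN",
    "TrainingError",
    "prepare_case",
    "build_network",
    "sample_patches",
    "train",
    "predict_probability",
    "binarize",
    "save_model",
    "load_model",
]


@dataclass
class NetworkConfig:
    """Architecture plus training hyper-parameters for one CNN."""

    n_pathways: int = 3
    downsample_factors: tuple = (1, 3, 5)
    conv_features: tuple = (90, 90, 110, 110, 110, 110, 130, 130)
    kernel: int = 3
    fc_features: int = 250
    n_classes: int = 2
    in_channels: int = 2
    patch_size: int = 25
    seed: int = 0
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 10
    batches_per_epoch: int = 20
    positive_fraction: float = 0.5
    leaky_slope: float = 0.1
    loss: str = "cross_entropy"

    def __post_init__(self):
        self.downsample_factors = tuple(self.downsample_factors)
        self.conv_features = tuple(self.conv_features)
        if self.n_pathways != len(self.downsample_factors):
            raise ValueError("n_pathways must match len(downsample_factors)")
        if self.downsample_factors[0] != 1:
            raise ValueError("first pathway must be at full resolution (factor 1)")
        if self.patch_size <= 2 * len(self.conv_features):
            raise ValueError(
                "patch_size must exceed 2 x number of conv layers "
                "(valid convolutions must leave a non-empty output tile)"
            )
        if self.kernel != 3:
            raise ValueError("only 3x3x3 kernels are supported")
        if self.loss != "cross_entropy":
            raise ValueError("only cross-entropy loss is supported")

    @property
    def n_conv(self) -> int:
        return len(self.conv_features)

    @property
    def tile_size(self) -> int:
        """Output tile edge: patch_size - 2 per valid convolution."""
        return self.patch_size - 2 * self.n_conv

    @property
    def receptive_halo(self) -> int:
        return self.n_conv  # 8 voxels of context per side at full resolution

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class TrainingPatch:
    """One multi-pathway training sample centred on a world location."""

    pathway_inputs: list  # per pathway: (p, p, p, in_channels)
    upsample_idx: list  # per pathway: None or (3, T) int array
    label_patch: np.ndarray  # (T, T, T) int
    center: tuple
    center_is_positive: bool


@dataclass
class PreparedCase:
    """A case with network-ready inputs: body mask + normalized channels."""

    case: CaseRecord
    body: np.ndarray  # bool
    net_input: np.ndarray  # (D, H, W, 2) float32: z-scored PET, clipped z-scored CT
    reference: Optional[np.ndarray]  # bool or None


class TrainingError(RuntimeError):
    pass


def prepare_case(case: CaseRecord) -> PreparedCase:
    """Body mask + per-channel normalization of PET and clipped CT.

    The HU clip to [-1000, 1000] bounds the influence of implants on the
    CT statistics; it affects only this network-input copy, never the HU
    volume used for bone exclusion.
    """
    body = body_mask(case.ct)
    pet_n = normalize(case.pet, body)
    ct_clipped = case.ct.with_data(np.clip(case.ct.data, -1000.0, 1000.0))
    ct_n = normalize(ct_clipped, body)
    x = np.stack([pet_n.data, ct_n.data], axis=-1).astype(np.float32)
    ref = None
    if case.reference_mask is not None:
        ref = case.reference_mask.data.astype(bool)
    return PreparedCase(case=case, body=body.data.astype(bool), net_input=x, reference=ref)


# ---------------------------------------------------------------------------
# Patch geometry


def _clip_extract(arr: np.ndarray, start: Sequence[int], size: Sequence[int]) -> np.ndarray:
    """Sub-array with clamped (edge-padded) indexing on the first 3 axes."""
    sel = tuple(
        np.clip(np.arange(s, s + sz), 0, dim - 1)
        for s, sz, dim in zip(start, size, arr.shape[:3])
    )
    return arr[np.ix_(*sel)]


def _block_average(x: np.ndarray, k: int) -> np.ndarray:
    d, h, w = (s // k for s in x.shape[:3])
    return x[: d * k, : h * k, : w * k].reshape(d, k, h, k, w, k, -1).mean(axis=(1, 3, 5))


def _lowres_patch_cells(tile_start: np.ndarray, tile: int, k: int) -> tuple[np.ndarray, int]:
    """First coarse cell and coarse-patch edge covering an output tile."""
    j0 = np.floor_divide(tile_start, k)
    m = math.ceil(tile / k) + 1
    return j0, m


def _extract_pathway_inputs(
    x: np.ndarray,
    tile_start: np.ndarray,
    config: NetworkConfig,
    tile: Optional[int] = None,
) -> tuple[list, list]:
    """Per-pathway input patches + upsample index maps for one output tile."""
    r = config.receptive_halo
    tile = config.tile_size if tile is None else int(tile)
    inputs, idxs = [], []
    for k in config.downsample_factors:
        if k == 1:
            patch = _clip_extract(x, tile_start - r, (tile + 2 * r,) * 3)
            inputs.append(patch)
            idxs.append(None)
        else:
            j0, m = _lowres_patch_cells(tile_start, tile, k)
            raw = _clip_extract(x, (j0 - r) * k, ((m + 2 * r) * k,) * 3)
            inputs.append(_block_average(raw, k).astype(np.float32))
            offs = np.arange(tile)
            idx = np.stack(
                [(tile_start[a] + offs) // k - j0[a] for a in range(3)]
            ).astype(np.intp)
            idxs.append(idx)
    return inputs, idxs


# ---------------------------------------------------------------------------
# Model


class MultiResCNN:
    """The multi-pathway network with explicit forward/backward passes."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.pathways = []
        for _k in config.downsample_factors:
            layers = []
            c_prev = config.in_channels
            for c in config.conv_features:
                layers.append(nn.Conv3D(c_prev, c, k=config.kernel, rng=rng))
                layers.append(nn.LeakyReLU(config.leaky_slope))
                c_prev = c
            self.pathways.append(layers)
        self.upsamplers = [
            None if k == 1 else nn.GatherUpsample() for k in config.downsample_factors
        ]
        c_cat = config.conv_features[-1] * config.n_pathways
        self.fc1 = nn.Pointwise(c_cat, config.fc_features, rng=rng)
        self.act1 = nn.LeakyReLU(config.leaky_slope)
        self.fc2 = nn.Pointwise(config.fc_features, config.fc_features, rng=rng)
        self.act2 = nn.LeakyReLU(config.leaky_slope)
        self.classifier = nn.Pointwise(config.fc_features, config.n_classes, rng=rng)

    def params(self):
        out = []
        for layers in self.pathways:
            for layer in layers:
                out.extend(layer.params())
        for layer in (self.fc1, self.fc2, self.classifier):
            out.extend(layer.params())
        return out

    def forward(self, pathway_inputs: list, upsample_idx: list, keep: bool = False):
        """Batched forward pass.

        ``pathway_inputs[p]``: (B, p_size, p_size, p_size, C_in);
        ``upsample_idx[p]``: None (full resolution) or (B, 3, T) ints.
        Returns logits (B, T, T, T, n_classes).
        """
        feats = []
        for p, x in enumerate(pathway_inputs):
            h = x
            for layer in self.pathways[p]:
                h = layer.forward(h, keep=keep)
            if self.upsamplers[p] is not None:
                h = self.upsamplers[p].forward(h, upsample_idx[p], keep=keep)
            feats.append(h)
        self._split = [f.shape[-1] for f in feats]
        h = np.concatenate(feats, axis=-1)
        h = self.act1.forward(self.fc1.forward(h, keep=keep), keep=keep)
        h = self.act2.forward(self.fc2.forward(h, keep=keep), keep=keep)
        return self.classifier.forward(h, keep=keep)

    def backward(self, g):
        g = self.classifier.backward(g)
        g = self.fc2.backward(self.act2.backward(g))
        g = self.fc1.backward(self.act1.backward(g))
        start = 0
        for p, width in enumerate(self._split):
            gp = g[..., start : start + width]
            start += width
            if self.upsamplers[p] is not None:
                gp = self.upsamplers[p].backward(gp)
            for layer in reversed(self.pathways[p]):
                gp = layer.backward(gp)

    def head_forward(self, features: np.ndarray) -> np.ndarray:
        """Apply the per-voxel head (fc1, fc2, classifier) to a feature map."""
        h = self.act1.forward(self.fc1.forward(features))
        h = self.act2.forward(self.fc2.forward(h))
        return self.classifier.forward(h)


def build_network(config: NetworkConfig) -> MultiResCNN:
    """Construct (and seed-initialize) the network described by ``config``."""
    return MultiResCNN(config)


# ---------------------------------------------------------------------------
# Patch sampling


def _sample_centers(
    prepared: PreparedCase, n: int, positive_fraction: float, rng: np.random.Generator
):
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must lie in [0, 1]")
    n_pos = int(round(n * positive_fraction))
    n_neg = n - n_pos
    ref = prepared.reference
    if n_pos > 0:
        if ref is None or not ref.any():
            raise TrainingError("no positive voxels available for positive sampling")
        pos_idx = np.argwhere(ref)
        pos = pos_idx[rng.integers(0, len(pos_idx), size=n_pos)]
    else:
        pos = np.empty((0, 3), dtype=np.intp)
    neg_pool = prepared.body if ref is None else (prepared.body & ~ref)
    neg_idx = np.argwhere(neg_pool)
    if n_neg > 0 and len(neg_idx) == 0:
        raise TrainingError("no negative voxels available for negative sampling")
    neg = neg_idx[rng.integers(0, len(neg_idx), size=n_neg)] if n_neg else np.empty((0, 3), dtype=np.intp)
    centers = np.concatenate([pos, neg], axis=0)
    flags = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    order = rng.permutation(n)
    return centers[order], flags[order]


def _extract_batch(prepared: PreparedCase, centers: np.ndarray, config: NetworkConfig):
    """Stack pathway inputs, upsample indices and label tiles for centers."""
    tile = config.tile_size
    starts = centers - tile // 2
    per_pathway_inputs = [[] for _ in config.downsample_factors]
    per_pathway_idx = [[] for _ in config.downsample_factors]
    labels = []
    ref = prepared.reference
    for s in starts:
        inputs, idxs = _extract_pathway_inputs(prepared.net_input, s, config)
        for p in range(len(inputs)):
            per_pathway_inputs[p].append(inputs[p])
            if idxs[p] is not None:
                per_pathway_idx[p].append(idxs[p])
        if ref is not None:
            labels.append(_clip_extract(ref.astype(np.int64), s, (tile,) * 3))
    batched_inputs = [np.stack(v) for v in per_pathway_inputs]
    batched_idx = [np.stack(v) if v else None for v in per_pathway_idx]
    lab = np.stack(labels) if labels else None
    return batched_inputs, batched_idx, lab


def sample_patches(
    case: CaseRecord | PreparedCase,
    n: int,
    positive_fraction: float = 0.5,
    seed: int = 0,
    config: Optional[NetworkConfig] = None,
) -> list[TrainingPatch]:
    """Draw ``n`` class-balanced training patches from one case.

    Exactly ``round(n * positive_fraction)`` patches are centred on
    reference-positive voxels; the rest on body voxels outside the
    reference.  Deterministic given ``seed``.
    """
    config = config or NetworkConfig()
    prepared = case if isinstance(case, PreparedCase) else prepare_case(case)
    rng = np.random.default_rng(seed)
    centers, flags = _sample_centers(prepared, n, positive_fraction, rng)
    tile = config.tile_size
    out = []
    for c, flag in zip(centers, flags):
        s = c - tile // 2
        inputs, idxs = _extract_pathway_inputs(prepared.net_input, s, config)
        label = (
            _clip_extract(prepared.reference.astype(np.int64), s, (tile,) * 3)
            if prepared.reference is not None
            else np.zeros((tile,) * 3, dtype=np.int64)
        )
        out.append(
            TrainingPatch(
                pathway_inputs=inputs,
                upsample_idx=idxs,
                label_patch=label,
                center=tuple(int(v) for v in c),
                center_is_positive=bool(flag),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Training


def train(
    cases: Sequence[CaseRecord | PreparedCase],
    config: NetworkConfig,
    val_cases: Optional[Sequence] = None,
    verbose: bool = False,
) -> tuple[MultiResCNN, dict]:
    """Train one CNN on balanced patches; returns (model, history).

    With ``val_cases`` the weights from the epoch with the lowest
    validation loss are restored at the end (model selection); otherwise
    the final weights are kept.  The history records per-epoch mean
    training loss (and validation loss when available).
    """
    prepared = [c if isinstance(c, PreparedCase) else prepare_case(c) for c in cases]
    trainable = [p for p in prepared if p.reference is not None and p.reference.any()]
    if not trainable:
        raise TrainingError("no training case with a non-empty reference mask")
    model = build_network(config)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    val_batches = None
    if val_cases:
        vprep = [c if isinstance(c, PreparedCase) else prepare_case(c) for c in val_cases]
        vprep = [p for p in vprep if p.reference is not None and p.reference.any()]
        vrng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        val_batches = []
        for p in vprep:
            centers, _ = _sample_centers(p, config.batch_size, config.positive_fraction, vrng)
            val_batches.append(_extract_batch(p, centers, config))

    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None)
    for epoch in range(config.epochs):
        losses = []
        for _ in range(config.batches_per_epoch):
            pc = trainable[rng.integers(len(trainable))]
            centers, _ = _sample_centers(pc, config.batch_size, config.positive_fraction, rng)
            inputs, idxs, labels = _extract_batch(pc, centers, config)
            logits = model.forward(inputs, idxs, keep=True)
            loss, grad, _ = nn.softmax_cross_entropy(logits, labels)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"training diverged (loss={loss}) at epoch {epoch}; "
                    f"lr={config.learning_rate}, seed={config.seed}"
                )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if val_batches:
            vlosses = []
            for inputs, idxs, labels in val_batches:
                logits = model.forward(inputs, idxs, keep=False)
                vloss, _, _ = nn.softmax_cross_entropy(logits, labels)
                vlosses.append(vloss)
            vmean = float(np.mean(vlosses))
            history["val_loss"].append(vmean)
            if vmean < best[0]:
                best = (vmean, [p.value.copy() for p in model.params()])
        if verbose:
            msg = f"epoch {epoch + 1}/{config.epochs} train_loss={history['train_loss'][-1]:.4f}"
            if history["val_loss"]:
                msg += f" val_loss={history['val_loss'][-1]:.4f}"
            print(msg)
    if val_batches and best[1] is not None:
        for p, w in zip(model.params(), best[1]):
            p.value[...] = w
    return model, history


# ---------------------------------------------------------------------------
# Dense inference


def _run_convs(layers, x: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Valid conv stack over a whole (edge-padded) volume, chunked on axis 0."""
    halo = 2 * sum(1 for l in layers if isinstance(l, nn.Conv3D))  # total shrink per axis
    d_out = x.shape[0] - halo
    if d_out <= chunk:
        h = x[None]
        for layer in layers:
            h = layer.forward(h)
        return h[0]
    parts = []
    for a in range(0, d_out, chunk):
        b = min(a + chunk, d_out)
        h = x[None, a : b + halo]
        for layer in layers:
            h = layer.forward(h)
        parts.append(h[0])
    return np.concatenate(parts, axis=0)


def predict_probability(
    model: MultiResCNN,
    pet: Volume,
    ct: Volume,
    body: Optional[np.ndarray] = None,
    tile_size: Optional[int] = None,
) -> Volume:
    """Dense whole-volume lymphoma-class probability.

    ``pet``/``ct`` must be the preprocessed (2 mm isotropic, z-scored)
    network inputs.  Voxels outside ``body`` (when given) are set to 0.
    The default path evaluates each pathway fully convolutionally over the
    edge-padded volume; ``tile_size`` instead assembles the map from
    non-overlapping output tiles, which yields the same probabilities (the
    coarse grids are anchored at the volume origin, not at tile centres).
    """
    if pet.shape != ct.shape:
        raise ValueError("PET and CT grids differ")
    config = model.config
    x = np.stack([pet.data, ct.data], axis=-1).astype(np.float32)
    shape = x.shape[:3]
    r = config.receptive_halo

    if tile_size is not None:
        t = int(tile_size)
        prob = np.zeros(shape, dtype=np.float32)
        for a0 in range(0, shape[0], t):
            for a1 in range(0, shape[1], t):
                for a2 in range(0, shape[2], t):
                    s = np.array([a0, a1, a2])
                    inputs, idxs = _extract_pathway_inputs(x, s, config, tile=t)
                    logits = model.forward(
                        [v[None] for v in inputs],
                        [None if i is None else i[None] for i in idxs],
                    )
                    tilep = nn.softmax(logits)[0, ..., 1].astype(np.float32)
                    e0 = min(a0 + t, shape[0])
                    e1 = min(a1 + t, shape[1])
                    e2 = min(a2 + t, shape[2])
                    prob[a0:e0, a1:e1, a2:e2] = tilep[: e0 - a0, : e1 - a1, : e2 - a2]
    else:
        feats = []
        for p_i, k in enumerate(config.downsample_factors):
            layers = model.pathways[p_i]
            if k == 1:
                xin = _clip_extract(x, (-r, -r, -r), tuple(s + 2 * r for s in shape))
                feats.append(_run_convs(layers, xin))
            else:
                m_cells = [math.ceil(s / k) for s in shape]
                raw = _clip_extract(
                    x, (-r * k, -r * k, -r * k), tuple((m + 2 * r) * k for m in m_cells)
                )
                low = _block_average(raw, k).astype(np.float32)
                f_low = _run_convs(layers, low)
                sel = np.ix_(*[np.arange(s) // k for s in shape])
                feats.append(f_low[sel])
        h = np.concatenate(feats, axis=-1)
        logits = model.head_forward(h)
        prob = nn.softmax(logits)[..., 1].astype(np.float32)

    prob = np.clip(prob, 0.0, 1.0)
    if body is not None:
        prob = prob * np.asarray(body, dtype=np.float32)
    return Volume(data=prob, spacing=pet.spacing, origin=pet.origin, modality=Modality.PROBABILITY)


def binarize(prob: Volume, cut_point: float = 0.5) -> np.ndarray:
    """Threshold a probability map: mask = {p >= cut_point}."""
    if prob.modality is not Modality.PROBABILITY:
        raise ValueError("binarize expects a PROBABILITY volume")
    if not 0.0 <= cut_point <= 1.0:
        raise ValueError("cut_point must lie in [0, 1]")
    return prob.data >= cut_point


# ---------------------------------------------------------------------------
# Checkpoints


def save_model(model: MultiResCNN, path: str | Path) -> None:
    """Checkpoint: JSON-encoded config + flat list of weight arrays (.npz)."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    np.savez_compressed(
        str(path), config=np.frombuffer(json.dumps(model.config.to_dict()).encode(), dtype=np.uint8), **arrays
    )


def load_model(path: str | Path) -> MultiResCNN:
    with np.load(str(path)) as data:
        config = NetworkConfig.from_dict(json.loads(bytes(data["config"]).decode()))
        model = build_network(config)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i}"]
    return model
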