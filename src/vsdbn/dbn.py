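"""Two-stage volumetric sparse DBN: group training, subject transfer, feature
and spatial-map extraction.

Stage 1 trains a stack of sparse RBMs greedily on the group matrix (volumes
as samples, voxels as visible units): layer 1 has Gaussian visibles on the
z-scored data; each upper layer is a Bernoulli-visible RBM fed the previous
layer's mean-field hidden probabilities.  Stage 2 copies the group weights
into a per-subject model and fine-tunes all layers on that subject's data at
a reduced learning rate, so atom k of the subject model stays in
correspondence with atom k of the group model — no post-hoc matching is
needed between stages.

Spatial maps follow the linear-combination rule: layer-L atom maps are the
columns of W1 @ W2 @ ... @ WL, optionally z-scored per map; the logistic
nonlinearities are deliberately ignored in map extraction (a linear
read-out of what each voxel contributes to each atom).  Hidden-layer
activations along the same mean-field pass are the temporal features.
"""

from __future__ import annotations

import copy
import json
from dataclasses import replace as _dc_replace
from dataclasses import dataclass, field

import h5py
import numpy as np

from .io_volumes import DataMatrix
from .rbm import RBMLayer, TrainConfig, hidden_conditional, train_rbm, \
    visible_conditional

__all__ = [
    "DBNModel",
    "TemporalFeatureSet",
    "SpatialMapSet",
    "train_group",
    "init_subject_from_group",
    "fine_tune_subject",
    "extract_temporal",
    "extract_maps",
    "dbn_reconstruction_loss",
    "save_model",
    "load_model",
]


@dataclass
class DBNModel:
    """Ordered RBM stack with a stage tag (``group`` or ``subject:<id>``)."""

    layers: list[RBMLayer]
    stage: str = "group"
    provenance: dict = field(default_factory=dict)
    loss_traces: list[list[float]] = field(default_factory=list)

    def __post_init__(self):
        for lower, upper in zip(self.layers, self.layers[1:]):
            if lower.n_hidden != upper.n_visible:
                raise ValueError(
                    f"layer sizes do not chain: {lower.n_hidden} -> "
                    f"{upper.n_visible}")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def architecture(self) -> tuple[int, ...]:
        return tuple(layer.n_hidden for layer in self.layers)

    @property
    def n_visible(self) -> int:
        return self.layers[0].n_visible


@dataclass
class TemporalFeatureSet:
    """Per-layer hidden-activation time courses (rows = TRs)."""

    features: list[np.ndarray]
    stage: str = "group"

    def layer(self, idx: int) -> np.ndarray:
        """1-based layer accessor (layer(1) == first hidden layer)."""
        return self.features[idx - 1]


@dataclass
class SpatialMapSet:
    """Per-layer map matrices, one row per atom, m columns."""

    maps: list[np.ndarray]
    zscored: bool = False
    stage: str = "group"

    def layer(self, idx: int) -> np.ndarray:
        return self.maps[idx - 1]


def _as_array(data) -> np.ndarray:
    return data.values if isinstance(data, DataMatrix) else np.asarray(
        data, dtype=float)


def train_group(data, arch: tuple[int, ...], cfg: TrainConfig,
                sparsity_target: float = 0.1,
                sparsity_weight: float = 3.0,
                hidden_bias_init: float = -2.0) -> DBNModel:
    """Greedy layer-wise stage-1 training on the group matrix.

    Each layer trains to convergence (``cfg.epochs`` epochs of CD) before its
    mean-field hidden probabilities become the next layer's input.  Per-layer
    seeds are derived deterministically from ``cfg.seed``.

    The default sparsity weight is deliberately strong: the sparsity penalty
    is what breaks the rotational degeneracy of a purely reconstruction-driven
    factorization and makes hidden units specialize to individual networks
    rather than mixtures of them.
    """
    x = _as_array(data)
    layers, traces = [], []
    for li, q in enumerate(arch):
        layer_cfg = _dc_replace(cfg, seed=(cfg.seed + 1000 * li) % (2**31))
        kind = "gaussian" if li == 0 else "bernoulli"
        rbm, losses = train_rbm(x, int(q), layer_cfg, visible_kind=kind,
                                sparsity_target=sparsity_target,
                                sparsity_weight=sparsity_weight,
                                hidden_bias_init=hidden_bias_init)
        layers.append(rbm)
        traces.append(losses)
        x = hidden_conditional(rbm, x)
    return DBNModel(layers=layers, stage="group",
                    provenance={"arch": list(arch), "seed": cfg.seed},
                    loss_traces=traces)


def init_subject_from_group(group: DBNModel, subject_id: str = "") -> DBNModel:
    """Stage-2 initialization: deep-copy the trained group weights.

    W1 seeds the visible-to-hidden-1 weights, W2 and W3 the successive
    hidden-to-hidden weights; biases are copied too.  Before any fine-tuning
    the subject model is bit-identical to the group model.
    """
    if not group.layers:
        raise RuntimeError("group model has no trained layers")
    model = DBNModel(layers=copy.deepcopy(group.layers),
                     stage=f"subject:{subject_id}",
                     provenance=dict(group.provenance, parent="group"),
                     loss_traces=[])
    return model


def fine_tune_subject(model: DBNModel, data, cfg: TrainConfig,
                      lr_factor: float = 1.0) -> DBNModel:
    """Fine-tune all layers greedily on one subject's data.

    Continues CD from the transferred weights at ``lr_factor`` times the
    stage-1 learning rate.  The default keeps the full rate: the subject
    stage sees far fewer samples per epoch than the group stage, and at a
    strongly reduced rate short fine-tuning runs leave the group weights
    numerically unchanged, erasing the individual variability the second
    stage exists to capture.  With ``cfg.epochs == 0`` the model is returned
    with weights untouched (the identity contract the two-stage
    correspondence rests on).
    """
    if not model.stage.startswith("subject"):
        raise RuntimeError("fine_tune_subject expects a subject-stage model")
    x = _as_array(data)
    layers, traces = [], []
    for li, rbm in enumerate(model.layers):
        lr = cfg.resolve_lr(rbm.visible_kind) * lr_factor
        layer_cfg = _dc_replace(cfg, learning_rate=lr,
                                 seed=(cfg.seed + 1000 * li + 7) % (2**31))
        tuned, losses = train_rbm(x, rbm.n_hidden, layer_cfg,
                                  visible_kind=rbm.visible_kind, rbm=copy.deepcopy(rbm))
        layers.append(tuned)
        traces.append(losses)
        x = hidden_conditional(tuned, x)
    return DBNModel(layers=layers, stage=model.stage,
                    provenance=model.provenance, loss_traces=traces)


def extract_temporal(model: DBNModel, data) -> TemporalFeatureSet:
    """Mean-field hidden probabilities of every layer for each TR (row)."""
    x = _as_array(data)
    if x.shape[1] != model.n_visible:
        raise ValueError(f"data has {x.shape[1]} columns, model expects "
                         f"{model.n_visible}")
    feats = []
    for rbm in model.layers:
        x = hidden_conditional(rbm, x)
        feats.append(x)
    return TemporalFeatureSet(features=feats, stage=model.stage)


def extract_maps(model: DBNModel, zscore: bool = True,
                 sign_normalize: bool = True) -> SpatialMapSet:
    """Linear-combination spatial maps: layer L = (W1 @ ... @ WL) columns.

    Each atom's map is a row of length m.  Because an RBM's weight sign is
    arbitrary, each map is optionally flipped so its maximum-magnitude voxel
    is positive; z-scoring (population sd) puts maps on a common scale for
    SCC/overlap comparisons.
    """
    maps = []
    prod = None
    for rbm in model.layers:
        prod = rbm.W if prod is None else prod @ rbm.W
        layer_maps = prod.T.copy()  # (q_L, m)
        if sign_normalize:
            peak = np.take_along_axis(
                layer_maps, np.abs(layer_maps).argmax(axis=1, keepdims=True),
                axis=1)
            layer_maps *= np.where(peak < 0, -1.0, 1.0)
        if zscore:
            mu = layer_maps.mean(axis=1, keepdims=True)
            sd = layer_maps.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            layer_maps = (layer_maps - mu) / sd
        maps.append(layer_maps)
    return SpatialMapSet(maps=maps, zscored=zscore, stage=model.stage)


def dbn_reconstruction_loss(model: DBNModel, data) -> float:
    """Mean-field up-down reconstruction MSE through the full stack.

    Propagates hidden probabilities to the top layer, then maps back down
    through each layer's visible conditional; the loss is the MSE between
    the input and its reconstruction.  This is the architecture-search
    fitness (testing loss of the model).
    """
    x0 = _as_array(data)
    x = x0
    for rbm in model.layers:
        x = hidden_conditional(rbm, x)
    for rbm in reversed(model.layers):
        x = visible_conditional(rbm, x)
    return float(np.mean((x0 - x) ** 2))


def save_model(model: DBNModel, path) -> str:
    """HDF5 weights + JSON-encoded metadata sidecar attribute."""
    with h5py.File(str(path), "w") as f:
        f.attrs["stage"] = model.stage
        f.attrs["meta"] = json.dumps({
            "provenance": model.provenance,
            "loss_traces": model.loss_traces,
        })
        for i, rbm in enumerate(model.layers):
            g = f.create_group(f"layer{i}")
            g.create_dataset("W", data=rbm.W, track_times=False)
            g.create_dataset("a", data=rbm.a, track_times=False)
            g.create_dataset("b", data=rbm.b, track_times=False)
            g.attrs["visible_kind"] = rbm.visible_kind
            g.attrs["sparsity_target"] = rbm.sparsity_target
            g.attrs["sparsity_weight"] = rbm.sparsity_weight
    return str(path)


def load_model(path) -> DBNModel:
    with h5py.File(str(path), "r") as f:
        meta = json.loads(f.attrs["meta"])
        layers = []
        for i in range(len([k for k in f.keys() if k.startswith("layer")])):
            g = f[f"layer{i}"]
            layers.append(RBMLayer(
                W=g["W"][...], a=g["a"][...], b=g["b"][...],
                visible_kind=str(g.attrs["visible_kind"]),
                sparsity_target=float(g.attrs["sparsity_target"]),
                sparsity_weight=float(g.attrs["sparsity_weight"])))
        return DBNModel(layers=layers, stage=str(f.attrs["stage"]),
                        provenance=meta["provenance"],
                        loss_traces=meta["loss_traces"])
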