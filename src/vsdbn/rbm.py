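"""Sparse restricted Boltzmann machines: energy, conditionals, CD training.

An RBM is a bipartite energy model over visible units ``v`` and hidden units
``h`` with parameters theta = {W, a, b}.  Two visible-unit families are
supported:

* ``bernoulli`` — E(v, h) = -a.v - b.h - v.W.h, the classical binary form,
  used for upper layers (whose inputs are activation probabilities in (0,1))
  and for the exact enumeration oracles.
* ``gaussian``  — E(v, h) = sum_i (v_i - a_i)^2 / 2 - b.h - v.W.h, for
  real-valued z-scored inputs with unit conditional variance; this is the
  default for the first layer trained directly on voxel data.

Training is contrastive divergence (CD-k) with momentum, weight decay and a
sparsity penalty that drives each hidden unit's mean activation toward a
target rate rho — the "sparse" in a volumetric sparse DBN.  All stochastic
steps draw from an explicit ``numpy`` Generator so runs are bit-reproducible
under a fixed seed.

The enumeration helpers at the bottom compute exact Boltzmann probabilities
by brute force for tiny Bernoulli RBMs (<= ~12 total units); they exist so
that the sampled conditionals and Gibbs dynamics can be validated against
the exact distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RBMLayer",
    "TrainConfig",
    "init_rbm",
    "energy",
    "hidden_conditional",
    "visible_conditional",
    "cd_update",
    "reconstruction_loss",
    "train_rbm",
    "enumerate_joint",
    "exact_hidden_conditional",
    "gibbs_chain",
]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class RBMLayer:
    """One RBM: weights ``W`` (n_visible x n_hidden), biases ``a``, ``b``."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray
    visible_kind: str = "gaussian"
    sparsity_target: float = 0.1
    sparsity_weight: float = 0.1

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2D")
        if self.a.shape != (self.W.shape[0],) or self.b.shape != (self.W.shape[1],):
            raise ValueError("bias shapes inconsistent with W")
        if self.visible_kind not in ("gaussian", "bernoulli"):
            raise ValueError(f"unknown visible_kind {self.visible_kind!r}")
        if not (np.isfinite(self.W).all() and np.isfinite(self.a).all()
                and np.isfinite(self.b).all()):
            raise ValueError("non-finite RBM parameters")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]


@dataclass
class TrainConfig:
    """CD training hyperparameters.

    ``learning_rate=None`` resolves to 0.01 for Bernoulli visibles and 0.001
    for Gaussian visibles.  Momentum ramps from its first to its second value
    at ``momentum_switch_epoch``.  ``test_fraction`` is the held-out share
    used when a train/test split is requested (architecture-search fitness).
    """

    learning_rate: float | None = None
    epochs: int = 50
    batch_size: int = 64
    cd_steps: int = 1
    momentum: tuple[float, float] = (0.5, 0.9)
    momentum_switch_epoch: int = 5
    weight_decay: float = 2e-4
    seed: int = 0
    test_fraction: float = 0.2

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size <= 0 or self.cd_steps <= 0:
            raise ValueError("epochs, batch_size, cd_steps must be positive")
        if not (0.0 < self.test_fraction <= 0.5):
            raise ValueError("test_fraction must be in (0, 0.5]")

    def resolve_lr(self, visible_kind: str) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 0.001 if visible_kind == "gaussian" else 0.01


def init_rbm(n_visible: int, n_hidden: int, visible_kind: str = "gaussian",
             rng: np.random.Generator | None = None, scale: float = 0.01,
             sparsity_target: float = 0.1, sparsity_weight: float = 0.1,
             hidden_bias_init: float = 0.0) -> RBMLayer:
    """Small-Gaussian weight init; biases zero (hidden bias configurable).

    Starting hidden biases negative (e.g. -2) begins training in the sparse
    regime, which speeds up the sparsity penalty's symmetry breaking.
    """
    rng = np.random.default_rng() if rng is None else rng
    W = rng.normal(0.0, scale, size=(n_visible, n_hidden))
    return RBMLayer(W=W, a=np.zeros(n_visible),
                    b=np.full(n_hidden, float(hidden_bias_init)),
                    visible_kind=visible_kind, sparsity_target=sparsity_target,
                    sparsity_weight=sparsity_weight)


def energy(rbm: RBMLayer, v: np.ndarray, h: np.ndarray) -> float:
    """Energy E(v, h | theta) of one joint configuration."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (rbm.n_visible,) or h.shape != (rbm.n_hidden,):
        raise ValueError(
            f"expected shapes ({rbm.n_visible},), ({rbm.n_hidden},); "
            f"got {v.shape}, {h.shape}")
    interaction = -float(v @ rbm.W @ h) - float(rbm.b @ h)
    if rbm.visible_kind == "bernoulli":
        return -float(rbm.a @ v) + interaction
    return 0.5 * float(np.sum((v - rbm.a) ** 2)) + interaction


def hidden_conditional(rbm: RBMLayer, v: np.ndarray) -> np.ndarray:
    """p(h_j = 1 | v) = logistic(b_j + sum_i v_i W_ij); rows if v is a batch."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != rbm.n_visible:
        raise ValueError(f"visible size {v.shape[-1]} != {rbm.n_visible}")
    return _sigmoid(v @ rbm.W + rbm.b)


def visible_conditional(rbm: RBMLayer, h: np.ndarray) -> np.ndarray:
    """Mean of p(v | h): logistic for Bernoulli visibles, a + W.h for Gaussian."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != rbm.n_hidden:
        raise ValueError(f"hidden size {h.shape[-1]} != {rbm.n_hidden}")
    pre = h @ rbm.W.T + rbm.a
    return _sigmoid(pre) if rbm.visible_kind == "bernoulli" else pre


@dataclass
class _Velocity:
    """Momentum state across cd_update calls."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    @classmethod
    def zeros_like(cls, rbm: RBMLayer) -> "_Velocity":
        return cls(np.zeros_like(rbm.W), np.zeros_like(rbm.a),
                   np.zeros_like(rbm.b))


def cd_update(rbm: RBMLayer, batch: np.ndarray, cfg: TrainConfig,
              rng: np.random.Generator, velocity: _Velocity | None = None,
              momentum: float | None = None,
              sample_hidden: bool = False) -> tuple[RBMLayer, float]:
    """One CD-k gradient step on a mini-batch.

    Positive phase uses the data and mean-field hidden probabilities.  By
    default the negative chain is also mean-field (deterministic given the
    weights and batch, which keeps whole training runs bit-reproducible);
    ``sample_hidden=True`` runs the classical chain on sampled binary
    hiddens.  Adds momentum, L2 weight decay on W, and the sparsity gradient
    pulling mean hidden activation toward ``sparsity_target``.  Returns the
    updated layer and the batch mean-squared one-step reconstruction error.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[1] != rbm.n_visible:
        raise ValueError(f"batch has {batch.shape[1]} columns, "
                         f"expected {rbm.n_visible}")
    lr = cfg.resolve_lr(rbm.visible_kind)
    mom = cfg.momentum[0] if momentum is None else momentum
    vel = _Velocity.zeros_like(rbm) if velocity is None else velocity
    nb = batch.shape[0]

    h0_prob = hidden_conditional(rbm, batch)
    if sample_hidden:
        h_state = (rng.random(h0_prob.shape) < h0_prob).astype(float)
    else:
        h_state = h0_prob
    v_recon = None
    for _ in range(cfg.cd_steps):
        v_recon = visible_conditional(rbm, h_state)
        hk_prob = hidden_conditional(rbm, v_recon)
        if sample_hidden:
            h_state = (rng.random(hk_prob.shape) < hk_prob).astype(float)
        else:
            h_state = hk_prob

    grad_W = (batch.T @ h0_prob - v_recon.T @ hk_prob) / nb
    grad_a = (batch - v_recon).mean(axis=0)
    grad_b = (h0_prob - hk_prob).mean(axis=0)

    if rbm.sparsity_weight > 0:
        # cross-entropy sparsity: push mean activation q_j toward rho
        q = h0_prob.mean(axis=0)
        sparse_grad = rbm.sparsity_weight * (rbm.sparsity_target - q)
        grad_b = grad_b + sparse_grad
        grad_W = grad_W + batch.T @ (h0_prob * (1 - h0_prob) * sparse_grad) / nb

    grad_W = grad_W - cfg.weight_decay * rbm.W

    vel.W = mom * vel.W + lr * grad_W
    vel.a = mom * vel.a + lr * grad_a
    vel.b = mom * vel.b + lr * grad_b
    W, a, b = rbm.W + vel.W, rbm.a + vel.a, rbm.b + vel.b
    if not (np.isfinite(W).all() and np.isfinite(a).all()
            and np.isfinite(b).all()):
        raise FloatingPointError(
            f"non-finite CD update (lr={lr}, |W|max={np.abs(rbm.W).max():.3g})")
    new = replace(rbm, W=W, a=a, b=b)
    recon_err = float(np.mean((batch - v_recon) ** 2))
    return new, recon_err


def reconstruction_loss(rbm: RBMLayer, data: np.ndarray) -> float:
    """Deterministic mean-field reconstruction MSE: v -> p(h|v) -> E[v|h]."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("empty data")
    h = hidden_conditional(rbm, data)
    v = visible_conditional(rbm, h)
    return float(np.mean((data - v) ** 2))


def train_rbm(data: np.ndarray, n_hidden: int, cfg: TrainConfig,
              visible_kind: str = "gaussian", sparsity_target: float = 0.1,
              sparsity_weight: float = 0.1, hidden_bias_init: float = 0.0,
              rbm: RBMLayer | None = None,
              sample_hidden: bool = False) -> tuple[RBMLayer, list[float]]:
    """Train one RBM with mini-batch CD; returns the layer and per-epoch loss.

    Pass ``rbm`` to continue training existing weights (used by the
    subject-level fine-tuning stage).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    rng = np.random.default_rng(cfg.seed)
    if rbm is None:
        rbm = init_rbm(data.shape[1], n_hidden, visible_kind, rng,
                       sparsity_target=sparsity_target,
                       sparsity_weight=sparsity_weight,
                       hidden_bias_init=hidden_bias_init)
    vel = _Velocity.zeros_like(rbm)
    losses: list[float] = []
    n = data.shape[0]
    for epoch in range(cfg.epochs):
        mom = cfg.momentum[0] if epoch < cfg.momentum_switch_epoch else cfg.momentum[1]
        order = rng.permutation(n)
        epoch_err, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            batch = data[order[start:start + cfg.batch_size]]
            rbm, err = cd_update(rbm, batch, cfg, rng, vel, momentum=mom,
                                 sample_hidden=sample_hidden)
            epoch_err += err
            n_batches += 1
        losses.append(epoch_err / max(n_batches, 1))
    return rbm, losses


# ---------------------------------------------------------------------------
# Exact enumeration oracles (tiny Bernoulli RBMs only)
# ---------------------------------------------------------------------------

def _binary_states(n: int) -> np.ndarray:
    return np.array(list(itertools.product([0.0, 1.0], repeat=n)))


def enumerate_joint(rbm: RBMLayer) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact Boltzmann joint p(v, h) = exp(-E) / Z by full enumeration.

    Returns (visible_states, hidden_states, joint) where
    ``joint[i, j] = p(v_i, h_j)``.  Only feasible for Bernoulli RBMs with a
    small total unit count; refuses anything above 16 units.
    """
    if rbm.visible_kind != "bernoulli":
        raise ValueError("enumeration oracle requires bernoulli visibles")
    if rbm.n_visible + rbm.n_hidden > 16:
        raise ValueError("too many units to enumerate")
    vs = _binary_states(rbm.n_visible)
    hs = _binary_states(rbm.n_hidden)
    E = np.array([[energy(rbm, v, h) for h in hs] for v in vs])
    un = np.exp(-(E - E.min()))  # shift for numerical safety
    return vs, hs, un / un.sum()


def exact_hidden_conditional(rbm: RBMLayer, v: np.ndarray) -> np.ndarray:
    """p(h_j = 1 | v) from the enumerated joint (independent oracle path)."""
    vs, hs, joint = enumerate_joint(rbm)
    row = np.flatnonzero((vs == np.asarray(v, dtype=float)).all(axis=1))
    if row.size != 1:
        raise ValueError("v is not a binary state of this RBM")
    pv = joint[row[0]]
    return (pv[:, None] * hs).sum(axis=0) / pv.sum()


def gibbs_chain(rbm: RBMLayer, n_steps: int,
                rng: np.random.Generator) -> np.ndarray:
    """Alternating Gibbs sampler; returns (n_steps, n_vis + n_hid) 0/1 states."""
    v = (rng.random(rbm.n_visible) < 0.5).astype(float)
    out = np.empty((n_steps, rbm.n_visible + rbm.n_hidden))
    for t in range(n_steps):
        ph = hidden_conditional(rbm, v)
        h = (rng.random(rbm.n_hidden) < ph).astype(float)
        pv = visible_conditional(rbm, h)
        v = (rng.random(rbm.n_visible) < pv).astype(float)
        out[t, :rbm.n_visible] = v
        out[t, rbm.n_visible:] = h
    return out
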