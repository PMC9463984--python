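"""Particle-swarm architecture search over (hidden layers, nodes per layer).

Each particle carries a continuous 2-D position (number of layers, number of
nodes — one shared node count for all layers); architectures are obtained by
rounding only at fitness evaluation, which keeps the swarm dynamics alive on
a discrete landscape.  Velocity and position follow the swarm update

    v <- w*v + c1*Rand1*(pbest - x) + c2*Rand2*(gbest - x)
    x <- x + v

with Rand1, Rand2 drawn per step and per dimension from [-1, 1] (a config
switch restores the classical [0, 1] draw).  Diversity is maintained with an
aging-evolution step: each iteration the oldest particle is retired and
replaced by a mutated copy of a tournament-sampled particle.  Fitness is the
held-out top-layer reconstruction loss of a sparse DBN trained at a reduced
epoch budget; the search range defaults to [2, 10] layers x [100, 800] nodes
with 30 particles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .dbn import dbn_reconstruction_loss, train_group
from .rbm import TrainConfig

logger = logging.getLogger("vsdbn")

__all__ = [
    "Particle",
    "SwarmConfig",
    "NASResult",
    "round_arch",
    "pso_step",
    "mutate_aging",
    "make_dbn_fitness",
    "toy_fitness",
    "run_nas",
    "run_nas_repeats",
]


@dataclass
class SwarmConfig:
    """Swarm hyperparameters; defaults follow the published search set-up."""

    n_particles: int = 30
    w: float = 0.1
    w_schedule: tuple[float, float] | None = None  # (start, end) linear decay
    c1: float = 2.0
    c2: float = 2.0
    rand_interval: tuple[float, float] = (-1.0, 1.0)
    layer_range: tuple[int, int] = (2, 10)
    node_range: tuple[int, int] = (100, 800)
    n_iterations: int = 40
    mutation_rate: float = 1.0
    tournament_size: int = 3
    eval_epochs: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.layer_range[0] > self.layer_range[1] or \
                self.node_range[0] > self.node_range[1]:
            raise ValueError("empty search range")

    @property
    def lo(self) -> np.ndarray:
        return np.array([self.layer_range[0], self.node_range[0]], dtype=float)

    @property
    def hi(self) -> np.ndarray:
        return np.array([self.layer_range[1], self.node_range[1]], dtype=float)

    def inertia(self, iteration: int) -> float:
        if self.w_schedule is None:
            return self.w
        w0, w1 = self.w_schedule
        frac = iteration / max(self.n_iterations - 1, 1)
        return w0 + (w1 - w0) * frac


@dataclass
class Particle:
    position: np.ndarray  # (layers, nodes), continuous
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float = np.inf
    age: int = 0

    @classmethod
    def random(cls, cfg: SwarmConfig, rng: np.random.Generator) -> "Particle":
        pos = rng.uniform(cfg.lo, cfg.hi)
        return cls(position=pos, velocity=np.zeros(2),
                   pbest_position=pos.copy())


def round_arch(position: np.ndarray) -> tuple[int, int]:
    """(layers, nodes) integers; rounding happens only here, at evaluation."""
    return int(round(position[0])), int(round(position[1]))


def pso_step(p: Particle, gbest_position: np.ndarray, cfg: SwarmConfig,
             rng: np.random.Generator, w: float | None = None) -> Particle:
    """One velocity + position update; position clipped to the search range."""
    w = cfg.w if w is None else w
    lo, hi = cfg.rand_interval
    r1 = rng.uniform(lo, hi, size=2)
    r2 = rng.uniform(lo, hi, size=2)
    vel = (w * p.velocity
           + cfg.c1 * r1 * (p.pbest_position - p.position)
           + cfg.c2 * r2 * (gbest_position - p.position))
    pos = np.clip(p.position + vel, cfg.lo, cfg.hi)
    return replace(p, position=pos, velocity=vel, age=p.age + 1)


def mutate_aging(swarm: list[Particle], cfg: SwarmConfig,
                 rng: np.random.Generator) -> list[Particle]:
    """Retire the oldest particle, insert a mutated tournament winner.

    The winner of a size-``tournament_size`` tournament (lowest personal-best
    fitness) is copied and perturbed by +-1 layer and/or +-Uniform(10, 50)
    nodes; the newcomer starts with zero velocity, age 0 and a fresh personal
    best.  With probability ``1 - mutation_rate`` the swarm is left unchanged.
    The global best is recorded outside the swarm, so retiring a particle can
    never lose it.
    """
    if not swarm or rng.random() >= cfg.mutation_rate:
        return swarm
    oldest = max(range(len(swarm)), key=lambda i: swarm[i].age)
    contenders = rng.choice(len(swarm), size=min(cfg.tournament_size,
                                                 len(swarm)), replace=False)
    winner = min(contenders, key=lambda i: swarm[i].pbest_fitness)
    pos = swarm[winner].position.copy()
    mutate_layer, mutate_nodes = rng.random() < 0.5, rng.random() < 0.5
    if not (mutate_layer or mutate_nodes):
        mutate_layer = True
    if mutate_layer:
        pos[0] += rng.choice([-1.0, 1.0])
    if mutate_nodes:
        pos[1] += rng.choice([-1.0, 1.0]) * rng.uniform(10.0, 50.0)
    pos = np.clip(pos, cfg.lo, cfg.hi)
    newcomer = Particle(position=pos, velocity=np.zeros(2),
                        pbest_position=pos.copy())
    out = list(swarm)
    out[oldest] = newcomer
    return out


def make_dbn_fitness(data, cfg: SwarmConfig):
    """Fitness closure: held-out top-layer reconstruction loss of a DBN.

    The data rows are split (seeded permutation, 20% held out); a DBN with
    the candidate architecture trains for ``cfg.eval_epochs`` epochs per
    layer on the training split and the full-stack mean-field reconstruction
    MSE on the test split is the fitness.  Results are cached per rounded
    architecture; training failures yield +inf with a warning.
    """
    from .io_volumes import DataMatrix
    x = data.values if isinstance(data, DataMatrix) else np.asarray(
        data, dtype=float)
    split_rng = np.random.default_rng(cfg.seed)
    order = split_rng.permutation(x.shape[0])
    n_test = max(1, int(round(0.2 * x.shape[0])))
    test, train = x[order[:n_test]], x[order[n_test:]]
    cache: dict[tuple[int, int], float] = {}

    def fitness(arch: tuple[int, int]) -> float:
        arch = (int(arch[0]), int(arch[1]))
        if arch in cache:
            return cache[arch]
        n_layers, n_nodes = arch
        tcfg = TrainConfig(epochs=cfg.eval_epochs, seed=cfg.seed)
        try:
            model = train_group(train, (n_nodes,) * n_layers, tcfg)
            fit = dbn_reconstruction_loss(model, test)
        except FloatingPointError as exc:
            warnings.warn(f"training diverged for arch {arch}: {exc}",
                          stacklevel=2)
            fit = np.inf
        cache[arch] = fit
        return fit

    return fitness


def toy_fitness(arch: tuple[int, int]) -> float:
    """Separable benchmark landscape with its optimum at (3, 146)."""
    n_layers, n_nodes = arch
    return abs(n_layers - 3) + abs(n_nodes - 146) / 100.0


@dataclass
class NASResult:
    gbest_arch: tuple[int, int]
    gbest_fitness: float
    gbest_trace: list[float]
    history: list[dict] = field(default_factory=list)


def run_nas(fitness, cfg: SwarmConfig) -> NASResult:
    """Full search: iterate evaluate -> record bests -> mutate -> swarm step.

    ``fitness`` maps a rounded (layers, nodes) architecture to a real loss;
    build one with :func:`make_dbn_fitness` or pass :func:`toy_fitness`.
    Returns the best architecture found, its fitness, and the per-iteration
    global-best trace (non-increasing by construction).
    """
    rng = np.random.default_rng(cfg.seed)
    swarm = [Particle.random(cfg, rng) for _ in range(cfg.n_particles)]
    gbest_pos, gbest_fit, gbest_arch = None, np.inf, None
    trace, history = [], []
    for it in range(cfg.n_iterations):
        for p in swarm:
            arch = round_arch(p.position)
            fit = fitness(arch)
            if fit < p.pbest_fitness:
                p.pbest_fitness = fit
                p.pbest_position = p.position.copy()
            if fit < gbest_fit:
                gbest_fit, gbest_pos, gbest_arch = fit, p.position.copy(), arch
        trace.append(gbest_fit)
        history.append({"iteration": it, "gbest_arch": gbest_arch,
                        "gbest_fitness": gbest_fit,
                        "positions": [round_arch(p.position) for p in swarm]})
        swarm = mutate_aging(swarm, cfg, rng)
        w = cfg.inertia(it)
        swarm = [pso_step(p, gbest_pos, cfg, rng, w=w) for p in swarm]
    logger.info("NAS done: gbest=%s fitness=%.6g", gbest_arch, gbest_fit)
    return NASResult(gbest_arch=gbest_arch, gbest_fitness=gbest_fit,
                     gbest_trace=trace, history=history)


def run_nas_repeats(fitness, cfg: SwarmConfig, n_repeats: int = 10) -> dict:
    """Independent repeated searches; reports the selection dispersion.

    Mirrors running the search several times and summarizing how stable the
    selected layer/node counts are across runs.
    """
    results = []
    for r in range(n_repeats):
        rcfg = replace(cfg, seed=(cfg.seed + 10007 * r) % (2**31))
        results.append(run_nas(fitness, rcfg))
    layers = np.array([r.gbest_arch[0] for r in results])
    nodes = np.array([r.gbest_arch[1] for r in results])
    fits = np.array([r.gbest_fitness for r in results])
    best = results[int(np.argmin(fits))]
    return {
        "results": results,
        "best_arch": best.gbest_arch,
        "layers": layers.tolist(),
        "nodes": nodes.tolist(),
        "layer_range": [int(layers.min()), int(layers.max())],
        "node_range": [int(nodes.min()), int(nodes.max())],
        "node_std": float(nodes.std()),
    }
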