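"""Augmented Dream Optimizer: a dream-optimizer / particle-swarm hybrid.

The dream optimizer (DOA) is a population metaheuristic built on a memory
metaphor: each iteration an agent resets to the best position it remembers
(its group's best during exploration, the global best during exploitation),
then "forgets" a few randomly chosen dimensions and re-organizes them — either
by a cosine-decayed random perturbation around the remembered best
(forgetting/supplementing) or by copying the coordinate of a random population
member (dream sharing). The augmented variant blends every DOA proposal with a
standard particle-swarm velocity update, ``alpha * x_doa + (1-alpha) * (x + v)``.

Minimization convention throughout; wrap the objective with negation to
maximize. All randomness flows from a single seeded generator, so identical
(seed, config, objective) triples reproduce identical runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "AdoConfig",
    "AdoState",
    "forget_count_exploration",
    "forget_count_exploitation",
    "exploration_factor",
    "exploitation_factor",
    "initialize_population",
    "pso_blend",
    "enforce_bounds",
    "optimize",
    "decode_position",
    "encode_theta",
    "hyperparameter_space",
    "space_from_yaml",
]


@dataclass(frozen=True)
class SearchSpace:
    """Box-bounded mixed search space.

    ``scale`` is per-dimension ``"linear"`` or ``"log10"``; log-scaled
    dimensions are searched in log10 units internally. ``kind`` is
    ``"continuous"``, ``"integer"`` or ``"categorical"``; categorical and
    integer dimensions are snapped only at decode time (``choices`` holds the
    admissible values for snapped dimensions).
    """

    lower: tuple[float, ...]
    upper: tuple[float, ...]
    scale: tuple[str, ...] | None = None
    kind: tuple[str, ...] | None = None
    names: tuple[str, ...] | None = None
    choices: dict[int, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower/upper must be 1-D and same length")
        if not np.all(hi > lo):
            raise ValueError("upper bound must exceed lower bound in every dimension")
        scale = self.scale or ("linear",) * lo.size
        for s, l in zip(scale, lo):
            if s == "log10" and l <= 0:
                raise ValueError("log10 scale requires positive lower bound")

    @property
    def dim(self) -> int:
        return len(self.lower)

    def internal_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Bounds on the search scale (log10 applied where requested)."""
        lo = np.asarray(self.lower, float).copy()
        hi = np.asarray(self.upper, float).copy()
        if self.scale:
            for j, s in enumerate(self.scale):
                if s == "log10":
                    lo[j], hi[j] = math.log10(lo[j]), math.log10(hi[j])
        return lo, hi


@dataclass(frozen=True)
class AdoConfig:
    N: int = 30
    Tmax: int = 100
    u: float = 0.9  # forgetting/supplementing vs dream-sharing switch
    n_groups: int = 5
    alpha_blend: float = 0.6  # DOA share in the DOA/PSO blend
    gamma1: float = 2.0
    gamma2: float = 2.0
    inertia: float = 0.7
    seed: int = 0
    paper_pso: bool = False  # drop the r1/r2 stochastic multipliers

    def __post_init__(self) -> None:
        if self.Tmax < 2:
            raise ValueError("Tmax must be >= 2")
        if self.N < self.n_groups:
            raise ValueError("population must be at least the number of groups")
        if not (0 <= self.u <= 1 and 0 <= self.alpha_blend <= 1):
            raise ValueError("u and alpha_blend must be in [0, 1]")

    @property
    def Td(self) -> int:
        """Exploration iterations (global-search phase), floor(0.9 * Tmax)."""
        return int(math.floor(0.9 * self.Tmax))


@dataclass
class AdoState:
    t: int
    positions: np.ndarray  # (N, Dim) on the internal scale
    velocities: np.ndarray
    fitness: np.ndarray  # (N,)
    pbest_pos: np.ndarray
    pbest_fit: np.ndarray
    groups: np.ndarray  # (N,) group index 0..n_groups-1
    group_best_pos: np.ndarray  # (n_groups, Dim)
    group_best_fit: np.ndarray
    global_best_pos: np.ndarray
    global_best_fit: float
    best_history: list[float]
    rng: np.random.Generator


# --------------------------------------------------------------------------
# schedules and forget counts
# --------------------------------------------------------------------------

def exploration_factor(t: int, Tmax: int, Td: int) -> float:
    """Cosine amplitude of the exploration perturbation; decays to 0 at t=Td."""
    return 0.5 * (math.cos(math.pi * (t + Tmax - Td) / Tmax) + 1.0)


def exploitation_factor(t: int, Tmax: int) -> float:
    """Cosine amplitude of the exploitation perturbation; decays to 0 at t=Tmax."""
    return 0.5 * (math.cos(math.pi * t / Tmax) + 1.0)


def _randi(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Inclusive randi with lo > hi resolved as lo <- hi."""
    if lo > hi:
        lo = hi
    return int(rng.integers(lo, hi + 1))


def forget_count_exploration(q: int, dim: int, rng: np.random.Generator) -> int:
    """Number of forgotten dimensions for group ``q`` (1..5) in exploration."""
    if not 1 <= q <= 5:
        raise ValueError("group index q must be in 1..5")
    lo = math.ceil(dim / (8 * q))
    hi = max(2, math.ceil(dim / (3 * q)))
    return min(max(_randi(rng, lo, hi), 1), dim)


def forget_count_exploitation(dim: int, rng: np.random.Generator) -> int:
    """Number of forgotten dimensions (shared by all agents) in exploitation."""
    hi = max(2, math.ceil(dim / 3))
    return min(max(_randi(rng, 2, hi), 1), dim)


# --------------------------------------------------------------------------
# population machinery
# --------------------------------------------------------------------------

def _evaluate(objective: Callable[[np.ndarray], float], pos: np.ndarray) -> float:
    val = objective(pos)
    try:
        val = float(val)
    except (TypeError, ValueError):
        return math.inf
    return val if math.isfinite(val) else math.inf


def initialize_population(
    space: SearchSpace, cfg: AdoConfig, objective: Callable[[np.ndarray], float]
) -> AdoState:
    """Uniform random population on the internal scale, round-robin groups."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = space.internal_bounds()
    positions = lo + rng.random((cfg.N, space.dim)) * (hi - lo)
    fitness = np.array([_evaluate(objective, p) for p in positions])
    groups = np.arange(cfg.N) % cfg.n_groups

    group_best_pos = np.zeros((cfg.n_groups, space.dim))
    group_best_fit = np.full(cfg.n_groups, math.inf)
    for g in range(cfg.n_groups):
        members = np.nonzero(groups == g)[0]
        best = members[np.argmin(fitness[members])]
        group_best_pos[g] = positions[best]
        group_best_fit[g] = fitness[best]
    gbest = int(np.argmin(fitness))

    return AdoState(
        t=0,
        positions=positions,
        velocities=np.zeros((cfg.N, space.dim)),
        fitness=fitness,
        pbest_pos=positions.copy(),
        pbest_fit=fitness.copy(),
        groups=groups,
        group_best_pos=group_best_pos,
        group_best_fit=group_best_fit,
        global_best_pos=positions[gbest].copy(),
        global_best_fit=float(fitness[gbest]),
        best_history=[float(fitness[gbest])],
        rng=rng,
    )


def pso_blend(
    doa_position: np.ndarray,
    current_position: np.ndarray,
    agent_i: int,
    state: AdoState,
    cfg: AdoConfig,
) -> np.ndarray:
    """Blend a DOA proposal with a particle-swarm candidate.

    The velocity update is ``v <- w v + g1 r1 (pbest - x) + g2 r2 (gbest - x)``
    with r1, r2 uniform [0,1] vectors (set to 1 under ``paper_pso``); the blend
    is ``alpha * x_doa + (1 - alpha) * (x + v)``.
    """
    dim = doa_position.size
    if cfg.paper_pso:
        r1 = r2 = np.ones(dim)
    else:
        r1, r2 = state.rng.random(dim), state.rng.random(dim)
    v = (
        cfg.inertia * state.velocities[agent_i]
        + cfg.gamma1 * r1 * (state.pbest_pos[agent_i] - current_position)
        + cfg.gamma2 * r2 * (state.global_best_pos - current_position)
    )
    state.velocities[agent_i] = v
    return cfg.alpha_blend * doa_position + (1.0 - cfg.alpha_blend) * (current_position + v)


def enforce_bounds(
    position: np.ndarray, space: SearchSpace, state: AdoState | None = None, agent_i: int = -1
) -> np.ndarray:
    """Repair out-of-bounds coordinates.

    Low-dimensional problems (Dim <= 15) resample a violating coordinate
    uniformly inside the box; higher-dimensional problems copy the coordinate
    from a random other agent (in bounds by induction). Falls back to uniform
    resampling when no population is available.
    """
    lo, hi = space.internal_bounds()
    pos = position.copy()
    bad = np.nonzero((pos < lo) | (pos > hi))[0]
    if bad.size == 0:
        return pos
    rng = state.rng if state is not None else np.random.default_rng()
    use_copy = space.dim > 15 and state is not None and state.positions.shape[0] > 1
    for j in bad:
        if use_copy:
            while True:
                m = int(rng.integers(state.positions.shape[0]))
                if m != agent_i:
                    break
            pos[j] = np.clip(state.positions[m, j], lo[j], hi[j])
        else:
            pos[j] = lo[j] + rng.random() * (hi[j] - lo[j])
    return pos


def _refresh_bests(state: AdoState, i: int, cfg: AdoConfig) -> None:
    f = state.fitness[i]
    if f < state.pbest_fit[i]:
        state.pbest_fit[i] = f
        state.pbest_pos[i] = state.positions[i].copy()
    g = state.groups[i]
    if f < state.group_best_fit[g]:
        state.group_best_fit[g] = f
        state.group_best_pos[g] = state.positions[i].copy()
    if f < state.global_best_fit:
        state.global_best_fit = float(f)
        state.global_best_pos = state.positions[i].copy()


def _iterate(
    state: AdoState,
    space: SearchSpace,
    cfg: AdoConfig,
    objective: Callable[[np.ndarray], float],
    explore: bool,
) -> None:
    rng = state.rng
    lo, hi = space.internal_bounds()
    span = hi - lo
    if explore:
        factor = exploration_factor(state.t, cfg.Tmax, cfg.Td)
    else:
        factor = exploitation_factor(state.t, cfg.Tmax)
        k_shared = forget_count_exploitation(space.dim, rng)

    for i in range(cfg.N):
        prev = state.positions[i].copy()
        if explore:
            g = state.groups[i]
            base = state.group_best_pos[g]
            k = forget_count_exploration(int(g) + 1, space.dim, rng)
        else:
            base = state.global_best_pos
            k = k_shared
        proposal = base.copy()
        dims = rng.choice(space.dim, size=k, replace=False)
        for j in dims:
            if (not explore) or rng.random() < cfg.u:
                # forgetting/supplementing: cosine-decayed uniform draw
                proposal[j] = base[j] + (lo[j] + rng.random() * span[j]) * factor
            else:
                # dream sharing: copy the coordinate of a random other agent
                while True:
                    m = int(rng.integers(cfg.N))
                    if m != i:
                        break
                proposal[j] = state.positions[m, j]
        blended = pso_blend(proposal, prev, i, state, cfg)
        state.positions[i] = enforce_bounds(blended, space, state, i)
        state.fitness[i] = _evaluate(objective, state.positions[i])
        _refresh_bests(state, i, cfg)

    state.t += 1
    state.best_history.append(state.global_best_fit)


def exploration_update(
    state: AdoState, space: SearchSpace, cfg: AdoConfig, objective
) -> AdoState:
    """One exploration iteration (group memories, dream sharing enabled)."""
    if state.t >= cfg.Td:
        raise ValueError("exploration updates require t < Td")
    _iterate(state, space, cfg, objective, explore=True)
    return state


def exploitation_update(
    state: AdoState, space: SearchSpace, cfg: AdoConfig, objective
) -> AdoState:
    """One exploitation iteration (global memory, shared forget count)."""
    if not cfg.Td <= state.t < cfg.Tmax:
        raise ValueError("exploitation updates require Td <= t < Tmax")
    _iterate(state, space, cfg, objective, explore=False)
    return state


def optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    cfg: AdoConfig,
    callback: Callable[[AdoState], None] | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Run the full schedule: Td exploration then Tmax - Td exploitation.

    The objective receives positions on the *internal* scale (use
    :func:`decode_position` inside the objective for hyperparameter spaces).
    Returns (best internal position, best fitness, best-so-far history).
    """
    state = initialize_population(space, cfg, objective)
    for _ in range(cfg.Td):
        exploration_update(state, space, cfg, objective)
        if callback:
            callback(state)
    for _ in range(cfg.Tmax - cfg.Td):
        exploitation_update(state, space, cfg, objective)
        if callback:
            callback(state)
    return state.global_best_pos.copy(), state.global_best_fit, list(state.best_history)


# --------------------------------------------------------------------------
# hyperparameter encoding
# --------------------------------------------------------------------------

def hyperparameter_space(epochs_range: tuple[int, int] = (50, 200)) -> SearchSpace:
    """The 5-D tuning space: learning rate (log10), batch size, dropout,
    kernel size and epoch count. ``epochs_range`` may be narrowed for
    scaled-down runs."""
    return SearchSpace(
        lower=(1e-5, 16.0, 0.2, 3.0, float(epochs_range[0])),
        upper=(1e-2, 128.0, 0.7, 5.0, float(epochs_range[1])),
        scale=("log10", "linear", "linear", "linear", "linear"),
        kind=("continuous", "categorical", "continuous", "categorical", "integer"),
        names=("learning_rate", "batch_size", "dropout", "kernel_size", "epochs"),
        choices={1: (16.0, 32.0, 64.0, 128.0), 3: (3.0, 5.0)},
    )


def decode_position(position: np.ndarray, space: SearchSpace) -> dict[str, float | int]:
    """Map an internal-scale position to named hyperparameter values.

    Log dimensions are exponentiated; categorical dimensions snap to the
    nearest admissible choice (ties to the lower value); integer dimensions
    round half away from zero.
    """
    names = space.names or tuple(f"x{j}" for j in range(space.dim))
    scale = space.scale or ("linear",) * space.dim
    kind = space.kind or ("continuous",) * space.dim
    out: dict[str, float | int] = {}
    for j in range(space.dim):
        v = float(position[j])
        if scale[j] == "log10":
            v = 10.0**v
        if kind[j] == "categorical":
            opts = space.choices[j]
            v = min(opts, key=lambda c: (abs(c - v), c))
            if float(v).is_integer():
                v = int(v)
        elif kind[j] == "integer":
            v = int(math.floor(v + 0.5))
        out[names[j]] = v
    return out


def encode_theta(theta: dict[str, float | int], space: SearchSpace) -> np.ndarray:
    """Inverse of :func:`decode_position` for exact values."""
    names = space.names or tuple(f"x{j}" for j in range(space.dim))
    scale = space.scale or ("linear",) * space.dim
    pos = np.zeros(space.dim)
    for j, name in enumerate(names):
        v = float(theta[name])
        pos[j] = math.log10(v) if scale[j] == "log10" else v
    return pos


def space_from_yaml(path) -> SearchSpace:
    """Load a search space from a YAML declaration.

    Expected layout::

        dimensions:
          - name: learning_rate
            lower: 1.0e-5
            upper: 1.0e-2
            scale: log10          # optional, default linear
            kind: continuous      # optional; continuous | integer | categorical
            choices: [16, 32]     # required for categorical
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    dims = doc["dimensions"]
    choices = {
        j: tuple(float(c) for c in d["choices"])
        for j, d in enumerate(dims)
        if d.get("kind") == "categorical"
    }
    return SearchSpace(
        lower=tuple(float(d["lower"]) for d in dims),
        upper=tuple(float(d["upper"]) for d in dims),
        scale=tuple(d.get("scale", "linear") for d in dims),
        kind=tuple(d.get("kind", "continuous") for d in dims),
        names=tuple(d["name"] for d in dims),
        choices=choices,
    )
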