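"""Self-propelled particle model with Morse-type social interactions.

N agents in the plane obey

    dx_i/dt = v_i,
    dv_i/dt = (alpha - beta |v_i|^2) v_i - grad_i U(x_i),
    U(x_i)  = sum_{j != i} [ C exp(-|x_i-x_j| / ell) - exp(-|x_i-x_j|) ],

the nondimensionalized form in which mass, attraction amplitude and
attraction length are unity, leaving four dimensionless parameters:
self-propulsion alpha, drag beta, repulsion amplitude ratio C and repulsion
length ratio ell. Depending on (C, ell) the group settles into one of seven
emergent phenotypes (mills, rings, swarms, escapes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._integrate import (
    R_SOFT,
    STATUS_OK,
    _integrate,
    _rhs,
)

__all__ = [
    "ModelParams",
    "Trajectory",
    "LibraryDataset",
    "SimulationError",
    "PARAM_VALUES",
    "PARAM_GRID",
    "PHENOTYPES",
    "PHENOTYPE_MAP",
    "social_force",
    "model_rhs",
    "simulate",
    "cap_escape",
    "phenotype_of",
    "generate_library",
]

#: The five values each of C and ell takes in the simulation library.
PARAM_VALUES = (0.1, 0.5, 0.9, 2.0, 3.0)

#: The 25 (C, ell) combinations in canonical order (C outer, ell inner).
PARAM_GRID = tuple((c, l) for c in PARAM_VALUES for l in PARAM_VALUES)

#: The seven emergent phenotypes, in a fixed canonical order.
PHENOTYPES = (
    "single_mill",
    "double_mill",
    "double_ring",
    "collective_swarm",
    "escape_symmetric",
    "escape_unsymmetric",
    "escape_collective",
)

#: Map from library (C, ell) combination to the phenotype it produces.
PHENOTYPE_MAP = {
    (0.5, 0.1): "single_mill",
    (0.9, 0.1): "single_mill",
    (2.0, 0.1): "single_mill",
    (2.0, 0.5): "single_mill",
    (3.0, 0.1): "single_mill",
    (0.9, 0.5): "double_mill",
    (0.1, 0.1): "double_ring",
    (0.5, 0.5): "double_ring",
    (0.9, 0.9): "double_ring",
    (0.1, 0.5): "collective_swarm",
    (0.1, 0.9): "collective_swarm",
    (0.1, 2.0): "collective_swarm",
    (0.1, 3.0): "collective_swarm",
    (0.5, 0.9): "collective_swarm",
    (0.5, 2.0): "collective_swarm",
    (0.5, 3.0): "collective_swarm",
    (0.9, 2.0): "collective_swarm",
    (0.9, 3.0): "collective_swarm",
    (2.0, 0.9): "escape_symmetric",
    (3.0, 0.9): "escape_symmetric",
    (2.0, 2.0): "escape_unsymmetric",
    (3.0, 2.0): "escape_unsymmetric",
    (3.0, 3.0): "escape_unsymmetric",
    (2.0, 3.0): "escape_collective",
    (3.0, 0.5): "escape_collective",
}


class SimulationError(RuntimeError):
    """Raised when the adaptive integrator fails (step underflow / blow-up)."""

    def __init__(self, message: str, params: "ModelParams | None" = None,
                 seed: int | None = None):
        super().__init__(message)
        self.params = params
        self.seed = seed


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless configuration of one simulation.

    alpha, beta : self-propulsion and drag strengths (defaults 1.5, 0.5).
    C, ell      : repulsion/attraction amplitude and length ratios.
    n_agents    : number of agents N (default 200).
    mass        : agent mass; 1 after nondimensionalization.
    """

    C: float
    ell: float
    alpha: float = 1.5
    beta: float = 0.5
    n_agents: int = 200
    mass: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0 or self.C <= 0 or self.ell <= 0:
            raise ValueError("alpha, beta, C and ell must all be positive")
        if self.n_agents < 1:
            raise ValueError("need at least one agent")


@dataclass
class Trajectory:
    """Positions/velocities of N agents sampled on a uniform time grid.

    positions, velocities : arrays of shape (N, M, 2).
    times                 : (M,) array, t_j = (j-1) * dt.
    """

    positions: np.ndarray
    velocities: np.ndarray
    times: np.ndarray
    dt: float
    params: ModelParams
    seed: int | None = None

    def __post_init__(self):
        n, m, d = self.positions.shape
        if d != 2 or self.velocities.shape != (n, m, 2):
            raise ValueError("positions/velocities must both be (N, M, 2)")
        if self.times.shape != (m,):
            raise ValueError("times must have one entry per frame")
        steps = np.diff(self.times)
        if m > 1 and not np.allclose(steps, self.dt, rtol=0, atol=1e-9):
            raise ValueError("times must be uniformly spaced by dt")

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]


@dataclass
class LibraryDataset:
    """An ensemble of simulations with their generating labels.

    labels[i] is the (C, ell) pair of trajectories[i]; phenotypes[i] the
    Table-of-phenotypes class that pair produces; seeds[i] the RNG seed.
    """

    trajectories: list
    labels: list
    phenotypes: list
    seeds: list
    reps_per_combo: int
    base_seed: int

    def __post_init__(self):
        if not (len(self.trajectories) == len(self.labels)
                == len(self.phenotypes) == len(self.seeds)):
            raise ValueError("library fields must have one entry per simulation")
        for lab, ph in zip(self.labels, self.phenotypes):
            if PHENOTYPE_MAP[lab] != ph:
                raise ValueError(f"phenotype {ph} inconsistent with label {lab}")

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def label_indices(self) -> np.ndarray:
        """Integer class labels: index of each (C, ell) in PARAM_GRID."""
        lut = {combo: i for i, combo in enumerate(PARAM_GRID)}
        return np.array([lut[lab] for lab in self.labels], dtype=np.intp)

    @property
    def phenotype_indices(self) -> np.ndarray:
        lut = {p: i for i, p in enumerate(PHENOTYPES)}
        return np.array([lut[p] for p in self.phenotypes], dtype=np.intp)


def phenotype_of(C: float, ell: float) -> str:
    """Phenotype produced by a library combination (C, ell).

    Only the 25 library combinations are mapped; anything else raises,
    deliberately — the map is an empirical lookup, not an extrapolation.
    """
    key = (float(C), float(ell))
    try:
        return PHENOTYPE_MAP[key]
    except KeyError:
        raise ValueError(f"(C, ell) = {key} is not a library combination") from None


def social_force(agent_index: int, positions: np.ndarray,
                 params: ModelParams) -> np.ndarray:
    """Morse social force -grad_i U on one agent, from a single frame.

    The force direction is softened at very short range,
    (x_i - x_j)/sqrt(r^2 + R_SOFT^2) with R_SOFT = 1e-4, so exactly
    coincident pairs contribute zero and near-coincident pairs vary smoothly
    (the direction is otherwise discontinuous where agents cross).
    """
    x = np.asarray(positions, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("positions must be finite")
    diffs = np.delete(x[agent_index] - x, agent_index, axis=0)  # (N-1, 2)
    r = np.hypot(diffs[:, 0], diffs[:, 1])
    up = -(params.C / params.ell) * np.exp(-r / params.ell) + np.exp(-r)
    coeff = -up / np.sqrt(r ** 2 + R_SOFT ** 2)
    return (coeff[:, None] * diffs).sum(axis=0)


def model_rhs(state: np.ndarray, params: ModelParams) -> np.ndarray:
    """Time derivative of the flat state [x_1..x_N, v_1..v_N] (length 4N).

    Vectorized numpy evaluation; the integrator uses an equivalent compiled
    kernel, and the two are cross-checked in the test suite.
    """
    y = np.asarray(state, dtype=float)
    if y.ndim != 1 or y.size % 4 != 0:
        raise ValueError("state must be a flat vector of length 4N")
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite state (integrator blow-up?)", params)
    n = y.size // 4
    x = y[: 2 * n].reshape(n, 2)
    v = y[2 * n:].reshape(n, 2)

    diffs = x[:, None, :] - x[None, :, :]  # (N, N, 2)
    r = np.sqrt((diffs ** 2).sum(axis=2))
    up = -(params.C / params.ell) * np.exp(-r / params.ell) + np.exp(-r)
    coeff = -up / np.sqrt(r ** 2 + R_SOFT ** 2)
    np.fill_diagonal(coeff, 0.0)
    force = (coeff[:, :, None] * diffs).sum(axis=1)

    speed2 = (v ** 2).sum(axis=1, keepdims=True)
    dv = (params.alpha - params.beta * speed2) * v + force / params.mass
    return np.concatenate([v.ravel(), dv.ravel()])


def simulate(params: ModelParams, seed: int, t_end: float = 100.0,
             dt: float = 0.05, rtol: float = 1e-6, atol: float = 1e-9,
             initial_state: tuple[np.ndarray, np.ndarray] | None = None,
             ) -> Trajectory:
    """Integrate the model from uniform random initial conditions.

    x_i(0), v_i(0) ~ Uniform[-1, 1]^2 drawn from a seeded generator; adaptive
    Dormand-Prince 4(5) stepping (rtol 1e-6 / atol 1e-9 by default) sampled at
    t_j = (j-1) dt, giving M = t_end/dt + 1 frames (2001 for the standard
    protocol).

    ``initial_state`` overrides the random draw with explicit (x0, v0); the
    seed is then recorded but unused.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    n = params.n_agents
    if initial_state is None:
        rng = np.random.default_rng(seed)
        x0 = rng.uniform(-1.0, 1.0, size=(n, 2))
        v0 = rng.uniform(-1.0, 1.0, size=(n, 2))
    else:
        x0, v0 = (np.asarray(a, dtype=float).reshape(n, 2) for a in initial_state)
    y0 = np.concatenate([x0.ravel(), v0.ravel()])

    m = int(round(t_end / dt)) + 1
    times = np.arange(m) * dt
    ys, status = _integrate(y0, times, rtol, atol,
                            params.alpha, params.beta, params.C, params.ell)
    if status != STATUS_OK:
        raise SimulationError(
            f"integrator failure (status {status}) at (C, ell) = "
            f"({params.C}, {params.ell}), seed {seed}", params, seed)

    positions = ys[:, : 2 * n].reshape(m, n, 2).transpose(1, 0, 2).copy()
    velocities = ys[:, 2 * n:].reshape(m, n, 2).transpose(1, 0, 2).copy()
    return Trajectory(positions, velocities, times, dt, params, seed)


def cap_escape(traj: Trajectory, threshold: float = 10.0) -> Trajectory:
    """Freeze escaped agents for the topological analyses.

    Each agent whose sup-norm distance from the origin reaches ``threshold``
    is held at its position at the first crossing frame for all later frames.
    Earlier frames — and velocities — are untouched. Idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pos = traj.positions.copy()
    sup = np.abs(pos).max(axis=2)  # (N, M)
    crossed = sup >= threshold
    for i in np.nonzero(crossed.any(axis=1))[0]:
        j0 = int(np.argmax(crossed[i]))
        pos[i, j0:] = pos[i, j0]
    return replace(traj, positions=pos)


def _seed_for(base_seed: int, combo_index: int, rep_index: int) -> int:
    # Reproducible in isolation: any one simulation can be regenerated from
    # its (base_seed, combo, rep) triple alone.
    return int(base_seed) + 1000 * combo_index + rep_index


def generate_library(reps: int, base_seed: int,
                     params_grid=None, n_agents: int = 200,
                     alpha: float = 1.5, beta: float = 0.5,
                     t_end: float = 100.0, dt: float = 0.05,
                     progress: bool = False) -> LibraryDataset:
    """Simulate ``reps`` runs for every (C, ell) combination in the grid.

    The default grid is the full 5 x 5 library (25 combinations); per-run
    seeds are base_seed + 1000 * combo_index + rep_index.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    grid = list(PARAM_GRID if params_grid is None else params_grid)
    trajectories, labels, phenotypes, seeds = [], [], [], []
    iterator = enumerate(grid)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic only
        iterator = enumerate(tqdm(grid, desc="combos"))
    for ci, (c, l) in iterator:
        params = ModelParams(C=c, ell=l, alpha=alpha, beta=beta,
                             n_agents=n_agents)
        pheno = phenotype_of(c, l)
        for ri in range(reps):
            seed = _seed_for(base_seed, ci, ri)
            trajectories.append(simulate(params, seed, t_end=t_end, dt=dt))
            labels.append((c, l))
            phenotypes.append(pheno)
            seeds.append(seed)
    return LibraryDataset(trajectories, labels, phenotypes, seeds,
                          reps_per_combo=reps, base_seed=base_seed)
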