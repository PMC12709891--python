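"""Bounded stochastic search combining sinh/cosh moves with swarm exchange.

The optimizer (SCPO) hybridises two mechanisms over a box-bounded domain:

* a sinh/cosh-bounded position update (SCHO-style) with an exploration phase
  that samples widely around the incumbent best and an exploitation phase
  whose step intensity grows with the iteration count, and
* a particle-swarm (PSO) velocity/position update driven by personal and
  global bests.

Each iteration applies the sinh/cosh move, evaluates, then the PSO move and
evaluates again; bounds are enforced by clamping.  The package uses it to
search the initial learning rate of the segmentation network in log10 space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SCPOConfig", "SwarmState", "init_swarm", "a1_coeff", "w1_coeff",
           "exploration_step", "exploitation_step", "pso_step",
           "scpo_minimize", "pso_minimize", "tune_learning_rate"]


@dataclass
class SCPOConfig:
    n_particles: int = 20
    dim: int = 1
    lb: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    ub: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    max_iter: int = 50
    u: float = 0.388          # first-phase sensitivity
    m: float = 1.0            # a1 sensitivity
    c1: float = 1.5           # individual learning factor
    c2: float = 1.5           # social learning factor
    w: float = 0.0            # inertia (the printed velocity update has none)
    phase_switch: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.lb = np.atleast_1d(np.asarray(self.lb, dtype=np.float64))
        self.ub = np.atleast_1d(np.asarray(self.ub, dtype=np.float64))
        if len(self.lb) != self.dim:
            self.lb = np.full(self.dim, float(self.lb[0]))
        if len(self.ub) != self.dim:
            self.ub = np.full(self.dim, float(self.ub[0]))
        if np.any(self.lb >= self.ub):
            raise ValueError("lb must be < ub per dimension")
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.phase_switch < 1:
            raise ValueError("phase_switch must be in (0, 1)")


@dataclass
class SwarmState:
    X: np.ndarray            # N x dim positions
    V: np.ndarray            # N x dim velocities
    fitness: np.ndarray      # N
    P: np.ndarray            # personal best positions
    P_fit: np.ndarray        # personal best fitnesses
    G_best: np.ndarray       # global best position
    G_fit: float
    t: int = 0


def _safe_eval(f, x: np.ndarray) -> float:
    try:
        v = float(f(x))
    except Exception:
        return np.inf
    return v if np.isfinite(v) else np.inf


def _clamp(X: np.ndarray, cfg: SCPOConfig) -> np.ndarray:
    return np.clip(X, cfg.lb, cfg.ub)


def init_swarm(cfg: SCPOConfig, f) -> SwarmState:
    rng = np.random.default_rng(cfg.seed)
    X = cfg.lb + rng.random((cfg.n_particles, cfg.dim)) * (cfg.ub - cfg.lb)
    fit = np.array([_safe_eval(f, x) for x in X])
    best = int(np.argmin(fit))
    return SwarmState(X=X, V=np.zeros_like(X), fitness=fit,
                      P=X.copy(), P_fit=fit.copy(),
                      G_best=X[best].copy(), G_fit=float(fit[best]))


def a1_coeff(t: int, cfg: SCPOConfig) -> float:
    """Linearly decreasing first-phase amplitude: -3.9 t/T + 3m."""
    return -3.9 * t / cfg.max_iter + 3.0 * cfg.m


def w1_coeff(t: int, cfg: SCPOConfig, rng: np.random.Generator):
    """W1 = r3 a1 (cosh r4 + u sinh r4 - 1) with r3, r4 ~ U[0,1]."""
    r3 = rng.random()
    r4 = rng.random()
    return r3 * a1_coeff(t, cfg) * (np.cosh(r4) + cfg.u * np.sinh(r4) - 1.0)


def exploration_step(state: SwarmState, cfg: SCPOConfig,
                     rng: np.random.Generator) -> SwarmState:
    """First phase: sample around the incumbent best with sinh/cosh bounds."""
    N, dim = state.X.shape
    r1 = rng.random((N, dim))
    r2 = rng.random((N, dim))
    W1 = np.empty((N, dim))
    for i in range(N):
        for j in range(dim):
            W1[i, j] = w1_coeff(state.t, cfg, rng)
    minus = state.G_best - r1 * W1 * state.X
    plus = state.G_best + r1 * W1 * state.X
    state.X = _clamp(np.where(r2 >= 0.5, minus, plus), cfg)
    return state


def exploitation_step(state: SwarmState, cfg: SCPOConfig,
                      rng: np.random.Generator) -> SwarmState:
    """Second phase: contract toward the best with iteration-growing intensity."""
    N, dim = state.X.shape
    r11 = rng.random((N, dim))
    r12 = rng.random((N, dim))
    r6 = rng.random((N, dim))
    a2 = 2.0 * state.t / cfg.max_iter
    W2 = r6 * a2
    step = r11 * (np.sinh(r11) / np.cosh(r12)) * W2 * (state.G_best - state.X)
    state.X = _clamp(state.X + step, cfg)
    return state


def pso_step(state: SwarmState, cfg: SCPOConfig,
             rng: np.random.Generator) -> SwarmState:
    """Velocity/position update from personal and global bests."""
    N, dim = state.X.shape
    r1 = rng.random((N, dim))
    r2 = rng.random((N, dim))
    state.V = (cfg.w * state.V
               + cfg.c1 * r1 * (state.P - state.X)
               + cfg.c2 * r2 * (state.G_best - state.X))
    state.X = _clamp(state.X + state.V, cfg)
    return state


def _update_bests(state: SwarmState, cfg: SCPOConfig, f) -> None:
    state.fitness = np.array([_safe_eval(f, x) for x in state.X])
    improved = state.fitness < state.P_fit
    state.P[improved] = state.X[improved]
    state.P_fit[improved] = state.fitness[improved]
    best = int(np.argmin(state.P_fit))
    if state.P_fit[best] < state.G_fit:
        state.G_fit = float(state.P_fit[best])
        state.G_best = state.P[best].copy()


def scpo_minimize(f, cfg: SCPOConfig):
    """Minimize f over the box; returns (x_best, f_best, history).

    history[t] is the best-so-far fitness after iteration t (non-increasing).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    state = init_swarm(cfg, f)
    history = []
    switch = cfg.phase_switch * cfg.max_iter
    for t in range(1, cfg.max_iter + 1):
        state.t = t
        if t <= switch:
            exploration_step(state, cfg, rng)
        else:
            exploitation_step(state, cfg, rng)
        _update_bests(state, cfg, f)
        pso_step(state, cfg, rng)
        _update_bests(state, cfg, f)
        history.append(state.G_fit)
    return state.G_best.copy(), state.G_fit, np.asarray(history)


def pso_minimize(f, cfg: SCPOConfig):
    """Plain PSO with the same evaluation budget (two moves per iteration)."""
    rng = np.random.default_rng(cfg.seed + 1)
    state = init_swarm(cfg, f)
    history = []
    for t in range(1, cfg.max_iter + 1):
        state.t = t
        pso_step(state, cfg, rng)
        _update_bests(state, cfg, f)
        pso_step(state, cfg, rng)
        _update_bests(state, cfg, f)
        history.append(state.G_fit)
    return state.G_best.copy(), state.G_fit, np.asarray(history)


def tune_learning_rate(probe, lb: float = 1e-8, ub: float = 1e-5,
                       cfg: SCPOConfig | None = None):
    """Search the initial learning rate in log10 space over [lb, ub].

    ``probe`` maps a learning rate to a validation loss.  Returns
    ``(lr, info)`` where info records the best fitness, the evaluation count
    and the best-so-far history.
    """
    if not 0 < lb < ub:
        raise ValueError("need 0 < lb < ub")
    if cfg is None:
        cfg = SCPOConfig(n_particles=6, dim=1, max_iter=8)
    cfg = SCPOConfig(n_particles=cfg.n_particles, dim=1,
                     lb=np.array([np.log10(lb)]), ub=np.array([np.log10(ub)]),
                     max_iter=cfg.max_iter, u=cfg.u, m=cfg.m, c1=cfg.c1,
                     c2=cfg.c2, w=cfg.w, phase_switch=cfg.phase_switch,
                     seed=cfg.seed)
    n_evals = 0

    def f(x):
        nonlocal n_evals
        n_evals += 1
        return _safe_eval(probe, 10.0 ** float(x[0]))

    x_best, f_best, history = scpo_minimize(f, cfg)
    lr = float(10.0 ** x_best[0])
    lr = min(max(lr, lb), ub)
    return lr, {"loss": f_best, "n_evals": n_evals, "history": history.tolist()}
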