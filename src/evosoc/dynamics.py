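"""Develop / mutate phase dynamics of the occupation network.

The simulator alternates two phases:

* **developing** -- the productivity vector relaxes to the attractor of

      dx_i/dt = a (C x)_i / x_i  -  b X          (ratio form)

  where ``X = sum(x)``.  The supporting inflow ``a (C x)_i`` is divided by the
  occupation's own productivity, so small supported occupations grow fast; the
  environmental restriction ``b X`` is shared by every occupation.  An active
  occupation whose productivity falls below ``limina`` during the relaxation
  ceases to function: its productivity drops to 0 and it stops supporting the
  others (eliminations cascade within one develop phase).  On an irreducible
  active structure the attractor is the Perron equilibrium
  ``x* = (a/b) * lambda_pf * v``.

* **mutating** -- inhabitants stochastically flow between occupations: each
  active occupation, visited in random order, fires with probability ``p_m``
  provided its productivity exceeds ``2*limina``; a firing transfers exactly
  ``limina`` productivity to a target occupation that is supported by at least
  one currently active occupation.  Inactive targets are (re)created at
  ``limina``.  Total productivity is conserved.

An equivalent rate form ``dx_i/dt = a (C x)_i - b X x_i`` (same equilibria,
time reparametrized) is available as ``rate_form="product"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .network import DERIVED, InterSocietySpec, SupportMatrix

__all__ = [
    "SocietyState",
    "EnvironmentParams",
    "StrengthProfile",
    "MutationEvent",
    "ScenarioConfig",
    "competing_strength",
    "environmental_restriction",
    "derivative",
    "develop",
    "eligible_targets",
    "mutate",
    "step",
]


class DevelopWarning(UserWarning):
    """Develop phase hit its iteration cap before converging."""


@dataclass
class SocietyState:
    """Per-occupation productivity with active/eliminated status."""

    x: np.ndarray
    active: np.ndarray
    phase_index: int = 0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        if self.x.shape != self.active.shape:
            raise ValueError("x and active must have the same shape")
        if np.any(self.x < 0):
            raise ValueError("productivity must be nonnegative")
        if np.any(self.x[~self.active] != 0):
            raise ValueError("inactive occupations must have zero productivity")

    @classmethod
    def from_x(cls, x, phase_index: int = 0) -> "SocietyState":
        x = np.asarray(x, dtype=float)
        return cls(x=x, active=x > 0, phase_index=phase_index)

    @property
    def total(self) -> float:
        return float(self.x.sum())

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def extinct(self) -> bool:
        return not self.active.any()

    def copy(self) -> "SocietyState":
        return SocietyState(self.x.copy(), self.active.copy(), self.phase_index)


@dataclass
class EnvironmentParams:
    """Supporting coefficient a, restriction coefficient b, pulse schedule."""

    a: float
    b: float = 1.0
    disturbance_schedule: dict = field(default_factory=dict)  # phase_index -> r_d

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        for phase, r_d in self.disturbance_schedule.items():
            if r_d < 1:
                raise ValueError(f"disturbance severity r_d must be >= 1, got {r_d} at phase {phase}")


@dataclass
class StrengthProfile:
    """Competing strengths Cs_i and the shared environmental restriction Ce."""

    Cs: np.ndarray
    Ce: float


@dataclass
class MutationEvent:
    """Transfer of a limina-sized productivity quantum from source to target."""

    source: int
    target: int
    amount: float


@dataclass
class ScenarioConfig:
    """Run configuration: thresholds, mutation, phase counts and solver options."""

    society: InterSocietySpec = None
    a_over_b: float = 100.0
    limina: float = 1.0
    p_m: float = 0.01
    cross_weight: float = 0.1
    n_phases: int = 1000
    n_reps: int = 50
    seed: int = 0
    r_d: float = 1.0
    pulse_phase: int = 100
    # develop solver options
    method: str = "relax"  # "relax" (damped normalized-support map) or "euler"
    rate_form: str = "ratio"  # "ratio" or "product"
    relax_damping: float = 0.5
    relax_rtol: float = 1e-12
    relax_max_iter: int = 100_000
    dt: float = 1e-3  # Euler step, in units of 1/b
    euler_tol: float = 1e-8  # residual tolerance, in units of (a/b)*b
    euler_max_iter: int = 10_000_000

    def __post_init__(self):
        if self.limina <= 0:
            raise ValueError(f"limina must be positive, got {self.limina}")
        if not 0 <= self.p_m <= 1:
            raise ValueError(f"p_m must be in [0, 1], got {self.p_m}")
        if not 0 <= self.cross_weight <= 1:
            raise ValueError(f"cross_weight must be in [0, 1], got {self.cross_weight}")
        if self.n_phases < 1:
            raise ValueError(f"n_phases must be >= 1, got {self.n_phases}")
        if self.a_over_b <= 0:
            raise ValueError(f"a_over_b must be positive, got {self.a_over_b}")
        if self.method not in ("relax", "euler"):
            raise ValueError(f"unknown develop method {self.method!r}")
        if self.rate_form not in ("ratio", "product"):
            raise ValueError(f"unknown rate_form {self.rate_form!r}")

    def env(self, disturbance_schedule: dict = None) -> EnvironmentParams:
        return EnvironmentParams(
            a=self.a_over_b, b=1.0, disturbance_schedule=disturbance_schedule or {}
        )


def _matrix(C) -> np.ndarray:
    return C.C if isinstance(C, SupportMatrix) else np.asarray(C, dtype=float)


def competing_strength(x, C, a: float) -> np.ndarray:
    """Cs_i = a * sum_j c_ij x_j; inactive occupations (x_j = 0) contribute nothing."""
    A = _matrix(C)
    x = np.asarray(x, dtype=float)
    if x.shape[0] != A.shape[1]:
        raise ValueError("dimension mismatch between x and C")
    return a * (A @ x)


def environmental_restriction(X: float, b: float) -> float:
    """Linear incremental restriction Ce = b * X shared by all occupations."""
    if X < 0:
        raise ValueError("total productivity cannot be negative")
    return b * X


def derivative(x, C, env: EnvironmentParams, active=None, rate_form: str = "ratio") -> np.ndarray:
    """Productivity change rates; zero for inactive occupations.

    ratio form:   dx_i/dt = a (C x)_i / x_i - b X
    product form: dx_i/dt = a (C x)_i - b X x_i   (same equilibria)
    """
    x = np.asarray(x, dtype=float)
    if active is None:
        active = x > 0
    active = np.asarray(active, dtype=bool)
    Cs = competing_strength(x, C, env.a)
    Ce = environmental_restriction(x.sum(), env.b)
    out = np.zeros_like(x)
    if rate_form == "ratio":
        if np.any(active & (x == 0)):
            raise ValueError("active occupation with zero productivity: eliminate first")
        out[active] = Cs[active] / x[active] - Ce
    elif rate_form == "product":
        out[active] = Cs[active] - Ce * x[active]
    else:
        raise ValueError(f"unknown rate_form {rate_form!r}")
    return out


def _eliminate(x, active, limina) -> np.ndarray:
    """Deactivate occupations below the functioning threshold; return mask of dead."""
    dead = active & (x < limina)
    if dead.any():
        x[dead] = 0.0
        active[dead] = False
    return dead


def _develop_relax(x, active, A, env, cfg):
    """Damped normalized-support relaxation to the attractor.

    One step is explicit Euler on the ratio-form dynamics with per-occupation
    time step ``dt_i = x_i / (b X)`` (equivalently ``dt_i = 1/(b X)`` for the
    product form), which maps ``x`` to ``a (C x) / (b X)``; damping with
    weight ``w`` guarantees convergence on periodic support structures.  Fixed
    points are exactly the Perron equilibria of the active substructure.
    """
    w = cfg.relax_damping
    converged = False
    for _ in range(cfg.relax_max_iter):
        X = x.sum()
        target = env.a * (A @ x) / (env.b * X)
        x_new = (1.0 - w) * x + w * target
        x_new[~active] = 0.0
        dead = _eliminate(x_new, active, cfg.limina)
        if not active.any():
            x = x_new
            break
        delta = np.max(np.abs(x_new - x))
        x = x_new
        if not dead.any() and delta <= cfg.relax_rtol * max(x.max(), 1.0):
            converged = True
            break
    else:
        warnings.warn("develop (relax) hit iteration cap before converging", DevelopWarning)
    return x, active, converged


def _develop_euler(x, active, A, env, cfg):
    """Uniform-step explicit Euler integration of the chosen rate form."""
    dt = cfg.dt / env.b
    tol = cfg.euler_tol * (env.a / env.b) * env.b
    converged = False
    for _ in range(cfg.euler_max_iter):
        X = x.sum()
        Cs = env.a * (A @ x)
        Ce = env.b * X
        if cfg.rate_form == "ratio":
            f = np.where(active, Cs / np.where(active, x, 1.0) - Ce, 0.0)
        else:
            f = np.where(active, Cs - Ce * x, 0.0)
        if np.max(np.abs(f), initial=0.0) <= tol:
            converged = True
            break
        x = x + dt * f
        x[~active] = 0.0
        _eliminate(x, active, cfg.limina)
        if not active.any():
            break
    else:
        warnings.warn("develop (euler) hit iteration cap before converging", DevelopWarning)
    return x, active, converged


def develop(state: SocietyState, C, env: EnvironmentParams, cfg: ScenarioConfig) -> SocietyState:
    """Relax the society to its attractor, eliminating sub-limina occupations.

    Returns a new state; if every occupation is eliminated the returned state
    is extinct (``state.extinct``) rather than raising.
    """
    if state.extinct:
        return state.copy()
    A = _matrix(C)
    x = state.x.copy()
    active = state.active.copy()
    solver = _develop_relax if cfg.method == "relax" else _develop_euler
    x, active, _ = solver(x, active, A, env, cfg)
    return SocietyState(x=x, active=active, phase_index=state.phase_index)


def eligible_targets(state: SocietyState, C, source: int = None) -> np.ndarray:
    """Indices that are supported by at least one active occupation.

    Inhabitants only move to occupations that can actually function, i.e. that
    receive support from the currently active set.  Inactive indices are
    included (destroyed occupations can be regenerated; new ones created).
    The source itself, if given, is excluded.
    """
    A = _matrix(C)
    supported = (A[:, state.active] != 0).any(axis=1)
    if source is not None:
        supported[source] = False
    return np.flatnonzero(supported)


def mutate(
    state: SocietyState,
    C,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    labels=None,
) -> tuple[SocietyState, list[MutationEvent]]:
    """Stochastic limina-sized productivity transfers between occupations.

    Active occupations are visited in a fresh uniformly random order; each
    fires with probability ``p_m`` if its current productivity strictly
    exceeds ``2*limina``.  The target is drawn from the eligible set with
    own-society targets at weight 1 and other-society targets at weight
    ``cfg.cross_weight``.  Total productivity is conserved exactly.
    """
    rng = np.random.default_rng(rng)
    if labels is None:
        labels = C.labels if isinstance(C, SupportMatrix) else None
    A = _matrix(C)
    x = state.x.copy()
    active = state.active.copy()
    events: list[MutationEvent] = []
    if not active.any():
        return SocietyState(x, active, state.phase_index), events

    order = rng.permutation(np.flatnonzero(active))
    u = rng.random(len(order))
    # active-supporter count per potential target, updated on (re)creation
    sup_count = A @ active.astype(float)
    lim = cfg.limina

    for src, draw in zip(order, u):
        if draw >= cfg.p_m:
            continue
        if x[src] <= 2.0 * lim:
            continue
        elig = sup_count > 0
        elig[src] = False
        idx = np.flatnonzero(elig)
        if idx.size == 0:
            continue
        if labels is None or cfg.cross_weight == 1.0:
            tgt = int(rng.choice(idx))
        else:
            w = np.where(labels[idx] == labels[src], 1.0, cfg.cross_weight)
            total_w = w.sum()
            if total_w == 0:
                continue
            tgt = int(rng.choice(idx, p=w / total_w))
        x[src] -= lim
        x[tgt] += lim
        events.append(MutationEvent(int(src), tgt, lim))
        if not active[tgt]:
            active[tgt] = True
            sup_count += A[:, tgt]
    return SocietyState(x, active, state.phase_index), events


def step(
    state: SocietyState,
    C,
    env: EnvironmentParams,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[SocietyState, list[MutationEvent]]:
    """One develop+mutate cycle; applies any scheduled disturbance pulse.

    A pulse of severity ``r_d`` amplifies the restriction coefficient to
    ``r_d * b`` for this phase's develop only.
    """
    if state.extinct:
        out = state.copy()
        out.phase_index += 1
        return out, []
    r_d = env.disturbance_schedule.get(state.phase_index, 1.0)
    phase_env = env if r_d == 1.0 else replace(env, b=env.b * r_d, disturbance_schedule={})
    developed = develop(state, C, phase_env, cfg)
    mutated, events = mutate(developed, C, cfg, rng)
    mutated.phase_index = state.phase_index + 1
    return mutated, events
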