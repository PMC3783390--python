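"""Scenario engines: self-boot, parasitism, disturbance, invasion, mutual support.

Each runner is deterministic given (config, seed) and returns a
:class:`Trajectory` recording, for every phase, the total productivity and
active occupation count of each society present.

Because the develop phase always relaxes to the attractor, a fully booted
society sits exactly at its Perron equilibrium at every phase boundary; the
scenario runners therefore initialise the original society directly at that
equilibrium instead of replaying the (long) self-boot, which leaves every
post-steady-state statistic unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network
from .dynamics import EnvironmentParams, ScenarioConfig, SocietyState, develop, step
from .network import InterSocietySpec, SupportMatrix

__all__ = [
    "Trajectory",
    "run_boot",
    "run_supporting",
    "run_disturbing",
    "run_invading",
    "run_mutual",
    "apply_disturbance",
    "SCENARIOS",
]


@dataclass
class Trajectory:
    """Per-phase records of a single scenario run."""

    phases: np.ndarray  # phase indices, 0..n_phases
    totals: dict  # society label -> array of per-phase total productivity
    counts: dict  # society label -> array of per-phase active counts
    final_state: SocietyState
    matrix: SupportMatrix
    config: ScenarioConfig
    seed: int = None
    events_per_phase: list = field(default_factory=list)

    @property
    def societies(self) -> list[str]:
        return list(self.totals)

    def extinct(self, label: str) -> bool:
        if label not in self.counts:
            raise KeyError(f"no society labelled {label!r} in this run")
        return self.counts[label][-1] == 0

    @property
    def extinction_flags(self) -> dict:
        return {s: self.extinct(s) for s in self.societies}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.societies:
            rows.append(
                pd.DataFrame(
                    {
                        "phase": self.phases,
                        "society": s,
                        "total_productivity": self.totals[s],
                        "active_count": self.counts[s],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def write_event_log(self, path) -> None:
        """Per-phase event log CSV: develop/disturb records with per-society
        totals and active counts, plus one row per mutation transfer."""
        r_d = getattr(self.config, "r_d", 1.0)
        pulse_phase = getattr(self.config, "pulse_phase", None)
        rows = []
        for k, phase in enumerate(self.phases):
            if k == 0:
                kind = "initial"
            elif r_d > 1.0 and pulse_phase is not None and phase == pulse_phase + 1:
                kind = "disturb"
            else:
                kind = "develop"
            row = {"phase": int(phase), "event": kind}
            for s in self.societies:
                row[f"total_{s}"] = self.totals[s][k]
                row[f"active_{s}"] = int(self.counts[s][k])
            rows.append(row)
            if 0 < k <= len(self.events_per_phase):
                for ev in self.events_per_phase[k - 1]:
                    rows.append(
                        {"phase": int(phase), "event": "mutate",
                         "source": ev.source, "target": ev.target, "amount": ev.amount}
                    )
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def _record(sm: SupportMatrix, state: SocietyState, totals, counts):
    for s in sm.societies:
        idx = sm.indices_of(s)
        totals[s].append(state.x[idx].sum())
        counts[s].append(int(state.active[idx].sum()))


def _run_phases(
    sm: SupportMatrix,
    state: SocietyState,
    env: EnvironmentParams,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    seed,
) -> Trajectory:
    totals = {s: [] for s in sm.societies}
    counts = {s: [] for s in sm.societies}
    events_log = []
    _record(sm, state, totals, counts)
    for _ in range(cfg.n_phases):
        state, events = step(state, sm, env, cfg, rng)
        events_log.append(events)
        _record(sm, state, totals, counts)
    return Trajectory(
        phases=np.arange(cfg.n_phases + 1),
        totals={s: np.asarray(v) for s, v in totals.items()},
        counts={s: np.asarray(v) for s, v in counts.items()},
        final_state=state,
        matrix=sm,
        config=cfg,
        seed=seed,
        events_per_phase=events_log,
    )


def _rng_and_seed(rng):
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng)), int(rng)
    return np.random.default_rng(rng), None


def _equilibrium_state(sm: SupportMatrix, label: str, cfg: ScenarioConfig) -> SocietyState:
    """All occupations of one society active at their Perron equilibrium."""
    idx = sm.indices_of(label)
    x = np.zeros(sm.n)
    x[idx] = network.equilibrium_productivity(sm.submatrix(idx), cfg.a_over_b, 1.0)
    return SocietyState.from_x(x)


def run_boot(cfg: ScenarioConfig, rng) -> Trajectory:
    """Self-boot: one self-supporting occupation seeds the whole society.

    The seed starts at ``limina``; mutation gradually (re)generates the other
    occupations until the society reaches full occupation, with total
    productivity fluctuating around ``(a/b) * lambda_pf``.
    """
    rng, seed = _rng_and_seed(rng)
    spec = cfg.society
    sm = network.generate_support_matrix(
        spec.n_o, spec.p_c_oo, rng, require_irreducible=True, ensure_self_supporter=True
    )
    self_supporters = np.flatnonzero(np.diag(sm.C))
    seed_occ = int(rng.choice(self_supporters))
    x = np.zeros(sm.n)
    x[seed_occ] = cfg.limina
    state = SocietyState.from_x(x)
    return _run_phases(sm, state, cfg.env(), cfg, rng, seed)


def run_supporting(cfg: ScenarioConfig, rng) -> Trajectory:
    """Parasitic derived society: supported by the original, gives nothing back.

    Requires ``p_c_do = 0``.  The original society starts at equilibrium;
    mutation populates the derived occupations, which hold productivity (and
    add to the environmental restriction) without supporting anyone unless
    ``p_c_dd > 0`` makes them mutually supportive.
    """
    rng, seed = _rng_and_seed(rng)
    spec = cfg.society
    if spec.p_c_do != 0:
        raise ValueError(
            "supporting (parasitism) scenario requires p_c_do = 0; "
            f"got p_c_do={spec.p_c_do}"
        )
    sm = network.generate_two_society_matrix(spec, rng)
    state = _equilibrium_state(sm, network.ORIGINAL, cfg)
    return _run_phases(sm, state, cfg.env(), cfg, rng, seed)


def apply_disturbance(
    state: SocietyState,
    C,
    env: EnvironmentParams,
    r_d: float,
    cfg: ScenarioConfig,
) -> SocietyState:
    """One develop phase under the amplified restriction ``b' = r_d * b``.

    Starting from equilibrium, survivors relax toward ``x / r_d``; occupations
    crossing ``limina`` on the way are eliminated and the cascade feeds back
    (dead occupations stop supporting but also stop competing for resources).
    """
    if r_d < 1:
        raise ValueError(f"disturbance severity must be >= 1, got {r_d}")
    pulsed = EnvironmentParams(a=env.a, b=env.b * r_d)
    return develop(state, C, pulsed, cfg)


def run_disturbing(cfg: ScenarioConfig, rng) -> Trajectory:
    """Single pulse disturbance of severity ``cfg.r_d`` at ``cfg.pulse_phase``.

    The society starts at its steady state; after the pulse the restriction
    returns to normal and any survivors seed the rebuild through mutation.
    """
    rng, seed = _rng_and_seed(rng)
    spec = cfg.society
    sm = network.generate_support_matrix(
        spec.n_o, spec.p_c_oo, rng, require_irreducible=True, ensure_self_supporter=True
    )
    state = _equilibrium_state(sm, network.ORIGINAL, cfg)
    if not 0 <= cfg.pulse_phase < cfg.n_phases:
        raise ValueError("pulse_phase must fall within the run length")
    env = cfg.env(disturbance_schedule={cfg.pulse_phase: cfg.r_d})
    return _run_phases(sm, state, env, cfg, rng, seed)


def run_invading(cfg: ScenarioConfig, rng) -> Trajectory:
    """Peaceful invasion: an intact foreign society enters the environment.

    No cross-support exists between the blocks (pure competition through the
    shared environment).  The incumbent starts at equilibrium; the invading
    squad is intact and enters with the productivity profile it held in its
    identical home environment -- its own Perron equilibrium.  Along that
    profile the whole invader block grows or declines uniformly, so the
    contest is decided by the spectral radii: the block with the larger
    ``lambda_pf`` takes over the environment.
    """
    rng, seed = _rng_and_seed(rng)
    spec = cfg.society
    if spec.n_i < 1:
        raise ValueError("invading scenario requires n_i >= 1")
    if spec.p_c_od or spec.p_c_do or spec.p_c_dd or spec.n_d:
        raise ValueError("invading scenario uses no derived society (competition only)")
    sm = network.generate_two_society_matrix(spec, rng)
    state = _equilibrium_state(sm, network.ORIGINAL, cfg)
    inv = sm.indices_of(network.INVADER)
    state.x[inv] = network.equilibrium_productivity(sm.submatrix(inv), cfg.a_over_b, 1.0)
    state.active[inv] = True
    return _run_phases(sm, state, cfg.env(), cfg, rng, seed)


def run_mutual(cfg: ScenarioConfig, rng) -> Trajectory:
    """Mutual support: derived occupations support the original society back.

    When the merged support structure is irreducible the two societies fuse
    into one with a larger spectral radius, hence a higher equilibrium total:
    the growth transition.  With all cross-probabilities zero this degenerates
    to the original society evolving alone.
    """
    rng, seed = _rng_and_seed(rng)
    sm = network.generate_two_society_matrix(cfg.society, rng)
    state = _equilibrium_state(sm, network.ORIGINAL, cfg)
    return _run_phases(sm, state, cfg.env(), cfg, rng, seed)


SCENARIOS = {
    "boot": run_boot,
    "supporting": run_supporting,
    "disturbing": run_disturbing,
    "invading": run_invading,
    "mutual": run_mutual,
}
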