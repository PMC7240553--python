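"""Langevin dynamics of two oppositely charged bead-spring chains.

The system is a stoichiometric pair of chains of equal length N with
ionization degree f = 1/2: charged and uncharged beads strictly alternate,
the H (polycation, hydrophobic) chain carries +1 charges and the P
(polyanion, hydrophilic) chain -1 charges.  The solvent is implicit: a
Yukawa attraction between H beads of depth |ε_HH| models declining solvent
quality, electrostatics is a direct non-periodic Coulomb sum (the solution
is so dilute that periodic images are irrelevant), and temperature is held
at kT = 1 by a Langevin thermostat.

Integration uses the BAOAB splitting of Langevin dynamics: a
velocity-Verlet-type scheme whose Ornstein-Uhlenbeck substep is exact, so
equipartition holds even at the stiff-bond time step (K = 10⁴ with dt =
0.005 puts the bond period at ~6 steps).  The damping constant D = 100 is
read in the LAMMPS ``damp`` convention by default: τ = 100 reduced time
units of weak friction, which leaves bead motion nearly inertial and lets
collapsed structures coalesce quickly.  The alternative strong-coupling
reading, "temperature relaxed within 100 time steps" (τ = damping·dt), is
available via ``damping_convention='steps'``; equilibrium averages agree
between the two, relaxation rates do not.

The annealing protocol mirrors the study design: relaxation at ε_HH = 0,
then a stepwise schedule ε_HH: 0 → -2.0 (step -0.1 by default, extensible
to -3.0), each stage split into an equilibration and a production run, with
snapshots taken during production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import kernels
from .forcefield import ForceField
from .types import BeadConfiguration

__all__ = [
    "SimProtocol",
    "SimState",
    "Trajectory",
    "make_initial_state",
    "compute_forces",
    "compute_energies",
    "step_langevin",
    "step_nve",
    "run_langevin",
    "run_protocol",
    "default_eps_schedule",
    "HardCoreOverlapError",
    "BlowUpError",
]


class HardCoreOverlapError(RuntimeError):
    pass


class BlowUpError(RuntimeError):
    pass


def default_eps_schedule(eps_min: float = -2.0, step: float = -0.1) -> tuple:
    """ε_HH stages 0-excluded: step, 2·step, ..., eps_min."""
    n = int(round(eps_min / step))
    return tuple(round(step * k, 10) for k in range(1, n + 1))


@dataclass(frozen=True)
class SimProtocol:
    N: int = 512                       # chain length per polyion
    dt: float = 0.005
    damping: float = 100.0                  # thermostat relaxation, see convention
    damping_convention: str = "time_units"  # 'time_units': τ = damping (LAMMPS damp); 'steps': τ = damping·dt
    kT: float = 1.0
    box_edge: float | None = None
    relax_steps: int = 4_000_000
    eps_schedule: tuple = field(default_factory=default_eps_schedule)
    equil_steps: int = 2_000_000
    prod_steps: int = 2_000_000
    snapshot_stride: int = 10_000
    seed: int = 0
    electrostatics_mode: str = "direct_nonperiodic"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.N < 2 or self.N % 2:
            raise ValueError("N must be an even integer >= 2")
        if min((self.relax_steps, self.equil_steps, self.prod_steps)) < 0:
            raise ValueError("step counts must be >= 0")
        eps = np.asarray(self.eps_schedule, dtype=float)
        if len(eps) and (np.diff(eps) > 1e-12).any():
            raise ValueError("eps_schedule must be monotone non-increasing")
        if self.electrostatics_mode == "ewald":
            raise NotImplementedError(
                "Ewald summation is not implemented; the dilute complex is "
                "handled by direct non-periodic summation"
            )
        if self.electrostatics_mode != "direct_nonperiodic":
            raise ValueError(f"unknown electrostatics mode {self.electrostatics_mode!r}")

    @property
    def tau(self) -> float:
        return self.damping * self.dt if self.damping_convention == "steps" else self.damping


@dataclass
class SimState:
    config: BeadConfiguration
    velocities: np.ndarray
    eps_hh: float
    step: int
    rng: np.random.Generator


# ---------------------------------------------------------------------------
# initial configuration
# ---------------------------------------------------------------------------

def _grow_confined_walk(n: int, b: float, radius: float, rng,
                        existing: np.ndarray | None, start: np.ndarray,
                        min_dist: float = 0.95, max_restarts: int = 200,
                        ) -> np.ndarray:
    """Excluded-volume walk; backtracks when sterically stuck.

    The minimum distance is enforced unconditionally — a single deep overlap
    in the start configuration injects an enormous WCA force spike that the
    weakly coupled thermostat cannot drain.
    """
    pts = np.empty((n, 3))
    pts[0] = start
    if existing is not None:
        # the start bead must respect the excluded volume too
        for _ in range(1000):
            if np.min(np.linalg.norm(existing - pts[0], axis=1)) >= min_dist:
                break
            pts[0] = start + rng.normal(0.0, b, 3)
        else:
            raise RuntimeError("no room for the second chain's start bead")
    i = 1
    restarts = 0
    while i < n:
        placed = False
        for _ in range(100):
            v = rng.normal(size=3)
            cand = pts[i - 1] + b * v / np.linalg.norm(v)
            if np.linalg.norm(cand) > radius:
                continue
            prev = pts[: i - 1]
            if len(prev) and np.min(np.linalg.norm(prev - cand, axis=1)) < min_dist:
                continue
            if existing is not None and np.min(
                np.linalg.norm(existing - cand, axis=1)
            ) < min_dist:
                continue
            pts[i] = cand
            placed = True
            break
        if placed:
            i += 1
        else:  # dead end: back up a few beads and regrow
            restarts += 1
            if restarts > max_restarts:
                raise RuntimeError(
                    "could not grow a self-avoiding start configuration; "
                    "confinement radius too small for the chain length"
                )
            i = max(1, i - 8)
    return pts


def make_initial_state(protocol: SimProtocol, ff: ForceField) -> SimState:
    """Two interleaved excluded-volume random walks in a sphere of radius N^0.6 b.

    Confining the initial coils avoids the long transient of two distant
    chains diffusing together before complexation.
    """
    rng = np.random.default_rng(protocol.seed)
    N = protocol.N
    radius = max(4.0, N ** 0.6 * ff.b)
    h = _grow_confined_walk(N, ff.b, radius, rng, None, np.zeros(3))
    p = _grow_confined_walk(N, ff.b, radius, rng, h,
                            h[0] + np.array([1.5 * ff.b, 0.0, 0.0]))
    pos = np.concatenate([h, p])
    chain = np.array(["H"] * N + ["P"] * N, dtype="<U1")
    charge = np.zeros(2 * N, dtype=np.int8)
    charge[0:N:2] = 1
    charge[N::2] = -1
    seq = np.arange(N - 1)
    bonds = np.concatenate(
        [np.column_stack([seq, seq + 1]), np.column_stack([seq + N, seq + N + 1])]
    )
    cfg = BeadConfiguration(pos, chain, charge, bonds=bonds,
                            box_edge=protocol.box_edge, meta={"N": N})
    vel = rng.normal(0.0, math.sqrt(protocol.kT), (2 * N, 3))
    return SimState(cfg, vel, 0.0, 0, rng)


# ---------------------------------------------------------------------------
# force evaluation
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _max_disp2(pos, ref):
    worst = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > worst:
            worst = d2
    return worst


@njit(cache=True, fastmath=True)
def _baoab_drift(pos, vel, forces, half_dt, c1, c2, noise):
    """B (half kick) + A (half drift) + O (exact OU) + A (half drift)."""
    for i in range(pos.shape[0]):
        for d in range(3):
            v = vel[i, d] + half_dt * forces[i, d]
            pos[i, d] += half_dt * v
            v = c1 * v + c2 * noise[i, d]
            pos[i, d] += half_dt * v
            vel[i, d] = v


class _ForceEvaluator:
    """Cached neighbor list + kernel dispatch for one configuration topology."""

    SKIN = 0.3

    def __init__(self, config: BeadConfiguration, ff: ForceField):
        n = config.n
        self.ff = ff
        self.is_h = config.is_h.astype(np.uint8)
        self.q = config.charge.astype(np.float64)
        self.charged_idx = np.flatnonzero(config.charge != 0).astype(np.int64)
        self.bonds = (config.bonds if config.bonds is not None
                      else np.zeros((0, 2), dtype=np.int64))
        p1 = np.full(n, -1, dtype=np.int64)
        p2 = np.full(n, -1, dtype=np.int64)
        for i, j in self.bonds:
            if p1[i] < 0:
                p1[i] = j
            else:
                p2[i] = j
            if p1[j] < 0:
                p1[j] = i
            else:
                p2[j] = i
        self.p1, self.p2 = p1, p2
        self._cap = max(64 * n, 8192)
        self._pairs = None
        self._ref = None
        self._cutoff = None

    def _ensure_list(self, pos: np.ndarray, eps_hh: float) -> None:
        cutoff_yk = self.ff.r_cy + self.SKIN if eps_hh != 0.0 else 0.0
        cutoff_lj = self.ff.r_c + self.SKIN
        key = (cutoff_lj, cutoff_yk)
        if (
            self._pairs is not None
            and key == self._cutoff
            and _max_disp2(pos, self._ref) < (self.SKIN / 2) ** 2
        ):
            return
        while True:
            li, lj, kl, yi, yj, ky = kernels.build_dual_pair_list(
                pos, cutoff_lj, cutoff_yk, self.is_h, self.p1, self.p2,
                self._cap,
            )
            if kl >= 0:
                break
            self._cap *= 2
        self._pairs = (li, lj, kl, yi, yj, ky)
        self._ref = pos.copy()
        self._cutoff = key

    def forces(self, pos: np.ndarray, eps_hh: float) -> tuple:
        """Returns (forces, energies dict, max bond deviation, min pair r²)."""
        self._ensure_list(pos, eps_hh)
        li, lj, kl, yi, yj, ky = self._pairs
        f = np.zeros_like(pos)
        e_lj, min_r2 = kernels.wca_forces(pos, li, lj, kl, self.ff.eps_lj,
                                          self.ff.sigma, f)
        e_yk = 0.0
        if eps_hh != 0.0 and ky:
            e_yk = kernels.yukawa_forces(pos, yi, yj, ky, eps_hh,
                                         self.ff.sigma, f)
        e_sr = e_lj + e_yk
        e_bond, max_dev = kernels.bond_forces(pos, self.bonds, self.ff.K,
                                              self.ff.b, f)
        e_coul = 0.0
        if self.ff.l_b != 0.0 and len(self.charged_idx) > 1:
            e_coul = kernels.coulomb_forces(pos, self.q, self.charged_idx,
                                            self.ff.l_b, f)
        energies = {"bond": e_bond, "short_range": e_sr, "coulomb": e_coul}
        return f, energies, max_dev, min_r2


def compute_forces(state: SimState, ff: ForceField) -> np.ndarray:
    """Per-bead forces -∇E for the current state (functional API)."""
    ev = _ForceEvaluator(state.config, ff)
    f, _, _, min_r2 = ev.forces(state.config.positions, state.eps_hh)
    if min_r2 < 1e-16:
        raise HardCoreOverlapError(
            f"bead pair at distance {math.sqrt(min_r2):.2e}σ (< 1e-8σ)"
        )
    return f


def compute_energies(state: SimState, ff: ForceField) -> dict:
    """Potential-energy breakdown plus kinetic and total energy."""
    ev = _ForceEvaluator(state.config, ff)
    _, energies, _, _ = ev.forces(state.config.positions, state.eps_hh)
    energies = dict(energies)
    energies["kinetic"] = 0.5 * float(np.sum(state.velocities**2))
    energies["potential"] = energies["bond"] + energies["short_range"] + energies["coulomb"]
    energies["total"] = energies["potential"] + energies["kinetic"]
    return energies


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------

def _ou_coeffs(protocol: SimProtocol) -> tuple[float, float]:
    c1 = math.exp(-protocol.dt / protocol.tau)
    c2 = math.sqrt(protocol.kT * (1.0 - c1 * c1))
    return c1, c2


def step_langevin(state: SimState, ff: ForceField, protocol: SimProtocol,
                  evaluator: _ForceEvaluator | None = None,
                  forces: np.ndarray | None = None) -> SimState:
    """One BAOAB update (in place). Seeded noise stream from state.rng."""
    ev = evaluator or _ForceEvaluator(state.config, ff)
    pos, vel = state.config.positions, state.velocities
    if forces is None:
        forces = ev.forces(pos, state.eps_hh)[0]
    c1, c2 = _ou_coeffs(protocol)
    noise = state.rng.standard_normal(pos.shape)
    _baoab_drift(pos, vel, forces, 0.5 * protocol.dt, c1, c2, noise)
    f, _, _, _ = ev.forces(pos, state.eps_hh)
    vel += 0.5 * protocol.dt * f
    state.step += 1
    if not np.isfinite(pos).all():
        raise BlowUpError(f"non-finite coordinates at step {state.step}")
    return state


def step_nve(state: SimState, ff: ForceField, dt: float,
             evaluator: _ForceEvaluator | None = None,
             forces: np.ndarray | None = None) -> SimState:
    """Plain velocity-Verlet step (no thermostat), for energy-drift checks."""
    ev = evaluator or _ForceEvaluator(state.config, ff)
    pos, vel = state.config.positions, state.velocities
    if forces is None:
        forces = ev.forces(pos, state.eps_hh)[0]
    vel += 0.5 * dt * forces
    pos += dt * vel
    f, _, _, _ = ev.forces(pos, state.eps_hh)
    vel += 0.5 * dt * f
    state.step += 1
    return state


def run_langevin(state: SimState, ff: ForceField, protocol: SimProtocol,
                 n_steps: int, evaluator: _ForceEvaluator | None = None,
                 sample_every: int = 0, sampler=None,
                 check_every: int = 2000) -> list:
    """Drive ``n_steps`` BAOAB updates; optionally collect sampler(state).

    The hot loop keeps the Verlet list cached and raises BlowUpError (with
    the offending step) on non-finite coordinates or a bond stretched beyond
    the 5% hard sanity bound.
    """
    ev = evaluator or _ForceEvaluator(state.config, ff)
    pos, vel = state.config.positions, state.velocities
    c1, c2 = _ou_coeffs(protocol)
    half_dt = 0.5 * protocol.dt
    f, _, max_dev, _ = ev.forces(pos, state.eps_hh)
    samples = []
    for k in range(n_steps):
        noise = state.rng.standard_normal(pos.shape)
        _baoab_drift(pos, vel, f, half_dt, c1, c2, noise)
        f, _, max_dev, _ = ev.forces(pos, state.eps_hh)
        vel += half_dt * f
        state.step += 1
        if sample_every and (k + 1) % sample_every == 0 and sampler is not None:
            samples.append(sampler(state))
        if (k + 1) % check_every == 0:
            if not np.isfinite(pos).all():
                raise BlowUpError(f"non-finite coordinates at step {state.step}")
            if len(ev.bonds) and max_dev > 0.05:
                raise BlowUpError(
                    f"bond deviation {max_dev:.3f} exceeds 5% at step {state.step}"
                )
    return samples


# ---------------------------------------------------------------------------
# annealing protocol
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    frames: list                 # BeadConfiguration snapshots (meta tags stage)
    stages: list                 # per-stage summaries
    protocol: SimProtocol
    ff: ForceField

    def stage_frames(self, eps_hh: float, phase: str = "production") -> list:
        return [f for f in self.frames
                if f.meta.get("eps_hh") == eps_hh and f.meta.get("phase") == phase]

    def production_half(self, eps_hh: float) -> list:
        """Second half of the production snapshots of one stage."""
        frames = self.stage_frames(eps_hh)
        return frames[len(frames) // 2:]


def _snapshot(state: SimState, phase: str, stage: int) -> BeadConfiguration:
    snap = state.config.copy()
    snap.meta.update(eps_hh=state.eps_hh, step=state.step, phase=phase,
                     stage=stage)
    return snap


def run_protocol(protocol: SimProtocol, ff: ForceField, log=None,
                 checkpoint_path=None) -> Trajectory:
    """Relaxation at ε_HH = 0, then the full annealing schedule.

    Snapshots are written every ``snapshot_stride`` steps during each
    production run (plus the final configuration of every stage); stage
    summaries carry the mean kinetic temperature of the production run.
    Fully reproducible for a fixed protocol + seed.  If ``checkpoint_path``
    is given, the last configuration is written there before a step error
    (blow-up, overlap) propagates.
    """
    state = make_initial_state(protocol, ff)
    ev = _ForceEvaluator(state.config, ff)
    frames: list = []
    stages: list = []

    def _stage(eps: float, equil: int, prod: int, idx: int) -> None:
        state.eps_hh = eps
        if equil:
            run_langevin(state, ff, protocol, equil, evaluator=ev)
        ke_acc: list = []

        def _sampler(st: SimState) -> None:
            frames.append(_snapshot(st, "production", idx))
            ke_acc.append(0.5 * float(np.sum(st.velocities**2)))

        if prod:
            stride = max(1, min(protocol.snapshot_stride, prod))
            run_langevin(state, ff, protocol, prod, evaluator=ev,
                         sample_every=stride, sampler=_sampler)
        if not frames or frames[-1].meta.get("step") != state.step:
            frames.append(_snapshot(state, "production" if prod else "relax", idx))
        temp = (np.mean(ke_acc) / (1.5 * state.config.n)) if ke_acc else float("nan")
        stages.append({"stage": idx, "eps_hh": eps, "kinetic_T": float(temp),
                       "step": state.step})
        if log is not None:
            log(stages[-1])

    try:
        _stage(0.0, protocol.relax_steps, 0, 0)
        for i, eps in enumerate(protocol.eps_schedule, start=1):
            _stage(float(eps), protocol.equil_steps, protocol.prod_steps, i)
    except Exception:
        if checkpoint_path is not None:
            from .io import write_snapshot

            write_snapshot(_snapshot(state, "checkpoint", -1), checkpoint_path)
        raise
    return Trajectory(frames, stages, protocol, ff)
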