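"""Langevin simulator: forces, integrators, thermostat, protocol."""

import numpy as np
import pytest

from ipec.forcefield import ForceField
from ipec.simulator import (BlowUpError, HardCoreOverlapError, SimProtocol,
                            SimState, compute_energies, compute_forces,
                            default_eps_schedule, make_initial_state,
                            run_langevin, run_protocol, step_langevin,
                            step_nve)
from ipec.types import BeadConfiguration


def _state(pos, chain, charge, bonds=None, vel=None, eps_hh=0.0, seed=0):
    cfg = BeadConfiguration(np.asarray(pos, float), chain,
                            np.asarray(charge, dtype=np.int8), bonds=bonds)
    v = np.zeros_like(cfg.positions) if vel is None else vel
    return SimState(cfg, v, eps_hh, 0, np.random.default_rng(seed))


def _random_bonded_state(rng, n=20, eps_hh=-1.0):
    """Two 10-bead chains, alternating charges, no hard overlaps."""
    pos = np.zeros((n, 3))
    pos[0] = rng.uniform(0, 1, 3)
    for i in range(1, n):
        if i == n // 2:
            pos[i] = pos[0] + [1.3, 0.4, 0.0]
            continue
        while True:
            step = rng.normal(size=3)
            cand = pos[i - 1] + step / np.linalg.norm(step)
            if np.min(np.linalg.norm(pos[:i] - cand, axis=1)) > 0.9:
                pos[i] = cand
                break
    half = n // 2
    chain = np.array(["H"] * half + ["P"] * half)
    charge = np.zeros(n, dtype=np.int8)
    charge[0:half:2] = 1
    charge[half::2] = -1
    seq = np.arange(half - 1)
    bonds = np.concatenate([np.column_stack([seq, seq + 1]),
                            np.column_stack([seq + half, seq + half + 1])])
    return _state(pos, chain, charge, bonds=bonds, eps_hh=eps_hh)


def test_isolated_uncharged_beads_feel_no_force():
    st = _state([[0, 0, 0], [10, 0, 0]], np.array(["H", "P"]), [0, 0])
    f = compute_forces(st, ForceField(l_b=1.0))
    assert np.allclose(f, 0.0)


def test_pair_forces_conserve_momentum(rng):
    st = _random_bonded_state(rng)
    f = compute_forces(st, ForceField(l_b=2.0, eps_hh=-1.0))
    assert np.allclose(f.sum(axis=0), 0.0, atol=1e-8)


def test_forces_match_finite_differences(rng):
    """Central finite differences of the total energy reproduce every force
    component (bond + WCA + Yukawa + Coulomb together)."""
    ff = ForceField(l_b=2.0, eps_hh=-1.0)
    st = _random_bonded_state(rng)
    f = compute_forces(st, ff)
    h = 1e-6
    scale = np.abs(f).max()
    for i in range(st.config.n):
        for d in range(3):
            for sgn, store in ((1, "up"), (-1, "dn")):
                st.config.positions[i, d] += sgn * h
                e = compute_energies(st, ff)["potential"]
                st.config.positions[i, d] -= sgn * h
                if store == "up":
                    e_up = e
                else:
                    e_dn = e
            fd = -(e_up - e_dn) / (2 * h)
            assert abs(fd - f[i, d]) < 1e-5 * max(scale, 1.0)


def test_hard_core_overlap_detected():
    st = _state([[0, 0, 0], [1e-9, 0, 0]], np.array(["H", "H"]), [0, 0])
    with pytest.raises(HardCoreOverlapError):
        compute_forces(st, ForceField())


def test_zero_temperature_equilibrium_is_fixed_point():
    st = _state([[0, 0, 0], [1.0, 0, 0]], np.array(["H", "P"]), [0, 0],
                bonds=np.array([[0, 1]]))
    proto = SimProtocol(N=2, kT=0.0, relax_steps=0, eps_schedule=())
    before = st.config.positions.copy()
    step_langevin(st, ForceField(l_b=0.0), proto)
    assert np.allclose(st.config.positions, before, atol=1e-14)
    assert np.allclose(st.velocities, 0.0)


def test_nve_energy_drift_small():
    """Velocity Verlet with the thermostat off: relative energy error < 1e-3
    over 1e4 steps in the dt <= 1e-3 regime (symplectic sanity; the K = 10⁴
    bond sets the fast time scale ω = 200)."""
    from ipec.simulator import _ForceEvaluator

    rng = np.random.default_rng(3)
    st = _random_bonded_state(rng)
    ff = ForceField(l_b=1.0, eps_hh=-0.5)
    st.velocities = rng.normal(0, 0.5, st.velocities.shape)
    ev = _ForceEvaluator(st.config, ff)
    e0 = compute_energies(st, ff)["total"]
    worst = 0.0
    for _ in range(10):
        for _ in range(1_000):
            step_nve(st, ff, dt=5e-4, evaluator=ev)
        worst = max(worst, abs(compute_energies(st, ff)["total"] - e0))
    assert worst / abs(e0) < 1e-3


def test_equipartition_of_thermostatted_gas():
    """Time-averaged kinetic energy per bead -> (3/2) kT within 2%."""
    n = 32
    rng = np.random.default_rng(5)
    pos = rng.uniform(0, 40, (n, 3))
    st = _state(pos, np.full(n, "H"), np.zeros(n, int), seed=11)
    # strong coupling so the velocity distribution decorrelates quickly
    proto = SimProtocol(N=2, relax_steps=0, eps_schedule=(),
                        damping_convention="steps")
    ff = ForceField(l_b=0.0)
    run_langevin(st, ff, proto, 2_000)
    samples = run_langevin(st, ff, proto, 100_000, sample_every=20,
                           sampler=lambda s: float(np.sum(s.velocities**2)))
    ke_per_bead = 0.5 * np.mean(samples) / n
    assert ke_per_bead == pytest.approx(1.5, rel=0.02)


def test_bond_sanity_bound_enforced():
    st = _state([[0, 0, 0], [1.2, 0, 0]], np.array(["H", "P"]), [0, 0],
                bonds=np.array([[0, 1]]))
    proto = SimProtocol(N=2, kT=0.0, relax_steps=0, eps_schedule=())
    with pytest.raises(BlowUpError, match="step"):
        run_langevin(st, ForceField(l_b=0.0), proto, 1, check_every=1)


def test_protocol_validation():
    with pytest.raises(ValueError):
        SimProtocol(N=3)  # odd
    with pytest.raises(ValueError):
        SimProtocol(eps_schedule=(-0.5, -0.1))  # increasing
    with pytest.raises(NotImplementedError):
        SimProtocol(electrostatics_mode="ewald")
    assert default_eps_schedule(-0.3, -0.1) == (-0.1, -0.2, -0.3)


def test_initial_state_layout():
    proto = SimProtocol(N=64, seed=9, relax_steps=0, eps_schedule=())
    st = make_initial_state(proto, ForceField())
    cfg = st.config
    assert cfg.n == 128
    assert (cfg.chain[:64] == "H").all() and (cfg.chain[64:] == "P").all()
    assert (cfg.charge == 1).sum() == 32 and (cfg.charge == -1).sum() == 32
    assert cfg.charge.sum() == 0
    lens = np.linalg.norm(
        cfg.positions[cfg.bonds[:, 0]] - cfg.positions[cfg.bonds[:, 1]], axis=1)
    assert np.allclose(lens, 1.0, atol=1e-9)


def test_relaxation_only_trajectory():
    proto = SimProtocol(N=16, relax_steps=200, eps_schedule=(), seed=1)
    traj = run_protocol(proto, ForceField(l_b=0.5))
    assert len(traj.frames) == 1
    assert traj.frames[0].meta["phase"] == "relax"
    assert traj.stages[0]["eps_hh"] == 0.0


def test_protocol_determinism():
    proto = SimProtocol(N=16, relax_steps=150, equil_steps=100, prod_steps=100,
                        snapshot_stride=50, seed=4,
                        eps_schedule=(-0.5, -1.0))
    ff = ForceField(l_b=0.5)
    t1 = run_protocol(proto, ff)
    t2 = run_protocol(proto, ff)
    assert len(t1.frames) == len(t2.frames)
    for a, b in zip(t1.frames, t2.frames):
        assert np.array_equal(a.positions, b.positions)
        assert a.meta["eps_hh"] == b.meta["eps_hh"]
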