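"""Spherical-harmonics order parameters Q_l and symmetry labelling."""

import math

import numpy as np
import pytest

from conftest import random_rotation
from ipec.structures import ShapeSpec, make_perforated_shell, make_shell
from ipec.symmetry import (angular_histogram, order_parameters,
                           order_parameters_from_histogram,
                           order_parameters_pair_sum, symmetry_label)
from ipec.types import BeadConfiguration


def _h_config(points):
    n = len(points)
    return BeadConfiguration(np.asarray(points, float),
                             np.full(n, "H", dtype="<U1"),
                             np.zeros(n, dtype=np.int8))


TETRAHEDRON = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / math.sqrt(3)

_g = (1 + math.sqrt(5)) / 2
ICOSAHEDRON = np.array(
    [[0, s1, s2 * _g] for s1 in (1, -1) for s2 in (1, -1)]
    + [[s1, s2 * _g, 0] for s1 in (1, -1) for s2 in (1, -1)]
    + [[s1 * _g, 0, s2] for s1 in (1, -1) for s2 in (1, -1)], dtype=float)
ICOSAHEDRON /= np.linalg.norm(ICOSAHEDRON, axis=1, keepdims=True)


def test_q0_equals_n(rng):
    cfg = _h_config(rng.normal(size=(57, 3)) + 5)
    spec = order_parameters(cfg, center=np.array([5.0, 5.0, 5.0]))
    assert spec.q[0] == pytest.approx(57, rel=1e-12)


def test_tetrahedron_closed_form():
    # Q_3 = (4 P_3(1) + 12 P_3(-1/3)) / 4 = (4 + 12·11/27)/4 = 20/9
    spec = order_parameters(_h_config(TETRAHEDRON), center=np.zeros(3))
    assert spec.q[3] == pytest.approx(20 / 9, abs=1e-10)
    assert spec.q[2] == pytest.approx(0.0, abs=1e-10)


def test_tetrahedron_nonzero_ranking():
    """The tetrahedral selection rules: Q2 = Q5 = 0 and the characteristic
    magnitude ordering Q3 > Q10 > Q7 > Q9 > Q4 among the nonzero values
    (the full exact spectrum also carries Q6 between Q10 and Q7, and a
    small Q8)."""
    q = order_parameters(_h_config(TETRAHEDRON), center=np.zeros(3)).q
    assert q[2] < 1e-10 and q[5] < 1e-10
    assert q[3] > q[10] > q[7] > q[9] > q[4] > 1e-8
    assert q[6] > 1e-8  # allowed by tetrahedral symmetry as well


def test_icosahedron_selection_rules():
    spec = order_parameters(_h_config(ICOSAHEDRON), center=np.zeros(3))
    assert spec.q[4] < 1e-8 and spec.q[8] < 1e-8
    assert spec.q[6] > 0.5 and spec.q[10] > 0.5


def test_dual_form_equivalence_random_configs(rng):
    for _ in range(15):
        n = int(rng.integers(5, 60))
        cfg = _h_config(rng.normal(size=(n, 3)))
        a = order_parameters(cfg).q
        b = order_parameters_pair_sum(cfg).q
        assert np.allclose(a, b, atol=1e-8)


def test_rotation_invariance(rng):
    cfg = _h_config(rng.normal(size=(40, 3)))
    base = order_parameters(cfg, center=np.zeros(3)).q
    for seed in (1, 2, 3):
        R = random_rotation(seed)
        rot = _h_config(cfg.positions @ R.T)
        q = order_parameters(rot, center=np.zeros(3)).q
        assert np.allclose(base, q, atol=1e-8)


def test_angular_histogram_basics():
    # all beads on +z axis -> single nonzero bin at theta-bin 0
    pts = np.column_stack([np.zeros(20), np.zeros(20), np.arange(1, 21)])
    hist = angular_histogram(_h_config(pts), center=np.zeros(3))
    assert hist.counts.sum() == 20
    assert hist.counts[0].sum() == 20
    nz_theta, _ = np.nonzero(hist.counts)
    assert set(nz_theta) == {0}


def test_angular_histogram_solid_angle_oracle():
    cfg = make_shell(ShapeSpec(kind="shell", n=20000, radius=10.0, seed=1))
    hist = angular_histogram(cfg, center=np.zeros(3))
    per_theta = hist.counts.sum(axis=1).astype(float)
    dcos = -np.diff(np.cos(hist.theta_edges))
    expected = 20000 * dcos / 2.0
    assert np.all(np.abs(per_theta - expected) < 5 * np.sqrt(expected) + 5)


def test_angular_histogram_center_bead_policy():
    pts = np.vstack([np.zeros(3), np.eye(3)])
    cfg = _h_config(pts)
    with pytest.raises(ValueError):
        angular_histogram(cfg, center=np.zeros(3), on_center="error")
    with pytest.warns(UserWarning):
        hist = angular_histogram(cfg, center=np.zeros(3), on_center="drop")
    assert hist.counts.sum() == 3


def test_binned_spectrum_close_to_exact_on_smooth_shell():
    cfg = make_shell(ShapeSpec(kind="shell", n=4000, radius=10.0, seed=2))
    exact = order_parameters(cfg, center=np.zeros(3))
    binned = order_parameters_from_histogram(
        angular_histogram(cfg, center=np.zeros(3)))
    # π/18 discretization: low-l structure agrees within a few counts
    assert binned.q[0] == pytest.approx(exact.q[0], rel=1e-12)
    assert np.all(np.abs(binned.q[1:7] - exact.q[1:7]) < 2.0)


def test_three_pore_shell_dominated_by_q3():
    dirs = np.array([[1, 0, 0], [-0.5, math.sqrt(3) / 2, 0],
                     [-0.5, -math.sqrt(3) / 2, 0]])
    cfg = make_perforated_shell(
        ShapeSpec(kind="perforated_shell", n=3000, radius=10.0,
                  pore_directions=dirs, pore_angular_radius=0.45)
    )
    spec = order_parameters(cfg, center=np.zeros(3))
    oracle = order_parameters_pair_sum(cfg, center=np.zeros(3))
    assert np.allclose(spec.q, oracle.q, atol=1e-8)
    assert np.argmax(spec.q[1:]) + 1 == 3
    lab = symmetry_label(spec)
    assert lab["label"] == "trigonal"


def test_symmetry_label_isotropic_shell():
    cfg = make_shell(ShapeSpec(kind="shell", n=3000, radius=10.0, seed=5))
    lab = symmetry_label(order_parameters(cfg, center=np.zeros(3)))
    assert lab["label"] == "isotropic"
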