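"""Shape factors, clusters, radial profiles, cavity detection, ion pairs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import rotated
from ipec.observables import (detect_cavity, ion_pair_fraction, max_cluster,
                              radial_profiles, shape_factors)
from ipec.structures import ShapeSpec, make_geometry, make_onion
from ipec.types import BeadConfiguration


def _config(points, chain=None, charge=None):
    n = len(points)
    chain = np.full(n, "H", dtype="<U1") if chain is None else chain
    charge = np.zeros(n, dtype=np.int8) if charge is None else charge
    return BeadConfiguration(np.asarray(points, float), chain, charge)


# -- shape factors ----------------------------------------------------------

def test_shape_factors_rotation_translation_permutation_invariant(rng):
    pts = rng.normal(size=(300, 3)) * [3.0, 1.5, 0.7]
    cfg = _config(pts)
    base = shape_factors(cfg)
    rot = shape_factors(rotated(cfg, seed=11))
    assert base.k1 == pytest.approx(rot.k1, abs=1e-10)
    assert base.k2 == pytest.approx(rot.k2, abs=1e-10)
    perm = shape_factors(_config(pts[rng.permutation(len(pts))]))
    assert base.k1 == pytest.approx(perm.k1, abs=1e-10)


def test_shape_factors_ordering_and_bounds(rng):
    s = shape_factors(_config(rng.normal(size=(50, 3))))
    assert 0 <= s.g1 <= s.g2 <= s.g3
    assert 0 <= s.k1 <= s.k2 <= 1


def test_shape_factors_degenerate_inputs():
    with pytest.raises(ValueError):
        shape_factors(np.zeros((1, 3)))
    with pytest.raises(ValueError):
        shape_factors(np.zeros((5, 3)))  # all coincident


# -- max cluster ------------------------------------------------------------

def _brute_force_components(pts, cutoff):
    """Independent O(n²) union-find oracle."""
    n = len(pts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pts[i] - pts[j]) <= cutoff:
                parent[find(i)] = find(j)
    sizes = {}
    for i in range(n):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    return sorted(sizes.values(), reverse=True)


def test_max_cluster_chain_examples():
    pts = [[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]
    cfg = _config(pts)
    assert max_cluster(cfg, selection="H0").m_max == 3
    pts = [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]]
    assert max_cluster(_config(pts), selection="H0").m_max == 1  # 1.5 > 1.4


def test_max_cluster_matches_brute_force_oracle(rng):
    pts = rng.uniform(0, 10, size=(200, 3))
    res = max_cluster(_config(pts), cutoff=1.4, selection="H0")
    oracle = _brute_force_components(pts, 1.4)
    assert list(res.sizes) == oracle
    assert res.normalized == oracle[0] / 200


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10_000))
def test_max_cluster_monotone_in_cutoff(seed):
    pts = np.random.default_rng(seed).uniform(0, 6, size=(60, 3))
    cfg = _config(pts)
    sizes = [max_cluster(cfg, cutoff=c, selection="H0").m_max
             for c in (0.05, 0.8, 1.4, 3.0, 100.0)]
    assert sizes == sorted(sizes)
    assert sizes[0] == 1 and sizes[-1] == 60


def test_max_cluster_empty_selection_errors():
    cfg = _config(np.zeros((3, 3)) + np.arange(3)[:, None])
    with pytest.raises(ValueError):
        max_cluster(cfg, selection="P0")


# -- radial profiles and cavity ---------------------------------------------

def test_radial_profile_uniform_ball_flat_then_zero():
    cfg = make_geometry(ShapeSpec(kind="filled_sphere", n=8000, radius=10.0))
    prof = radial_profiles(cfg, n_bins=20, r_max=14.0)
    total = prof.total_density
    inner = total[(prof.r > 2) & (prof.r < 8)]
    assert inner.std() / inner.mean() < 0.2
    assert np.all(total[prof.r > 11] == 0)


def test_radial_profile_counts_conserved():
    cfg = make_geometry(ShapeSpec(kind="vesicle", n=3000))
    prof = radial_profiles(cfg, n_bins=25)
    assert sum(c.sum() for c in prof.counts.values()) == cfg.n


def test_vesicle_profile_hollow_with_bracketing_p_peaks():
    cfg = make_geometry(ShapeSpec(kind="vesicle", n=4000, inner_radius=6.0,
                                  thickness=3.0))
    prof = radial_profiles(cfg, n_bins=24)
    res = detect_cavity(prof)
    assert res["hollow"]
    assert res["cavity_radius"] == pytest.approx(6.0, abs=1.5)
    hd = prof.density["H+"] + prof.density["H0"]
    pd_ = prof.density["P-"] + prof.density["P0"]
    i_h = np.argmax(hd)
    p_peaks = np.flatnonzero(pd_ > 0.5 * pd_.max())
    assert p_peaks.min() < i_h < p_peaks.max()


def test_filled_and_onion_not_hollow():
    ball = make_geometry(ShapeSpec(kind="filled_sphere", n=4000, radius=9.0))
    assert not detect_cavity(radial_profiles(ball, n_bins=18))["hollow"]
    onion = make_onion(seed=0)
    assert not detect_cavity(radial_profiles(onion, n_bins=18))["hollow"]


# -- ion pairs ---------------------------------------------------------------

def _charged_pair(r):
    return BeadConfiguration(
        np.array([[0.0, 0, 0], [r, 0, 0]]),
        np.array(["H", "P"]),
        np.array([1, -1], dtype=np.int8),
    )


def test_ion_pair_toy_examples():
    assert ion_pair_fraction(_charged_pair(1.0)).psi_b == 1.0
    assert ion_pair_fraction(_charged_pair(1.6)).psi_b == 0.0  # beyond 1.5 b


def test_ion_pair_matches_brute_force(rng):
    n = 300
    pts = rng.uniform(0, 8, size=(n, 3))
    chain = np.where(np.arange(n) % 2 == 0, "H", "P").astype("<U1")
    charge = np.where(np.arange(n) % 2 == 0, 1, -1).astype(np.int8)
    charge[rng.random(n) < 0.3] = 0
    charge[(chain == "H") & (charge == -1)] = 0
    cfg = BeadConfiguration(pts, chain, charge)
    res = ion_pair_fraction(cfg, r_b=1.5)
    # brute force: all opposite-sign pairs
    plus, minus = pts[charge == 1], pts[charge == -1]
    d = np.linalg.norm(plus[:, None] - minus[None], axis=2)
    engaged = (d <= 1.5).any(axis=1).sum() + (d <= 1.5).any(axis=0).sum()
    assert res.n_engaged == engaged
    assert res.psi_b == engaged / (len(plus) + len(minus))
    assert res.n_contacts == int((d <= 1.5).sum())


def test_ion_pair_monotone_in_cutoff(rng):
    pts = rng.uniform(0, 6, size=(100, 3))
    chain = np.where(np.arange(100) % 2 == 0, "H", "P").astype("<U1")
    charge = np.where(np.arange(100) % 2 == 0, 1, -1).astype(np.int8)
    cfg = BeadConfiguration(pts, chain, charge)
    psis = [ion_pair_fraction(cfg, r_b=r).psi_b for r in (0.5, 1.0, 1.5, 2.5)]
    assert psis == sorted(psis)


def test_ion_pair_requires_both_signs():
    cfg = _config(np.random.default_rng(0).uniform(0, 3, (10, 3)))
    with pytest.raises(ValueError):
        ion_pair_fraction(cfg)
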