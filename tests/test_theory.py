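"""Analytical core-shell / vesicle free energies and the transition line."""

import math
from dataclasses import replace

import pytest

from ipec.theory import (InfeasibleGeometryError, TheoryParams,
                         free_energy_core_shell, free_energy_vesicle,
                         minimize_structure, transition_bjerrum,
                         transition_line, _cavity_term)

BASE = TheoryParams(N=1.0e4, f=0.5, l_b=1.0, chi=6.0, B=4.0)


def test_kappa_definition():
    p = TheoryParams(f=0.5, l_b=2.0, B=4.0)
    assert p.kappa == pytest.approx(math.sqrt(4 * math.pi * 0.25 * 2.0 / 4.0))


def test_only_mixing_survives_without_chi_and_electrostatics():
    p = replace(BASE, chi=0.0, l_b=0.0)
    s = free_energy_core_shell(p, D=2.0 * 13.4)
    assert s.terms["surface"] == 0.0
    assert s.terms["self_energy"] == 0.0
    assert s.terms["adsorption"] == 0.0
    assert s.terms["volume"] != 0.0
    assert s.f_total == pytest.approx(s.terms["volume"])


def test_unscreened_adsorption_limit():
    # the printed form times (1 + κD) equals the bare -l_B f² N² / (2D)
    D = 20.0
    s = free_energy_core_shell(BASE, D)
    bare = -0.5 * BASE.l_b * BASE.f**2 * BASE.N**2 / D
    assert s.terms["adsorption"] * (1 + BASE.kappa * D) == pytest.approx(bare)


def test_term_signs_and_breakdown_sums():
    for D in (14.0, 20.0, 40.0):
        s = free_energy_core_shell(BASE, D)
        assert s.terms["surface"] >= 0
        assert s.terms["self_energy"] >= 0
        assert s.terms["adsorption"] <= 0
        assert math.isfinite(s.terms["volume"])
        assert s.f_total == pytest.approx(sum(s.terms.values()))
    v = free_energy_vesicle(BASE, R=10.0, D=6.0)
    assert v.terms["surface"] >= 0 and v.terms["self_energy"] >= 0
    assert v.terms["adsorption"] <= 0


def test_vesicle_reduces_to_core_shell_as_cavity_vanishes():
    D = 15.0
    cs = free_energy_core_shell(BASE, D)
    ves = free_energy_vesicle(BASE, R=1e-9, D=D)
    # self-energy: the spherical-layer form's R->0 limit IS the ball form
    assert ves.terms["self_energy"] / cs.terms["self_energy"] == pytest.approx(1.0, rel=1e-6)
    assert ves.terms["adsorption"] == pytest.approx(cs.terms["adsorption"], rel=1e-6)
    assert ves.terms["volume"] == pytest.approx(cs.terms["volume"], rel=1e-6)
    # the printed two-surface term keeps both boundaries: factor 2 residue
    assert ves.terms["surface"] / cs.terms["surface"] == pytest.approx(2.0, rel=1e-6)


def test_cavity_term_flat_interface_asymptotics():
    # printed sinh/cosh expression approaches 2/(x(x-1)) for large κR
    kappa, lf2n2, y = 0.9, 1.0e6, 0.3
    x = 25.0
    exact = _cavity_term(kappa, lf2n2, y, x / kappa)
    asym = -0.25 * kappa * lf2n2 * y**2 * 2.0 / (x * (x - 1.0))
    assert exact == pytest.approx(asym, rel=0.01)
    assert exact < 0


def test_y_factor_zeroes_outer_attraction_structure():
    # (1-y)² multiplies both outer-surface terms
    R, D = 12.0, 4.6
    v_lo = free_energy_vesicle(BASE, R=R, D=D)
    assert 0 < v_lo.y < 1
    outer = -0.5 * BASE.l_b * BASE.f**2 * BASE.N**2 * (1 - v_lo.y) ** 2 / (
        (R + D) * (1 + BASE.kappa * (R + D)))
    cavity = _cavity_term(BASE.kappa, BASE.l_b * BASE.f**2 * BASE.N**2,
                          v_lo.y, R)
    assert v_lo.terms["adsorption"] == pytest.approx(outer + cavity)


def test_infeasible_geometry_raises():
    with pytest.raises(InfeasibleGeometryError):
        free_energy_core_shell(BASE, D=1.0)  # phi_H >> 1
    with pytest.raises(InfeasibleGeometryError):
        free_energy_vesicle(BASE, R=5.0, D=0.5)


def test_minimizer_first_order_condition_in_stability_region():
    """Near the transition both branches have interior dense minima; the
    core-shell minimizer is stationary and locally convex there."""
    p = TheoryParams(N=1024, l_b=0.6)
    s = minimize_structure(p, "core_shell")
    assert not s.diagnostics["at_bound"]
    d = s.D

    def f(x):
        return free_energy_core_shell(p, x).f_total

    h = 1e-6 * d
    grad = (f(d + h) - f(d - h)) / (2 * h)
    curv = (f(d + h) - 2 * f(d) + f(d - h)) / h**2
    scale = abs(f(d)) / d
    assert abs(grad) < 1e-3 * scale
    assert curv > 0


def test_core_shell_unstable_branch_flagged():
    """Far beyond the transition F(D) decreases toward dissolution and the
    bounded scan reports a boundary minimum."""
    s = minimize_structure(BASE, "core_shell")  # N = 1e4, l_B = 1
    assert s.diagnostics["at_bound"]


def test_structure_preference_small_vs_large_coupling():
    weak = TheoryParams(N=512, l_b=0.3)
    strong = TheoryParams(N=1.0e4, l_b=2.0)
    assert (minimize_structure(weak, "core_shell").f_total
            < minimize_structure(weak, "vesicle").f_total)
    assert (minimize_structure(strong, "vesicle").f_total
            < minimize_structure(strong, "core_shell").f_total)


def test_transition_line_shape_and_cavity_growth():
    rows = transition_line(TheoryParams(), [512, 1024, 2048])
    lbs = [r["l_b"] for r in rows]
    assert lbs == sorted(lbs, reverse=True)  # l_B*(N) strictly decreasing
    cav = [r["cavity_diameter"] for r in rows]
    assert cav == sorted(cav)                # 2R grows along the line
    assert all(c >= 5.0 for c in cav)        # larger than the monomer size


def test_transition_shifts_with_f_and_B():
    base = transition_bjerrum(TheoryParams(N=1024))["l_b"]
    lower_f = transition_bjerrum(TheoryParams(N=1024, f=0.45))["l_b"]
    lower_B = transition_bjerrum(TheoryParams(N=1024, B=3.0))["l_b"]
    assert lower_f > base   # weaker ionization -> core-shell region grows
    assert lower_B < base   # larger B pushes the line to higher N, l_B


def test_no_transition_reported_as_nan():
    rows = transition_line(TheoryParams(), [1.0e6])
    assert math.isnan(rows[0]["l_b"])
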