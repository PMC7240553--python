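"""Analytical free energy of the core-shell and vesicle structures.

The hydrophobic polycation (N beads, ionization degree f, monomer volume
υ_H, size a_H) collapses into a dense region — a filled ball of radius D
(core-shell) or a spherical layer of thickness D around a cavity of radius
R (vesicle) — and the hydrophilic polyanion adsorbs onto its surface(s).
Lengths are measured in a, volumes in υ, energies in k_BT; the defaults
υ_H/υ_S = 1, υ_H/a_H³ = 1, χ = 6 describe a very poor solvent for the
polycation and equal monomer/solvent volumes.

Free-energy terms (total, not per monomer):

* Flory-Huggins mixing in the dense region,
  F_vol = N χ (1-φ_H) + n_s ln(1-φ_H), with n_s = N (υ_H/υ_S)(1-φ_H)/φ_H
  solvent molecules inside and φ_H the polycation volume fraction fixed by
  the geometry;
* surface energy F_surf = (a_H/υ_H) χ φ_H² S over the hydrophobic
  surface(s) (for the vesicle the printed form uses S = 4π((R+D)² + D²));
* electrostatic self-energy W of the dense region,
  W = (1/10) l_B f² N² / D for the ball, and for the spherical layer
  W = (1/2) l_B f² N² (1-y)² (D³R³/(R+D) + 2D³R² + D⁴R + D⁵/5)
      / (3R²D + 3RD² + D³)²,
  whose R → 0, y → 0 limit reproduces the ball expression exactly;
* the screened electrostatic attraction of the adsorbed polyanion, combined
  with its excluded-volume penalty (second virial coefficient B >> υ_P):
  for the ball  F_el+exc = -(1/2) l_B f² N² / (D (1 + κD)), and for the
  vesicle the outer-surface term -(1/2) l_B f² N² (1-y)² / ((R+D)(1+κ(R+D)))
  plus the cavity term
  -(κ l_B f² N² y²/4) (sinh 2κR - (cosh 2κR - 1)/κR)
                       / (κR cosh κR - sinh κR)²,
  where κ = sqrt(4π f² l_B / B) is the inverse screening length of the
  adsorbed layer and y the fraction of polycation surface units facing the
  cavity, y = φ_H S_in a_H / (N υ_H).

Minimizing F over D (core-shell) or (R, D) (vesicle) and comparing the
minima yields the core-shell/vesicle transition line in the (N, l_B) plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

__all__ = [
    "TheoryParams",
    "StructureEnergy",
    "free_energy_core_shell",
    "free_energy_vesicle",
    "minimize_structure",
    "transition_line",
    "transition_bjerrum",
    "InfeasibleGeometryError",
]


class InfeasibleGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class TheoryParams:
    """Dimensionless theory inputs (lengths in a, volumes in υ, energy kT)."""

    N: float = 1.0e4
    f: float = 0.5
    l_b: float = 1.0
    chi: float = 6.0
    B: float = 4.0            # second virial coefficient, units of υ_P
    v_h_over_v_s: float = 1.0
    v_h_over_a3: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1:
            raise ValueError("ionization degree f must lie in (0, 1]")
        for name in ("N", "B", "v_h_over_v_s", "v_h_over_a3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.l_b < 0 or self.chi < 0:
            raise ValueError("l_b and chi must be >= 0")

    @property
    def kappa(self) -> float:
        """Inverse screening length of the adsorbed polyanion layer."""
        return math.sqrt(4 * math.pi * self.f**2 * self.l_b / self.B)

    @property
    def v(self) -> float:
        """Monomer volume in units of a³."""
        return self.v_h_over_a3


@dataclass(frozen=True)
class StructureEnergy:
    structure: str            # 'core_shell' | 'vesicle'
    D: float                  # ball radius or layer thickness, units of a
    R: float                  # cavity radius (0 for core_shell)
    y: float                  # polycation surface fraction on the cavity side
    phi_h: float
    f_total: float
    terms: dict               # breakdown: volume, surface, self_energy, adsorption
    diagnostics: dict = None  # minimizers attach convergence info here

    def __post_init__(self) -> None:
        assert abs(sum(self.terms.values()) - self.f_total) < 1e-6 * max(
            1.0, abs(self.f_total)
        )


def _flory(params: TheoryParams, phi: float) -> float:
    n_s = params.N * params.v_h_over_v_s * (1.0 - phi) / phi
    mix = n_s * math.log1p(-phi) if phi < 1.0 else 0.0
    return params.N * params.chi * (1.0 - phi) + mix


def free_energy_core_shell(params: TheoryParams, D: float) -> StructureEnergy:
    """Total free energy of the dense ball of radius D with adsorbed shell."""
    if D <= 0:
        raise InfeasibleGeometryError("D must be positive")
    vol = 4.0 * math.pi / 3.0 * D**3
    phi = params.N * params.v / vol
    if phi > 1.0 + 1e-12:
        raise InfeasibleGeometryError(f"phi_H = {phi:.3f} > 1 at D = {D:.3f}")
    phi = min(phi, 1.0)
    lf2n2 = params.l_b * params.f**2 * params.N**2
    terms = {
        "volume": _flory(params, phi),
        "self_energy": 0.1 * lf2n2 / D,
        # a_H/υ_H = 1/υ with lengths in units of a
        "surface": 4.0 * math.pi * D**2 * (1.0 / params.v) * params.chi * phi**2,
        "adsorption": -0.5 * lf2n2 / (D * (1.0 + params.kappa * D)),
    }
    return StructureEnergy("core_shell", D, 0.0, 0.0, phi,
                           sum(terms.values()), terms)


def _cavity_term(kappa: float, lf2n2: float, y: float, R: float) -> float:
    """Screened attraction of the polyanion trapped in the cavity."""
    x = kappa * R
    if y == 0.0 or x == 0.0:
        return 0.0
    if x < 1e-3:
        # series: (sinh 2x - (cosh 2x - 1)/x) / (x cosh x - sinh x)² ≈ (2x³/3)/(x³/3)²
        ratio = 6.0 / x**3
    elif x > 30.0:
        # flat-interface limit: numerator → e^{2x}(1-1/x)/2, denom → (x-1)² e^{2x}/4
        ratio = 2.0 / (x * (x - 1.0))
    else:
        denom = (x * math.cosh(x) - math.sinh(x)) ** 2
        ratio = (math.sinh(2 * x) - (math.cosh(2 * x) - 1.0) / x) / denom
    return -0.25 * kappa * lf2n2 * y**2 * ratio


def free_energy_vesicle(params: TheoryParams, R: float, D: float) -> StructureEnergy:
    """Total free energy of the spherical layer (cavity R, thickness D)."""
    if D <= 0 or R < 0:
        raise InfeasibleGeometryError("need D > 0 and R >= 0")
    vol = 4.0 * math.pi / 3.0 * ((R + D) ** 3 - R**3)
    phi = params.N * params.v / vol
    if phi > 1.0 + 1e-12:
        raise InfeasibleGeometryError(f"phi_H = {phi:.3f} > 1 at (R, D) = ({R:.3f}, {D:.3f})")
    phi = min(phi, 1.0)
    y = phi * 4.0 * math.pi * R**2 / (params.N * params.v)  # a_H = 1
    if y >= 1.0:
        raise InfeasibleGeometryError(f"surface fraction y = {y:.3f} >= 1")
    lf2n2 = params.l_b * params.f**2 * params.N**2
    kap = params.kappa
    shell_factor = 3 * R**2 * D + 3 * R * D**2 + D**3
    self_num = D**3 * R**3 / (R + D) + 2 * D**3 * R**2 + D**4 * R + D**5 / 5.0
    terms = {
        "volume": _flory(params, phi),
        "self_energy": 0.5 * lf2n2 * (1.0 - y) ** 2 * self_num / shell_factor**2,
        "surface": 4.0 * math.pi * ((R + D) ** 2 + D**2)
        * (1.0 / params.v) * params.chi * phi**2,
        "adsorption": (
            -0.5 * lf2n2 * (1.0 - y) ** 2 / ((R + D) * (1.0 + kap * (R + D)))
            + _cavity_term(kap, lf2n2, y, R)
        ),
    }
    return StructureEnergy("vesicle", D, R, y, phi, sum(terms.values()), terms)


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def _d_min(params: TheoryParams) -> float:
    """Smallest ball radius with φ_H = 1."""
    return (3.0 * params.N * params.v / (4.0 * math.pi)) ** (1.0 / 3.0)


def _minimize_core_shell(params: TheoryParams) -> StructureEnergy:
    """Minimize F(D) for the dense ball over D in [D(φ=1), 12 D(φ=1)].

    Outside the core-shell stability region (large N·l_B) F(D) can decrease
    monotonically toward the dissolved state; the bounded scan then returns
    the edge value with ``diagnostics["at_bound"]`` set.
    """
    d0 = _d_min(params)
    grid = d0 * np.geomspace(1.0 + 1e-9, 12.0, 240)
    vals = [free_energy_core_shell(params, d).f_total for d in grid]
    i = int(np.argmin(vals))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(
        lambda d: free_energy_core_shell(params, d).f_total,
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10 * d0},
    )
    cand = [free_energy_core_shell(params, d) for d in (float(res.x), grid[i])]
    best = min(cand, key=lambda s: s.f_total)
    at_bound = best.D <= grid[0] * (1 + 1e-8) or best.D >= grid[-1] * (1 - 1e-8)
    return replace(best, diagnostics={"at_bound": bool(at_bound)})


def _vesicle_geometry(params: TheoryParams, R: float, phi: float) -> float:
    """Thickness D such that the layer holds all N monomers at fraction φ."""
    shell_vol = 3.0 * params.N * params.v / (4.0 * math.pi * phi)
    return (R**3 + shell_vol) ** (1.0 / 3.0) - R


def _minimize_vesicle(params: TheoryParams) -> StructureEnergy:
    d0 = _d_min(params)

    def objective(z) -> float:
        R = math.exp(z[0])
        phi = 1.0 / (1.0 + math.exp(-z[1]))
        D = _vesicle_geometry(params, R, phi)
        try:
            return free_energy_vesicle(params, R, D).f_total
        except InfeasibleGeometryError:
            return 1e30

    # multi-start grid over cavity radius and density guards the double-well
    # structure near the transition
    r_grid = d0 * np.geomspace(1e-3, 60.0, 60)
    phi_grid = np.array([0.5, 0.8, 0.95, 0.999])
    best_z, best_v = None, np.inf
    for R in r_grid:
        for phi in phi_grid:
            z = (math.log(R), math.log(phi / (1 - phi)))
            v = objective(z)
            if v < best_v:
                best_v, best_z = v, z
    res = optimize.minimize(objective, best_z, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 4000})
    z = res.x if res.fun <= best_v else np.asarray(best_z)
    R = math.exp(z[0])
    phi = 1.0 / (1.0 + math.exp(-z[1]))
    out = free_energy_vesicle(params, R, _vesicle_geometry(params, R, phi))
    return replace(out, diagnostics={"converged": bool(res.success)})


def minimize_structure(params: TheoryParams, structure: str) -> StructureEnergy:
    """Global minimum of the chosen structure's free energy.

    Coarse deterministic grid scan followed by local refinement; multi-start
    over the cavity radius guards against the core-shell/vesicle double well
    near the transition.
    """
    if structure == "core_shell":
        return _minimize_core_shell(params)
    if structure == "vesicle":
        return _minimize_vesicle(params)
    raise ValueError(f"unknown structure {structure!r}")


# ---------------------------------------------------------------------------
# transition line
# ---------------------------------------------------------------------------

def _delta_f(params: TheoryParams, l_b: float) -> float:
    p = replace(params, l_b=l_b)
    return (minimize_structure(p, "vesicle").f_total
            - minimize_structure(p, "core_shell").f_total)


def transition_bjerrum(params: TheoryParams, l_b_range=(0.05, 50.0),
                       rtol: float = 1e-4) -> dict:
    """Bjerrum length l_B* where F_vesicle = F_core-shell at fixed N.

    Scans for a sign change of ΔF(l_B) on a log grid, then bisects.  Returns
    the crossing plus both minimizers there; raises if ΔF never changes sign
    (reported as "no transition" by :func:`transition_line`).
    """
    grid = np.geomspace(*l_b_range, 40)
    vals = [_delta_f(params, lb) for lb in grid]
    sign_change = None
    for i in range(len(grid) - 1):
        if vals[i] == 0 or (vals[i] > 0) != (vals[i + 1] > 0):
            sign_change = i
            break
    if sign_change is None:
        raise ValueError(f"no core-shell/vesicle transition for l_B in {l_b_range}")
    lo, hi = grid[sign_change], grid[sign_change + 1]
    l_star = optimize.brentq(lambda lb: _delta_f(params, lb), lo, hi,
                             rtol=rtol)
    p = replace(params, l_b=l_star)
    ves = minimize_structure(p, "vesicle")
    cs = minimize_structure(p, "core_shell")
    return {"l_b": float(l_star), "vesicle": ves, "core_shell": cs,
            "cavity_diameter": 2.0 * ves.R}


def transition_line(params: TheoryParams, n_values) -> list[dict]:
    """The (N, l_B*) transition curve for a sequence of chain lengths.

    Entries where no sign change exists in the scanned l_B window carry
    ``l_b = nan`` (no transition).
    """
    out = []
    for n in n_values:
        p = replace(params, N=float(n))
        try:
            row = transition_bjerrum(p)
            out.append({"N": float(n), "l_b": row["l_b"],
                        "cavity_diameter": row["cavity_diameter"],
                        "D_vesicle": row["vesicle"].D,
                        "R_vesicle": row["vesicle"].R,
                        "D_core_shell": row["core_shell"].D,
                        "F_vesicle": row["vesicle"].f_total,
                        "F_core_shell": row["core_shell"].f_total})
        except ValueError:
            out.append({"N": float(n), "l_b": float("nan"),
                        "cavity_diameter": float("nan"),
                        "D_vesicle": float("nan"), "R_vesicle": float("nan"),
                        "D_core_shell": float("nan"),
                        "F_vesicle": float("nan"),
                        "F_core_shell": float("nan")})
    return out
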