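"""The coarse-grained force field of the two-chain complex.

Four terms, all in reduced units (ε_LJ = σ = m_b = k_BT = 1):

* stiff harmonic bonds ``E = K (r - b)²`` with K = 10⁴, b = 1σ, keeping bond
  length fluctuations under 1%;
* WCA excluded volume: the repulsive part of Lennard-Jones, shifted so it
  vanishes continuously at r_c = 2^(1/6) σ;
* an implicit-solvent Yukawa-type attraction between hydrophobic (H-H) bead
  pairs, ``E = ε_αβ (σ/r) (1 - (r/r_cY)²)²`` cut at r_cY = 4σ, with
  ε_HH <= 0 encoding solvent quality and ε_HP = ε_PP = 0 (good solvent for
  the polyanion);
* unscreened Coulomb ``E = l_B q_i q_j / r`` between charged beads, with the
  Bjerrum length l_B setting the electrostatic strength (no explicit
  counterions: in the dilute stoichiometric complex they are released far
  from the aggregate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ForceField",
    "bond_energy",
    "lj_energy",
    "yukawa_energy",
    "coulomb_energy",
    "R_C_FACTOR",
]

R_C_FACTOR = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceField:
    K: float = 10000.0      # bond spring constant, energy/σ²
    b: float = 1.0          # bond length, σ
    eps_lj: float = 1.0
    sigma: float = 1.0
    eps_hh: float = 0.0     # solvent-quality parameter, <= 0
    eps_pp: float = 0.0
    eps_hp: float = 0.0
    l_b: float = 1.0        # Bjerrum length, σ

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("bond constant K must be positive")
        if self.eps_hh > 0:
            raise ValueError("eps_hh must be <= 0 (attractive or off)")
        if self.l_b < 0:
            raise ValueError("Bjerrum length must be >= 0")

    @property
    def r_c(self) -> float:
        """WCA cutoff, exactly 2^(1/6) σ."""
        return R_C_FACTOR * self.sigma

    @property
    def r_cy(self) -> float:
        """Yukawa cutoff, 4σ."""
        return 4.0 * self.sigma

    def yukawa_eps(self, pair_kind: str) -> float:
        try:
            return {"HH": self.eps_hh, "PP": self.eps_pp,
                    "HP": self.eps_hp, "PH": self.eps_hp}[pair_kind]
        except KeyError:
            raise ValueError(f"unknown pair kind {pair_kind!r}") from None


def bond_energy(r, ff: ForceField):
    """Stiff spring, E = K (r - b)²."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    return ff.K * (r - ff.b) ** 2


def lj_energy(r, ff: ForceField):
    """WCA repulsion, zero at and beyond r_c = 2^(1/6) σ."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    s6 = (ff.sigma / r) ** 6
    e = 4.0 * ff.eps_lj * (s6 * s6 - s6 + 0.25)
    return np.where(r <= ff.r_c, e, 0.0)


def yukawa_energy(r, pair_kind: str, ff: ForceField):
    """Solvent-induced attraction, ε_αβ (σ/r)(1-(r/r_cY)²)², zero beyond 4σ."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    eps = ff.yukawa_eps(pair_kind)
    u = 1.0 - (r / ff.r_cy) ** 2
    e = eps * (ff.sigma / r) * u * u
    return np.where(r <= ff.r_cy, e, 0.0)


def coulomb_energy(r, q_i, q_j, ff: ForceField):
    """Unscreened Coulomb in k_BT units: l_B q_i q_j / r."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    return ff.l_b * np.asarray(q_i, dtype=float) * np.asarray(q_j, dtype=float) / r
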