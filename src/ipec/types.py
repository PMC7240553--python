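"""Core in-memory containers shared by all stages.

A :class:`BeadConfiguration` is one snapshot of the two-chain system (or of a
geometric fixture): bead coordinates in units of the Lennard-Jones length
``σ``, a per-bead species tag (``H`` = hydrophobic polycation, ``P`` =
hydrophilic polyanion) and a per-bead integer charge (+1 on charged H beads,
-1 on charged P beads, 0 on nonionic beads).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BeadConfiguration", "TYPE_CODES", "type_codes_to_species"]

#: integer type codes used in LAMMPS dumps / extended XYZ: 1=H charged,
#: 2=H nonionic, 3=P charged, 4=P nonionic.
TYPE_CODES = {("H", 1): 1, ("H", 0): 2, ("P", -1): 3, ("P", 0): 4}
_CODE_TO_SPECIES = {v: k for k, v in TYPE_CODES.items()}


def type_codes_to_species(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decode integer type codes into (chain, charge) arrays."""
    codes = np.asarray(codes, dtype=int)
    bad = set(np.unique(codes)) - set(_CODE_TO_SPECIES)
    if bad:
        raise ValueError(f"unknown bead type codes: {sorted(bad)}")
    chain = np.array([_CODE_TO_SPECIES[c][0] for c in codes], dtype="<U1")
    charge = np.array([_CODE_TO_SPECIES[c][1] for c in codes], dtype=np.int8)
    return chain, charge


@dataclass
class BeadConfiguration:
    """Positions plus species/charge bookkeeping for one snapshot.

    Parameters
    ----------
    positions : (n, 3) float array, units of σ.
    chain : (n,) array of 'H' / 'P' species tags.
    charge : (n,) integer array, each entry in {-1, 0, +1}.
    bonds : optional (m, 2) integer array of bonded index pairs.
    box_edge : optional periodic box edge L (absent = non-periodic).
    """

    positions: np.ndarray
    chain: np.ndarray
    charge: np.ndarray
    bonds: np.ndarray | None = None
    box_edge: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.chain = np.asarray(self.chain, dtype="<U1")
        self.charge = np.asarray(self.charge, dtype=np.int8)
        if self.bonds is not None:
            self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.positions)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.chain) != n or len(self.charge) != n:
            raise ValueError("chain/charge length mismatch with positions")
        if not np.isin(self.chain, ["H", "P"]).all():
            raise ValueError("chain tags must be 'H' or 'P'")
        if not np.isin(self.charge, [-1, 0, 1]).all():
            raise ValueError("charges must be -1, 0 or +1")
        if ((self.charge == 1) & (self.chain != "H")).any():
            raise ValueError("+1 charges are carried by H beads only")
        if ((self.charge == -1) & (self.chain != "P")).any():
            raise ValueError("-1 charges are carried by P beads only")
        if self.bonds is not None and len(self.bonds) and (
            self.bonds.min() < 0 or self.bonds.max() >= n
        ):
            raise ValueError("bond indices out of range")

    # -- convenience ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def charged(self) -> np.ndarray:
        return self.charge != 0

    @property
    def is_h(self) -> np.ndarray:
        return self.chain == "H"

    @property
    def is_p(self) -> np.ndarray:
        return self.chain == "P"

    @property
    def type_codes(self) -> np.ndarray:
        codes = np.empty(self.n, dtype=np.int64)
        for (sp, q), code in TYPE_CODES.items():
            codes[(self.chain == sp) & (self.charge == q)] = code
        return codes

    def center_of_mass(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def species_mask(self, species: str) -> np.ndarray:
        """Mask for one of 'H', 'P', 'H+', 'H0', 'P-', 'P0', 'all'."""
        if species == "all":
            return np.ones(self.n, dtype=bool)
        if species in ("H", "P"):
            return self.chain == species
        table = {
            "H+": (self.chain == "H") & (self.charge == 1),
            "H0": (self.chain == "H") & (self.charge == 0),
            "P-": (self.chain == "P") & (self.charge == -1),
            "P0": (self.chain == "P") & (self.charge == 0),
        }
        try:
            return table[species]
        except KeyError:
            raise ValueError(f"unknown species selector {species!r}") from None

    def copy(self) -> "BeadConfiguration":
        return BeadConfiguration(
            self.positions.copy(),
            self.chain.copy(),
            self.charge.copy(),
            None if self.bonds is None else self.bonds.copy(),
            self.box_edge,
            dict(self.meta),
        )
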