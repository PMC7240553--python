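"""Morphology taxonomy: observable bundles -> labels -> diagrams.

The classifier is a deterministic rule cascade over per-snapshot observables
(shape factors, maximal-cluster fraction, radial profiles, ion-pair
fraction, pore count, Q_l spectrum).  The underlying study identifies
morphologies by visual inspection and by where curves rise; the numeric
thresholds here operationalize those calls and are tuned on the labelled
synthetic fixtures (every threshold is exposed on :class:`Thresholds`).

Taxonomy: coil, sphere_filled, core_shell_dense, necklace, cylinder, torus,
vesicle, perforated_vesicle, onion, structured_solid.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .observables import (detect_cavity, ion_pair_fraction, max_cluster,
                          radial_profiles, shape_factors)
from .symmetry import order_parameters
from .types import BeadConfiguration

__all__ = [
    "TAXONOMY",
    "Thresholds",
    "MorphologyRecord",
    "record_from_config",
    "classify",
    "count_pores",
    "build_diagram",
    "MARKERS",
]

TAXONOMY = (
    "coil",
    "sphere_filled",
    "core_shell_dense",
    "necklace",
    "cylinder",
    "torus",
    "vesicle",
    "perforated_vesicle",
    "onion",
    "structured_solid",
)

#: diagram marker coding, one symbol per label
MARKERS = {
    "coil": "~",
    "sphere_filled": "●",
    "core_shell_dense": "⊕",
    "necklace": "⋯",
    "cylinder": "—",
    "torus": "◇",
    "vesicle": "○",
    "perforated_vesicle": "◆",
    "onion": "◐",
    "structured_solid": "◑",
}


@dataclass(frozen=True)
class Thresholds:
    sphericity: float = 0.8       # k1, k2 >= this -> spherical
    coil_mmax: float = 0.10       # maximal-cluster fraction below -> coil
    coil_density: float = 0.15    # overall bead density below -> swollen
    necklace_hi: float = 0.75     # upper edge of the 2<M_max>/N rise window
    cylinder_k1: float = 0.40
    cylinder_k2: float = 0.80
    eps_good_solvent: float = -0.25   # ε_HH above this counts as good solvent
    q_structured: float = 8.0     # dominant Q_l (l >= 3) marking segregation
    # ψ_b gates, calibrated to this implementation's measured scale: the
    # weak-coupling core-shell complexes reach ψ_b ≈ 0.32-0.38, strongly
    # segregated solids 0.5+, strongly coupled layered/hollow states 0.85+
    psi_high: float = 0.45
    psi_low: float = 0.40
    min_cavity_radius: float = 2.0
    cavity_rel_threshold: float = 0.05
    pore_gap_factor: float = 2.2  # pore gap vs mean angular bead spacing
    pore_min_probes: int = 4      # probe directions per genuine pore
    axis_hole_frac: float = 0.002


@dataclass
class MorphologyRecord:
    """Observable bundle for one snapshot plus the control variables."""

    k1: float
    k2: float
    mmax_frac: float              # M_max / n_selected = 2<M_max>/N for f=1/2
    density: float                # beads per σ³ inside the gyration sphere
    psi_b: float
    hollow: bool
    cavity_radius: float
    central_h_peak: bool
    dense_h_core: bool
    pore_count: int
    q_dominant_l: int
    q_dominant: float
    axis_hole: bool
    N: int | None = None
    l_b: float | None = None
    eps_hh: float | None = None
    label: str | None = None

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# observable extraction
# ---------------------------------------------------------------------------

_N_PROBES = 1500


def count_pores(config: BeadConfiguration, th: Thresholds = Thresholds()) -> int:
    """Count empty angular patches (pores) in the H-bead wall.

    Quasi-uniform probe directions are marked "in pore" when their angular
    distance to every H bead exceeds ``pore_gap_factor`` times the mean
    angular bead spacing √(4π/n) (so sampling holes of an intact shell are
    ignored — the detector is conservative for sparse shells); in-pore
    probes are clustered by angular adjacency and clusters of at least
    ``pore_min_probes`` probes count as pores.  Grid-free, hence free of
    polar-bin artifacts.
    """
    from .structures import fibonacci_sphere

    mask = config.species_mask("H")
    d = config.positions[mask] - config.center_of_mass()
    r = np.linalg.norm(d, axis=1)
    keep = r > 1e-6
    d, r = d[keep], r[keep]
    n = len(d)
    if n < 16:
        return 0
    unit = d / r[:, None]
    probes = fibonacci_sphere(_N_PROBES)
    gap = max(0.12, th.pore_gap_factor * math.sqrt(4 * math.pi / n))
    nearest = np.arccos(np.clip((probes @ unit.T).max(axis=1), -1.0, 1.0))
    in_pore = np.flatnonzero(nearest > gap)
    if len(in_pore) == 0:
        return 0
    # cluster in-pore probes: adjacency at ~1.6× the probe lattice spacing
    link = 1.6 * math.sqrt(4 * math.pi / _N_PROBES)
    p = probes[in_pore]
    adj = np.arccos(np.clip(p @ p.T, -1, 1)) < link
    seen = np.zeros(len(p), dtype=bool)
    pores = 0
    for start in range(len(p)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for v in np.flatnonzero(adj[u] & ~seen):
                seen[v] = True
                stack.append(v)
        if size >= th.pore_min_probes:
            pores += 1
    return pores


def _h_profile_flags(config: BeadConfiguration, n_bins: int) -> tuple:
    """(hollow dict, central_h_peak, dense_h_core) from the radial profile."""
    profile = radial_profiles(config, n_bins=n_bins)
    cavity = detect_cavity(profile)
    hd = profile.density["H+"] + profile.density["H0"]
    pdn = profile.density["P-"] + profile.density["P0"]
    peak = hd.max()
    central_h_peak = False
    dense_h_core = False
    if peak > 0:
        h_c = hd[:2].max()       # innermost ~2σ
        p_c = pdn[:2].max()
        # high-low-high radial pattern of H marks the onion's buried core:
        # a central H peak, a dip in the intermediate P-rich layer, and the
        # main H wall further out
        occupied = np.flatnonzero(hd > 0.3 * peak)
        i_last = int(occupied[-1]) if len(occupied) else 0
        if i_last > 3 and h_c >= 0.3 * peak:
            dip = float(hd[2:i_last].min())
            central_h_peak = dip < 0.5 * min(h_c, hd[i_last])
        dense_h_core = h_c > 2.0 * max(p_c, 1e-12) and h_c >= 0.5 * peak
    return cavity, central_h_peak, dense_h_core


def _axis_hole(config: BeadConfiguration, th: Thresholds) -> bool:
    """True when the symmetry axis through the centroid passes through void.

    The candidate axis is the eigenvector of the smallest gyration moment
    (the ring axis of an oblate torus); material on the axis (disks,
    cylinders seen end-on, filled spheres) defeats the test.
    """
    pts = config.positions - config.positions.mean(axis=0)
    gyr = pts.T @ pts / len(pts)
    w, v = np.linalg.eigh(gyr)
    axis = v[:, 0]
    rho = np.linalg.norm(pts - np.outer(pts @ axis, axis), axis=1)
    ref = np.median(rho)
    if ref <= 0:
        return False
    frac = float(np.mean(rho < 0.25 * ref))
    return frac < th.axis_hole_frac


def record_from_config(config: BeadConfiguration, N: int | None = None,
                       l_b: float | None = None, eps_hh: float | None = None,
                       th: Thresholds = Thresholds(),
                       cluster_cutoff: float = 1.4,
                       pair_cutoff: float = 1.5) -> MorphologyRecord:
    """Compute the full observable bundle the classifier consumes."""
    shape = shape_factors(config)
    try:
        cluster = max_cluster(config, cutoff=cluster_cutoff, selection="H0")
        mmax = cluster.normalized
    except ValueError:
        mmax = float("nan")
    try:
        psi = ion_pair_fraction(config, r_b=pair_cutoff).psi_b
    except ValueError:
        psi = float("nan")
    r_span = np.linalg.norm(
        config.positions - config.positions.mean(axis=0), axis=1
    ).max()
    n_bins = int(np.clip(r_span, 12, 60))
    cavity, central_h_peak, dense_h_core = _h_profile_flags(config, n_bins)
    spectrum = order_parameters(config, "H")
    ranked = [(l, q) for l, q in spectrum.ranked(l_min=3)]
    q_l, q_val = ranked[0]
    # mean density inside the equivalent uniform ball (R = sqrt(5/3) r_g)
    r_eff = math.sqrt(5.0 / 3.0 * (shape.g1 + shape.g2 + shape.g3))
    density = config.n / (4.0 * math.pi / 3.0 * max(r_eff, 1e-9) ** 3)
    return MorphologyRecord(
        k1=shape.k1, k2=shape.k2, mmax_frac=mmax, density=density, psi_b=psi,
        hollow=cavity["hollow"], cavity_radius=cavity["cavity_radius"],
        central_h_peak=central_h_peak, dense_h_core=dense_h_core,
        pore_count=count_pores(config, th), q_dominant_l=q_l, q_dominant=q_val,
        axis_hole=_axis_hole(config, th), N=N, l_b=l_b, eps_hh=eps_hh,
    )


# ---------------------------------------------------------------------------
# the rule cascade
# ---------------------------------------------------------------------------

def _nearest_prototype(k1: float, k2: float) -> str:
    protos = {"cylinder": (0.0, 1.0), "torus": (0.5, 0.55), "necklace": (0.2, 0.9)}
    return min(protos, key=lambda lab: (k1 - protos[lab][0]) ** 2
               + (k2 - protos[lab][1]) ** 2)


def classify(record: MorphologyRecord, th: Thresholds = Thresholds()) -> str:
    """Deterministic label for one observable bundle.

    Pure function of the record: identical bundles yield identical labels.
    """
    needed = (record.k1, record.k2, record.mmax_frac)
    if any(x is None or (isinstance(x, float) and math.isnan(x)) for x in needed):
        raise ValueError("incomplete record: k1, k2 and mmax_frac are required")
    spherical = record.k1 >= th.sphericity and record.k2 >= th.sphericity
    loose = record.mmax_frac < th.coil_mmax
    good_solvent = record.eps_hh is not None and record.eps_hh >= th.eps_good_solvent
    swollen = record.density < th.coil_density
    if loose and (good_solvent or swollen or not spherical):
        return "coil"
    if not spherical:
        if record.mmax_frac <= th.necklace_hi:
            return "necklace"
        if record.k1 < th.cylinder_k1 and record.k2 > th.cylinder_k2:
            return "cylinder"
        if record.axis_hole:
            return "torus"
        return _nearest_prototype(record.k1, record.k2)
    if record.hollow:
        return "perforated_vesicle" if record.pore_count >= 1 else "vesicle"
    if record.central_h_peak:
        return "onion"
    psi = record.psi_b if not math.isnan(record.psi_b) else 0.0
    if record.q_dominant >= th.q_structured and psi >= th.psi_high:
        return "structured_solid"
    if psi <= th.psi_low and record.dense_h_core:
        return "core_shell_dense"
    return "sphere_filled"


# ---------------------------------------------------------------------------
# morphology diagrams
# ---------------------------------------------------------------------------

def build_diagram(records: list[MorphologyRecord],
                  axes: tuple[str, str] = ("eps_hh", "l_b"),
                  th: Thresholds = Thresholds()) -> pd.DataFrame:
    """Tabulate classified records on a control-variable grid.

    Columns: axis1, axis2, label, marker.  Records lacking a label are
    classified on the fly; duplicate grid cells raise a conflict error.
    """
    a1, a2 = axes
    rows = []
    for rec in records:
        label = rec.label or classify(rec, th)
        rows.append({
            a1: getattr(rec, a1), a2: getattr(rec, a2),
            "label": label, "marker": MARKERS.get(label, "?"),
        })
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=[a1, a2], keep=False)
    if dup.any():
        cells = df.loc[dup, [a1, a2]].drop_duplicates().values.tolist()
        raise ValueError(f"duplicate diagram cells at {cells}")
    return df.sort_values([a1, a2]).reset_index(drop=True)
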