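"""Synthetic bead configurations with known geometry.

Every observable, the shell-symmetry analyzer and the morphology classifier
are tested against configurations built here, without running any dynamics:
filled spheres, spherical shells (plain and perforated at polyhedron-face
directions), vesicles (inner P shell / H wall / outer P shell), cylinders,
tori, disks, lines, necklaces and random coils, plus composite fixtures for
the layered morphologies (core-shell, onion, structured solid).

The fixtures are geometric, not thermodynamic: no attempt is made to produce
Boltzmann-weighted ensembles.  Quasi-uniform sampling on the sphere uses a
deterministic Fibonacci lattice; filled bodies use low-discrepancy radial
stratification.  All randomness (jitter, loose coronas, random walks) flows
from ``spec.seed``, so identical spec + seed reproduces a configuration
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .types import BeadConfiguration

__all__ = [
    "ShapeSpec",
    "make_shell",
    "make_perforated_shell",
    "make_geometry",
    "make_structure",
    "make_core_shell",
    "make_onion",
    "make_structured_solid",
    "polyhedron_directions",
    "fibonacci_sphere",
    "morphology_fixture",
    "MORPHOLOGY_LABELS",
]

_GOLDEN = math.pi * (3.0 - math.sqrt(5.0))  # golden angle

GEOMETRY_KINDS = (
    "filled_sphere",
    "shell",
    "vesicle",
    "perforated_shell",
    "cylinder",
    "torus",
    "disk",
    "line",
    "necklace",
    "random_coil",
)


class InvalidSpecError(ValueError):
    """Raised when a ShapeSpec is degenerate or inconsistent."""


@dataclass
class ShapeSpec:
    """Parameters of one synthetic structure.

    Lengths are in units of σ.  Only the fields relevant to ``kind`` are
    used; validation is per kind.  ``pore_directions`` may be an (k, 3)
    array of unit vectors or the name of a polyhedron whose face-center
    directions are used (tetrahedron, cube, octahedron, dodecahedron).
    """

    kind: str
    n: int = 1000
    radius: float = 10.0
    inner_radius: float = 6.0
    thickness: float = 3.0
    length: float = 40.0
    major_radius: float = 10.0
    minor_radius: float = 2.0
    n_spheres: int = 4
    sphere_radius: float = 3.5
    bond_length: float = 1.0
    species: str = "H"
    pore_directions: object = None
    pore_angular_radius: float = 0.4
    noise_sd: float = 0.0
    seed: int = 0

    def validated(self) -> "ShapeSpec":
        if self.kind not in GEOMETRY_KINDS:
            raise InvalidSpecError(f"unknown kind {self.kind!r}")
        if self.n < 1:
            raise InvalidSpecError("bead count must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        positive = {
            "filled_sphere": ("radius",),
            "shell": ("radius",),
            "vesicle": ("inner_radius", "thickness"),
            "perforated_shell": ("radius",),
            "cylinder": ("radius", "length"),
            "torus": ("major_radius", "minor_radius"),
            "disk": ("radius",),
            "line": ("bond_length",),
            "necklace": ("sphere_radius",),
            "random_coil": ("bond_length",),
        }[self.kind]
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be > 0 for kind {self.kind!r}")
        if self.kind == "torus" and self.minor_radius >= self.major_radius:
            raise InvalidSpecError("torus needs minor_radius < major_radius")
        if self.kind in ("shell", "perforated_shell") and self.n < 4:
            raise InvalidSpecError("shell needs at least 4 beads")
        if self.pore_directions is not None:
            if not 0 < self.pore_angular_radius < math.pi / 2:
                raise InvalidSpecError("pore angular radius must lie in (0, π/2)")
        return self


# ---------------------------------------------------------------------------
# low-level samplers
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (deterministic lattice)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    phi = _GOLDEN * i
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _fibonacci_ball(n: int, radius: float) -> np.ndarray:
    """Low-discrepancy filling of a ball.

    Directions from the Fibonacci lattice; radii from an independent
    equidistributed sequence (frac((i+1/2)·√2)) so radius does not correlate
    with the lattice's pole-to-pole drift.
    """
    u = np.mod((np.arange(n) + 0.5) * math.sqrt(2.0), 1.0)
    r = radius * u ** (1.0 / 3.0)
    return fibonacci_sphere(n) * r[:, None]


def _fermat_disk(n: int, radius: float) -> np.ndarray:
    """Deterministic sunflower lattice on a planar disk (z = 0)."""
    i = np.arange(n)
    r = radius * np.sqrt((i + 0.5) / n)
    phi = _GOLDEN * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), np.zeros(n)])


def _shell_points(n: int, radius: float) -> np.ndarray:
    return radius * fibonacci_sphere(n)


def _thick_shell_points(n: int, r_lo: float, r_hi: float, rng) -> np.ndarray:
    """Quasi-uniform filling of the spherical layer r in [r_lo, r_hi]."""
    u = (np.arange(n) + 0.5) / n
    r = (r_lo**3 + u * (r_hi**3 - r_lo**3)) ** (1.0 / 3.0)
    dirs = fibonacci_sphere(n)
    # decorrelate the radial ordering from the Fibonacci ordering
    rng.shuffle(r)
    return dirs * r[:, None]


def _dense_h_body(predicate, lo, hi, rng, spacing: float = 1.25,
                  jitter: float = 0.08) -> tuple[np.ndarray, np.ndarray]:
    """Melt-density H body on two interpenetrating cubic sublattices.

    Dense collapsed cores are liquid-like: near-uniform density with a
    well-defined nearest-neighbor distance, so a Poisson (ideal-gas) fill
    badly underestimates contact connectivity.  Here the nonionic beads sit
    on a cubic lattice (face neighbors at ``spacing`` < 1.4σ, so the
    nonionic contact network is connected by construction) and the charged
    beads on the body-centered offsets, giving overall density 2/spacing³
    ≈ 1σ⁻³ and an equal charged/uncharged split.

    Returns (positions, charges).
    """
    axes = [np.arange(a + spacing / 2, b, spacing) for a, b in zip(lo, hi)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = grid + spacing / 2.0
    corner = grid[predicate(grid)]
    body = centers[predicate(centers)]
    if len(corner) == 0:
        raise InvalidSpecError("degenerate region: no lattice sites inside")
    pts = np.concatenate([corner, body])
    charge = np.concatenate(
        [np.zeros(len(corner), dtype=np.int8), np.ones(len(body), dtype=np.int8)]
    )
    return pts + rng.normal(0.0, jitter, pts.shape), charge


def _jitter(points: np.ndarray, sd: float, rng) -> np.ndarray:
    if sd > 0:
        points = points + rng.normal(0.0, sd, points.shape)
    return points


def _alternating_charges(n: int, species: str, start_charged: bool = True) -> np.ndarray:
    """Charged/uncharged alternation along the bead order (f = 1/2)."""
    q = 1 if species == "H" else -1
    charge = np.zeros(n, dtype=np.int8)
    offset = 0 if start_charged else 1
    charge[offset::2] = q
    return charge


def _assemble(parts: list, bonds=None, meta=None) -> BeadConfiguration:
    """Parts are (points, species) or (points, species, charges).

    Without explicit charges, charged/uncharged alternation along the bead
    order is applied (sign from the species).
    """
    pos, chain, charge = [], [], []
    for part in parts:
        pts, sp = part[0], part[1]
        q = part[2] if len(part) > 2 else _alternating_charges(len(pts), sp)
        if sp == "P":
            q = -np.abs(q)
        pos.append(pts)
        chain.append(np.full(len(pts), sp, dtype="<U1"))
        charge.append(np.asarray(q, dtype=np.int8))
    charge = np.concatenate(charge)
    # stoichiometric fixtures are exactly neutral: trim the excess charges
    # (from the tail) whenever both signs are present
    total = int(charge.sum())
    if total > 0 and (charge == -1).any():
        charge[np.flatnonzero(charge == 1)[::-1][:total]] = 0
    elif total < 0 and (charge == 1).any():
        charge[np.flatnonzero(charge == -1)[::-1][:-total]] = 0
    return BeadConfiguration(np.concatenate(pos), np.concatenate(chain),
                             charge, bonds=bonds, meta=meta or {})


# ---------------------------------------------------------------------------
# polyhedron face directions (canonical orientation)
# ---------------------------------------------------------------------------

def polyhedron_directions(name: str) -> np.ndarray:
    """Unit vectors toward the face centers of a regular polyhedron.

    Canonical (unrotated) orientation; downstream rotation-invariance tests
    apply random rotations to the generated configurations.
    """
    if name == "tetrahedron":
        v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    elif name == "cube":
        v = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
    elif name == "octahedron":
        v = np.array([[sx, sy, sz] for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)], float)
    elif name == "dodecahedron":
        # face centers of the dodecahedron = vertices of the icosahedron
        g = (1 + math.sqrt(5)) / 2
        v = np.array(
            [[0, s1, s2 * g] for s1 in (1, -1) for s2 in (1, -1)]
            + [[s1, s2 * g, 0] for s1 in (1, -1) for s2 in (1, -1)]
            + [[s1 * g, 0, s2] for s1 in (1, -1) for s2 in (1, -1)],
            float,
        )
    else:
        raise InvalidSpecError(f"unknown polyhedron {name!r}")
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _resolve_pores(spec: ShapeSpec) -> np.ndarray:
    dirs = spec.pore_directions
    if dirs is None:
        return np.zeros((0, 3))
    if isinstance(dirs, str):
        dirs = polyhedron_directions(dirs)
    dirs = np.asarray(dirs, dtype=float).reshape(-1, 3)
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(norms < 1e-12):
        raise InvalidSpecError("pore directions must be nonzero vectors")
    return dirs / norms[:, None]


def _cut_pores(points: np.ndarray, dirs: np.ndarray, cap: float) -> np.ndarray:
    """Keep points whose angular distance to every pore axis exceeds cap."""
    if len(dirs) == 0:
        return points
    r = np.linalg.norm(points, axis=1)
    unit = points / np.where(r > 0, r, 1.0)[:, None]
    cosang = unit @ dirs.T
    keep = np.all(cosang < math.cos(cap), axis=1)
    if not keep.any():
        raise InvalidSpecError("pore caps cover the whole sphere")
    return points[keep]


# ---------------------------------------------------------------------------
# spec-level generators
# ---------------------------------------------------------------------------

def make_shell(spec: ShapeSpec) -> BeadConfiguration:
    """Quasi-uniform spherical shell (Fibonacci lattice plus seeded jitter)."""
    spec = replace(spec, kind="shell").validated()
    rng = np.random.default_rng(spec.seed)
    pts = _jitter(_shell_points(spec.n, spec.radius), spec.noise_sd, rng)
    return _assemble([(pts, spec.species)], meta={"kind": "shell", "radius": spec.radius})


def make_perforated_shell(spec: ShapeSpec) -> BeadConfiguration:
    """Spherical shell with empty caps at the given pore directions."""
    spec = replace(spec, kind="perforated_shell").validated()
    dirs = _resolve_pores(spec)
    rng = np.random.default_rng(spec.seed)
    pts = _cut_pores(_shell_points(spec.n, spec.radius), dirs, spec.pore_angular_radius)
    pts = _jitter(pts, spec.noise_sd, rng)
    meta = {"kind": "perforated_shell", "radius": spec.radius, "n_pores": len(dirs)}
    return _assemble([(pts, spec.species)], meta=meta)


def _make_vesicle(spec: ShapeSpec) -> BeadConfiguration:
    """Inner P shell + H spherical layer + outer P shell, optional pores."""
    r_in, t = spec.inner_radius, spec.thickness
    r_out = r_in + t
    rng = np.random.default_rng(spec.seed)
    n_h = spec.n // 2
    n_p = spec.n - n_h
    # split the P beads between the two bounding shells in proportion to area
    w_in = r_in**2 / (r_in**2 + r_out**2)
    n_p_in = max(4, int(round(w_in * n_p)))
    n_p_out = n_p - n_p_in
    wall = _thick_shell_points(n_h, r_in + 0.6, r_out - 0.6, rng)
    inner = _shell_points(n_p_in, r_in)
    outer = _shell_points(n_p_out, r_out)
    dirs = _resolve_pores(spec)
    if len(dirs):
        wall = _cut_pores(wall, dirs, spec.pore_angular_radius)
    parts = [
        (_jitter(wall, spec.noise_sd, rng), "H"),
        (_jitter(inner, spec.noise_sd, rng), "P"),
        (_jitter(outer, spec.noise_sd, rng), "P"),
    ]
    meta = {"kind": "vesicle", "inner_radius": r_in, "outer_radius": r_out,
            "n_pores": len(dirs)}
    return _assemble(parts, meta=meta)


def _make_filled_sphere(spec: ShapeSpec) -> BeadConfiguration:
    rng = np.random.default_rng(spec.seed)
    pts = _jitter(_fibonacci_ball(spec.n, spec.radius), spec.noise_sd, rng)
    # intermixed species, emulating the good-solvent homogeneous complex
    chain = np.where(np.arange(spec.n) % 2 == 0, "H", "P").astype("<U1")
    charge = np.zeros(spec.n, dtype=np.int8)
    charge[0::4] = 1     # every other H bead
    charge[1::4] = -1    # every other P bead
    nplus, nminus = int((charge == 1).sum()), int((charge == -1).sum())
    if nplus > nminus:  # keep the fixture stoichiometric
        charge[np.flatnonzero(charge == 1)[-(nplus - nminus):]] = 0
    return BeadConfiguration(pts, chain, charge, meta={"kind": "filled_sphere"})


def _make_cylinder(spec: ShapeSpec) -> BeadConfiguration:
    """Dense H core cylinder wrapped in a loose P sheath, axis along z.

    The H core is a melt-density lattice fill; ``spec.n`` only sets the
    P-sheath population.
    """
    rng = np.random.default_rng(spec.seed)
    a, L = spec.radius, spec.length
    a_core = 0.75 * a
    core, core_q = _dense_h_body(
        lambda g: g[:, 0] ** 2 + g[:, 1] ** 2 < a_core**2,
        (-a_core, -a_core, -L / 2), (a_core, a_core, L / 2), rng,
    )
    n_sheath = max(16, spec.n - len(core))
    u = rng.random(n_sheath)
    r = np.sqrt(a_core**2 + u * (a**2 + 2 * a + 1 - a_core**2))
    phi = rng.random(n_sheath) * 2 * math.pi
    z = (rng.random(n_sheath) - 0.5) * L
    sheath = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    parts = [
        (_jitter(core, spec.noise_sd, rng), "H", core_q),
        (_jitter(sheath, spec.noise_sd, rng), "P"),
    ]
    return _assemble(parts, meta={"kind": "cylinder"})


def _make_torus(spec: ShapeSpec) -> BeadConfiguration:
    """Solid torus, dense H tube with a loose P sheath, axis along z."""
    rng = np.random.default_rng(spec.seed)
    R, r = spec.major_radius, spec.minor_radius

    def _minor_dist2(g):
        rho = np.sqrt(g[:, 0] ** 2 + g[:, 1] ** 2)
        return (rho - R) ** 2 + g[:, 2] ** 2

    r_core = 0.8 * r
    ext = R + r
    core, core_q = _dense_h_body(lambda g: _minor_dist2(g) < r_core**2,
                                 (-ext, -ext, -r), (ext, ext, r), rng)

    def _tube(n, s_lo, s_hi):
        out = []
        got = 0
        while got < n:
            m = 2 * (n - got) + 16
            u = rng.random(m) * 2 * math.pi           # angle around main axis
            s = np.sqrt(s_lo**2 + rng.random(m) * (s_hi**2 - s_lo**2))
            psi = rng.random(m) * 2 * math.pi
            keep = rng.random(m) < (R + s * np.cos(psi)) / (R + s_hi)  # Jacobian
            u, s, psi = u[keep], s[keep], psi[keep]
            rho = R + s * np.cos(psi)
            out.append(np.column_stack([rho * np.cos(u), rho * np.sin(u),
                                        s * np.sin(psi)]))
            got += len(u)
        return np.concatenate(out)[:n]

    n_sheath = max(16, spec.n - len(core))
    sheath = _tube(n_sheath, r_core, r + 1.0)
    parts = [
        (_jitter(core, spec.noise_sd, rng), "H", core_q),
        (_jitter(sheath, spec.noise_sd, rng), "P"),
    ]
    return _assemble(parts, meta={"kind": "torus"})


def _make_disk(spec: ShapeSpec) -> BeadConfiguration:
    rng = np.random.default_rng(spec.seed)
    pts = _fermat_disk(spec.n, spec.radius)
    if spec.thickness > 0:
        pts[:, 2] += (rng.random(spec.n) - 0.5) * spec.thickness
    pts = _jitter(pts, spec.noise_sd, rng)
    chain = np.where(np.arange(spec.n) % 2 == 0, "H", "P").astype("<U1")
    charge = np.zeros(spec.n, dtype=np.int8)
    return BeadConfiguration(pts, chain, charge, meta={"kind": "disk"})


def _make_line(spec: ShapeSpec) -> BeadConfiguration:
    rng = np.random.default_rng(spec.seed)
    z = np.arange(spec.n) * spec.bond_length
    pts = np.column_stack([np.zeros(spec.n), np.zeros(spec.n), z - z.mean()])
    pts = _jitter(pts, spec.noise_sd, rng)
    bonds = np.column_stack([np.arange(spec.n - 1), np.arange(1, spec.n)])
    chain = np.full(spec.n, spec.species, dtype="<U1")
    charge = _alternating_charges(spec.n, spec.species)
    return BeadConfiguration(pts, chain, charge, bonds=bonds, meta={"kind": "line"})


def _make_necklace(spec: ShapeSpec) -> BeadConfiguration:
    """m dense H spheres with loose P coronas threaded on a line."""
    rng = np.random.default_rng(spec.seed)
    m = spec.n_spheres
    if m < 2:
        raise InvalidSpecError("necklace needs at least 2 spheres")
    rs = spec.sphere_radius
    spacing = 2.8 * rs
    centers = np.column_stack(
        [np.zeros(m), np.zeros(m), (np.arange(m) - (m - 1) / 2) * spacing]
    )
    np_per = (spec.n // 2) // m
    h_parts, q_parts, p_parts = [], [], []
    for c in centers:
        ball, ball_q = _dense_h_body(lambda g: (g**2).sum(axis=1) < rs**2,
                                     (-rs, -rs, -rs), (rs, rs, rs), rng)
        h_parts.append(ball + c)
        q_parts.append(ball_q)
        corona = _thick_shell_points(np_per, rs + 0.4, rs + 2.2, rng) + c
        p_parts.append(corona)
    h = _jitter(np.concatenate(h_parts), spec.noise_sd, rng)
    hq = np.concatenate(q_parts)
    p = _jitter(np.concatenate(p_parts), spec.noise_sd, rng)
    bonds_h = np.column_stack([np.arange(len(h) - 1), np.arange(1, len(h))])
    bonds_p = np.column_stack([np.arange(len(p) - 1), np.arange(1, len(p))]) + len(h)
    cfg = _assemble([(h, "H", hq), (p, "P")],
                    bonds=np.concatenate([bonds_h, bonds_p]),
                    meta={"kind": "necklace", "n_spheres": m})
    return cfg


def _grow_walk(n: int, b: float, rng, existing: np.ndarray | None, min_dist: float = 0.9,
               start: np.ndarray | None = None) -> np.ndarray:
    """Excluded-volume random walk with bond length b (retry-on-overlap)."""
    pts = np.empty((n, 3))
    pts[0] = np.zeros(3) if start is None else start
    occupied = [existing] if existing is not None and len(existing) else []
    for i in range(1, n):
        ok = False
        for _ in range(80):
            v = rng.normal(size=3)
            cand = pts[i - 1] + b * v / np.linalg.norm(v)
            prev = pts[: max(0, i - 1)]
            near = False
            if len(prev) and np.min(np.linalg.norm(prev - cand, axis=1)) < min_dist:
                near = True
            if not near:
                for arr in occupied:
                    if np.min(np.linalg.norm(arr - cand, axis=1)) < min_dist:
                        near = True
                        break
            if not near:
                pts[i] = cand
                ok = True
                break
        if not ok:  # sterically stuck: step anyway (rare, keeps generator total)
            v = rng.normal(size=3)
            pts[i] = pts[i - 1] + b * v / np.linalg.norm(v)
    return pts


def _make_random_coil(spec: ShapeSpec) -> BeadConfiguration:
    """Two interleaved excluded-volume random walks with bond length b."""
    rng = np.random.default_rng(spec.seed)
    n_each = spec.n // 2
    h = _grow_walk(n_each, spec.bond_length, rng, None)
    p = _grow_walk(spec.n - n_each, spec.bond_length, rng, h,
                   start=h[0] + np.array([1.2, 0.0, 0.0]))
    h = _jitter(h, spec.noise_sd, rng)
    p = _jitter(p, spec.noise_sd, rng)
    nh = len(h)
    bonds_h = np.column_stack([np.arange(nh - 1), np.arange(1, nh)])
    bonds_p = np.column_stack([np.arange(len(p) - 1), np.arange(1, len(p))]) + nh
    return _assemble([(h, "H"), (p, "P")], bonds=np.concatenate([bonds_h, bonds_p]),
                     meta={"kind": "random_coil"})


_GEOMETRY_DISPATCH = {
    "filled_sphere": _make_filled_sphere,
    "vesicle": _make_vesicle,
    "cylinder": _make_cylinder,
    "torus": _make_torus,
    "disk": _make_disk,
    "line": _make_line,
    "necklace": _make_necklace,
    "random_coil": _make_random_coil,
}


def make_geometry(spec: ShapeSpec) -> BeadConfiguration:
    """Build one of the non-shell geometric fixtures (see GEOMETRY_KINDS)."""
    spec = spec.validated()
    try:
        fn = _GEOMETRY_DISPATCH[spec.kind]
    except KeyError:
        raise InvalidSpecError(
            f"kind {spec.kind!r} is handled by make_shell/make_perforated_shell"
        ) from None
    return fn(spec)


def make_structure(spec: ShapeSpec) -> BeadConfiguration:
    """Unified dispatch over every ShapeSpec kind."""
    spec = spec.validated()
    if spec.kind == "shell":
        return make_shell(spec)
    if spec.kind == "perforated_shell":
        return make_perforated_shell(spec)
    return make_geometry(spec)


# ---------------------------------------------------------------------------
# composite fixtures for the layered spherical morphologies
# ---------------------------------------------------------------------------

def make_core_shell(core_radius: float = 7.0, corona_thickness: float = 5.0,
                    seed: int = 0, noise_sd: float = 0.0,
                    ) -> BeadConfiguration:
    """Dense hydrophobic core with a loose hydrophilic corona.

    Emulates the weak-electrostatics poor-solvent complex: the H chain packs
    into a compact ball, the P chain forms a swollen shell, and only the
    interfacial charges can pair, so the ion-pair fraction stays low.
    """
    rng = np.random.default_rng(seed)
    rc = core_radius
    core, core_q = _dense_h_body(lambda g: (g**2).sum(axis=1) < rc**2,
                                 (-rc, -rc, -rc), (rc, rc, rc), rng)
    corona = _thick_shell_points(len(core), core_radius + 0.4,
                                 core_radius + corona_thickness, rng)
    parts = [(_jitter(core, noise_sd, rng), "H", core_q),
             (_jitter(corona, noise_sd, rng), "P")]
    return _assemble(parts, meta={"kind": "core_shell"})


def make_onion(core_radius: float = 3.5, p_layer: float = 2.5, wall: float = 3.0,
               density: float = 0.7, seed: int = 0, noise_sd: float = 0.0,
               ) -> BeadConfiguration:
    """Layered sphere: H core, P layer, H wall, thin outer P coat."""
    rng = np.random.default_rng(seed)
    r1 = core_radius
    r2 = r1 + p_layer
    r3 = r2 + wall
    vol = lambda a, b: 4 * math.pi / 3 * (b**3 - a**3)
    core, core_q = _dense_h_body(lambda g: (g**2).sum(axis=1) < r1**2,
                                 (-r1, -r1, -r1), (r1, r1, r1), rng)
    wall, wall_q = _dense_h_body(
        lambda g: ((r2 + 0.3) ** 2 < (g**2).sum(axis=1))
        & ((g**2).sum(axis=1) < r3**2),
        (-r3, -r3, -r3), (r3, r3, r3), rng,
    )
    n_p = max(8, int(0.5 * density * vol(r1, r2)))
    n_coat = max(8, int(0.8 * 4 * math.pi * r3**2))
    parts = [
        (_jitter(core, noise_sd, rng), "H", core_q),
        (_jitter(_thick_shell_points(n_p, r1 + 0.3, r2, rng), noise_sd, rng), "P"),
        (_jitter(wall, noise_sd, rng), "H", wall_q),
        (_jitter(_shell_points(n_coat, r3 + 0.7), noise_sd, rng), "P"),
    ]
    return _assemble(parts, meta={"kind": "onion"})


def make_structured_solid(inner_radius: float = 3.5, wall: float = 3.0,
                          pore_directions: object = "tetrahedron",
                          pore_angular_radius: float = 0.45, seed: int = 0,
                          noise_sd: float = 0.0) -> BeadConfiguration:
    """Filled sphere with strongly segregated chains keeping pore symmetry.

    The former perforated-vesicle wall (H) persists, but the cavity and the
    pores are filled by the hydrophilic chain, so the particle is solid while
    the angular distribution of H beads still carries the polyhedral symmetry.
    """
    rng = np.random.default_rng(seed)
    r1, r2 = inner_radius, inner_radius + wall
    dirs = _resolve_pores(
        ShapeSpec(kind="shell", pore_directions=pore_directions,
                  pore_angular_radius=pore_angular_radius)
    )
    body, body_q = _dense_h_body(lambda g: (g**2).sum(axis=1) < r2**2,
                                 (-r2, -r2, -r2), (r2, r2, r2), rng)
    r = np.linalg.norm(body, axis=1)
    unit = body / np.where(r > 0, r, 1.0)[:, None]
    in_wall = r > r1
    in_pore = np.any(unit @ dirs.T > math.cos(pore_angular_radius), axis=1)
    h_sel = in_wall & ~in_pore
    n_coat = max(8, int(0.8 * 4 * math.pi * r2**2))
    coat = _shell_points(n_coat, r2 + 0.7)
    parts = [
        (_jitter(body[h_sel], noise_sd, rng), "H", body_q[h_sel]),
        (_jitter(np.concatenate([body[~h_sel], coat]), noise_sd, rng), "P",
         np.concatenate([body_q[~h_sel], _alternating_charges(n_coat, "P")])),
    ]
    return _assemble(parts, meta={"kind": "structured_solid", "n_pores": len(dirs)})


# ---------------------------------------------------------------------------
# labelled morphology fixtures (one per taxonomy label)
# ---------------------------------------------------------------------------

MORPHOLOGY_LABELS = (
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


def _random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def morphology_fixture(label: str, seed: int = 0, noise_sd: float = 0.0,
                       rotate: bool = True) -> BeadConfiguration:
    """A labelled fixture with mildly randomized parameters and orientation.

    Used to exercise the classifier over its whole taxonomy.  Parameter
    ranges are chosen so each label's defining observables stay in regime
    (e.g. dense connected H cores for cylinder/torus, dilute coils).
    """
    rng = np.random.default_rng(seed)
    if label == "coil":
        cfg = _make_random_coil(ShapeSpec(kind="random_coil", n=int(rng.integers(700, 1100)),
                                          noise_sd=noise_sd, seed=int(rng.integers(2**31))))
    elif label == "sphere_filled":
        R = rng.uniform(8, 11)
        n = int(0.7 * 4 * math.pi / 3 * R**3)
        cfg = _make_filled_sphere(ShapeSpec(kind="filled_sphere", n=n, radius=R,
                                            noise_sd=noise_sd, seed=int(rng.integers(2**31))))
    elif label == "core_shell_dense":
        cfg = make_core_shell(core_radius=rng.uniform(6, 8.5),
                              corona_thickness=rng.uniform(4, 6),
                              seed=int(rng.integers(2**31)), noise_sd=noise_sd)
    elif label == "necklace":
        m = int(rng.integers(3, 6))
        rs = rng.uniform(3.0, 4.2)
        n = int(2 * 0.7 * m * 4 * math.pi / 3 * rs**3)
        cfg = _make_necklace(ShapeSpec(kind="necklace", n=n, n_spheres=m, sphere_radius=rs,
                                       noise_sd=noise_sd, seed=int(rng.integers(2**31))))
    elif label == "cylinder":
        a = rng.uniform(2.6, 3.4)
        L = rng.uniform(35, 55)
        n = int(1.0 * math.pi * a**2 * L)  # melt-like density of the collapsed core
        cfg = _make_cylinder(ShapeSpec(kind="cylinder", n=n, radius=a, length=L,
                                       noise_sd=noise_sd, seed=int(rng.integers(2**31))))
    elif label == "torus":
        R = rng.uniform(10, 12)
        r = rng.uniform(2.6, 3.2)
        n = int(1.0 * 2 * math.pi**2 * R * r**2)
        cfg = _make_torus(ShapeSpec(kind="torus", n=n, major_radius=R, minor_radius=r,
                                    noise_sd=noise_sd, seed=int(rng.integers(2**31))))
    elif label == "vesicle":
        cfg = _make_vesicle(ShapeSpec(kind="vesicle", n=4000,
                                      inner_radius=rng.uniform(5.5, 7.0),
                                      thickness=rng.uniform(3.0, 4.0),
                                      noise_sd=noise_sd, seed=int(rng.integers(2**31))))
    elif label == "perforated_vesicle":
        poly = ("tetrahedron", "cube", "octahedron")[int(rng.integers(3))]
        cfg = _make_vesicle(ShapeSpec(kind="vesicle", n=4000,
                                      inner_radius=rng.uniform(5.5, 7.0),
                                      thickness=rng.uniform(3.0, 4.0),
                                      pore_directions=poly,
                                      pore_angular_radius=rng.uniform(0.35, 0.45),
                                      noise_sd=noise_sd, seed=int(rng.integers(2**31))))
    elif label == "onion":
        cfg = make_onion(core_radius=rng.uniform(3.0, 4.2), p_layer=rng.uniform(2.2, 3.0),
                         wall=rng.uniform(2.8, 3.5), seed=int(rng.integers(2**31)),
                         noise_sd=noise_sd)
    elif label == "structured_solid":
        poly = ("tetrahedron", "cube")[int(rng.integers(2))]
        cfg = make_structured_solid(inner_radius=rng.uniform(3.2, 4.0),
                                    wall=rng.uniform(2.8, 3.4), pore_directions=poly,
                                    pore_angular_radius=rng.uniform(0.42, 0.5),
                                    seed=int(rng.integers(2**31)), noise_sd=noise_sd)
    else:
        raise ValueError(f"unknown morphology label {label!r}")
    if rotate:
        Rm = _random_rotation(rng)
        cfg.positions = cfg.positions @ Rm.T
    cfg.meta["label"] = label
    return cfg
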