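"""Snapshot and table I/O.

Two plain-text snapshot formats are supported:

* extended XYZ — one tag + coordinates per line; the tag encodes species and
  charge: ``HC`` (charged H, +1), ``H`` (nonionic H), ``PC`` (charged P,
  -1), ``P`` (nonionic P);
* the LAMMPS dump dialect ``id type q x y z`` with integer types
  1 = H charged, 2 = H nonionic, 3 = P charged, 4 = P nonionic.

Coordinates are written with 9 significant digits and round-trip bit-exactly
at that stored precision.  Tables are plain CSV via pandas with a stable
column order.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BeadConfiguration, type_codes_to_species

__all__ = ["write_snapshot", "read_snapshot", "write_table", "load_config_file"]

_XYZ_TAGS = {("H", 1): "HC", ("H", 0): "H", ("P", -1): "PC", ("P", 0): "P"}
_TAG_TO_SPECIES = {v: k for k, v in _XYZ_TAGS.items()}
_TYPE_CHARGE = {1: 1, 2: 0, 3: -1, 4: 0}


class SnapshotFormatError(ValueError):
    pass


def _detect_format(path: Path) -> str:
    return "lammps_dump" if path.suffix in (".dump", ".lammpstrj") else "xyz"


def write_snapshot(config: BeadConfiguration, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt == "xyz":
        _write_xyz(config, path)
    elif fmt == "lammps_dump":
        _write_dump(config, path)
    else:
        raise ValueError(f"unknown snapshot format {fmt!r}")


def read_snapshot(path, fmt: str | None = None) -> BeadConfiguration:
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "lammps_dump":
        return _read_dump(path)
    raise ValueError(f"unknown snapshot format {fmt!r}")


# -- extended XYZ -----------------------------------------------------------

def _write_xyz(config: BeadConfiguration, path: Path) -> None:
    meta = {k: v for k, v in config.meta.items()
            if isinstance(v, (int, float, str, bool))}
    if config.box_edge is not None:
        meta["box_edge"] = config.box_edge
    lines = [str(config.n), "ipec " + json.dumps(meta)]
    for (sp, q), (x, y, z) in zip(zip(config.chain, config.charge),
                                  config.positions):
        tag = _XYZ_TAGS[(sp, int(q))]
        lines.append(f"{tag} {x:.9g} {y:.9g} {z:.9g}")
    path.write_text("\n".join(lines) + "\n")


def _read_xyz(path: Path) -> BeadConfiguration:
    raw = path.read_text().splitlines()
    if not raw:
        raise SnapshotFormatError(f"{path}: empty file")
    try:
        n = int(raw[0].split()[0])
    except (ValueError, IndexError):
        raise SnapshotFormatError(f"{path}: line 1: expected bead count") from None
    meta = {}
    if len(raw) > 1 and raw[1].startswith("ipec "):
        try:
            meta = json.loads(raw[1][5:])
        except json.JSONDecodeError:
            meta = {}
    pos = np.empty((n, 3))
    chain = np.empty(n, dtype="<U1")
    charge = np.empty(n, dtype=np.int8)
    for i in range(n):
        lineno = i + 3
        if i + 2 >= len(raw):
            raise SnapshotFormatError(
                f"{path}: truncated after bead {i} (line {lineno - 1})"
            )
        parts = raw[i + 2].split()
        if len(parts) < 4 or parts[0] not in _TAG_TO_SPECIES:
            raise SnapshotFormatError(
                f"{path}: line {lineno}: bad record {raw[i + 2]!r}"
            )
        chain[i], charge[i] = _TAG_TO_SPECIES[parts[0]]
        pos[i] = [float(v) for v in parts[1:4]]
    box = meta.pop("box_edge", None)
    return BeadConfiguration(pos, chain, charge, box_edge=box, meta=meta)


# -- LAMMPS dump ------------------------------------------------------------

def _write_dump(config: BeadConfiguration, path: Path) -> None:
    L = config.box_edge if config.box_edge is not None else 0.0
    codes = config.type_codes
    lines = [
        "ITEM: TIMESTEP",
        str(int(config.meta.get("step", 0))),
        "ITEM: NUMBER OF ATOMS",
        str(config.n),
        "ITEM: BOX BOUNDS pp pp pp",
        f"0 {L:.9g}", f"0 {L:.9g}", f"0 {L:.9g}",
        "ITEM: ATOMS id type q x y z",
    ]
    for i, (code, q, (x, y, z)) in enumerate(
        zip(codes, config.charge, config.positions), start=1
    ):
        lines.append(f"{i} {code} {int(q)} {x:.9g} {y:.9g} {z:.9g}")
    path.write_text("\n".join(lines) + "\n")


def _read_dump(path: Path) -> BeadConfiguration:
    raw = path.read_text().splitlines()
    try:
        i_n = raw.index("ITEM: NUMBER OF ATOMS")
        n = int(raw[i_n + 1])
        i_atoms = next(i for i, ln in enumerate(raw)
                       if ln.startswith("ITEM: ATOMS"))
    except (ValueError, StopIteration, IndexError):
        raise SnapshotFormatError(f"{path}: not a LAMMPS dump") from None
    cols = raw[i_atoms].split()[2:]
    try:
        c_id = cols.index("id")
        c_type = cols.index("type")
        c_xyz = [cols.index(ax) for ax in "xyz"]
    except ValueError:
        raise SnapshotFormatError(
            f"{path}: dump needs id, type, x, y, z columns (got {cols})"
        ) from None
    c_q = cols.index("q") if "q" in cols else None
    if c_q is None:
        warnings.warn(f"{path}: no q column; charges inferred from type codes")
    pos = np.empty((n, 3))
    codes = np.empty(n, dtype=np.int64)
    charge = np.empty(n, dtype=np.int8)
    for i in range(n):
        lineno = i_atoms + 2 + i
        if i_atoms + 1 + i >= len(raw):
            raise SnapshotFormatError(
                f"{path}: truncated after atom {i} (line {lineno - 1})"
            )
        parts = raw[i_atoms + 1 + i].split()
        if len(parts) != len(cols):
            raise SnapshotFormatError(f"{path}: line {lineno}: bad record")
        idx = int(parts[c_id]) - 1
        if not 0 <= idx < n:
            raise SnapshotFormatError(f"{path}: line {lineno}: id out of range")
        code = int(parts[c_type])
        if code not in _TYPE_CHARGE:
            raise SnapshotFormatError(
                f"{path}: line {lineno}: unknown type code {code}"
            )
        codes[idx] = code
        charge[idx] = (int(float(parts[c_q])) if c_q is not None
                       else _TYPE_CHARGE[code])
        pos[idx] = [float(parts[c]) for c in c_xyz]
    chain, charge_from_type = type_codes_to_species(codes)
    if c_q is None:
        charge = charge_from_type
    box = None
    try:
        i_box = next(i for i, ln in enumerate(raw)
                     if ln.startswith("ITEM: BOX BOUNDS"))
        lo, hi = (float(v) for v in raw[i_box + 1].split()[:2])
        if hi > lo:
            box = hi - lo
    except (StopIteration, ValueError, IndexError):
        pass
    return BeadConfiguration(pos, chain, charge, box_edge=box)


# -- tables and configs -----------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_config_file(path) -> dict:
    """TOML or JSON run configuration."""
    path = Path(path)
    if path.suffix == ".json":
        return json.loads(path.read_text())
    import tomllib

    return tomllib.loads(path.read_text())
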