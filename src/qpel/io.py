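"""Readers/writers: extended-XYZ structures, CSV tables, JSON models, manifests.

Coordinates live in Angstrom on disk (XYZ convention) and nm internally;
conversion happens only at this boundary.  Tables are CSV with documented
headers (temperatures in K, energies kJ/mol, entropies J/(mol K));
fitted landscape parameters go to JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, StructureError
from .ringpolymer import RPParams, RPState
from .topology import Configuration, Topology, water_topology
from .units import ANGSTROM_PER_NM, NM_PER_ANGSTROM

THERMO_COLUMNS = ["T", "E", "E_IS", "E_vib", "S", "S_IS", "D"]


# ---------------------------------------------------------- extended XYZ
def write_xyz(path, config: Configuration, comment_extra: str = ""):
    """Write one frame of extended XYZ (Lattice in the comment line, Angstrom)."""
    L = config.box * ANGSTROM_PER_NM
    lattice = f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}"'
    lines = [str(config.topology.n_sites),
             f'{lattice} Properties=species:S:1:pos:R:3 {comment_extra}'.rstrip()]
    for sp, xyz in zip(config.topology.species, config.positions * ANGSTROM_PER_NM):
        lines.append(f"{sp} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path, isotope: str | None = None) -> Configuration:
    """Read one extended-XYZ frame back into a Configuration (nm internally)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ParseError("file too short for an XYZ frame", line=1)
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError("first line must be the atom count", line=1)
    if len(lines) < 2 + n:
        raise ParseError(f"expected {n} atom records", line=len(lines))
    comment = lines[1]
    if "Lattice=" not in comment:
        raise ParseError("comment line lacks Lattice=", line=2)
    lat = comment.split('Lattice="')[1].split('"')[0].split()
    cell = np.array(lat, dtype=float).reshape(3, 3)
    if not np.allclose(cell, np.diag(np.diag(cell))) or len(set(np.diag(cell))) != 1:
        raise ParseError("only cubic lattices are supported", line=2)
    L = cell[0, 0] * NM_PER_ANGSTROM
    species, pos = [], []
    for i, ln in enumerate(lines[2 : 2 + n]):
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError("atom record needs species + 3 coordinates", line=3 + i)
        species.append(parts[0])
        pos.append([float(p) for p in parts[1:4]])
    pos = np.array(pos) * NM_PER_ANGSTROM
    if n % 3:
        raise ParseError("site count is not a multiple of 3 (O,H1,H2 molecules)")
    if isotope is None:
        isotope = _guess_isotope(species)
    topo = water_topology(n // 3, isotope)
    return Configuration(pos, L, topo)


def _guess_isotope(species: list[str]) -> str:
    labels = set(species) - {"O"}
    for iso, lab in {"H2O": {"H"}, "D2O": {"D"}, "T2O": {"T"}, "HDO": {"H", "D"}}.items():
        if labels == lab:
            return iso
    raise ParseError(f"cannot infer isotopologue from species {sorted(labels)}")


def write_rpstate_xyz(path, state: RPState):
    """Extended XYZ with n_atoms*n_b rows plus atom/bead index columns."""
    if state.topology is None or state.box is None:
        raise StructureError("RPState lacks topology/box")
    L = state.box * ANGSTROM_PER_NM
    n_atoms, n_b = state.n_atoms, state.n_b
    lines = [
        str(n_atoms * n_b),
        f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}" '
        f"Properties=species:S:1:pos:R:3:atom:I:1:bead:I:1 n_b={n_b} T={state.params.T}",
    ]
    for a in range(n_atoms):
        sp = state.topology.species[a]
        for k in range(n_b):
            xyz = state.positions[k, a] * ANGSTROM_PER_NM
            lines.append(
                f"{sp} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f} {a} {k}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_rpstate_xyz(path, isotope: str | None = None) -> RPState:
    lines = Path(path).read_text().splitlines()
    n_rows = int(lines[0].split()[0])
    comment = lines[1]
    kv = dict(
        tok.split("=", 1) for tok in comment.split() if "=" in tok and '"' not in tok
    )
    if "n_b" not in kv or "T" not in kv:
        raise ParseError("ring-polymer XYZ needs n_b= and T= in the comment", line=2)
    n_b, T = int(kv["n_b"]), float(kv["T"])
    lat = comment.split('Lattice="')[1].split('"')[0].split()
    L = float(lat[0]) * NM_PER_ANGSTROM
    n_atoms = n_rows // n_b
    species = [None] * n_atoms
    pos = np.empty((n_b, n_atoms, 3))
    for i, ln in enumerate(lines[2 : 2 + n_rows]):
        parts = ln.split()
        if len(parts) < 6:
            raise ParseError("row needs species, xyz, atom, bead", line=3 + i)
        a, k = int(parts[4]), int(parts[5])
        species[a] = parts[0]
        pos[k, a] = [float(p) for p in parts[1:4]]
    pos *= NM_PER_ANGSTROM
    if isotope is None:
        isotope = _guess_isotope(species)
    topo = water_topology(n_atoms // 3, isotope)
    params = RPParams(n_b=n_b, T=T, masses=topo.masses)
    return RPState(pos, params, topo, L)


# ----------------------------------------------------------------- tables
def write_thermo_csv(path, df: pd.DataFrame):
    missing = [c for c in ("T",) if c not in df.columns]
    if missing:
        raise ParseError(f"thermo table lacks required columns {missing}")
    df.to_csv(path, index=False)


def read_thermo_csv(path, required=("T", "E", "E_IS")) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def write_model_json(path, model: dict):
    Path(path).write_text(json.dumps(_jsonable(model), indent=2, sort_keys=True))


def read_model_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


# --------------------------------------------------------------- manifest
MANIFEST_SCHEMA = {
    "required": ["config_hash", "seed", "stages", "outputs", "package_version"],
}


def config_hash(config: dict) -> str:
    payload = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def write_manifest(path, config: dict, seed: int, stages: list[str], outputs: dict):
    from . import __version__

    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "stages": stages,
        "outputs": _jsonable(outputs),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def validate_manifest(manifest: dict):
    missing = [k for k in MANIFEST_SCHEMA["required"] if k not in manifest]
    if missing:
        raise ParseError(f"manifest missing required keys {missing}")
    return True
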