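"""Molecular surfaces with per-vertex physical properties.

A surface is a triangulated mesh whose vertices carry, in addition to their
position, the two principal curvatures (kappa_max, kappa_min), an
electrostatic potential and a hydrophobicity value.  Pockets are subsets of
the vertex set of one surface and are the unit all downstream comparison
operates on.

File formats
------------
``surface-tsv``
    header line ``#protein <id> nv <N> nf <M>`` followed by N vertex lines
    ``v <id> <x> <y> <z> <kmax> <kmin> <pot> <hyd>`` and M face lines
    ``f <i> <j> <k>`` (whitespace separated, 0-based vertex indices).
``pockets``
    lines ``pocket <protein_id> <pocket_id> <comma-separated vertex ids>``.

Atom coordinates are read from standard PDB files via Biopython.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    MismatchError,
    ParseError,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Van der Waals radii in Angstrom, by element symbol (Bondi-style values).
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
}

#: Fallback radius for elements missing from the table, Angstrom.
DEFAULT_VDW_RADIUS = 1.7


@dataclass(frozen=True)
class SurfaceVertex:
    """One mesh vertex with its structural and physical properties."""

    id: int
    position: tuple[float, float, float]
    kappa_max: float  # maximum principal curvature, 1/A
    kappa_min: float  # minimum principal curvature, 1/A
    potential: float  # electrostatic potential, surface-source units
    hydrophobicity: float  # dimensionless scale value

    def __post_init__(self) -> None:
        vals = (*self.position, self.kappa_max, self.kappa_min,
                self.potential, self.hydrophobicity)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError(f"vertex {self.id}: non-finite value")
        if self.kappa_max < self.kappa_min:
            raise ValidationError(
                f"vertex {self.id}: kappa_max {self.kappa_max} < "
                f"kappa_min {self.kappa_min}")


@dataclass
class MolecularSurface:
    """Triangulated molecular surface of one protein."""

    protein_id: str
    vertices: list[SurfaceVertex]
    faces: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [v.id for v in self.vertices]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"{self.protein_id}: duplicate vertex ids")
        self._id_set = set(ids)
        if self.faces and len(self.vertices) < 3:
            raise ValidationError(
                f"{self.protein_id}: faces present but fewer than 3 vertices")
        for tri in self.faces:
            for idx in tri:
                if idx not in self._id_set:
                    raise ValidationError(
                        f"{self.protein_id}: face {tri} references missing "
                        f"vertex {idx}")

    @property
    def vertex_ids(self) -> set[int]:
        return self._id_set

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def positions(self) -> np.ndarray:
        """(n, 3) array of vertex positions in file order."""
        return np.array([v.position for v in self.vertices], dtype=float)


@dataclass
class AtomSet:
    """Atom coordinates with van der Waals radii, input to pocket scanning."""

    protein_id: str
    atoms: list[tuple[str, tuple[float, float, float], float]]

    def __post_init__(self) -> None:
        for elem, pos, radius in self.atoms:
            if radius <= 0:
                raise ValidationError(f"atom {elem}: non-positive radius")
            if not all(np.isfinite(c) for c in pos):
                raise ValidationError(f"atom {elem}: non-finite position")

    def positions(self) -> np.ndarray:
        return np.array([a[1] for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a[2] for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class Pocket:
    """A candidate interaction site: a vertex subset of one surface."""

    pocket_id: str
    protein_id: str
    vertex_ids: frozenset[int]
    size_rank: int = 0

    def __post_init__(self) -> None:
        if not self.vertex_ids:
            raise ValidationError(f"pocket {self.pocket_id}: empty vertex set")


# ---------------------------------------------------------------------------
# surface-tsv I/O


def read_surface(path: str | Path) -> MolecularSurface:
    """Read a molecular surface from a ``surface-tsv`` file.

    Vertex order is preserved from the file.  Raises :class:`ParseError`
    naming the line number on malformed rows and :class:`ValidationError`
    when a face references a missing vertex.
    """
    path = Path(path)
    vertices: list[SurfaceVertex] = []
    faces: list[tuple[int, int, int]] = []
    protein_id = path.stem
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            try:
                if parts[0] == "#protein":
                    protein_id = parts[1]
                elif parts[0] == "v":
                    vertices.append(SurfaceVertex(
                        id=int(parts[1]),
                        position=(float(parts[2]), float(parts[3]),
                                  float(parts[4])),
                        kappa_max=float(parts[5]),
                        kappa_min=float(parts[6]),
                        potential=float(parts[7]),
                        hydrophobicity=float(parts[8]),
                    ))
                elif parts[0] == "f":
                    faces.append((int(parts[1]), int(parts[2]),
                                  int(parts[3])))
                elif parts[0].startswith("#"):
                    continue
                else:
                    raise ParseError(
                        f"{path}:{lineno}: unknown record '{parts[0]}'")
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row "
                                 f"({exc})") from exc
    return MolecularSurface(protein_id=protein_id, vertices=vertices,
                            faces=faces)


def write_surface(surface: MolecularSurface, path: str | Path) -> None:
    """Write a surface in ``surface-tsv`` format (6 decimal places)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#protein {surface.protein_id} nv {len(surface.vertices)} "
                 f"nf {len(surface.faces)}\n")
        for v in surface.vertices:
            x, y, z = v.position
            fh.write(f"v {v.id} {x:.6f} {y:.6f} {z:.6f} "
                     f"{v.kappa_max:.6f} {v.kappa_min:.6f} "
                     f"{v.potential:.6f} {v.hydrophobicity:.6f}\n")
        for i, j, k in surface.faces:
            fh.write(f"f {i} {j} {k}\n")


# ---------------------------------------------------------------------------
# PDB atoms


def read_atoms(path: str | Path, include_hetero: bool = False) -> AtomSet:
    """Read atom coordinates from a PDB file.

    One atom is produced per ATOM record (plus HETATM records when
    ``include_hetero``); the van der Waals radius comes from
    :data:`VDW_RADII` with a 1.7 A fallback for unknown elements.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    atoms: list[tuple[str, tuple[float, float, float], float]] = []
    for atom in structure.get_atoms():
        hetfield = atom.get_parent().get_id()[0]
        if hetfield != " " and not include_hetero:
            continue
        elem = (atom.element or "").upper()
        radius = VDW_RADII.get(elem)
        if radius is None:
            log.warning("unknown element %r in %s: using fallback radius "
                        "%.2f A", elem, path, DEFAULT_VDW_RADIUS)
            radius = DEFAULT_VDW_RADIUS
        x, y, z = atom.coord
        atoms.append((elem, (float(x), float(y), float(z)), radius))
    if not atoms:
        raise EmptyInputError(f"{path}: no ATOM records")
    return AtomSet(protein_id=path.stem, atoms=atoms)


# ---------------------------------------------------------------------------
# pockets


def pocket_vertices(surface: MolecularSurface,
                    pocket: Pocket) -> list[SurfaceVertex]:
    """Vertices of ``pocket`` on ``surface``, in ascending id order."""
    if pocket.protein_id != surface.protein_id:
        raise MismatchError(
            f"pocket {pocket.pocket_id} belongs to {pocket.protein_id}, "
            f"not {surface.protein_id}")
    missing = pocket.vertex_ids - surface.vertex_ids
    if missing:
        raise MismatchError(
            f"pocket {pocket.pocket_id}: vertex ids {sorted(missing)} not "
            f"on surface {surface.protein_id}")
    by_id = {v.id: v for v in surface.vertices}
    return [by_id[i] for i in sorted(pocket.vertex_ids)]


def read_pockets(path: str | Path) -> list[Pocket]:
    """Read a pocket set file (``pocket <protein> <id> <v1,v2,...>``)."""
    pockets: list[Pocket] = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] != "pocket" or len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: malformed pocket row")
            vids = frozenset(int(t) for t in parts[3].split(","))
            pockets.append(Pocket(pocket_id=parts[2], protein_id=parts[1],
                                  vertex_ids=vids, size_rank=len(pockets) + 1))
    return pockets


def write_pockets(pockets: Iterable[Pocket], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for p in pockets:
            vids = ",".join(str(i) for i in sorted(p.vertex_ids))
            fh.write(f"pocket {p.protein_id} {p.pocket_id} {vids}\n")


def surfaces_equal(a: MolecularSurface, b: MolecularSurface,
                   tol: float = 1e-6) -> bool:
    """Structural equality of two surfaces up to float formatting."""
    if a.protein_id != b.protein_id or len(a.vertices) != len(b.vertices):
        return False
    if sorted(map(tuple, a.faces)) != sorted(map(tuple, b.faces)):
        return False
    for va, vb in zip(a.vertices, b.vertices):
        if va.id != vb.id:
            return False
        fa = (*va.position, va.kappa_max, va.kappa_min, va.potential,
              va.hydrophobicity)
        fb = (*vb.position, vb.kappa_max, vb.kappa_min, vb.potential,
              vb.hydrophobicity)
        if any(abs(x - y) > tol for x, y in zip(fa, fb)):
            return False
    return True
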