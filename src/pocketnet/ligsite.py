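"""Grid-based pocket detection (LIGSITE-style protein-solvent-protein scan).

The protein is embedded in a cubic grid; cells whose center falls within the
van der Waals radius of any atom are *protein*, the rest *solvent*.  Seven
scan directions (the three axes and the four cube diagonals) are swept; a
solvent cell scores one protein-solvent-protein (PSP) event per direction
along which protein occurs both before and after it.  Cells with enough PSP
events are clustered into connected components, and each component is mapped
to the surface vertices near its cells, yielding candidate pockets ranked by
component size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptyInputError, ValidationError
from .surface import AtomSet, MolecularSurface, Pocket

log = logging.getLogger(__name__)

#: The seven LIGSITE scan directions: x, y, z and the four cube diagonals.
SCAN_DIRECTIONS = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1),
)


@dataclass(frozen=True)
class PocketParams:
    """Tunable parameters of the pocket scan (lengths in Angstrom)."""

    spacing: float = 1.0          # grid cell edge
    margin: float = 4.0           # solvent padding around the atom bbox
    min_psp: int = 3              # PSP events required for a pocket cell
    connectivity: int = 26        # 6 (faces) or 26 (faces+edges+corners)
    min_cluster_cells: int = 5    # discard smaller components
    vertex_map_radius: float = 2.0  # cell-center -> surface-vertex radius
    max_pockets: int = 30         # keep the largest components only
    min_pocket_vertices: int = 10  # drop pockets mapping to fewer vertices

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.margin <= 0:
            raise ValidationError("spacing and margin must be positive")
        if not 1 <= self.min_psp <= 7:
            raise ValidationError("min_psp must be in [1, 7]")
        if self.connectivity not in (6, 26):
            raise ValidationError("connectivity must be 6 or 26")


@dataclass
class OccupancyGrid:
    """Boolean protein/solvent grid of cubic cells; cell (i,j,k) covers
    ``origin + spacing * [ijk, ijk+1)`` per axis, so its center sits at
    ``origin + spacing * (ijk + 0.5)``."""

    origin: np.ndarray
    spacing: float
    occupancy: np.ndarray  # bool, shape = dims

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    def cell_centers(self, cells: np.ndarray) -> np.ndarray:
        """(n, 3) centers of the given (n, 3) integer cell indices."""
        return self.origin + self.spacing * (
            np.asarray(cells, dtype=float) + 0.5)


@dataclass
class PSPGrid:
    """Per-cell PSP event counts (0..7); protein cells hold 0."""

    grid: OccupancyGrid
    counts: np.ndarray  # int, same shape as occupancy


def build_grid(atoms: AtomSet, params: PocketParams) -> OccupancyGrid:
    """Occupancy grid over the atom bounding box plus ``margin``.

    A cell is protein iff its center lies within the vdW radius of any atom.
    """
    if not atoms.atoms:
        raise EmptyInputError("empty atom set")
    pos = atoms.positions()
    rad = atoms.radii()
    lo = pos.min(axis=0) - params.margin
    hi = pos.max(axis=0) + params.margin
    dims = np.maximum(np.ceil((hi - lo) / params.spacing).astype(int), 1)
    # center the grid on the padded bounding box so coarse grids stay
    # symmetric around the atoms
    lo = (lo + hi) / 2 - dims * params.spacing / 2
    occ = np.zeros(tuple(dims), dtype=bool)
    # mark cells per atom within a local index window
    for p, r in zip(pos, rad):
        lo_idx = np.floor((p - r - lo) / params.spacing - 0.5).astype(int)
        hi_idx = np.ceil((p + r - lo) / params.spacing - 0.5).astype(int)
        lo_idx = np.clip(lo_idx, 0, dims - 1)
        hi_idx = np.clip(hi_idx, 0, dims - 1)
        ranges = [np.arange(a, b + 1) for a, b in zip(lo_idx, hi_idx)]
        ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
        centers = lo + params.spacing * (np.stack(
            [ii, jj, kk], axis=-1).astype(float) + 0.5)
        close = np.linalg.norm(centers - p, axis=-1) <= r
        occ[ii[close], jj[close], kk[close]] = True
    return OccupancyGrid(origin=lo, spacing=params.spacing, occupancy=occ)


def _shift(arr: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """Shift a 3-D boolean array by ``d`` cells, zero-filling the border."""
    out = np.zeros_like(arr)
    src = []
    dst = []
    for axis, step in enumerate(d):
        n = arr.shape[axis]
        step = min(max(step, -n), n)
        length = n - abs(step)
        if step >= 0:
            src.append(slice(0, length))
            dst.append(slice(step, step + length))
        else:
            src.append(slice(-step, -step + length))
            dst.append(slice(0, length))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _protein_ahead(occ: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """True where some protein cell lies strictly behind along direction d,
    i.e. ``out[c] = OR over t >= 1 of occ[c - t*d]``.

    Computed by doubling the shift distance, O(log L) passes over the grid.
    """
    # after each iteration `ahead` covers shifts t in [1, covered]
    ahead = _shift(occ, d)
    covered = 1
    max_extent = max(n for n, s in zip(occ.shape, d) if s != 0)
    while covered < max_extent:
        ahead = ahead | _shift(ahead, tuple(covered * s for s in d))
        covered *= 2
    return ahead


def scan_psp(grid: OccupancyGrid) -> PSPGrid:
    """Count, per solvent cell, the scan directions along which the cell is
    enclosed by protein on both sides (PSP events, at most 7)."""
    occ = grid.occupancy
    counts = np.zeros(occ.shape, dtype=np.int8)
    for d in SCAN_DIRECTIONS:
        before = _protein_ahead(occ, d)
        after = _protein_ahead(occ, tuple(-s for s in d))
        counts += (before & after & ~occ)
    return PSPGrid(grid=grid, counts=counts)


def cluster_pocket_cells(psp: PSPGrid,
                         params: PocketParams) -> list[np.ndarray]:
    """Connected components of solvent cells with count >= min_psp.

    Components smaller than ``min_cluster_cells`` are discarded; the rest
    are sorted by cell count descending, ties broken by the lexicographically
    smallest cell coordinate.  Each component is an (n, 3) integer array of
    cell indices in lexicographic order.
    """
    mask = (~psp.grid.occupancy) & (psp.counts >= params.min_psp)
    if params.connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    else:
        structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(mask, structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        cells = np.argwhere(labels == lab)
        if len(cells) < params.min_cluster_cells:
            continue
        order = np.lexsort((cells[:, 2], cells[:, 1], cells[:, 0]))
        clusters.append(cells[order])
    clusters.sort(key=lambda c: (-len(c), tuple(c[0])))
    return clusters


def extract_pockets(surface: MolecularSurface, atoms: AtomSet,
                    params: PocketParams | None = None) -> list[Pocket]:
    """Full pocket scan: grid, PSP sweep, clustering, vertex mapping.

    Each cluster becomes the set of surface vertices within
    ``vertex_map_radius`` of any of its cell centers; pockets mapping to
    fewer than ``min_pocket_vertices`` vertices are dropped and at most
    ``max_pockets`` are returned, ranked by cluster size.
    """
    if params is None:
        params = PocketParams()
    if surface.protein_id != atoms.protein_id:
        log.warning("surface %s and atoms %s have different protein ids",
                    surface.protein_id, atoms.protein_id)
    grid = build_grid(atoms, params)
    psp = scan_psp(grid)
    clusters = cluster_pocket_cells(psp, params)
    if not clusters:
        log.warning("%s: no pocket cells found", surface.protein_id)
        return []
    verts = surface.positions()
    ids = np.array([v.id for v in surface.vertices])
    tree = cKDTree(verts)
    pockets: list[Pocket] = []
    for cells in clusters:
        centers = grid.cell_centers(cells)
        near = set()
        for hits in tree.query_ball_point(centers, params.vertex_map_radius):
            near.update(hits)
        if len(near) < params.min_pocket_vertices:
            continue
        rank = len(pockets) + 1
        pockets.append(Pocket(
            pocket_id=f"{surface.protein_id}:p{rank}",
            protein_id=surface.protein_id,
            vertex_ids=frozenset(int(ids[i]) for i in near),
            size_rank=rank,
        ))
        if len(pockets) >= params.max_pockets:
            break
    if not pockets:
        log.warning("%s: no pockets above the size thresholds",
                    surface.protein_id)
    return pockets
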