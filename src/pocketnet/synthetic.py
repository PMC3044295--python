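"""Synthetic fixtures with the statistical structure the method assumes.

Real interaction sites are conjectured to share distinctive shape and
physical-property distributions among interacting (network-neighboring)
proteins, while the rest of the surface is unremarkable.  The generator
realizes that premise directly:

* every protein surface carries one *planted* site pocket whose vertex
  properties are drawn from its family's narrow Gaussian signature, plus
  decoy pockets drawn from broad background distributions (uniform over
  each histogram's range);
* a ``noise`` level in [0, 1] replaces each planted-site vertex by a
  background draw with that probability, so noise 0 is a clean signal and
  noise 1 makes the planted site statistically indistinguishable from a
  decoy;
* proteins of one family share a signature and are wired so that same-family
  proteins are predominantly within network distance two of each other —
  the guilt-by-association structure the predictor exploits.

A separate geometric fixture — a solid pseudo-atom sphere with a
hemispherical notch of known surface vertices — feeds the grid-scanning
pocket-extraction tests; the pipeline fixtures above bypass extraction by
constructing pocket memberships directly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull

from .clusters import DescriptorSet
from .errors import ConfigError, ValidationError
from .histograms import featurize_pocket
from .network import PPINetwork
from .surface import AtomSet, MolecularSurface, Pocket, SurfaceVertex

#: property ranges matching the four histogram specs
_KAPPA_LIM = 1.5     # keeps M in [-1.5, 1.5] and G in [-2.25, 2.25]
_POT_LIM = 0.6
_HYD_LIM = 5.0


@dataclass(frozen=True)
class SiteSignature:
    """Narrow per-property distributions of one family's planted site."""

    family_id: str
    mean_kmax: float
    mean_kmin: float
    mean_potential: float
    mean_hydrophobicity: float
    spread_kappa: float = 0.015
    spread_potential: float = 0.008
    spread_hydrophobicity: float = 0.1

    def __post_init__(self) -> None:
        if not (-_KAPPA_LIM <= self.mean_kmin <= self.mean_kmax
                <= _KAPPA_LIM):
            raise ValidationError("kappa means out of range or unordered")
        if abs(self.mean_potential) > _POT_LIM:
            raise ValidationError("potential mean out of range")
        if abs(self.mean_hydrophobicity) > _HYD_LIM:
            raise ValidationError("hydrophobicity mean out of range")
        if min(self.spread_kappa, self.spread_potential,
               self.spread_hydrophobicity) <= 0:
            raise ValidationError("spreads must be positive")


def default_signatures(n_families: int,
                       rng: np.random.Generator) -> list[SiteSignature]:
    """Well-separated signatures: means spaced across each property range."""
    sigs = []
    for f in range(n_families):
        frac = (f + 0.5) / n_families
        jit = rng.uniform(-0.05, 0.05, size=4)
        kmax = 0.4 + 0.9 * frac + jit[0]
        kmin = -1.3 + 0.9 * frac + jit[1]
        sigs.append(SiteSignature(
            family_id=f"F{f}",
            mean_kmax=float(np.clip(kmax, -_KAPPA_LIM, _KAPPA_LIM)),
            mean_kmin=float(np.clip(kmin, -_KAPPA_LIM, kmax)),
            mean_potential=float(-0.45 + 0.9 * frac + jit[2] * 0.2),
            mean_hydrophobicity=float(-4.0 + 8.0 * frac + jit[3] * 4),
        ))
    return sigs


@dataclass
class SyntheticDataset:
    """A complete in-memory study: surfaces, pockets, network and truth."""

    surfaces: dict[str, MolecularSurface]
    pockets: dict[str, list[Pocket]]
    network: PPINetwork
    truth: dict[str, str]              # protein -> true-site pocket id
    targets: list[str]
    families: dict[str, str]           # protein -> family id
    config: dict
    _descriptor_set: DescriptorSet | None = field(default=None, repr=False)

    def descriptor_set(self) -> DescriptorSet:
        """Featurize every pocket of every protein (cached)."""
        if self._descriptor_set is None:
            self._descriptor_set = DescriptorSet({
                prot: [featurize_pocket(self.surfaces[prot], p)
                       for p in self.pockets[prot]]
                for prot in self.surfaces
            })
        return self._descriptor_set


# ---------------------------------------------------------------------------
# single protein


def _background_properties(n: int, rng: np.random.Generator):
    """Uniform draws over each histogram's range; kappas sorted so
    kappa_max >= kappa_min."""
    kk = np.sort(rng.uniform(-_KAPPA_LIM, _KAPPA_LIM, size=(n, 2)), axis=1)
    return (kk[:, 1], kk[:, 0],
            rng.uniform(-_POT_LIM, _POT_LIM, size=n),
            rng.uniform(-_HYD_LIM, _HYD_LIM, size=n))


def _signature_properties(sig: SiteSignature, n: int, noise: float,
                          rng: np.random.Generator):
    """Signature Gaussians blended with background by ``noise``.

    Each vertex is independently replaced by a background draw with
    probability ``noise``, so noise 0 is the pure signature, noise 1 is
    exactly the background distribution, and intermediate levels thin the
    shared signal gradually.
    """
    kmax = rng.normal(sig.mean_kmax, sig.spread_kappa, size=n)
    kmin = rng.normal(sig.mean_kmin, sig.spread_kappa, size=n)
    pot = rng.normal(sig.mean_potential, sig.spread_potential, size=n)
    hyd = rng.normal(sig.mean_hydrophobicity, sig.spread_hydrophobicity,
                     size=n)
    lo, hi = np.minimum(kmax, kmin), np.maximum(kmax, kmin)
    kmax, kmin = hi, lo
    bmax, bmin, bpot, bhyd = _background_properties(n, rng)
    bg = rng.random(n) < noise
    return (np.where(bg, bmax, kmax), np.where(bg, bmin, kmin),
            np.where(bg, bpot, pot), np.where(bg, bhyd, hyd))


def make_protein(protein_id: str, signature: SiteSignature,
                 n_decoys: int = 29, noise: float = 0.0,
                 seed: int | np.random.Generator = 0,
                 n_vertices: int = 500, pocket_size: int = 10,
                 ) -> tuple[MolecularSurface, list[Pocket], str]:
    """One synthetic surface with a planted site and decoy pockets.

    The surface is a triangulated point sphere of ``n_vertices`` vertices;
    pockets are disjoint vertex blocks of ``pocket_size`` vertices, one
    drawn from the family signature (the planted site, at a random ordinal
    among the pockets) and the rest from the background.  Deterministic for
    a given seed.
    """
    if n_decoys < 0:
        raise ConfigError("n_decoys must be >= 0")
    if not 0.0 <= noise <= 1.0:
        raise ConfigError(f"noise {noise} outside [0, 1]")
    n_pockets = n_decoys + 1
    if n_pockets * pocket_size > n_vertices:
        raise ConfigError("too many pockets for the vertex budget")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    # geometry: points on a sphere; the hull triangulates all of them
    xyz = rng.normal(size=(n_vertices, 3))
    xyz *= 15.0 / np.linalg.norm(xyz, axis=1, keepdims=True)
    faces = [tuple(int(i) for i in s) for s in ConvexHull(xyz).simplices]

    kmax, kmin, pot, hyd = _background_properties(n_vertices, rng)
    true_ordinal = int(rng.integers(n_pockets))  # position among pockets
    pockets: list[Pocket] = []
    truth_id = ""
    for j in range(n_pockets):
        vids = range(j * pocket_size, (j + 1) * pocket_size)
        pid = f"{protein_id}:p{j + 1:02d}"
        if j == true_ordinal:
            sl = slice(j * pocket_size, (j + 1) * pocket_size)
            kmax[sl], kmin[sl], pot[sl], hyd[sl] = _signature_properties(
                signature, pocket_size, noise, rng)
            truth_id = pid
        pockets.append(Pocket(pocket_id=pid, protein_id=protein_id,
                              vertex_ids=frozenset(vids),
                              size_rank=j + 1))
    vertices = [
        SurfaceVertex(id=i, position=tuple(map(float, xyz[i])),
                      kappa_max=float(kmax[i]), kappa_min=float(kmin[i]),
                      potential=float(np.clip(pot[i], -_POT_LIM, _POT_LIM)),
                      hydrophobicity=float(np.clip(hyd[i], -_HYD_LIM,
                                                   _HYD_LIM)))
        for i in range(n_vertices)
    ]
    surface = MolecularSurface(protein_id=protein_id, vertices=vertices,
                               faces=faces)
    return surface, pockets, truth_id


# ---------------------------------------------------------------------------
# network-level dataset


def make_network(n_families: int = 2, proteins_per_family: int = 5,
                 n_targets: int = 0, edge_model: str = "community",
                 noise: float = 0.0, n_decoys: int = 29,
                 seed: int = 0, pocket_size: int = 10,
                 n_vertices: int = 500) -> SyntheticDataset:
    """A family-structured PPI network with planted interaction sites.

    Proteins of one family share a site signature.  Each family is wired as
    a star on its first member (so any two family members are within
    distance two) plus extra intra-family edges; family hubs form a path,
    keeping the graph connected.  The ``scale-free`` edge model adds
    degree-proportional extra edges across the whole graph instead of
    intra-family ones.  All proteins are annotated with their true site
    except the ``n_targets`` masked ones (chosen by the seed), whose truth
    is retained for evaluation.
    """
    total = n_families * proteins_per_family
    if proteins_per_family < 2:
        raise ConfigError("each family needs >= 2 proteins")
    if n_targets >= total:
        raise ConfigError("n_targets must be below the protein count")
    if edge_model not in ("community", "scale-free"):
        raise ConfigError(f"unknown edge model {edge_model!r}")
    rng = np.random.default_rng(seed)
    signatures = default_signatures(n_families, rng)

    surfaces: dict[str, MolecularSurface] = {}
    pockets: dict[str, list[Pocket]] = {}
    truth: dict[str, str] = {}
    families: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for f, sig in enumerate(signatures):
        fam = []
        for i in range(proteins_per_family):
            pid = f"F{f}P{i}"
            surf, pks, tr = make_protein(
                pid, sig, n_decoys=n_decoys, noise=noise, seed=rng,
                n_vertices=n_vertices, pocket_size=pocket_size)
            surfaces[pid], pockets[pid], truth[pid] = surf, pks, tr
            families[pid] = sig.family_id
            fam.append(pid)
        members[sig.family_id] = fam

    net = PPINetwork(proteins=surfaces)
    fam_lists = list(members.values())
    for fam in fam_lists:
        hub = fam[0]
        for other in fam[1:]:
            net.add_edge(hub, other)
        if edge_model == "community":
            # extra edges among interior members only: the last member
            # stays a plain leaf so it can serve as the family bridge
            for a, b in itertools.combinations(fam[1:-1], 2):
                if rng.random() < 0.3:
                    net.add_edge(a, b)
    # bridge consecutive families leaf-to-leaf: keeps the graph connected
    # while leaving each protein's distance-<=2 neighborhood dominated by
    # its own family (at most one cross-family pair anywhere)
    for fam_a, fam_b in zip(fam_lists, fam_lists[1:]):
        net.add_edge(fam_a[-1], fam_b[-1])
    if edge_model == "scale-free":
        all_prot = sorted(surfaces)
        n_extra = total  # sparse heavy-tail wiring
        for _ in range(n_extra):
            deg = np.array([net.graph.degree(p) + 1 for p in all_prot],
                           dtype=float)
            a = all_prot[int(rng.choice(len(all_prot), p=deg / deg.sum()))]
            b = all_prot[int(rng.integers(len(all_prot)))]
            if a != b:
                net.add_edge(a, b)

    all_prot = sorted(surfaces)
    targets = sorted(rng.choice(all_prot, size=n_targets, replace=False)
                     ) if n_targets else []
    targets = [str(t) for t in targets]
    for p in all_prot:
        if p not in targets:
            net.set_known_site(p, truth[p])

    config = dict(n_families=n_families,
                  proteins_per_family=proteins_per_family,
                  n_targets=n_targets, edge_model=edge_model, noise=noise,
                  n_decoys=n_decoys, seed=seed, pocket_size=pocket_size,
                  n_vertices=n_vertices)
    return SyntheticDataset(surfaces=surfaces, pockets=pockets, network=net,
                            truth=truth, targets=targets, families=families,
                            config=config)


def make_complement_dataset(seed: int = 0, noise: float = 0.0,
                            n_decoys: int = 29, pocket_size: int = 10,
                            n_vertices: int = 500) -> SyntheticDataset:
    """A dataset exercising the complement loop.

    On top of a 2-families-of-5 network, three unannotated targets of
    family F0 hang off the F0 hub in a chain ``hub - T3 - T2 - T1``: T3 and
    T2 can anchor on annotated proteins in round 0, but every annotated
    protein is at distance >= 3 from T1, so T1 only becomes predictable
    after its chain neighbors acquire assumed sites.
    """
    ds = make_network(n_families=2, proteins_per_family=5, n_targets=0,
                      noise=noise, n_decoys=n_decoys, seed=seed,
                      pocket_size=pocket_size, n_vertices=n_vertices)
    rng = np.random.default_rng(seed + 1_000_003)
    sig_f0 = default_signatures(2, np.random.default_rng(seed))[0]
    chain = ["F0T3", "F0T2", "F0T1"]
    for pid in chain:
        surf, pks, tr = make_protein(pid, sig_f0, n_decoys=n_decoys,
                                     noise=noise, seed=rng,
                                     n_vertices=n_vertices,
                                     pocket_size=pocket_size)
        ds.surfaces[pid], ds.pockets[pid], ds.truth[pid] = surf, pks, tr
        ds.families[pid] = sig_f0.family_id
        ds.network.graph.add_node(pid)
    ds.network.add_edge("F0P0", "F0T3")
    ds.network.add_edge("F0T3", "F0T2")
    ds.network.add_edge("F0T2", "F0T1")
    ds.targets = ["F0T1", "F0T2", "F0T3"]
    ds.config["chain_targets"] = list(ds.targets)
    ds._descriptor_set = None
    return ds


# ---------------------------------------------------------------------------
# geometric fixture for the grid scan


def make_notch_sphere(radius: float = 10.0, depth: float = 4.0,
                      seed: int = 0, atom_spacing: float = 1.5,
                      atom_radius: float = 1.7, n_surface: int = 600,
                      ) -> tuple[MolecularSurface, AtomSet, set[int]]:
    """Solid pseudo-atom ball with a hemispherical surface notch.

    Atoms fill a cubic lattice inside the sphere; those within ``depth`` of
    the notch center (the north pole) are removed, carving an invagination.
    Surface sample points lie on the outer sphere (outside the notch) and on
    the notch cavity wall; the cavity-wall vertex ids are the ground truth
    a pocket scan should recover.  ``depth`` 0 gives the convex control
    fixture with no cavity (and no notch vertices).
    """
    if not 0.0 <= depth < radius:
        raise ConfigError("need 0 <= depth < radius")
    rng = np.random.default_rng(seed)
    grid = np.arange(-radius, radius + atom_spacing / 2, atom_spacing)
    pts = np.array(np.meshgrid(grid, grid, grid,
                               indexing="ij")).reshape(3, -1).T
    inside = np.linalg.norm(pts, axis=1) <= radius
    pts = pts[inside]
    # carve center recessed below the pole: the invagination's mouth is
    # then narrower than its interior, so cavity cells are enclosed along
    # the diagonal scan directions as well as the horizontal axes
    carve = np.array([0.0, 0.0, radius - depth / 2])
    if depth > 0:
        pts = pts[np.linalg.norm(pts - carve, axis=1) > depth]
    atoms = AtomSet(protein_id="notch-sphere",
                    atoms=[("C", tuple(map(float, p)), atom_radius)
                           for p in pts])

    # surface samples: sphere shell (outside the notch) + cavity wall
    shell_r = radius + atom_radius - 0.5
    dirs = rng.normal(size=(n_surface, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    shell = shell_r * dirs
    shell = shell[np.linalg.norm(shell - carve, axis=1) > depth + 1.0]
    verts = [tuple(map(float, p)) for p in shell]
    notch_ids: set[int] = set()
    if depth > 0:
        # cavity wall = boundary of the carved void after vdW erosion
        wall_r = max(depth - atom_radius, depth / 2)
        n_wall = max(40, int(n_surface // 6))
        wdirs = rng.normal(size=(n_wall, 3))
        wdirs /= np.linalg.norm(wdirs, axis=1, keepdims=True)
        wdirs[:, 2] = -np.abs(wdirs[:, 2])  # wall points face into the ball
        wall = carve + wall_r * wdirs
        wall = wall[np.linalg.norm(wall, axis=1) <= radius]
        notch_ids = set(range(len(verts), len(verts) + len(wall)))
        verts.extend(tuple(map(float, p)) for p in wall)

    vertices = [SurfaceVertex(id=i, position=p, kappa_max=0.0, kappa_min=0.0,
                              potential=0.0, hydrophobicity=0.0)
                for i, p in enumerate(verts)]
    surface = MolecularSurface(protein_id="notch-sphere", vertices=vertices,
                               faces=[])
    return surface, atoms, notch_ids
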