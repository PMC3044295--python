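"""Neighboring-protein cluster extraction.

A *neighboring protein cluster* for a target is a subset ``ps`` of its
distance-<=2 neighbors, of size 2..k, containing at least one protein with a
known (or assumed) interaction site.  The subset's score is

    S_set(ps) = max { S_pkt(p^1, ..., p^n) : p^i a pocket of the i-th member }

i.e. the similarity of the most similar pocket combination across members.
Subsets whose rank (number of strictly better subsets) is below Z are kept
as clusters.

Search strategy
---------------
S_pkt can only shrink when a pocket is added to a combination, so a partial
combination's similarity is an upper bound on all of its extensions; the
pocket search is a depth-first scan pruned on that bound.  Likewise
``S_set`` over a superset of proteins never exceeds ``S_set`` over a subset,
so the best pair similarity between any two members bounds a subset's score;
subsets are processed in decreasing bound order and skipped once they can no
longer reach the top Z.  Pruning is exact: values, witnesses and ranks match
exhaustive enumeration.  Ties are broken deterministically (pocket ids, then
member-id tuples).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import EmptyInputError, NoAnchorError, ValidationError
from .histograms import PocketDescriptor
from .network import NeighborSet

@dataclass(frozen=True)
class ClusterParams:
    k: int = 4        # maximum subset cardinality
    Z: int = 1        # rank cutoff: keep subsets with rank < Z
    prune: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.Z < 1:
            raise ValidationError("Z must be >= 1")


@dataclass
class NeighborCluster:
    """One extracted cluster: its members, score and witness pockets."""

    members: tuple[str, ...]            # sorted protein ids
    s_set: float
    witness: dict[str, str]             # protein id -> pocket id of argmax
    rank: int = 0


@dataclass
class ClusterSet:
    clusters: list[NeighborCluster]

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self):
        return len(self.clusters)


class DescriptorSet:
    """Dense-matrix store of pocket descriptors for a set of proteins.

    Each protein's pockets are stacked into an (n_pockets, 1420) count
    matrix (the four histograms concatenated), with pockets in ascending
    pocket-id order.  Pairwise best-match similarities between proteins are
    cached; they depend only on the descriptors, so one cache serves every
    masking/round of an experiment.
    """

    def __init__(self,
                 descriptors: Mapping[str, Sequence[PocketDescriptor]]) -> None:
        self.pocket_ids: dict[str, list[str]] = {}
        self.matrices: dict[str, np.ndarray] = {}
        self._seg: np.ndarray | None = None   # segment start offsets
        self._nbins: int | None = None        # concatenated length
        for prot, descs in descriptors.items():
            descs = sorted(descs, key=lambda d: d.pocket_id)
            ids = [d.pocket_id for d in descs]
            if len(set(ids)) != len(ids):
                raise ValidationError(f"{prot}: duplicate pocket ids")
            if descs and self._seg is None:
                sizes = [h.spec.n_bins for h in descs[0].histograms]
                self._seg = np.cumsum([0] + sizes[:-1])
                self._nbins = sum(sizes)
            mat = np.zeros((len(descs), self._nbins or 0))
            for row, d in enumerate(descs):
                mat[row] = np.concatenate([h.counts for h in d.histograms])
            self.pocket_ids[prot] = ids
            self.matrices[prot] = mat
        self._pair_cache: dict[tuple[str, str], tuple[float, int, int]] = {}

    @property
    def proteins(self) -> list[str]:
        return sorted(self.matrices)

    def n_pockets(self, protein: str) -> int:
        return len(self.pocket_ids[protein])

    # -- similarity kernels ----------------------------------------------

    def _combo_value(self, run_min: np.ndarray, run_max: np.ndarray) -> float:
        mins = np.add.reduceat(run_min, self._seg)
        maxs = np.add.reduceat(run_max, self._seg)
        j = np.divide(mins, maxs, out=np.zeros(len(self._seg)),
                      where=maxs > 0)
        return float(j.prod())

    def _leaf_values(self, run_min: np.ndarray, run_max: np.ndarray,
                     mat: np.ndarray) -> np.ndarray:
        """S_pkt of (run combo + each row of ``mat``), vectorized."""
        mins = np.add.reduceat(np.minimum(run_min, mat), self._seg, axis=1)
        maxs = np.add.reduceat(np.maximum(run_max, mat), self._seg, axis=1)
        j = np.divide(mins, maxs, out=np.zeros_like(mins), where=maxs > 0)
        return j.prod(axis=1)

    def pair_best(self, a: str, b: str) -> tuple[float, int, int]:
        """Best pocket-pair similarity between proteins ``a`` and ``b``.

        Returns (value, row index in a, row index in b); the argmax is the
        lexicographically first by (a-pocket, b-pocket) id order.
        """
        key = (a, b) if a <= b else (b, a)
        hit = self._pair_cache.get(key)
        if hit is None:
            ma, mb = self.matrices[key[0]], self.matrices[key[1]]
            if len(ma) == 0 or len(mb) == 0:
                hit = (0.0, -1, -1)
            else:
                mins = np.minimum(ma[:, None, :], mb[None, :, :])
                maxs = np.maximum(ma[:, None, :], mb[None, :, :])
                smin = np.add.reduceat(mins, self._seg, axis=2)
                smax = np.add.reduceat(maxs, self._seg, axis=2)
                j = np.divide(smin, smax, out=np.zeros_like(smin),
                              where=smax > 0)
                s = j.prod(axis=2)
                flat = int(np.argmax(s))
                ia, ib = np.unravel_index(flat, s.shape)
                hit = (float(s[ia, ib]), int(ia), int(ib))
            self._pair_cache[key] = hit
        if (a, b) == key:
            return hit
        return (hit[0], hit[2], hit[1])


def subset_similarity(ds: DescriptorSet, proteins: Sequence[str],
                      prune: bool = True) -> tuple[float, dict[str, str]]:
    """S_set of a protein subset and one witness pocket combination.

    Maximizes S_pkt over the Cartesian product of the members' pockets by
    depth-first search; with ``prune`` the partial-combination bound cuts
    branches that cannot beat the incumbent (ties are never pruned, so the
    returned witness is the lexicographically first argmax either way).
    """
    members = sorted(proteins)
    for p in members:
        if p not in ds.matrices or ds.n_pockets(p) == 0:
            raise EmptyInputError(f"protein {p} has no pocket descriptors")
    mats = [ds.matrices[p] for p in members]
    best = -1.0
    best_combo: tuple[int, ...] | None = None

    def dfs(depth: int, run_min: np.ndarray, run_max: np.ndarray,
            combo: tuple[int, ...]) -> None:
        nonlocal best, best_combo
        if depth == len(members) - 1:
            vals = ds._leaf_values(run_min, run_max, mats[depth])
            i = int(np.argmax(vals))
            if vals[i] > best:
                best = float(vals[i])
                best_combo = combo + (i,)
            return
        for i, row in enumerate(mats[depth]):
            new_min = np.minimum(run_min, row)
            new_max = np.maximum(run_max, row)
            if prune and ds._combo_value(new_min, new_max) < best:
                continue
            dfs(depth + 1, new_min, new_max, combo + (i,))

    if len(members) == 1:
        vals = ds._leaf_values(
            np.full(ds._nbins, np.inf), np.zeros(ds._nbins), mats[0])
        i = int(np.argmax(vals))
        best, best_combo = float(vals[i]), (i,)
    else:
        first = mats[0]
        for i, row in enumerate(first):
            dfs(1, row.copy(), row.copy(), (i,))
    witness = {p: ds.pocket_ids[p][j] for p, j in zip(members, best_combo)}
    return best, witness


def max_combo_with_target(ds: DescriptorSet, members: Sequence[str],
                          target: str,
                          prune: bool = True) -> tuple[float, list[str]]:
    """Maximize S_pkt over member-pocket x target-pocket combinations.

    Returns the maximum and *all* target pocket ids that appear in some
    maximizing combination (the pockets Eq-style voting credits).
    """
    members = sorted(members)
    for p in (*members, target):
        if p not in ds.matrices or ds.n_pockets(p) == 0:
            raise EmptyInputError(f"protein {p} has no pocket descriptors")
    mats = [ds.matrices[p] for p in members]
    tmat = ds.matrices[target]
    best = -1.0
    best_targets: set[int] = set()

    def dfs(depth: int, run_min: np.ndarray, run_max: np.ndarray) -> None:
        nonlocal best, best_targets
        if depth == len(members):
            vals = ds._leaf_values(run_min, run_max, tmat)
            vmax = float(vals.max())
            if vmax > best:
                best = vmax
                best_targets = set(np.nonzero(vals == vmax)[0])
            elif vmax == best:
                best_targets |= set(np.nonzero(vals == best)[0])
            return
        for row in mats[depth]:
            new_min = np.minimum(run_min, row)
            new_max = np.maximum(run_max, row)
            if prune and ds._combo_value(new_min, new_max) < best:
                continue
            dfs(depth + 1, new_min, new_max)

    dfs(0, np.full(ds._nbins, np.inf), np.zeros(ds._nbins))
    ids = ds.pocket_ids[target]
    return best, sorted(ids[i] for i in best_targets)


def count_candidate_subsets(n_members: int, n_annotated: int, k: int) -> int:
    """Number of subsets of size 2..k intersecting the annotated set,
    by inclusion-exclusion: sum_n C(m, n) - C(m - a, n)."""
    if n_annotated > n_members:
        raise ValidationError("n_annotated exceeds n_members")
    free = n_members - n_annotated
    return sum(math.comb(n_members, n) - math.comb(free, n)
               for n in range(2, k + 1))


def enumerate_clusters(nbrs: NeighborSet, ds: DescriptorSet,
                       params: ClusterParams | None = None) -> ClusterSet:
    """Score every anchored subset of the neighbor set and keep the top Z.

    A subset qualifies when 2 <= |ps| <= k and it contains at least one
    annotated protein; the returned clusters are those whose rank — the
    number of subsets with strictly larger S_set — is below Z, so ties at
    the boundary are all included.  Raises :class:`NoAnchorError` when the
    neighborhood has no annotated protein at all.
    """
    if params is None:
        params = ClusterParams()
    anchors = set(nbrs.annotated)
    if not anchors:
        raise NoAnchorError(f"target {nbrs.target}: no annotated neighbor")
    members = sorted(nbrs.members)
    subsets = [combo
               for size in range(2, params.k + 1)
               for combo in itertools.combinations(members, size)
               if anchors.intersection(combo)]
    expected = count_candidate_subsets(len(members), len(anchors), params.k)
    assert len(subsets) == expected, "enumeration count mismatch"

    def pair_bound(combo: tuple[str, ...]) -> float:
        return min(ds.pair_best(a, b)[0]
                   for a, b in itertools.combinations(combo, 2))

    if params.prune:
        order = sorted(subsets, key=lambda c: (-pair_bound(c), c))
    else:
        order = sorted(subsets)

    scored: list[tuple[float, tuple[str, ...], dict[str, str]]] = []
    for combo in order:
        if params.prune:
            bound = pair_bound(combo)
            n_better = sum(1 for s, _, _ in scored if s > bound)
            if n_better >= params.Z:
                break  # bounds only decrease from here on
        if len(combo) == 2:
            val, ia, ib = ds.pair_best(combo[0], combo[1])
            witness = {combo[0]: ds.pocket_ids[combo[0]][ia],
                       combo[1]: ds.pocket_ids[combo[1]][ib]}
        else:
            val, witness = subset_similarity(ds, combo, prune=params.prune)
        scored.append((val, combo, witness))

    clusters = []
    for val, combo, witness in scored:
        rank = sum(1 for s, _, _ in scored if s > val)
        if rank < params.Z:
            assert 2 <= len(combo) <= params.k and anchors.intersection(combo)
            clusters.append(NeighborCluster(members=combo, s_set=val,
                                            witness=witness, rank=rank))
    clusters.sort(key=lambda c: (-c.s_set, c.members))
    return ClusterSet(clusters=clusters)


def write_cluster_report(cs: ClusterSet, fh) -> None:
    fh.write("members\ts_set\twitness\trank\n")
    for c in cs:
        wit = ",".join(f"{p}={c.witness[p]}" for p in c.members)
        fh.write(f"{'+'.join(c.members)}\t{c.s_set:.6g}\t{wit}\t{c.rank}\n")
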