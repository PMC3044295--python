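"""Independent brute-force oracles the optimized code paths are checked
against.  Deliberately naive: per-bin python loops, full Cartesian products,
no pruning, no vectorization."""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np

from pocketnet.histograms import PocketDescriptor


def naive_histogram_similarity(count_rows: Sequence[Sequence[float]]) -> float:
    """Generalized Jaccard by an explicit per-bin loop."""
    num = 0.0
    den = 0.0
    for bins in zip(*count_rows):
        num += min(bins)
        den += max(bins)
    return num / den if den > 0 else 0.0


def naive_pocket_similarity(descs: Sequence[PocketDescriptor]) -> float:
    s = 1.0
    for i in range(4):
        s *= naive_histogram_similarity(
            [list(d.histograms[i].counts) for d in descs])
    return s


def brute_subset_similarity(
        pockets: Mapping[str, Sequence[PocketDescriptor]],
        proteins: Sequence[str]) -> tuple[float, dict[str, str]]:
    """Exhaustive max of S_pkt over the pocket Cartesian product.

    Proteins in sorted order, pockets in ascending id order, first argmax
    kept — the same lexicographic tie-break the optimized search promises.
    """
    members = sorted(proteins)
    pocket_lists = [sorted(pockets[p], key=lambda d: d.pocket_id)
                    for p in members]
    best = -1.0
    witness: dict[str, str] = {}
    for combo in itertools.product(*pocket_lists):
        s = naive_pocket_similarity(combo)
        if s > best:
            best = s
            witness = {p: d.pocket_id for p, d in zip(members, combo)}
    return best, witness


def brute_enumerate_clusters(
        pockets: Mapping[str, Sequence[PocketDescriptor]],
        members: Sequence[str], annotated: Sequence[str],
        k: int, Z: int):
    """No-pruning cluster extraction: score every anchored subset, compute
    strict ranks, keep rank < Z.  Returns [(members, s_set, witness, rank)]
    sorted like the production code."""
    anchors = set(annotated)
    subsets = [c for n in range(2, k + 1)
               for c in itertools.combinations(sorted(members), n)
               if anchors.intersection(c)]
    scored = [(brute_subset_similarity(pockets, c), c) for c in subsets]
    out = []
    for (val, wit), combo in scored:
        rank = sum(1 for (v, _), _ in scored if v > val)
        if rank < Z:
            out.append((combo, val, wit, rank))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def brute_psp_counts(occ: np.ndarray) -> np.ndarray:
    """Per-cell, per-direction enclosure check by explicit line walking."""
    dirs = [(1, 0, 0), (0, 1, 0), (0, 0, 1),
            (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1)]
    nx, ny, nz = occ.shape
    counts = np.zeros(occ.shape, dtype=int)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if occ[x, y, z]:
                    continue
                for d in dirs:
                    if (_hits_protein(occ, (x, y, z), d)
                            and _hits_protein(occ, (x, y, z),
                                              tuple(-s for s in d))):
                        counts[x, y, z] += 1
    return counts


def _hits_protein(occ, start, d) -> bool:
    x, y, z = start
    while True:
        x, y, z = x + d[0], y + d[1], z + d[2]
        if not (0 <= x < occ.shape[0] and 0 <= y < occ.shape[1]
                and 0 <= z < occ.shape[2]):
            return False
        if occ[x, y, z]:
            return True
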