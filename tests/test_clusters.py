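"""Cluster extraction: subset scoring, enumeration, counting, pruning."""

import numpy as np
import pytest

from conftest import random_tiny_descriptor, tiny_descriptor
from _oracles import brute_enumerate_clusters, brute_subset_similarity
from pocketnet.clusters import (
    ClusterParams,
    DescriptorSet,
    count_candidate_subsets,
    enumerate_clusters,
    max_combo_with_target,
    subset_similarity,
)
from pocketnet.errors import EmptyInputError, NoAnchorError, ValidationError
from pocketnet.network import NeighborSet


def _random_instance(seed, n_proteins=None, max_pockets=4):
    rng = np.random.default_rng(seed)
    n = n_proteins or int(rng.integers(2, 5))
    pockets = {}
    for i in range(n):
        prot = f"P{i}"
        pockets[prot] = [random_tiny_descriptor(f"{prot}:p{j}", rng)
                         for j in range(int(rng.integers(1,
                                                         max_pockets + 1)))]
    return pockets


def test_identical_single_pockets_score_one():
    d = tiny_descriptor("A:p1", [[1, 0, 2, 0, 0], [1, 1, 0, 0], [2, 0, 0],
                                 [1, 0, 1]])
    e = tiny_descriptor("B:p1", [[1, 0, 2, 0, 0], [1, 1, 0, 0], [2, 0, 0],
                                 [1, 0, 1]])
    ds = DescriptorSet({"A": [d], "B": [e]})
    val, witness = subset_similarity(ds, ["A", "B"])
    assert val == pytest.approx(1.0)
    assert witness == {"A": "A:p1", "B": "B:p1"}


@pytest.mark.parametrize("seed", range(40))
def test_subset_similarity_equals_brute_force(seed):
    pockets = _random_instance(seed)
    ds = DescriptorSet(pockets)
    proteins = sorted(pockets)
    want_val, want_wit = brute_subset_similarity(pockets, proteins)
    for prune in (True, False):
        val, wit = subset_similarity(ds, proteins, prune=prune)
        assert val == pytest.approx(want_val)
        assert wit == want_wit


def test_member_without_pockets_rejected():
    ds = DescriptorSet({"A": [], "B": [random_tiny_descriptor(
        "B:p1", np.random.default_rng(0))]})
    with pytest.raises(EmptyInputError):
        subset_similarity(ds, ["A", "B"])


@pytest.mark.parametrize("args,expected", [
    ((6, 2, 4), 39),   # (15-6) + (20-4) + (15-1)
    ((3, 3, 3), 4),    # every size-2,3 subset hits the annotated set
    ((4, 0, 3), 0),
    ((10, 10, 4), 45 + 120 + 210),
])
def test_count_candidate_subsets(args, expected):
    assert count_candidate_subsets(*args) == expected


def test_count_candidate_subsets_validates():
    with pytest.raises(ValidationError):
        count_candidate_subsets(3, 5, 4)


def _neighbor_set(members, annotated, target="T"):
    return NeighborSet(target=target, members=frozenset(members),
                       annotated=frozenset(annotated))


@pytest.mark.parametrize("seed", range(25))
def test_enumeration_matches_no_pruning_oracle(seed):
    rng = np.random.default_rng(seed + 500)
    n = int(rng.integers(3, 7))
    pockets = {f"P{i}": [random_tiny_descriptor(f"P{i}:p{j}", rng)
                         for j in range(int(rng.integers(1, 6)))]
               for i in range(n)}
    members = sorted(pockets)
    n_annot = int(rng.integers(1, n + 1))
    annotated = members[:n_annot]
    k = int(rng.integers(2, 5))
    Z = int(rng.integers(1, 4))
    ds = DescriptorSet(pockets)
    nbrs = _neighbor_set(members, annotated)
    want = brute_enumerate_clusters(pockets, members, annotated, k, Z)
    for prune in (True, False):
        got = enumerate_clusters(nbrs, ds,
                                 ClusterParams(k=k, Z=Z, prune=prune))
        assert [(c.members, c.rank) for c in got] \
            == [(w[0], w[3]) for w in want]
        for c, w in zip(got, want):
            assert c.s_set == pytest.approx(w[1])
            assert c.witness == w[2]


def test_fig_style_enumeration_six_neighbors_two_annotated():
    rng = np.random.default_rng(7)
    pockets = {f"P{i}": [random_tiny_descriptor(f"P{i}:p{j}", rng)
                         for j in range(3)] for i in range(6)}
    members = sorted(pockets)
    nbrs = _neighbor_set(members, members[:2])
    got = enumerate_clusters(nbrs, DescriptorSet(pockets),
                             ClusterParams(k=4, Z=1, prune=False))
    # of the 39 qualifying subsets only the top-similarity one(s) survive
    assert count_candidate_subsets(6, 2, 4) == 39
    assert len(got) >= 1
    top = got.clusters[0]
    assert 2 <= len(top.members) <= 4
    assert set(top.members) & set(members[:2])
    assert top.rank == 0


def test_no_anchor_condition_is_distinct():
    rng = np.random.default_rng(1)
    pockets = {f"P{i}": [random_tiny_descriptor(f"P{i}:p0", rng)]
               for i in range(3)}
    nbrs = _neighbor_set(sorted(pockets), [])
    with pytest.raises(NoAnchorError):
        enumerate_clusters(nbrs, DescriptorSet(pockets))


def test_boundary_ties_all_returned():
    d = [[2, 0, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0], [1, 0, 0]]
    pockets = {p: [tiny_descriptor(f"{p}:p1", d)] for p in "ABC"}
    ds = DescriptorSet(pockets)
    nbrs = _neighbor_set(["A", "B", "C"], ["A", "B", "C"])
    got = enumerate_clusters(nbrs, ds, ClusterParams(k=2, Z=1))
    # all three pairs are identical-score: rank 0 for each, all kept
    assert len(got) == 3
    assert [c.members for c in got] == [("A", "B"), ("A", "C"), ("B", "C")]


def test_max_combo_with_target_reports_all_tied_winners():
    base = [[1, 0, 1, 0, 0], [1, 1, 0, 0], [1, 0, 0], [1, 0, 0]]
    far = [[0, 0, 0, 0, 1], [0, 0, 0, 1], [0, 0, 1], [0, 0, 1]]
    pockets = {
        "A": [tiny_descriptor("A:p1", base)],
        "T": [tiny_descriptor("T:p1", far), tiny_descriptor("T:p2", base),
              tiny_descriptor("T:p3", base)],
    }
    ds = DescriptorSet(pockets)
    val, winners = max_combo_with_target(ds, ["A"], "T")
    assert val == pytest.approx(1.0)
    assert winners == ["T:p2", "T:p3"]


@pytest.mark.parametrize("seed", range(10))
def test_max_combo_prune_consistency(seed):
    rng = np.random.default_rng(seed + 900)
    pockets = {f"P{i}": [random_tiny_descriptor(f"P{i}:p{j}", rng)
                         for j in range(3)] for i in range(3)}
    pockets["T"] = [random_tiny_descriptor(f"T:p{j}", rng)
                    for j in range(4)]
    ds = DescriptorSet(pockets)
    a = max_combo_with_target(ds, ["P0", "P1", "P2"], "T", prune=True)
    b = max_combo_with_target(ds, ["P0", "P1", "P2"], "T", prune=False)
    assert a[0] == pytest.approx(b[0])
    assert a[1] == b[1]
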