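"""Voting, single-pass prediction, and the iterative complement loop."""

import numpy as np
import pytest

from conftest import tiny_descriptor
from pocketnet.clusters import ClusterParams, ClusterSet, DescriptorSet, \
    NeighborCluster
from pocketnet.network import PPINetwork
from pocketnet.predict import (
    IterationParams,
    predict_iterative,
    predict_once,
    vote_pockets,
)

# base patterns over the tiny specs; X/Y disjoint, Z overlaps both
_X = [[1, 0, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0], [1, 0, 0]]
_Y = [[0, 1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0], [1, 0, 0]]
_Z = [[1, 1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0], [1, 0, 0]]
_W = [[0, 0, 0, 0, 2], [0, 0, 0, 2], [0, 0, 2], [0, 0, 2]]


def _decoy(i):
    """Protein-specific decoy: weight split so no two proteins' decoys
    coincide (a shared decoy would act as a universal pocket)."""
    return [[0, 0, 0, i, 9 - i], [0, 0, i, 9 - i], [0, i, 9 - i],
            [0, i, 9 - i]]


def _cluster(members, s_set=1.0):
    return NeighborCluster(members=tuple(sorted(members)), s_set=s_set,
                           witness={})


def test_vote_single_maximizer():
    ds = DescriptorSet({
        "A": [tiny_descriptor("A:p1", _X)],
        "B": [tiny_descriptor("B:p1", _X)],
        "T": [tiny_descriptor("T:p1", _W), tiny_descriptor("T:p3", _X)],
    })
    res = vote_pockets(ds, "T", ClusterSet([_cluster(["A", "B"])]))
    assert res.status == "predicted"
    assert [(s.pocket_id, s.votes) for s in res.ranking] == [("T:p3", 1)]
    assert res.ranking[0].best_similarity == pytest.approx(1.0)


def test_vote_tie_gives_both_pockets_one_vote():
    ds = DescriptorSet({
        "A": [tiny_descriptor("A:p1", _X)],
        "B": [tiny_descriptor("B:p1", _X)],
        "C": [tiny_descriptor("C:p1", _Z)],
        "T": [tiny_descriptor("T:p3", _X), tiny_descriptor("T:p7", _Y)],
    })
    # cluster {A,B} matches only p3 exactly; singleton C ties p3 with p7
    res = vote_pockets(ds, "T", ClusterSet([_cluster(["A", "B"]),
                                            _cluster(["C"])]))
    assert [(s.pocket_id, s.votes) for s in res.ranking] \
        == [("T:p3", 2), ("T:p7", 1)]


def test_vote_statuses():
    ds = DescriptorSet({"A": [tiny_descriptor("A:p1", _X)], "T": []})
    assert vote_pockets(ds, "T", ClusterSet([_cluster(["A"])])).status \
        == "no-pockets"
    ds2 = DescriptorSet({"T": [tiny_descriptor("T:p1", _X)]})
    assert vote_pockets(ds2, "T", ClusterSet([])).status == "no-anchor"


def _family_ds(extra=None):
    """A/B carry pattern X sites; decoys W.  Optional extra proteins."""
    prots = {
        "A": [tiny_descriptor("A:p1", _X), tiny_descriptor("A:p2",
                                                           _decoy(1))],
        "B": [tiny_descriptor("B:p1", _X), tiny_descriptor("B:p2",
                                                           _decoy(2))],
        "T1": [tiny_descriptor("T1:p1", _decoy(3)),
               tiny_descriptor("T1:p2", _X)],
        "T2": [tiny_descriptor("T2:p1", _X),
               tiny_descriptor("T2:p2", _decoy(4))],
    }
    prots.update(extra or {})
    return DescriptorSet(prots)


def test_predict_once_anchor_reachability():
    # chain T1 - A(known) - T2: both targets anchored in round 0
    net = PPINetwork(edges=[("T1", "A"), ("A", "T2"), ("A", "B")])
    net.set_known_site("A", "A:p1")
    net.set_known_site("B", "B:p1")
    ds = _family_ds()
    out = predict_once(net, ds, targets=["T1", "T2"])
    assert out["T1"].status == "predicted"
    assert out["T2"].status == "predicted"
    assert out["T1"].top(1) == ["T1:p2"]  # the planted X pocket wins
    assert out["T2"].top(1) == ["T2:p1"]


def test_predict_once_no_anchor_beyond_distance_two():
    # T1 - T2 - B - A(known): A is at distance 3 from T1
    net = PPINetwork(edges=[("T1", "T2"), ("T2", "B"), ("B", "A")])
    net.set_known_site("A", "A:p1")
    ds = _family_ds(extra={"B": [tiny_descriptor("B:p1", _X)]})
    out = predict_once(net, ds, targets=["T1", "T2"])
    assert out["T1"].status == "no-anchor"
    assert out["T2"].status == "predicted"


def test_iterative_complement_promotes_and_rescues():
    # round 0: T1 sees no annotation; after T2's site is assumed, T1 anchors
    net = PPINetwork(edges=[("T1", "T2"), ("T2", "B"), ("B", "A")])
    net.set_known_site("A", "A:p1")
    ds = _family_ds(extra={"B": [tiny_descriptor("B:p1", _X)]})
    rounds = predict_iterative(net, ds, targets=["T1", "T2"])
    assert rounds[0]["T1"].status == "no-anchor"
    assert rounds[1]["T1"].status == "predicted"
    assert rounds[1]["T1"].top(1) == ["T1:p2"]
    # complement property: once predicted, predicted in all later rounds
    for r in sorted(rounds)[1:]:
        assert rounds[r]["T1"].status == "predicted"
    # promotions stay internal: the caller's network is untouched
    assert net.assumed_sites == {}


def test_iterative_all_unreachable_terminates():
    net = PPINetwork(edges=[("T1", "T2")])
    ds = _family_ds()
    params = IterationParams(max_rounds=3, stop_on_fixpoint=False)
    rounds = predict_iterative(net, ds, iter_params=params,
                               targets=["T1", "T2"])
    assert sorted(rounds) == [0, 1, 2]
    assert all(rounds[r][t].status == "no-anchor"
               for r in rounds for t in ("T1", "T2"))


def test_fixpoint_stops_after_repeat_round():
    net = PPINetwork(edges=[("T1", "T2"), ("T2", "B"), ("B", "A")])
    net.set_known_site("A", "A:p1")
    ds = _family_ds(extra={"B": [tiny_descriptor("B:p1", _X)]})
    rounds = predict_iterative(
        net, ds, iter_params=IterationParams(max_rounds=5),
        targets=["T1", "T2"])
    # the loop stops as soon as one round reproduces the one before it,
    # well before the max_rounds cap
    rs = sorted(rounds)
    assert len(rs) < 5
    last, prev = rs[-1], rs[-2]
    for t in ("T1", "T2"):
        assert rounds[prev][t].signature() == rounds[last][t].signature()


def test_prediction_is_deterministic():
    net = PPINetwork(edges=[("T1", "A"), ("A", "B"), ("A", "T2")])
    net.set_known_site("A", "A:p1")
    net.set_known_site("B", "B:p1")
    ds = _family_ds()
    r1 = predict_iterative(net, ds, targets=["T1", "T2"])
    r2 = predict_iterative(net, ds, targets=["T1", "T2"])
    assert {r: {t: r1[r][t].signature() for t in r1[r]} for r in r1} \
        == {r: {t: r2[r][t].signature() for t in r2[r]} for r in r2}


def test_votes_bounded_and_pockets_belong_to_target():
    net = PPINetwork(edges=[("T1", "A"), ("A", "B")])
    net.set_known_site("A", "A:p1")
    net.set_known_site("B", "B:p1")
    ds = _family_ds()
    out = predict_once(net, ds, ClusterParams(Z=3), targets=["T1"])
    res = out["T1"]
    n_clusters_max = 3  # at most Z ranks of clusters plus boundary ties
    target_pockets = set(ds.pocket_ids["T1"])
    for s in res.ranking:
        assert s.pocket_id in target_pockets
        assert 1 <= s.votes
    assert sum(s.votes for s in res.ranking) \
        <= (n_clusters_max + 3) * len(target_pockets)
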