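"""Pocket voting and the iterative complement/feedback prediction loop.

Each extracted neighbor cluster casts votes: the combination of one pocket
per cluster member plus one target pocket is maximized over all choices, and
every target pocket appearing in some maximizing combination receives one
vote from that cluster (at most one vote per cluster per pocket).  Pockets
are ranked by votes, then by the best similarity they achieved, then by id.

The iterative loop re-runs prediction after promoting each predicted
target's top pocket to an *assumed* interaction site.  This complements
targets that initially had no annotated neighbor (their neighbors may now
carry assumed sites) and feeds back revised clusters for everyone else.
A target's own assumed site is never visible to its own prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .clusters import (
    ClusterParams,
    ClusterSet,
    DescriptorSet,
    enumerate_clusters,
    max_combo_with_target,
)
from .errors import NoAnchorError, ValidationError
from .network import PPINetwork, neighbors_within_two, promote_assumed

log = logging.getLogger(__name__)


@dataclass
class PocketScore:
    pocket_id: str
    votes: int
    best_similarity: float


@dataclass
class PredictionResult:
    """Ranked pockets of one target in one round."""

    target: str
    ranking: list[PocketScore]
    round: int = 0
    status: str = "predicted"  # predicted | no-anchor | no-pockets

    def top(self, n: int) -> list[str]:
        return [ps.pocket_id for ps in self.ranking[:n]]

    def signature(self) -> tuple:
        """Hashable content for fixpoint comparison between rounds."""
        return (self.status, tuple((p.pocket_id, p.votes, p.best_similarity)
                                   for p in self.ranking))


@dataclass(frozen=True)
class IterationParams:
    max_rounds: int = 3       # total rounds recorded, including round 0
    promote_top: int = 1
    stop_on_fixpoint: bool = True

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValidationError("max_rounds must be >= 1")


def vote_pockets(ds: DescriptorSet, target: str,
                 clusters: ClusterSet, round_no: int = 0,
                 prune: bool = True) -> PredictionResult:
    """Accumulate cluster votes over the target's pockets and rank them."""
    if target not in ds.matrices or ds.n_pockets(target) == 0:
        return PredictionResult(target=target, ranking=[], round=round_no,
                                status="no-pockets")
    if len(clusters) == 0:
        return PredictionResult(target=target, ranking=[], round=round_no,
                                status="no-anchor")
    votes: dict[str, int] = {}
    best: dict[str, float] = {}
    for cluster in clusters:
        value, winners = max_combo_with_target(ds, cluster.members, target,
                                               prune=prune)
        for pid in winners:
            votes[pid] = votes.get(pid, 0) + 1
            best[pid] = max(best.get(pid, 0.0), value)
    ranking = sorted(
        (PocketScore(pid, votes[pid], best[pid]) for pid in votes),
        key=lambda s: (-s.votes, -s.best_similarity, s.pocket_id))
    return PredictionResult(target=target, ranking=ranking, round=round_no,
                            status="predicted")


def predict_once(net: PPINetwork, ds: DescriptorSet,
                 cluster_params: ClusterParams | None = None,
                 targets: Sequence[str] | None = None,
                 round_no: int = 0) -> dict[str, PredictionResult]:
    """One prediction pass over the given targets.

    Targets default to every protein without a known site.  A target whose
    distance-<=2 neighborhood has no annotated protein gets status
    ``no-anchor``; one without pockets gets ``no-pockets``.
    """
    if cluster_params is None:
        cluster_params = ClusterParams()
    if targets is None:
        targets = sorted(p for p in net.proteins if p not in net.known_sites)
    out: dict[str, PredictionResult] = {}
    for target in targets:
        if target not in ds.matrices or ds.n_pockets(target) == 0:
            out[target] = PredictionResult(target=target, ranking=[],
                                           round=round_no,
                                           status="no-pockets")
            continue
        nbrs = neighbors_within_two(net, target)
        usable = frozenset(p for p in nbrs.members if p in ds.matrices
                           and ds.n_pockets(p) > 0)
        nbrs = type(nbrs)(target=target, members=usable,
                          annotated=nbrs.annotated & usable)
        try:
            clusters = enumerate_clusters(nbrs, ds, cluster_params)
        except NoAnchorError:
            out[target] = PredictionResult(target=target, ranking=[],
                                           round=round_no,
                                           status="no-anchor")
            continue
        out[target] = vote_pockets(ds, target, clusters, round_no=round_no,
                                   prune=cluster_params.prune)
    return out


def predict_iterative(
        net: PPINetwork, ds: DescriptorSet,
        cluster_params: ClusterParams | None = None,
        iter_params: IterationParams | None = None,
        targets: Sequence[str] | None = None,
) -> dict[int, dict[str, PredictionResult]]:
    """Repeated prediction with promotion of predicted sites.

    Round 0 is a plain pass; before each later round every predicted
    target's top pocket is promoted to an assumed site (overwriting any
    earlier assumption — latest round wins) and all targets are re-predicted
    from scratch against the augmented annotations.  Stops after
    ``max_rounds`` recorded rounds, or earlier when a round reproduces the
    previous round's rankings exactly.
    """
    if iter_params is None:
        iter_params = IterationParams()
    work = net.copy()  # promotions stay internal to this call
    if targets is None:
        targets = sorted(p for p in work.proteins
                         if p not in work.known_sites)
    rounds: dict[int, dict[str, PredictionResult]] = {}
    rounds[0] = predict_once(work, ds, cluster_params, targets, round_no=0)
    for r in range(1, iter_params.max_rounds):
        for target, res in rounds[r - 1].items():
            if res.status == "predicted" and res.ranking:
                for pid in res.top(iter_params.promote_top):
                    promote_assumed(work, target, pid)
        rounds[r] = predict_once(work, ds, cluster_params, targets,
                                 round_no=r)
        if iter_params.stop_on_fixpoint:
            prev, cur = rounds[r - 1], rounds[r]
            if all(prev[t].signature() == cur[t].signature()
                   for t in targets):
                break
    return rounds


def structure_only_ranking(ds: DescriptorSet, target: str,
                           annotated: Iterable[str],
                           prune: bool = True) -> PredictionResult:
    """Structure-only baseline: no network, no clusters.

    Every annotated protein in the dataset acts alone: its best-matching
    target pockets (by max S_pkt over its pockets x target pockets) each
    receive one vote.  Network topology is ignored entirely.
    """
    voters = sorted(p for p in annotated
                    if p != target and p in ds.matrices
                    and ds.n_pockets(p) > 0)
    if target not in ds.matrices or ds.n_pockets(target) == 0:
        return PredictionResult(target=target, ranking=[],
                                status="no-pockets")
    if not voters:
        return PredictionResult(target=target, ranking=[],
                                status="no-anchor")
    votes: dict[str, int] = {}
    best: dict[str, float] = {}
    for p in voters:
        value, winners = max_combo_with_target(ds, [p], target, prune=prune)
        for pid in winners:
            votes[pid] = votes.get(pid, 0) + 1
            best[pid] = max(best.get(pid, 0.0), value)
    ranking = sorted(
        (PocketScore(pid, votes[pid], best[pid]) for pid in votes),
        key=lambda s: (-s.votes, -s.best_similarity, s.pocket_id))
    return PredictionResult(target=target, ranking=ranking,
                            status="predicted")


def write_prediction_report(rounds: dict[int, dict[str, PredictionResult]],
                            fh) -> None:
    fh.write("round\ttarget\trank\tpocket_id\tvotes\tbest_similarity\t"
             "status\n")
    for r in sorted(rounds):
        for target in sorted(rounds[r]):
            res = rounds[r][target]
            if not res.ranking:
                fh.write(f"{r}\t{target}\t-\t-\t-\t-\t{res.status}\n")
            for i, ps in enumerate(res.ranking, start=1):
                fh.write(f"{r}\t{target}\t{i}\t{ps.pocket_id}\t{ps.votes}\t"
                         f"{ps.best_similarity:.6g}\t{res.status}\n")
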