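"""Protein-protein interaction network with interaction-site annotations.

The graph is undirected and unweighted (a :class:`networkx.Graph` underneath).
Each protein may carry at most one interaction-site annotation: either a
*known* site (experimental ground truth) or an *assumed* site assigned by the
prediction feedback loop.  Neighborhoods are taken at shortest-path distance
at most two from a target, the radius within which guilt-by-association is
applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .errors import ConflictError, LookupError_, ValidationError

log = logging.getLogger(__name__)


@dataclass
class NeighborSet:
    """Distance-<=2 neighborhood of a target protein.

    ``members`` is the neighbor set P; ``annotated`` is the subset S of
    members carrying a known or assumed interaction site.
    """

    target: str
    members: frozenset[str]
    annotated: frozenset[str]

    def __post_init__(self) -> None:
        if self.target in self.members:
            raise ValidationError("target may not be its own neighbor")
        if not self.annotated <= self.members:
            raise ValidationError("annotated proteins must be members")


class PPINetwork:
    """Undirected PPI graph plus known/assumed interaction-site maps."""

    def __init__(self, edges: Iterable[tuple[str, str]] = (),
                 proteins: Iterable[str] = ()) -> None:
        self.graph = nx.Graph()
        self.graph.add_nodes_from(proteins)
        for u, v in edges:
            self.add_edge(u, v)
        self.known_sites: dict[str, str] = {}
        self.assumed_sites: dict[str, str] = {}

    # -- construction -----------------------------------------------------

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            log.warning("self-loop %s-%s rejected", u, v)
            return
        self.graph.add_edge(u, v)

    def set_known_site(self, protein: str, pocket_id: str) -> None:
        if protein not in self.graph:
            raise ValidationError(f"annotation for unknown protein {protein}")
        if protein in self.assumed_sites:
            raise ConflictError(
                f"{protein} already has an assumed site; a protein never "
                f"carries both a known and an assumed site")
        self.known_sites[protein] = pocket_id

    @property
    def proteins(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def copy(self) -> "PPINetwork":
        out = PPINetwork()
        out.graph = self.graph.copy()
        out.known_sites = dict(self.known_sites)
        out.assumed_sites = dict(self.assumed_sites)
        return out

    def masked(self, targets: Iterable[str]) -> "PPINetwork":
        """Copy with the known sites of ``targets`` removed (leave-n-out)."""
        out = self.copy()
        for t in targets:
            out.known_sites.pop(t, None)
        out.assumed_sites = {}
        return out

    def site_of(self, protein: str) -> str | None:
        """Known site if present, else assumed site, else None."""
        return self.known_sites.get(protein,
                                    self.assumed_sites.get(protein))


def neighbors_within_two(net: PPINetwork, target: str) -> NeighborSet:
    """All proteins at shortest-path distance 1 or 2 from ``target``.

    The annotated subset contains members with a known or assumed site; the
    target itself is excluded from its own neighborhood, so its own assumed
    site can never feed back into its own prediction.
    """
    if target not in net.graph:
        raise LookupError_(f"unknown protein {target}")
    dist = nx.single_source_shortest_path_length(net.graph, target, cutoff=2)
    members = frozenset(p for p, d in dist.items() if 0 < d <= 2)
    annotated = frozenset(
        p for p in members
        if p in net.known_sites or p in net.assumed_sites)
    return NeighborSet(target=target, members=members, annotated=annotated)


def promote_assumed(net: PPINetwork, protein: str,
                    pocket_id: str) -> PPINetwork:
    """Record a predicted pocket as the assumed interaction site.

    A protein with a known site cannot receive an assumed one; re-promotion
    in a later round overwrites the earlier assumed site (latest wins).
    Mutates and returns ``net``.
    """
    if protein in net.known_sites:
        raise ConflictError(f"{protein} already has a known site")
    if protein not in net.graph:
        raise LookupError_(f"unknown protein {protein}")
    net.assumed_sites[protein] = pocket_id
    return net


def read_network(edge_path: str | Path,
                 annotation_path: str | Path | None = None) -> PPINetwork:
    """Read an edge list (two ids per line, ``#`` comments) and optionally
    an annotation file with ``site <protein_id> <pocket_id>`` lines."""
    net = PPINetwork()
    with Path(edge_path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValidationError(f"bad edge line: {line!r}")
            net.graph.add_node(parts[0])
            net.graph.add_node(parts[1])
            net.add_edge(parts[0], parts[1])
    if annotation_path is not None:
        with Path(annotation_path).open() as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 3 or parts[0] != "site":
                    raise ValidationError(f"bad annotation line: {line!r}")
                net.set_known_site(parts[1], parts[2])
    return net


def write_network(net: PPINetwork, edge_path: str | Path,
                  annotation_path: str | Path | None = None) -> None:
    with Path(edge_path).open("w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u} {v}\n")
    if annotation_path is not None:
        with Path(annotation_path).open("w") as fh:
            for p in sorted(net.known_sites):
                fh.write(f"site {p} {net.known_sites[p]}\n")
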