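"""Generator contracts: determinism, planted-signal margin, masking,
network structure."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pocketnet.clusters import DescriptorSet
from pocketnet.errors import ConfigError
from pocketnet.histograms import featurize_pocket
from pocketnet.network import neighbors_within_two
from pocketnet.similarity import pocket_similarity
from pocketnet.surface import pocket_vertices, surfaces_equal
from pocketnet.synthetic import (
    default_signatures,
    make_complement_dataset,
    make_network,
    make_notch_sphere,
    make_protein,
)


def _sig(seed=0):
    return default_signatures(1, np.random.default_rng(seed))[0]


def test_make_protein_deterministic():
    s1, p1, t1 = make_protein("P", _sig(), n_decoys=5, seed=11)
    s2, p2, t2 = make_protein("P", _sig(), n_decoys=5, seed=11)
    assert t1 == t2
    assert surfaces_equal(s1, s2)
    assert [(p.pocket_id, p.vertex_ids) for p in p1] \
        == [(p.pocket_id, p.vertex_ids) for p in p2]


def test_make_protein_validates_inputs():
    with pytest.raises(ConfigError):
        make_protein("P", _sig(), noise=1.5)
    with pytest.raises(ConfigError):
        make_protein("P", _sig(), n_decoys=-1)
    with pytest.raises(ConfigError):
        make_protein("P", _sig(), n_decoys=100, n_vertices=100)


def test_planted_site_margin_at_zero_noise():
    """True-site pockets of two same-family proteins are more similar to
    each other than any true/decoy or decoy/decoy pair across them."""
    sig = _sig(3)
    sa, pa, ta = make_protein("A", sig, n_decoys=8, noise=0.0, seed=1)
    sb, pb, tb = make_protein("B", sig, n_decoys=8, noise=0.0, seed=2)
    da = {p.pocket_id: featurize_pocket(sa, p) for p in pa}
    db = {p.pocket_id: featurize_pocket(sb, p) for p in pb}
    true_sim = pocket_similarity([da[ta], db[tb]])
    others = max(pocket_similarity([da[i], db[j]])
                 for i in da for j in db if (i, j) != (ta, tb))
    assert true_sim > others


def test_noise_one_site_indistinguishable_from_background():
    """At noise 1 a two-sample test cannot separate site vertices from
    decoy vertices on any property (alpha = 0.01)."""
    sig = _sig(5)
    surf, pockets, truth = make_protein("P", sig, n_decoys=29, noise=1.0,
                                        seed=7)
    true_pocket = next(p for p in pockets if p.pocket_id == truth)
    site = pocket_vertices(surf, true_pocket)
    decoy_ids = set().union(*(p.vertex_ids for p in pockets
                              if p.pocket_id != truth))
    decoys = [v for v in surf.vertices if v.id in decoy_ids]
    for attr in ("kappa_max", "kappa_min", "potential", "hydrophobicity"):
        a = [getattr(v, attr) for v in site]
        b = [getattr(v, attr) for v in decoys]
        assert stats.ks_2samp(a, b).pvalue > 0.01


def test_generated_values_respect_invariants():
    surf, pockets, _ = make_protein("P", _sig(1), n_decoys=10, noise=0.3,
                                    seed=3)
    for v in surf.vertices:  # construction enforces these, spot-check anyway
        assert v.kappa_max >= v.kappa_min
        assert -0.6 <= v.potential <= 0.6
        assert -5.0 <= v.hydrophobicity <= 5.0
    ids = {p.pocket_id for p in pockets}
    assert len(ids) == len(pockets) == 11


def test_network_every_protein_near_samefamily_annotation():
    ds = make_network(n_families=2, proteins_per_family=5, n_targets=1,
                      n_decoys=4, seed=9)
    assert len(ds.targets) == 1
    for tgt in ds.targets:
        nbrs = neighbors_within_two(ds.network.masked(ds.targets), tgt)
        fam = ds.families[tgt]
        assert any(ds.families[p] == fam for p in nbrs.annotated)


def test_network_masking_and_truth_bookkeeping():
    ds = make_network(n_families=2, proteins_per_family=3, n_targets=2,
                      n_decoys=3, seed=4)
    assert set(ds.truth) == set(ds.surfaces)
    for t in ds.targets:
        assert t not in ds.network.known_sites
        assert ds.truth[t] in {p.pocket_id for p in ds.pockets[t]}
    annotated = set(ds.network.known_sites)
    assert annotated == set(ds.surfaces) - set(ds.targets)


def test_network_dataset_deterministic_and_connected():
    import networkx as nx
    d1 = make_network(seed=5, n_decoys=3)
    d2 = make_network(seed=5, n_decoys=3)
    assert d1.network.edges == d2.network.edges
    assert d1.truth == d2.truth
    assert nx.is_connected(d1.network.graph)


def test_scale_free_model_keeps_family_contract():
    ds = make_network(edge_model="scale-free", n_targets=1, n_decoys=3,
                      seed=2)
    tgt = ds.targets[0]
    nbrs = neighbors_within_two(ds.network, tgt)
    assert any(ds.families[p] == ds.families[tgt] for p in nbrs.annotated)


def test_config_errors():
    with pytest.raises(ConfigError):
        make_network(proteins_per_family=1)
    with pytest.raises(ConfigError):
        make_network(n_families=2, proteins_per_family=2, n_targets=4)
    with pytest.raises(ConfigError):
        make_network(edge_model="ring")


def test_complement_dataset_round_zero_anchor_structure():
    ds = make_complement_dataset(seed=1, n_decoys=4)
    net = ds.network
    nbrs_t1 = neighbors_within_two(net, "F0T1")
    assert not nbrs_t1.annotated  # T1 cannot anchor in round 0
    assert neighbors_within_two(net, "F0T2").annotated
    assert neighbors_within_two(net, "F0T3").annotated


def test_notch_sphere_deterministic_and_validated():
    a = make_notch_sphere(10, 4, seed=3)
    b = make_notch_sphere(10, 4, seed=3)
    assert surfaces_equal(a[0], b[0])
    assert a[2] == b[2]
    with pytest.raises(ConfigError):
        make_notch_sphere(10, 12, seed=0)
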