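"""Shared fixtures: tiny surfaces, compact descriptor builders."""

from __future__ import annotations

import numpy as np
import pytest

from pocketnet.histograms import Histogram, HistogramSpec, PocketDescriptor
from pocketnet.surface import MolecularSurface, Pocket, SurfaceVertex

# Compact four-histogram layout for combinatorial tests: same structure as
# the canonical M/G/C/H specs but few bins, so naive oracles stay cheap.
TINY_SPECS = (
    HistogramSpec("M", 0.0, 5.0, 1.0),
    HistogramSpec("G", 0.0, 4.0, 1.0),
    HistogramSpec("C", 0.0, 3.0, 1.0),
    HistogramSpec("H", 0.0, 3.0, 1.0),
)


def tiny_descriptor(pocket_id: str, counts) -> PocketDescriptor:
    """Descriptor from four raw count arrays over the TINY_SPECS bins."""
    hists = [Histogram(spec=s, counts=np.asarray(c, dtype=float))
             for s, c in zip(TINY_SPECS, counts)]
    return PocketDescriptor(pocket_id=pocket_id, hist_M=hists[0],
                            hist_G=hists[1], hist_C=hists[2],
                            hist_H=hists[3])


def random_tiny_descriptor(pocket_id: str,
                           rng: np.random.Generator) -> PocketDescriptor:
    counts = [rng.integers(0, 4, size=s.n_bins) for s in TINY_SPECS]
    return tiny_descriptor(pocket_id, counts)


@pytest.fixture
def square_surface() -> MolecularSurface:
    """Four vertices, two faces; simple distinct property values."""
    verts = [
        SurfaceVertex(0, (0.0, 0.0, 0.0), 1.0, -0.5, 0.1, 2.0),
        SurfaceVertex(1, (1.0, 0.0, 0.0), 0.0, 0.0, -0.2, -1.0),
        SurfaceVertex(2, (0.0, 1.0, 0.0), 0.5, 0.5, 0.3, 0.0),
        SurfaceVertex(3, (1.0, 1.0, 0.0), -1.0, -2.0, -0.55, 4.5),
    ]
    return MolecularSurface(protein_id="toy", vertices=verts,
                            faces=[(0, 1, 2), (1, 2, 3)])


@pytest.fixture
def square_pocket() -> Pocket:
    return Pocket(pocket_id="toy:p1", protein_id="toy",
                  vertex_ids=frozenset({0, 2}), size_rank=1)
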