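"""Fixed-bin property histograms describing a pocket.

A pocket is summarized by four histograms over its vertices:

* ``M`` — mean curvature, (kappa_max + kappa_min) / 2, range [-3, 3], bin 0.01
* ``G`` — Gaussian curvature, kappa_max * kappa_min, range [-3, 3], bin 0.01
* ``C`` — electrostatic potential, range [-0.6, 0.6], bin 0.01
* ``H`` — hydrophobicity, range [-5, 5], bin 0.1

Bins are half-open ``[low, high)`` except the final bin, which is closed.
Out-of-range values are clamped into the edge bins so that every histogram's
total count equals the pocket's vertex count (mass conservation) — the
similarity denominator then reflects pocket size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError, ValidationError
from .surface import MolecularSurface, Pocket, pocket_vertices


@dataclass(frozen=True)
class HistogramSpec:
    """Binning rule for one property: [vmin, vmax] split into bins of width d."""

    name: str
    vmin: float
    vmax: float
    d: float

    def __post_init__(self) -> None:
        if self.vmax <= self.vmin or self.d <= 0:
            raise ValidationError(f"bad histogram spec {self.name}")

    @property
    def n_bins(self) -> int:
        return int(round((self.vmax - self.vmin) / self.d))


M_SPEC = HistogramSpec("M", -3.0, 3.0, 0.01)   # 600 bins
G_SPEC = HistogramSpec("G", -3.0, 3.0, 0.01)   # 600 bins
C_SPEC = HistogramSpec("C", -0.6, 0.6, 0.01)   # 120 bins
H_SPEC = HistogramSpec("H", -5.0, 5.0, 0.1)    # 100 bins

CANONICAL_SPECS = {"M": M_SPEC, "G": G_SPEC, "C": C_SPEC, "H": H_SPEC}


@dataclass
class Histogram:
    spec: HistogramSpec
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.spec.n_bins,):
            raise ValidationError(
                f"histogram {self.spec.name}: expected {self.spec.n_bins} "
                f"bins, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValidationError("negative histogram count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class PocketDescriptor:
    """The four histograms (M, G, C, H) of one pocket."""

    pocket_id: str
    hist_M: Histogram
    hist_G: Histogram
    hist_C: Histogram
    hist_H: Histogram

    @property
    def histograms(self) -> tuple[Histogram, Histogram, Histogram, Histogram]:
        return (self.hist_M, self.hist_G, self.hist_C, self.hist_H)


def mean_curvature(kappa_max, kappa_min):
    """M = (kappa_max + kappa_min) / 2."""
    return (np.asarray(kappa_max) + np.asarray(kappa_min)) / 2.0


def gaussian_curvature(kappa_max, kappa_min):
    """G = kappa_max * kappa_min."""
    return np.asarray(kappa_max) * np.asarray(kappa_min)


def bin_index(value: float, spec: HistogramSpec) -> int:
    """Bin of ``value``: floor((value - vmin)/d), clamped into range."""
    if not np.isfinite(value):
        raise ValidationError(f"non-finite value {value!r}")
    idx = int(np.floor((value - spec.vmin) / spec.d))
    return min(max(idx, 0), spec.n_bins - 1)


def bin_indices(values: np.ndarray, spec: HistogramSpec) -> np.ndarray:
    """Vectorized :func:`bin_index`."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite property value")
    idx = np.floor((values - spec.vmin) / spec.d).astype(int)
    return np.clip(idx, 0, spec.n_bins - 1)


def _histogram(values: np.ndarray, spec: HistogramSpec,
               normalize: bool) -> Histogram:
    counts = np.bincount(bin_indices(values, spec),
                         minlength=spec.n_bins).astype(float)
    if normalize and counts.sum() > 0:
        counts = counts / counts.sum()
    return Histogram(spec=spec, counts=counts)


def featurize_pocket(surface: MolecularSurface, pocket: Pocket,
                     normalize: bool = False) -> PocketDescriptor:
    """Build the four-histogram descriptor of a pocket.

    With ``normalize`` (off by default) each histogram is divided by the
    vertex count, making pockets of different sizes comparable as
    frequency distributions instead of raw counts.
    """
    verts = pocket_vertices(surface, pocket)
    if not verts:
        raise EmptyInputError(f"pocket {pocket.pocket_id} is empty")
    kmax = np.array([v.kappa_max for v in verts])
    kmin = np.array([v.kappa_min for v in verts])
    pot = np.array([v.potential for v in verts])
    hyd = np.array([v.hydrophobicity for v in verts])
    return PocketDescriptor(
        pocket_id=pocket.pocket_id,
        hist_M=_histogram(mean_curvature(kmax, kmin), M_SPEC, normalize),
        hist_G=_histogram(gaussian_curvature(kmax, kmin), G_SPEC, normalize),
        hist_C=_histogram(pot, C_SPEC, normalize),
        hist_H=_histogram(hyd, H_SPEC, normalize),
    )


def write_descriptor(desc: PocketDescriptor, fh) -> None:
    """Sparse text dump: one ``(<hist> <bin> <count>)`` line per nonzero bin."""
    fh.write(f"descriptor {desc.pocket_id}\n")
    for hist in desc.histograms:
        for k in np.nonzero(hist.counts)[0]:
            fh.write(f"{hist.spec.name} {int(k)} {hist.counts[k]:g}\n")
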