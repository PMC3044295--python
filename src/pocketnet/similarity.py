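"""N-way histogram and pocket similarity.

The similarity of N histograms sharing one bin spec is the generalized
(multi-way) Jaccard coefficient

    J(A_1, ..., A_N) = sum_k min_i(a_ik) / sum_k max_i(a_ik)

where ``a_ik`` is the count in bin k of histogram i; when every histogram is
empty the denominator vanishes and J is defined as 0 (an empty pocket is no
evidence of similarity).  The similarity of N pockets is the product of the
four per-property Jaccard factors:

    S_pkt(p_1, ..., p_N) = J(M's) * J(G's) * J(C's) * J(H's)

Both quantities lie in [0, 1], are permutation invariant, and can only
shrink when another histogram/pocket is added to the comparison (mins fall,
maxes rise) — the monotone-shrinkage property the cluster search prunes on.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import EmptyInputError, MismatchError
from .histograms import Histogram, PocketDescriptor


def histogram_similarity(hists: Sequence[Histogram]) -> float:
    """Generalized Jaccard similarity of >=1 histograms with a shared spec."""
    if not hists:
        raise EmptyInputError("no histograms")
    spec = hists[0].spec
    for h in hists[1:]:
        if h.spec != spec:
            raise MismatchError(
                f"mixed histogram specs: {spec.name} vs {h.spec.name}")
    stack = np.stack([h.counts for h in hists])
    denom = stack.max(axis=0).sum()
    if denom == 0:
        return 0.0
    return float(stack.min(axis=0).sum() / denom)


def pocket_similarity(descriptors: Sequence[PocketDescriptor]) -> float:
    """S_pkt: product of the four histogram Jaccard factors."""
    if not descriptors:
        raise EmptyInputError("no descriptors")
    s = 1.0
    for i in range(4):
        s *= histogram_similarity([d.histograms[i] for d in descriptors])
    return s
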