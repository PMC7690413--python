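"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import itertools
import re

import numpy as np


def trajectory_oracle(bits) -> str:
    """Regular-expression classifier: 1+, 1+0+, 0+1+, else unstable."""
    s = "".join("1" if b else "0" for b in bits)
    if re.fullmatch("1+", s):
        return "stable"
    if re.fullmatch("1+0+", s):
        return "lost"
    if re.fullmatch("0+1+", s):
        return "emerging"
    return "unstable"


def all_series(length: int):
    return itertools.product([False, True], repeat=length)


def upgma_cophenetic_oracle(d: np.ndarray) -> np.ndarray:
    """Brute-force average-linkage agglomeration.

    Clusters are merged closest-pair first (lowest-index tie-break); the
    inter-cluster distance is always recomputed as the mean of the original
    leaf-to-leaf dissimilarities, which is exactly the UPGMA criterion.
    """
    n = d.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pairs = [(i, j) for i in clusters[a] for j in clusters[b]]
                avg = float(np.mean([d[i, j] for i, j in pairs]))
                if best is None or avg < best[0] - 1e-15:
                    best = (avg, a, b)
        avg, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = avg
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r from raw covariance sums; p from the t distribution."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
    t = r * np.sqrt(n - 2) / np.sqrt(max(1 - r * r, 1e-300))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)
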