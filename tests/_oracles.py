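"""Independent brute-force oracles shared by threshold tests."""

import numpy as np


def brute_force_kmeans_split(values):
    """Exhaustive 1-D two-group split minimizing within-group SSE (naive)."""
    v = np.sort(np.asarray(values, dtype=float))
    best_k, best_sse = None, np.inf
    for k in range(1, len(v)):
        lo, hi = v[:k], v[k:]
        sse = np.sum((lo - lo.mean()) ** 2) + np.sum((hi - hi.mean()) ** 2)
        if sse < best_sse:
            best_k, best_sse = k, sse
    return best_k, best_sse


def brute_force_otsu(values, n_bins):
    """Between-class variance maximization over all histogram bin edges.

    Splits separated by empty bins tie exactly; like the implementation
    (and reference implementations), the middle maximizer is taken.
    Returns (edge, best_between, edges, between).
    """
    counts, edges = np.histogram(np.asarray(values, float), bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    between = np.full(n_bins - 1, -np.inf)
    for i in range(1, n_bins):
        w0, w1 = counts[:i].sum(), counts[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = np.sum(counts[:i] * centers[:i]) / w0
        mu1 = np.sum(counts[i:] * centers[i:]) / w1
        between[i - 1] = w0 * w1 * (mu0 - mu1) ** 2 / total**2
    maximizers = np.flatnonzero(between >= between.max() * (1 - 1e-12))
    best = int(round(float(np.mean(maximizers))))
    return edges[best + 1], between[best], edges, between
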