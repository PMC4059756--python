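"""Independent brute-force oracles used by the test suite.

These deliberately mirror the literal textbook procedures (quadratic/cubic
recomputation) rather than the package's optimised implementations.
"""

import itertools

import numpy as np


def naive_average_linkage(dist: np.ndarray, n_clusters: int):
    """Literal bottom-up agglomeration: every step recomputes every
    inter-cluster distance as the mean over all cross pairs from the original
    distance matrix. Clusters are keyed by their smallest member index; ties
    resolve to the lexicographically smallest key pair and the merged cluster
    keeps the smaller key."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    history = []
    while len(clusters) > n_clusters:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        history.append((i, j, d))
    labels = np.empty(n, dtype=int)
    for new, key in enumerate(sorted(clusters)):
        labels[clusters[key]] = new
    return labels, history


def fine_grid_gamma_peak(t0: float, a: float, b: float, dt: float = 1e-4):
    """Brute-force maximisation of the gamma-variate on a very fine grid."""
    t = np.arange(t0, t0 + 10 * a * b, dt)
    tau = t - t0
    with np.errstate(invalid="ignore"):
        f = np.where(tau > 0, tau**a * np.exp(-tau / b), 0.0)
    i = int(np.argmax(f))
    return float(f[i]), float(t[i])


def fine_grid_fwhm(t0: float, a: float, b: float, dt: float = 1e-4):
    """Brute-force full width at half maximum of the gamma-variate."""
    t = np.arange(t0, t0 + 20 * a * b, dt)
    tau = t - t0
    with np.errstate(invalid="ignore"):
        f = np.where(tau > 0, tau**a * np.exp(-tau / b), 0.0)
    half = f.max() / 2.0
    above = np.flatnonzero(f >= half)
    return float(t[above[-1]] - t[above[0]])
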