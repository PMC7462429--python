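"""Shared oracles and small data builders used across test modules."""

import numpy as np
import pandas as pd


def likert(latent: np.ndarray) -> np.ndarray:
    """Quartile discretization of a latent matrix to 1..4."""
    cuts = latent.std() * np.array([-0.6745, 0.0, 0.6745])
    return np.searchsorted(cuts, latent.ravel()).reshape(latent.shape) + 1


def planted_loading_ratings(n=300, noise_sd=0.2, seed=1):
    """Two item clusters x 3 orthogonal factors in perfect simple structure;
    returns the Likert table and the planted loading matrix."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((n, 6))
    gA, gB = rng.standard_normal((n, 2)).T
    loadings = np.zeros((18, 6))
    latent = np.empty((n, 18))
    for k in range(18):
        fac = (k % 3) + (3 if k >= 9 else 0)
        loadings[k, fac] = 0.9
        common = 0.35 * (gA if k < 9 else gB)
        latent[:, k] = 0.9 * f[:, fac] + common + noise_sd * rng.standard_normal(n)
    df = pd.DataFrame(likert(latent),
                      columns=[f"item_{k:02d}" for k in range(18)],
                      index=[f"S{i}" for i in range(n)])
    return df, loadings


def brute_force_betweenness(w: np.ndarray) -> np.ndarray:
    """Floyd-Warshall distances plus explicit shortest-path counting;
    independent of the networkx-based implementation."""
    N = w.shape[0]
    d = np.full((N, N), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(N):
        for j in range(N):
            if i != j and w[i, j] != 0:
                d[i, j] = 1.0 / abs(w[i, j])
    for k in range(N):
        for i in range(N):
            for j in range(N):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]

    def n_paths(s, t, memo):
        if s == t:
            return 1
        if (s, t) in memo:
            return memo[(s, t)]
        total = 0
        for u in range(N):
            if u != t and w[u, t] != 0 and \
                    abs(d[s, u] + 1.0 / abs(w[u, t]) - d[s, t]) < 1e-9:
                total += n_paths(s, u, memo)
        memo[(s, t)] = total
        return total

    b = np.zeros(N)
    for s in range(N):
        memo = {}
        for t in range(s + 1, N):
            if not np.isfinite(d[s, t]):
                continue
            sigma = n_paths(s, t, memo)
            if sigma == 0:
                continue
            for v in range(N):
                if v in (s, t) or not np.isfinite(d[s, v]) \
                        or not np.isfinite(d[v, t]):
                    continue
                if abs(d[s, v] + d[v, t] - d[s, t]) < 1e-9:
                    b[v] += n_paths(s, v, memo) * n_paths(v, t, {}) / sigma
    if N > 2:
        b *= 2.0 / ((N - 1) * (N - 2))
    return b


def best_overlap(truth_edges, components, fwe_p):
    """Largest-Jaccard match between a planted edge set and NBS components.

    Returns (jaccard, fwe_p) for the best-matching component, or (0, 1).
    """
    truth = set(truth_edges)
    best = (0.0, 1.0)
    for comp, p in zip(components, fwe_p):
        edges = set(comp.edges)
        jac = len(truth & edges) / len(truth | edges)
        if jac > best[0]:
            best = (jac, float(p))
    return best
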