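"""Independent brute-force oracles used only by the tests.

These deliberately avoid every library routine the implementation relies on:
silhouette is computed from the O(n^2) pairwise-distance definition, WCSS by
exhaustive enumeration of all label assignments, and evaluation metrics by
plain arithmetic.
"""

import itertools

import numpy as np


def silhouette_bruteforce(X, labels):
    """Mean silhouette from the definition: per point, a = mean distance to
    its own cluster's other members, b = min over other clusters of the mean
    distance to that cluster; s = (b - a) / max(a, b); singletons score 0."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(X)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([dist[i, j] for j in own])
        b = np.inf
        for c in set(labels.tolist()) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, np.mean([dist[i, j] for j in members]))
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def wcss_of_assignment(X, labels):
    """WCSS of a fixed assignment with centroids at the cluster means."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    total = 0.0
    for c in set(labels.tolist()):
        pts = X[labels == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def wcss_exhaustive(X, k):
    """Global minimum WCSS over every assignment of n points to k non-empty
    clusters (feasible only for tiny n)."""
    n = len(X)
    best = np.inf
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) != k:
            continue
        best = min(best, wcss_of_assignment(X, np.array(assignment)))
    return best


def rmse_r2_arithmetic(y, pred):
    """Plain-arithmetic RMSE and R-squared."""
    y = np.asarray(y, float)
    pred = np.asarray(pred, float)
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return rmse, 1.0 - ss_res / ss_tot
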