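"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by direct enumeration or a textbook
formula, deliberately avoiding the library code paths it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np


def ward_merge_partitions(X: np.ndarray) -> list[list[frozenset]]:
    """Greedy Ward agglomeration by exhaustive pair search.

    At each step merge the pair of clusters whose union minimizes the
    increase in total within-cluster sum of squares,
    delta(A, B) = |A||B|/(|A|+|B|) * ||mean_A - mean_B||^2.
    Returns the partition after every merge.
    """
    X = np.asarray(X, float)
    clusters = [frozenset([i]) for i in range(len(X))]
    out = []
    while len(clusters) > 1:
        best, best_pair = np.inf, None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            a = np.array(sorted(clusters[i]))
            b = np.array(sorted(clusters[j]))
            ma, mb = X[a].mean(axis=0), X[b].mean(axis=0)
            delta = len(a) * len(b) / (len(a) + len(b)) * np.sum((ma - mb) ** 2)
            if delta < best - 1e-12:
                best, best_pair = delta, (i, j)
        i, j = best_pair
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        out.append(sorted(clusters, key=lambda c: sorted(c)))
    return out


def linkage_partitions(Z: np.ndarray, n: int) -> list[list[frozenset]]:
    """Partition sequence implied by a scipy linkage matrix."""
    clusters = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, _, _) in enumerate(Z):
        new = clusters.pop(int(a)) | clusters.pop(int(b))
        clusters[n + step] = new
        out.append(sorted(clusters.values(), key=lambda c: sorted(c)))
    return out


def nearest_centroid_labels(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distances with explicit loops; ties -> lowest index."""
    labels = []
    for p in points:
        dists = [float(np.sqrt(np.sum((p - c) ** 2))) for c in centroids]
        best = min(range(len(dists)), key=lambda k: (dists[k], k))
        labels.append(best + 1)
    return np.array(labels)


def pca_eig(X: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA via dense eigendecomposition of the sample covariance.

    Returns (eigenvalues desc, loadings p x m, scores n x m); loading signs
    follow the largest-magnitude-entry-positive convention.
    """
    X = np.asarray(X, float)
    mu = X.mean(axis=0)
    cov = np.cov(X - mu, rowvar=False, ddof=1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:m]
    w, v = w[order], v[:, order]
    for j in range(v.shape[1]):
        idx = int(np.argmax(np.abs(v[:, j])))
        if v[idx, j] < 0:
            v[:, j] = -v[:, j]
    return w, v, (X - mu) @ v


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by the direct formula."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return np.clip(adj, 0, 1)


def logrank_chi2(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank statistic by direct per-event-time accumulation."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    all_times = np.concatenate([times_a[events_a == 1], times_b[events_b == 1]])
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(all_times):
        n1 = np.sum(times_a >= t)
        n2 = np.sum(times_b >= t)
        d1 = np.sum((times_a == t) & (events_a == 1))
        d2 = np.sum((times_b == t) & (events_b == 1))
        n, d = n1 + n2, d1 + d2
        if n < 2 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)


def km_curve(times, events) -> list[tuple[float, float]]:
    """Product-limit estimate by hand: [(event time, S(t)), ...]."""
    times, events = np.asarray(times, float), np.asarray(events, int)
    s = 1.0
    out = []
    for t in np.unique(times[events == 1]):
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / n_at_risk
        out.append((float(t), float(s)))
    return out


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Breslow partial log-likelihood for a single covariate (no ties needed)."""
    times, events, x = map(np.asarray, (times, events, x))
    ll = 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return float(ll)


def cox_score_test(times, events, x) -> float:
    """Score (Rao) test statistic of a single-covariate Cox model at beta=0.

    U = sum over events of (x_i - xbar_risk); V accumulates the risk-set
    variance of x; the statistic U^2/V equals the log-rank chi-squared for a
    binary covariate on tie-free data.
    """
    times, events, x = map(np.asarray, (times, events, x))
    u, v = 0.0, 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        xb = x[risk].mean()
        u += x[i] - xb
        v += np.mean((x[risk] - xb) ** 2)
    return float(u**2 / v)


def chi2_pearson_p(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared p via the direct statistic and the chi2 CDF."""
    from scipy.stats import chi2

    t = np.asarray(table, float)
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    expected = rows @ cols / t.sum()
    stat = float(np.sum((t - expected) ** 2 / expected))
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, float(chi2.sf(stat, dof))
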