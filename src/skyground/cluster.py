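"""k-medoids (PAM) and cluster-number estimation.

The spectral-species workflow first asks *how many* clusters a plot's
pixels form, then partitions them.  The cluster count is taken as the
round-half-up mean of the optima of an ensemble of cluster-validity
indices (default ten: Calinski-Harabasz, Hartigan, Krzanowski-Lai,
silhouette, C-index, Davies-Bouldin, Duda-Hart, pseudo-t2,
Ratkowsky-Lance, Ball-Hall), each evaluated on k-medoids partitions over a
candidate range.  Indices defined for hierarchical splits (Duda-Hart,
pseudo-t2, Hartigan) are applied to the nested sequence of partition
within-group sums of squares, the standard partition-based adaptation.

PAM is the classical BUILD + SWAP algorithm on a precomputed distance
matrix, deterministic with ties broken toward the lowest index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = ["PAMResult", "pam_cluster", "ClusterNumberEstimate", "estimate_cluster_number",
           "DEFAULT_INDICES"]


@dataclass(frozen=True)
class PAMResult:
    labels: np.ndarray  # cluster index per point, 0..k-1
    medoids: np.ndarray  # point indices of the medoids
    cost: float  # total distance of points to their medoids


def pam_cluster(D: np.ndarray, k: int, seed: int = 0, max_iter: int = 200) -> PAMResult:
    """Partitioning Around Medoids on a distance matrix.

    BUILD greedily seeds medoids by largest cost reduction; SWAP exchanges
    a medoid for a non-medoid while any swap lowers the total distance.
    Fully deterministic: the seed argument is accepted for interface
    symmetry but the algorithm never draws random numbers.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=0)))]
    d_near = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_near[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        d_near = np.minimum(d_near, D[:, c])

    medoids_arr = np.array(sorted(medoids))

    # SWAP
    for _ in range(max_iter):
        dm = D[:, medoids_arr]  # (n, k)
        near_col = np.argmin(dm, axis=1)
        d1 = dm[np.arange(n), near_col]
        if k > 1:
            dm2 = dm.copy()
            dm2[np.arange(n), near_col] = np.inf
            d2 = dm2.min(axis=1)
        else:
            d2 = np.full(n, np.inf)
        cost = d1.sum()
        best = (0.0, None, None)
        for mi in range(k):
            base = np.where(near_col == mi, d2, d1)
            cand = np.minimum(D, base[:, None]).sum(axis=0)  # cost per replacement h
            cand[medoids_arr] = np.inf
            h = int(np.argmin(cand))
            delta = cand[h] - cost
            if delta < best[0] - 1e-12:
                best = (delta, mi, h)
        if best[1] is None:
            break
        medoids_arr[best[1]] = best[2]
        medoids_arr = np.sort(medoids_arr)

    dm = D[:, medoids_arr]
    labels = np.argmin(dm, axis=1)
    labels[medoids_arr] = np.arange(k)  # medoids own their clusters
    cost = dm[np.arange(n), labels].sum()
    return PAMResult(labels, medoids_arr, float(cost))


# --------------------------------------------------------------------------
# validity indices
# --------------------------------------------------------------------------

DEFAULT_INDICES = (
    "calinski_harabasz",
    "hartigan",
    "krzanowski_lai",
    "silhouette",
    "c_index",
    "davies_bouldin",
    "duda_hart",
    "pseudo_t2",
    "ratkowsky_lance",
    "ball_hall",
)


def _wgss(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(labels):
        sub = X[labels == c]
        w += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return w


def _wgss_per_var(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    w = np.zeros(X.shape[1])
    for c in np.unique(labels):
        sub = X[labels == c]
        w += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    return w


def _duda_critical(n: int, p: int, z: float = 3.2) -> float:
    v = 1.0 - 2.0 / (np.pi * p) - z * np.sqrt(2.0 * (1.0 - 8.0 / (np.pi**2 * p)) / (n * p))
    return max(v, 1e-3)


@dataclass(frozen=True)
class ClusterNumberEstimate:
    per_index: dict[str, int]
    mean_k: float
    chosen_k: int
    k_range: tuple[int, int]


def _first_argmax(vals: np.ndarray) -> int:
    vals = np.where(np.isnan(vals), -np.inf, vals)
    return int(np.argmax(vals))


def _first_argmin(vals: np.ndarray) -> int:
    vals = np.where(np.isnan(vals), np.inf, vals)
    return int(np.argmin(vals))


def estimate_cluster_number(
    X: np.ndarray,
    k_range: tuple[int, int] | None = None,
    indices=DEFAULT_INDICES,
    seed: int = 0,
    variance_tol: float = 1e-12,
) -> ClusterNumberEstimate:
    """Ensemble estimate of the number of clusters among pixel spectra.

    Each index proposes an optimal k over ``k_range`` (default
    ``[2, min(20, n - 1)]``) computed from k-medoids partitions of the
    Euclidean distance matrix; the chosen k is the round-half-up mean of
    the proposals.  Near-zero total variance short-circuits to k = 1.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 pixels")
    total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
    if total_ss / n < variance_tol * max(1.0, float((X**2).sum() / n)):
        return ClusterNumberEstimate({name: 1 for name in indices}, 1.0, 1, (1, 1))
    if k_range is None:
        k_range = (2, min(20, n - 1))
    k_lo, k_hi = k_range
    if not (2 <= k_lo <= k_hi <= n - 1):
        raise ValueError("invalid k_range")

    diff2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2) if n <= 600 else None
    if diff2 is not None:
        D = np.sqrt(np.maximum(diff2, 0.0))
    else:
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(X))

    ks = list(range(max(k_lo - 1, 1), min(k_hi + 2, n) ))  # pad for difference-based indices
    labels_by_k: dict[int, np.ndarray] = {1: np.zeros(n, dtype=int)}
    W: dict[int, float] = {1: total_ss}
    Wv: dict[int, np.ndarray] = {1: ((X - X.mean(axis=0)) ** 2).sum(axis=0)}
    for k in ks:
        if k == 1 or k in labels_by_k:
            continue
        res = pam_cluster(D, k)
        labels_by_k[k] = res.labels
        W[k] = _wgss(X, res.labels)
        Wv[k] = _wgss_per_var(X, res.labels)

    cand = np.array([k for k in range(k_lo, k_hi + 1)])
    eps = 1e-12 * max(total_ss, 1.0)

    # exact-partition short-circuit: if some k reproduces the pixels exactly
    # (zero within-group variance), the data contain exactly that many
    # distinct signatures and no validity index is needed.  This happens for
    # noise-free pure-pixel renders where normalization collapses each
    # species to a single point.
    exact = [k for k in cand if W[k] <= 1e-9 * total_ss]
    if exact:
        k0 = int(exact[0])
        return ClusterNumberEstimate({name: k0 for name in indices}, float(k0), k0, (k_lo, k_hi))

    def ch(k):
        lb = labels_by_k[k]
        if len(np.unique(lb)) < 2:
            return -np.inf
        if W[k] < eps:
            return np.inf
        return calinski_harabasz_score(X, lb)

    def sil(k):
        lb = labels_by_k[k]
        if len(np.unique(lb)) < 2 or len(np.unique(lb)) >= n:
            return -np.inf
        return silhouette_score(D, lb, metric="precomputed")

    def db(k):
        lb = labels_by_k[k]
        if len(np.unique(lb)) < 2:
            return np.inf
        return davies_bouldin_score(X, lb)

    iu = np.triu_indices(n, k=1)
    all_pairs = np.sort(D[iu])
    cum = np.concatenate([[0.0], np.cumsum(all_pairs)])

    def c_index(k):
        lb = labels_by_k[k]
        s = 0.0
        nw = 0
        for c in np.unique(lb):
            idx = np.where(lb == c)[0]
            if idx.size < 2:
                continue
            sub = D[np.ix_(idx, idx)]
            s += sub[np.triu_indices(idx.size, k=1)].sum()
            nw += idx.size * (idx.size - 1) // 2
        if nw == 0:
            return np.inf
        smin = cum[nw]
        smax = cum[-1] - cum[-1 - nw]
        if smax - smin < 1e-300:
            return 0.0
        return (s - smin) / (smax - smin)

    per_index: dict[str, int] = {}
    for name in indices:
        if name == "calinski_harabasz":
            per_index[name] = int(cand[_first_argmax(np.array([ch(k) for k in cand]))])
        elif name == "silhouette":
            per_index[name] = int(cand[_first_argmax(np.array([sil(k) for k in cand]))])
        elif name == "davies_bouldin":
            per_index[name] = int(cand[_first_argmin(np.array([db(k) for k in cand]))])
        elif name == "c_index":
            per_index[name] = int(cand[_first_argmin(np.array([c_index(k) for k in cand]))])
        elif name == "ball_hall":
            # largest drop of mean within-cluster SSE between successive k
            drops = np.array([W[k - 1] / (k - 1) - W[k] / k for k in cand])
            per_index[name] = int(cand[_first_argmax(drops)])
        elif name == "hartigan":
            vals = []
            for k in cand:
                wk1 = W.get(k + 1, np.nan)
                if not np.isfinite(wk1) or wk1 < eps:
                    vals.append(0.0 if W[k] < eps else np.inf)
                else:
                    vals.append((W[k] / wk1 - 1.0) * (n - k - 1))
            vals = np.array(vals)
            small = np.where(vals <= 10.0)[0]
            per_index[name] = int(cand[small[0]]) if small.size else int(cand[_first_argmin(vals)])
        elif name == "krzanowski_lai":
            vals = []
            for k in cand:
                d1 = (k - 1) ** (2.0 / p) * W.get(k - 1, np.nan) - k ** (2.0 / p) * W[k]
                d2 = k ** (2.0 / p) * W[k] - (k + 1) ** (2.0 / p) * W.get(k + 1, np.nan)
                vals.append(abs(d1) / abs(d2) if abs(d2) > 1e-300 else np.inf)
            per_index[name] = int(cand[_first_argmax(np.array(vals))])
        elif name == "duda_hart":
            crit = _duda_critical(n, p)
            ratios = []
            for k in cand:
                wk, wk1 = W[k], W.get(k + 1, np.nan)
                ratios.append(1.0 if wk < eps else wk1 / wk)
            ratios = np.array(ratios)
            ok = np.where(ratios >= crit)[0]
            per_index[name] = int(cand[ok[0]]) if ok.size else int(cand[_first_argmax(ratios)])
        elif name == "pseudo_t2":
            crit = _duda_critical(n, p)
            vals, thr = [], []
            for k in cand:
                wk, wk1 = W[k], W.get(k + 1, np.nan)
                if wk < eps:
                    vals.append(0.0)
                elif not np.isfinite(wk1) or wk1 < eps:
                    vals.append(np.inf)
                else:
                    vals.append((wk - wk1) / wk1 * (n - k - 1))
                thr.append((1.0 - crit) / crit * (n - k - 1))
            vals, thr = np.array(vals), np.array(thr)
            ok = np.where(vals <= thr)[0]
            per_index[name] = int(cand[ok[0]]) if ok.size else int(cand[_first_argmin(vals)])
        elif name == "ratkowsky_lance":
            tssv = Wv[1]
            vals = []
            for k in cand:
                bg = np.maximum(tssv - Wv[k], 0.0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    ratio = np.where(tssv > 0, bg / tssv, 0.0)
                vals.append(np.sqrt(ratio).mean() / np.sqrt(k))
            per_index[name] = int(cand[_first_argmax(np.array(vals))])
        else:
            raise ValueError(f"unknown validity index {name!r}")

    mean_k = float(np.mean(list(per_index.values())))
    chosen = int(np.floor(mean_k + 0.5))  # round half up
    return ClusterNumberEstimate(per_index, mean_k, chosen, (k_lo, k_hi))
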