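"""Trait-table preparation and phylogenetic-comparative utilities.

Covers four jobs that precede the community-level analyses:

* **Phylogenetic eigenvectors** — eigendecomposition of the double-centered
  squared patristic distance matrix (classical PCoA of the phylogeny),
  used as predictors when imputing missing traits.
* **Imputation** — iterative random-forest imputation (missForest-style):
  each trait with holes is regressed on the other traits plus the
  eigenvectors, cycling until successive imputations stop improving.
* **Phylogenetic signal and model adequacy** — Pagel's lambda by maximum
  likelihood on [0, 1], and a BM-vs-OU adequacy screen scored with Akaike
  weights and evidence ratios.
* **Trait dendrogram** — Gower distances clustered with UPGMA and rescaled
  so the root age matches the phylogeny's, giving a time-calibrated
  trait-space tree usable wherever a phylogeny is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestRegressor

from . import trees

log = logging.getLogger(__name__)

__all__ = [
    "PhyloEigenvectors",
    "SignalEstimate",
    "AdequacyResult",
    "compute_phylo_eigenvectors",
    "impute_traits",
    "estimate_lambda",
    "simulate_bm_traits",
    "adequacy_bm_ou",
    "gower_distance",
    "build_trait_dendrogram",
]


# --------------------------------------------------------------------------
# phylogenetic eigenvectors
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhyloEigenvectors:
    species: list[str]
    vectors: np.ndarray  # species x E, orthonormal
    eigenvalues: np.ndarray  # non-increasing


def compute_phylo_eigenvectors(tree: dendropy.Tree, n_vectors: int | None = None) -> PhyloEigenvectors:
    """Top eigenvectors of ``-1/2 J D^2 J`` (D = patristic distances).

    When ``n_vectors`` is None, the smallest set explaining 95% of the
    positive-eigenvalue trace is kept, capped at 30.
    """
    labels, D = trees.patristic_matrix(tree)
    n = len(labels)
    if n < 3:
        raise ValueError("need a tree with at least 3 tips")
    if np.allclose(D, 0.0):
        raise ValueError("degenerate distances: all patristic distances are zero")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-10, 1e-12 * abs(vals[0]))
    if n_vectors is None:
        pv = vals[pos]
        cum = np.cumsum(pv) / pv.sum()
        n_vectors = min(int(np.searchsorted(cum, 0.95) + 1), 30, int(pos.sum()))
    if n_vectors >= n:
        raise ValueError("n_vectors must be smaller than the number of tips")
    return PhyloEigenvectors(labels, vecs[:, :n_vectors], vals[:n_vectors])


# --------------------------------------------------------------------------
# missForest-style imputation
# --------------------------------------------------------------------------


def impute_traits(
    traits: pd.DataFrame,
    eigenvectors: PhyloEigenvectors | None = None,
    n_vectors_used: int | None = None,
    seed: int = 0,
    max_iter: int = 8,
    n_estimators: int = 100,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fill missing trait cells with iterative random-forest regression.

    Traits are visited in order of increasing missingness; each round
    re-predicts the missing cells of one trait from all other traits (and
    the phylogenetic eigenvectors when given).  Iteration stops when the
    change between successive imputations first increases (missForest
    stopping rule) or ``max_iter`` is hit.  Observed cells are never
    altered.  Returns the completed table and a per-trait out-of-bag R^2
    as an imputation-error estimate.
    """
    traits = traits.copy()
    cols = list(traits.columns)
    for c in cols:
        n_obs = traits[c].notna().sum()
        if n_obs == 0:
            raise ValueError(f"trait column {c!r} has no observed values")
    mask = traits.isna()
    if not mask.to_numpy().any():
        return traits, {c: float("nan") for c in cols}

    X_extra = None
    if eigenvectors is not None:
        ev = pd.DataFrame(
            eigenvectors.vectors, index=eigenvectors.species,
            columns=[f"pev{i}" for i in range(eigenvectors.vectors.shape[1])],
        )
        if n_vectors_used is not None:
            ev = ev.iloc[:, :n_vectors_used]
        X_extra = ev.reindex(traits.index)

    # initialize with column means
    work = traits.copy()
    for c in cols:
        work[c] = work[c].fillna(traits[c].mean())

    order = sorted(cols, key=lambda c: mask[c].sum())
    rng = np.random.default_rng(seed)
    oob: dict[str, float] = {}
    prev_change = np.inf
    prev_work = work.copy()
    for _ in range(max_iter):
        for c in order:
            miss = mask[c].to_numpy()
            if not miss.any():
                oob.setdefault(c, float("nan"))
                continue
            others = [o for o in cols if o != c]
            X = work[others]
            if X_extra is not None:
                X = pd.concat([X, X_extra], axis=1)
            rf = RandomForestRegressor(
                n_estimators=n_estimators,
                random_state=int(rng.integers(2**31 - 1)),
                oob_score=True,
                bootstrap=True,
                min_samples_leaf=2,
            )
            rf.fit(X.loc[~miss].to_numpy(), work.loc[~miss, c].to_numpy())
            work.loc[miss, c] = rf.predict(X.loc[miss].to_numpy())
            oob[c] = float(rf.oob_score_)
        num = sum(
            ((work[c] - prev_work[c]) ** 2).sum() for c in cols
        )
        den = sum((work[c] ** 2).sum() for c in cols)
        change = num / den if den > 0 else 0.0
        if change >= prev_change:
            work = prev_work  # revert to the better previous round
            break
        prev_change, prev_work = change, work.copy()

    out = traits.where(~mask, work)
    return out, oob


# --------------------------------------------------------------------------
# Pagel's lambda
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalEstimate:
    trait: str
    lam: float
    loglik: float
    loglik_lambda0: float
    loglik_lambda1: float
    interval: tuple[float, float]


def _gls_profile_loglik(y: np.ndarray, V: np.ndarray) -> float:
    """Log-likelihood of y ~ N(mu 1, sigma^2 V) profiled over mu, sigma^2."""
    n = y.size
    L = np.linalg.cholesky(V)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    one = np.ones(n)
    Vi_y = np.linalg.solve(V, y)
    Vi_1 = np.linalg.solve(V, one)
    mu = (one @ Vi_y) / (one @ Vi_1)
    r = y - mu
    s2 = float(r @ np.linalg.solve(V, r)) / n
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def estimate_lambda(tree: dendropy.Tree, trait, trait_name: str = "trait") -> SignalEstimate:
    """Maximum-likelihood Pagel's lambda on [0, 1].

    The lambda transform multiplies the off-diagonal Brownian covariance
    (shared path lengths) while leaving tip variances unchanged; the
    likelihood is optimized by bounded scalar search with a profile
    interval at 1.92 log-likelihood units (chi-square 95%).
    """
    labels, C = trees.shared_path_matrix(tree)
    if hasattr(trait, "reindex"):
        y = trait.reindex(labels).to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    if y.size != len(labels):
        raise ValueError("trait length does not match tree tips")
    if len(labels) < 10:
        raise ValueError("need at least 10 tips")
    if not np.all(np.isfinite(y)):
        raise ValueError("trait has non-finite values")
    if np.var(y) == 0:
        raise ValueError("trait has zero variance")

    def nll(lam):
        return -_gls_profile_loglik(y, _lambda_cov(C, lam))

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam_hat = float(np.clip(res.x, 0.0, 1.0))
    ll_hat = -float(res.fun)
    # bounded search can miss a boundary optimum; check both ends
    ll0, ll1 = -nll(0.0), -nll(1.0)
    for lam_b, ll_b in ((0.0, ll0), (1.0, ll1)):
        if ll_b > ll_hat:
            lam_hat, ll_hat = lam_b, ll_b

    cut = ll_hat - 1.92
    lo = 0.0 if ll0 >= cut else optimize.brentq(lambda l: -nll(l) - cut, 0.0, lam_hat)
    hi = 1.0 if ll1 >= cut else optimize.brentq(lambda l: -nll(l) - cut, lam_hat, 1.0)
    return SignalEstimate(trait_name, lam_hat, ll_hat, ll0, ll1, (float(lo), float(hi)))


# --------------------------------------------------------------------------
# BM vs OU adequacy
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AdequacyResult:
    aic_bm: np.ndarray
    aic_ou: np.ndarray
    akaike_weight_bm: np.ndarray
    evidence_ratio: np.ndarray  # AICW(best) / AICW(other), per replicate
    best: list[str]  # "BM" | "OU" | "indecisive" | "failed"
    fraction_bm: float
    fraction_ou: float
    fraction_indecisive: float
    n_failed: int = 0


def simulate_bm_traits(tree: dendropy.Tree, n_traits: int, sigma2: float = 1.0,
                       seed: int = 0) -> pd.DataFrame:
    """Independent Brownian traits on the tree (root state 0)."""
    labels, C = trees.shared_path_matrix(tree)
    L = np.linalg.cholesky(C * sigma2 + 1e-12 * np.eye(len(labels)))
    rng = np.random.default_rng(seed)
    X = L @ rng.standard_normal((len(labels), n_traits))
    return pd.DataFrame(X, index=labels, columns=[f"t{i}" for i in range(n_traits)])


def _fit_bm(y: np.ndarray, C: np.ndarray) -> tuple[float, int]:
    return _gls_profile_loglik(y, C), 2  # mu/sigma2 (sigma2 profiled, counted)


def _ou_cov(C: np.ndarray, alpha: float) -> np.ndarray:
    """OU covariance on an ultrametric tree with a free (non-stationary) root.

    Cov(i, j) = (1 / (2 alpha)) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij))
    with shared time t_ij and patristic distance d_ij; the overall rate is
    profiled out.
    """
    t = C  # shared path lengths
    d = np.diag(C)[:, None] + np.diag(C)[None, :] - 2 * C
    with np.errstate(over="ignore"):
        V = np.exp(-alpha * d) * (1.0 - np.exp(-2.0 * alpha * t)) / (2.0 * alpha)
    return V


def _fit_ou(y: np.ndarray, C: np.ndarray) -> tuple[float, int]:
    depth = float(np.diag(C).max())

    def nll(log_alpha):
        a = np.exp(log_alpha)
        V = _ou_cov(C, a)
        try:
            return -_gls_profile_loglik(y, V + 1e-10 * np.eye(len(y)))
        except np.linalg.LinAlgError:
            return np.inf

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(1e-4 / depth), np.log(50.0 / depth)), method="bounded",
        options={"xatol": 1e-6},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("OU optimizer failed")
    # three parameters: mean, rate (profiled but counted), alpha
    return -float(res.fun), 3


def adequacy_bm_ou(
    tree: dendropy.Tree,
    n_sim: int = 100,
    seed: int = 0,
    indecisive_ratio: float = 2.0,
    traits: pd.DataFrame | None = None,
) -> AdequacyResult:
    """Simulate BM traits, refit BM and OU, score with Akaike weights.

    A replicate is "indecisive" when the ratio of the larger to the smaller
    Akaike weight is below ``indecisive_ratio``; optimizer failures are
    flagged, never silently dropped.  Pass ``traits`` to score an existing
    trait table instead of simulating.
    """
    if traits is None and n_sim < 10:
        raise ValueError("need n_sim >= 10")
    labels, C = trees.shared_path_matrix(tree)
    if traits is None:
        traits = simulate_bm_traits(tree, n_sim, seed=seed)
    else:
        traits = traits.reindex(labels)
    Y = traits.to_numpy(dtype=float)
    n = Y.shape[0]
    aic_bm, aic_ou, w_bm, er, best = [], [], [], [], []
    n_failed = 0
    for j in range(Y.shape[1]):
        y = Y[:, j]
        try:
            ll_b, k_b = _fit_bm(y, C)
            ll_o, k_o = _fit_ou(y, C)
        except (RuntimeError, np.linalg.LinAlgError):
            n_failed += 1
            best.append("failed")
            aic_bm.append(np.nan); aic_ou.append(np.nan)
            w_bm.append(np.nan); er.append(np.nan)
            continue
        a_b, a_o = 2 * k_b - 2 * ll_b, 2 * k_o - 2 * ll_o
        d = np.array([a_b, a_o]) - min(a_b, a_o)
        w = np.exp(-0.5 * d)
        w = w / w.sum()
        ratio = w.max() / max(w.min(), 1e-300)
        aic_bm.append(a_b); aic_ou.append(a_o)
        w_bm.append(w[0]); er.append(ratio)
        if ratio < indecisive_ratio:
            best.append("indecisive")
        else:
            best.append("BM" if w[0] > w[1] else "OU")
    n_ok = len(best)
    return AdequacyResult(
        np.array(aic_bm), np.array(aic_ou), np.array(w_bm), np.array(er), best,
        fraction_bm=best.count("BM") / n_ok,
        fraction_ou=best.count("OU") / n_ok,
        fraction_indecisive=best.count("indecisive") / n_ok,
        n_failed=n_failed,
    )


# --------------------------------------------------------------------------
# Gower distance + UPGMA dendrogram
# --------------------------------------------------------------------------


def gower_distance(traits: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Gower distance: per-trait range-normalized absolute differences
    averaged over the traits observed in both species.

    Zero-range traits are skipped with a logged warning.
    """
    if traits.shape[0] < 2:
        raise ValueError("need at least 2 species")
    X = traits.to_numpy(dtype=float)
    n, k = X.shape
    keep = []
    for j, c in enumerate(traits.columns):
        col = X[:, j]
        obs = col[np.isfinite(col)]
        rng_ = obs.max() - obs.min() if obs.size else 0.0
        if rng_ == 0.0:
            log.warning("gower_distance: trait %r has zero range, skipped", c)
            continue
        keep.append((j, rng_))
    if not keep:
        raise ValueError("no traits with positive range")
    D = np.zeros((n, n))
    W = np.zeros((n, n))
    for j, rng_ in keep:
        col = X[:, j]
        ok = np.isfinite(col)
        both = np.outer(ok, ok)
        diff = np.abs(col[:, None] - col[None, :]) / rng_
        diff = np.where(both, np.nan_to_num(diff), 0.0)
        D += diff
        W += both
    with np.errstate(invalid="ignore"):
        G = np.where(W > 0, D / np.maximum(W, 1), 0.0)
    np.fill_diagonal(G, 0.0)
    return list(traits.index), G


def build_trait_dendrogram(
    labels: list[str], distance: np.ndarray, root_age: float
) -> dendropy.Tree:
    """UPGMA dendrogram rescaled so the root sits at ``root_age``.

    UPGMA output is ultrametric by construction; one global scaling factor
    calibrates the root height, mirroring how a trait dendrogram is aligned
    with a time-calibrated phylogeny.
    """
    distance = np.asarray(distance, dtype=float)
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    if distance.shape[0] != distance.shape[1] or not np.allclose(distance, distance.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    n = len(labels)
    Z = hierarchy.linkage(squareform(distance, checks=False), method="average")
    heights = np.zeros(2 * n - 1)  # node height = cophenetic distance / 2
    heights[n:] = Z[:, 2] / 2.0
    top = heights[-1]
    if top == 0:
        raise ValueError("all distances are zero; dendrogram is degenerate")
    scale = root_age / top

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[int, dendropy.Node] = {}
    for i, lab in enumerate(labels):
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(lab)
        nodes[i] = nd
    for m in range(Z.shape[0]):
        a, b = int(Z[m, 0]), int(Z[m, 1])
        parent = dendropy.Node()
        h = heights[n + m]
        for child in (a, b):
            nd = nodes[child]
            nd.edge.length = (h - heights[child]) * scale
            parent.add_child(nd)
        nodes[n + m] = parent
    tree.seed_node = nodes[2 * n - 2]
    tree.seed_node.edge.length = None
    return tree
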