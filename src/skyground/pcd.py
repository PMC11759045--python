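"""Pairwise community dissimilarity (PCD).

PCD compares two communities through the variance of Brownian tip states
on a phylogeny (or a calibrated trait dendrogram): the phylogenetic
component asks how much variance in one community's species remains after
conditioning on the other community, relative to the unconditioned
variance; the compositional component depends only on how many species the
plots share.  Both are normalized against random draws from the species
pool, so random assemblages expect PCD = 1, values below 1 mean the plots
are more similar than random, above 1 more dissimilar.  The total
decomposes multiplicatively: ``PCD = PCD_comp * PCD_phy``.

The conditional-variance formulation follows the covariance-based
definition of Ives & Helmus (2010); the pool is the union of species over
the analyzed plots unless a pool correlation matrix is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import dendropy
import numpy as np
import pandas as pd

from . import trees

log = logging.getLogger(__name__)

__all__ = ["PCDResult", "phylo_correlation", "expected_conditional_psv", "pcd_pair", "pcd_matrix"]


@dataclass(frozen=True)
class PCDResult:
    plot_a: str
    plot_b: str
    pcd_total: float
    pcd_comp: float
    pcd_phy: float


def phylo_correlation(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Correlation of tip states under Brownian motion.

    Shared-path-length covariance scaled to unit diagonal; requires an
    ultrametric tree (or calibrated dendrogram) so the diagonal is
    constant.
    """
    if not trees.is_ultrametric(tree, tol=1e-6):
        raise ValueError("PCD requires an ultrametric tree or calibrated dendrogram")
    labels, C = trees.shared_path_matrix(tree)
    d = np.sqrt(np.diag(C))
    V = C / np.outer(d, d)
    np.fill_diagonal(V, 1.0)
    return labels, V


def _psv(M: np.ndarray, n: int) -> float:
    # mean off-diagonal complement: (n tr(M) - sum(M)) / (n (n - 1));
    # a single species uses n^2 in the denominator (pair convention)
    den = n * (n - 1) if n > 1 else n * n
    return (n * np.trace(M) - M.sum()) / den


def _conditional(V: np.ndarray, pick1: np.ndarray, pick2: np.ndarray) -> float:
    C11 = V[np.ix_(pick1, pick1)]
    C22 = V[np.ix_(pick2, pick2)]
    C12 = V[np.ix_(pick1, pick2)]
    S11 = C11 - C12 @ np.linalg.solve(C22, C12.T)
    return _psv(S11, len(pick1))


def expected_conditional_psv(
    V: np.ndarray, max_richness: int, reps: int = 2000, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Monte-Carlo null: expected PSV of a random pair of species
    conditional on a random community of each richness 1..max_richness,
    plus the pool PSV.  Vectorized over replicates with batched solves."""
    n = V.shape[0]
    rng = np.random.default_rng(seed)
    ssii = np.zeros(max_richness)
    n1 = 2
    for n2 in range(1, max_richness + 1):
        pick1 = np.empty((reps, n1), dtype=np.intp)
        pick2 = np.empty((reps, n2), dtype=np.intp)
        for r in range(reps):
            pick1[r] = rng.choice(n, size=n1, replace=False)
            pick2[r] = rng.choice(n, size=n2, replace=False)
        C11 = V[pick1[:, :, None], pick1[:, None, :]]
        C22 = V[pick2[:, :, None], pick2[:, None, :]]
        C12 = V[pick1[:, :, None], pick2[:, None, :]]
        X = np.linalg.solve(C22, np.swapaxes(C12, 1, 2))
        S11 = C11 - C12 @ X
        tr = S11[:, 0, 0] + S11[:, 1, 1]
        ssii[n2 - 1] = float((n1 * tr - S11.sum(axis=(1, 2))).mean() / (n1 * (n1 - 1)))
    scii = 1.0 - (V.sum() - np.trace(V)) / (n * (n - 1))
    return ssii, float(scii)


def pcd_pair(
    V: np.ndarray,
    labels: list[str],
    comm_a,
    comm_b,
    ssii: np.ndarray | None = None,
    scii: float | None = None,
    reps: int = 2000,
    seed: int = 0,
    name_a: str = "A",
    name_b: str = "B",
) -> PCDResult:
    """PCD between two communities (presence sets) over a pool correlation.

    ``ssii``/``scii`` are the random-assemblage normalizers; computing them
    per call is wasteful, so matrix-level callers precompute them once.
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    pick1 = np.array([idx[s] for s in comm_a], dtype=np.intp)
    pick2 = np.array([idx[s] for s in comm_b], dtype=np.intp)
    if pick1.size == 0 or pick2.size == 0:
        raise ValueError("communities must be nonempty")
    n = V.shape[0]
    n1, n2 = pick1.size, pick2.size
    if ssii is None or scii is None:
        ssii, scii = expected_conditional_psv(V, max(n1, n2), reps=reps, seed=seed)

    C11 = V[np.ix_(pick1, pick1)]
    C22 = V[np.ix_(pick2, pick2)]
    C12 = V[np.ix_(pick1, pick2)]
    S11 = C11 - C12 @ np.linalg.solve(C22, C12.T)
    S22 = C22 - C12.T @ np.linalg.solve(C11, C12)
    sc11, ss11 = _psv(C11, n1), _psv(S11, n1)
    sc22, ss22 = _psv(C22, n2), _psv(S22, n2)
    D = (n1 * ss11 + n2 * ss22) / (n1 * sc11 + n2 * sc22)

    union = len(set(pick1.tolist()) | set(pick2.tolist()))
    dsor = 2.0 * union / (2.0 * union + (n1 - union) + (n2 - union)) - 1.0
    pred_d = (n1 * ssii[n2 - 1] + n2 * ssii[n1 - 1]) / (n1 * scii + n2 * scii)
    pred_dsor = 1.0 - 2.0 * n1 * n2 / ((n1 + n2) * n)

    pcd_total = D / pred_d
    pcd_comp = dsor / pred_dsor
    pcd_phy = pcd_total / pcd_comp if pcd_comp != 0 else float("nan")
    return PCDResult(name_a, name_b, float(pcd_total), float(pcd_comp), float(pcd_phy))


def pcd_matrix(
    tree_or_corr,
    community: pd.DataFrame,
    reps: int = 2000,
    seed: int = 0,
    dimension: str = "phylogenetic",
) -> pd.DataFrame:
    """All-pairs PCD over the plots of a community table.

    ``tree_or_corr`` is a dendropy tree/dendrogram or a precomputed
    ``(labels, correlation)`` pair.  The pool is the union of species over
    the analyzed plots; plots with fewer than one species are skipped with
    a warning.  Returns the upper-triangle long table.
    """
    if isinstance(tree_or_corr, dendropy.Tree):
        labels, V = phylo_correlation(tree_or_corr)
    else:
        labels, V = tree_or_corr
        V = np.asarray(V, dtype=float)

    present: dict[str, list[str]] = {}
    for plot, grp in community.groupby("plot", sort=True):
        sp = sorted(set(grp.loc[grp["percent_cover"] > 0, "species"]) & set(labels))
        if len(sp) < 1:
            log.warning("pcd_matrix: plot %s has no pool species, skipped", plot)
            continue
        present[plot] = sp
    plots = list(present)
    if len(plots) < 2:
        raise ValueError("need at least 2 usable plots")

    pool = sorted(set().union(*present.values()))
    idx = [labels.index(s) for s in pool]
    Vp = V[np.ix_(idx, idx)]
    max_r = max(len(s) for s in present.values())
    ssii, scii = expected_conditional_psv(Vp, max_r, reps=reps, seed=seed)

    rows = []
    for i, a in enumerate(plots):
        for b in plots[i + 1 :]:
            res = pcd_pair(Vp, pool, present[a], present[b], ssii=ssii, scii=scii,
                           name_a=a, name_b=b)
            rows.append((a, b, dimension, res.pcd_total, res.pcd_comp, res.pcd_phy))
    return pd.DataFrame(rows, columns=["plot_a", "plot_b", "dimension",
                                       "pcd_total", "pcd_comp", "pcd_phy"])
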