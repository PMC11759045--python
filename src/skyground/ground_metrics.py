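"""Plot-level diversity metrics for the taxonomic, trait, and phylogenetic
dimensions.

The module implements the classical Hill-number family (richness *S*,
Shannon *H*, Simpson *D*), mean pairwise distance (MPD, renamed MTD/MSD in
trait/spectral space), Faith's phylogenetic diversity (PD, rooted variant),
the distance-based dispersion family ``qD(.M)`` — the "effective number of
distinct species" combining richness, dispersion evenness, and the mean
scaled distance — and standardized effect sizes (SES) against a
label-shuffling null.

Conventions
-----------
* ``qD(.M) = 1 + (S - 1) * qE(T) * M'`` with distances pre-scaled to [0, 1]
  by a global maximum; at ``q = 0`` this reduces to ``1 + (S - 1) * M'``.
* MPD is unweighted by abundance (mean over unordered pairs).
* Faith's PD includes the stem path to the root; for a single member it is
  the root-to-tip path length.
* SES uses a taxa-label shuffle holding plot richness fixed (999 reps by
  default), which is equivalent to drawing the same number of species
  uniformly from the pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from . import trees

__all__ = [
    "AbundanceVector",
    "DispersionComponents",
    "SESResult",
    "relative_abundance",
    "taxonomic_metrics",
    "mean_pairwise_distance",
    "faith_pd",
    "patristic_matrix",
    "dispersion_qD",
    "ses_mean_pairwise",
    "ses_standardize",
    "community_metric_table",
]


@dataclass(frozen=True)
class AbundanceVector:
    """Relative abundances of the species present in one plot."""

    species: tuple[str, ...]
    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.size == 0 or np.any(p <= 0):
            raise ValueError("abundances must be positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")


@dataclass(frozen=True)
class DispersionComponents:
    S: int
    m_i: np.ndarray  # per-species mean scaled distance to the others
    M_prime: float  # magnitude of dispersion, mean of m_i
    qDT: float  # effective number of equally distinct species
    qET: float  # evenness component qDT / S
    qDTM: float  # effective number of distinct species, 1 + (S-1)*qET*M'


@dataclass(frozen=True)
class SESResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_null: int
    seed: int


def relative_abundance(cover, species=None) -> AbundanceVector:
    """Convert a percent-cover row into relative abundances.

    Zero-cover species are dropped.  ``cover`` may be a mapping
    species -> cover or an array paired with ``species``.
    """
    if hasattr(cover, "items"):
        items = [(s, float(c)) for s, c in cover.items()]
    else:
        cov = np.asarray(cover, dtype=float)
        if species is None:
            species = [f"sp{i}" for i in range(cov.size)]
        items = list(zip(species, cov))
    items = [(s, c) for s, c in items if c > 0]
    if not items:
        raise ValueError("plot has no species with positive cover")
    total = sum(c for _, c in items)
    return AbundanceVector(
        species=tuple(s for s, _ in items),
        p=np.array([c / total for _, c in items]),
    )


def taxonomic_metrics(abund: AbundanceVector) -> dict[str, float]:
    """Richness S (q=0), Shannon H (q=1), Simpson D (q=2)."""
    p = abund.p
    return {
        "S": float(p.size),
        "H": float(-(p * np.log(p)).sum()),
        "D": float(1.0 - (p**2).sum()),
    }


def _submatrix(D: np.ndarray, labels: list[str], members) -> np.ndarray:
    idx = {lab: i for i, lab in enumerate(labels)}
    missing = [m for m in members if m not in idx]
    if missing:
        raise KeyError(f"unknown species {missing[0]!r}")
    sel = [idx[m] for m in members]
    return D[np.ix_(sel, sel)]


def mean_pairwise_distance(D: np.ndarray, labels=None, members=None) -> float:
    """Unweighted mean of pairwise distances among community members.

    Returns NaN (a missing-value marker, not zero) for fewer than two
    members.
    """
    if labels is not None and members is not None:
        D = _submatrix(np.asarray(D, float), list(labels), list(members))
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        return float("nan")
    iu = np.triu_indices(n, k=1)
    return float(D[iu].mean())


def faith_pd(tree: dendropy.Tree, members) -> float:
    """Faith's PD: branch length of the minimal rooted subtree spanning
    *members*, including the path to the root."""
    members = set(members)
    known = set(trees.tip_labels(tree))
    unknown = members - known
    if unknown:
        raise KeyError(f"unknown species {sorted(unknown)[0]!r}")
    total = 0.0
    for nd in tree.postorder_node_iter():
        if nd.parent_node is None:
            continue
        tips = {lf.taxon.label for lf in nd.leaf_iter()}
        if tips & members:
            total += nd.edge.length or 0.0
    return float(total)


def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip-to-tip path-length distances (delegates to :mod:`skyground.trees`)."""
    return trees.patristic_matrix(tree)


def dispersion_qD(
    D: np.ndarray,
    p: np.ndarray,
    q: float,
    *,
    abundance_weighted: bool = True,
) -> DispersionComponents:
    """Dispersion family ``qD(.M)`` on a distance matrix scaled to [0, 1].

    ``m_i`` is each member's mean scaled distance to the other members, and
    ``M'`` their mean.  The Hill aggregation runs over the per-species
    dispersion profile ``omega_i \\propto p_i * m_i`` (set
    ``abundance_weighted=False`` for ``omega_i \\propto m_i``); at q = 0
    the profile reduces to counting so ``0D(.M) = 1 + (S - 1) M'``.

    A single-member community returns 1 by convention.
    """
    D = np.asarray(D, dtype=float)
    p = np.asarray(p, dtype=float)
    S = p.size
    if D.shape != (S, S):
        raise ValueError("distance matrix and abundance vector disagree in size")
    if S == 1:
        return DispersionComponents(1, np.zeros(1), 0.0, 1.0, 1.0, 1.0)
    if D.min() < -1e-12 or D.max() > 1.0 + 1e-12:
        raise ValueError("distances must be pre-scaled to [0, 1]")

    m_i = D.sum(axis=1) / (S - 1)
    M = float(m_i.mean())

    if q == 0:
        qDT, qET = float(S), 1.0
    else:
        w = p * m_i if abundance_weighted else m_i.copy()
        tot = w.sum()
        if tot <= 0:  # all distances zero: no dispersion at all
            return DispersionComponents(S, m_i, M, float(S), 1.0, 1.0)
        w = w / tot
        w = w[w > 0]
        if q == 1:
            qDT = float(np.exp(-(w * np.log(w)).sum()))
        else:
            qDT = float((w**q).sum() ** (1.0 / (1.0 - q)))
        qET = qDT / S
    qDTM = 1.0 + (S - 1) * qET * M
    return DispersionComponents(S, m_i, M, qDT, qET, qDTM)


def ses_standardize(observed: float, null_values, seed: int = 0) -> SESResult:
    """Standardized effect size of an observed value against null draws."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size < 99:
        raise ValueError("need at least 99 null replicates")
    mu = float(null_values.mean())
    sd = float(null_values.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null: zero standard deviation")
    return SESResult(float(observed), mu, sd, (float(observed) - mu) / sd, null_values.size, seed)


def ses_mean_pairwise(
    D: np.ndarray,
    labels: list[str],
    members,
    n_null: int = 999,
    seed: int = 0,
) -> SESResult:
    """SES of the mean pairwise distance under a taxa-label shuffle.

    Holding richness fixed, each null replicate draws the same number of
    species uniformly without replacement from the pool and recomputes the
    mean pairwise distance.  Vectorized over replicates.
    """
    D = np.asarray(D, dtype=float)
    S = len(list(members))
    if S < 2:
        raise ValueError("SES of MPD needs at least 2 members")
    obs = mean_pairwise_distance(D, labels, members)
    rng = np.random.default_rng(seed)
    n_pool = D.shape[0]
    picks = np.empty((n_null, S), dtype=np.intp)
    for r in range(n_null):
        picks[r] = rng.choice(n_pool, size=S, replace=False)
    sub = D[picks[:, :, None], picks[:, None, :]]  # (n_null, S, S)
    iu = np.triu_indices(S, k=1)
    nulls = sub[:, iu[0], iu[1]].mean(axis=1)
    return ses_standardize(obs, nulls, seed=seed)


def community_metric_table(
    community,  # DataFrame: plot, site, species, percent_cover
    trait_dist: tuple[list[str], np.ndarray] | None = None,
    tree: dendropy.Tree | None = None,
    q_orders=(0, 1, 2),
    n_null: int = 999,
    seed: int = 0,
):
    """Long-format metric table (plot, site, dimension, metric, q, value, z).

    Distances for the dispersion family are scaled by the global maximum
    within each dimension so values are comparable across plots.
    """
    import pandas as pd

    rows = []
    phylo = trees.patristic_matrix(tree) if tree is not None else None

    def scaled(mat):
        mx = mat.max()
        return mat / mx if mx > 0 else mat

    for plot_i, ((plot, site), grp) in enumerate(community.groupby(["plot", "site"], sort=True)):
        plot_seed = (seed + 9973 * (plot_i + 1)) & 0x7FFFFFFF
        abund = relative_abundance(dict(zip(grp["species"], grp["percent_cover"])))
        tax = taxonomic_metrics(abund)
        for m, v in tax.items():
            rows.append((plot, site, "taxonomic", m, {"S": 0, "H": 1, "D": 2}[m], v, np.nan))
        for dim, pack in (("trait", trait_dist), ("phylogenetic", phylo)):
            if pack is None:
                continue
            labels, Dm = pack
            sub = _submatrix(Dm, labels, abund.species)
            name = "MTD" if dim == "trait" else "MPD"
            S = len(abund.species)
            mpd = mean_pairwise_distance(sub)
            z = np.nan
            if S >= 2:
                z = ses_mean_pairwise(Dm, labels, abund.species, n_null=n_null, seed=plot_seed).z
            rows.append((plot, site, dim, name, np.nan, mpd, z))
            subs = _submatrix(scaled(Dm), labels, abund.species)
            for q in q_orders:
                comp = dispersion_qD(subs, abund.p, q)
                mname = "qD(TM)" if dim == "trait" else "qD(PM)"
                rows.append((plot, site, dim, mname, q, comp.qDTM, np.nan))
        if tree is not None:
            rows.append((plot, site, "phylogenetic", "PD", np.nan, faith_pd(tree, abund.species), np.nan))
    return pd.DataFrame(rows, columns=["plot", "site", "dimension", "metric", "q", "value", "z"])
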