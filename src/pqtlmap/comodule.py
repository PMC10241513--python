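"""Weighted co-expression networks built on the biweight midcorrelation.

The biweight midcorrelation (bicor) is an outlier-robust correlation: each
vector is median-centred, observations are down-weighted by Tukey's biweight
of their distance from the median in units of 9*MAD, and the correlation is
taken between the weighted, centred vectors. Network adjacency is
|bicor|^beta (unsigned, soft thresholding), from which the topological
overlap measure (TOM) quantifies shared neighbourhoods:

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

Modules are average-linkage clusters of 1 - TOM under a static tree cut;
each module is summarised by its eigengene, the first principal component of
the standardized member profiles, sign-aligned with the mean member profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "CoexprModule",
    "bicor",
    "bicor_pvalue",
    "bicor_matrix",
    "tom_similarity",
    "build_modules",
    "module_eigengene",
    "module_hotspot_overlap",
]

UNASSIGNED = "grey"

_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
]


@dataclass
class CoexprModule:
    label: str
    members: list[str]
    eigengene: pd.Series  # strain-indexed, unit variance
    variance_explained: float
    soft_power: float


def _biweight(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Weighted, median-centred copy of x; second value True if Pearson fallback."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))  # unscaled MAD
    if mad == 0:
        # Degenerate spread: fall back to mean-centring (Pearson behaviour).
        return x - x.mean(), True
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w, False


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two vectors on pairwise-complete entries.

    Falls back to the Pearson correlation for a vector whose MAD is zero.
    Raises ValueError with fewer than 3 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 complete pairs, got {int(ok.sum())}")
    gx, fx = _biweight(x[ok])
    gy, fy = _biweight(y[ok])
    if fx or fy:
        # a degenerate MAD invalidates the biweight for the whole pair
        gx = x[ok] - x[ok].mean()
        gy = y[ok] - y[ok].mean()
    nx = np.linalg.norm(gx)
    ny = np.linalg.norm(gy)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance vector")
    return float(np.clip((gx @ gy) / (nx * ny), -1.0, 1.0))


def bicor_pvalue(r: float, n: int) -> float:
    """Two-tailed p for a correlation via the Student t transform.

    t = r * sqrt((n-2) / (1-r^2)) against t with n-2 degrees of freedom.
    |r| = 1 returns p = 0 (the transform diverges).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(r)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bicor_matrix(X: pd.DataFrame | np.ndarray, min_pairs: int = 3) -> np.ndarray:
    """All-pairs bicor of the rows of X (features x samples).

    Complete data uses a single vectorised pass. Under missingness each pair
    is computed on its complete cases; pairs with fewer than ``min_pairs``
    shared samples get correlation 0 with a warning.
    """
    A = np.asarray(X, dtype=float)
    p = A.shape[0]
    if not np.isnan(A).any():
        G = np.empty_like(A)
        fallback = np.zeros(p, dtype=bool)
        for i in range(p):
            G[i], fallback[i] = _biweight(A[i])
        norms = np.linalg.norm(G, axis=1)
        norms[norms == 0] = 1.0
        G /= norms[:, None]
        C = np.clip(G @ G.T, -1.0, 1.0)
        if fallback.any():
            # pairs touching a zero-MAD feature revert to Pearson entirely
            P = A - A.mean(axis=1, keepdims=True)
            pn = np.linalg.norm(P, axis=1)
            pn[pn == 0] = 1.0
            P /= pn[:, None]
            CP = np.clip(P @ P.T, -1.0, 1.0)
            touch = fallback[:, None] | fallback[None, :]
            C = np.where(touch, CP, C)
        np.fill_diagonal(C, 1.0)
        return C
    C = np.eye(p)
    short = 0
    for i in range(p):
        for j in range(i + 1, p):
            try:
                C[i, j] = C[j, i] = bicor(A[i], A[j])
            except ValueError:
                C[i, j] = C[j, i] = 0.0
                short += 1
    if short:
        warnings.warn(f"{short} feature pairs had < {min_pairs} shared samples; set to 0", stacklevel=2)
    return C


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with zero diagonal."""
    A = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    T = (L + A) / denom
    np.fill_diagonal(T, 1.0)
    return np.clip(T, 0.0, 1.0)


def build_modules(
    abundance: pd.DataFrame,
    soft_power: float = 6.0,
    min_size: int = 10,
    cut_height: float = 0.9,
) -> list[CoexprModule]:
    """Cluster features into co-expression modules (features x strains input).

    Adjacency |bicor|^soft_power; average-linkage hierarchical clustering of
    1 - TOM; static cut at ``cut_height``. Clusters smaller than ``min_size``
    are pooled into the unassigned ("grey") module, which is not returned.
    Module labels are colour names assigned by decreasing size. All-constant
    features are dropped with a warning.
    """
    values = abundance.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        spread = np.nanstd(values, axis=1)
    keep = np.isfinite(spread) & (spread > 0)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant/empty features", stacklevel=2)
    X = abundance.loc[keep]
    if X.shape[0] < min_size:
        return []
    C = bicor_matrix(X)
    A = np.abs(C) ** soft_power
    T = tom_similarity(A)
    dist = 1.0 - T
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = average(squareform(dist, checks=False))
    labels = fcluster(Z, t=cut_height, criterion="distance")

    ids = np.asarray(X.index)
    clusters = [ids[labels == c].tolist() for c in np.unique(labels)]
    clusters = [m for m in clusters if len(m) >= min_size]
    clusters.sort(key=len, reverse=True)

    modules = []
    for rank, members in enumerate(clusters):
        label = _COLORS[rank] if rank < len(_COLORS) else f"module{rank + 1}"
        eig, ve = module_eigengene(X, members)
        modules.append(
            CoexprModule(
                label=label,
                members=members,
                eigengene=eig,
                variance_explained=ve,
                soft_power=soft_power,
            )
        )
    return modules


def module_eigengene(
    abundance: pd.DataFrame, members: list[str]
) -> tuple[pd.Series, float]:
    """First principal component over strains of the standardized members.

    Missing values are imputed with the feature mean; zero-variance members
    are dropped with a warning. The eigengene is scaled to unit variance and
    sign-aligned so its correlation with the mean member profile is >= 0.
    Returns (eigengene, fraction of variance explained).
    """
    if len(members) < 2:
        raise ValueError("need at least 2 members")
    X = abundance.loc[members].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(X, axis=1)
        X = np.where(np.isnan(X), mu[:, None], X)
        sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance members", stacklevel=2)
        X, mu, sd = X[keep], mu[keep], sd[keep]
        if X.shape[0] < 2:
            raise ValueError("fewer than 2 usable members")
    Zs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    U, S, Vt = np.linalg.svd(Zs, full_matrices=False)
    eig = Vt[0]
    ve = float(S[0] ** 2 / np.sum(S**2))
    mean_profile = Zs.mean(axis=0)
    if mean_profile.std() == 0:
        mean_profile = Zs[0]  # perfectly anti-correlated pair: align with first member
    if np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig = -eig
    eig = eig / eig.std()
    return pd.Series(eig, index=abundance.columns, name="eigengene"), ve


def module_hotspot_overlap(
    module_members: list[str] | set,
    hotspot_members: list[str] | set,
    background: list[str] | set,
) -> tuple[float, float]:
    """Fraction of hotspot members inside the module, with hypergeometric p.

    The overlap fraction is |module ∩ hotspot| / |hotspot| (how much of the
    hotspot's fan-out the module captures); enrichment p is the upper
    hypergeometric tail against the shared feature universe ``background``.
    """
    from .enrich import hypergeom_enrich

    hs = set(hotspot_members)
    if not hs:
        raise ValueError("empty hotspot member set")
    mod = set(module_members)
    frac = len(mod & hs) / len(hs)
    res = hypergeom_enrich(query=mod, category=hs, background=set(background))
    return frac, res.p
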