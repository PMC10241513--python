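"""Linear-mixed-model association scans with kinship correction.

The model for a strain-level response y (a protein's log abundance, a module
eigengene, or a clinical trait) is

    y = X b + g x_j + u + e,     u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I)

where K is a genotype-derived kinship matrix capturing population structure
and x_j the allele dosage at marker j. Following the factored-spectral
approach, K is eigendecomposed once per trait; the variance ratio
delta = sigma_e^2 / sigma_g^2 is estimated by maximum likelihood under the
null (no marker) and held fixed across the genome. Each marker is then tested
by a 1-d.f. likelihood-ratio test in the rotated (whitened) model, which
reduces to weighted least squares and makes a full scan a single vectorised
pass. LOD = LRT / (2 ln 10).

ML (not REML) is used throughout because the LRT compares models with
different fixed effects. Missing response values are handled per trait by
complete-case analysis with the kinship sub-matrixed accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simdata import GenotypePanel

__all__ = [
    "Kinship",
    "NullFit",
    "compute_kinship",
    "fit_null",
    "scan_lmm",
    "scan_ols",
    "scan_features",
    "genomic_inflation",
    "permutation_threshold",
    "GENOMEWIDE_ALPHA",
    "LOG10_FACTOR",
]

# Genome-wide significance threshold used throughout (configurable in the
# pipeline): panel-specific value established for this mapping population.
GENOMEWIDE_ALPHA = 4.1e-6

LOG10_FACTOR = 2.0 * np.log(10.0)

_PSD_TOL = 1e-8
_MIN_P = 1e-300


@dataclass
class Kinship:
    """Strain-by-strain genetic similarity; the random-effect covariance."""

    matrix: np.ndarray
    strain_ids: list[str]
    method: str = "standardized-dot"

    def subset(self, idx: np.ndarray) -> "Kinship":
        ids = [self.strain_ids[i] for i in idx]
        return Kinship(self.matrix[np.ix_(idx, idx)], ids, self.method)


@dataclass
class NullFit:
    """Null-model ML fit: variance components and the cached rotation."""

    delta: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # U, strains x strains
    y_rot: np.ndarray
    X_rot: np.ndarray


def compute_kinship(panel: GenotypePanel, strain_idx: np.ndarray | None = None) -> Kinship:
    """K = Z Z' / M over column-standardized polymorphic markers.

    Monomorphic markers (on the analysis subset) are dropped. The resulting
    matrix is symmetric PSD with unit average diagonal.
    """
    G = panel.alleles.astype(float)
    ids = list(panel.strain_ids)
    if strain_idx is not None:
        G = G[strain_idx, :]
        ids = [ids[i] for i in strain_idx]
    if G.shape[0] < 2:
        raise ValueError("need at least 2 strains")
    sd = G.std(axis=0)
    poly = sd > 0
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic markers")
    Z = (G[:, poly] - G[:, poly].mean(axis=0)) / sd[poly]
    K = (Z @ Z.T) / poly.sum()
    K = (K + K.T) / 2.0
    return Kinship(matrix=K, strain_ids=ids)


def _profile_negll(log_delta: float, S: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = 1.0 / (S + delta)
    sw = np.sqrt(w)
    A = Xr * sw[:, None]
    b = yr * sw
    beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    rss = float(np.sum((b - A @ beta) ** 2))
    n = yr.size
    if rss <= 0:
        return np.inf
    ll = -0.5 * (n * np.log(2 * np.pi) + np.sum(np.log(S + delta)) + n * np.log(rss / n) + n)
    return -ll


def fit_null(
    y: np.ndarray,
    K: Kinship,
    covariates: np.ndarray | None = None,
    grid: tuple[float, float, int] = (1e-5, 1e5, 100),
) -> NullFit:
    """Maximize the profiled null log-likelihood over delta.

    The search evaluates a log-spaced grid (default 100 points on 1e-5..1e5)
    and refines the best bracket by golden-section to relative tolerance 1e-6.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if np.ptp(y) == 0:
        raise ValueError("constant response: null model is undefined")
    M = np.asarray(K.matrix, dtype=float)
    if M.shape != (n, n):
        raise ValueError("kinship not conformable with y")
    S, U = np.linalg.eigh(M)
    if S.min() < -_PSD_TOL * max(np.trace(M), 1.0):
        raise ValueError("kinship is not positive semidefinite beyond tolerance")
    S = np.clip(S, 0.0, None)

    X = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    yr = U.T @ y
    Xr = U.T @ X

    lo, hi, npts = grid
    lgrid = np.log(np.geomspace(lo, hi, int(npts)))
    vals = np.array([_profile_negll(ld, S, yr, Xr) for ld in lgrid])
    i = int(np.argmin(vals))
    log_delta = float(lgrid[i])
    if 0 < i < len(lgrid) - 1 and vals[i] < vals[i - 1] and vals[i] < vals[i + 1]:
        res = optimize.minimize_scalar(
            _profile_negll,
            bracket=(lgrid[i - 1], lgrid[i], lgrid[i + 1]),
            args=(S, yr, Xr),
            method="golden",
            options={"xtol": 1e-6},
        )
        if np.isfinite(res.fun) and res.fun <= vals[i]:
            log_delta = float(res.x)

    delta = float(np.exp(log_delta))
    w = 1.0 / (S + delta)
    sw = np.sqrt(w)
    A = Xr * sw[:, None]
    b = yr * sw
    beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    rss = float(np.sum((b - A @ beta) ** 2))
    sigma_g2 = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi) + np.sum(np.log(S + delta)) + n * np.log(sigma_g2) + n)
    return NullFit(
        delta=delta,
        sigma_g2=sigma_g2,
        sigma_e2=delta * sigma_g2,
        loglik=float(ll),
        eigenvalues=S,
        eigenvectors=U,
        y_rot=yr,
        X_rot=Xr,
    )


def _scan_rotated(
    null: NullFit, G_rot: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-marker LRT with delta fixed at the null estimate."""
    n = null.y_rot.size
    w = 1.0 / (null.eigenvalues + null.delta)
    sw = np.sqrt(w)
    A = null.X_rot * sw[:, None]
    b = null.y_rot * sw
    Q, _ = np.linalg.qr(A)
    r0 = b - Q @ (Q.T @ b)
    rss0 = float(r0 @ r0)
    Gw = G_rot * sw[:, None]
    RG = Gw - Q @ (Q.T @ Gw)
    denom = np.einsum("ij,ij->j", RG, RG)
    num = RG.T @ r0
    scale = max(rss0, 1.0) * n
    degenerate = denom <= 1e-12 * scale
    safe = np.where(degenerate, 1.0, denom)
    beta = np.where(degenerate, 0.0, num / safe)
    rss1 = np.clip(rss0 - np.where(degenerate, 0.0, num**2 / safe), 1e-300, None)
    lrt = np.where(degenerate, 0.0, n * np.log(rss0 / rss1))
    lrt = np.clip(lrt, 0.0, None)
    p = np.clip(stats.chi2.sf(lrt, df=1), _MIN_P, 1.0)
    p = np.where(degenerate, 1.0, p)
    return beta, p, lrt / LOG10_FACTOR, degenerate


def scan_lmm(
    y: np.ndarray,
    panel: GenotypePanel,
    K: Kinship,
    null: NullFit,
    strain_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """Genome scan of one response with the variance ratio fixed at the null fit.

    Returns one row per marker: marker_id, chrom, pos_bp, beta, p, lod, flag,
    n_used. Markers monomorphic on the analysis subset (or collinear with the
    covariates) are emitted with p=1, beta=0 and a flag rather than dropped.
    """
    G = panel.alleles.astype(float)
    if strain_idx is not None:
        G = G[strain_idx, :]
    if G.shape[0] != null.y_rot.size:
        raise ValueError("null fit and genotype subset have different strain counts")
    mono = G.std(axis=0) == 0
    G_rot = null.eigenvectors.T @ G
    beta, p, lod, degen = _scan_rotated(null, G_rot)
    beta = np.where(mono, 0.0, beta)
    p = np.where(mono, 1.0, p)
    lod = np.where(mono | degen, 0.0, lod)
    flag = np.where(mono, "monomorphic", np.where(degen, "collinear", ""))
    return pd.DataFrame(
        {
            "marker_id": panel.marker_ids,
            "chrom": panel.chrom,
            "pos_bp": panel.pos_bp,
            "beta": beta,
            "p": p,
            "lod": lod,
            "flag": flag,
            "n_used": G.shape[0],
        }
    )


def scan_ols(y: np.ndarray, panel: GenotypePanel, strain_idx: np.ndarray | None = None) -> pd.DataFrame:
    """Naive single-marker regression scan (no kinship): the inflation baseline."""
    y = np.asarray(y, dtype=float)
    G = panel.alleles.astype(float)
    if strain_idx is not None:
        G = G[strain_idx, :]
    n = y.size
    yc = y - y.mean()
    Gc = G - G.mean(axis=0)
    denom = np.einsum("ij,ij->j", Gc, Gc)
    mono = denom <= 0
    safe = np.where(mono, 1.0, denom)
    beta = (Gc.T @ yc) / safe
    rss0 = float(yc @ yc)
    rss1 = np.clip(rss0 - beta**2 * safe, 1e-300, None)
    lrt = np.where(mono, 0.0, n * np.log(rss0 / rss1))
    p = np.where(mono, 1.0, np.clip(stats.chi2.sf(lrt, df=1), _MIN_P, 1.0))
    return pd.DataFrame(
        {
            "marker_id": panel.marker_ids,
            "chrom": panel.chrom,
            "pos_bp": panel.pos_bp,
            "beta": np.where(mono, 0.0, beta),
            "p": p,
            "lod": np.clip(lrt, 0, None) / LOG10_FACTOR,
            "flag": np.where(mono, "monomorphic", ""),
            "n_used": n,
        }
    )


def scan_features(
    abundance: pd.DataFrame,
    panel: GenotypePanel,
    K: Kinship | None = None,
    min_strains: int = 10,
) -> pd.DataFrame:
    """LMM scan of every feature in an abundance table (features x strains).

    Each feature is analysed on its complete cases; the kinship matrix is
    sub-matrixed per missingness pattern (patterns are grouped so the
    eigendecomposition is reused). Features observed in fewer than
    ``min_strains`` strains are skipped.
    """
    if K is None:
        K = compute_kinship(panel)
    cols = list(abundance.columns)
    if cols != list(panel.strain_ids):
        abundance = abundance.reindex(columns=panel.strain_ids)
    results = []
    patterns: dict[bytes, list[str]] = {}
    values = abundance.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    for i, fid in enumerate(abundance.index):
        patterns.setdefault(observed[i].tobytes(), []).append(fid)
    for key, fids in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        idx = np.flatnonzero(mask)
        if idx.size < min_strains:
            continue
        Ksub = K.matrix[np.ix_(idx, idx)]
        Kin = Kinship(Ksub, [panel.strain_ids[i] for i in idx], K.method)
        for fid in fids:
            yv = values[abundance.index.get_loc(fid), idx]
            if np.ptp(yv) == 0:
                continue
            null = fit_null(yv, Kin)
            rec = scan_lmm(yv, panel, Kin, null, strain_idx=idx)
            rec.insert(0, "feature_id", fid)
            results.append(rec)
    if not results:
        return pd.DataFrame(
            columns=["feature_id", "marker_id", "chrom", "pos_bp", "beta", "p", "lod", "flag", "n_used"]
        )
    return pd.concat(results, ignore_index=True)


def genomic_inflation(p: np.ndarray) -> float:
    """Genomic inflation factor: median observed chi2(1) over its null median."""
    chi2 = stats.chi2.isf(np.clip(np.asarray(p, float), _MIN_P, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def permutation_threshold(
    y: np.ndarray,
    panel: GenotypePanel,
    K: Kinship,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Permutation-based genome-wide p-value threshold (off by default).

    Permutes the response across strains, rescans, and returns the alpha
    quantile of the per-permutation minimum p. The fixed published threshold
    (GENOMEWIDE_ALPHA) is used by default in the pipeline; this utility exists
    for sensitivity analyses.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    minima = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        null = fit_null(yp, K)
        minima[b] = scan_lmm(yp, panel, K, null)["p"].min()
    return float(np.quantile(minima, alpha))
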