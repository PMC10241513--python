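"""LOD-drop mediation and multiparent founder allele effects.

Mediation asks whether a candidate gene's abundance explains a trans-QTL:
the locus LOD for a target is recomputed with the candidate added as a
covariate, and the drop delta_lod = lod_marginal - lod_conditional ranks
candidates. A large drop means the locus signal flows through the candidate
— the signature of a local driver.

For diversity-outbred cohorts the locus is described by an n x 8
founder-haplotype dosage matrix; allele effects are estimated by least
squares under a sum-to-zero contrast, and concordance of two loci's
effect vectors (e.g. a target's and its candidate driver's) is their Pearson
correlation. Because a single locus is analysed at a time, plain
least-squares LOD is used here (no kinship term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import DO_FOUNDERS, FounderDosage

__all__ = [
    "MediationRecord",
    "FounderEffectVector",
    "lod_linear",
    "dosage_design",
    "mediation_scan",
    "founder_effects",
    "effect_concordance",
]


@dataclass
class MediationRecord:
    target: str
    mediator: str
    lod_marginal: float
    lod_conditional: float
    flag: str = ""

    @property
    def delta_lod(self) -> float:
        return self.lod_marginal - self.lod_conditional


@dataclass
class FounderEffectVector:
    effects: np.ndarray  # length 8, sums to zero over estimable founders
    se: np.ndarray
    founders: tuple[str, ...] = DO_FOUNDERS
    flags: list[str] = field(default_factory=list)


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def lod_linear(y: np.ndarray, X1: np.ndarray, X0: np.ndarray) -> float:
    """LOD = (n/2) log10(RSS0 / RSS1) comparing nested least-squares fits.

    ``X0``'s column space must be contained in ``X1``'s. Rank-deficient
    designs are handled by the least-norm solution with a warning. When the
    null already fits exactly (RSS0 ~ 0) the LOD is defined as 0.
    """
    y = np.asarray(y, dtype=float)
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    n = y.size
    if X1.shape[0] != n or X0.shape[0] != n:
        raise ValueError("design row counts must match y")
    if n <= X1.shape[1]:
        raise ValueError("need n > number of columns in X1")
    rss1, rank1 = _rss(y, X1)
    rss0, _ = _rss(y, X0)
    if rank1 < X1.shape[1]:
        warnings.warn("rank-deficient design; using pseudo-inverse solution", stacklevel=2)
    tiny = 1e-12 * max(float(y @ y), 1.0)
    if rss0 <= tiny:
        return 0.0
    rss1 = max(rss1, tiny)
    return max(0.0, (n / 2.0) * np.log10(rss0 / rss1))


def dosage_design(dosages: FounderDosage | np.ndarray) -> np.ndarray:
    """Sum-to-zero locus design (n x 7) from an n x 8 founder dosage matrix.

    Rows of the dosage matrix sum to 2, making the 8 columns collinear with
    the intercept; projecting onto a sum-to-zero contrast basis removes the
    redundancy while preserving the 7 d.f. of the locus.
    """
    D = dosages.dosages if isinstance(dosages, FounderDosage) else np.asarray(dosages, float)
    return D @ _contrast_basis(8)


def _contrast_basis(m: int) -> np.ndarray:
    """Orthonormal basis (m x m-1) of the sum-to-zero subspace."""
    A = np.eye(m) - np.full((m, m), 1.0 / m)
    U, S, _ = np.linalg.svd(A)
    return U[:, : m - 1]


def mediation_scan(
    target: np.ndarray | pd.Series,
    locus: np.ndarray,
    candidates: pd.DataFrame,
) -> pd.DataFrame:
    """LOD-drop mediation of one target's locus signal against candidates.

    ``locus`` is the locus design (allele dosage column for an inbred panel,
    or the 7-column founder contrast design from :func:`dosage_design`);
    ``candidates`` is features x individuals on the same individuals as
    ``target``. For each candidate c the conditional LOD compares
    y ~ 1 + c + locus against y ~ 1 + c. Missing candidate values are handled
    per candidate by complete-case analysis, with the marginal LOD recomputed
    on the same individuals so delta_lod compares like with like. Records are
    sorted by delta_lod descending; candidates collinear with the locus
    design are flagged, not dropped.
    """
    y = np.asarray(pd.Series(target), dtype=float)
    L = np.atleast_2d(np.asarray(locus, dtype=float))
    if L.shape[0] != y.size:
        L = L.T
    ok_base = np.isfinite(y) & np.all(np.isfinite(L), axis=1)

    rows = []
    values = candidates.to_numpy(dtype=float)
    for i, cid in enumerate(candidates.index):
        c_full = values[i]
        ok = ok_base & np.isfinite(c_full)
        ys, Ls, c = y[ok], L[ok], c_full[ok][:, None]
        ones = np.ones((ys.size, 1))
        X1 = np.hstack([ones, Ls])
        lod_marg = lod_linear(ys, X1, ones)
        Xc0 = np.hstack([ones, c])
        Xc1 = np.hstack([ones, c, Ls])
        flag = ""
        if np.linalg.matrix_rank(Xc1) < np.linalg.matrix_rank(X1) + 1:
            flag = "collinear"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lod_cond = lod_linear(ys, Xc1, Xc0)
        rows.append((cid, lod_marg, lod_cond, lod_marg - lod_cond, flag))
    out = pd.DataFrame(
        rows, columns=["mediator", "lod_marginal", "lod_conditional", "delta_lod", "flag"]
    )
    return out.sort_values("delta_lod", ascending=False, ignore_index=True)


def aggregate_mediation(
    targets: pd.DataFrame,
    locus: np.ndarray,
    candidates: pd.DataFrame,
) -> pd.DataFrame:
    """Candidate ranking by mean LOD drop across a set of co-mapping targets.

    Runs :func:`mediation_scan` for every row of ``targets`` (each candidate
    is never scored against itself as target) and averages the LODs per
    candidate. When a hotspot fans out to many targets through one driver,
    averaging over the fan-out suppresses the per-target noise that can let a
    fellow target edge out the true mediator in a single scan.

    Candidates are ranked by mean conditional LOD (ascending): a complete
    mediator drives the locus signal to the null in every target. With
    complete data this ordering coincides with mean delta_lod descending;
    under missingness it is preferred because each candidate's complete-case
    subset shifts its marginal LOD, which contaminates delta across
    candidates while leaving the conditional comparison fair.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    marg: dict[str, float] = {}
    cond: dict[str, float] = {}
    for tid, y in targets.iterrows():
        cands = candidates.drop(index=tid) if tid in candidates.index else candidates
        scan = mediation_scan(y, locus, cands)
        for rec in scan.itertuples():
            sums[rec.mediator] = sums.get(rec.mediator, 0.0) + rec.delta_lod
            marg[rec.mediator] = marg.get(rec.mediator, 0.0) + rec.lod_marginal
            cond[rec.mediator] = cond.get(rec.mediator, 0.0) + rec.lod_conditional
            counts[rec.mediator] = counts.get(rec.mediator, 0) + 1
    rows = [
        (
            cid,
            sums[cid] / counts[cid],
            marg[cid] / counts[cid],
            cond[cid] / counts[cid],
            counts[cid],
        )
        for cid in sums
    ]
    out = pd.DataFrame(
        rows,
        columns=["mediator", "mean_delta_lod", "mean_lod_marginal", "mean_lod_conditional", "n_targets"],
    )
    return out.sort_values("mean_lod_conditional", ascending=True, ignore_index=True)


def founder_effects(y: np.ndarray | pd.Series, dosages: FounderDosage) -> FounderEffectVector:
    """Least-squares founder allele effects at one locus.

    Fits y on an intercept plus 7 sum-to-zero founder contrasts and
    back-transforms to the 8-vector of effects (expression units per dosage)
    summing to zero. A founder absent from the sample is flagged unestimable
    and reported as NaN; the remaining effects sum to zero among themselves.
    """
    y = np.asarray(pd.Series(y), dtype=float)
    D = np.asarray(dosages.dosages, dtype=float)
    n = y.size
    if n < 16:
        raise ValueError("need at least 16 individuals")
    if D.shape != (n, 8):
        raise ValueError("dosages must be n x 8")
    if not np.allclose(D.sum(axis=1), 2.0, atol=1e-6):
        raise ValueError("dosage rows must sum to 2 (diploid)")

    present = D.sum(axis=0) > 0
    flags = [] if present.all() else [
        f"founder {dosages.founders[i]} absent; effect unestimable"
        for i in np.flatnonzero(~present)
    ]
    m = int(present.sum())
    P = _contrast_basis(m)
    X = np.hstack([np.ones((n, 1)), D[:, present] @ P])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / max(dof, 1)
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    eff_sub = P @ beta[1:]
    se_sub = np.sqrt(np.clip(np.diag(P @ cov[1:, 1:] @ P.T), 0.0, None))
    effects = np.full(8, np.nan)
    se = np.full(8, np.nan)
    effects[present] = eff_sub
    se[present] = se_sub
    return FounderEffectVector(effects=effects, se=se, founders=dosages.founders, flags=flags)


def effect_concordance(e1: FounderEffectVector, e2: FounderEffectVector) -> float:
    """Pearson correlation of two loci's founder-effect vectors.

    High positive concordance supports a shared causal variant acting in the
    same direction at both loci (e.g. target and candidate driver).
    """
    if e1.founders != e2.founders:
        raise ValueError("founder labels/order differ")
    a, b = np.asarray(e1.effects, float), np.asarray(e2.effects, float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance effect vector; concordance undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
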