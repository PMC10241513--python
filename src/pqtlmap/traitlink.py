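"""Genotype-stratified trait comparisons and robust trait correlations.

At a peak marker, strains split into the two homozygous allele groups of an
inbred panel; group differences in a protein, eigengene or clinical trait are
tested by the pooled-variance (Student) unpaired two-tailed t-test, reporting
the direction of the allele effect. Feature-by-trait relationships use the
biweight midcorrelation with its t-based p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .comodule import bicor, bicor_pvalue
from .simdata import GenotypePanel

__all__ = ["StratifiedComparison", "genotype_stratify", "trait_correlation", "stratify_many"]


@dataclass
class StratifiedComparison:
    marker_id: str
    n0: int
    n1: int
    mean0: float
    mean1: float
    sd0: float
    sd1: float
    t: float
    p: float
    direction: int  # sign(mean1 - mean0): effect of the alternate allele


def genotype_stratify(
    values: np.ndarray | pd.Series,
    panel: GenotypePanel,
    marker_id: str,
) -> StratifiedComparison:
    """Pooled-variance Student t-test between the two homozygous allele groups.

    ``values`` is a strain-level vector aligned with the panel (a pd.Series is
    aligned by strain id). Strains with missing values are dropped; alleles
    other than 0/1 (residual heterozygous calls in user data) are excluded
    with a warning. Each group needs n >= 2 and the pooled variance must be
    positive.
    """
    if isinstance(values, pd.Series):
        values = values.reindex(panel.strain_ids).to_numpy(dtype=float)
    else:
        values = np.asarray(values, dtype=float)
    g = panel.genotype(marker_id)
    ok = ~np.isnan(values)
    odd = ok & ~np.isin(g, (0, 1))
    if odd.any():
        warnings.warn(f"excluding {int(odd.sum())} non-homozygous calls at {marker_id}", stacklevel=2)
        ok &= ~odd
    v0 = values[ok & (g == 0)]
    v1 = values[ok & (g == 1)]
    if len(v0) < 2 or len(v1) < 2:
        raise ValueError(f"marker {marker_id}: need >= 2 strains per allele group")
    sp2 = (np.sum((v0 - v0.mean()) ** 2) + np.sum((v1 - v1.mean()) ** 2)) / (len(v0) + len(v1) - 2)
    if sp2 <= 0:
        raise ValueError(f"marker {marker_id}: zero pooled variance")
    se = np.sqrt(sp2 * (1 / len(v0) + 1 / len(v1)))
    t = (v1.mean() - v0.mean()) / se
    p = float(2.0 * stats.t.sf(abs(t), df=len(v0) + len(v1) - 2))
    return StratifiedComparison(
        marker_id=marker_id,
        n0=len(v0),
        n1=len(v1),
        mean0=float(v0.mean()),
        mean1=float(v1.mean()),
        sd0=float(v0.std(ddof=1)),
        sd1=float(v1.std(ddof=1)),
        t=float(t),
        p=min(p, 1.0),
        direction=int(np.sign(v1.mean() - v0.mean())),
    )


def trait_correlation(
    feature: np.ndarray | pd.Series, trait: np.ndarray | pd.Series
) -> tuple[float, float, int]:
    """Biweight midcorrelation between a feature and a trait.

    Pairwise-complete; returns (r, two-tailed p, n pairs used). Series inputs
    are aligned on their shared index.
    """
    if isinstance(feature, pd.Series) and isinstance(trait, pd.Series):
        common = feature.index.intersection(trait.index)
        feature = feature.reindex(common).to_numpy(dtype=float)
        trait = trait.reindex(common).to_numpy(dtype=float)
    x = np.asarray(feature, dtype=float)
    y = np.asarray(trait, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    r = bicor(x[ok], y[ok])
    return r, bicor_pvalue(r, int(ok.sum())), int(ok.sum())


def stratify_many(
    table: pd.DataFrame, panel: GenotypePanel, marker_ids: list[str]
) -> pd.DataFrame:
    """Stratified comparisons for each (trait row, marker) pair with BH q.

    ``table`` is traits/features x strains. Pairs failing group-size or
    variance preconditions are skipped. Raw p and BH-adjusted q are reported.
    """
    rows = []
    for trait_id, vals in table.iterrows():
        for mid in marker_ids:
            try:
                c = genotype_stratify(vals, panel, mid)
            except ValueError:
                continue
            rows.append(
                {
                    "trait": trait_id,
                    "marker_id": mid,
                    "n0": c.n0,
                    "n1": c.n1,
                    "mean0": c.mean0,
                    "mean1": c.mean1,
                    "t": c.t,
                    "p": c.p,
                    "direction": c.direction,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
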