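"""Category enrichment of feature sets by the hypergeometric upper tail.

Given a query set (e.g. the members of a trans-hotspot), a category set
(e.g. complex-I proteins) and a background universe (all quantified features),
the enrichment p-value is P(overlap >= k) under sampling without replacement.
The tail is accumulated in log space (log-binomials via gammaln, combined with
logsumexp) so that extreme enrichments do not underflow. Multiple categories
are corrected by Benjamini-Hochberg.

This is a plain hypergeometric test: the modified one-sided EASE variant used
by some annotation servers is deliberately not replicated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "hypergeom_enrich", "enrich_table"]


@dataclass
class EnrichmentResult:
    category: str
    k: int  # overlap
    K: int  # category size
    n: int  # query size
    N: int  # background size
    p: float
    q: float = np.nan


def _log_comb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact in log space."""
    if k <= 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    if i.size == 0:
        return float(k <= 0)
    logp = _log_comb(np.full_like(i, K, dtype=float), i.astype(float))
    logp += _log_comb(np.full_like(i, N - K, dtype=float), (n - i).astype(float))
    logp -= _log_comb(float(N), float(n))
    return float(min(np.exp(logsumexp(logp)), 1.0))


def hypergeom_enrich(query, category, background, label: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``category`` in ``query``.

    Both query and category must be subsets of ``background``; violations are
    reported by id in the error message.
    """
    q, c, bg = set(query), set(category), set(background)
    stray_q = q - bg
    stray_c = c - bg
    if stray_q or stray_c:
        parts = []
        if stray_q:
            parts.append(f"query ids outside background: {sorted(stray_q)[:10]}")
        if stray_c:
            parts.append(f"category ids outside background: {sorted(stray_c)[:10]}")
        raise ValueError("; ".join(parts))
    k = len(q & c)
    p = _hypergeom_sf(k, len(bg), len(c), len(q))
    return EnrichmentResult(category=label, k=k, K=len(c), n=len(q), N=len(bg), p=max(p, 5e-324))


def enrich_table(query, categories: dict, background) -> list[EnrichmentResult]:
    """Enrichment of each category with BH adjustment, sorted by p.

    Empty categories are skipped with a warning. With a single tested
    category the adjusted q equals p.
    """
    if not categories:
        raise ValueError("need at least one category")
    results = []
    for name, members in categories.items():
        members = set(members)
        if not members:
            warnings.warn(f"skipping empty category {name!r}", stacklevel=2)
            continue
        results.append(hypergeom_enrich(query, members, background, label=name))
    if not results:
        return []
    _, qvals, _, _ = multipletests([r.p for r in results], method="fdr_bh")
    for r, qv in zip(results, qvals):
        r.q = float(qv)
    results.sort(key=lambda r: r.p)
    return results
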