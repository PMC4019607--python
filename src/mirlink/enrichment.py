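"""Pathway over-representation by the right-tailed Fisher exact test.

For a query of n genes drawn from a universe of N, a pathway of K genes
overlapping the query in k gives the hypergeometric right-tail
probability

    p = sum_{i=k..min(n,K)} C(K,i) C(N-K, n-i) / C(N,n),

the chance of an overlap at least as large arising by chance alone.
Pathways are ranked by ascending p (ties: descending ratio k/K, then
lexical id) and the top-K listed, with the covered fraction — the share
of query genes inside the union of the listed pathways — reported as a
summary statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .errors import ParameterError

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    pathway_id: str
    k: int  # overlap
    K: int  # pathway size
    n: int  # query size
    N: int  # universe size
    p_right: float
    ratio: float  # k / K
    rank: int = 0
    q: float | None = None


def fisher_right_tail(k: int, n: int, K: int, N: int) -> float:
    """P(overlap >= k) under the hypergeometric null; in (0, 1]."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ParameterError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_pathways(
    query: set[str],
    pathways: dict[str, set[str]],
    universe: set[str] | None = None,
    top_k: int = 30,
    adjust: str = "none",
) -> list[EnrichmentResult]:
    """Rank pathways by right-tail Fisher p on the overlap with ``query``.

    The universe defaults to the union of all pathway genes; query genes
    outside it are logged and clipped.  Optional Benjamini-Hochberg
    q-values (``adjust="BH"``, computed over all pathways) are attached
    without changing the rank order.  Returns the top ``top_k`` results.
    """
    if adjust not in ("none", "BH"):
        raise ParameterError(f"adjust must be 'none' or 'BH', got {adjust!r}")
    if not pathways:
        return []
    if universe is None:
        universe = set().union(*pathways.values())
    stray = set(query) - universe
    if stray:
        log.info("clipping %d query genes outside the universe", len(stray))
    query_in = set(query) & universe
    n, N = len(query_in), len(universe)
    results = []
    for name in sorted(pathways):
        members = pathways[name] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query_in)
        results.append(
            EnrichmentResult(
                pathway_id=name,
                k=k,
                K=K,
                n=n,
                N=N,
                p_right=fisher_right_tail(k, n, K, N),
                ratio=k / K,
            )
        )
    results.sort(key=lambda r: (r.p_right, -r.ratio, r.pathway_id))
    if adjust == "BH":
        m = len(results)
        ps = np.array([r.p_right for r in results])
        # p's are already ascending; running minimum from the tail
        q = np.minimum.accumulate((ps * m / np.arange(1, m + 1))[::-1])[::-1]
        for r, qv in zip(results, np.minimum(q, 1.0)):
            r.q = float(qv)
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results[:top_k]


def covered_fraction(
    results: list[EnrichmentResult], query: set[str], pathways: dict[str, set[str]]
) -> tuple[int, float]:
    """Query genes inside the union of the listed pathways.

    Returns (count, fraction of the query) — e.g. 140 of 348 gives
    0.402 (40.2%).
    """
    union: set[str] = set()
    for r in results:
        union |= pathways[r.pathway_id]
    covered = len(set(query) & union)
    return covered, covered / len(query) if query else 0.0


def summary(
    results: list[EnrichmentResult], query: set[str], pathways: dict[str, set[str]]
) -> dict:
    """Machine-readable enrichment summary, percentage at one decimal."""
    covered, frac = covered_fraction(results, query, pathways)
    return {
        "n_query": len(query),
        "n_pathways_listed": len(results),
        "covered_genes": covered,
        "covered_fraction_pct": round(100.0 * frac, 1),
    }
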