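"""Categorical fold-enrichment and hypergeometric set testing.

A query protein set (e.g. the proteins more abundant in one secretome) is
compared with a detected-proteins background across an annotation
vocabulary (molecular function, biological process, site of expression,
pathway...). For each category the fold enrichment is the category's
frequency in the query over its frequency in the background, and a
one-sided hypergeometric tail probability tests over- or
under-representation; Benjamini-Hochberg correction is applied across all
categories of the vocabulary.

The background is deliberately the *detected* protein universe, not a
whole-proteome one, and unannotated proteins stay in the background size N
(they dilute K/N) — this matches how secretome catalogues are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class AnnotationSet:
    """One annotation vocabulary: category name -> member accessions."""

    vocabulary: str
    categories: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.categories.items():
            if not members:
                raise ValueError(f"category {name!r} has no members")


@dataclass(frozen=True)
class EnrichmentRecord:
    category: str
    k: int  # overlap |query & category|
    n: int  # query size
    K: int  # category size within background
    N: int  # background size
    fold: float
    p_value: float
    q_value: float
    direction: str  # "enriched" | "depleted"


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): the query-vs-background frequency ratio; 0 when k=0."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K and N must all be positive")
    if k < 0 or k > min(n, K):
        raise ValueError(f"infeasible overlap k={k} for n={n}, K={K}")
    return (k / n) / (K / N)


def hypergeom_test(k: int, n: int, K: int, N: int, direction: str) -> float:
    """One-sided hypergeometric tail probability for an overlap of k.

    ``direction='enriched'`` returns P[X >= k] and ``'depleted'`` returns
    P[X <= k], for X ~ Hypergeometric(N, K, n) — the overlap between a
    size-n draw and a size-K category in a size-N background. Both tails
    include the observed point.
    """
    if n <= 0 or K <= 0 or N <= 0 or n > N or K > N:
        raise ValueError("require 0 < n <= N and 0 < K <= N")
    if k < 0 or k > min(n, K):
        raise ValueError(f"infeasible overlap k={k} for n={n}, K={K}")
    if direction == "enriched":
        return float(hypergeom.sf(k - 1, N, K, n))
    if direction == "depleted":
        return float(hypergeom.cdf(k, N, K, n))
    raise ValueError(f"direction must be 'enriched' or 'depleted', got {direction!r}")


def enrich_set(
    query: set[str],
    background: set[str],
    annotations: AnnotationSet,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Test every category of a vocabulary against a query set.

    Category membership is intersected with the background before testing.
    The direction is chosen from the observed fold (enriched when the query
    frequency meets or exceeds the background frequency, depleted
    otherwise), with the matching one-sided tail as p-value. q-values are
    Benjamini-Hochberg over all tested categories; records are sorted by
    ascending p, ties broken by descending fold then category name.

    ``alpha`` is carried for downstream significance calls; it does not
    affect the returned statistics.
    """
    if not query:
        raise ValueError("empty query set")
    stray = sorted(query - background)
    if stray:
        shown = ", ".join(stray[:5]) + ("..." if len(stray) > 5 else "")
        raise ValueError(f"query accessions missing from background: {shown}")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")

    N = len(background)
    n = len(query)
    rows = []
    for category in sorted(annotations.categories):
        members = annotations.categories[category] & background
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        fold = fold_enrichment(k, n, K, N)
        direction = "enriched" if k / n >= K / N else "depleted"
        p = hypergeom_test(k, n, K, N, direction)
        rows.append((category, k, K, fold, p, direction))
    if not rows:
        return []

    _, q_values, _, _ = multipletests([r[4] for r in rows], method="fdr_bh")
    records = [
        EnrichmentRecord(
            category=category,
            k=k,
            n=n,
            K=K,
            N=N,
            fold=fold,
            p_value=p,
            q_value=float(q),
            direction=direction,
        )
        for (category, k, K, fold, p, direction), q in zip(rows, q_values)
    ]
    records.sort(key=lambda r: (r.p_value, -r.fold, r.category))
    return records
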