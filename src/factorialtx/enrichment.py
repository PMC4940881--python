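"""Hypergeometric over-representation tests for annotation terms, TF regulons
and network shells.

The statistic is the exact upper tail of the hypergeometric distribution:
drawing n genes from a population of N in which K carry a term, the p-value
of observing k carriers is P(X >= k). The tail is summed in log space
(log-gamma binomials) for numerical stability at genome scale. Correction is
Bonferroni (the convention used for TF-regulon screening) or none.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

from .containers import EnrichmentResult
from .errors import DataError

log = logging.getLogger(__name__)


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int, strict: bool = False) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    ``X`` counts annotated genes in a sample of ``n`` drawn without
    replacement from a population of ``N`` genes of which ``K`` are
    annotated. With ``strict=True`` the exclusive tail P(X > k) is returned
    instead — the convention of MATLAB's ``1 - hygecdf(k, N, K, n)``, which
    some published worked examples follow.
    """
    for name, value in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(value) != value or value < 0:
            raise DataError(f"hypergeometric parameter {name}={value} must be a non-negative integer")
    k, n, K, N = int(k), int(n), int(K), int(N)
    if K > N or n > N or k > n:
        raise DataError(f"hypergeometric bounds violated: k={k} n={n} K={K} N={N}")

    start = k + 1 if strict else k
    support_lo = max(0, n - (N - K))  # every draw annotated below this is impossible
    support_hi = min(n, K)
    if start <= support_lo:
        return 1.0
    if start > support_hi:
        return 0.0
    log_denom = _log_comb(N, n)
    log_terms = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - log_denom
        for i in range(start, support_hi + 1)
    ]
    m = max(log_terms)
    total = m + math.log(sum(math.exp(t - m) for t in log_terms))
    return min(1.0, math.exp(total))


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, m * p)


def enrich_annotation(
    gene_set: Iterable[str],
    annotation: Mapping[str, set[str]],
    universe: Iterable[str],
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Term over-representation of ``gene_set`` against ``universe``.

    One result is produced per term annotated to at least one gene of the
    set; the Bonferroni multiplier m is the number of terms tested. Results
    are sorted by ascending p, ties broken by term id. Genes outside the
    universe are dropped (logged).
    """
    if correction not in ("none", "bonferroni"):
        raise DataError(f"unknown correction {correction!r}")
    universe = set(universe)
    if not universe:
        raise DataError("empty universe for enrichment")
    gene_set = set(gene_set)
    dropped = gene_set - universe
    if dropped:
        log.warning("enrich_annotation: %d query gene(s) outside the universe dropped", len(dropped))
    gene_set &= universe

    term_pop: dict[str, int] = {}
    term_hits: dict[str, int] = {}
    for gene in universe:
        for term in annotation.get(gene, ()):
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in gene_set:
                term_hits[term] = term_hits.get(term, 0) + 1

    tested = sorted(term_hits)
    m = len(tested)
    N, n = len(universe), len(gene_set)
    results = []
    for term in tested:
        k, K = term_hits[term], term_pop[term]
        p = hypergeom_upper_tail(k, n, K, N)
        p_adj = _bonferroni(p, m) if correction == "bonferroni" else p
        results.append(
            EnrichmentResult(term, k, n, K, N, p, p_adj, significant=p_adj < alpha)
        )
    results.sort(key=lambda r: (r.p, r.term))
    return results


def enrich_tfs(
    gene_set: Iterable[str],
    regulons: Mapping[str, set[str]],
    universe: Iterable[str] | None = None,
    alpha: float = 1e-4,
) -> list[EnrichmentResult]:
    """Transcription-factor regulon enrichment with Bonferroni correction.

    The population is restricted to genes with at least one documented
    regulator (intersected with ``universe``, e.g. the transcriptome, when
    given); the query is likewise intersected. K is each TF's target count
    within the population, and the Bonferroni multiplier is the number of
    TFs with at least one target there. TFs with no target in the query are
    reported with k = 0.
    """
    if not regulons:
        raise DataError("empty regulon map")
    regulated = set().union(*regulons.values())
    population = regulated if universe is None else regulated & set(universe)
    if not population:
        raise DataError("no regulated genes in the universe")
    query = set(gene_set) & population
    if not query:
        raise DataError("query is empty after intersecting with the regulated population")

    in_pop = {tf: targets & population for tf, targets in regulons.items()}
    tested = sorted(tf for tf, targets in in_pop.items() if targets)
    m = len(tested)
    N, n = len(population), len(query)
    results = []
    for tf in tested:
        K = len(in_pop[tf])
        k = len(in_pop[tf] & query)
        p = hypergeom_upper_tail(k, n, K, N)
        p_adj = _bonferroni(p, m)
        results.append(EnrichmentResult(tf, k, n, K, N, p, p_adj, significant=p_adj < alpha))
    results.sort(key=lambda r: (r.p, r.term))
    return results
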