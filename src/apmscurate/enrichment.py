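"""Over-representation analysis of curated hit lists against gene sets.

For a hit list of size n drawn from a universe of N symbols, and a gene
set with K members in the universe of which k are hits, significance is
the exact upper-tail hypergeometric probability

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

with a Benjamini-Hochberg q across all sets tested in a collection, a
Haldane-corrected odds ratio for effect size, a standardized deviation

    z = (k - nK/N) / sqrt( nK(N-K)(N-n) / (N^2 (N-1)) )

and the combined ranking score c = z * (-log10 p).  The combined score is
zero when p = 1 or z = 0, and negative for depleted sets.  The z here is
the hypergeometric standardization, not the rank-based deviation of web
enrichment services, which depends on service-side background permutation
tables and is not reproducible offline.

The default universe is the detected proteome (every protein quantified in
any IP arm) intersected with the collection's members — the standard guard
against abundance bias in AP-MS over-representation analysis.

Symbols are matched case-insensitively throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # hits in set
    K: int  # universe members in set
    n: int  # hit-list size
    N: int  # universe size
    p: float
    q: float
    odds: float
    z: float
    combined: float


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k)."""
    _check_counts(k, K, n, N)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")


def odds_ratio(k: int, K: int, n: int, N: int, correction: float = 0.5) -> float:
    """2x2 odds ratio, Haldane-corrected only when a cell is zero.

    The table is (in set & hit, in set & not hit, not in set & hit,
    not in set & not hit) = (k, K-k, n-k, N-K-n+k).
    """
    _check_counts(k, K, n, N)
    cells = (k, K - k, n - k, N - K - n + k)
    c = correction if any(v == 0 for v in cells) else 0.0
    return ((cells[0] + c) * (cells[3] + c)) / ((cells[1] + c) * (cells[2] + c))


def hypergeom_z(k: int, K: int, n: int, N: int) -> float:
    """Standardized deviation of k from its hypergeometric expectation.

    Degenerate margins (sd = 0: empty or full set, empty or full hit list,
    or N = 1) give z = 0.
    """
    _check_counts(k, K, n, N)
    if N <= 1:
        return 0.0
    mean = n * K / N
    var = n * K * (N - K) * (N - n) / (N * N * (N - 1))
    if var == 0:
        return 0.0
    return (k - mean) / math.sqrt(var)


def combined_score(p: float, z: float, base: float = 10.0) -> float:
    """Ranking score z * (-log p); zero when p = 1 or z = 0, may be negative."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return z * (-math.log(p, base))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    hits: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    min_set: int = 3,
    max_set: int = 2000,
) -> list[EnrichmentResult]:
    """Test every adequately sized set of a collection for over-representation.

    Sets are restricted to the universe first; sets with fewer than
    ``min_set`` or more than ``max_set`` universe members are skipped.
    Hits outside the universe are dropped with a logged count.  Results are
    sorted by combined score descending, ties broken by p ascending then
    set name.  BH adjustment spans all tested sets of the collection.
    """
    uni = frozenset(s.casefold() for s in universe)
    if not uni:
        raise ConfigurationError("enrichment universe is empty")
    hit_set = frozenset(s.casefold() for s in hits)
    outside = hit_set - uni
    if outside:
        logger.warning("dropping %d hit(s) outside the universe", len(outside))
        hit_set &= uni

    n, N = len(hit_set), len(uni)
    rows: list[tuple[str, int, int]] = []
    for name in sorted(collection.sets):
        members = collection.sets[name].members & uni
        K = len(members)
        if not min_set <= K <= max_set:
            continue
        rows.append((name, K, len(members & hit_set)))
    if not rows:
        logger.warning("no gene set within [%d, %d] members after universe restriction", min_set, max_set)
        return []

    p_values = [hypergeom_p(k, K, n, N) for (_, K, k) in rows]
    q_values = bh_adjust(p_values)
    results = []
    for (name, K, k), p, q in zip(rows, p_values, q_values):
        z = hypergeom_z(k, K, n, N)
        results.append(
            EnrichmentResult(
                set_name=name, k=k, K=K, n=n, N=N,
                p=p, q=float(q),
                odds=odds_ratio(k, K, n, N),
                z=z, combined=combined_score(p, z),
            )
        )
    results.sort(key=lambda r: (-r.combined, r.p, r.set_name))
    return results


def default_universe(detected: Iterable[str], collection: GeneSetCollection) -> frozenset[str]:
    """Detected-proteome background: detected symbols that appear in the collection."""
    return frozenset(s.casefold() for s in detected) & collection.all_members


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("set\tk\tK\tn\tN\tp\tq\todds\tz\tcombined\n")
        for r in results:
            fh.write(
                f"{r.set_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p:.6g}\t{r.q:.6g}\t{r.odds:.6g}\t{r.z:.6g}\t{r.combined:.6g}\n"
            )
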