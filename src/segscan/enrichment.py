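"""Over/underrepresentation engine: two-tailed hypergeometric tests with
Bonferroni correction and a signed representation log-odds score.

Given a gene universe of size N, a category with K members in the universe
and a test set of n genes of which k fall in the category, the number of
category genes drawn is hypergeometric.  The two-tailed p value follows the
minimum-likelihood convention: the sum of the probabilities of all feasible
overlaps no more probable than the observed one (with a small relative
tolerance guarding floating ties).  Each category's p value is Bonferroni-
multiplied by the number of categories tested; the replication default for
the significance level is alpha = 0.0025.

The representation score mirrors the scan statistic: sign +1/-1 for over-/
underrepresentation relative to the genome-wide rate K/N, magnitude
``log10((1 - p)/p)``, so categories depleted in the set plot downward and
enriched ones upward.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .bsa_scan import P_FLOOR, log_odds

#: Replication-mode significance level for Bonferroni-adjusted p values.
DEFAULT_ALPHA = 0.0025

#: Relative tolerance when comparing probability masses for the
#: minimum-likelihood two-sided sum; guards against floating-point ties.
TIE_RTOL = 1e-7

RESULT_COLUMNS = [
    "category", "N", "K", "n", "k", "expected",
    "p_two", "p_adj", "significant", "rep_log_odds", "direction",
]


def _check_counts(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not (max(0, n + K - N) <= k <= min(K, n)):
        raise ValueError(
            f"overlap k={k} outside the feasible range "
            f"[{max(0, n + K - N)}, {min(K, n)}] for N={N}, K={K}, n={n}"
        )


def hypergeom_two_tailed_support(
    N: int, K: int, n: int, method: Literal["min-likelihood", "double"] = "min-likelihood"
) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed p value for *every* feasible overlap k at (N, K, n).

    Returns the support array and matching p values.  ``min-likelihood``
    (default) sums all masses <= the observed mass times (1 + TIE_RTOL);
    ``double`` doubles the smaller one-sided tail (capped at 1).
    """
    _check_counts(N, K, n, max(0, n + K - N))
    lo, hi = max(0, n + K - N), min(K, n)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    if method == "min-likelihood":
        order = np.argsort(pmf, kind="stable")
        csum = np.cumsum(pmf[order])
        # for each k, total mass of outcomes no more probable than it;
        # normalising by the full mass keeps "all outcomes qualify" at
        # exactly 1 despite pmf rounding
        pos = np.searchsorted(pmf[order], pmf * (1.0 + TIE_RTOL), side="right")
        p = csum[pos - 1] / csum[-1]
    elif method == "double":
        cdf = np.cumsum(pmf)
        sf = np.cumsum(pmf[::-1])[::-1]
        p = 2.0 * np.minimum(cdf, sf)
    else:
        raise ValueError(f"unknown two-sided method {method!r}")
    return support, np.minimum(p, 1.0)


def hypergeom_two_tailed(
    N: int, K: int, n: int, k: int,
    method: Literal["min-likelihood", "double"] = "min-likelihood",
) -> float:
    """Two-tailed hypergeometric probability of overlap ``k`` (see module
    docstring for the parametrisation and the two-sided convention)."""
    _check_counts(N, K, n, k)
    support, p = hypergeom_two_tailed_support(N, K, n, method)
    return float(p[k - support[0]])


def hypergeom_tails(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """One-sided (lower, upper) inclusive tail probabilities."""
    _check_counts(N, K, n, k)
    return float(hypergeom.cdf(k, N, K, n)), float(hypergeom.sf(k - 1, N, K, n))


def bonferroni(p_values: Iterable[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m * p)`` per value.

    ``m`` defaults to the number of supplied p values and must be at least
    that number when given explicitly.
    """
    p = np.asarray(list(p_values), dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    m_eff = len(p) if m is None else int(m)
    if m_eff < len(p):
        raise ValueError(f"m = {m_eff} smaller than the number of tests ({len(p)})")
    return np.minimum(1.0, m_eff * p)


def representation_log_odds(N: int, K: int, n: int, k: int, p_two: float) -> float:
    """Signed representation score: sign(k/n - K/N) * log10((1-p)/p).

    Zero when the set hits the category at exactly the genome-wide rate;
    large positive for strong overrepresentation, large negative for
    strong underrepresentation (clamped to +/-300 via the probability
    floor shared with the genome scan).
    """
    _check_counts(N, K, n, k)
    if not 0 < p_two <= 1:
        raise ValueError("p_two must lie in (0, 1]")
    if n == 0 or N == 0:
        return 0.0
    diff = k * N - K * n  # sign of k/n - K/N on integers
    sign = (diff > 0) - (diff < 0)
    return float(sign * log_odds(p_two))


def frequency_log_odds_ratio(N: int, K: int, n: int, k: int) -> float:
    """Alternative descriptive score: log10 odds ratio of in-set vs
    genome-wide category odds, ``log10[(k/(n-k)) / (K/(N-K))]``; +/-inf at
    the boundaries."""
    _check_counts(N, K, n, k)
    set_odds = np.inf if n == k else k / (n - k)
    genome_odds = np.inf if N == K else K / (N - K)
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(np.log10(set_odds) - np.log10(genome_odds))


def enrich(
    test_set: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    m: int | None = None,
    method: Literal["min-likelihood", "double"] = "min-likelihood",
) -> pd.DataFrame:
    """Test every category for over/underrepresentation in ``test_set``.

    Parameters
    ----------
    test_set, universe
        Gene identifiers; the test set must be contained in the universe.
    annotations
        category id -> member genes; members outside the universe are an
        error (annotations and universe must agree on the gene space).
    m
        Bonferroni family size; defaults to the number of categories
        tested in this run.

    Returns
    -------
    One row per category, ordered by ``p_two`` then category id, with the
    counts, two-tailed p, Bonferroni-adjusted p, significance at ``alpha``
    and the signed representation log odds.
    """
    universe_set = set(universe)
    test = set(test_set)
    outside = test - universe_set
    if outside:
        raise ValueError(f"test genes outside the universe: {sorted(outside)[:10]}")
    N, n = len(universe_set), len(test)
    rows = []
    for category in sorted(annotations):
        members = set(annotations[category])
        stray = members - universe_set
        if stray:
            raise ValueError(
                f"category {category!r} has members outside the universe: {sorted(stray)[:10]}"
            )
        K = len(members)
        k = len(members & test)
        p_two = hypergeom_two_tailed(N, K, n, k, method)
        rows.append((category, N, K, n, k, K * n / N if N else 0.0, p_two,
                     representation_log_odds(N, K, n, k, p_two)))
    df = pd.DataFrame(
        rows, columns=["category", "N", "K", "n", "k", "expected", "p_two", "rep_log_odds"]
    )
    df["p_adj"] = bonferroni(df["p_two"], m=m) if len(df) else []
    df["significant"] = df["p_adj"] <= alpha
    diff = df["k"] * df["N"] - df["K"] * df["n"]
    df["direction"] = np.select([diff > 0, diff < 0], ["over", "under"], "none")
    df = df.sort_values(["p_two", "category"], kind="stable").reset_index(drop=True)
    return df[RESULT_COLUMNS]
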