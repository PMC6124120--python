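"""Independent brute-force oracles used by the test suite.

These deliberately recompute probabilities by exhaustive enumeration over
the full outcome grid, sharing no code path with the package's bounded
cdf/sf implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom, hypergeom


def binomial_diff_p_scalar(k_u: int, n_u: int, k_m: int, n_m: int) -> float:
    """P(|K_U*n_M - K_M*n_U| >= |k_u*n_M - k_m*n_U|) by double enumeration."""
    p_hat = (k_u + k_m) / (n_u + n_m)
    t_obs = abs(k_u * n_m - k_m * n_u)
    total = 0.0
    for i in range(n_u + 1):
        pi = binom.pmf(i, n_u, p_hat)
        for j in range(n_m + 1):
            if abs(i * n_m - j * n_u) >= t_obs:
                total += pi * binom.pmf(j, n_m, p_hat)
    return min(total, 1.0)


def binomial_diff_p_grid(n_u: int, n_m: int) -> np.ndarray:
    """Oracle p for every (k_u, k_m); returns an (n_u+1, n_m+1) array.

    Enumerates the outer-product outcome grid once per pooled total: all
    outcomes are sorted by |i*n_m - j*n_u| and suffix-summed, so each
    observed difference reads its tail off the enumeration directly.
    """
    i = np.arange(n_u + 1)[:, None]
    j = np.arange(n_m + 1)[None, :]
    absd = np.abs(i * n_m - j * n_u).ravel()
    order = np.argsort(absd, kind="stable")
    absd_sorted = absd[order]
    out = np.empty((n_u + 1, n_m + 1))
    for s in range(n_u + n_m + 1):
        p_hat = s / (n_u + n_m)
        grid = np.outer(binom.pmf(np.arange(n_u + 1), n_u, p_hat),
                        binom.pmf(np.arange(n_m + 1), n_m, p_hat))
        suffix = np.concatenate([np.cumsum(grid.ravel()[order][::-1])[::-1], [0.0]])
        ku = np.arange(max(0, s - n_m), min(s, n_u) + 1)
        km = s - ku
        t_obs = np.abs(ku * n_m - km * n_u)
        pos = np.searchsorted(absd_sorted, t_obs, side="left")
        out[ku, km] = np.minimum(suffix[pos], 1.0)
    return out


def hypergeom_two_tailed_oracle(N: int, K: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-likelihood two-sided p for every feasible overlap, by direct
    mass enumeration with a broadcast comparison matrix."""
    lo, hi = max(0, n + K - N), min(K, n)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    qualifies = pmf[None, :] <= pmf[:, None] * (1.0 + 1e-7)  # row = observed k
    return support, np.minimum((qualifies * pmf[None, :]).sum(axis=1), 1.0)


def haldane(d_morgans: float) -> float:
    """Map function: recombination fraction at genetic distance d."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def f2_two_locus_haplotype_probs(r: float) -> dict[str, float]:
    """Closed-form haploid F2 two-locus haplotype frequencies.

    An F2 gamete takes both loci from the same (random) F1 parent with
    probability 1 - r, else one locus from each of two independent F1s.
    F1 haplotypes are parental with probability (1 - r)/2 each and
    recombinant with probability r/2 each.
    """
    same = 1.0 - r
    parental = same * (1.0 - r) / 2.0 + r * 0.25
    recomb = same * r / 2.0 + r * 0.25
    return {"MM": parental, "UU": parental, "MU": recomb, "UM": recomb}
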