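"""Exact-binomial genome scan for bulked segregant analysis.

Two pools of segregating haploid progeny, enriched for opposite phenotypes,
are sequenced in bulk; at each biallelic SNP we observe alt/ref read counts
``(k_U, n_U)`` and ``(k_M, n_M)``.  Under the null hypothesis that a marker
is unlinked to any causal locus, both pools sample reads from the same
underlying allele frequency, estimated by the pooled MLE
``p_hat = (k_U + k_M) / (n_U + n_M)``.  The scan statistic asks: given
``p_hat``, how probable is a pool-frequency difference at least as large in
magnitude as the one observed, with the two pool counts modelled as
independent binomials at ``p_hat``?  Conditioning on the *observed* pooled
frequency rather than the Mendelian 1:2 expectation makes the test robust to
alleles that changed frequency through a growth-rate advantage during pool
propagation: only sampling error or phenotype-linked selection can move the
two pools apart.

The reported score is ``log10((1 - p) / p)`` — the log odds against the
chance explanation — so that strongly associated markers score high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

logger = logging.getLogger(__name__)

#: Probability floor applied before the log-odds ratio; bounds the statistic
#: to [-300, 300] and keeps it finite at p = 1 and at underflowing p.
P_FLOOR = 1e-300

SCAN_COLUMNS = [
    "chrom", "pos", "k_U", "n_U", "k_M", "n_M",
    "p_hat", "d_obs", "p_exact", "log_odds", "neg_log10_p", "direction",
]

REGION_COLUMNS = ["chrom", "start", "end", "peak_pos", "peak_log_odds", "n_snps"]


def _validate_counts(k_u, n_u, k_m, n_m) -> None:
    k_u, n_u, k_m, n_m = (np.asarray(x) for x in (k_u, n_u, k_m, n_m))
    if np.any(n_u < 1) or np.any(n_m < 1):
        raise ValueError("both pools need depth >= 1")
    if np.any(k_u < 0) or np.any(k_m < 0) or np.any(k_u > n_u) or np.any(k_m > n_m):
        raise ValueError("allele counts must satisfy 0 <= k <= n")


def exact_difference_probability(
    k_u: int, n_u: int, k_m: int, n_m: int,
    *, sided: str = "two", null: str = "binomial",
) -> float:
    """Exact tail probability of the observed pool-frequency difference.

    With ``p_hat = (k_u + k_m)/(n_u + n_m)`` and independent
    ``K_U ~ Binom(n_u, p_hat)``, ``K_M ~ Binom(n_m, p_hat)``, returns

        P( |K_U * n_m - K_M * n_u|  >=  |k_u * n_m - k_m * n_u| )

    for the default two-sided test.  The comparison is done on the
    cross-multiplied integers, so ties at the observed difference are exact
    and inclusive (the observed outcome always counts; the result is > 0).

    Parameters
    ----------
    sided
        ``"two"`` (magnitude tail, default) or ``"one"`` (tail in the
        observed direction only).
    null
        ``"binomial"`` — two independent binomials at the pooled MLE
        (default); ``"conditional"`` — hypergeometric null conditioning on
        the total alt count across pools (Fisher-exact-style), offered for
        sensitivity analysis.
    """
    _validate_counts(k_u, n_u, k_m, n_m)
    if null == "conditional":
        return _p_exact_conditional(int(k_u), int(n_u), int(k_m), int(n_m), sided)
    if null != "binomial":
        raise ValueError(f"unknown null model: {null!r}")
    out = exact_difference_probability_batch(
        np.array([k_u]), np.array([n_u]), np.array([k_m]), np.array([n_m]),
        sided=sided,
    )
    return float(out[0])


def exact_difference_probability_batch(
    k_u: np.ndarray, n_u: np.ndarray, k_m: np.ndarray, n_m: np.ndarray,
    *, sided: str = "two",
) -> np.ndarray:
    """Vectorised :func:`exact_difference_probability` (binomial null).

    Rows are grouped by ``(n_u, n_m, k_u + k_m)``; within a group the null
    is identical so the binomial pmf and its cumulative sums are computed
    once.  Per SNP the qualifying outcomes are located with exact integer
    bounds: ``|i*n_m - j*n_u| >= T`` holds iff ``j <= (i*n_m - T)/n_u`` or
    ``j >= (i*n_m + T)/n_u``, so each tail is a cdf/sf lookup.  The
    cumulative sums are formed from the pmf itself, which makes the result
    identical (to summation round-off) to exhaustive enumeration over the
    (n_u+1) x (n_m+1) outcome grid.
    """
    if sided not in ("two", "one"):
        raise ValueError(f"sided must be 'two' or 'one', got {sided!r}")
    k_u = np.asarray(k_u, dtype=np.int64)
    n_u = np.asarray(n_u, dtype=np.int64)
    k_m = np.asarray(k_m, dtype=np.int64)
    n_m = np.asarray(n_m, dtype=np.int64)
    _validate_counts(k_u, n_u, k_m, n_m)

    # signed observed difference on the integer cross-multiplied scale
    d_signed = k_m * n_u - k_u * n_m  # positive when pool M is alt-enriched
    total = k_u + k_m
    out = np.empty(len(k_u), dtype=float)

    keys = np.stack([n_u, n_m, total], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    for g, (nu, nm, s) in enumerate(uniq):
        idx = np.nonzero(inverse == g)[0]
        p_hat = s / (nu + nm)
        i = np.arange(nu + 1)
        pmf_u = binom.pmf(i, nu, p_hat)
        pmf_m = binom.pmf(np.arange(nm + 1), nm, p_hat)
        # cdf[j+1] = P(K_M <= j); sf[j] = P(K_M >= j); both padded for clipping
        cdf_m = np.concatenate([[0.0], np.cumsum(pmf_m)])
        sf_m = np.concatenate([np.cumsum(pmf_m[::-1])[::-1], [0.0]])

        t = np.abs(d_signed[idx])[:, None]  # (rows, 1)
        im = i[None, :] * nm                # (1, nu+1)
        # upper tail on K_M: j*nu >= i*nm + T  <=>  j >= ceil((i*nm + T)/nu)
        hi = -((-(im + t)) // nu)
        # lower tail: j*nu <= i*nm - T  <=>  j <= floor((i*nm - T)/nu)
        lo = (im - t) // nu
        hi = np.clip(hi, 0, nm + 1)
        lo = np.clip(lo, -1, nm)
        upper = (pmf_u[None, :] * sf_m[hi]).sum(axis=1)
        if sided == "two":
            lower = (pmf_u[None, :] * cdf_m[lo + 1]).sum(axis=1)
            p = upper + lower
            p[np.abs(d_signed[idx]) == 0] = 1.0
        else:
            # inclusive tail in the observed direction (d = 0 counts upward)
            lower = (pmf_u[None, :] * cdf_m[lo + 1]).sum(axis=1)
            p = np.where(d_signed[idx] >= 0, upper, lower)
        out[idx] = np.minimum(p, 1.0)
    return out


def _p_exact_conditional(k_u: int, n_u: int, k_m: int, n_m: int, sided: str) -> float:
    """Conditional-null variant: K_U ~ Hypergeom given the total alt count."""
    s = k_u + k_m
    lo = max(0, s - n_m)
    hi = min(s, n_u)
    ku = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ku, n_u + n_m, s, n_u)
    d = (s - ku) * n_u - ku * n_m  # signed difference per outcome
    d_obs = k_m * n_u - k_u * n_m
    if sided == "two":
        mask = np.abs(d) >= abs(d_obs)
    else:
        mask = d >= d_obs if d_obs >= 0 else d <= d_obs
    if d_obs == 0:
        return 1.0
    return float(min(pmf[mask].sum(), 1.0))


def log_odds(p_exact: float | np.ndarray) -> float | np.ndarray:
    """Log odds against the chance explanation: ``log10((1 - p) / p)``.

    Both numerator and denominator are floored at :data:`P_FLOOR`, so the
    statistic is finite on (0, 1]: +300 at an underflowing p, and the clamp
    minimum (-300) at p = 1, where there is no evidence of association.
    """
    p = np.asarray(p_exact, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p_exact must lie in (0, 1]")
    result = np.log10(np.maximum(1.0 - p, P_FLOOR) / np.maximum(p, P_FLOOR))
    return float(result) if np.isscalar(p_exact) else result


def scan(
    counts: pd.DataFrame,
    *,
    min_depth: int = 10,
    sided: str = "two",
) -> pd.DataFrame:
    """Per-SNP exact-binomial scan over a two-pool allele-count table.

    Parameters
    ----------
    counts
        Table with columns ``chrom, pos, refU, altU, refM, altM`` (the
        synthetic generator's schema and the TSV/VCF readers' output).
    min_depth
        SNPs with depth below this in either pool are skipped (logged).
    sided
        Passed to :func:`exact_difference_probability_batch`.

    Returns
    -------
    DataFrame with one row per retained SNP: pooled frequency ``p_hat``,
    signed observed difference ``d_obs`` (pool M minus pool U), exact tail
    probability, log-odds score, ``-log10(p)`` and the direction sign.
    """
    required = {"chrom", "pos", "refU", "altU", "refM", "altM"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    df = counts.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if df.duplicated(subset=["chrom", "pos"]).any():
        dups = df[df.duplicated(subset=["chrom", "pos"])]
        raise ValueError(
            f"duplicate (chrom, pos) entries: {dups[['chrom', 'pos']].head().values.tolist()}"
        )
    if df.empty:
        return pd.DataFrame(columns=SCAN_COLUMNS)

    n_u = (df["refU"] + df["altU"]).to_numpy(np.int64)
    n_m = (df["refM"] + df["altM"]).to_numpy(np.int64)
    keep = (n_u >= max(min_depth, 1)) & (n_m >= max(min_depth, 1))
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.info("scan: skipped %d SNPs below depth %d", n_skipped, min_depth)
    df = df.loc[keep].reset_index(drop=True)
    if df.empty:
        logger.warning("scan: no SNPs passed the depth filter")
        return pd.DataFrame(columns=SCAN_COLUMNS)

    k_u = df["altU"].to_numpy(np.int64)
    k_m = df["altM"].to_numpy(np.int64)
    n_u, n_m = n_u[keep], n_m[keep]
    p_exact = exact_difference_probability_batch(k_u, n_u, k_m, n_m, sided=sided)
    d_obs = k_m / n_m - k_u / n_u
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["pos"].astype(np.int64),
        "k_U": k_u, "n_U": n_u, "k_M": k_m, "n_M": n_m,
        "p_hat": (k_u + k_m) / (n_u + n_m),
        "d_obs": d_obs,
        "p_exact": p_exact,
        "log_odds": log_odds(p_exact),
        "neg_log10_p": -np.log10(np.maximum(p_exact, P_FLOOR)),
        "direction": np.sign(d_obs).astype(int),
    })
    return out


@dataclass(frozen=True)
class CandidateRegion:
    """A run of above-threshold SNPs merged within ``max_gap`` bp."""

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    peak_pos: int
    peak_log_odds: float
    n_snps: int


def call_regions(
    scan_df: pd.DataFrame, threshold: float, max_gap: int = 500_000
) -> pd.DataFrame:
    """Merge above-threshold SNPs into candidate regions.

    SNPs on the same chromosome with ``log_odds >= threshold`` whose
    positions differ by at most ``max_gap`` bp are merged; each region
    reports its peak SNP (ties broken by leftmost position).  Output is
    ordered by descending peak log odds, then chromosome and start.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    regions: list[CandidateRegion] = []
    hits = scan_df[scan_df["log_odds"] >= threshold]
    for chrom, sub in hits.groupby("chrom", sort=True):
        sub = sub.sort_values("pos", kind="stable")
        pos = sub["pos"].to_numpy(np.int64)
        lod = sub["log_odds"].to_numpy(float)
        breaks = np.nonzero(np.diff(pos) > max_gap)[0] + 1
        for seg_pos, seg_lod in zip(np.split(pos, breaks), np.split(lod, breaks)):
            peak = int(np.argmax(seg_lod))  # argmax returns first (leftmost) max
            regions.append(CandidateRegion(
                chrom=chrom,
                start=int(seg_pos[0]),
                end=int(seg_pos[-1]),
                peak_pos=int(seg_pos[peak]),
                peak_log_odds=float(seg_lod[peak]),
                n_snps=len(seg_pos),
            ))
    regions.sort(key=lambda r: (-r.peak_log_odds, str(r.chrom), r.start))
    return pd.DataFrame([r.__dict__ for r in regions], columns=REGION_COLUMNS)
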