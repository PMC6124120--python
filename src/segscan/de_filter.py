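"""Replicate QC and fold-change filtering of FPKM expression tables.

The input is a gene x sample matrix of FPKM values for two strains (an
evolved isolate and its ancestor) across a set of time points with >= 2
biological replicates each.  Two operations mirror the study workflow:

1. Replicate agreement QC: Pearson r over genes for every within-condition
   replicate pair (the study reported r > 0.98 in all pairwise
   comparisons); pairs below a configurable floor are flagged, not fatal.
2. Differential-expression filtering: a gene is differentially expressed at
   a time point when the across-replicate mean FPKMs differ by at least
   fourfold, i.e. |log2 ratio| >= 2, with an optional per-gene/time-point
   significance mask standing in for an upstream DE test.

Column naming convention: ``<strain>_<time>_r<replicate>``, e.g.
``evolved_9h_r2``; strains default to ("ancestor", "evolved").
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_STRAINS = ("ancestor", "evolved")

_COLUMN_RE = re.compile(r"^(?P<strain>.+)_(?P<time>[^_]+)_r(?P<rep>\d+)$")


def parse_condition_columns(columns) -> pd.DataFrame:
    """Parse ``strain_time_rep`` column names into a condition table."""
    rows = []
    for col in columns:
        m = _COLUMN_RE.match(str(col))
        if not m:
            raise ValueError(
                f"column {col!r} does not match '<strain>_<time>_r<replicate>'"
            )
        rows.append((col, m["strain"], m["time"], int(m["rep"])))
    return pd.DataFrame(rows, columns=["column", "strain", "time", "replicate"])


def _validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.index.duplicated().any():
        raise ValueError("gene ids must be unique")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return parse_condition_columns(matrix.columns)


def replicate_correlation(matrix: pd.DataFrame, qc_floor: float = 0.98) -> pd.DataFrame:
    """Pairwise Pearson r (and r^2) between replicates of each condition.

    Pairs with r below ``qc_floor`` are logged as QC warnings.  A constant
    replicate vector has no defined correlation; the pair is reported with
    NaN and a warning.
    """
    cond = _validate_matrix(matrix)
    rows = []
    for (strain, time), grp in cond.groupby(["strain", "time"], sort=True):
        cols = list(grp.sort_values("replicate")["column"])
        if len(cols) < 2:
            raise ValueError(f"condition ({strain}, {time}) has < 2 replicates")
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                x = matrix[cols[i]].to_numpy(float)
                y = matrix[cols[j]].to_numpy(float)
                if np.std(x) == 0 or np.std(y) == 0:
                    logger.warning(
                        "replicate_correlation: constant vector in (%s, %s); "
                        "r undefined for %s vs %s", strain, time, cols[i], cols[j],
                    )
                    r = np.nan
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                    if r < qc_floor:
                        logger.warning(
                            "replicate QC: r = %.4f < %.2f for %s vs %s",
                            r, qc_floor, cols[i], cols[j],
                        )
                rows.append((strain, time, cols[i], cols[j], r, r * r))
    return pd.DataFrame(
        rows, columns=["strain", "time", "rep_a", "rep_b", "r", "r_squared"]
    )


def _condition_means(matrix: pd.DataFrame, strains: tuple[str, str]) -> dict:
    """Mean FPKM per (strain, time), keyed by (strain, time) -> Series."""
    cond = _validate_matrix(matrix)
    present = set(cond["strain"])
    for s in strains:
        if s not in present:
            raise ValueError(f"strain {s!r} absent from columns (found {sorted(present)})")
    means = {}
    for (strain, time), grp in cond.groupby(["strain", "time"], sort=True):
        means[(strain, time)] = matrix[list(grp["column"])].mean(axis=1)
    return means


def log2_ratio_table(
    matrix: pd.DataFrame,
    pseudocount: float = 0.1,
    strains: tuple[str, str] = DEFAULT_STRAINS,
) -> pd.DataFrame:
    """Gene x time-point table of log2(evolved mean + c) - log2(ancestor mean + c).

    ``pseudocount`` c >= 0; with c = 0 a zero mean on one side yields an
    infinite ratio (sign preserved), which any finite fold threshold
    treats as differentially expressed, and 0/0 yields NaN (never
    selected).  The default c = 0.1 FPKM keeps all ratios finite.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    ancestor, evolved = strains
    means = _condition_means(matrix, strains)
    times_anc = {t for s, t in means if s == ancestor}
    times_evo = {t for s, t in means if s == evolved}
    if times_anc != times_evo:
        raise ValueError(
            f"time points differ between strains: {sorted(times_anc)} vs {sorted(times_evo)}"
        )
    times = sorted(times_anc, key=_time_sort_key)
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for t in times:
            num = means[(evolved, t)].to_numpy(float) + pseudocount
            den = means[(ancestor, t)].to_numpy(float) + pseudocount
            # log2 of the quotient (not a log difference): exact-power
            # ratios like 40/10 stay exactly at the fold boundary
            out[t] = np.log2(num / den)
    return pd.DataFrame(out, index=matrix.index)


def _time_sort_key(t: str):
    m = re.match(r"^(\d+(?:\.\d+)?)", str(t))
    return (0, float(m.group(1)), str(t)) if m else (1, 0.0, str(t))


def mean_log2_ratio(
    matrix: pd.DataFrame,
    gene: str,
    time: str,
    pseudocount: float = 0.1,
    strains: tuple[str, str] = DEFAULT_STRAINS,
) -> float:
    """log2 ratio of mean FPKMs (evolved over ancestor) for one gene/time."""
    table = log2_ratio_table(matrix, pseudocount, strains)
    if gene not in table.index:
        raise KeyError(f"unknown gene {gene!r}")
    if time not in table.columns:
        raise KeyError(f"unknown time point {time!r}")
    return float(table.loc[gene, time])


@dataclass
class DEGeneSet:
    """Per-time-point differential-expression calls with signs.

    ``over``/``under`` hold genes whose evolved-strain expression is at
    least ``fold``-fold above/below the ancestor at that time point; a gene
    may be overexpressed at one time point and underexpressed at another.
    ``union`` is the "at one or more time points" set.
    """

    fold: float
    log2_ratio: pd.DataFrame
    over: dict[str, set] = field(default_factory=dict)
    under: dict[str, set] = field(default_factory=dict)

    @property
    def times(self) -> list[str]:
        return list(self.log2_ratio.columns)

    def at(self, time: str) -> set:
        return self.over[time] | self.under[time]

    @property
    def union(self) -> set:
        out: set = set()
        for t in self.times:
            out |= self.at(t)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene, time, log2_ratio, direction."""
        rows = []
        for t in self.times:
            for g in sorted(self.over[t]):
                rows.append((g, t, float(self.log2_ratio.loc[g, t]), "over"))
            for g in sorted(self.under[t]):
                rows.append((g, t, float(self.log2_ratio.loc[g, t]), "under"))
        return pd.DataFrame(rows, columns=["gene", "time", "log2_ratio", "direction"])


def select_de_genes(
    matrix: pd.DataFrame,
    fold: float = 4.0,
    pseudocount: float = 0.1,
    mask: pd.DataFrame | None = None,
    strains: tuple[str, str] = DEFAULT_STRAINS,
) -> DEGeneSet:
    """Fold-change filter: |log2 ratio| >= log2(fold), inclusive.

    Parameters
    ----------
    fold
        Fold-change threshold (> 1); the default 4 corresponds to
        |log2 ratio| >= 2.
    mask
        Optional boolean gene x time table; when given, a gene is selected
        at a time point only if the mask also flags it (stands in for an
        upstream statistical-significance call, which this package does not
        re-implement).
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    table = log2_ratio_table(matrix, pseudocount, strains)
    cut = np.log2(fold)
    result = DEGeneSet(fold=fold, log2_ratio=table)
    for t in table.columns:
        ratios = table[t]
        sel_over = ratios >= cut
        sel_under = ratios <= -cut
        if mask is not None:
            if t not in mask.columns:
                raise ValueError(f"significance mask lacks time point {t!r}")
            flagged = mask[t].reindex(table.index).fillna(False).astype(bool)
            sel_over &= flagged
            sel_under &= flagged
        result.over[t] = set(table.index[sel_over])
        result.under[t] = set(table.index[sel_under])
    return result
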