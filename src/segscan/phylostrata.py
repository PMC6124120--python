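"""Phylostratum assignment from tabular homology-search results.

A gene's phylostratum is the most inclusive taxonomic group in which
homologues are detectable — a proxy for the gene's evolutionary age.  The
default ladder spans eight nested strata around *Chlamydomonas
reinhardtii*, from the genus itself out to all cellular organisms:

    Chlamydomonas < volvocine < Chlamydomonadales < Chlorophyceae
    < Chlorophyta < Viridiplantae < Eukaryota < cellular organisms

("volvocine" is the *Chlamydomonas* + *Gonium* + *Volvox* clade.)  Hits are
protein-homology search rows (query gene, subject sequence, subject taxon,
E-value); a hit counts as evidence of homology when its E-value is
*strictly* below the threshold (default 0.001).  Taxa are resolved to
strata through a user-supplied two-column mapping table, frozen into a
file rather than fetched from live taxonomy services, so analyses are
reproducible offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_STRATA = (
    "Chlamydomonas",
    "volvocine",
    "Chlamydomonadales",
    "Chlorophyceae",
    "Chlorophyta",
    "Viridiplantae",
    "Eukaryota",
    "cellular organisms",
)

DEFAULT_E_MAX = 0.001

HITS_COLUMNS = ["query", "subject", "taxon", "evalue"]


@dataclass(frozen=True)
class StratumLadder:
    """Ordered nested strata plus a taxon -> stratum resolution map.

    ``strata`` runs from least inclusive (lineage-specific) to most
    inclusive; ``taxon_map`` sends each subject taxon identifier to the
    least-inclusive stratum containing it.
    """

    strata: tuple[str, ...] = DEFAULT_STRATA
    taxon_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.strata) < 1 or len(set(self.strata)) != len(self.strata):
            raise ValueError("strata must be a non-empty list of unique names")
        if self.taxon_map:
            bad = {s for s in self.taxon_map.values()} - set(self.strata)
            if bad:
                raise ValueError(f"taxon_map references unknown strata: {sorted(bad)}")

    def rank(self, stratum: str) -> int:
        """Position on the ladder; higher = more inclusive."""
        try:
            return self.strata.index(stratum)
        except ValueError:
            raise KeyError(f"unknown stratum {stratum!r}") from None

    def resolve(self, taxon: str) -> str | None:
        if not self.taxon_map:
            return None
        return self.taxon_map.get(str(taxon))


def load_taxon_map(path, strata: tuple[str, ...] = DEFAULT_STRATA) -> StratumLadder:
    """Build a ladder from a two-column TSV (taxon, stratum)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon", "stratum"],
                     dtype=str, comment="#")
    dup = df["taxon"].duplicated()
    if dup.any():
        raise ValueError(f"taxon mapped twice: {sorted(df['taxon'][dup].unique())}")
    return StratumLadder(strata=strata, taxon_map=dict(zip(df["taxon"], df["stratum"])))


def filter_hits(hits: pd.DataFrame, e_max: float = DEFAULT_E_MAX) -> pd.DataFrame:
    """Keep hits with E-value strictly below ``e_max`` (order preserved).

    A hit at exactly ``e_max`` is *not* homologous evidence — the threshold
    is a strict inequality.
    """
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    if hits.empty:
        return hits
    if not pd.api.types.is_numeric_dtype(hits["evalue"]):
        raise ValueError("E-values must be numeric")
    ev = hits["evalue"].astype(float)
    if (ev < 0).any() or (ev == float("inf")).any() or ev.isna().any():
        raise ValueError("E-values must be finite and non-negative")
    return hits[ev < e_max]


def assign_phylostratum(
    gene: str,
    hits: pd.DataFrame,
    ladder: StratumLadder,
    universe: Iterable[str] | None = None,
    on_unknown_taxon: Literal["skip", "error"] = "skip",
    exclude_self: bool = True,
) -> str:
    """Stratum of one gene from its (already E-value-filtered) hits.

    The assignment is the *most inclusive* stratum among the gene's hits —
    the oldest detectable homology.  A gene with no surviving non-self hits
    is lineage-specific and takes the least-inclusive stratum.  The gene's
    identity self-hit (query == subject id) is excluded by default; other
    same-species hits count as least-stratum evidence through the taxon map.
    """
    table = assign_phylostrata(
        hits[hits["query"] == gene], ladder,
        universe=[gene], on_unknown_taxon=on_unknown_taxon,
        exclude_self=exclude_self,
    )
    if universe is not None and gene not in set(universe):
        raise KeyError(f"gene {gene!r} absent from the query universe")
    return table.loc[gene, "stratum"]


def assign_phylostrata(
    hits: pd.DataFrame,
    ladder: StratumLadder,
    universe: Iterable[str],
    on_unknown_taxon: Literal["skip", "error"] = "skip",
    exclude_self: bool = True,
) -> pd.DataFrame:
    """Assign every gene in ``universe`` to exactly one stratum.

    Parameters
    ----------
    hits
        Filtered homology table with columns ``query, subject, taxon,
        evalue`` (see :func:`filter_hits`; no E-value filtering happens
        here).
    on_unknown_taxon
        ``"skip"`` drops hits whose taxon is absent from the ladder's map
        (logged); ``"error"`` raises.

    Returns
    -------
    DataFrame indexed by gene with columns ``stratum`` and ``rank``.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty gene universe")
    df = hits.copy()
    extra = set(df["query"]) - set(universe)
    if extra:
        raise ValueError(f"hits reference genes outside the universe: {sorted(extra)[:5]}")
    if exclude_self and len(df):
        df = df[df["query"].astype(str) != df["subject"].astype(str)]
    if len(df):
        resolved = df["taxon"].astype(str).map(lambda t: ladder.resolve(t))
        unknown = resolved.isna()
        if unknown.any():
            taxa = sorted(df.loc[unknown, "taxon"].astype(str).unique())
            if on_unknown_taxon == "error":
                raise ValueError(f"unmapped taxa: {taxa}")
            logger.warning("assign_phylostrata: skipping %d hits with unmapped taxa %s",
                           int(unknown.sum()), taxa[:5])
            df = df[~unknown]
            resolved = resolved[~unknown]
        df = df.assign(rank=resolved.map(ladder.rank))
    ranks = pd.Series(0, index=pd.Index(universe, name="gene"), dtype=int)
    if len(df):
        best = df.groupby("query")["rank"].max()
        ranks.loc[best.index] = best.astype(int)
    return pd.DataFrame({
        "stratum": [ladder.strata[r] for r in ranks],
        "rank": ranks,
    }, index=ranks.index)


def stratum_census(assignments: pd.DataFrame, ladder: StratumLadder) -> pd.Series:
    """Genome-wide count of genes per stratum (ladder order; sums to N).

    These per-stratum totals are the expected frequencies for the
    enrichment tests: the null is that a gene set draws from each stratum
    at its genome-wide rate.
    """
    counts = assignments["stratum"].value_counts()
    return pd.Series(
        [int(counts.get(s, 0)) for s in ladder.strata],
        index=pd.Index(ladder.strata, name="stratum"),
        name="n_genes",
    )


def strata_as_annotations(assignments: pd.DataFrame) -> dict[str, set]:
    """Repackage assignments as category -> gene-set annotations for the
    enrichment engine."""
    return {
        stratum: set(sub.index)
        for stratum, sub in assignments.groupby("stratum")
    }
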