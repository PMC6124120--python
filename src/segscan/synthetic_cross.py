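"""Synthetic haploid F2 cross and pooled-sequencing generator.

Emulates the experimental design behind a bulked-segregant mapping study in
a haploid green alga: two parents (a multicellular isolate and its
unicellular wild-type relative) are crossed, F1 progeny are intercrossed to
produce a large F2 pool, F2 individuals are sorted into phenotype-enriched
pools (with a configurable misclassification rate standing in for imperfect
settling selection), and each pool is sequenced to a target mean depth,
yielding per-SNP ref/alt read counts with known ground truth.

Model choices
-------------
* Meiosis: crossover count per chromosome ~ Poisson(genetic length in
  Morgans), crossover positions uniform on the genetic map, no
  interference — i.e. the Haldane model, so the recombination fraction at
  map distance d is (1 - exp(-2d))/2 in closed form.
* Genotypes are boolean marker vectors: True = the multicellular parent's
  allele (the "alt"/derived allele in output tables).
* Pool sequencing: per SNP, depth ~ Poisson(lambda); every read comes from
  a uniformly random pool member and is flipped with the per-read error
  rate e.  Because members are redrawn per read, the alt count is exactly
  Binomial(depth, f(1-e) + (1-f)e) with f the pool allele frequency, and is
  sampled that way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

PHENOTYPES = ("unicellular", "multicellular")

COUNTS_COLUMNS = ["chrom", "pos", "ref", "alt", "refU", "altU", "refM", "altM", "alt_origin"]


@dataclass(frozen=True)
class Chromosome:
    id: str
    length_bp: int
    length_morgans: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"chromosome {self.id}: length_bp must be >= 1")
        if self.length_morgans < 0:
            raise ValueError(f"chromosome {self.id}: genetic length must be >= 0")


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome sizes plus ordered biallelic marker positions.

    Markers are 1-based bp positions of SNPs segregating between the two
    parents; genetic positions are obtained by linear interpolation of the
    chromosome's genetic length over its physical length.
    """

    chromosomes: tuple[Chromosome, ...]
    markers: dict[str, np.ndarray] = field(compare=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("GenomeMap needs at least one chromosome")
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chromosome ids")
        markers = {}
        for c in self.chromosomes:
            pos = np.asarray(self.markers.get(c.id, ()), dtype=np.int64)
            if np.any(pos < 1) or np.any(pos > c.length_bp):
                raise ValueError(f"chromosome {c.id}: marker positions outside [1, length]")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"chromosome {c.id}: marker positions must be strictly increasing")
            markers[c.id] = pos
        object.__setattr__(self, "markers", markers)

    @property
    def n_markers(self) -> int:
        return sum(len(self.markers[c.id]) for c in self.chromosomes)

    def marker_table(self) -> pd.DataFrame:
        """All markers as a (chrom, pos) table in genome order."""
        frames = [
            pd.DataFrame({"chrom": c.id, "pos": self.markers[c.id]})
            for c in self.chromosomes
        ]
        return pd.concat(frames, ignore_index=True)

    def marker_slices(self) -> dict[str, slice]:
        """Per-chromosome slices into the concatenated marker axis."""
        out, offset = {}, 0
        for c in self.chromosomes:
            n = len(self.markers[c.id])
            out[c.id] = slice(offset, offset + n)
            offset += n
        return out

    def marker_index(self, chrom: str, pos: int) -> int:
        """Index of a marker on the concatenated axis; KeyError if absent."""
        sl = self.marker_slices().get(chrom)
        if sl is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        pos_arr = self.markers[chrom]
        i = int(np.searchsorted(pos_arr, pos))
        if i == len(pos_arr) or pos_arr[i] != pos:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return sl.start + i


def default_genome(
    n_chromosomes: int = 17,
    markers_per_chromosome: int = 20,
    length_bp: int = 1_000_000,
    length_morgans: float = 1.0,
) -> GenomeMap:
    """Conventional synthetic genome: 17 chromosomes of 1 Morgan each, with
    evenly spaced markers (matching the chromosome count of *C. reinhardtii*;
    marker density and physical size are simulator conventions)."""
    spacing = length_bp // markers_per_chromosome
    positions = np.arange(1, markers_per_chromosome + 1) * spacing - spacing // 2
    return GenomeMap(
        chromosomes=tuple(
            Chromosome(str(i + 1), length_bp, length_morgans)
            for i in range(n_chromosomes)
        ),
        markers={str(i + 1): positions.copy() for i in range(n_chromosomes)},
    )


@dataclass(frozen=True)
class CrossConfig:
    """Everything needed to generate one synthetic bulked-segregant dataset.

    Parameters
    ----------
    causal_loci
        (chromosome id, bp position) pairs; each must coincide with a marker.
    phenotype_model
        ``"ALL"`` — multicellular iff the derived (multicellular-parent)
        allele is present at every causal locus; ``"ANY"`` — at any locus.
    misclassification_rate
        Probability an individual is sorted into the phenotypically wrong
        pool; collapses the iterated growth/centrifugation enrichment into
        a single stochastic sorting step.
    pool_depth
        Mean sequencing depth per SNP for the (unicellular, multicellular)
        pools.
    seq_error_rate
        Per-read probability the observed allele is flipped.
    n_f2, n_f1
        Sizes of the F2 population and of the intermediate F1 pool from
        which random F1 x F1 matings are drawn.
    growth_locus, growth_advantage
        Optional growth-rate model: carriers of the derived allele at this
        marker contribute reads with weight ``growth_advantage`` relative
        to non-carriers (emulating expansion during pool propagation, the
        scenario that motivates testing against the observed pooled
        frequency instead of 1:1).  Off by default.
    """

    genome: GenomeMap = field(default_factory=default_genome)
    causal_loci: tuple[tuple[str, int], ...] = ()
    phenotype_model: Literal["ALL", "ANY"] = "ALL"
    misclassification_rate: float = 0.05
    pool_depth: tuple[float, float] = (155.0, 128.0)
    seq_error_rate: float = 0.001
    n_f2: int = 2000
    n_f1: int = 200
    seed: int = 0
    growth_locus: tuple[str, int] | None = None
    growth_advantage: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.misclassification_rate < 1:
            raise ValueError("misclassification_rate must lie in [0, 1)")
        if not 0 <= self.seq_error_rate <= 0.05:
            raise ValueError("seq_error_rate must lie in [0, 0.05]")
        if min(self.pool_depth) <= 0:
            raise ValueError("pool mean depths must be positive")
        if self.n_f2 < 2:
            raise ValueError("n_f2 must be >= 2")
        if self.n_f1 < 2:
            raise ValueError("n_f1 must be >= 2")
        if self.phenotype_model not in ("ALL", "ANY"):
            raise ValueError("phenotype_model must be 'ALL' or 'ANY'")
        for chrom, pos in self.causal_loci:
            self.genome.marker_index(chrom, pos)  # raises if off-marker
        if self.growth_locus is not None:
            self.genome.marker_index(*self.growth_locus)
            if self.growth_advantage <= 0:
                raise ValueError("growth_advantage must be positive")

    def causal_indices(self) -> np.ndarray:
        return np.array(
            [self.genome.marker_index(c, p) for c, p in self.causal_loci],
            dtype=np.int64,
        )


def simulate_meiosis(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    gmap: GenomeMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic product of an a x b zygote (Poisson/Haldane model).

    Per chromosome the crossover count is Poisson with mean equal to the
    genetic length in Morgans, crossover positions are uniform on the
    genetic map, and the starting parent is chosen with probability 1/2;
    markers take the active parent's allele between crossovers.
    """
    n = gmap.n_markers
    parent_a = np.asarray(parent_a, dtype=bool)
    parent_b = np.asarray(parent_b, dtype=bool)
    if parent_a.shape != (n,) or parent_b.shape != (n,):
        raise ValueError("parent genotypes do not match the genome map")
    child = np.empty(n, dtype=bool)
    for c, sl in zip(gmap.chromosomes, gmap.marker_slices().values()):
        length = c.length_morgans
        n_co = rng.poisson(length) if length > 0 else 0
        start = rng.integers(2)  # 0 -> parent_a, 1 -> parent_b
        marker_g = gmap.markers[c.id] / c.length_bp * length
        if n_co:
            co = np.sort(rng.uniform(0.0, length, n_co))
            parity = (start + np.searchsorted(co, marker_g)) % 2
        else:
            parity = np.full(len(marker_g), start)
        child[sl] = np.where(parity == 0, parent_a[sl], parent_b[sl])
    return child


def simulate_f2_population(config: CrossConfig) -> np.ndarray:
    """F2 genotype matrix (n_f2 x n_markers boolean; True = derived allele).

    The F1 pool holds ``n_f1`` meiotic products of the parental cross
    (all-derived x all-ancestral); each F2 individual is one meiotic
    product of a random pair of distinct F1 parents.  Reproducible: the
    whole generation is driven by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    return _simulate_f2(config, rng)


def _simulate_f2(config: CrossConfig, rng: np.random.Generator) -> np.ndarray:
    gmap = config.genome
    n = gmap.n_markers
    p_multi = np.ones(n, dtype=bool)
    p_uni = np.zeros(n, dtype=bool)
    f1 = np.stack([
        simulate_meiosis(p_multi, p_uni, gmap, rng) for _ in range(config.n_f1)
    ])
    f2 = np.empty((config.n_f2, n), dtype=bool)
    for i in range(config.n_f2):
        a = rng.integers(config.n_f1)
        b = (a + 1 + rng.integers(config.n_f1 - 1)) % config.n_f1  # distinct mate
        f2[i] = simulate_meiosis(f1[a], f1[b], gmap, rng)
    return f2


def assign_phenotype(genotype: np.ndarray, config: CrossConfig) -> str:
    """Deterministic phenotype from the causal-locus allele vector."""
    return assign_phenotypes(np.asarray(genotype, dtype=bool)[None, :], config)[0]


def assign_phenotypes(population: np.ndarray, config: CrossConfig) -> np.ndarray:
    """Vectorised phenotype call; returns an array of phenotype strings."""
    idx = config.causal_indices()
    if len(idx) == 0:
        multi = np.zeros(population.shape[0], dtype=bool)
    elif config.phenotype_model == "ALL":
        multi = population[:, idx].all(axis=1)
    else:
        multi = population[:, idx].any(axis=1)
    return np.where(multi, PHENOTYPES[1], PHENOTYPES[0])


def select_pools(
    phenotypes: Sequence[str] | np.ndarray,
    misclassification_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sort individuals into (pool_U, pool_M) index arrays.

    Each individual lands in its phenotype-matched pool with probability
    1 - epsilon and in the other pool with probability epsilon.  Either
    pool may come back empty.
    """
    if not 0 <= misclassification_rate < 1:
        raise ValueError("misclassification rate must lie in [0, 1)")
    phenotypes = np.asarray(phenotypes)
    is_multi = phenotypes == PHENOTYPES[1]
    flip = rng.random(len(phenotypes)) < misclassification_rate
    goes_multi = is_multi ^ flip
    return np.nonzero(~goes_multi)[0], np.nonzero(goes_multi)[0]


def sample_pool_reads(
    pool: np.ndarray,
    population: np.ndarray,
    gmap: GenomeMap,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
    member_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled sequencing of one pool: per-SNP (ref_count, alt_count).

    Depth per SNP is Poisson(mean_depth); each read observes a uniformly
    random pool member's allele (optionally weighted by ``member_weights``)
    flipped with probability ``error_rate``.
    """
    if len(pool) == 0:
        raise ValueError("cannot sequence an empty pool")
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    geno = population[np.asarray(pool, dtype=np.int64)]
    if member_weights is None:
        f = geno.mean(axis=0)
    else:
        w = np.asarray(member_weights, dtype=float)
        f = (geno * w[:, None]).sum(axis=0) / w.sum()
    depth = rng.poisson(mean_depth, gmap.n_markers)
    p_alt = f * (1.0 - error_rate) + (1.0 - f) * error_rate
    alt = rng.binomial(depth, p_alt)
    return depth - alt, alt


def simulate_pool_counts(config: CrossConfig) -> tuple[pd.DataFrame, dict]:
    """End-to-end generation: cross, sort, sequence.

    Returns
    -------
    counts
        Table with columns ``chrom, pos, ref, alt, refU, altU, refM, altM,
        alt_origin`` — the scan's input schema.  The alt allele is always
        the multicellular parent's (``alt_origin`` True); ref/alt bases are
        the placeholder letters A/C.
    truth
        Ground-truth ledger: causal loci, pool memberships, pool allele
        frequencies and every generative parameter, enabling parameter-
        recovery tests downstream.
    """
    rng = np.random.default_rng(config.seed)
    population = _simulate_f2(config, rng)
    phenotypes = assign_phenotypes(population, config)
    pool_u, pool_m = select_pools(phenotypes, config.misclassification_rate, rng)
    if len(pool_u) == 0 or len(pool_m) == 0:
        raise RuntimeError(
            "a pool came back empty; increase n_f2 or check the phenotype model"
        )

    weights_u = weights_m = None
    if config.growth_locus is not None and config.growth_advantage != 1.0:
        gi = config.genome.marker_index(*config.growth_locus)
        w = np.where(population[:, gi], config.growth_advantage, 1.0)
        weights_u, weights_m = w[pool_u], w[pool_m]

    lam_u, lam_m = config.pool_depth
    ref_u, alt_u = sample_pool_reads(
        pool_u, population, config.genome, lam_u, config.seq_error_rate, rng, weights_u
    )
    ref_m, alt_m = sample_pool_reads(
        pool_m, population, config.genome, lam_m, config.seq_error_rate, rng, weights_m
    )
    counts = config.genome.marker_table()
    counts["ref"] = "A"
    counts["alt"] = "C"
    counts["refU"] = ref_u
    counts["altU"] = alt_u
    counts["refM"] = ref_m
    counts["altM"] = alt_m
    counts["alt_origin"] = True
    truth = {
        "causal_loci": list(config.causal_loci),
        "phenotype_model": config.phenotype_model,
        "misclassification_rate": config.misclassification_rate,
        "pool_depth": list(config.pool_depth),
        "seq_error_rate": config.seq_error_rate,
        "n_f2": config.n_f2,
        "n_f1": config.n_f1,
        "seed": config.seed,
        "pool_U_ids": pool_u.tolist(),
        "pool_M_ids": pool_m.tolist(),
        "n_multicellular": int((phenotypes == PHENOTYPES[1]).sum()),
        "freq_U": population[pool_u].mean(axis=0).tolist(),
        "freq_M": population[pool_m].mean(axis=0).tolist(),
    }
    return counts, truth
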