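"""Forward-in-time simulation of a diploid breeding population.

This module provides the stochastic machinery behind every simulated
experiment in the package: a marker/QTL genome on a genetic map, founder
populations with drift-induced linkage disequilibrium, meiosis under the
Haldane model (Poisson crossovers, no interference), an additive
quantitative trait, and the pedigree bookkeeping needed downstream for
inbreeding and diversity accounting.

The genome is purely additive and biallelic.  Haplotypes are stored as
``uint8`` arrays over the union of marker and QTL loci; markers are the
loci visible to genomic evaluation (relationship matrices,
heterozygosity), QTL carry the trait effects and are never used for
evaluation, mirroring chip-based genomic selection where causal loci are
not on the chip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SEX_MALE",
    "SEX_FEMALE",
    "UNKNOWN_PARENT",
    "ConfigurationError",
    "GenomeSpec",
    "TraitModel",
    "Individual",
    "Pedigree",
    "Population",
    "simulate_founders",
    "sample_gamete",
    "sample_gametes_batch",
    "random_union_offspring",
    "make_offspring",
    "make_offspring_batch",
    "assign_trait",
    "assign_phenotypes",
]

SEX_MALE = 0
SEX_FEMALE = 1
UNKNOWN_PARENT = 0


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


class GenomeSpec:
    """Layout of a simulated diploid genome.

    Parameters
    ----------
    n_chromosomes:
        Number of autosomes.
    chromosome_length:
        Genetic length of every chromosome in centimorgans.
    marker_positions, qtl_positions:
        Per-chromosome sequences of strictly increasing positions (cM).
        Marker and QTL positions must be disjoint within a chromosome.
    founder_allele_freq_range:
        ``(low, high)`` bounds, both in (0, 1), from which the initial
        allele frequency of every locus is drawn uniformly.
    """

    def __init__(
        self,
        n_chromosomes: int,
        chromosome_length: float,
        marker_positions: Sequence[Sequence[float]],
        qtl_positions: Sequence[Sequence[float]],
        founder_allele_freq_range: tuple[float, float] = (0.05, 0.95),
    ):
        if n_chromosomes <= 0:
            raise ConfigurationError("n_chromosomes must be positive")
        if chromosome_length <= 0:
            raise ConfigurationError("chromosome_length must be positive")
        if len(marker_positions) != n_chromosomes or len(qtl_positions) != n_chromosomes:
            raise ConfigurationError(
                "marker_positions and qtl_positions must have one entry per chromosome"
            )
        lo, hi = founder_allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(
                f"founder_allele_freq_range must satisfy 0 < low <= high < 1, got {founder_allele_freq_range}"
            )
        self.n_chromosomes = int(n_chromosomes)
        self.chromosome_length = float(chromosome_length)
        self.founder_allele_freq_range = (float(lo), float(hi))
        self.marker_positions = tuple(
            np.asarray(p, dtype=float) for p in marker_positions
        )
        self.qtl_positions = tuple(np.asarray(p, dtype=float) for p in qtl_positions)

        chrom_loci_pos = []
        chrom_is_qtl = []
        for ci in range(self.n_chromosomes):
            mk, qt = self.marker_positions[ci], self.qtl_positions[ci]
            for name, arr in (("marker", mk), ("qtl", qt)):
                if arr.size and not np.all(np.diff(arr) > 0):
                    raise ConfigurationError(
                        f"{name} positions must be strictly increasing on chromosome {ci + 1}"
                    )
                if arr.size and (arr.min() < 0 or arr.max() > self.chromosome_length):
                    raise ConfigurationError(
                        f"{name} positions outside [0, {self.chromosome_length}] on chromosome {ci + 1}"
                    )
            if np.intersect1d(mk, qt).size:
                raise ConfigurationError(
                    f"marker and QTL positions overlap on chromosome {ci + 1}"
                )
            pos = np.concatenate([mk, qt])
            is_qtl = np.concatenate(
                [np.zeros(mk.size, dtype=bool), np.ones(qt.size, dtype=bool)]
            )
            order = np.argsort(pos, kind="stable")
            chrom_loci_pos.append(pos[order])
            chrom_is_qtl.append(is_qtl[order])

        self._chrom_loci_pos = chrom_loci_pos
        sizes = [p.size for p in chrom_loci_pos]
        ends = np.cumsum(sizes)
        starts = ends - sizes
        self.chrom_slices = list(zip(starts.tolist(), ends.tolist()))
        self.n_loci = int(ends[-1]) if sizes else 0
        self.is_qtl = (
            np.concatenate(chrom_is_qtl) if sizes else np.zeros(0, dtype=bool)
        )
        self.marker_index = np.nonzero(~self.is_qtl)[0]
        self.qtl_index = np.nonzero(self.is_qtl)[0]
        self.n_markers = self.marker_index.size
        self.n_qtl = self.qtl_index.size

    @classmethod
    def default(
        cls,
        n_chromosomes: int = 10,
        chromosome_length: float = 100.0,
        n_markers_per_chrom: int = 200,
        n_qtl_per_chrom: int = 20,
        founder_allele_freq_range: tuple[float, float] = (0.05, 0.95),
    ) -> "GenomeSpec":
        """Desk-scale genome: 10 x 100 cM, 2,000 markers and 200 QTL in total.

        Markers are evenly spaced; QTL sit between markers so the two sets
        are disjoint.
        """
        L = chromosome_length
        markers = [
            (np.arange(n_markers_per_chrom) + 0.5) * L / n_markers_per_chrom
            for _ in range(n_chromosomes)
        ]
        # offset QTL by a fraction of the marker spacing so positions never collide
        qtl = [
            (np.arange(n_qtl_per_chrom) + 0.5) * L / n_qtl_per_chrom
            + 0.37 * L / n_markers_per_chrom
            for _ in range(n_chromosomes)
        ]
        return cls(n_chromosomes, L, markers, qtl, founder_allele_freq_range)

    def marker_names(self) -> list[str]:
        names = []
        for ci in range(self.n_chromosomes):
            s, e = self.chrom_slices[ci]
            flags = self.is_qtl[s:e]
            j = 0
            for f in flags:
                if not f:
                    j += 1
                    names.append(f"c{ci + 1}m{j}")
        return names

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"GenomeSpec(n_chromosomes={self.n_chromosomes}, "
            f"length={self.chromosome_length} cM, "
            f"markers={self.n_markers}, qtl={self.n_qtl})"
        )


@dataclass(frozen=True)
class TraitModel:
    """Additive trait architecture with fixed variance components.

    ``sigma2_g`` and ``sigma2_e`` default to the milk-yield components used
    throughout the package (genetic variance 423,390 kg^2, residual variance
    987,910 kg^2, heritability 0.3).  ``qtl_effects`` are allele-substitution
    effects per QTL; :func:`assign_trait` rescales them so the founder
    true-breeding-value variance matches ``sigma2_g`` exactly.
    """

    qtl_effects: np.ndarray
    sigma2_g: float = 423_390.0
    sigma2_e: float = 987_910.0

    def __post_init__(self):
        object.__setattr__(
            self, "qtl_effects", np.asarray(self.qtl_effects, dtype=float)
        )
        if self.qtl_effects.ndim != 1:
            raise ConfigurationError("qtl_effects must be a 1-D array")
        if self.sigma2_g <= 0:
            raise ConfigurationError("sigma2_g must be positive")
        if self.sigma2_e < 0:
            raise ConfigurationError("sigma2_e must be non-negative")

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)

    @classmethod
    def draw(
        cls,
        genome: GenomeSpec,
        rng: np.random.Generator,
        sigma2_g: float = 423_390.0,
        sigma2_e: float = 987_910.0,
    ) -> "TraitModel":
        """Standard-normal QTL effects, to be calibrated by :func:`assign_trait`."""
        return cls(rng.standard_normal(genome.n_qtl), sigma2_g, sigma2_e)


@dataclass
class Individual:
    """A single diploid animal; mostly a convenience view over :class:`Population`."""

    id: int
    sire_id: int
    dam_id: int
    sex: int
    birth_generation: int
    haplotypes: np.ndarray  # (2, n_loci) uint8
    tbv: float = np.nan
    phenotype: float = np.nan
    weight: float = 1.0


@dataclass
class Pedigree:
    """Ordered pedigree records: parents always precede offspring.

    ``ids`` may be any hashable labels; ``sire_ids``/``dam_ids`` use
    ``UNKNOWN_PARENT`` (0 or "0") as the missing-parent sentinel.
    """

    ids: np.ndarray
    sire_ids: np.ndarray
    dam_ids: np.ndarray
    generation: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.sire_ids = np.asarray(self.sire_ids)
        self.dam_ids = np.asarray(self.dam_ids)
        self.generation = np.asarray(self.generation)
        n = self.ids.size
        if not (self.sire_ids.size == self.dam_ids.size == self.generation.size == n):
            raise ValueError("pedigree arrays must have equal length")
        if len(set(self.ids.tolist())) != n:
            raise ValueError("pedigree ids must be unique")
        self._index = {i: k for k, i in enumerate(self.ids.tolist())}
        # parents must be listed before their offspring
        sidx, didx = self.parent_indices()
        rows = np.arange(n)
        if np.any(sidx >= rows) or np.any(didx >= rows):
            raise ValueError("pedigree is not ordered: a parent appears after its offspring")

    @property
    def n(self) -> int:
        return int(self.ids.size)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of sire and dam per individual, -1 when unknown."""

        def lookup(parents):
            out = np.full(self.ids.size, -1, dtype=np.int64)
            for k, p in enumerate(parents.tolist()):
                if p in self._index:
                    out[k] = self._index[p]
            return out

        return lookup(self.sire_ids), lookup(self.dam_ids)

    def index_of(self, id_) -> int:
        return self._index[id_]

    @property
    def is_founder(self) -> np.ndarray:
        sidx, didx = self.parent_indices()
        return (sidx < 0) & (didx < 0)


class Population:
    """Array-backed collection of individuals sharing one genome.

    Rows are append-only; all per-individual attributes are parallel numpy
    arrays.  ``haps`` has shape ``(n, 2, n_loci)``.
    """

    def __init__(self, genome: GenomeSpec):
        self.genome = genome
        L = genome.n_loci
        self.ids = np.empty(0, dtype=np.int64)
        self.sire = np.empty(0, dtype=np.int64)
        self.dam = np.empty(0, dtype=np.int64)
        self.sex = np.empty(0, dtype=np.uint8)
        self.generation = np.empty(0, dtype=np.int32)
        self.haps = np.empty((0, 2, L), dtype=np.uint8)
        self.tbv = np.empty(0, dtype=float)
        self.phenotype = np.empty(0, dtype=float)
        self.weight = np.empty(0, dtype=float)
        self._index: dict[int, int] = {}

    # -- construction -------------------------------------------------
    def _append(
        self,
        ids,
        sire,
        dam,
        sex,
        generation,
        haps,
        tbv=None,
        phenotype=None,
        weight=None,
    ) -> np.ndarray:
        ids = np.asarray(ids, dtype=np.int64)
        k = ids.size
        for i in ids.tolist():
            if i in self._index:
                raise ValueError(f"duplicate individual id {i}")
        start = self.n
        self.ids = np.concatenate([self.ids, ids])
        self.sire = np.concatenate([self.sire, np.asarray(sire, dtype=np.int64)])
        self.dam = np.concatenate([self.dam, np.asarray(dam, dtype=np.int64)])
        self.sex = np.concatenate([self.sex, np.asarray(sex, dtype=np.uint8)])
        self.generation = np.concatenate(
            [self.generation, np.asarray(generation, dtype=np.int32)]
        )
        self.haps = np.concatenate([self.haps, np.asarray(haps, dtype=np.uint8)])
        self.tbv = np.concatenate(
            [self.tbv, np.full(k, np.nan) if tbv is None else np.asarray(tbv, float)]
        )
        self.phenotype = np.concatenate(
            [
                self.phenotype,
                np.full(k, np.nan) if phenotype is None else np.asarray(phenotype, float),
            ]
        )
        self.weight = np.concatenate(
            [self.weight, np.ones(k) if weight is None else np.asarray(weight, float)]
        )
        for off, i in enumerate(ids.tolist()):
            self._index[i] = start + off
        return np.arange(start, start + k)

    def copy(self) -> "Population":
        new = Population(self.genome)
        for name in ("ids", "sire", "dam", "sex", "generation", "haps", "tbv", "phenotype", "weight"):
            setattr(new, name, getattr(self, name).copy())
        new._index = dict(self._index)
        return new

    # -- accessors ----------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.ids.size)

    def next_id(self) -> int:
        return int(self.ids.max(initial=0)) + 1

    def rows_of(self, ids: Sequence[int]) -> np.ndarray:
        return np.asarray([self._index[i] for i in ids], dtype=np.intp)

    def dosages(self, rows=None) -> np.ndarray:
        h = self.haps if rows is None else self.haps[rows]
        return h.sum(axis=1, dtype=np.uint8)

    def marker_dosages(self, rows=None) -> np.ndarray:
        return self.dosages(rows)[:, self.genome.marker_index]

    def qtl_dosages(self, rows=None) -> np.ndarray:
        return self.dosages(rows)[:, self.genome.qtl_index]

    def marker_allele_freqs(self, rows=None) -> np.ndarray:
        return self.marker_dosages(rows).mean(axis=0) / 2.0

    def individual(self, row: int) -> Individual:
        return Individual(
            id=int(self.ids[row]),
            sire_id=int(self.sire[row]),
            dam_id=int(self.dam[row]),
            sex=int(self.sex[row]),
            birth_generation=int(self.generation[row]),
            haplotypes=self.haps[row].copy(),
            tbv=float(self.tbv[row]),
            phenotype=float(self.phenotype[row]),
            weight=float(self.weight[row]),
        )

    def pedigree(self) -> Pedigree:
        return Pedigree(
            self.ids.copy(), self.sire.copy(), self.dam.copy(), self.generation.copy()
        )


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def sample_gametes_batch(
    haps: np.ndarray, parent_rows, genome: GenomeSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw one recombinant gamete from each of ``parent_rows``.

    Crossover counts per chromosome are Poisson with mean equal to the map
    length in Morgans; crossover positions are uniform on the chromosome
    (Haldane, no interference).  Returns an array of shape
    ``(len(parent_rows), n_loci)``.
    """
    parent_rows = np.asarray(parent_rows, dtype=np.intp)
    m = parent_rows.size
    out = np.empty((m, genome.n_loci), dtype=np.uint8)
    morgans = genome.chromosome_length / 100.0
    for ci, (s, e) in enumerate(genome.chrom_slices):
        pos = genome._chrom_loci_pos[ci]
        k = rng.poisson(morgans, m)
        start = rng.integers(0, 2, m)
        src = np.repeat(start[:, None], e - s, axis=1)
        kmax = int(k.max(initial=0))
        if kmax > 0:
            rows = np.nonzero(k > 0)[0]
            xo = rng.uniform(0.0, genome.chromosome_length, size=(rows.size, kmax))
            valid = np.arange(kmax)[None, :] < k[rows][:, None]
            cnt = ((xo[:, None, :] < pos[None, :, None]) & valid[:, None, :]).sum(axis=2)
            src[rows] = (start[rows][:, None] + cnt) % 2
        out[:, s:e] = haps[parent_rows[:, None], src, np.arange(s, e)[None, :]]
    return out


def sample_gamete(
    parent: Individual, genome: GenomeSpec, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant haplotype from a single parent."""
    if parent.haplotypes.shape != (2, genome.n_loci):
        raise ValueError("parent haplotypes do not match the genome")
    return sample_gametes_batch(parent.haplotypes[None, :, :], [0], genome, rng)[0]


def random_union_offspring(
    haps: np.ndarray,
    male_rows,
    female_rows,
    n_offspring: int,
    genome: GenomeSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random-mating offspring haplotypes: each offspring draws a uniform
    random sire among ``male_rows`` and dam among ``female_rows``."""
    male_rows = np.asarray(male_rows, dtype=np.intp)
    female_rows = np.asarray(female_rows, dtype=np.intp)
    sires = male_rows[rng.integers(0, male_rows.size, n_offspring)]
    dams = female_rows[rng.integers(0, female_rows.size, n_offspring)]
    g1 = sample_gametes_batch(haps, sires, genome, rng)
    g2 = sample_gametes_batch(haps, dams, genome, rng)
    return np.stack([g1, g2], axis=1)


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def simulate_founders(
    genome: GenomeSpec,
    n_males: int,
    n_females: int,
    n_burnin_generations: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    burnin_size: int = 500,
) -> Population:
    """Generate a founder population with drift-induced LD.

    Initial allele frequencies are drawn uniformly from the genome's
    ``founder_allele_freq_range``; haplotype alleles are independent
    Bernoulli draws at those frequencies.  ``n_burnin_generations`` of
    random mating at constant size ``burnin_size`` (half of each sex)
    then build up linkage disequilibrium and some drift before the final
    generation is expanded to ``n_males + n_females`` individuals.

    The returned individuals are pedigree founders: both parents unknown,
    birth generation 0.  True breeding values are left unset until
    :func:`assign_trait` is called.
    """
    if n_males <= 0 or n_females <= 0:
        raise ConfigurationError("founder counts must be positive")
    if n_burnin_generations < 0:
        raise ConfigurationError("n_burnin_generations must be >= 0")
    if burnin_size < 2:
        raise ConfigurationError("burnin_size must be at least 2")
    if rng is None:
        rng = np.random.default_rng(seed)

    lo, hi = genome.founder_allele_freq_range
    p0 = rng.uniform(lo, hi, genome.n_loci)
    n = n_males + n_females

    if n_burnin_generations == 0:
        haps = (rng.random((n, 2, genome.n_loci)) < p0).astype(np.uint8)
    else:
        nb = burnin_size
        nbm = nb // 2
        haps = (rng.random((nb, 2, genome.n_loci)) < p0).astype(np.uint8)
        males = np.arange(nbm)
        females = np.arange(nbm, nb)
        for g in range(n_burnin_generations):
            n_off = n if g == n_burnin_generations - 1 else nb
            haps = random_union_offspring(haps, males, females, n_off, genome, rng)

    pop = Population(genome)
    sexes = np.concatenate(
        [np.full(n_males, SEX_MALE, np.uint8), np.full(n_females, SEX_FEMALE, np.uint8)]
    )
    pop._append(
        ids=np.arange(1, n + 1),
        sire=np.zeros(n, dtype=np.int64),
        dam=np.zeros(n, dtype=np.int64),
        sex=sexes,
        generation=np.zeros(n, dtype=np.int32),
        haps=haps,
    )
    return pop


# ---------------------------------------------------------------------------
# trait and offspring
# ---------------------------------------------------------------------------

def assign_trait(
    population: Population, trait: TraitModel, rescale: bool = True
) -> TraitModel:
    """Compute true breeding values and, optionally, calibrate QTL effects.

    With ``rescale=True`` the QTL effects are multiplied by a single
    constant so that the sample variance (ddof=1) of the population's true
    breeding values equals ``trait.sigma2_g`` exactly.  The population's
    ``tbv`` array is filled in place and the calibrated model returned.
    """
    qd = population.qtl_dosages().astype(float)
    tbv = qd @ trait.qtl_effects
    if rescale:
        v = tbv.var(ddof=1)
        if v <= 0:
            raise ConfigurationError(
                "TBV variance is zero (all QTL monomorphic); cannot calibrate"
            )
        fac = float(np.sqrt(trait.sigma2_g / v))
        trait = replace(trait, qtl_effects=trait.qtl_effects * fac)
        tbv = tbv * fac
    population.tbv[:] = tbv
    return trait


def assign_phenotypes(
    population: Population,
    rows,
    trait: TraitModel,
    rng: np.random.Generator,
    weight: float = 1.0,
) -> None:
    """Phenotype = TBV + Normal(0, sigma2_e / weight) for the given rows.

    A weight above 1 emulates a progeny-tested record (the average of many
    daughter performances), which carries proportionally less residual
    noise; records re-enter GBLUP with the same weight.
    """
    rows = np.asarray(rows, dtype=np.intp)
    noise_sd = float(np.sqrt(trait.sigma2_e / weight))
    population.phenotype[rows] = population.tbv[rows] + rng.normal(
        0.0, noise_sd, rows.size
    )
    population.weight[rows] = weight


def make_offspring(
    sire: Individual,
    dam: Individual,
    sex: int,
    generation: int,
    genome: GenomeSpec,
    trait: TraitModel,
    rng: np.random.Generator,
    new_id: int = 0,
    with_phenotype: bool = False,
) -> Individual:
    """Mate two individuals and return their offspring.

    The offspring inherits one recombinant gamete from each parent; its
    TBV is the dosage-weighted sum of QTL effects, and its phenotype (when
    requested) adds Normal(0, sigma2_e) residual noise.
    """
    if sire.sex != SEX_MALE:
        raise ConfigurationError(f"sire {sire.id} is not male")
    if dam.sex != SEX_FEMALE:
        raise ConfigurationError(f"dam {dam.id} is not female")
    g1 = sample_gamete(sire, genome, rng)
    g2 = sample_gamete(dam, genome, rng)
    haps = np.stack([g1, g2])
    tbv = float(haps.sum(axis=0)[genome.qtl_index] @ trait.qtl_effects)
    pheno = np.nan
    if with_phenotype:
        pheno = tbv + float(rng.normal(0.0, np.sqrt(trait.sigma2_e)))
    return Individual(
        id=new_id,
        sire_id=sire.id,
        dam_id=dam.id,
        sex=sex,
        birth_generation=generation,
        haplotypes=haps,
        tbv=tbv,
        phenotype=pheno,
    )


def make_offspring_batch(
    population: Population,
    sire_rows,
    dam_rows,
    sexes,
    generation: int,
    trait: TraitModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce one offspring per (sire, dam) pair and append to the population.

    Returns the row indices of the new individuals.
    """
    sire_rows = np.asarray(sire_rows, dtype=np.intp)
    dam_rows = np.asarray(dam_rows, dtype=np.intp)
    if sire_rows.size != dam_rows.size:
        raise ValueError("sire_rows and dam_rows must have equal length")
    if np.any(population.sex[sire_rows] != SEX_MALE):
        raise ConfigurationError("all sires must be male")
    if np.any(population.sex[dam_rows] != SEX_FEMALE):
        raise ConfigurationError("all dams must be female")
    g1 = sample_gametes_batch(population.haps, sire_rows, population.genome, rng)
    g2 = sample_gametes_batch(population.haps, dam_rows, population.genome, rng)
    haps = np.stack([g1, g2], axis=1)
    tbv = (
        haps.sum(axis=1)[:, population.genome.qtl_index].astype(float)
        @ trait.qtl_effects
    )
    k = sire_rows.size
    start_id = population.next_id()
    return population._append(
        ids=np.arange(start_id, start_id + k),
        sire=population.ids[sire_rows],
        dam=population.ids[dam_rows],
        sex=np.asarray(sexes, dtype=np.uint8),
        generation=np.full(k, generation, dtype=np.int32),
        haps=haps,
        tbv=tbv,
    )
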