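"""Genome map, phased populations, and synthetic founder generation.

The downstream breeding, trait and prediction machinery consumes a single
in-memory representation: a :class:`PhasedPopulation` holding a roster
(pandas DataFrame) and a haplotype matrix over a :class:`GenomeMap`.
Founders can either be generated synthetically — three differentiated pig
breeds under a Balding–Nichols model — or read from phased VCF / PLINK text
files (see :mod:`crossgp.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeMap",
    "FounderConfig",
    "BreedSpec",
    "PhasedPopulation",
    "ConfigurationError",
    "GenerationError",
    "generate_founders",
    "uniform_map",
    "hudson_fst",
]

ROSTER_COLUMNS = ["id", "sex", "breed", "generation", "sire", "dam"]


class ConfigurationError(ValueError):
    """Invalid generator or breeding configuration."""


class GenerationError(RuntimeError):
    """Synthetic data generation failed (e.g. MAF floor unreachable)."""


@dataclass(frozen=True)
class GenomeMap:
    """Marker map over one or more chromosomes.

    Positions are 1-based base pairs, strictly increasing within each
    chromosome, as in VCF.
    """

    chromosomes: tuple[str, ...]
    lengths: np.ndarray          # per-chromosome length in bp
    marker_chrom: np.ndarray     # int codes into `chromosomes`, per marker
    marker_pos: np.ndarray       # 1-based bp, per marker
    marker_ids: tuple[str, ...]
    ref_alleles: tuple[str, ...] = ()
    alt_alleles: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.marker_chrom) != len(self.marker_pos):
            raise ConfigurationError("marker_chrom and marker_pos length mismatch")
        for c in range(len(self.chromosomes)):
            pos = self.marker_pos[self.marker_chrom == c]
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ConfigurationError(
                    f"marker positions not strictly increasing on {self.chromosomes[c]}"
                )
            if pos.size and pos.max() > self.lengths[c]:
                raise ConfigurationError(
                    f"marker position beyond length of {self.chromosomes[c]}"
                )
        if not self.ref_alleles:
            object.__setattr__(self, "ref_alleles", ("A",) * self.n_markers)
        if not self.alt_alleles:
            object.__setattr__(self, "alt_alleles", ("G",) * self.n_markers)

    @property
    def n_markers(self) -> int:
        return len(self.marker_pos)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def chrom_marker_indices(self, c: int) -> np.ndarray:
        """Marker indices (map order) belonging to chromosome code ``c``."""
        return np.flatnonzero(self.marker_chrom == c)


def uniform_map(n_chromosomes: int = 5, chrom_length: int = 100_000_000,
                markers_per_chrom: int = 400) -> GenomeMap:
    """Evenly spaced marker map: the default desk-scale genome."""
    if n_chromosomes < 1 or markers_per_chrom < 1:
        raise ConfigurationError("need at least one chromosome and one marker")
    chroms = tuple(f"chr{i + 1}" for i in range(n_chromosomes))
    pos_single = np.linspace(1, chrom_length, markers_per_chrom, dtype=np.int64)
    marker_pos = np.tile(pos_single, n_chromosomes)
    marker_chrom = np.repeat(np.arange(n_chromosomes), markers_per_chrom)
    ids = tuple(
        f"{chroms[c]}_{p}" for c, p in zip(marker_chrom, marker_pos)
    )
    return GenomeMap(
        chromosomes=chroms,
        lengths=np.full(n_chromosomes, chrom_length, dtype=np.int64),
        marker_chrom=marker_chrom,
        marker_pos=marker_pos,
        marker_ids=ids,
    )


@dataclass
class PhasedPopulation:
    """Roster plus phased haplotypes over a genome map.

    ``haplotypes`` has shape ``(2 * n_individuals, n_markers)`` with alleles
    in {0, 1}; rows ``2i`` and ``2i + 1`` are the two haplotypes of roster
    row ``i``.  Dosage (allele count of the alternate allele) is therefore
    always in {0, 1, 2} and there is no missingness.
    """

    roster: pd.DataFrame
    haplotypes: np.ndarray
    genome: GenomeMap

    def __post_init__(self):
        missing = [c for c in ROSTER_COLUMNS if c not in self.roster.columns]
        if missing:
            raise ConfigurationError(f"roster missing columns {missing}")
        if self.haplotypes.shape != (2 * len(self.roster), self.genome.n_markers):
            raise ConfigurationError("haplotype matrix shape does not match roster/map")

    @property
    def n(self) -> int:
        return len(self.roster)

    @property
    def ids(self) -> np.ndarray:
        return self.roster["id"].to_numpy()

    def dosages(self, individuals: np.ndarray | None = None,
                markers: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele dosage matrix (individuals x markers)."""
        h = self.haplotypes
        if individuals is None:
            d = h[0::2] + h[1::2]
        else:
            idx = np.asarray(individuals)
            d = h[2 * idx] + h[2 * idx + 1]
        if markers is not None:
            d = d[:, markers]
        return d

    def index_of(self, ids) -> np.ndarray:
        """Roster row indices of the given individual ids (order preserved)."""
        lookup = pd.Series(np.arange(self.n), index=self.roster["id"])
        idx = lookup.reindex(ids)
        if idx.isna().any():
            missing = list(pd.Index(ids)[idx.isna().to_numpy()][:5])
            raise KeyError(f"ids not in roster: {missing}...")
        return idx.to_numpy(dtype=np.int64)

    def subset(self, individuals) -> "PhasedPopulation":
        idx = np.asarray(individuals)
        rows = np.empty(2 * idx.size, dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return PhasedPopulation(
            roster=self.roster.iloc[idx].reset_index(drop=True),
            haplotypes=self.haplotypes[rows],
            genome=self.genome,
        )

    def allele_frequencies(self, individuals: np.ndarray | None = None) -> np.ndarray:
        d = self.dosages(individuals)
        return d.mean(axis=0) / 2.0


@dataclass(frozen=True)
class BreedSpec:
    name: str
    boars: int
    sows: int
    fst: float = 0.15

    def __post_init__(self):
        if self.boars <= 0 or self.sows <= 0:
            raise ConfigurationError(f"{self.name}: boar/sow counts must be > 0")
        if not (0.0 <= self.fst < 1.0):
            raise ConfigurationError(f"{self.name}: F_ST must be in [0, 1)")


@dataclass(frozen=True)
class FounderConfig:
    """Configuration of the synthetic founder generator.

    Breed allele frequencies follow a Balding–Nichols model: a shared
    ancestral frequency p0 ~ Uniform(freq_lo, freq_hi) per locus, then per
    breed p_b ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F) with F the breed's
    differentiation parameter.

    Founder linkage has two modes.  ``linkage='mosaic'`` (default) draws a
    small pool of base haplotypes per breed (alleles Bernoulli(p_b) per
    locus) and builds each founder haplotype as a recombinant mosaic of
    pool members with exponentially distributed segment lengths — emulating
    the extensive haplotype sharing (and hence marker LD) of a breed with
    small effective population size, as on a real genotyping panel.
    ``linkage='independent'`` draws every locus independently within breed,
    so founder LD is zero and disequilibrium accrues only through pedigree
    co-segregation downstream.
    """

    breeds: tuple[BreedSpec, ...]
    n_chromosomes: int = 5
    chrom_length: int = 100_000_000
    markers_per_chrom: int = 400
    freq_lo: float = 0.05
    freq_hi: float = 0.95
    maf_floor: float = 0.01
    max_redraws: int = 100
    linkage: str = "mosaic"
    pool_size: int = 8                   # base haplotypes per breed (mosaic)
    mean_segment_bp: float = 10_000_000  # expected mosaic segment length
    seed: int = 0

    def __post_init__(self):
        if not self.breeds:
            raise ConfigurationError("at least one breed required")
        if self.n_chromosomes < 1 or self.markers_per_chrom < 1:
            raise ConfigurationError("zero markers or chromosomes")
        if not (0.0 <= self.maf_floor < 0.5):
            raise ConfigurationError("MAF floor must be in [0, 0.5)")
        if self.linkage not in {"mosaic", "independent"}:
            raise ConfigurationError(f"unknown linkage mode {self.linkage!r}")
        if self.linkage == "mosaic" and self.pool_size < 2:
            raise ConfigurationError("mosaic pool needs at least 2 haplotypes")


def full_scale_founder_config(markers_per_chrom: int = 400, seed: int = 0,
                               n_chromosomes: int = 5) -> FounderConfig:
    """Founder roster matching the real ancestral panel's breed/sex counts:
    Duroc 10 boars/50 sows, Landrace 10/100, Yorkshire 20/500 (690 pigs)."""
    return FounderConfig(
        breeds=(
            BreedSpec("Duroc", 10, 50),
            BreedSpec("Landrace", 10, 100),
            BreedSpec("Yorkshire", 20, 500),
        ),
        n_chromosomes=n_chromosomes,
        markers_per_chrom=markers_per_chrom,
        seed=seed,
    )


def _breed_frequencies(p0: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    if fst == 0.0:
        return p0.copy()
    a = p0 * (1.0 - fst) / fst
    b = (1.0 - p0) * (1.0 - fst) / fst
    return rng.beta(a, b)


def _mosaic_base_indices(genome: GenomeMap, n_hap: int, pool: int,
                         mean_segment_bp: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Which pool haplotype each founder haplotype carries at each marker:
    segments with exponential length, independent pool choice per segment."""
    base = np.empty((n_hap, genome.n_markers), dtype=np.int16)
    for c in range(genome.n_chromosomes):
        cols = genome.chrom_marker_indices(c)
        L = float(genome.lengths[c])
        pos = genome.marker_pos[cols].astype(float)
        for h in range(n_hap):
            n_sw = rng.poisson(L / mean_segment_bp)
            if n_sw == 0:
                base[h, cols] = rng.integers(0, pool)
                continue
            bps = np.sort(rng.uniform(0.0, L, n_sw))
            seg_ids = rng.integers(0, pool, n_sw + 1)
            base[h, cols] = seg_ids[np.searchsorted(bps, pos)]
    return base


def generate_founders(config: FounderConfig) -> PhasedPopulation:
    """Generate phased founders for the configured breeds.

    Every retained marker segregates in the pooled panel with minor allele
    frequency at least ``config.maf_floor``; loci failing the floor are
    redrawn (new ancestral and breed frequencies, new alleles) up to
    ``config.max_redraws`` times.  In mosaic mode the haplotype-segment
    structure is drawn once and kept; only the allele content is redrawn.
    """
    genome = uniform_map(config.n_chromosomes, config.chrom_length,
                         config.markers_per_chrom)
    rng = np.random.default_rng(config.seed)
    m = genome.n_markers

    counts = [(b.name, b.boars, b.sows) for b in config.breeds]
    n_total = sum(b + s for _, b, s in counts)

    hap = np.empty((2 * n_total, m), dtype=np.int8)
    rows, ids, sexes, breeds = 0, [], [], []
    breed_slices: list[tuple[BreedSpec, slice]] = []
    for spec in config.breeds:
        nb = spec.boars + spec.sows
        breed_slices.append((spec, slice(rows, rows + nb)))
        for j in range(nb):
            ids.append(f"{spec.name[0]}F{j:04d}")
            sexes.append("male" if j < spec.boars else "female")
            breeds.append(spec.name)
        rows += nb

    mosaics: dict[str, np.ndarray] = {}
    if config.linkage == "mosaic":
        for spec, sl in breed_slices:
            nb = sl.stop - sl.start
            mosaics[spec.name] = _mosaic_base_indices(
                genome, 2 * nb, config.pool_size, config.mean_segment_bp, rng)

    active = np.arange(m)
    p0 = rng.uniform(config.freq_lo, config.freq_hi, size=m)
    for attempt in range(config.max_redraws + 1):
        for spec, sl in breed_slices:
            pb = _breed_frequencies(p0[active], spec.fst, rng)
            nb = sl.stop - sl.start
            if config.linkage == "mosaic":
                pool = (rng.random((config.pool_size, active.size))
                        < pb).astype(np.int8)
                base = mosaics[spec.name][:, active]
                draws = pool[base, np.arange(active.size)[None, :]]
            else:
                draws = (rng.random((2 * nb, active.size)) < pb).astype(np.int8)
            hap[2 * sl.start:2 * sl.stop, active] = draws
        freq = hap[:, active].mean(axis=0)
        maf = np.minimum(freq, 1.0 - freq)
        bad = maf < config.maf_floor
        if not bad.any():
            break
        active = active[bad]
        p0[active] = rng.uniform(config.freq_lo, config.freq_hi, size=active.size)
    freq = hap.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    if (maf < config.maf_floor).any():
        n_bad = int((maf < config.maf_floor).sum())
        raise GenerationError(
            f"{n_bad} loci below MAF floor {config.maf_floor} after "
            f"{config.max_redraws} redraws"
        )

    roster = pd.DataFrame({
        "id": ids,
        "sex": sexes,
        "breed": breeds,
        "generation": "GGP1",
        "sire": None,
        "dam": None,
    })
    return PhasedPopulation(roster=roster, haplotypes=hap, genome=genome)


def hudson_fst(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Hudson's F_ST estimator (ratio of averages) between two populations
    given dosage matrices (individuals x markers)."""
    na, nb = dosages_a.shape[0], dosages_b.shape[0]
    pa = dosages_a.mean(axis=0) / 2.0
    pb = dosages_b.mean(axis=0) / 2.0
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na * 2 - 1) - pb * (1 - pb) / (nb * 2 - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    ok = den > 0
    return float(num[ok].sum() / den[ok].sum())
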