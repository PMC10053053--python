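"""Meiosis and the DLY three-way crossbreeding system.

The simulated system mirrors commercial pig production: a purebred nucleus
(great-grandparent, GGP) of Duroc, Landrace and Yorkshire is expanded
within breed into grandparent (GP) generations; Landrace boars x Yorkshire
sows produce the LY parent (P) generation; Duroc terminal boars x LY sows
produce the commercial DLY (C) generation.  The nucleus is replaced twice
(100% of males, 50% of females) from GP recruits drawn evenly across dam
families, so |GGP2| = |GGP3| = |GGP1| per breed.  No directional selection
is applied anywhere.

Meiosis draws 4-6 crossovers per chromosome (uniform on {4,5,6}),
breakpoints uniform on physical length, no interference, no mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founders import ConfigurationError, GenomeMap, PhasedPopulation

__all__ = [
    "MeiosisModel",
    "BreedingSystemConfig",
    "SystemPopulations",
    "BreedingError",
    "make_gamete",
    "make_gametes",
    "mate",
    "run_breeding_system",
    "select_candidates",
    "full_scale_config",
    "desk_scale_config",
]


class BreedingError(RuntimeError):
    """Breeding system cannot proceed (e.g. insufficient eligible parents)."""


@dataclass(frozen=True)
class MeiosisModel:
    min_crossovers: int = 4
    max_crossovers: int = 6
    interference: bool = False   # fixed off
    mutation: bool = False       # fixed off

    def __post_init__(self):
        if not (0 <= self.min_crossovers <= self.max_crossovers):
            raise ConfigurationError("need 0 <= min_crossovers <= max_crossovers")


def make_gametes(haplotypes: np.ndarray, parent_idx: np.ndarray,
                 genome: GenomeMap, model: MeiosisModel,
                 rng: np.random.Generator, chunk: int = 16384) -> np.ndarray:
    """Vectorised meiosis: one gamete per entry of ``parent_idx``.

    ``haplotypes`` is the (2n x m) phased matrix; parent ``p`` contributes
    rows ``2p`` and ``2p + 1``.  Per chromosome, each gamete draws a
    crossover count uniformly on {min..max}, places breakpoints uniformly
    over (0, length), starts from a uniformly chosen parental haplotype and
    switches at each breakpoint.
    """
    parent_idx = np.asarray(parent_idx, dtype=np.int64)
    n = parent_idx.size
    m = genome.n_markers
    out = np.empty((n, m), dtype=np.int8)
    kmax = model.max_crossovers
    for c in range(genome.n_chromosomes):
        cols = genome.chrom_marker_indices(c)
        if cols.size == 0:
            continue
        pos = genome.marker_pos[cols].astype(np.float64)
        L = float(genome.lengths[c])
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            nb = hi - lo
            start = rng.integers(0, 2, size=nb)
            if kmax > 0:
                k = rng.integers(model.min_crossovers, kmax + 1, size=nb)
                bp = rng.uniform(0.0, L, size=(nb, kmax))
                bp[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
                crossings = (bp[:, :, None] < pos[None, None, :]).sum(axis=1)
                src = (start[:, None] + crossings) % 2
            else:
                src = np.broadcast_to(start[:, None], (nb, cols.size))
            p = parent_idx[lo:hi]
            h0 = haplotypes[np.ix_(2 * p, cols)]
            h1 = haplotypes[np.ix_(2 * p + 1, cols)]
            out[lo:hi, cols] = np.where(src == 0, h0, h1)
    return out


def make_gamete(parent_haplotypes: np.ndarray, genome: GenomeMap,
                model: MeiosisModel, rng: np.random.Generator) -> np.ndarray:
    """Single gamete from one parent's (2 x m) haplotype pair."""
    pair = np.asarray(parent_haplotypes)
    if pair.shape != (2, genome.n_markers):
        raise ConfigurationError("parent haplotypes do not cover the map")
    return make_gametes(pair, np.array([0]), genome, model, rng)[0]


def _litter_sexes(litter_size: int) -> list[str]:
    n_m = litter_size // 2 + litter_size % 2
    return ["male"] * n_m + ["female"] * (litter_size - n_m)


def mate(pop: PhasedPopulation, sire_id: str, dam_id: str, n_progeny: int,
         model: MeiosisModel, rng: np.random.Generator,
         sexes: list[str] | None = None, breed: str | None = None,
         generation: str = "F1") -> PhasedPopulation:
    """Mate one sire x dam pair; each progeny receives one paternal and one
    maternal gamete.  Returns the progeny as their own population."""
    if n_progeny <= 0:
        raise ConfigurationError("progeny count must be > 0")
    si, di = pop.index_of([sire_id])[0], pop.index_of([dam_id])[0]
    s_sex = pop.roster.iloc[si]["sex"]
    d_sex = pop.roster.iloc[di]["sex"]
    if s_sex == d_sex:
        raise BreedingError(f"same-sex pairing: {sire_id} ({s_sex}) x {dam_id}")
    if s_sex != "male":
        raise BreedingError(f"sire {sire_id} is not male")
    if sexes is None:
        sexes = _litter_sexes(n_progeny)
    if breed is None:
        b_s, b_d = pop.roster.iloc[si]["breed"], pop.roster.iloc[di]["breed"]
        breed = b_s if b_s == b_d else f"{b_s}x{b_d}"
    pat = make_gametes(pop.haplotypes, np.full(n_progeny, si), pop.genome, model, rng)
    mat = make_gametes(pop.haplotypes, np.full(n_progeny, di), pop.genome, model, rng)
    hap = np.empty((2 * n_progeny, pop.genome.n_markers), dtype=np.int8)
    hap[0::2], hap[1::2] = pat, mat
    roster = pd.DataFrame({
        "id": [f"{generation}_{sire_id}x{dam_id}_{j}" for j in range(n_progeny)],
        "sex": sexes,
        "breed": breed,
        "generation": generation,
        "sire": sire_id,
        "dam": dam_id,
    })
    return PhasedPopulation(roster=roster, haplotypes=hap, genome=pop.genome)


@dataclass(frozen=True)
class BreedingSystemConfig:
    """Counts defining the crossbreeding design.

    Defaults are the full production scale: 10 progeny per sow (5m/5f),
    LY cross 100 Landrace boars x 2000 Yorkshire sows, DLY cross 100 Duroc
    boars (from GP2) x 10,000 LY sows, GGP replacement 100% males / 50%
    females with GP recruits 10m/25f Duroc, 10m/50f Landrace, 20m/250f
    Yorkshire, and 4 candidates (2m/2f) per GGP3 sow.
    """

    litter_size: int = 10
    ly_boars: int = 100          # Landrace boars for the LY cross (from GP1)
    ly_sows: int = 2000          # Yorkshire sows for the LY cross (from GP1)
    dly_boars: int = 100         # Duroc terminal boars (from GP2)
    dly_sows: int = 10_000       # LY sows for the DLY cross
    recruits: dict = field(default_factory=lambda: {
        "Duroc": (10, 25), "Landrace": (10, 50), "Yorkshire": (20, 250)})
    candidates_per_sow: tuple[int, int] = (2, 2)   # (males, females)
    seed: int = 0

    def __post_init__(self):
        if self.litter_size <= 0:
            raise ConfigurationError("litter size must be > 0")


def full_scale_config(seed: int = 0) -> BreedingSystemConfig:
    return BreedingSystemConfig(seed=seed)


def desk_scale_config(seed: int = 0) -> BreedingSystemConfig:
    """Reduced design preserving the production ratios (see docs):
    3900 GP per generation, 4000 LY, 20,000 DLY."""
    return BreedingSystemConfig(
        ly_boars=20, ly_sows=400, dly_boars=20, dly_sows=2000,
        recruits={"Duroc": (6, 15), "Landrace": (6, 30), "Yorkshire": (12, 150)},
        seed=seed,
    )


@dataclass
class SystemPopulations:
    """All animals of a breeding-system run plus generation membership.

    ``population.roster['generation']`` records where an animal was created
    (GGP1, GP1, GP2, GP3, P, C).  GGP2 and GGP3 are *composed* of existing
    animals (retained GGP females plus GP recruits); their membership is in
    ``membership`` alongside the creation generations and the candidate set.
    """

    population: PhasedPopulation
    membership: dict[str, np.ndarray]
    candidate_idx: np.ndarray

    def generation_indices(self, label: str) -> np.ndarray:
        return self.membership[label]

    def counts(self) -> dict[str, int]:
        return {k: int(v.size) for k, v in self.membership.items()}

    @property
    def n_distinct(self) -> int:
        """Distinct animals across the whole system (GGP2/GGP3 members are
        already counted in their creation generation)."""
        return self.population.n


class _Recorder:
    """Accumulates roster rows and haplotypes with preallocated storage."""

    def __init__(self, founders: PhasedPopulation, total: int):
        g = founders.genome
        self.genome = g
        self.hap = np.empty((2 * total, g.n_markers), dtype=np.int8)
        nf = founders.n
        self.hap[: 2 * nf] = founders.haplotypes
        r = founders.roster
        self.ids = list(r["id"])
        self.sex = list(r["sex"])
        self.breed = list(r["breed"])
        self.gen = list(r["generation"])
        self.sire = list(r["sire"])
        self.dam = list(r["dam"])
        self.n = nf

    def add_batch(self, ids, sexes, breeds, gen, sires, dams,
                  pat: np.ndarray, mat: np.ndarray) -> np.ndarray:
        k = len(ids)
        lo = self.n
        self.hap[2 * lo:2 * (lo + k):2] = pat
        self.hap[2 * lo + 1:2 * (lo + k):2] = mat
        self.ids.extend(ids)
        self.sex.extend(sexes)
        self.breed.extend(breeds)
        self.gen.extend([gen] * k)
        self.sire.extend(sires)
        self.dam.extend(dams)
        self.n += k
        return np.arange(lo, lo + k)

    def finish(self) -> PhasedPopulation:
        roster = pd.DataFrame({
            "id": self.ids, "sex": self.sex, "breed": self.breed,
            "generation": self.gen, "sire": self.sire, "dam": self.dam,
        })
        return PhasedPopulation(roster=roster, haplotypes=self.hap[: 2 * self.n],
                                genome=self.genome)


def _blocks(sows: np.ndarray, boars: np.ndarray, rng: np.random.Generator
            ) -> tuple[np.ndarray, np.ndarray]:
    """Assign each dam to exactly one sire in randomised blocks of (near)
    equal size.  Returns per-sow sire indices aligned with shuffled sows."""
    sows = rng.permutation(sows)
    groups = np.array_split(sows, boars.size)
    sire_per_sow = np.concatenate([
        np.full(g.size, b, dtype=np.int64) for g, b in zip(groups, boars)
    ])
    return sows, sire_per_sow


def _expand(rec: _Recorder, boars: np.ndarray, sows: np.ndarray, breed: str,
            gen: str, litter: int, model: MeiosisModel,
            rng: np.random.Generator) -> np.ndarray:
    """Within-breed one-male-to-many-females expansion, ``litter`` progeny
    per sow with a fixed half-male/half-female pattern."""
    if boars.size == 0 or sows.size == 0:
        raise BreedingError(f"no eligible parents for {gen} {breed}")
    sows, sire_per_sow = _blocks(sows, boars, rng)
    dam_idx = np.repeat(sows, litter)
    sire_idx = np.repeat(sire_per_sow, litter)
    sexes = _litter_sexes(litter) * sows.size
    pat = make_gametes(rec.hap, sire_idx, rec.genome, model, rng)
    mat = make_gametes(rec.hap, dam_idx, rec.genome, model, rng)
    tag = breed[0] if "x" not in breed else breed
    ids = [f"{gen}_{tag}_{j:06d}" for j in range(dam_idx.size)]
    sires = [rec.ids[i] for i in sire_idx]
    dams = [rec.ids[i] for i in dam_idx]
    return rec.add_batch(ids, sexes, [breed] * len(ids), gen, sires, dams, pat, mat)


def _recruit_round_robin(rec: _Recorder, gp_idx: np.ndarray, need_m: int,
                         need_f: int, rng: np.random.Generator) -> np.ndarray:
    """Pick GP recruits round-robin across dam families (sorted by dam id)
    so that every GGP lineage is covered as evenly as possible."""
    dams = np.array([rec.dam[i] for i in gp_idx])
    sexes = np.array([rec.sex[i] for i in gp_idx])
    fam_ids = sorted(set(dams))
    picked: list[int] = []
    for sex_label, need in (("male", need_m), ("female", need_f)):
        pools = {
            f: list(rng.permutation(gp_idx[(dams == f) & (sexes == sex_label)]))
            for f in fam_ids
        }
        got = 0
        while got < need:
            advanced = False
            for f in fam_ids:
                if got >= need:
                    break
                if pools[f]:
                    picked.append(pools[f].pop())
                    got += 1
                    advanced = True
            if not advanced:
                raise BreedingError(
                    f"cannot recruit {need} {sex_label}s from GP families")
    return np.asarray(picked, dtype=np.int64)


def _replace_nucleus(rec: _Recorder, ggp_idx: np.ndarray, gp_idx: np.ndarray,
                     recruits: tuple[int, int], rng: np.random.Generator
                     ) -> np.ndarray:
    """Form the next GGP: keep a random 50% of current GGP females, replace
    all males and the other females with GP recruits."""
    sexes = np.array([rec.sex[i] for i in ggp_idx])
    females = ggp_idx[sexes == "female"]
    keep_f = rng.permutation(females)[: females.size // 2]
    need_m, need_f_total = recruits
    rec_idx = _recruit_round_robin(rec, gp_idx, need_m, need_f_total, rng)
    return np.sort(np.concatenate([keep_f, rec_idx]))


def run_breeding_system(founders: PhasedPopulation,
                        config: BreedingSystemConfig | None = None,
                        model: MeiosisModel | None = None) -> SystemPopulations:
    """Execute the full crossbreeding design from phased founders.

    Produces GP1/GP2/GP3 by within-breed expansion of the (replaced)
    nucleus, the LY parent generation, the DLY commercial generation, and
    the purebred candidate subset of GP3.  All randomness derives from
    ``config.seed``.
    """
    config = config or BreedingSystemConfig()
    model = model or MeiosisModel()
    rng = np.random.default_rng(config.seed)
    litter = config.litter_size

    roster = founders.roster
    breeds = [b for b in ["Duroc", "Landrace", "Yorkshire"]
              if b in set(roster["breed"])]
    if set(breeds) != {"Duroc", "Landrace", "Yorkshire"}:
        raise BreedingError("founders must contain Duroc, Landrace and Yorkshire")

    by_breed_sows = {
        b: ((roster["breed"] == b) & (roster["sex"] == "female")).sum()
        for b in breeds
    }
    gp_size = litter * sum(by_breed_sows.values())
    total = founders.n + 3 * gp_size \
        + litter * config.ly_sows + litter * config.dly_sows
    rec = _Recorder(founders, total)

    ggp1 = np.arange(founders.n)
    membership: dict[str, np.ndarray] = {"GGP1": ggp1}

    def breed_parents(idx: np.ndarray, breed: str):
        sex = np.array([rec.sex[i] for i in idx])
        brd = np.array([rec.breed[i] for i in idx])
        sel = brd == breed
        return idx[sel & (sex == "male")], idx[sel & (sex == "female")]

    # nucleus expansions: GGP1 -> GP1, GGP2 -> GP2, GGP3 -> GP3
    ggp = ggp1
    gp_generations: dict[str, np.ndarray] = {}
    ggp3 = None
    for g in (1, 2, 3):
        gp_parts = []
        for b in breeds:
            boars, sows = breed_parents(ggp, b)
            gp_parts.append(_expand(rec, boars, sows, b, f"GP{g}", litter, model, rng))
        gp_idx = np.concatenate(gp_parts)
        gp_generations[f"GP{g}"] = gp_idx
        membership[f"GP{g}"] = gp_idx
        if g < 3:
            parts = []
            for b in breeds:
                bm = np.array([rec.breed[i] for i in ggp]) == b
                gpm = np.array([rec.breed[i] for i in gp_idx]) == b
                parts.append(_replace_nucleus(
                    rec, ggp[bm], gp_idx[gpm], config.recruits[b], rng))
            ggp = np.concatenate(parts)
            membership[f"GGP{g + 1}"] = ggp
            if g == 2:
                ggp3 = ggp

    # LY parent generation: Landrace boars x Yorkshire sows from GP1
    gp1 = gp_generations["GP1"]
    l_boars, _ = breed_parents(gp1, "Landrace")
    _, y_sows = breed_parents(gp1, "Yorkshire")
    if l_boars.size < config.ly_boars or y_sows.size < config.ly_sows:
        raise BreedingError("insufficient GP1 parents for the LY cross")
    lb = rng.permutation(l_boars)[: config.ly_boars]
    ys = rng.permutation(y_sows)[: config.ly_sows]
    ly_idx = _cross(rec, lb, ys, "LY", "P", litter, model, rng)
    membership["P"] = ly_idx

    # DLY commercial generation: Duroc boars (GP2) x LY sows
    gp2 = gp_generations["GP2"]
    d_boars, _ = breed_parents(gp2, "Duroc")
    ly_sex = np.array([rec.sex[i] for i in ly_idx])
    ly_females = ly_idx[ly_sex == "female"]
    if d_boars.size < config.dly_boars or ly_females.size < config.dly_sows:
        raise BreedingError("insufficient parents for the DLY cross")
    db = rng.permutation(d_boars)[: config.dly_boars]
    lys = rng.permutation(ly_females)[: config.dly_sows]
    dly_idx = _cross(rec, db, lys, "DLY", "C", litter, model, rng)
    membership["C"] = dly_idx

    population = rec.finish()
    system = SystemPopulations(population=population, membership=membership,
                               candidate_idx=np.empty(0, dtype=np.int64))
    system.candidate_idx = select_candidates(
        system, ggp3, config.candidates_per_sow, rng)
    return system


def _cross(rec: _Recorder, boars: np.ndarray, sows: np.ndarray, breed: str,
           gen: str, litter: int, model: MeiosisModel,
           rng: np.random.Generator) -> np.ndarray:
    return _expand(rec, boars, sows, breed, gen, litter, model, rng)


def select_candidates(system: SystemPopulations, ggp3_idx: np.ndarray,
                      per_sow: tuple[int, int],
                      rng: np.random.Generator) -> np.ndarray:
    """Candidate subset of GP3: ``per_sow`` (males, females) picked at
    random from the progeny of each GGP3 sow."""
    pop = system.population
    roster = pop.roster
    gp3 = system.membership["GP3"]
    sex3 = roster["sex"].to_numpy()[gp3]
    dam3 = roster["dam"].to_numpy()[gp3]
    ggp_sex = roster["sex"].to_numpy()[ggp3_idx]
    sow_ids = roster["id"].to_numpy()[ggp3_idx[ggp_sex == "female"]]
    need_m, need_f = per_sow
    chosen: list[np.ndarray] = []
    for sid in sow_ids:
        prog = gp3[dam3 == sid]
        males = prog[sex3[dam3 == sid] == "male"]
        females = prog[sex3[dam3 == sid] == "female"]
        if males.size < need_m or females.size < need_f:
            raise BreedingError(
                f"GGP3 sow {sid} lacks {need_m}m/{need_f}f progeny")
        chosen.append(rng.permutation(males)[:need_m])
        chosen.append(rng.permutation(females)[:need_f])
    return np.sort(np.concatenate(chosen))
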