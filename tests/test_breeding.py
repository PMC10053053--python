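import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossgp.breeding import (
    BreedingError,
    BreedingSystemConfig,
    MeiosisModel,
    make_gamete,
    make_gametes,
    mate,
    run_breeding_system,
)
from crossgp.founders import (
    BreedSpec,
    ConfigurationError,
    FounderConfig,
    GenomeMap,
    PhasedPopulation,
    generate_founders,
    uniform_map,
)


def _pop_from_haps(hap_pairs, sexes, genome):
    n = len(sexes)
    roster = pd.DataFrame({
        "id": [f"I{i}" for i in range(n)], "sex": sexes,
        "breed": "Duroc", "generation": "GGP1", "sire": None, "dam": None})
    return PhasedPopulation(roster=roster, haplotypes=np.asarray(hap_pairs),
                            genome=genome)


class TestMakeGamete:
    def test_homozygote_invariance(self):
        g = uniform_map(2, 1_000_000, 30)
        hap = np.tile(np.array([0, 1, 1, 0, 1] * 12, dtype=np.int8), (2, 1))
        rng = np.random.default_rng(0)
        for _ in range(5):
            gam = make_gamete(hap, g, MeiosisModel(), rng)
            np.testing.assert_array_equal(gam, hap[0])

    def test_crossover_count_on_dense_map(self):
        # haplotypes all-0 / all-1: switch count along the gamete equals the
        # number of breakpoints landing in marker-covered intervals
        g = uniform_map(1, 1_000_000, 2000)
        hap = np.vstack([np.zeros(2000, np.int8), np.ones(2000, np.int8)])
        rng = np.random.default_rng(1)
        counts = []
        for _ in range(200):
            gam = make_gamete(hap, g, MeiosisModel(), rng)
            counts.append(int(np.abs(np.diff(gam.astype(int))).sum()))
        assert min(counts) >= 0 and max(counts) <= 6
        assert np.mean(counts) == pytest.approx(5.0, abs=0.4)
        assert all(c >= 3 for c in counts)  # dense markers rarely hide one

    def test_transmission_frequency_half(self):
        g = uniform_map(1, 1000, 1)
        hap = np.array([[0], [1]], dtype=np.int8)
        rng = np.random.default_rng(2)
        gams = make_gametes(np.vstack([hap] ), np.zeros(10_000, dtype=int),
                            g, MeiosisModel(), rng)
        freq0 = 1.0 - gams.mean()
        assert freq0 == pytest.approx(0.5, abs=0.015)

    def test_map_mismatch_rejected(self):
        g = uniform_map(1, 1000, 5)
        with pytest.raises(ConfigurationError):
            make_gamete(np.zeros((2, 4), np.int8), g, MeiosisModel(),
                        np.random.default_rng(0))

    def test_alleles_always_parental(self):
        g = uniform_map(2, 500_000, 25)
        rng = np.random.default_rng(3)
        hap = (rng.random((2, 50)) < 0.5).astype(np.int8)
        for _ in range(10):
            gam = make_gamete(hap, g, MeiosisModel(), rng)
            assert np.all((gam == hap[0]) | (gam == hap[1]))


class TestMate:
    @pytest.fixture
    def parents(self):
        g = uniform_map(1, 1_000_000, 40)
        haps = np.zeros((4, 40), dtype=np.int8)
        haps[0:2] = 1  # sire homozygous 1 -> dosage 2; dam dosage 0
        return _pop_from_haps(haps, ["male", "female"], g)

    def test_forced_heterozygote(self, parents):
        prog = mate(parents, "I0", "I1", 6, MeiosisModel(),
                    np.random.default_rng(0))
        np.testing.assert_array_equal(prog.dosages(), np.ones((6, 40)))
        assert list(prog.roster["sire"]) == ["I0"] * 6

    def test_litter_sex_pattern(self, parents):
        prog = mate(parents, "I0", "I1", 10, MeiosisModel(),
                    np.random.default_rng(0))
        assert (prog.roster["sex"] == "male").sum() == 5
        assert (prog.roster["sex"] == "female").sum() == 5

    def test_same_sex_rejected(self, parents):
        with pytest.raises(BreedingError):
            mate(parents, "I1", "I0", 2, MeiosisModel(),
                 np.random.default_rng(0))

    def test_mendelian_segregation(self):
        g = uniform_map(1, 1000, 1)
        haps = np.array([[0], [1], [0], [1]], dtype=np.int8)  # both het
        pop = _pop_from_haps(haps, ["male", "female"], g)
        prog = mate(pop, "I0", "I1", 1000, MeiosisModel(),
                    np.random.default_rng(4))
        obs = np.bincount(prog.dosages()[:, 0], minlength=3)
        chi2, p = stats.chisquare(obs, f_exp=[250, 500, 250])
        assert p > 0.001


class TestBreedingSystem:
    def test_generation_counts(self, small_system):
        c = small_system.counts()
        # 12 sows total x litter 10 per GP generation
        assert c["GP1"] == c["GP2"] == c["GP3"] == 120
        assert c["P"] == 20 and c["C"] == 100
        assert c["GGP1"] == c["GGP2"] == c["GGP3"] == 18

    def test_nucleus_constancy_per_breed(self, small_system):
        r = small_system.population.roster
        for label in ("GGP1", "GGP2", "GGP3"):
            idx = small_system.membership[label]
            by = r.iloc[idx].groupby(["breed", "sex"]).size()
            for b in ("Duroc", "Landrace", "Yorkshire"):
                assert by[(b, "male")] == 2 and by[(b, "female")] == 4

    def test_cross_breed_labels(self, small_system):
        r = small_system.population.roster
        assert set(r.loc[r["generation"] == "P", "breed"]) == {"LY"}
        assert set(r.loc[r["generation"] == "C", "breed"]) == {"DLY"}

    def test_mendelian_consistency_exhaustive(self, small_system):
        pop = small_system.population
        r = pop.roster
        ids = pd.Series(np.arange(pop.n), index=r["id"])
        nonfounders = r.index[r["sire"].notna()]
        for i in nonfounders[:100]:
            si, di = ids[r.loc[i, "sire"]], ids[r.loc[i, "dam"]]
            pat, mat = pop.haplotypes[2 * i], pop.haplotypes[2 * i + 1]
            assert np.all((pat == pop.haplotypes[2 * si])
                          | (pat == pop.haplotypes[2 * si + 1]))
            assert np.all((mat == pop.haplotypes[2 * di])
                          | (mat == pop.haplotypes[2 * di + 1]))

    def test_no_new_alleles(self, small_system):
        pop = small_system.population
        founders = small_system.membership["GGP1"]
        f_dos = pop.dosages(founders)
        fixed0 = f_dos.max(axis=0) == 0
        fixed1 = f_dos.min(axis=0) == 2
        all_dos = pop.dosages()
        assert np.all(all_dos[:, fixed0] == 0)
        assert np.all(all_dos[:, fixed1] == 2)

    def test_candidates_from_each_ggp3_sow(self, small_system):
        pop = small_system.population
        cand = small_system.candidate_idx
        r = pop.roster
        assert cand.size == 4 * 12  # 2m/2f per GGP3 sow, 12 sows
        sexes = r["sex"].to_numpy()[cand]
        assert (sexes == "male").sum() == (sexes == "female").sum()
        assert set(r["generation"].to_numpy()[cand]) == {"GP3"}

    def test_scaled_counts_arithmetic(self):
        # one-fifth of production scale in every parent count -> every
        # generation is exactly one fifth of full size
        founders = generate_founders(FounderConfig(
            breeds=(BreedSpec("Duroc", 2, 10), BreedSpec("Landrace", 2, 20),
                    BreedSpec("Yorkshire", 4, 100)),
            n_chromosomes=2, markers_per_chrom=25, seed=8))
        config = BreedingSystemConfig(
            ly_boars=20, ly_sows=400, dly_boars=20, dly_sows=2000,
            recruits={"Duroc": (2, 5), "Landrace": (2, 10),
                      "Yorkshire": (4, 50)}, seed=9)
        system = run_breeding_system(founders, config)
        c = system.counts()
        assert c["GP1"] == c["GP2"] == c["GP3"] == 6500 // 5
        assert c["P"] == 20_000 // 5 and c["C"] == 100_000 // 5
        assert system.candidate_idx.size == 2600 // 5

    def test_insufficient_parents_raises(self, small_system):
        founders = generate_founders(FounderConfig(
            breeds=(BreedSpec("Duroc", 2, 4), BreedSpec("Landrace", 2, 4),
                    BreedSpec("Yorkshire", 2, 4)),
            n_chromosomes=1, markers_per_chrom=10, seed=1))
        config = BreedingSystemConfig(
            ly_boars=50, ly_sows=2, dly_boars=2, dly_sows=10,
            recruits={"Duroc": (2, 2), "Landrace": (2, 2),
                      "Yorkshire": (2, 2)}, seed=2)
        with pytest.raises(BreedingError, match="LY cross"):
            run_breeding_system(founders, config)

    def test_reproducible_from_seed(self):
        founders = generate_founders(FounderConfig(
            breeds=(BreedSpec("Duroc", 2, 4), BreedSpec("Landrace", 2, 4),
                    BreedSpec("Yorkshire", 2, 4)),
            n_chromosomes=1, markers_per_chrom=10, seed=1))
        config = BreedingSystemConfig(
            ly_boars=2, ly_sows=2, dly_boars=2, dly_sows=10,
            recruits={"Duroc": (2, 2), "Landrace": (2, 2),
                      "Yorkshire": (2, 2)}, seed=2)
        a = run_breeding_system(founders, config)
        b = run_breeding_system(founders, config)
        np.testing.assert_array_equal(a.population.haplotypes,
                                      b.population.haplotypes)
        np.testing.assert_array_equal(a.candidate_idx, b.candidate_idx)
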