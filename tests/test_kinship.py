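import numpy as np
import pytest

from crossgp.founders import BreedSpec, ConfigurationError, FounderConfig, \
    generate_founders, uniform_map
from crossgp.kinship import (
    GenotypeMatrixView,
    cross_ibs,
    ld_prune,
    moment_ibd,
    pairwise_ibs,
    pairwise_r2,
    vanraden_grm,
)


def brute_force_grm(d, p):
    n, m = d.shape
    g = np.zeros((n, n))
    denom = 2 * sum(p[i] * (1 - p[i]) for i in range(m))
    for j in range(n):
        for k in range(n):
            acc = 0.0
            for i in range(m):
                acc += (d[j, i] - 2 * p[i]) * (d[k, i] - 2 * p[i])
            g[j, k] = acc / denom
    return g


def brute_force_ibs(d):
    n, m = d.shape
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            shared = sum(2 - abs(int(d[j, i]) - int(d[k, i])) for i in range(m))
            out[j, k] = shared / (2 * m)
    return out


class TestGrm:
    def test_duplicate_symmetry(self):
        d = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 0, 0, 1]])
        g = vanraden_grm(GenotypeMatrixView.from_dosages(d)).matrix
        assert g[0, 1] == pytest.approx(g[0, 0])
        assert g[0, 1] == pytest.approx(g[1, 1])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(3, 4))
        view = GenotypeMatrixView.from_dosages(d)
        g = vanraden_grm(view).matrix
        np.testing.assert_allclose(g, brute_force_grm(d, view.frequencies),
                                   rtol=1e-12)

    def test_outbred_diagonal_near_one(self):
        pop = generate_founders(FounderConfig(
            breeds=(BreedSpec("A", 250, 250),), n_chromosomes=2,
            markers_per_chrom=500, linkage="independent", seed=1))
        g = vanraden_grm(GenotypeMatrixView.from_dosages(pop.dosages())).matrix
        assert np.diag(g).mean() == pytest.approx(1.0, abs=0.05)

    def test_psd(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(20, 50))
        g = vanraden_grm(GenotypeMatrixView.from_dosages(d)).matrix
        assert np.linalg.eigvalsh(g).min() >= -1e-8

    def test_monomorphic_rejected(self):
        with pytest.raises(ConfigurationError):
            vanraden_grm(GenotypeMatrixView.from_dosages(np.full((3, 4), 2)))

    def test_relatedness_orders_grm(self, small_system):
        pop = small_system.population
        r = pop.roster
        gp1 = small_system.membership["GP1"]
        view = GenotypeMatrixView.from_dosages(pop.dosages(gp1))
        g = vanraden_grm(view).matrix
        dams = r["dam"].to_numpy()[gp1]
        full_sib_vals, unrelated_vals = [], []
        for j in range(60):
            for k in range(j + 1, 60):
                (full_sib_vals if dams[j] == dams[k] else unrelated_vals
                 ).append(g[j, k])
        assert np.mean(full_sib_vals) > np.mean(unrelated_vals)


class TestIbs:
    def test_self_is_one(self):
        d = np.array([[0, 1, 2], [2, 1, 0]])
        ibs = pairwise_ibs(GenotypeMatrixView.from_dosages(d)).matrix
        assert np.allclose(np.diag(ibs), 1.0)

    def test_opposite_homozygotes_zero(self):
        d = np.array([[0, 0, 0], [2, 2, 2]])
        ibs = pairwise_ibs(GenotypeMatrixView.from_dosages(d)).matrix
        assert ibs[0, 1] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(5, 12))
        ibs = pairwise_ibs(GenotypeMatrixView.from_dosages(d)).matrix
        np.testing.assert_allclose(ibs, brute_force_ibs(d), rtol=1e-12)

    def test_cross_ibs_matches_double_loop(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, size=(4, 10))
        b = rng.integers(0, 3, size=(3, 10))
        out = cross_ibs(GenotypeMatrixView.from_dosages(a),
                        GenotypeMatrixView.from_dosages(b))
        for j in range(4):
            for k in range(3):
                shared = np.sum(2 - np.abs(a[j] - b[k]))
                assert out[j, k] == pytest.approx(shared / 20)


class TestMomentIbd:
    def test_duplicate_individual(self):
        pop = generate_founders(FounderConfig(
            breeds=(BreedSpec("A", 50, 50),), n_chromosomes=2,
            markers_per_chrom=400, linkage="independent", seed=5))
        d = pop.dosages()
        dd = np.vstack([d, d[:1]])  # duplicate of the first individual
        view = GenotypeMatrixView(dd, d.mean(axis=0) / 2, "panel")
        pi = moment_ibd(view).matrix
        assert pi[0, -1] == pytest.approx(1.0, abs=0.05)

    def test_parent_offspring(self, small_system):
        pop = small_system.population
        r = pop.roster
        gp1 = small_system.membership["GP1"]
        child = gp1[0]
        sire = r.index[r["id"] == r.loc[child, "sire"]][0]
        panel = pop.dosages(small_system.membership["GGP1"])
        pair = pop.dosages(np.array([child, sire]))
        view = GenotypeMatrixView(pair, panel.mean(axis=0) / 2, "founders")
        pi = moment_ibd(view).matrix
        assert pi[0, 1] == pytest.approx(0.5, abs=0.12)

    def test_stratification_bias_documented(self):
        # two founders of differentiated breeds, pooled frequencies:
        # apparent PI_HAT is biased above zero
        pop = generate_founders(FounderConfig(
            breeds=(BreedSpec("A", 25, 25, fst=0.3),
                    BreedSpec("B", 25, 25, fst=0.3)),
            n_chromosomes=2, markers_per_chrom=400, linkage="independent",
            seed=6))
        d = pop.dosages()
        a_mean = d[:50].mean(axis=0)
        view = GenotypeMatrixView(d[:50], d.mean(axis=0) / 2, "pooled")
        pi_within_a = moment_ibd(view).matrix
        off = pi_within_a[np.triu_indices(50, 1)]
        assert off.mean() > 0.0

    def test_monomorphic_panel_rejected(self):
        view = GenotypeMatrixView(np.ones((3, 4)), np.ones(4), "x")
        with pytest.raises(ConfigurationError):
            moment_ibd(view)


class TestLdPrune:
    def test_identical_columns_one_survives(self):
        g = uniform_map(1, 1000, 4)
        rng = np.random.default_rng(7)
        col = rng.integers(0, 3, 30)
        d = np.column_stack([col, col, rng.integers(0, 3, 30),
                             rng.integers(0, 3, 30)])
        kept = ld_prune(d, g, window=4, step=2, r2_max=0.2)
        assert 0 in kept and 1 not in kept

    def test_independent_markers_survive(self):
        g = uniform_map(1, 100_000, 50)
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, size=(500, 50))
        kept = ld_prune(d, g, window=10, step=5, r2_max=0.2)
        assert kept.size == 50

    def test_postcondition_brute_force(self):
        g = uniform_map(1, 1_000_000, 200)
        rng = np.random.default_rng(9)
        base = rng.integers(0, 3, size=(100, 40))
        # 5 correlated copies of each base column, lightly mutated
        cols = []
        for i in range(200):
            c = base[:, i // 5].copy()
            flip = rng.random(100) < 0.05
            c[flip] = rng.integers(0, 3, flip.sum())
            cols.append(c)
        d = np.column_stack(cols)
        kept = ld_prune(d, g, window=50, step=10, r2_max=0.2)
        sd = d[:, kept].std(axis=0)
        for a in range(kept.size):
            for b in range(a + 1, min(a + 50, kept.size)):
                if sd[a] == 0 or sd[b] == 0:
                    continue
                if kept[b] - kept[a] < 50:  # same window at some offset
                    r2 = pairwise_r2(d[:, kept[a]], d[:, kept[b]])
                    assert r2 <= 0.2 + 1e-9

    def test_window_too_small(self):
        g = uniform_map(1, 1000, 4)
        with pytest.raises(ConfigurationError):
            ld_prune(np.zeros((3, 4)), g, window=1)


class TestPairwiseR2:
    def test_identical_columns(self):
        x = np.array([0, 1, 2, 1, 0, 2])
        assert pairwise_r2(x, x) == pytest.approx(1.0)

    def test_sign_invariance(self):
        x = np.array([0, 1, 2, 1, 0, 2])
        assert pairwise_r2(x, 2 - x) == pytest.approx(1.0)

    def test_hand_computed(self):
        x = np.array([0.0, 1, 2, 1, 0, 2])
        y = np.array([1.0, 1, 2, 0, 0, 2])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov**2 / (x.var() * y.var())
        assert pairwise_r2(x, y) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            pairwise_r2(np.ones(5), np.arange(5))
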