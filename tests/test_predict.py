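import numpy as np
import pytest

from crossgp.founders import BreedSpec, ConfigurationError, FounderConfig, \
    generate_founders
from crossgp.kinship import GenotypeMatrixView, vanraden_grm
from crossgp.predict import (
    BslmmSpec,
    VarianceComponents,
    bslmm_fit,
    gblup_predict,
    gebv_from_effects,
    reml_fit,
)


def _unrelated_panel(n, m, seed):
    pop = generate_founders(FounderConfig(
        breeds=(BreedSpec("A", n // 2, n - n // 2),), n_chromosomes=2,
        markers_per_chrom=m // 2, linkage="independent", seed=seed))
    return pop.dosages()


class TestReml:
    def test_null_trait_ratio_near_zero(self):
        d = _unrelated_panel(400, 400, seed=1)
        G = vanraden_grm(GenotypeMatrixView.from_dosages(d)).matrix
        y = np.random.default_rng(2).normal(0, 1, 400)
        vc = reml_fit(y, G)
        assert vc.h2 < 0.05

    def test_recovers_moderate_heritability(self):
        d = _unrelated_panel(800, 600, seed=3)
        G = vanraden_grm(GenotypeMatrixView.from_dosages(d)).matrix
        rng = np.random.default_rng(4)
        ests = []
        eig = np.linalg.eigh(G)
        for rep in range(5):
            b = rng.normal(0, 1, 600)
            g = (d - d.mean(axis=0)) @ b
            g *= 1.0 / g.std()
            y = g + rng.normal(0, 1, 800)
            ests.append(reml_fit(y, eig=(np.maximum(eig[0], 0), eig[1])).h2)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.08)

    def test_too_few_observations(self):
        with pytest.raises(ConfigurationError):
            reml_fit(np.array([1.0, 2.0]), np.eye(2))

    def test_variances_nonnegative(self):
        d = _unrelated_panel(100, 100, seed=5)
        G = vanraden_grm(GenotypeMatrixView.from_dosages(d)).matrix
        y = np.random.default_rng(6).normal(size=100)
        vc = reml_fit(y, G)
        assert vc.sigma_u2 >= 0 and vc.sigma_e2 > 0


class TestGblup:
    def _mme_oracle(self, y, G, lam):
        """Direct dense mixed-model solve on the reference block."""
        n = len(y)
        Vinv = np.linalg.inv(G[:n, :n] + lam * np.eye(n))
        ones = np.ones(n)
        mu = ones @ Vinv @ y / (ones @ Vinv @ ones)
        return G[:, :n] @ Vinv @ (y - mu), mu

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, size=(6, 20))
        G = vanraden_grm(GenotypeMatrixView.from_dosages(d)).matrix
        y = rng.normal(0, 1, 4)
        vc = VarianceComponents(1.0, 0.5, 0.0, True)
        pred = gblup_predict(y, G, vc, np.arange(4), np.arange(6))
        expected, _ = self._mme_oracle(y, G, 0.5)
        np.testing.assert_allclose(pred.gebv, expected, atol=1e-8)

    def test_interpolation_limit(self):
        # candidate genotypically identical to a reference animal, tiny
        # shrinkage: its GEBV approaches that animal's centered record
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, size=(5, 40))
        d = np.vstack([d, d[0]])
        G = vanraden_grm(GenotypeMatrixView.from_dosages(d)).matrix
        G += 1e-6 * np.eye(6)
        y = rng.normal(0, 1, 5)
        vc = VarianceComponents(1.0, 1e-8, 0.0, True)
        pred = gblup_predict(y, G, vc, np.arange(5), np.array([5]))
        _, mu = self._mme_oracle(y, G, 1e-8)
        assert pred.gebv[0] == pytest.approx(y[0] - mu, abs=1e-3)

    def test_shrinkage_limit(self):
        rng = np.random.default_rng(9)
        d = rng.integers(0, 3, size=(6, 30))
        G = vanraden_grm(GenotypeMatrixView.from_dosages(d)).matrix
        y = rng.normal(0, 1, 4)
        vc = VarianceComponents(1e-12, 1.0, 0.0, True)
        pred = gblup_predict(y, G, vc, np.arange(4), np.arange(6))
        assert np.max(np.abs(pred.gebv)) < 1e-6

    def test_location_invariance(self):
        rng = np.random.default_rng(10)
        d = rng.integers(0, 3, size=(8, 30))
        G = vanraden_grm(GenotypeMatrixView.from_dosages(d)).matrix
        y = rng.normal(0, 1, 6)
        vc = VarianceComponents(1.0, 1.0, 0.0, True)
        a = gblup_predict(y, G, vc, np.arange(6), np.arange(8))
        b = gblup_predict(y + 100.0, G, vc, np.arange(6), np.arange(8))
        np.testing.assert_allclose(a.gebv, b.gebv, atol=1e-8)


class TestBslmm:
    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        X = rng.integers(0, 3, size=(200, 300)).astype(float)
        X -= X.mean(axis=0)
        y = rng.normal(0, 1, 200)
        fit = bslmm_fit(y, X, BslmmSpec(chain_length=2000, seed=0))
        assert fit.genetic_proportion < 0.1
        assert np.max(np.abs(fit.beta_mean)) < 0.1

    def test_signal_recovery(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.integers(0, 3, size=(300, 500)).astype(float)
            X -= X.mean(axis=0)
            g = X[:, 42] * 1.0
            y = g + rng.normal(0, g.std(), 300)  # QTL explains half
            fit = bslmm_fit(y, X, BslmmSpec(chain_length=2000, seed=seed))
            if np.argmax(np.abs(fit.beta_mean)) == 42:
                hits += 1
        assert hits == 5

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(12)
        X = rng.integers(0, 3, size=(100, 80)).astype(float)
        X -= X.mean(axis=0)
        y = rng.normal(0, 1, 100)
        a = bslmm_fit(y, X, BslmmSpec(chain_length=500, seed=7))
        b = bslmm_fit(y, X, BslmmSpec(chain_length=500, seed=7))
        np.testing.assert_array_equal(a.beta_mean, b.beta_mean)

    def test_invalid_chain(self):
        with pytest.raises(ConfigurationError):
            BslmmSpec(chain_length=10, burn_in_fraction=1.0)


class TestGebvFromEffects:
    def test_zero_effects(self):
        out = gebv_from_effects(np.zeros(4), np.ones((3, 4)))
        np.testing.assert_array_equal(out.gebv, np.zeros(3))

    def test_single_effect_selects_column(self):
        d = np.arange(12).reshape(3, 4)
        beta = np.array([0.0, 1.0, 0.0, 0.0])
        np.testing.assert_array_equal(gebv_from_effects(beta, d).gebv, d[:, 1])

    def test_hand_product(self):
        d = np.array([[0, 1, 2, 1], [2, 2, 0, 0], [1, 0, 1, 2]])
        beta = np.array([0.5, -1.0, 2.0, 0.25])
        np.testing.assert_allclose(gebv_from_effects(beta, d).gebv, d @ beta)

    def test_panel_mismatch(self):
        with pytest.raises(ConfigurationError):
            gebv_from_effects(np.zeros(3), np.ones((2, 4)))
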