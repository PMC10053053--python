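import numpy as np
import pytest

from crossgp.breeding import BreedingSystemConfig, run_breeding_system
from crossgp.founders import BreedSpec, FounderConfig, generate_founders
from crossgp.traits import compute_tbv, rescale_to_vg, sample_qtl, simulate_phenotype


@pytest.fixture(scope="session")
def tiny_founders():
    """Two tiny breeds, independent-loci mode, for low-level checks."""
    cfg = FounderConfig(
        breeds=(BreedSpec("Duroc", 2, 2), BreedSpec("Yorkshire", 2, 2)),
        n_chromosomes=2, markers_per_chrom=20, linkage="independent", seed=11,
    )
    return generate_founders(cfg)


@pytest.fixture(scope="session")
def small_system():
    """A miniature but complete crossbreeding run: three breeds, two
    chromosomes, every tier of the pyramid populated."""
    founders = generate_founders(FounderConfig(
        breeds=(BreedSpec("Duroc", 2, 4), BreedSpec("Landrace", 2, 4),
                BreedSpec("Yorkshire", 2, 4)),
        n_chromosomes=2, markers_per_chrom=60, seed=5,
    ))
    config = BreedingSystemConfig(
        litter_size=10,
        ly_boars=2, ly_sows=2, dly_boars=2, dly_sows=10,
        recruits={"Duroc": (2, 2), "Landrace": (2, 2), "Yorkshire": (2, 2)},
        seed=6,
    )
    return run_breeding_system(founders, config)


@pytest.fixture(scope="session")
def small_trait(small_system):
    """Trait over the small system: 20 QTL, Vg = 1, h2 = 0.3 phenotypes."""
    pop = small_system.population
    rng = np.random.default_rng(17)
    arch = sample_qtl(pop.subset(small_system.membership["GGP1"]), 20, rng=rng)
    dq = pop.dosages(markers=arch.qtl_indices)
    arch = rescale_to_vg(arch, dq)
    tbv = compute_tbv(dq, arch)
    trait = simulate_phenotype(tbv, 0.3, rng=np.random.default_rng(18))
    return arch, trait
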